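"""Automatic iterative (isodata) thresholding and the flexible threshold.

The automatic threshold ``t`` is the fixed point of the intermeans
iteration ``t <- (mean(pixels <= t) + mean(pixels > t)) / 2`` started from
the global mean. A single flexibility parameter ``d`` in [0, 1] then moves
the effective threshold between ``t`` (d = 0) and ``m1`` (d = 1), where
``m1`` is the mean of the pixels strictly above ``t``:

    T = t + d * (m1 - t)

"Above threshold" always means strictly greater than.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageStack

__all__ = ["ThresholdResult", "auto_threshold", "flexible_threshold"]

_MAX_ITER = 500


@dataclass(frozen=True)
class ThresholdResult:
    """Automatic threshold ``t``, above-threshold mean ``m1``, flexibility
    ``d`` and the effective threshold ``T = t + d*(m1 - t)``."""

    t: float
    m1: float
    d: float
    T: float


def _as_values(image) -> np.ndarray:
    if isinstance(image, ImageStack):
        return np.asarray(image.voxels, dtype=float).ravel()
    return np.asarray(image, dtype=float).ravel()


def auto_threshold(image) -> ThresholdResult:
    """Isodata/intermeans automatic threshold of an image or masked region.

    Parameters
    ----------
    image
        An :class:`~knobkit.core.ImageStack`, or any array of intensities
        (e.g. the voxels of one nucleus).

    Returns
    -------
    ThresholdResult
        With ``d = 0`` and ``T = t``.

    Raises
    ------
    ValueError
        If the image is constant (degenerate histogram).
    """
    x = _as_values(image)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("degenerate histogram: image is constant")
    tol = 1e-6 * (hi - lo)
    t = float(x.mean())
    for _ in range(_MAX_ITER):
        above = x > t
        # both classes are non-empty for t in [min, max) reached from the mean
        m0 = float(x[~above].mean())
        m1 = float(x[above].mean())
        t_new = 0.5 * (m0 + m1)
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    else:
        raise RuntimeError("intermeans iteration did not converge in 500 rounds")
    m1 = float(x[x > t].mean())
    return ThresholdResult(t=t, m1=m1, d=0.0, T=t)


def flexible_threshold(image, d: float) -> ThresholdResult:
    """Effective threshold ``T = t + d*(m1 - t)`` for ``d`` in [0, 1].

    ``d = 0`` reproduces the automatic threshold; ``d = 1`` raises it to the
    mean of the above-threshold pixels. Because ``m1 >= t``, ``T`` is
    non-decreasing in ``d``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"flexibility parameter d must be in [0, 1], got {d}")
    base = auto_threshold(image)
    return ThresholdResult(t=base.t, m1=base.m1, d=float(d), T=base.t + d * (base.m1 - base.t))
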