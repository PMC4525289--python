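"""One-colour microarray expression chain with paralog cross-hybridization correction.

The chain mirrors a custom Agilent-style analysis: per-probe intensity is
the median of its spots' ``gProcessedSignal``; a probe is detected when
the mean of its spots' ``gIsWellAboveBG`` flags exceeds 0.55; intensities
are normalized by the 75-percentile method (the value at 75% set to
2,500); probes for duplicated genes are divided by gene copy number;
probes that cross-hybridize with a paralogue are corrected with dedicated
mismatch correction probes; biological replicates are combined by
geometric mean; strain values are divided by the matched control strain;
and gene sets are formed by strict fold-change cuts across strains, with
a chi-square test of category composition against a random expectation.

Cross-hybridization model
-------------------------
Probes for two paralogous genes A and B are designed at the same coding
position; m mismatches between the paralogues separate them. Assuming
every mismatch attenuates hybridization by the same factor alpha in
[0, 1), the perfect-match probes see

    I_PA = s_A + alpha^m * s_B          I_PB = s_B + alpha^m * s_A

and a correction probe for A (the same sequence with one extra mismatch,
averaged over the two alternate bases) sees

    I_CA = alpha * s_A + alpha^(m+1) * s_B = alpha * I_PA

so alpha is estimated directly as I_CA / I_PA and the true abundances
(s_A, s_B) follow from a 2x2 linear solve. Negative solutions are floored
at 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_probes",
    "percentile_normalize",
    "ParalogCorrection",
    "correct_pair",
    "paralog_correct",
    "copy_number_adjust",
    "differential_ratios",
    "fold_change_sets",
    "category_analysis",
    "probe_to_gene_values",
]

DETECTION_CUTOFF = 0.55


def summarize_probes(spots: pd.DataFrame) -> pd.DataFrame:
    """Median-of-spots probe intensities and detection flags.

    ``spots`` needs columns ``probe_id``, ``gProcessedSignal`` and
    ``gIsWellAboveBG`` (one row per spot; probes are spotted multiply).
    A probe is detected when the mean of its flags is strictly above 0.55.
    """
    required = {"probe_id", "gProcessedSignal", "gIsWellAboveBG"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table is missing columns: {sorted(missing)}")
    if spots["probe_id"].isna().any():
        raise ValueError("spot with no probe id")
    grouped = spots.groupby("probe_id")
    out = pd.DataFrame(
        {
            "intensity": grouped["gProcessedSignal"].median(),
            "detected": grouped["gIsWellAboveBG"].mean() > DETECTION_CUTOFF,
        }
    )
    if (grouped.size() < 1).any():
        raise ValueError("probe with zero spots")
    return out


def percentile_normalize(values, q: float = 75.0, target: float = 2500.0):
    """Scale intensities so the q-th percentile equals ``target``.

    The percentile uses linear interpolation between order statistics.
    Because the operation is a single positive scalar factor, ratios
    between probes are unchanged and the operation is idempotent.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty intensity vector")
    p = float(np.percentile(arr, q))
    if p <= 0:
        raise ValueError(f"{q}th percentile is not positive; cannot normalize")
    scaled = arr * (target / p)
    if isinstance(values, pd.Series):
        return pd.Series(scaled, index=values.index)
    return scaled


@dataclass
class ParalogCorrection:
    s_a: float
    s_b: float
    alpha: float
    floored: bool


def correct_pair(
    i_pa: float,
    i_pb: float,
    m_ab: int,
    alpha: float | None = None,
    i_corr_a: float | None = None,
    i_corr_b: float | None = None,
) -> ParalogCorrection:
    """Solve the cross-hybridization system for one paralog pair.

    ``alpha`` may be supplied (global mode) or fitted from the correction
    probes (``i_corr_a``/``i_corr_b``, each already averaged over its two
    alternate-base variants). ``m_ab`` is the mismatch count between the
    paralogues' probe regions; ``m_ab = 0`` means the probes are identical
    and the system is singular.
    """
    if m_ab < 1:
        raise ValueError("paralog probes with zero mismatches: system is singular")
    if alpha is None:
        estimates = []
        if i_corr_a is not None and i_pa > 0:
            estimates.append(i_corr_a / i_pa)
        if i_corr_b is not None and i_pb > 0:
            estimates.append(i_corr_b / i_pb)
        if not estimates:
            raise ValueError("alpha not supplied and no usable correction probe")
        alpha = float(np.mean(estimates))
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"mismatch attenuation alpha must be in [0, 1), got {alpha}")
    w = alpha**m_ab
    mat = np.array([[1.0, w], [w, 1.0]])
    s = np.linalg.solve(mat, np.array([i_pa, i_pb], dtype=float))
    floored = bool((s < 0).any())
    s = np.clip(s, 0.0, None)
    return ParalogCorrection(s_a=float(s[0]), s_b=float(s[1]), alpha=alpha, floored=floored)


def copy_number_adjust(values: pd.Series, copy_numbers: pd.Series) -> pd.Series:
    """Divide each gene's intensity by its (integer, >= 1) copy number."""
    cn = copy_numbers.reindex(values.index)
    if cn.isna().any():
        raise ValueError("missing copy number for some genes")
    if not np.allclose(cn, np.round(cn)):
        raise ValueError("copy numbers must be integers")
    if (cn < 1).any():
        raise ValueError("copy numbers must be >= 1")
    return values / cn.astype(float)


def paralog_correct(
    probe_intensities: pd.Series,
    annotation: pd.DataFrame,
    alpha: float | str = "fit",
) -> tuple[pd.Series, pd.DataFrame]:
    """Correct all annotated paralog pairs in a probe-intensity vector.

    ``annotation`` has one row per probe: ``probe_id`` (index or column),
    ``gene``, ``probe_type`` ('pm' or 'correction'), ``target_gene``,
    ``pair_id`` (NaN/empty for unpaired probes) and ``pair_mismatches``.
    ``alpha`` is either a global float or ``'fit'`` (per pair, from the
    correction probes). Returns per-gene values (perfect-match intensity
    for unpaired genes, corrected abundance for paired ones) and a table
    of the per-pair fits.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    pm = ann[ann["probe_type"] == "pm"]
    gene_values = pd.Series(
        {row["gene"]: probe_intensities[pid] for pid, row in pm.iterrows()},
        dtype=float,
    )
    fits = []
    pair_ids = [p for p in ann["pair_id"].dropna().unique() if p != ""]
    for pair in pair_ids:
        sub = ann[ann["pair_id"] == pair]
        pm_sub = sub[sub["probe_type"] == "pm"]
        if len(pm_sub) != 2:
            raise ValueError(f"pair {pair!r} needs exactly two perfect-match probes")
        (pid_a, row_a), (pid_b, row_b) = list(pm_sub.iterrows())
        m_ab = int(row_a["pair_mismatches"])
        corr = sub[sub["probe_type"] == "correction"]

        def _corr_value(target_gene: str) -> float | None:
            pids = corr.index[corr["target_gene"] == target_gene]
            if len(pids) == 0:
                return None
            # average over the two alternate-base variants
            return float(probe_intensities[pids].mean())

        res = correct_pair(
            i_pa=float(probe_intensities[pid_a]),
            i_pb=float(probe_intensities[pid_b]),
            m_ab=m_ab,
            alpha=None if alpha == "fit" else float(alpha),
            i_corr_a=_corr_value(row_a["gene"]),
            i_corr_b=_corr_value(row_b["gene"]),
        )
        gene_values[row_a["gene"]] = res.s_a
        gene_values[row_b["gene"]] = res.s_b
        fits.append(
            {"pair_id": pair, "gene_a": row_a["gene"], "gene_b": row_b["gene"],
             "alpha": res.alpha, "floored": res.floored}
        )
    return gene_values, pd.DataFrame(fits)


def probe_to_gene_values(
    spots: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float | str = "fit",
    q: float = 75.0,
    target: float = 2500.0,
) -> pd.DataFrame:
    """Full per-replicate chain: summarize, normalize, copy-adjust, correct.

    Returns a per-gene frame with columns ``value`` and ``detected``.
    """
    probes = summarize_probes(spots)
    probes["intensity"] = percentile_normalize(probes["intensity"], q=q, target=target)
    gene_values, _ = paralog_correct(probes["intensity"], annotation, alpha=alpha)
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    pm = ann[ann["probe_type"] == "pm"]
    copy_numbers = pd.Series(
        {row["gene"]: int(row.get("copy_number", 1)) for _, row in pm.iterrows()}
    )
    gene_values = copy_number_adjust(gene_values, copy_numbers)
    detected = pd.Series(
        {row["gene"]: bool(probes["detected"][pid]) for pid, row in pm.iterrows()}
    )
    return pd.DataFrame({"value": gene_values, "detected": detected.reindex(gene_values.index)})


def differential_ratios(
    strain_replicates: pd.DataFrame, control_replicates: pd.DataFrame
) -> pd.DataFrame:
    """Combine replicates by geometric mean and take the strain/control ratio.

    Inputs are gene x replicate frames over matched gene sets. Where the
    control's combined value is 0 the ratio is undefined (NaN, flagged).
    """
    if not strain_replicates.index.equals(control_replicates.index):
        control_replicates = control_replicates.reindex(strain_replicates.index)
        if control_replicates.isna().any().any():
            raise ValueError("strain and control gene sets do not match")
    combined_s = _geometric_mean(strain_replicates)
    combined_c = _geometric_mean(control_replicates)
    undefined = combined_c <= 0
    ratio = combined_s / combined_c.where(~undefined)
    return pd.DataFrame(
        {
            "combined_strain": combined_s,
            "combined_control": combined_c,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "undefined": undefined,
        }
    )


def _geometric_mean(df: pd.DataFrame) -> pd.Series:
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensities")
    with np.errstate(divide="ignore"):
        return pd.Series(np.exp(np.log(vals).mean(axis=1)), index=df.index).fillna(0.0)


def fold_change_sets(
    ratios: pd.DataFrame, strains: list[str] | None = None, fold: float = 2.0
) -> dict[str, set]:
    """Genes beyond a strict fold cut in every listed strain.

    ``ratios`` is a gene x strain frame of strain/control ratios. ``up`` is
    the set with ratio strictly greater than ``fold`` in all strains,
    ``down`` strictly below ``1/fold`` in all; a gene at exactly the fold
    is excluded.
    """
    strains = strains or list(ratios.columns)
    sub = ratios[strains]
    up = set(sub.index[(sub > fold).all(axis=1)])
    down = set(sub.index[(sub < 1.0 / fold).all(axis=1)])
    return {"up": up, "down": down}


def category_analysis(
    labels, expected_proportions: dict[str, float]
) -> dict:
    """Category composition of a gene set vs a random expectation.

    ``labels`` assigns each gene one of the categories in
    ``expected_proportions`` (which must be exhaustive, disjoint and sum
    to 1). Reports per-category counts, nearest-integer percentages, and
    the chi-square statistic sum((obs - exp)^2 / exp) with
    df = categories - 1 against expected counts total * proportion.
    """
    labels = pd.Series(list(labels))
    cats = list(expected_proportions)
    if not math.isclose(sum(expected_proportions.values()), 1.0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    unknown = set(labels) - set(cats)
    if unknown:
        raise ValueError(f"labels outside the expected categories: {sorted(unknown)}")
    total = len(labels)
    counts = {c: int((labels == c).sum()) for c in cats}
    chi2 = 0.0
    for c in cats:
        exp = total * expected_proportions[c]
        if exp == 0:
            raise ValueError(f"expected count is zero for category {c!r}")
        chi2 += (counts[c] - exp) ** 2 / exp
    df = len(cats) - 1
    return {
        "counts": counts,
        "percent": {c: int(round(100.0 * counts[c] / total)) for c in cats},
        "chi2": float(chi2),
        "df": df,
        "pvalue": float(stats.chi2.sf(chi2, df)),
        "total": total,
    }
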