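"""Simulators for SIM-like nucleus stacks, bead fields and microarray tables.

Every generator is a pure function of its parameters and a seed, and
returns the ground truth alongside the data, so each analysis stage can
be validated without any real acquisition.

The nucleus scene emulates a fission-yeast interphase nucleus (~2 um
diameter) imaged at SIM-like resolution: a DAPI channel built from a
Gaussian-smoothed lognormal chromatin field, optional compact "knob"
bodies (density multiplier above the nuclear median) and dim "silent
focus" shells at the nuclear rim; marker channels mix a DAPI-derived
template with an independent field under a colocalization weight w in
[0, 1]. All channels are blurred with a separable anisotropic Gaussian
point-spread function (FWHM 120 nm lateral / 300 nm axial), marker
channels are mis-registered by their true per-channel transform, and
Poisson shot noise plus Gaussian read noise is applied (defaults give
SNR ~ 10 at the median nuclear intensity). Structured-illumination
reconstruction artifacts and spectral bleed-through are not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageStack, sphere_volume_nm3
from .registration import TransformParams, apply_transform

__all__ = [
    "SceneParams",
    "SceneTruth",
    "generate_nucleus_scene",
    "generate_bead_field",
    "ArrayParams",
    "ArrayTruth",
    "generate_probe_table",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# nucleus scenes


@dataclass
class SceneParams:
    shape: tuple[int, int, int] = (28, 96, 96)
    voxel_size: tuple[float, float, float] = (125.0, 40.0, 40.0)
    n_nuclei: int = 1
    nucleus_radius_nm: float = 1000.0
    knob_count: int = 1  # per nucleus
    knob_radius_nm: float = 300.0
    knob_density: float = 2.5
    silent_focus_count: int = 1
    silent_focus_radius_nm: float = 150.0
    silent_focus_density: float = 0.6
    marker_weights: dict[str, float] = field(default_factory=lambda: {"marker": 0.8})
    marker_transforms: dict[str, TransformParams] = field(default_factory=dict)
    texture_sigma_log: float = 0.15
    texture_smooth_nm: float = 120.0
    psf_fwhm_lateral_nm: float = 120.0
    psf_fwhm_axial_nm: float = 300.0
    poisson_photons: float = 100.0  # photons per unit intensity; 0 disables
    read_noise_sd: float = 0.02  # intensity units; 0 disables
    locus_channel: bool = False
    locus_proximal_fraction: float = 0.8
    locus_radius_nm: float = 100.0
    locus_intensity: float = 3.0

    def validate(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if self.nucleus_radius_nm <= 0 or self.knob_radius_nm <= 0:
            raise ValueError("sizes must be positive")
        for name, w in self.marker_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"colocalization weight for {name!r} must be in [0, 1]")
        if not 0.0 <= self.locus_proximal_fraction <= 1.0:
            raise ValueError("locus_proximal_fraction must be in [0, 1]")
        if self.knob_count < 0 or self.silent_focus_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SceneTruth:
    """Everything the generator planted, in physical nm coordinates."""

    seed: int
    nucleus_centers_nm: list[tuple[float, float, float]]
    nucleus_radius_nm: float
    knob_centers_nm: list[list[tuple[float, float, float]]]  # per nucleus
    knob_radius_nm: float
    knob_volume_nm3: float
    silent_focus_centers_nm: list[list[tuple[float, float, float]]]
    marker_weights: dict[str, float]
    marker_transforms: dict[str, TransformParams]
    locus_proximal: list[bool] | None
    locus_centers_nm: list[tuple[float, float, float]] | None
    noise: dict

    def knob_count(self) -> int:
        return sum(len(k) for k in self.knob_centers_nm)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_transforms"] = {
            k: dataclasses.asdict(v) for k, v in self.marker_transforms.items()
        }
        return d


def _coord_grids(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _sphere_mask(grids, center, radius):
    zz, yy, xx = grids
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def _smooth_lognormal_field(rng, shape, voxel_size, sigma_log, smooth_nm):
    """Unit-median lognormal field with the given log-sd after smoothing."""
    raw = rng.standard_normal(shape)
    sig_vox = tuple(smooth_nm / s for s in voxel_size)
    sm = ndimage.gaussian_filter(raw, sig_vox)
    sd = sm.std()
    if sd == 0:
        sd = 1.0
    return np.exp(sigma_log * sm / sd)


def _psf_sigmas_vox(params: SceneParams):
    dz, dy, dx = params.voxel_size
    return (
        params.psf_fwhm_axial_nm * FWHM_TO_SIGMA / dz,
        params.psf_fwhm_lateral_nm * FWHM_TO_SIGMA / dy,
        params.psf_fwhm_lateral_nm * FWHM_TO_SIGMA / dx,
    )


def _place_nuclei(rng, params: SceneParams):
    """Random non-touching nucleus centres, kept away from the frame edge."""
    extent = np.asarray(params.shape) * np.asarray(params.voxel_size)
    r = params.nucleus_radius_nm
    margin = r + 100.0
    if np.any(extent < 2 * margin):
        raise ValueError("frame too small for the requested nucleus radius")
    min_sep = 2 * r + 300.0
    # dart-throwing with restarts: sequential rejection alone can wedge
    # itself into configurations with no room for the last nucleus
    for _restart in range(200):
        centers: list[np.ndarray] = []
        for _dart in range(400):
            c = np.array([rng.uniform(margin, e - margin) for e in extent])
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                centers.append(c)
                if len(centers) == params.n_nuclei:
                    return centers
    raise ValueError("could not place the requested number of non-touching nuclei")


def _random_point_in_ball(rng, max_radius):
    while True:
        p = rng.uniform(-max_radius, max_radius, size=3)
        if np.linalg.norm(p) <= max_radius:
            return p


def _apply_noise(rng, img, params: SceneParams):
    out = img.astype(float)
    if params.poisson_photons > 0:
        out = rng.poisson(np.clip(out, 0, None) * params.poisson_photons) / params.poisson_photons
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_nucleus_scene(
    params: SceneParams | None = None, seed: int = 0
) -> tuple[dict[str, ImageStack], SceneTruth]:
    """Generate a multichannel nucleus scene and its ground truth.

    Returns channel stacks keyed by name (always ``"DAPI"``; one stack per
    marker weight; optionally ``"locus"``) and the :class:`SceneTruth`.
    Identical parameters and seed give bit-identical output.
    """
    params = params or SceneParams()
    params.validate()
    rng = np.random.default_rng(seed)
    shape, vs = params.shape, params.voxel_size
    grids = _coord_grids(shape, vs)

    centers = _place_nuclei(rng, params)
    nucleus_mask = np.zeros(shape, dtype=bool)
    for c in centers:
        nucleus_mask |= _sphere_mask(grids, c, params.nucleus_radius_nm)

    chromatin = _smooth_lognormal_field(
        rng, shape, vs, params.texture_sigma_log, params.texture_smooth_nm
    )
    dapi_pre = np.where(nucleus_mask, chromatin, 0.0)
    median_density = float(np.median(chromatin[nucleus_mask])) if nucleus_mask.any() else 1.0

    knob_centers: list[list[tuple[float, float, float]]] = []
    focus_centers: list[list[tuple[float, float, float]]] = []
    for c in centers:
        # knobs: compact condensed bodies well inside the nucleus
        placed: list[np.ndarray] = []
        inner = params.nucleus_radius_nm - params.knob_radius_nm - 100.0
        for _ in range(params.knob_count):
            for _try in range(5000):
                p = c + _random_point_in_ball(rng, inner)
                if all(
                    np.linalg.norm(p - q) >= 3 * params.knob_radius_nm for q in placed
                ):
                    placed.append(p)
                    break
            else:
                raise ValueError("could not place non-overlapping knobs")
        knob_centers.append([tuple(p) for p in placed])
        for p in placed:
            m = _sphere_mask(grids, p, params.knob_radius_nm)
            dapi_pre[m] = params.knob_density * chromatin[m]
        # silent foci: dim shells at the nuclear rim
        foci = []
        rim = params.nucleus_radius_nm - params.silent_focus_radius_nm
        for _ in range(params.silent_focus_count):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            p = c + rim * direction
            foci.append(tuple(p))
            m = _sphere_mask(grids, p, params.silent_focus_radius_nm) & nucleus_mask
            dapi_pre[m] = params.silent_focus_density * median_density
        focus_centers.append(foci)

    psf = _psf_sigmas_vox(params)

    def finish(pre: np.ndarray, transform: TransformParams | None, channel: str) -> ImageStack:
        img = ndimage.gaussian_filter(pre, psf)
        stack = ImageStack(voxels=img, voxel_size=vs, channel=channel)
        if transform is not None and transform != TransformParams.identity():
            stack = apply_transform(stack, transform)
        noisy = _apply_noise(rng, stack.voxels, params)
        return ImageStack(voxels=noisy, voxel_size=vs, channel=channel)

    stacks: dict[str, ImageStack] = {"DAPI": finish(dapi_pre, None, "DAPI")}

    for name, w in params.marker_weights.items():
        independent = np.where(
            nucleus_mask,
            _smooth_lognormal_field(
                rng, shape, vs, params.texture_sigma_log, params.texture_smooth_nm
            ),
            0.0,
        )
        pre = w * dapi_pre + (1.0 - w) * independent
        stacks[name] = finish(pre, params.marker_transforms.get(name), name)

    locus_proximal = None
    locus_centers = None
    if params.locus_channel:
        locus_pre = np.zeros(shape)
        locus_proximal, locus_centers = [], []
        for c, knobs_here in zip(centers, knob_centers):
            proximal = bool(rng.random() < params.locus_proximal_fraction)
            if proximal and knobs_here:
                k = np.asarray(knobs_here[int(rng.integers(len(knobs_here)))])
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                # locus surface within ~100 nm of the knob surface
                p = k + (params.knob_radius_nm + params.locus_radius_nm + 50.0) * direction
            else:
                for _try in range(5000):
                    p = c + _random_point_in_ball(
                        rng, params.nucleus_radius_nm - params.locus_radius_nm
                    )
                    if all(
                        np.linalg.norm(p - np.asarray(k))
                        >= params.knob_radius_nm + params.locus_radius_nm + 600.0
                        for k in knobs_here
                    ):
                        break
                else:
                    raise ValueError("could not place a distal locus")
            locus_proximal.append(proximal)
            locus_centers.append(tuple(p))
            locus_pre[_sphere_mask(grids, p, params.locus_radius_nm)] = params.locus_intensity
        stacks["locus"] = finish(locus_pre, None, "locus")

    truth = SceneTruth(
        seed=seed,
        nucleus_centers_nm=[tuple(c) for c in centers],
        nucleus_radius_nm=params.nucleus_radius_nm,
        knob_centers_nm=knob_centers,
        knob_radius_nm=params.knob_radius_nm,
        knob_volume_nm3=sphere_volume_nm3(params.knob_radius_nm),
        silent_focus_centers_nm=focus_centers,
        marker_weights=dict(params.marker_weights),
        marker_transforms={
            k: params.marker_transforms.get(k, TransformParams.identity())
            for k in params.marker_weights
        },
        locus_proximal=locus_proximal,
        locus_centers_nm=locus_centers,
        noise={
            "poisson_photons": params.poisson_photons,
            "read_noise_sd": params.read_noise_sd,
        },
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# bead fields


def generate_bead_field(
    true_transform: TransformParams,
    n_beads: int = 100,
    seed: int = 0,
    shape: tuple[int, int, int] = (24, 64, 64),
    voxel_size: tuple[float, float, float] = (125.0, 40.0, 40.0),
    margin_nm: float = 500.0,
    snr: float = np.inf,
    psf_fwhm_lateral_nm: float = 120.0,
    psf_fwhm_axial_nm: float = 300.0,
) -> tuple[ImageStack, ImageStack, np.ndarray]:
    """Reference/moving multicolour-bead pair for registration calibration.

    The moving stack is the reference resampled under ``true_transform``
    with independent Gaussian noise (sd = bead peak / snr) added to both
    stacks. Returns (reference, moving, bead positions in nm). Raises if
    the transform pushes every bead out of frame.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads")
    rng = np.random.default_rng(seed)
    shape_arr = np.asarray(shape)
    vs = np.asarray(voxel_size, dtype=float)
    extent = shape_arr * vs
    if np.any(extent <= 2 * margin_nm):
        raise ValueError("frame too small for the bead margin")
    positions = rng.uniform(margin_nm, extent - margin_nm, size=(n_beads, 3))

    sig = (
        psf_fwhm_axial_nm * FWHM_TO_SIGMA / vs[0],
        psf_fwhm_lateral_nm * FWHM_TO_SIGMA / vs[1],
        psf_fwhm_lateral_nm * FWHM_TO_SIGMA / vs[2],
    )

    def render(points_nm: np.ndarray) -> np.ndarray:
        # trilinear sub-voxel splat followed by the Gaussian PSF; beads
        # falling outside the frame are simply absent
        field = np.zeros(shape)
        for p in points_nm:
            f = p / vs - 0.5
            base = np.floor(f).astype(int)
            frac = f - base
            for dz in (0, 1):
                for dy in (0, 1):
                    for dx in (0, 1):
                        i = base + (dz, dy, dx)
                        if np.any(i < 0) or np.any(i >= shape_arr):
                            continue
                        w = (
                            (frac[0] if dz else 1 - frac[0])
                            * (frac[1] if dy else 1 - frac[1])
                            * (frac[2] if dx else 1 - frac[2])
                        )
                        field[tuple(i)] += w
        return ndimage.gaussian_filter(field, sig)

    ref_clean = render(positions)
    peak = float(ref_clean.max())
    if peak > 0:
        ref_clean = ref_clean / peak

    # a bead at physical position b appears in the moving frame at T^-1(b)
    center = 0.5 * extent
    inv = np.linalg.inv(true_transform.matrix())
    landed = (inv @ (positions - center - true_transform.translation()).T).T + center
    in_frame = np.all((landed > 0) & (landed < extent), axis=1)
    if not in_frame.any():
        raise ValueError("transform pushes all beads out of frame")
    moving_clean = render(landed)
    if peak > 0:
        moving_clean = moving_clean / peak

    def noisy(arr):
        if not np.isfinite(snr) or snr <= 0:
            return arr
        return np.clip(arr + rng.normal(0.0, 1.0 / snr, size=arr.shape), 0.0, None)

    reference = ImageStack(voxels=noisy(ref_clean), voxel_size=voxel_size, channel="beads_ref")
    moving = ImageStack(voxels=noisy(moving_clean), voxel_size=voxel_size, channel="beads_mov")
    return reference, moving, positions


# ---------------------------------------------------------------------------
# microarray tables


@dataclass
class ArrayParams:
    n_genes: int = 300
    n_pairs: int = 5
    pair_mismatches: int = 3
    alpha: float = 0.1
    spots_per_probe: int = 3
    replicates: int = 2
    strains: tuple[str, ...] = ("strainA", "strainB", "strainC")
    n_up: int = 20
    up_fold: float = 4.0
    noise_cv: float = 0.05
    duplicated_fraction: float = 0.05
    low_expressed_fraction: float = 0.1
    abundance_log_mean: float = np.log(500.0)
    abundance_log_sd: float = 1.0
    detection_floor: float = 100.0

    def validate(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("mismatch attenuation alpha must be in [0, 1)")
        if self.n_pairs < 1:
            raise ValueError("need at least one paralog pair")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.pair_mismatches < 1:
            raise ValueError("paired probes need at least one mismatch")


@dataclass
class ArrayTruth:
    seed: int
    alpha: float
    abundance: dict[str, pd.Series]  # per strain (and "control"), per gene
    up_genes: set
    copy_numbers: pd.Series
    pair_genes: list[tuple[str, str]]
    expected_ratio: pd.DataFrame  # gene x strain, exact for zero noise


def _gene_names(n):
    return [f"gene{i:04d}" for i in range(n)]


def _build_annotation(params: ArrayParams, genes, copy_numbers, pairs):
    rows = []
    paired = {g for pair in pairs for g in pair}
    for g in genes:
        rows.append(
            {
                "probe_id": f"P_{g}",
                "gene": g,
                "probe_type": "pm",
                "target_gene": g,
                "copy_number": int(copy_numbers[g]),
                "pair_id": None,
                "pair_mismatches": np.nan,
            }
        )
    for k, (a, b) in enumerate(pairs):
        pair_id = f"pair{k:02d}"
        for g in (a, b):
            for row in rows:
                if row["gene"] == g:
                    row["pair_id"] = pair_id
                    row["pair_mismatches"] = params.pair_mismatches
            for variant in (1, 2):  # two alternate-base correction probes
                rows.append(
                    {
                        "probe_id": f"C_{g}_v{variant}",
                        "gene": g,
                        "probe_type": "correction",
                        "target_gene": g,
                        "copy_number": 1,
                        "pair_id": pair_id,
                        "pair_mismatches": params.pair_mismatches,
                    }
                )
    return pd.DataFrame(rows)


def _model_probe_intensities(annotation, abundance, alpha, m):
    """Noise-free probe intensities under the cross-hybridization model."""
    ann = annotation.set_index("probe_id")
    partner = {}
    for pair_id, sub in ann[ann["probe_type"] == "pm"].groupby("pair_id"):
        if pair_id is None:
            continue
        g = list(sub["gene"])
        partner[g[0]], partner[g[1]] = g[1], g[0]
    vals = {}
    for pid, row in ann.iterrows():
        g = row["gene"]
        s = abundance[g]
        other = partner.get(g)
        if row["probe_type"] == "pm":
            v = s + (alpha**m * abundance[other] if other else 0.0)
            v *= row["copy_number"]
        else:  # correction probe: one extra mismatch on everything it sees
            v = alpha * s + (alpha ** (m + 1) * abundance[other] if other else 0.0)
        vals[pid] = v
    return pd.Series(vals)


def generate_probe_table(
    params: ArrayParams | None = None, seed: int = 0
) -> tuple[dict[str, list[pd.DataFrame]], pd.DataFrame, ArrayTruth]:
    """Generate spot-level one-colour array tables with planted truth.

    Returns ``(tables, annotation, truth)`` where ``tables`` maps each
    strain name (plus ``"control"``) to its list of replicate spot tables
    (columns ``probe_id``, ``gProcessedSignal``, ``gIsWellAboveBG``).

    Differentially expressed genes are planted only among genes whose
    ``up_fold``-scaled intensity stays strictly below the 75th-percentile
    anchor of the control probe vector, so the per-replicate percentile
    normalization factor is identical across strains and the noise-free
    chain recovers the planted folds exactly.
    """
    params = params or ArrayParams()
    params.validate()
    rng = np.random.default_rng(seed)
    genes = _gene_names(params.n_genes)

    base = pd.Series(
        np.exp(rng.normal(params.abundance_log_mean, params.abundance_log_sd, params.n_genes)),
        index=genes,
    )
    low = rng.random(params.n_genes) < params.low_expressed_fraction
    base[low] = base[low].clip(upper=params.detection_floor * 0.5)

    copy_numbers = pd.Series(1, index=genes)
    dup = rng.random(params.n_genes) < params.duplicated_fraction
    copy_numbers[dup] = 2

    # paralog pairs among well-expressed, single-copy genes
    eligible_pair = [g for g in genes if not low[genes.index(g)] and copy_numbers[g] == 1]
    pair_pool = list(rng.permutation(eligible_pair))
    pairs = [(pair_pool[2 * i], pair_pool[2 * i + 1]) for i in range(params.n_pairs)]
    paired = {g for p in pairs for g in p}

    annotation = _build_annotation(params, genes, copy_numbers, pairs)
    control_model = _model_probe_intensities(
        annotation, base, params.alpha, params.pair_mismatches
    )

    # the lower 75th-percentile anchor of the control probe vector
    v = np.sort(control_model.to_numpy())
    k = int(np.floor(0.75 * (len(v) - 1)))
    anchor = v[k]
    eligible_up = [
        g
        for g in genes
        if g not in paired
        and copy_numbers[g] == 1
        and base[g] >= params.detection_floor
        and base[g] * params.up_fold < 0.999 * anchor
    ]
    if len(eligible_up) < params.n_up:
        raise ValueError(
            f"only {len(eligible_up)} genes eligible for planted up-regulation; "
            f"increase n_genes or lower n_up"
        )
    up_genes = set(rng.choice(eligible_up, size=params.n_up, replace=False))

    abundance = {"control": base}
    for strain in params.strains:
        ab = base.copy()
        ab[list(up_genes)] = ab[list(up_genes)] * params.up_fold
        abundance[strain] = ab

    def spot_table(model: pd.Series, rep_rng) -> pd.DataFrame:
        rows = []
        for pid, val in model.items():
            for _ in range(params.spots_per_probe):
                if params.noise_cv > 0:
                    sig = val * rep_rng.lognormal(0.0, params.noise_cv)
                else:
                    sig = val
                flag = 1 if val >= params.detection_floor else int(rep_rng.random() < 0.3)
                rows.append(
                    {"probe_id": pid, "gProcessedSignal": sig, "gIsWellAboveBG": flag}
                )
        return pd.DataFrame(rows)

    tables: dict[str, list[pd.DataFrame]] = {}
    for name in ["control", *params.strains]:
        model = _model_probe_intensities(
            annotation, abundance[name], params.alpha, params.pair_mismatches
        )
        tables[name] = [spot_table(model, rng) for _ in range(params.replicates)]

    expected = pd.DataFrame(
        {
            s: (abundance[s] / base).astype(float)
            for s in params.strains
        }
    )
    truth = ArrayTruth(
        seed=seed,
        alpha=params.alpha,
        abundance=abundance,
        up_genes=up_genes,
        copy_numbers=copy_numbers,
        pair_genes=pairs,
        expected_ratio=expected,
    )
    return tables, annotation, truth
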