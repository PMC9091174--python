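"""Synthetic inputs for every pipeline stage, with planted ground truth.

The study's raw data — bright-field diameter measurements, confocal stacks of
Hoechst/EdU-stained nuclei, Oct4/Gata4 marker mid-sections, and qPCR Ct
tables — are emulated here so the downstream quantification can be tested
end-to-end against known truth.  Every generator is deterministic given its
seed.

Study conditions baked into the defaults: cohorts of 24 EBs per stage
measured in 2–8 directions with a diameter CV of a few percent; EdU-labelled
fractions from ~75% (day 1) down to ~17% (day 10) with a uniform→surface
shift of the labelled cells; the three-zone EB archetype (outer Gata4+ ExEn
shell, inner Oct4+ epiblast-like shell, central cavity); and triplicate qPCR
normalised to Hprt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .containers import SectionImage, ZStack

__all__ = [
    "CohortSpec",
    "StackSpec",
    "SectionSpec",
    "StackGroundTruth",
    "gen_diameter_cohort",
    "gen_nuclei_stack",
    "gen_marker_section",
    "gen_eb_mask",
    "gen_qpcr_table",
]


# ---------------------------------------------------------------------------
# diameter cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of an EB cohort of one or more differentiation stages.

    ``stages`` is a list of ``(stage_label, mean_diameter_um, cv)`` tuples,
    with ``cv`` the between-EB coefficient of variation of the true diameter
    (a fraction, e.g. 0.03 for 3%).  Each EB is then "measured" in 2–8
    directions, mimicking multi-directional calliper measurements on
    bright-field images; the per-direction jitter models mild shape
    anisotropy plus measurement error and scales with the stage CV so that a
    zero-CV cohort is measured exactly.
    """

    stages: tuple[tuple[str, float, float], ...]
    n_per_stage: int = 24
    cell_line: str = "ESB"
    condition: str = "FBS"
    direction_noise_frac: float = 0.3  # per-direction sd = frac * cv * true_d
    seed: int = 0

    def __post_init__(self):
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        for label, mean_d, cv in self.stages:
            if mean_d <= 0:
                raise ValueError(f"stage {label!r}: mean diameter must be > 0")
            if cv < 0:
                raise ValueError(f"stage {label!r}: CV must be >= 0")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at ±3 sd (keeps diameters positive for CV ≤ 1/3)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > 3 * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) > 3 * sd
    return out


def gen_diameter_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a long-format diameter table for a cohort.

    Columns: ``eb_id, cell_line, stage, condition, direction_index,
    diameter_um, true_diameter_um`` — one row per measured direction, the
    planted true diameter carried alongside.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for stage_label, mean_d, cv in spec.stages:
        true_d = _truncnorm(rng, mean_d, cv * mean_d, spec.n_per_stage)
        n_dirs = rng.integers(2, 9, size=spec.n_per_stage)  # 2..8 inclusive
        for i in range(spec.n_per_stage):
            eb_id = f"{spec.cell_line}_{stage_label}_{i:03d}"
            k = int(n_dirs[i])
            jitter_sd = spec.direction_noise_frac * cv * true_d[i]
            measured = _truncnorm(rng, true_d[i], jitter_sd, k)
            for j in range(k):
                rows.append(
                    (eb_id, spec.cell_line, stage_label, spec.condition,
                     j, float(measured[j]), float(true_d[i]))
                )
    return pd.DataFrame(
        rows,
        columns=["eb_id", "cell_line", "stage", "condition",
                 "direction_index", "diameter_um", "true_diameter_um"],
    )


# ---------------------------------------------------------------------------
# nuclei stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """Specification of a two-channel (nuclei + EdU) confocal-like stack.

    ``spatial_mode`` controls where nuclei sit in the circular EB cross
    section: ``"uniform"`` places centres uniformly over the disk,
    ``"surface"`` confines them to the outer 20% of the radius — the
    uniform→surface shift seen as proliferating cells retreat to the EB
    surface during differentiation.
    """

    eb_radius_um: float = 125.0
    n_nuclei: int = 150
    labeled_fraction: float = 0.75
    spatial_mode: str = "uniform"
    nucleus_area_range_um2: tuple[float, float] = (40.0, 120.0)
    pixel_size_um: float = 0.5
    n_planes: int = 20
    noise_sd: float = 0.03
    allow_touching: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in [0, 1]")
        lo, hi = self.nucleus_area_range_um2
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("nucleus areas must be positive and ordered")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.eb_radius_um <= 0:
            raise ValueError("eb_radius_um must be positive")
        if self.spatial_mode not in ("uniform", "surface"):
            raise ValueError("spatial_mode must be 'uniform' or 'surface'")


@dataclass
class StackGroundTruth:
    """Planted nuclei: one row per nucleus per plane.

    Columns of ``table``: ``plane, x_px, y_px, radius_px, area_um2, labeled``.
    """

    table: pd.DataFrame
    spec: StackSpec

    def n_labeled(self, plane: int | None = None) -> int:
        t = self.table if plane is None else self.table[self.table["plane"] == plane]
        return int(t["labeled"].sum())

    def n_total(self, plane: int | None = None) -> int:
        t = self.table if plane is None else self.table[self.table["plane"] == plane]
        return len(t)


def _place_nuclei(rng: np.random.Generator, spec: StackSpec, radii_px: np.ndarray,
                  r_field_px: float) -> np.ndarray:
    """Dart-throwing placement of nucleus centres (non-overlapping unless
    ``allow_touching``, in which case a fraction of pairs are planted just
    touching to exercise the watershed)."""
    n = spec.n_nuclei
    centers = np.empty((n, 2))
    placed = 0
    max_r = radii_px.max()
    # keep whole nuclei inside the EB disk
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not place nuclei without overlap; lower n_nuclei")
        r_limit = r_field_px - radii_px[placed] - 1
        u = rng.random()
        if spec.spatial_mode == "uniform":
            rad = r_limit * math.sqrt(u)
        else:  # surface: uniform over the outer-20% annulus (by area)
            r0 = 0.8 * r_limit
            rad = math.sqrt(r0 ** 2 + u * (r_limit ** 2 - r0 ** 2))
        theta = rng.random() * 2 * math.pi
        cand = np.array([rad * math.cos(theta), rad * math.sin(theta)])
        if placed:
            gap = 1.0 if not spec.allow_touching else -1.0
            d = np.linalg.norm(centers[:placed] - cand, axis=1)
            if np.any(d < radii_px[:placed] + radii_px[placed] + gap):
                continue
        centers[placed] = cand
        placed += 1
    return centers


def gen_nuclei_stack(spec: StackSpec) -> tuple[ZStack, StackGroundTruth]:
    """Render a two-channel nuclei/EdU stack with planted ground truth.

    Exactly ``round(labeled_fraction * n_nuclei)`` nuclei per plane are also
    painted into the EdU channel; the labelled subset is the first block of a
    seeded shuffle, so planted fractions are exact rather than binomial.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    r_field_px = spec.eb_radius_um / px
    size = int(math.ceil(2 * r_field_px)) + 8
    cx = size / 2.0

    n_labeled = round(spec.labeled_fraction * spec.n_nuclei)
    lo, hi = spec.nucleus_area_range_um2

    nuc = np.zeros((spec.n_planes, size, size), dtype=np.float32)
    edu = np.zeros_like(nuc)
    rows = []
    for p in range(spec.n_planes):
        areas = rng.uniform(lo, hi, spec.n_nuclei)
        radii_px = np.sqrt(areas / math.pi) / px
        centers = _place_nuclei(rng, spec, radii_px, r_field_px)
        labeled = np.zeros(spec.n_nuclei, dtype=bool)
        order = rng.permutation(spec.n_nuclei)
        labeled[order[:n_labeled]] = True
        for i in range(spec.n_nuclei):
            yx = (centers[i, 1] + cx, centers[i, 0] + cx)
            rr, cc = draw_disk(yx, radii_px[i], shape=(size, size))
            nuc[p, rr, cc] = 0.85
            if labeled[i]:
                edu[p, rr, cc] = 0.85
            rows.append((p, float(yx[1]), float(yx[0]), float(radii_px[i]),
                         float(areas[i]), bool(labeled[i])))
    if spec.noise_sd > 0:
        nuc += rng.normal(0, spec.noise_sd, nuc.shape).astype(np.float32)
        edu += rng.normal(0, spec.noise_sd, edu.shape).astype(np.float32)
        np.clip(nuc, 0, None, out=nuc)
        np.clip(edu, 0, None, out=edu)

    stack = ZStack(np.stack([nuc, edu]), pixel_size_um=px)
    gt = StackGroundTruth(
        table=pd.DataFrame(
            rows, columns=["plane", "x_px", "y_px", "radius_px", "area_um2", "labeled"]
        ),
        spec=spec,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# marker sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionSpec:
    """Specification of an Oct4/Gata4 mid-section of the three-zone archetype.

    Geometry is concentric: a central cavity of ``cavity_diameter_um``, an
    Epi-l (Oct4-bright) shell, and an outer ExEn (Gata4-bright) shell of
    thickness ``exen_thickness_um``.  ``boundary_jitter_px`` is the sd of a
    smooth angular perturbation applied to each zone boundary.
    """

    total_diameter_um: float = 600.0
    cavity_diameter_um: float = 387.6
    exen_thickness_um: float = 40.0
    gata4_intensity: float = 0.9
    oct4_intensity: float = 0.9
    background: float = 0.03
    boundary_jitter_px: float = 0.0
    noise_sd: float = 0.01
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.total_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("diameters and pixel size must be positive")
        if self.cavity_diameter_um < 0 or self.exen_thickness_um < 0:
            raise ValueError("zone sizes must be >= 0")
        if self.gata4_intensity < 0 or self.oct4_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.cavity_diameter_um + 2 * self.exen_thickness_um > self.total_diameter_um:
            raise ValueError("cavity + 2*ExEn thickness exceeds total diameter")


def _smooth_angular_noise(rng: np.random.Generator, theta: np.ndarray,
                          sd: float, n_modes: int = 6) -> np.ndarray:
    """Smooth zero-mean periodic field with pointwise sd ``sd``."""
    if sd == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    coef_sd = sd / math.sqrt(n_modes)
    for k in range(1, n_modes + 1):
        a, b = rng.normal(0, coef_sd, 2)
        out += a * np.cos(k * theta) + b * np.sin(k * theta)
    return out


def gen_marker_section(spec: SectionSpec) -> SectionImage:
    """Render the concentric two-channel section with stored geometry.

    Gata4 is bright only in the outer shell, Oct4 only in the Epi-l shell;
    the cavity is near-zero in both.  Zone boundaries (cavity edge, Epi-l
    outer edge, EB outer edge) each get an independent smooth angular jitter.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    R = spec.total_diameter_um / 2 / px
    r_cav = spec.cavity_diameter_um / 2 / px
    r_epi = R - spec.exen_thickness_um / px

    size = int(math.ceil(2 * R)) + 16
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)

    jit = spec.boundary_jitter_px
    r_cav_b = r_cav + _smooth_angular_noise(rng, theta, jit) if r_cav > 0 else np.zeros_like(r)
    r_epi_b = r_epi + _smooth_angular_noise(rng, theta, jit)
    r_out_b = R + _smooth_angular_noise(rng, theta, jit)

    inside = r <= r_out_b
    cavity = inside & (r < r_cav_b)
    exen = inside & (r >= r_epi_b)
    epil = inside & ~cavity & ~exen

    gata4 = np.full((size, size), 0.0, dtype=np.float32)
    oct4 = np.full((size, size), 0.0, dtype=np.float32)
    gata4[inside] = spec.background
    oct4[inside] = spec.background
    gata4[exen] = spec.gata4_intensity
    oct4[epil] = spec.oct4_intensity
    if spec.noise_sd > 0:
        gata4 += rng.normal(0, spec.noise_sd, gata4.shape).astype(np.float32)
        oct4 += rng.normal(0, spec.noise_sd, oct4.shape).astype(np.float32)
        np.clip(gata4, 0, None, out=gata4)
        np.clip(oct4, 0, None, out=oct4)

    return SectionImage(
        data=np.stack([gata4, oct4]),
        pixel_size_um=px,
        ground_truth={
            "total_diameter_um": spec.total_diameter_um,
            "cavity_diameter_um": spec.cavity_diameter_um,
            "exen_thickness_um": spec.exen_thickness_um,
            "center_px": (c, c),
        },
    )


def gen_eb_mask(radius_px: float = 200.0, radial_noise_frac: float = 0.02,
                seed: int = 0, n_modes: int = 6) -> np.ndarray:
    """Binary mask of a near-circular EB silhouette.

    The boundary radius is perturbed multiplicatively by a smooth angular
    field with pointwise sd ``radial_noise_frac`` — the mild non-circularity
    of real EB outlines whose circularity/roundness stays near 0.9–1.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    size = int(math.ceil(2 * radius_px * (1 + 4 * radial_noise_frac))) + 8
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    pert = _smooth_angular_noise(rng, theta, radial_noise_frac, n_modes)
    return r <= radius_px * (1.0 + pert)


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def gen_qpcr_table(
    genes: list[str],
    conditions: list[str],
    effects: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "Hprt",
    baselines: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format Ct table with planted fold changes.

    ``effects[condition][gene]`` is the planted expression fold change
    relative to the first condition (default 1 everywhere); the target Ct is
    lowered by log2(fold) cycles.  The reference gene gets its own baseline
    and no effect.  Returns ``(ct_table, truth)`` where ``ct_table`` has
    columns ``sample, gene, replicate, ct`` and ``truth`` columns
    ``sample, gene, fold``.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    if reference_gene in genes:
        raise ValueError("reference gene must not be listed among targets")
    rng = np.random.default_rng(seed)
    effects = effects or {}
    baselines = baselines or {}
    base = {g: baselines.get(g, 24.0) for g in genes}
    base[reference_gene] = baselines.get(reference_gene, 20.0)

    rows, truth_rows = [], []
    for cond in conditions:
        cond_fx = effects.get(cond, {})
        for g in genes + [reference_gene]:
            fold = 1.0 if g == reference_gene else float(cond_fx.get(g, 1.0))
            if fold <= 0:
                raise ValueError("planted fold changes must be positive")
            mu = base[g] - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((cond, g, rep, float(ct)))
            if g != reference_gene:
                truth_rows.append((cond, g, fold))
    ct_table = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    truth = pd.DataFrame(truth_rows, columns=["sample", "gene", "fold"])
    return ct_table, truth
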