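"""Volumetric bookkeeping for EB cohorts.

Diameters measured in 2–8 directions are averaged per EB; the EB is treated
as a sphere (circularity/roundness ≈ 0.9 justifies this), so volumes follow
πd³/6 and the three-zone archetype decomposes into concentric-shell volume
fractions.  Growth is expressed as late/early volume ratios and cohort
variability as the percent coefficient of variation of mean diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton, regionprops

__all__ = [
    "EBRecord",
    "PatternProportions",
    "VolumeLedger",
    "ShapeDescriptors",
    "mean_diameter",
    "sphere_volume",
    "shape_descriptors",
    "concentric_decomposition",
    "volume_ledger",
    "growth_ratio",
    "cohort_growth_ratio",
    "cohort_cv",
    "cohort_summary",
    "round_half_up",
    "plot_pattern_proportions",
]


@dataclass(frozen=True)
class EBRecord:
    """One EB with its multi-directional diameter measurements."""

    eb_id: str
    stage: str
    condition: str
    cell_line: str
    diameters_um: tuple[float, ...]

    def __post_init__(self):
        if not 2 <= len(self.diameters_um) <= 8:
            raise ValueError("need 2-8 diameter measurements per EB")
        if any(d <= 0 for d in self.diameters_um):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class PatternProportions:
    """Volumetric fractions of the three archetype zones (sum to 1)."""

    exen_frac: float
    epil_frac: float
    cavity_frac: float

    def __post_init__(self):
        for name, v in (("exen", self.exen_frac), ("epil", self.epil_frac),
                        ("cavity", self.cavity_frac)):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}_frac outside [0, 1]: {v}")
        if abs(self.exen_frac + self.epil_frac + self.cavity_frac - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass(frozen=True)
class VolumeLedger:
    """Conservation ledger: total = cavity + EdU-labelled + unlabelled cellular volume."""

    total_vol: float
    cavity_vol: float
    cellular_vol: float
    edu_labeled_vol: float
    edu_unlabeled_vol: float


@dataclass(frozen=True)
class ShapeDescriptors:
    circularity: float
    roundness: float
    aspect_ratio: float


def mean_diameter(record: EBRecord) -> float:
    """Arithmetic mean of the 2–8 per-direction diameters."""
    return float(np.mean(record.diameters_um))


def sphere_volume(diameter_um: float) -> float:
    """Sphere volume πd³/6 in µm³."""
    if diameter_um < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * diameter_um ** 3 / 6.0


def shape_descriptors(mask: np.ndarray, pixel_size_um: float = 1.0) -> ShapeDescriptors:
    """Circularity, roundness and aspect ratio of a single binary object.

    circularity = 4πA/P² with a Crofton (diagonal-corrected) perimeter
    estimate, clipped at 1; roundness = 4A/(π·major²); aspect ratio =
    major/minor from the ellipse fit.  The pixel size cancels in all three.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = cc_label(mask)
    if labels.max() != 1:
        raise ValueError("mask must contain exactly one connected component")
    props = regionprops(labels)[0]
    area = props.area
    perim = perimeter_crofton(mask, directions=4)
    major = props.axis_major_length
    minor = props.axis_minor_length
    if minor == 0 or perim == 0:
        raise ValueError("degenerate (line-like) mask")
    circularity = min(1.0, 4 * math.pi * area / perim ** 2)
    roundness = min(1.0, 4 * area / (math.pi * major ** 2))
    return ShapeDescriptors(
        circularity=float(circularity),
        roundness=float(roundness),
        aspect_ratio=float(major / minor),
    )


def concentric_decomposition(total_d: float, cavity_d: float,
                             exen_thickness: float) -> PatternProportions:
    """Volume fractions of concentric spherical shells.

    cavity = (d_cav/d)³; ExEn = 1 − ((d − 2t)/d)³; Epi-l takes the rest.
    """
    if total_d <= 0 or cavity_d < 0 or exen_thickness < 0:
        raise ValueError("diameters must be positive, zones non-negative")
    if cavity_d + 2 * exen_thickness > total_d:
        raise ValueError("cavity + 2*ExEn thickness exceeds total diameter")
    cavity_frac = (cavity_d / total_d) ** 3
    exen_frac = 1.0 - ((total_d - 2 * exen_thickness) / total_d) ** 3
    epil_frac = 1.0 - cavity_frac - exen_frac
    return PatternProportions(exen_frac=exen_frac, epil_frac=epil_frac,
                              cavity_frac=cavity_frac)


def volume_ledger(total_vol: float, cavity_vol: float, edu_fraction: float) -> VolumeLedger:
    """Split the cellular volume (total − cavity) into EdU-labelled and unlabelled parts."""
    if not 0 <= edu_fraction <= 1:
        raise ValueError("edu_fraction must be in [0, 1]")
    if cavity_vol < 0 or total_vol < 0 or cavity_vol > total_vol:
        raise ValueError("need 0 <= cavity_vol <= total_vol")
    cellular = total_vol - cavity_vol
    labeled = edu_fraction * cellular
    return VolumeLedger(
        total_vol=float(total_vol),
        cavity_vol=float(cavity_vol),
        cellular_vol=float(cellular),
        edu_labeled_vol=float(labeled),
        edu_unlabeled_vol=float(cellular - labeled),
    )


def growth_ratio(vol_late: float, vol_early: float) -> float:
    """Late/early volume ratio (unit-free)."""
    if vol_early <= 0:
        raise ValueError("early volume must be > 0")
    return float(vol_late) / float(vol_early)


def _stage_mean_volume(table: pd.DataFrame, stage: str) -> float:
    sub = table[table["stage"] == stage]
    if sub.empty:
        raise ValueError(f"stage {stage!r} not in table")
    mean_d = sub.groupby("eb_id")["diameter_um"].mean()
    return float(mean_d.apply(sphere_volume).mean())


def cohort_growth_ratio(table: pd.DataFrame, stage_late: str, stage_early: str) -> float:
    """Ratio of stage mean volumes from a long-format diameter table.

    Per EB, directions are averaged first and the volume computed from the
    mean diameter; the ratio compares stage means.
    """
    return growth_ratio(_stage_mean_volume(table, stage_late),
                        _stage_mean_volume(table, stage_early))


def cohort_cv(values) -> float:
    """Percent coefficient of variation, 100·sd/mean with sample sd (n−1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(100.0 * values.std(ddof=1) / mean)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-stage summary: n, mean diameter, CV%, mean volume.

    Input is the long-format diameter table; per-EB mean diameters are the
    unit of analysis.
    """
    out = []
    for (stage,), sub in table.groupby(["stage"]):
        mean_d = sub.groupby("eb_id")["diameter_um"].mean()
        out.append({
            "stage": stage,
            "n_ebs": len(mean_d),
            "mean_diameter_um": float(mean_d.mean()),
            "cv_percent": cohort_cv(mean_d) if len(mean_d) > 1 else np.nan,
            "mean_volume_um3": float(mean_d.apply(sphere_volume).mean()),
        })
    return pd.DataFrame(out)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (matches hand-rounded ratios)."""
    return int(math.floor(x + 0.5))


def plot_pattern_proportions(proportions: dict[str, PatternProportions], path=None):
    """Stacked-bar plot of ExEn / Epi-l / cavity volume fractions per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(proportions)
    exen = [proportions[k].exen_frac * 100 for k in labels]
    epil = [proportions[k].epil_frac * 100 for k in labels]
    cav = [proportions[k].cavity_frac * 100 for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(labels), 4))
    ax.bar(labels, exen, label="ExEn", color="#9467bd")
    ax.bar(labels, epil, bottom=exen, label="Epi-l", color="#d62728")
    bottoms = [a + b for a, b in zip(exen, epil)]
    ax.bar(labels, cav, bottom=bottoms, label="cavity", color="#c7c7c7")
    ax.set_ylabel("volumetric ratio (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
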