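"""French-flag morphogen-threshold model of EB patterning and scaling.

A morphogen supplied by the culture medium at constant boundary
concentration ``c_s`` diffuses into a spherical EB and is taken up by the
cells at a first-order rate.  At steady state the radial profile is

    c(r) = c_s · (R/r) · sinh(r/λ) / sinh(R/λ),    λ = √(D/k),

monotonically increasing from the centre to ``c_s`` at the surface.
Concentration thresholds T1 > T2 > T3 assign fates by position: the outer
high-concentration shell (c ≥ T1) becomes extraembryonic endoderm (ExEn),
the intermediate shell (T2 ≤ c < T1) stays epiblast-like (Epi-l), and the
low-concentration core (c < T2; the regime T3 labels) undergoes apoptosis
and cavitation.  Because c depends on position only through r/R and R/λ,
proportions are exactly invariant under (R, λ) → (aR, aλ): patterns scale
with EB size when the diffusion length scales with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .morphometry import PatternProportions

__all__ = [
    "MorphogenModel",
    "ThresholdSet",
    "FateMap",
    "steady_profile",
    "classify_french_flag",
    "scaling_experiment",
    "plot_french_flag",
]


@dataclass(frozen=True)
class MorphogenModel:
    """Spherical diffusion–uptake model: radius R, diffusion length λ, boundary c_s."""

    R: float
    lam: float
    c_s: float = 1.0

    def __post_init__(self):
        if self.R <= 0 or self.lam <= 0 or self.c_s <= 0:
            raise ValueError("R, lambda and c_s must all be positive")


@dataclass(frozen=True)
class ThresholdSet:
    """Fate thresholds, same units as c_s; strictly ordered T1 > T2 > T3 ≥ 0.

    Two boundaries (T1, T2) define the three zones; T3 labels the sub-T2
    apoptosis/cavitation regime and is validated but not a zone boundary.
    """

    T1: float
    T2: float
    T3: float = 0.0

    def __post_init__(self):
        if not (self.T1 > self.T2 > self.T3 >= 0):
            raise ValueError("thresholds must satisfy T1 > T2 > T3 >= 0")


@dataclass(frozen=True)
class FateMap:
    """Fate boundary radii and the resulting volumetric proportions.

    ``r1`` is the ExEn inner radius (c = T1), ``r2`` the Epi-l inner /
    cavity outer radius (c = T2); 0 ≤ r2 ≤ r1 ≤ R.
    """

    r1: float
    r2: float
    proportions: PatternProportions
    exen_absent: bool = False


def steady_profile(model: MorphogenModel, r) -> np.ndarray | float:
    """Steady-state concentration c(r) for 0 ≤ r ≤ R.

    Evaluated in the overflow-safe form
    c(r) = c_s·(R/r)·exp((r−R)/λ)·(1−e^(−2r/λ))/(1−e^(−2R/λ)),
    with the analytic limit c(0) = c_s·(R/λ)/sinh(R/λ).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > model.R * (1 + 1e-12)):
        raise ValueError("r must lie in [0, R]")
    R, lam, c_s = model.R, model.lam, model.c_s
    x = r_arr / lam
    X = R / lam
    denom = -np.expm1(-2.0 * X)  # 1 - exp(-2R/λ)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = c_s * (R / np.where(r_arr == 0, np.nan, r_arr)) \
            * np.exp(x - X) * (-np.expm1(-2.0 * x)) / denom
    if np.isscalar(r) or r_arr.ndim == 0:
        if float(r_arr) == 0.0:
            return _c_center(model)
        return float(c)
    c = np.where(r_arr == 0, _c_center(model), c)
    return c


def _c_center(model: MorphogenModel) -> float:
    X = model.R / model.lam
    # (R/λ)/sinh(R/λ) in overflow-safe form
    return float(model.c_s * X * 2.0 * math.exp(-X) / -math.expm1(-2.0 * X))


def _threshold_radius(model: MorphogenModel, T: float) -> float:
    """Radius where c(r) = T (c is monotone increasing in r)."""
    c0 = _c_center(model)
    if T <= c0:
        return 0.0
    if T >= model.c_s:
        return model.R
    return float(brentq(lambda r: steady_profile(model, r) - T, 0.0, model.R,
                        xtol=1e-12 * model.R))


def classify_french_flag(model: MorphogenModel, thresholds: ThresholdSet) -> FateMap:
    """Partition the sphere into ExEn / Epi-l / cavity by thresholding c(r).

    ExEn where c ≥ T1, Epi-l where T2 ≤ c < T1, cavity where c < T2.  If T1
    exceeds the boundary concentration the whole sphere is below T1; the
    result is flagged with ``exen_absent`` rather than raising.
    """
    r1 = _threshold_radius(model, thresholds.T1)
    r2 = _threshold_radius(model, thresholds.T2)
    R = model.R
    cavity = (r2 / R) ** 3
    exen = 1.0 - (r1 / R) ** 3
    epil = 1.0 - cavity - exen
    return FateMap(
        r1=r1,
        r2=r2,
        proportions=PatternProportions(exen_frac=exen, epil_frac=epil,
                                       cavity_frac=cavity),
        exen_absent=thresholds.T1 >= model.c_s,
    )


def scaling_experiment(
    sizes: list[float],
    thresholds: ThresholdSet,
    scaling_rule: str = "lambda_proportional",
    lam_over_R: float = 1.0 / 3.0,
    lam_fixed: float | None = None,
    c_s: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Pattern proportions across EB sizes under two diffusion-length rules.

    ``lambda_proportional`` keeps λ/R fixed (default 1/3), so the
    nondimensional profile — and hence the proportions — is identical for
    every size: scaling invariance.  ``lambda_fixed`` keeps λ at an absolute
    value (default: λ of the smallest size under ``lam_over_R``), so larger
    EBs see a steeper relative gradient and the proportions drift.  Returns
    the per-size table and the maximum deviation of any fraction from its
    value at the first size.
    """
    if not sizes:
        raise ValueError("need at least one size")
    if scaling_rule not in ("lambda_proportional", "lambda_fixed"):
        raise ValueError("unknown scaling_rule")
    if lam_fixed is None:
        lam_fixed = lam_over_R * min(sizes)
    rows = []
    for R in sizes:
        lam = lam_over_R * R if scaling_rule == "lambda_proportional" else lam_fixed
        fate = classify_french_flag(MorphogenModel(R=R, lam=lam, c_s=c_s), thresholds)
        rows.append({
            "R_um": R,
            "lambda_um": lam,
            "r1_um": fate.r1,
            "r2_um": fate.r2,
            "exen_frac": fate.proportions.exen_frac,
            "epil_frac": fate.proportions.epil_frac,
            "cavity_frac": fate.proportions.cavity_frac,
        })
    table = pd.DataFrame(rows)
    fracs = table[["exen_frac", "epil_frac", "cavity_frac"]].to_numpy()
    max_dev = float(np.abs(fracs - fracs[0]).max())
    return table, max_dev


def plot_french_flag(model: MorphogenModel, thresholds: ThresholdSet, path=None):
    """Radial profile with threshold lines and shaded fate zones."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fate = classify_french_flag(model, thresholds)
    r = np.linspace(0, model.R, 400)
    c = steady_profile(model, r)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.axvspan(0, fate.r2, color="#c7c7c7", alpha=0.6, label="cavity")
    ax.axvspan(fate.r2, fate.r1, color="#d62728", alpha=0.25, label="Epi-l")
    ax.axvspan(fate.r1, model.R, color="#9467bd", alpha=0.3, label="ExEn")
    ax.plot(r, c, "k-", lw=2)
    for T, name in ((thresholds.T1, "T1"), (thresholds.T2, "T2"),
                    (thresholds.T3, "T3")):
        ax.axhline(T, ls="--", lw=0.8, color="0.3")
        ax.annotate(name, (model.R * 0.01, T), va="bottom", fontsize=8)
    ax.set_xlabel("radius r (µm)")
    ax.set_ylabel("morphogen concentration c(r)")
    ax.legend(frameon=False, fontsize=8, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
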