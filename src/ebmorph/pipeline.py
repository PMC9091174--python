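"""End-to-end orchestration: simulate → measure → count → decompose → express
→ stats → frenchflag, with one results directory per run.

Every output table carries provenance columns (seed, config hash); the JSON
summary is deterministic for a given config and seed.  Stage failures raise
:class:`StageError` naming the stage; outputs of completed stages are kept.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import cluster_heatmap, dct_matrix, ddct, scale_profiles
from .imaging import count_edu_fraction, measure_pattern_radii
from .morphometry import (PatternProportions, cohort_growth_ratio, cohort_summary,
                          concentric_decomposition, plot_pattern_proportions,
                          round_half_up, sphere_volume, volume_ledger)
from .patterning import (MorphogenModel, ThresholdSet, classify_french_flag,
                         plot_french_flag, scaling_experiment)
from .stats import GroupedSamples, one_way_anova, posthoc, ttest_unpaired
from .synthetic import (CohortSpec, SectionSpec, StackSpec, gen_diameter_cohort,
                        gen_marker_section, gen_nuclei_stack, gen_qpcr_table)

__all__ = ["RunConfig", "StageError", "run_full_analysis"]

ALL_STAGES = ("simulate", "measure", "count", "decompose", "express",
              "stats", "frenchflag")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run.

    Growth factors are EB10/EB1 diameter-cube (volume) ratios per cell line
    and medium; pattern fractions are the planted ExEn and cavity volume
    fractions used to build marker-section geometry.  Image sizes default to
    small-but-representative stacks so a full run stays fast.
    """

    out_dir: str = "ebmorph_results"
    seed: int = 0
    alpha: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES

    cell_lines: tuple[str, ...] = ("ESB", "EGB", "ECB")
    eb1_diameter_um: float = 250.0
    cv_early: float = 0.03
    cv_late: float = 0.06
    n_per_stage: int = 24
    volume_ratios_fbs: tuple[float, ...] = (14.0, 12.0, 13.0)
    volume_ratios_ksr: tuple[float, ...] = (6.0, 8.0, 9.0)

    stack_n_planes: int = 5
    stack_n_nuclei: int = 80
    stack_pixel_um: float = 0.8
    stack_radius_um: float = 100.0
    edu_fraction_eb1: float = 0.75
    edu_fraction_eb10: float = 0.17

    section_total_um: float = 600.0
    exen_frac_fbs: float = 0.26
    cavity_frac_fbs: float = 0.27
    exen_frac_ksr: float = 0.20
    cavity_frac_ksr: float = 0.215

    qpcr_genes: tuple[str, ...] = ("Oct4", "Nanog", "Gata4", "Pax6", "Bry", "Mvh")
    qpcr_noise_sd: float = 0.15

    ff_radius_um: float = 300.0
    ff_lam_over_R: float = 1.0 / 3.0
    ff_T1: float = 0.84
    ff_T2: float = 0.53
    ff_T3: float = 0.20
    ff_sizes_um: tuple[float, ...] = (79.4, 100.0, 171.0, 215.4)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "cell_lines", "volume_ratios_fbs", "volume_ratios_ksr",
                    "qpcr_genes", "ff_sizes_um"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Short hash of the analysis parameters (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(canon.encode()).hexdigest()[:8]


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = cfg.seed
    df["config_hash"] = cfg.config_hash()
    return df


def _section_geometry(total_d: float, exen_frac: float, cavity_frac: float):
    cavity_d = total_d * cavity_frac ** (1.0 / 3.0)
    exen_t = total_d / 2.0 * (1.0 - (1.0 - exen_frac) ** (1.0 / 3.0))
    return cavity_d, exen_t


def run_full_analysis(config: RunConfig) -> dict:
    """Run the enabled stages and return the JSON-serialisable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages_run": list(config.stages),
    }
    log_lines = [f"ebmorph {__version__}", f"seed {config.seed}",
                 f"config_hash {config.config_hash()}"]
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "measure": _stage_measure,
        "count": _stage_count,
        "decompose": _stage_decompose,
        "express": _stage_express,
        "stats": _stage_stats,
        "frenchflag": _stage_frenchflag,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            runners[stage](config, out, state, summary)
            log_lines.append(f"stage {stage}: ok")
        except Exception as exc:  # partial outputs retained
            log_lines.append(f"stage {stage}: FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise StageError(stage, exc) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    tables = []
    for li, line in enumerate(cfg.cell_lines):
        for medium, ratios in (("FBS", cfg.volume_ratios_fbs),
                               ("KSR", cfg.volume_ratios_ksr)):
            d10 = cfg.eb1_diameter_um * ratios[li] ** (1.0 / 3.0)
            spec = CohortSpec(
                stages=(("EB1", cfg.eb1_diameter_um, cfg.cv_early),
                        ("EB10", d10, cfg.cv_late)),
                n_per_stage=cfg.n_per_stage,
                cell_line=line,
                condition=medium,
                seed=int(rng.integers(2 ** 31)),
            )
            tables.append(gen_diameter_cohort(spec))
    state["diameters"] = pd.concat(tables, ignore_index=True)
    _stamp(state["diameters"], cfg).to_csv(out / "diameters.csv", index=False)

    state["stacks"] = {}
    # the late-stage EB is larger; 1.5x radius keeps the surface-confined
    # nuclei placeable without overlap
    for stage, frac, mode, rad in (
            ("EB1", cfg.edu_fraction_eb1, "uniform", cfg.stack_radius_um),
            ("EB10", cfg.edu_fraction_eb10, "surface", 1.5 * cfg.stack_radius_um)):
        spec = StackSpec(
            eb_radius_um=rad,
            n_nuclei=cfg.stack_n_nuclei,
            labeled_fraction=frac,
            spatial_mode=mode,
            pixel_size_um=cfg.stack_pixel_um,
            n_planes=cfg.stack_n_planes,
            seed=int(rng.integers(2 ** 31)),
        )
        stack, gt = gen_nuclei_stack(spec)
        stack.write(out / f"stack_{stage}.tiff")
        state["stacks"][stage] = (stack, gt)

    state["sections"] = {}
    for medium, exen_f, cav_f in (("FBS", cfg.exen_frac_fbs, cfg.cavity_frac_fbs),
                                  ("KSR", cfg.exen_frac_ksr, cfg.cavity_frac_ksr)):
        cav_d, exen_t = _section_geometry(cfg.section_total_um, exen_f, cav_f)
        spec = SectionSpec(
            total_diameter_um=cfg.section_total_um,
            cavity_diameter_um=cav_d,
            exen_thickness_um=exen_t,
            boundary_jitter_px=2.0,
            seed=int(rng.integers(2 ** 31)),
        )
        section = gen_marker_section(spec)
        section.write(out / f"section_{medium}.tiff")
        state["sections"][medium] = section

    effects = {
        "EB10_FBS": {"Oct4": 0.15, "Nanog": 0.1, "Gata4": 12.0, "Pax6": 1.8,
                     "Bry": 1.6, "Mvh": 1.3},
        "EB10_KSR": {"Oct4": 0.35, "Nanog": 0.3, "Gata4": 5.0, "Pax6": 1.2,
                     "Bry": 1.1, "Mvh": 1.1},
    }
    ct, truth = gen_qpcr_table(
        genes=list(cfg.qpcr_genes),
        conditions=["EB1_FBS", "EB10_FBS", "EB10_KSR"],
        effects=effects,
        noise_sd=cfg.qpcr_noise_sd,
        seed=int(rng.integers(2 ** 31)),
    )
    state["ct_table"] = ct
    state["qpcr_truth"] = truth
    _stamp(ct, cfg).to_csv(out / "ct_table.csv", index=False)


def _stage_measure(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    table = state["diameters"]
    rows = []
    ratios = {}
    for (line, medium), sub in table.groupby(["cell_line", "condition"]):
        summ = cohort_summary(sub)
        summ.insert(0, "cell_line", line)
        summ.insert(1, "condition", medium)
        rows.append(summ)
        ratio = cohort_growth_ratio(sub, "EB10", "EB1")
        ratios[f"{line}_{medium}"] = {"ratio": ratio,
                                      "rounded": round_half_up(ratio)}
    pd.concat(rows, ignore_index=True).pipe(_stamp, cfg).to_csv(
        out / "cohort_summary.csv", index=False)
    summary["growth_ratios"] = ratios


def _stage_count(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    results = {}
    rows = []
    for stage, (stack, gt) in state["stacks"].items():
        res = count_edu_fraction(stack)
        results[stage] = {
            "stack_percent": res.stack_percent,
            "n_planes_used": res.n_planes_used,
            "planted_percent": 100.0 * gt.spec.labeled_fraction,
        }
        for p, pct in enumerate(res.per_plane_percent):
            rows.append({"stage": stage, "plane": p, "edu_percent": pct})
    pd.DataFrame(rows).pipe(_stamp, cfg).to_csv(out / "edu_per_plane.csv", index=False)
    summary["edu_fractions"] = results


def _stage_decompose(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    props: dict[str, PatternProportions] = {}
    rows = []
    for medium, section in state["sections"].items():
        cav_d, epi_d, tot_d = measure_pattern_radii(section)
        p = concentric_decomposition(tot_d, cav_d, (tot_d - epi_d) / 2.0)
        props[medium] = p
        rows.append({
            "condition": medium, "cavity_d_um": cav_d, "epil_outer_d_um": epi_d,
            "total_d_um": tot_d, "exen_frac": p.exen_frac,
            "epil_frac": p.epil_frac, "cavity_frac": p.cavity_frac,
        })
        # ledger: combine measured cavity with the counted EdU fraction
        if "edu_fractions" in summary:
            edu = summary["edu_fractions"].get("EB10", {}).get("stack_percent")
            if edu is not None:
                led = volume_ledger(sphere_volume(tot_d),
                                    sphere_volume(cav_d), edu / 100.0)
                rows[-1]["edu_labeled_vol_um3"] = led.edu_labeled_vol
                rows[-1]["edu_unlabeled_vol_um3"] = led.edu_unlabeled_vol
    pd.DataFrame(rows).pipe(_stamp, cfg).to_csv(out / "pattern_proportions.csv",
                                                index=False)
    plot_pattern_proportions(props, out / "pattern_proportions.png")
    summary["pattern_proportions"] = {
        k: {"exen": p.exen_frac, "epil": p.epil_frac, "cavity": p.cavity_frac}
        for k, p in props.items()
    }


def _stage_express(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    fold = ddct(state["ct_table"], reference_sample="EB1_FBS")
    _stamp(fold, cfg).to_csv(out / "fold_changes.csv", index=False)
    scaled = scale_profiles(dct_matrix(fold))
    _, leaf_order = cluster_heatmap(scaled, heatmap_path=out / "expression_heatmap.png")
    summary["fold_changes"] = {
        f"{r.sample}:{r.gene}": float(r.fold)
        for r in fold.itertuples() if r.sample != "EB1_FBS"
    }
    summary["cluster_leaf_order"] = [str(g) for g in leaf_order]


def _stage_stats(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    table = state["diameters"]
    fbs10 = table[(table["condition"] == "FBS") & (table["stage"] == "EB10")]
    vols = {
        line: sub.groupby("eb_id")["diameter_um"].mean().apply(sphere_volume).to_numpy()
        for line, sub in fbs10.groupby("cell_line")
    }
    groups = GroupedSamples(vols)
    F, dfb, dfw, p = one_way_anova(groups)
    ph = posthoc(groups, method="tukey", alpha=cfg.alpha)
    _stamp(ph, cfg).to_csv(out / "posthoc_volumes.csv", index=False)
    ttests = {}
    for line in cfg.cell_lines:
        sub = table[table["cell_line"] == line]
        d_fbs = sub[(sub["condition"] == "FBS") & (sub["stage"] == "EB10")]
        d_ksr = sub[(sub["condition"] == "KSR") & (sub["stage"] == "EB10")]
        a = d_fbs.groupby("eb_id")["diameter_um"].mean().apply(sphere_volume)
        b = d_ksr.groupby("eb_id")["diameter_um"].mean().apply(sphere_volume)
        t, df, pt = ttest_unpaired(a, b)
        ttests[line] = {"t": t, "df": df, "p": pt}
    summary["statistics"] = {
        "anova_eb10_volumes": {"F": F, "df_between": dfb, "df_within": dfw, "p": p},
        "ttest_fbs_vs_ksr_eb10": ttests,
    }


def _stage_frenchflag(cfg: RunConfig, out: Path, state: dict, summary: dict) -> None:
    model = MorphogenModel(R=cfg.ff_radius_um, lam=cfg.ff_lam_over_R * cfg.ff_radius_um)
    thresholds = ThresholdSet(T1=cfg.ff_T1, T2=cfg.ff_T2, T3=cfg.ff_T3)
    fate = classify_french_flag(model, thresholds)
    plot_french_flag(model, thresholds, out / "french_flag.png")
    prop_tbl, dev_prop = scaling_experiment(
        list(cfg.ff_sizes_um), thresholds, "lambda_proportional",
        lam_over_R=cfg.ff_lam_over_R)
    fix_tbl, dev_fix = scaling_experiment(
        list(cfg.ff_sizes_um), thresholds, "lambda_fixed",
        lam_over_R=cfg.ff_lam_over_R)
    _stamp(prop_tbl, cfg).to_csv(out / "scaling_lambda_proportional.csv", index=False)
    _stamp(fix_tbl, cfg).to_csv(out / "scaling_lambda_fixed.csv", index=False)
    summary["french_flag"] = {
        "model": {"R_um": model.R, "lambda_um": model.lam, "c_s": model.c_s,
                  "T1": thresholds.T1, "T2": thresholds.T2, "T3": thresholds.T3},
        "proportions": {"exen": fate.proportions.exen_frac,
                        "epil": fate.proportions.epil_frac,
                        "cavity": fate.proportions.cavity_frac},
        "scaling_max_dev_lambda_proportional": dev_prop,
        "scaling_max_dev_lambda_fixed": dev_fix,
    }
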