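"""qPCR relative quantification (2^−ΔΔCt) and expression-profile clustering.

Ct values are aggregated by replicate mean, normalised to a reference gene
(Hprt by default) to give ΔCt, referenced to a chosen sample to give ΔΔCt,
and expressed as fold change 2^−ΔΔCt.  Profiles of averaged ΔCt values are
z-scored per gene and clustered hierarchically with Euclidean distances for
heatmap display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

__all__ = ["ddct", "dct_matrix", "scale_profiles", "cluster_heatmap"]


def ddct(
    ct_table: pd.DataFrame,
    reference_sample: str,
    reference_gene: str = "Hprt",
) -> pd.DataFrame:
    """Comparative 2^−ΔΔCt quantification.

    ``ct_table`` is long-format with columns ``sample, gene, replicate, ct``.
    Per sample, replicate Ct values are averaged; ΔCt = mean Ct(target) −
    mean Ct(reference gene); ΔΔCt subtracts the reference sample's ΔCt; the
    fold change is 2^−ΔΔCt (so the reference sample's fold is exactly 1 for
    every gene).  Returns a tidy table with columns ``sample, gene, dct,
    ddct, fold``.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from table")
    if reference_sample not in mean_ct.index:
        raise ValueError(f"reference sample {reference_sample!r} missing from table")
    missing = mean_ct[reference_gene].isna()
    if missing.any():
        raise ValueError(
            f"reference gene {reference_gene!r} missing for samples: "
            f"{list(mean_ct.index[missing])}"
        )
    targets = [g for g in mean_ct.columns if g != reference_gene]
    dct = mean_ct[targets].sub(mean_ct[reference_gene], axis=0)
    ddct_tbl = dct.sub(dct.loc[reference_sample], axis=1)
    fold = 2.0 ** (-ddct_tbl)
    out = (
        pd.concat(
            {"dct": dct, "ddct": ddct_tbl, "fold": fold}, names=["quantity"]
        )
        .stack()
        .unstack("quantity")
        .reset_index()
    )
    out.attrs["reference_sample"] = reference_sample
    out.attrs["reference_gene"] = reference_gene
    return out[["sample", "gene", "dct", "ddct", "fold"]]


def dct_matrix(fold_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a ddct output table into a genes × samples ΔCt matrix."""
    return fold_table.pivot(index="gene", columns="sample", values="dct")


def scale_profiles(matrix: pd.DataFrame | np.ndarray, axis: str = "gene") -> pd.DataFrame:
    """z-score a genes × conditions ΔCt matrix.

    ``axis='gene'`` (default) centres and scales each row to mean 0, sample
    sd 1 (as R's ``scale`` does column-wise on the transposed matrix); rows
    with zero sd become all zeros.  ``axis='condition'`` scales columns.
    """
    m = pd.DataFrame(matrix).astype(float)
    if axis == "condition":
        return scale_profiles(m.T, axis="gene").T
    if axis != "gene":
        raise ValueError("axis must be 'gene' or 'condition'")
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    centred = m.sub(mu, axis=0)
    scaled = centred.div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return scaled


def cluster_heatmap(
    scaled: pd.DataFrame,
    method: str = "complete",
    heatmap_path=None,
):
    """Hierarchical clustering of profile rows with Euclidean distances.

    Returns ``(linkage_matrix, leaf_order)``; with ``heatmap_path`` also
    writes a dendrogram + heatmap figure.  Complete linkage is the default
    (configurable); clustering is deterministic for a given matrix.
    """
    scaled = pd.DataFrame(scaled)
    if scaled.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(pdist(scaled.to_numpy(), metric="euclidean"), method=method)
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    leaf_order = [scaled.index[i] for i in leaves]
    if heatmap_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax_d, ax_h) = plt.subplots(
            1, 2, figsize=(7, 0.6 * scaled.shape[0] + 2),
            gridspec_kw={"width_ratios": [1, 3]},
        )
        dendrogram(Z, orientation="left", labels=list(scaled.index), ax=ax_d,
                   color_threshold=0)
        ordered = scaled.iloc[leaves[::-1]]
        im = ax_h.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax_h.set_yticks(range(len(ordered)), list(ordered.index))
        ax_h.set_xticks(range(ordered.shape[1]), list(ordered.columns),
                        rotation=45, ha="right")
        fig.colorbar(im, ax=ax_h, label="scaled ΔCt")
        fig.tight_layout()
        fig.savefig(heatmap_path, dpi=120)
        plt.close(fig)
    return Z, leaf_order
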