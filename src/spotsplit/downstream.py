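"""Post-deconvolution statistics: normalization, markers, dot plots, annotation.

Mirrors the conventional single-cell workflow on the putative cells produced
by the deconvolution: library-size log-normalization, Wilcoxon rank-sum
cluster markers with BH correction (default thresholds ``|log2FC| > 1`` and
``q < 0.005``), dot-plot summary statistics, and signature-based cluster
annotation via a hypergeometric overrepresentation test against user-supplied
gene signatures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .multitest import bh_adjust
from .spatial_io import PutativeCellSet

logger = logging.getLogger(__name__)


@dataclass
class NormalizedCellMatrix:
    """Log-normalized genes x cells expression with its cluster labels."""

    values: pd.DataFrame  # genes x cells
    labels: pd.Series  # cell -> cluster label
    scale_factor: float

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("cluster label missing for some cells")


def log_normalize(cells: PutativeCellSet, scale_factor: float = 10_000.0) -> NormalizedCellMatrix:
    """``ln(1 + count / cell_total * scale_factor)`` per gene and cell.

    Cells with zero total counts are dropped with a warning.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = cells.counts.toarray().astype(float)
    totals = counts.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        logger.warning("log_normalize: dropping %d zero-count cell(s)", int((~keep).sum()))
    counts = counts[:, keep]
    totals = totals[keep]
    values = np.log1p(counts / totals * scale_factor)
    kept_ids = [c for c, k in zip(cells.cell_ids, keep) if k]
    labels = pd.Series(
        [l for l, k in zip(cells.clusters, keep) if k], index=kept_ids, name="cluster"
    )
    return NormalizedCellMatrix(
        values=pd.DataFrame(values, index=cells.gene_ids, columns=kept_ids),
        labels=labels,
        scale_factor=scale_factor,
    )


def _log2fc_expm1(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Seurat-style fold change: log2 ratio of expm1-means with pseudocount 1."""
    return float(np.log2((np.expm1(x_in).mean() + 1.0) / (np.expm1(x_out).mean() + 1.0)))


def cluster_markers(
    norm: NormalizedCellMatrix,
    labels: pd.Series | None = None,
    lfc_min: float = 1.0,
    q_max: float = 0.005,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of each cluster against all other cells.

    Per (cluster, gene): two-sided rank-sum p of cluster vs rest on the
    normalized values, expm1-mean log2 fold change, expressing fractions, and
    a BH q-value computed across genes within the cluster.  A row is flagged
    significant iff ``|log2FC| > lfc_min`` and ``q < q_max``.  Clusters with
    fewer than ``min_cells`` cells are excluded with a warning.
    """
    labels = norm.labels if labels is None else labels.reindex(norm.values.columns)
    sizes = labels.value_counts()
    usable = [c for c in sizes.index if sizes[c] >= min_cells]
    skipped = [c for c in sizes.index if sizes[c] < min_cells]
    if skipped:
        logger.warning("cluster_markers: excluding small cluster(s): %s", skipped)
    if len(usable) < 2:
        raise ValueError("cluster_markers: need at least 2 clusters with enough cells")

    mat = norm.values.to_numpy()
    records = []
    label_arr = labels.to_numpy()
    in_any_usable = np.isin(label_arr, usable)
    for cluster in usable:
        mask_in = label_arr == cluster
        mask_out = in_any_usable & ~mask_in
        pvals = np.empty(mat.shape[0])
        for i in range(mat.shape[0]):
            x, y = mat[i, mask_in], mat[i, mask_out]
            if np.ptp(np.concatenate([x, y])) == 0.0:
                pvals[i] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals[i] = scipy.stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="auto"
                ).pvalue
        qvals = bh_adjust(pvals)
        for i, gene in enumerate(norm.values.index):
            x, y = mat[i, mask_in], mat[i, mask_out]
            lfc = _log2fc_expm1(x, y)
            records.append(
                {
                    "cluster": cluster,
                    "gene": gene,
                    "log2fc": lfc,
                    "pct_in": float((x > 0).mean()),
                    "pct_out": float((y > 0).mean()),
                    "pval": pvals[i],
                    "qval": qvals[i],
                    "significant": bool(abs(lfc) > lfc_min and qvals[i] < q_max),
                }
            )
    out = pd.DataFrame.from_records(records)
    out.attrs["lfc_min"] = lfc_min
    out.attrs["q_max"] = q_max
    return out


def dotplot_stats(
    norm: NormalizedCellMatrix,
    genes: list[str],
    labels: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Dot-plot summary: percent of expressing cells and z-scored mean expression.

    Returns a (cluster, gene) table with ``pct_expressing`` (percent of the
    cluster's cells with a positive value) and ``z_mean`` (the cluster mean
    normalized expression z-scored across clusters per gene), plus the list of
    requested genes absent from the matrix (skipped).
    """
    labels = norm.labels if labels is None else labels.reindex(norm.values.columns)
    known = [g for g in genes if g in norm.values.index]
    skipped = [g for g in genes if g not in norm.values.index]
    if skipped:
        logger.warning("dotplot_stats: unknown gene(s) skipped: %s", skipped)
    clusters = list(pd.unique(labels))
    pct = pd.DataFrame(index=known, columns=clusters, dtype=float)
    mean = pd.DataFrame(index=known, columns=clusters, dtype=float)
    for c in clusters:
        sub = norm.values.loc[known, labels[labels == c].index]
        pct[c] = (sub > 0).mean(axis=1) * 100.0
        mean[c] = sub.mean(axis=1)
    mu = mean.mean(axis=1)
    sd = mean.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = mean.sub(mu, axis=0).div(sd, axis=0)
    records = [
        {
            "cluster": c,
            "gene": g,
            "pct_expressing": pct.at[g, c],
            "z_mean": z.at[g, c],
        }
        for g in known
        for c in clusters
    ]
    return pd.DataFrame.from_records(records), skipped


@dataclass
class SignatureSet:
    """Named cell-type gene signatures over a stated gene universe."""

    signatures: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"signature {name!r} is empty")
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"signature {name!r} has genes outside the universe, e.g. "
                    f"{sorted(extra)[:3]}"
                )

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str]) -> "SignatureSet":
        sigs: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sigs[parts[0]] = {g for g in parts[2:] if g} & universe
        return cls(signatures=sigs, universe=universe)


def annotate_clusters(
    markers: pd.DataFrame,
    signatures: SignatureSet,
    top_n: int = 50,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of signatures in each cluster's markers.

    For each cluster the ``top_n`` significant markers (by p-value) are tested
    for overlap with each signature via the hypergeometric upper tail given
    the signature universe; q-values are BH-corrected across signatures within
    each cluster, and each cluster is labeled by its top enrichment.
    """
    universe = signatures.universe
    marker_genes = set(markers["gene"])
    if not marker_genes <= universe:
        raise ValueError("signature universe must contain every marker gene")
    M = len(universe)
    records = []
    for cluster, sub in markers.groupby("cluster", sort=False):
        top = (
            sub[sub["significant"]]
            .sort_values(["pval", "qval", "gene"])
            .head(top_n)["gene"]
            .tolist()
        )
        N = len(top)
        pvals, names, overlaps = [], [], []
        for name, sig in signatures.signatures.items():
            k = len(set(top) & sig)
            if N == 0 or k == 0:
                p = 1.0
            else:
                p = float(scipy.stats.hypergeom.sf(k - 1, M, len(sig), N))
            names.append(name)
            overlaps.append(k)
            pvals.append(p)
        qvals = bh_adjust(pvals)
        for name, k, p, q in zip(names, overlaps, pvals, qvals):
            records.append(
                {
                    "cluster": cluster,
                    "signature": name,
                    "overlap": k,
                    "n_markers": N,
                    "pval": p,
                    "qval": q,
                }
            )
    out = pd.DataFrame.from_records(records)
    out["top_hit"] = False
    for cluster, sub in out.groupby("cluster", sort=False):
        best = sub.sort_values(["qval", "pval", "signature"]).index[0]
        out.loc[best, "top_hit"] = True
    return out
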