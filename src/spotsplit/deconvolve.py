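"""Co-expression-module deconvolution of spatial spots into putative cells.

The algorithm proceeds in five stages:

1. binarize the gene x spot UMI matrix (1 iff count > 0);
2. gene-gene distances ``d = 1 - r`` where ``r`` is the Pearson correlation
   of the binary spot profiles (the phi coefficient); genes detected in too
   few spots, or in every spot, are excluded (their binary profile has no
   usable variance);
3. average-linkage hierarchical clustering of the distance matrix, cut at a
   fixed cophenetic height (default 1.5) to obtain gene modules;
4. per module, fit a negative binomial to the per-spot module UMI sums
   (method of moments, Poisson fallback when variance <= mean), call the
   module present in spots whose sum exceeds the fitted 85th percentile, and
   estimate cell counts as ``floor(sum / min present sum)``;
5. split each present (module, spot) sum into that many putative single
   cells by a seeded per-gene multinomial partition (exact count
   conservation) and place the cells uniformly in the spot footprint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.sparse as sp
import scipy.spatial.distance
import scipy.stats

from .spatial_io import GeneSpotMatrix, PutativeCellSet, SpotLayout

logger = logging.getLogger(__name__)


def binarize(matrix: GeneSpotMatrix | sp.spmatrix) -> sp.csr_matrix:
    """1 where the count is positive, 0 elsewhere (idempotent)."""
    counts = matrix.counts if isinstance(matrix, GeneSpotMatrix) else sp.csr_matrix(matrix)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("binarize: negative entries")
    out = counts.copy()
    out.data = (out.data > 0).astype(np.int8)
    out.eliminate_zeros()
    return sp.csr_matrix(out)


def gene_distance(
    binary: sp.spmatrix,
    gene_ids: list[str],
    min_prevalence: int = 3,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Pairwise ``1 - phi`` distances between binary gene profiles.

    Genes nonzero in fewer than ``min_prevalence`` spots are excluded as
    ``"low prevalence"``; genes nonzero in every spot as ``"zero variance"``
    (Pearson is undefined on a constant profile).  Returns the distance
    matrix, the retained gene ids and the exclusion list.
    """
    binary = sp.csr_matrix(binary)
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    n_genes, n_spots = binary.shape
    if n_genes != len(gene_ids):
        raise ValueError("gene_ids length disagrees with the matrix")
    prevalence = np.asarray((binary > 0).sum(axis=1)).ravel()
    excluded: list[tuple[str, str]] = []
    keep = np.ones(n_genes, dtype=bool)
    for i, g in enumerate(gene_ids):
        if prevalence[i] < min_prevalence:
            keep[i] = False
            excluded.append((g, "low prevalence"))
        elif prevalence[i] == n_spots:
            keep[i] = False
            excluded.append((g, "zero variance"))
    if keep.sum() < 2:
        raise ValueError("gene_distance: fewer than 2 retained genes")
    retained = [g for g, k in zip(gene_ids, keep) if k]
    profiles = binary[keep].toarray().astype(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist, retained, excluded


@dataclass
class GeneClusterSet:
    """Partition of retained genes into co-expression modules."""

    assignments: dict[str, str]  # gene -> module label
    excluded: list[tuple[str, str]]
    cut_height: float
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("GeneClusterSet: no genes assigned")

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, module in self.assignments.items():
            out.setdefault(module, []).append(gene)
        return out

    @property
    def singletons(self) -> list[str]:
        return [m for m, genes in self.modules.items() if len(genes) == 1]


def cluster_genes(
    dist: np.ndarray,
    gene_ids: list[str],
    cut_height: float = 1.5,
    linkage: str = "average",
    excluded: list[tuple[str, str]] | None = None,
) -> GeneClusterSet:
    """Agglomerative clustering of the gene distance matrix.

    The dendrogram is cut at cophenetic distance ``cut_height``; modules are
    labeled ``M1, M2, ...`` in decreasing size.  Singleton modules are allowed
    and reported via :attr:`GeneClusterSet.singletons`.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method=linkage)
    flat = scipy.cluster.hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    # stable module names: decreasing size, ties broken by first member order
    order: dict[int, int] = {}
    sizes = pd.Series(flat).value_counts()
    first_member = {c: int(np.argmax(flat == c)) for c in sizes.index}
    for rank, c in enumerate(
        sorted(sizes.index, key=lambda c: (-sizes[c], first_member[c])), start=1
    ):
        order[c] = rank
    assignments = {g: f"M{order[c]}" for g, c in zip(gene_ids, flat)}
    cs = GeneClusterSet(
        assignments=assignments,
        excluded=list(excluded or []),
        cut_height=cut_height,
        linkage=linkage,
    )
    if cs.singletons:
        logger.info("cluster_genes: %d singleton module(s)", len(cs.singletons))
    return cs


def module_spot_sums(matrix: GeneSpotMatrix, clusters: GeneClusterSet) -> pd.DataFrame:
    """Module x spot matrix of raw UMI sums over each module's genes."""
    modules = clusters.modules
    if not modules:
        raise ValueError("module_spot_sums: empty module set")
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in clusters.assignments if g not in gene_index]
    if missing:
        raise ValueError(f"module genes absent from matrix, e.g. {missing[:3]}")
    names = sorted(modules, key=lambda m: int(m[1:]) if m[1:].isdigit() else 0)
    rows = []
    for m in names:
        idx = [gene_index[g] for g in modules[m]]
        rows.append(np.asarray(matrix.counts[idx].sum(axis=0)).ravel())
    return pd.DataFrame(
        np.vstack(rows).astype(np.int64), index=names, columns=matrix.barcodes
    )


@dataclass(frozen=True)
class NBParams:
    """Negative binomial in (mean, dispersion) form: var = m + m^2/r."""

    mean: float
    dispersion: float  # inf => Poisson
    family: Literal["NB", "Poisson"]

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def fit_nb(values) -> NBParams:
    """Method-of-moments NB fit with Poisson fallback when variance <= mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("fit_nb: need at least 2 values")
    if (x < 0).any():
        raise ValueError("fit_nb: negative values")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if m == 0.0:
        logger.warning("fit_nb: degenerate all-zero sample; threshold will be 0")
        return NBParams(mean=0.0, dispersion=math.inf, family="Poisson")
    if v <= m:
        return NBParams(mean=m, dispersion=math.inf, family="Poisson")
    return NBParams(mean=m, dispersion=m * m / (v - m), family="NB")


def nb_quantile(params: NBParams, q: float) -> int:
    """Smallest integer k with CDF(k) >= q under the fitted family."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if params.mean == 0.0:
        return 0
    if params.family == "Poisson":
        dist = scipy.stats.poisson(mu=params.mean)
    else:
        r = params.dispersion
        dist = scipy.stats.nbinom(n=r, p=r / (r + params.mean))
    k = int(dist.ppf(q))
    # make the defining inequality exact with respect to the CDF
    while k > 0 and dist.cdf(k - 1) >= q:
        k -= 1
    while dist.cdf(k) < q:
        k += 1
    return k


@dataclass
class SpotDeconvolution:
    """Per-module presence thresholds, presence calls and cell counts."""

    module_sums: pd.DataFrame  # modules x spots (retained modules only)
    thresholds: pd.Series  # module -> integer threshold
    presence: pd.DataFrame  # modules x spots, bool
    min_sums: pd.Series  # module -> minimum UMI sum over present spots
    cell_counts: pd.DataFrame  # modules x spots, int
    percentile: float
    nb_params: dict[str, NBParams]
    dropped_modules: list[str] = field(default_factory=list)


def call_presence_and_counts(
    sums: pd.DataFrame,
    percentile: float = 0.85,
    rounding: Literal["floor", "half-up"] = "floor",
) -> SpotDeconvolution:
    """Call module presence per spot and estimate cell counts.

    Per module the NB is fitted over all per-spot sums (zeros included); the
    presence threshold is its ``percentile`` quantile, and presence requires
    the sum to exceed it strictly.  ``min_sum`` is the smallest sum among
    present spots, so present spots always yield at least one cell; modules
    present in no spot are dropped and reported.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    if rounding not in ("floor", "half-up"):
        raise ValueError("rounding must be 'floor' or 'half-up'")
    thresholds, min_sums, nb_params = {}, {}, {}
    presence = pd.DataFrame(False, index=sums.index, columns=sums.columns)
    counts = pd.DataFrame(0, index=sums.index, columns=sums.columns, dtype=np.int64)
    dropped: list[str] = []
    for m in sums.index:
        row = sums.loc[m].to_numpy()
        params = fit_nb(row)
        nb_params[m] = params
        thr = nb_quantile(params, percentile)
        thresholds[m] = thr
        present = row > thr
        if not present.any():
            dropped.append(m)
            continue
        min_sum = int(row[present].min())
        min_sums[m] = min_sum
        ratio = row[present] / min_sum
        if rounding == "floor":
            c = np.floor(ratio).astype(np.int64)
        else:
            c = np.floor(ratio + 0.5).astype(np.int64)
        presence.loc[m, present] = True
        counts.loc[m, present] = c
    if dropped:
        logger.info("call_presence_and_counts: dropped modules with no presence: %s", dropped)
    keep = [m for m in sums.index if m not in dropped]
    if not keep:
        raise ValueError("call_presence_and_counts: no module is present in any spot")
    return SpotDeconvolution(
        module_sums=sums.loc[keep],
        thresholds=pd.Series({m: thresholds[m] for m in keep}, dtype=np.int64),
        presence=presence.loc[keep],
        min_sums=pd.Series(min_sums, dtype=np.int64).loc[keep],
        cell_counts=counts.loc[keep],
        percentile=percentile,
        nb_params={m: nb_params[m] for m in keep},
        dropped_modules=dropped,
    )


def split_into_cells(
    matrix: GeneSpotMatrix,
    clusters: GeneClusterSet,
    deconv: SpotDeconvolution,
    layout: SpotLayout,
    seed: int,
) -> PutativeCellSet:
    """Split each present (module, spot) into its putative single cells.

    The spot's module gene counts are partitioned among the cells by a seeded
    equal-probability multinomial per gene, conserving counts exactly; each
    cell is placed uniformly at random in the disk of radius
    ``layout.spot_radius`` around its spot center.
    """
    missing = [b for b in matrix.barcodes if b not in set(layout.positions.index)]
    if missing:
        raise ValueError(f"layout missing barcodes, e.g. {missing[:3]}")
    rng = np.random.default_rng(seed)
    modules = clusters.modules
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    dense = matrix.counts.tocsc()

    cell_ids: list[str] = []
    cell_clusters: list[str] = []
    cell_barcodes: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []

    counter = 0
    for s_idx, barcode in enumerate(matrix.barcodes):
        spot_col = dense[:, s_idx].toarray().ravel()
        cx = float(layout.positions.at[barcode, "x"])
        cy = float(layout.positions.at[barcode, "y"])
        for m in deconv.cell_counts.index:
            n = int(deconv.cell_counts.at[m, barcode])
            if n == 0:
                continue
            gidx = [gene_index[g] for g in modules[m]]
            first_cell = len(cell_ids)
            for _ in range(n):
                cell_ids.append(f"cell-{counter:06d}")
                cell_clusters.append(m)
                cell_barcodes.append(barcode)
                rho = layout.spot_radius * math.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                xs.append(cx + rho * math.cos(theta))
                ys.append(cy + rho * math.sin(theta))
                counter += 1
            for g in gidx:
                total = int(spot_col[g])
                if total == 0:
                    continue
                if n == 1:
                    shares = np.array([total])
                else:
                    shares = rng.multinomial(total, np.full(n, 1.0 / n))
                for j, v in enumerate(shares):
                    if v:
                        rows.append(g)
                        cols.append(first_cell + j)
                        vals.append(int(v))

    if not cell_ids:
        raise ValueError("split_into_cells: no cells to create")
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(matrix.n_genes, len(cell_ids)), dtype=np.int64
    ).tocsr()
    return PutativeCellSet(
        cell_ids=cell_ids,
        clusters=cell_clusters,
        source_barcodes=cell_barcodes,
        x=np.array(xs),
        y=np.array(ys),
        counts=counts,
        gene_ids=list(matrix.gene_ids),
    )


def assigned_matrix(cells: PutativeCellSet, barcodes: list[str]) -> sp.csr_matrix:
    """Genes x spots matrix of counts assigned to cells (for conservation checks)."""
    col = {b: i for i, b in enumerate(barcodes)}
    indicator = sp.coo_matrix(
        (
            np.ones(cells.n_cells),
            (np.arange(cells.n_cells), [col[b] for b in cells.source_barcodes]),
        ),
        shape=(cells.n_cells, len(barcodes)),
    )
    return sp.csr_matrix(cells.counts @ indicator).astype(np.int64)


@dataclass(frozen=True)
class DeconvolutionConfig:
    cut_height: float = 1.5
    percentile: float = 0.85
    min_prevalence: int = 3
    linkage: str = "average"
    rounding: Literal["floor", "half-up"] = "floor"
    seed: int = 0


@dataclass
class DeconvolutionResult:
    cells: PutativeCellSet
    deconv: SpotDeconvolution
    clusters: GeneClusterSet
    report: dict


def run_deconvolution(
    matrix: GeneSpotMatrix,
    layout: SpotLayout,
    config: DeconvolutionConfig = DeconvolutionConfig(),
) -> DeconvolutionResult:
    """Run the full pipeline: binarize, cluster genes, threshold, split.

    Fully deterministic given ``config.seed``.  The report records gene
    exclusions, module sizes, dropped modules and the count mass that was not
    assigned to any cell (excluded genes, and module counts in spots where the
    module was not called present).
    """
    if matrix.counts.nnz == 0:
        raise ValueError("run_deconvolution: empty count matrix")
    binary = binarize(matrix)
    dist, retained, excluded = gene_distance(
        binary, matrix.gene_ids, min_prevalence=config.min_prevalence
    )
    clusters = cluster_genes(
        dist,
        retained,
        cut_height=config.cut_height,
        linkage=config.linkage,
        excluded=excluded,
    )
    sums = module_spot_sums(matrix, clusters)
    deconv = call_presence_and_counts(
        sums, percentile=config.percentile, rounding=config.rounding
    )
    cells = split_into_cells(matrix, clusters, deconv, layout, seed=config.seed)
    assigned = assigned_matrix(cells, matrix.barcodes)
    unassigned = int(matrix.counts.sum() - assigned.sum())
    report = {
        "seed": config.seed,
        "n_genes": matrix.n_genes,
        "n_spots": matrix.n_spots,
        "n_cells": cells.n_cells,
        "excluded_genes": excluded,
        "module_sizes": {m: len(g) for m, g in clusters.modules.items()},
        "dropped_modules": deconv.dropped_modules,
        "total_counts": int(matrix.counts.sum()),
        "assigned_counts": int(assigned.sum()),
        "unassigned_counts": unassigned,
    }
    return DeconvolutionResult(cells=cells, deconv=deconv, clusters=clusters, report=report)
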