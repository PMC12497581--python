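"""Synthetic data with ground truth for every pipeline stage.

Three generators emulate the study designs the pipeline targets, so that
recovery can be scored against a known truth without any external download:

* :func:`generate_spatial` — Visium-like spot matrices.  Cells of ``n_types``
  cell types are mixed into spots (1-10 cells each in realistic settings);
  each type expresses its own gene module with negative-binomial counts, all
  other genes at a low background rate.  The default configuration loosely
  mirrors a placenta-like tissue with one dominant cell type (80% of cells,
  emulating the erythroid compartment) and four minor types.
* :func:`generate_bulk` — an nCounter-style probe panel (endogenous +
  housekeeping + positive/negative controls) with per-sample lane effects and
  a known set of spiked differentially expressed genes.
* :func:`generate_secretome` — a multiplex cytokine panel with log-normal
  concentrations and known shifted analytes.

All negative-binomial draws use the (mean ``m``, dispersion ``r``)
parameterization with variance ``m + m^2/r`` (Poisson in the limit r -> inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bulk import BulkExpressionTable, SecretomePanel
from .spatial_io import GeneSpotMatrix, SpotLayout


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """NB(mean, dispersion) draws; mean 0 yields exact zeros."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


@dataclass(frozen=True)
class SpatialSimConfig:
    """Study conditions for the spatial simulator.

    Defaults: 5 cell types with proportions (0.8, 0.05, 0.05, 0.05, 0.05),
    500 spots of 2-8 cells, 20 genes per type module plus 40 background genes,
    module genes at 4 mean UMI per cell (dispersion 2), background 0.05 UMI.
    """

    n_types: int = 5
    genes_per_module: int = 20
    n_background_genes: int = 40
    n_spots: int = 500
    cells_per_spot_range: tuple[int, int] = (2, 8)
    type_proportions: tuple[float, ...] = (0.80, 0.05, 0.05, 0.05, 0.05)
    expr_mean: float = 4.0
    nb_dispersion: float = 2.0
    background_rate: float = 0.05
    spot_pitch: float = 100.0
    spot_radius: float = 27.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cells_per_spot_range
        if self.n_types < 1:
            raise ValueError("n_types must be a positive integer")
        if self.genes_per_module < 1:
            raise ValueError("genes_per_module must be a positive integer")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be nonnegative")
        if self.n_spots < 1:
            raise ValueError("n_spots must be a positive integer")
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_spot_range must satisfy 1 <= lo <= hi")
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        props = np.asarray(self.type_proportions, dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must be nonnegative and sum to 1")
        if self.expr_mean <= 0:
            raise ValueError("expr_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.spot_pitch <= 0:
            raise ValueError("spot_pitch must be positive")
        if not 0 < self.spot_radius < self.spot_pitch / 2:
            raise ValueError("spot_radius must lie in (0, spot_pitch/2)")


@dataclass
class SyntheticTruth:
    """Ground truth of a spatial simulation.

    ``cell_gene_counts`` retains every per-cell draw (cells x genes) so exact
    count conservation can be asserted downstream.
    """

    gene_module: dict[str, str | None]
    spot_composition: pd.DataFrame  # spots x types, integer cell counts
    cell_assignments: pd.DataFrame  # cell_id, type, spot
    cell_gene_counts: sp.csr_matrix
    type_names: list[str] = field(default_factory=list)


def generate_spatial(
    config: SpatialSimConfig,
) -> tuple[GeneSpotMatrix, SpotLayout, SyntheticTruth]:
    """Simulate a Visium-like dataset on a hexagonal-offset spot grid."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cells_per_spot_range

    type_names = [f"T{t}" for t in range(config.n_types)]
    gene_ids: list[str] = []
    gene_module: dict[str, str | None] = {}
    for t, name in enumerate(type_names):
        for g in range(config.genes_per_module):
            gid = f"{name}_g{g:02d}"
            gene_ids.append(gid)
            gene_module[gid] = name
    for g in range(config.n_background_genes):
        gid = f"BG_g{g:02d}"
        gene_ids.append(gid)
        gene_module[gid] = None
    n_genes = len(gene_ids)

    barcodes = [f"SPOT-{i:05d}" for i in range(config.n_spots)]
    layout = _hex_layout(barcodes, config.spot_pitch, config.spot_radius)

    n_cells_per_spot = rng.integers(lo, hi + 1, size=config.n_spots)
    total_cells = int(n_cells_per_spot.sum())
    cell_types = rng.choice(
        config.n_types, size=total_cells, p=np.asarray(config.type_proportions)
    )
    cell_spot = np.repeat(np.arange(config.n_spots), n_cells_per_spot)

    means = np.full((total_cells, n_genes), config.background_rate, dtype=float)
    for t in range(config.n_types):
        rows = cell_types == t
        start = t * config.genes_per_module
        means[np.ix_(rows, range(start, start + config.genes_per_module))] = config.expr_mean
    cell_counts = _nb_draw(rng, means, config.nb_dispersion)

    spot_counts = np.zeros((n_genes, config.n_spots), dtype=np.int64)
    np.add.at(spot_counts.T, cell_spot, cell_counts)

    composition = np.zeros((config.n_spots, config.n_types), dtype=np.int64)
    np.add.at(composition, (cell_spot, cell_types), 1)
    truth = SyntheticTruth(
        gene_module=gene_module,
        spot_composition=pd.DataFrame(composition, index=barcodes, columns=type_names),
        cell_assignments=pd.DataFrame(
            {
                "cell_id": [f"truthcell-{i:06d}" for i in range(total_cells)],
                "type": [type_names[t] for t in cell_types],
                "spot": [barcodes[s] for s in cell_spot],
            }
        ),
        cell_gene_counts=sp.csr_matrix(cell_counts),
        type_names=type_names,
    )
    matrix = GeneSpotMatrix(
        counts=sp.csr_matrix(spot_counts), gene_ids=gene_ids, barcodes=barcodes
    )
    return matrix, layout, truth


def _hex_layout(barcodes: Sequence[str], pitch: float, radius: float) -> SpotLayout:
    n = len(barcodes)
    n_cols = max(1, math.ceil(math.sqrt(n)))
    rows, cols, xs, ys = [], [], [], []
    for i in range(n):
        r, c = divmod(i, n_cols)
        rows.append(r)
        cols.append(c)
        xs.append(pitch * (c + 0.5 * (r % 2)))
        ys.append(pitch * (math.sqrt(3) / 2) * r)
    positions = pd.DataFrame(
        {
            "in_tissue": 1,
            "array_row": rows,
            "array_col": cols,
            "x": xs,
            "y": ys,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return SpotLayout(positions=positions, spot_radius=radius)


@dataclass(frozen=True)
class BulkSimConfig:
    """Study conditions for the probe-panel simulator.

    The panel layout mirrors a mouse immunology nCounter panel scaled down to
    200 endogenous probes, with 15 housekeeping, 6 positive-control and
    8 negative-control probes; per-sample lane effects are log-normal.
    """

    n_genes: int = 200
    n_housekeeping: int = 15
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_samples_per_group: int = 5
    n_de_genes: int = 10
    de_log2fc: float = 2.0
    baseline_mean: float = 500.0
    nb_dispersion: float = 500.0
    lane_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_housekeeping", "n_pos_controls", "n_neg_controls",
                     "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must satisfy 0 <= n_de_genes <= n_genes")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class BulkTruth:
    de_genes: list[str]
    de_log2fc: float
    lane_factors: pd.Series


def generate_bulk(config: BulkSimConfig) -> tuple[BulkExpressionTable, BulkTruth]:
    """Simulate a two-group probe-count panel with spiked fold changes.

    Group B means of the true DE genes are the group A means multiplied by
    ``2**de_log2fc``; positive controls share a fixed ladder of means across
    samples up to the lane effect; negative controls sit near zero;
    housekeeping probes are never differential.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    endo = [f"Gene{g:03d}" for g in range(config.n_genes)]
    hk = [f"HK{h:02d}" for h in range(config.n_housekeeping)]
    pos = [f"POS_{chr(ord('A') + i)}" for i in range(config.n_pos_controls)]
    neg = [f"NEG_{chr(ord('A') + i)}" for i in range(config.n_neg_controls)]
    genes = endo + hk + pos + neg
    classes = pd.Series(
        ["endogenous"] * len(endo)
        + ["housekeeping"] * len(hk)
        + ["positive"] * len(pos)
        + ["negative"] * len(neg),
        index=genes,
        name="probe_class",
    )

    n = config.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=samples, name="group")

    endo_means = config.baseline_mean * rng.lognormal(0.0, 0.5, size=config.n_genes)
    hk_means = np.full(config.n_housekeeping, 2.0 * config.baseline_mean)
    pos_means = config.baseline_mean * (2.0 ** np.arange(5, 5 - config.n_pos_controls, -1))
    neg_means = np.full(config.n_neg_controls, 0.5)
    base = np.concatenate([endo_means, hk_means, pos_means, neg_means])

    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    de_genes = [endo[i] for i in sorted(de_idx)]

    mean_matrix = np.tile(base[:, None], (1, 2 * n))
    mean_matrix[sorted(de_idx), n:] *= 2.0 ** config.de_log2fc
    lane = rng.lognormal(0.0, config.lane_sd, size=2 * n)
    counts = _nb_draw(rng, mean_matrix * lane[None, :], config.nb_dispersion)

    table = BulkExpressionTable(
        values=pd.DataFrame(counts, index=genes, columns=samples, dtype=float),
        probe_class=classes,
        groups=groups,
    )
    truth = BulkTruth(
        de_genes=de_genes,
        de_log2fc=config.de_log2fc,
        lane_factors=pd.Series(lane, index=samples),
    )
    return table, truth


@dataclass
class SecretomeTruth:
    diff_analytes: list[str]
    log2fc: float


def generate_secretome(
    n_analytes: int = 13,
    n_per_group: int = 4,
    diff_analytes: Iterable[int | str] = (),
    log2fc: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.15,
) -> tuple[SecretomePanel, SecretomeTruth]:
    """Simulate a multiplex cytokine panel with log-normal concentrations.

    ``diff_analytes`` (names or indices) get their group-B log2 concentration
    shifted by ``log2fc``; ``noise_sd`` is the within-group standard deviation
    on the log2 scale.
    """
    if n_analytes < 1:
        raise ValueError("n_analytes must be positive")
    if n_per_group < 1:
        raise ValueError("each group needs at least one sample")
    analytes = [f"Cytokine{i + 1:02d}" for i in range(n_analytes)]
    diff: list[str] = []
    for a in diff_analytes:
        name = analytes[a] if isinstance(a, (int, np.integer)) else str(a)
        if name not in analytes:
            raise ValueError(f"unknown analyte {name!r}")
        diff.append(name)

    rng = np.random.default_rng(seed)
    base_log2 = rng.uniform(5.0, 10.0, size=n_analytes)
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)

    log2conc = np.tile(base_log2[:, None], (1, 2 * n_per_group))
    shift_rows = [analytes.index(a) for a in diff]
    log2conc[shift_rows, n_per_group:] += log2fc
    log2conc = log2conc + rng.normal(0.0, noise_sd, size=log2conc.shape)

    panel = SecretomePanel(
        concentrations=pd.DataFrame(2.0 ** log2conc, index=analytes, columns=samples),
        groups=groups,
    )
    return panel, SecretomeTruth(diff_analytes=diff, log2fc=log2fc)
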