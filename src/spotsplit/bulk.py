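"""Bulk-omics statistics for immune expression panels and secretome assays.

Covers four stages used around the spatial pipeline:

* nCounter-style two-step lane normalization (positive controls, then
  housekeeping genes) and the median-threshold expressed-gene filter;
* DESeq-style median-of-ratios size factors with a Welch-test differential
  expression stage (thresholds ``|log2FC| > 1`` and ``q < 0.001``);
* multiplex secretome differential tests (``|log2FC| > 2``, ``q < 0.01``);
* cross-species pseudobulk comparison (symbol mapping, joint normalization,
  per-gene z-scoring, pairwise R^2).

The differential-expression stage is deliberately a transparent
normalize + Welch + BH pipeline rather than a negative-binomial GLM; it keeps
the same interface and decision thresholds, and the trade-off is documented in
``docs/methods.md``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .multitest import bh_adjust

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")

#: Housekeeping probes of the mouse immunology nCounter panel.
MOUSE_IMMUNOLOGY_HOUSEKEEPING = (
    "Alas1", "Gusb", "Oaz1", "Polr2a", "Ppia", "Rpl19", "Sdha",
)


@dataclass
class BulkExpressionTable:
    """Genes x samples expression values with probe classes and group labels."""

    values: pd.DataFrame  # genes x samples, nonnegative reals
    probe_class: pd.Series  # gene -> endogenous|housekeeping|positive|negative
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        self.probe_class = self.probe_class.reindex(self.values.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class.index[self.probe_class.isna()])[:3]
            raise ValueError(f"probe_class missing for genes, e.g. {missing}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("group label missing for some samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    def subset_class(self, cls: str) -> pd.DataFrame:
        return self.values.loc[self.probe_class == cls]

    def with_values(self, values: pd.DataFrame) -> "BulkExpressionTable":
        return BulkExpressionTable(
            values=values,
            probe_class=self.probe_class.loc[values.index],
            groups=self.groups,
        )


@dataclass
class SecretomePanel:
    """Analytes x samples concentrations (pg/mL) with group labels."""

    concentrations: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.concentrations.columns)
        if self.groups.isna().any():
            raise ValueError("group label missing for some samples")
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("concentrations must be nonnegative")


@dataclass
class NanoStringNormalization:
    table: BulkExpressionTable
    pos_factors: pd.Series
    hk_factors: pd.Series


def _geomean_columns(df: pd.DataFrame, what: str) -> pd.Series:
    vals = df.to_numpy(float)
    if (vals <= 0).any():
        sample = df.columns[np.argwhere(vals <= 0)[0][1]]
        raise ValueError(
            f"nanostring_normalize: {what} probes contain a zero/negative value in "
            f"sample {sample!r}; geometric mean undefined"
        )
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=df.columns)


def nanostring_normalize(
    table: BulkExpressionTable, center: str = "arithmetic"
) -> NanoStringNormalization:
    """Two-step lane normalization against positive controls then housekeeping.

    For each step the per-sample factor is the mean over samples of the
    per-sample geometric mean of the control probes, divided by that sample's
    geometric mean; both factors are applied multiplicatively to every probe.
    ``center`` selects how the per-sample geometric means are averaged
    (``"arithmetic"``, the vendor default, or ``"geometric"``).
    """
    if center not in ("arithmetic", "geometric"):
        raise ValueError("center must be 'arithmetic' or 'geometric'")

    def _factors(df: pd.DataFrame, what: str) -> pd.Series:
        gm = _geomean_columns(df, what)
        grand = gm.mean() if center == "arithmetic" else np.exp(np.log(gm).mean())
        return grand / gm

    pos = table.subset_class("positive")
    if pos.empty:
        raise ValueError("nanostring_normalize: no positive-control probes")
    hk = table.subset_class("housekeeping")
    if hk.empty:
        raise ValueError("nanostring_normalize: no housekeeping probes")

    pos_factors = _factors(pos, "positive-control")
    after_pos = table.values.mul(pos_factors, axis=1)
    hk_factors = _factors(after_pos.loc[table.probe_class == "housekeeping"], "housekeeping")
    normalized = after_pos.mul(hk_factors, axis=1)
    return NanoStringNormalization(
        table=table.with_values(normalized),
        pos_factors=pos_factors,
        hk_factors=hk_factors,
    )


def filter_expressed(table: BulkExpressionTable) -> tuple[BulkExpressionTable, float]:
    """Drop endogenous genes below the global median expression in all samples.

    The threshold is the median of log2(x+1)-transformed endogenous values; a
    gene is removed only when every one of its samples is strictly below it.
    Control probes are untouched.  Returns the filtered table (original scale)
    and the threshold (log2 scale).
    """
    endo = table.subset_class("endogenous")
    if endo.empty:
        raise ValueError("filter_expressed: no endogenous genes")
    log = np.log2(endo.to_numpy(float) + 1.0)
    threshold = float(np.median(log))
    keep_endo = (log >= threshold).any(axis=1)
    keep_genes = [
        g
        for g in table.values.index
        if table.probe_class[g] != "endogenous" or keep_endo[endo.index.get_loc(g)]
    ]
    return table.with_values(table.values.loc[keep_genes]), threshold


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample size factors.

    Reference genes are those with a positive count in every sample; the
    factor of sample *s* is the median over reference genes of
    ``count(g, s) / geometric_mean_over_samples(count(g, .))``.
    """
    vals = counts.to_numpy(float)
    ref = (vals > 0).all(axis=1)
    if not ref.any():
        raise ValueError("size_factors: no gene has nonzero counts in every sample")
    refvals = vals[ref]
    log_geomean = np.log(refvals).mean(axis=1, keepdims=True)
    ratios = refvals / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample p; degenerate zero-variance pairs resolve by the means."""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)


def _two_groups(groups: pd.Series) -> tuple[str, str]:
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    return labels[0], labels[1]


def _group_test(
    log_values: pd.DataFrame,
    groups: pd.Series,
    lfc_min: float,
    q_max: float,
) -> pd.DataFrame:
    """Per-row Welch test of group2 vs group1 on already-log2 values."""
    g1, g2 = _two_groups(groups)
    cols1 = groups.index[groups == g1]
    cols2 = groups.index[groups == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = log_values[cols1].to_numpy(float)
    b = log_values[cols2].to_numpy(float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    pvals = np.array([_welch(a[i], b[i]) for i in range(a.shape[0])])
    qvals = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "pval": pvals,
            "qval": qvals,
            "significant": (np.abs(lfc) > lfc_min) & (qvals < q_max),
        },
        index=log_values.index,
    )
    out.attrs["lfc_min"] = lfc_min
    out.attrs["q_max"] = q_max
    out.attrs["comparison"] = f"{g2} vs {g1}"
    return out


def differential_expression(
    table: BulkExpressionTable | pd.DataFrame,
    groups: pd.Series | None = None,
    lfc_min: float = 1.0,
    q_max: float = 0.001,
) -> pd.DataFrame:
    """Size-factor-normalized Welch differential expression with BH correction.

    Counts are scaled by median-of-ratios size factors, log2(x+1)-transformed
    and tested per gene (second group vs first, in sorted label order);
    a gene is flagged when ``|log2FC| > lfc_min`` and ``q < q_max``.  When a
    :class:`BulkExpressionTable` is passed, only endogenous probes are tested.
    """
    if isinstance(table, BulkExpressionTable):
        counts = table.subset_class("endogenous")
        groups = table.groups if groups is None else groups
    else:
        counts = table
    if groups is None:
        raise ValueError("groups required when passing a bare DataFrame")
    factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    return _group_test(np.log2(norm + 1.0), groups, lfc_min, q_max)


def secretome_test(
    panel: SecretomePanel, lfc_min: float = 2.0, q_max: float = 0.01
) -> pd.DataFrame:
    """Per-analyte Welch tests on log2(x+1) concentrations with BH correction."""
    conc = panel.concentrations
    nonzero = conc.sum(axis=1) > 0
    if (~nonzero).any():
        logger.warning(
            "secretome_test: excluding all-zero analytes: %s",
            list(conc.index[~nonzero]),
        )
    conc = conc.loc[nonzero]
    if conc.empty:
        raise ValueError("secretome_test: no nonzero analytes")
    return _group_test(np.log2(conc + 1.0), panel.groups, lfc_min, q_max)


def default_mouse_to_human(symbol: str) -> str:
    return symbol.upper()


@dataclass
class CrossSpeciesResult:
    zscores: pd.DataFrame  # shared genes x all samples
    r_squared: pd.DataFrame  # samples x samples
    dropped_genes: list[str] = field(default_factory=list)


def pseudobulk(counts: pd.DataFrame, sample_labels: pd.Series) -> pd.DataFrame:
    """Aggregate a cells x genes UMI table to genes x samples pseudobulk sums."""
    labels = pd.Series(sample_labels, index=counts.index)
    return counts.groupby(labels).sum().T


def crossspecies_compare(
    mouse: pd.DataFrame,
    human_cells: pd.DataFrame,
    human_samples: pd.Series,
    name_map: Mapping[str, str] | None = None,
    r2_on: str = "zscore",
) -> CrossSpeciesResult:
    """Compare mouse bulk profiles with human single-cell pseudobulk profiles.

    Human counts (cells x genes) are aggregated per sample; mouse symbols are
    mapped to human (explicit ``name_map`` entries override the default
    uppercase rule); the shared genes are jointly size-factor normalized,
    log2(x+1) transformed and z-scored per gene across all samples; ``r2`` is
    the squared Pearson correlation between sample profiles, computed on the
    z-scored matrix by default (``r2_on="log"`` uses the log2 matrix).
    """
    if r2_on not in ("zscore", "log"):
        raise ValueError("r2_on must be 'zscore' or 'log'")
    human_bulk = pseudobulk(human_cells, human_samples)

    name_map = dict(name_map or {})
    mapped = pd.Index([name_map.get(g, default_mouse_to_human(g)) for g in mouse.index])
    if mapped.has_duplicates:
        dup = mapped[mapped.duplicated()][0]
        raise ValueError(f"crossspecies_compare: mapped symbol {dup!r} is not unique")
    mouse_mapped = mouse.set_axis(mapped, axis=0)

    shared = mouse_mapped.index.intersection(human_bulk.index)
    dropped = [g for g in mouse_mapped.index if g not in shared]
    if dropped:
        logger.info("crossspecies_compare: %d mouse genes without a human match", len(dropped))
    if shared.empty:
        raise ValueError("crossspecies_compare: no shared genes after mapping")

    joint = pd.concat([mouse_mapped.loc[shared], human_bulk.loc[shared]], axis=1)
    factors = size_factors(joint)
    log = np.log2(joint.div(factors, axis=1) + 1.0)
    mu = log.mean(axis=1)
    sd = log.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = log.sub(mu, axis=0).div(sd, axis=0)
    basis = z if r2_on == "zscore" else log
    r2 = basis.corr(method="pearson") ** 2
    return CrossSpeciesResult(zscores=z, r_squared=r2, dropped_genes=dropped)
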