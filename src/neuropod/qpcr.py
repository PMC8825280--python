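"""Single-cell RT-qPCR processing.

Implements the Biomark-style pipeline: per-well quality control (threshold
0.65) and housekeeping-gene exclusion, relative quantification
RQ = 2^(Cq_cutoff - Cq) with a Cq cutoff of 34 and an RQ of 0.5 for
undetected wells, per-gene z-scoring of log2 quantities, two-group
differential expression with Benjamini-Hochberg q-values, and
receptor-coexpression classification (e.g. Slc5a1 x Tas1r3) summarized per
mouse as mean +- s.e.m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CqMatrix",
    "RQMatrix",
    "ReceptorClassSummary",
    "HOUSEKEEPING_GENES",
    "quality_filter",
    "cq_to_rq",
    "rq_matrix",
    "normalize_per_gene",
    "differential_expression",
    "classify_receptors",
]

HOUSEKEEPING_GENES = ("Gapdh", "Actb1")
DEFAULT_CQ_CUTOFF = 34.0
UNDETECTED_RQ = 0.5
DEFAULT_QUALITY_THRESHOLD = 0.65


@dataclass
class CqMatrix:
    """Cells x genes quantification-cycle values with per-well quality.

    ``cq`` holds the Cq value where the transcript was detected and NaN where
    it was not; ``quality`` holds the instrument's 0-1 per-well quality score;
    ``metadata`` (indexed like ``cq``) carries at least ``group`` and, for
    multi-animal summaries, ``mouse_id``.
    """

    cq: pd.DataFrame
    quality: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if self.cq.shape != self.quality.shape:
            raise ValueError("cq and quality matrices must have the same shape")
        if not self.cq.index.equals(self.metadata.index):
            raise ValueError("metadata index must match the cell index")
        q = self.quality.to_numpy(dtype=float)
        if np.nanmin(q, initial=1.0) < 0 or np.nanmax(q, initial=0.0) > 1:
            raise ValueError("quality scores must lie in [0, 1]")

    @property
    def genes(self) -> list:
        return list(self.cq.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.cq.notna()


@dataclass
class RQMatrix:
    """Linear relative quantities with provenance of undetected substitutions."""

    linear: pd.DataFrame
    substituted: pd.DataFrame  # True where the 0.5 floor replaced an undetected well
    metadata: pd.DataFrame
    cq_cutoff: float = DEFAULT_CQ_CUTOFF

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.linear)


@dataclass(frozen=True)
class ReceptorClassSummary:
    """Per-mouse receptor-coexpression percentages and their across-mice summary."""

    gene_a: str
    gene_b: str
    per_cell: pd.Series  # cell -> class label
    per_mouse_pct: pd.DataFrame  # mouse x {neither, a_only, b_only, both}
    mean_pct: pd.Series
    sem_pct: pd.Series | None  # None with a single mouse


def quality_filter(
    m: CqMatrix,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    housekeeping: tuple = HOUSEKEEPING_GENES,
) -> tuple[CqMatrix, pd.DataFrame]:
    """Apply per-well quality control and housekeeping-gene exclusion.

    Wells with quality below ``quality_threshold`` are set to undetected;
    cells with no detected transcript for *either* housekeeping gene are then
    dropped.  Returns the filtered matrix and a report listing each dropped
    cell with its reason.  The operation is idempotent.
    """
    if m.cq.empty:
        raise ValueError("empty Cq matrix")
    missing = [g for g in housekeeping if g not in m.cq.columns]
    if missing:
        raise ValueError(f"housekeeping genes absent from the panel: {missing}")
    cq = m.cq.where(m.quality >= quality_threshold)
    hk_ok = cq[list(housekeeping)].notna().any(axis=1)
    dropped = cq.index[~hk_ok]
    report = pd.DataFrame(
        {"cell": dropped, "reason": ["no detected housekeeping gene"] * len(dropped)}
    )
    filtered = CqMatrix(
        cq=cq.loc[hk_ok].copy(),
        quality=m.quality.loc[hk_ok].copy(),
        metadata=m.metadata.loc[hk_ok].copy(),
    )
    return filtered, report


def cq_to_rq(cq, cq_cutoff: float = DEFAULT_CQ_CUTOFF):
    """RQ = 2^(cutoff - Cq); undetected wells (NaN) map to 0.5.

    Accepts scalars or array-likes; NaN encodes "no detectable transcript".
    Cq values above the cutoff simply yield RQ < 1.
    """
    arr = np.asarray(cq, dtype=float)
    rq = np.where(np.isnan(arr), UNDETECTED_RQ, np.power(2.0, cq_cutoff - arr))
    if np.ndim(cq) == 0:
        return float(rq)
    return rq


def rq_matrix(m: CqMatrix, cq_cutoff: float = DEFAULT_CQ_CUTOFF) -> RQMatrix:
    """Convert a (quality-filtered) Cq matrix to relative quantities."""
    substituted = m.cq.isna()
    linear = pd.DataFrame(
        cq_to_rq(m.cq.to_numpy(), cq_cutoff), index=m.cq.index, columns=m.cq.columns
    )
    return RQMatrix(linear=linear, substituted=substituted,
                    metadata=m.metadata.copy(), cq_cutoff=cq_cutoff)


def normalize_per_gene(log2_rq: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score each gene column to mean 0, s.d. 1 (population s.d., ddof=0).

    Zero-variance genes are returned as all-zero columns with a warning.
    """
    if log2_rq.shape[0] < 2:
        raise ValueError("need at least two cells per gene to normalize")
    mean = log2_rq.mean(axis=0)
    sd = log2_rq.std(axis=0, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance genes set to zero columns: {list(log2_rq.columns[flat])}",
            stacklevel=2,
        )
    z = (log2_rq - mean) / sd.replace(0, np.nan)
    return z.fillna(0.0)


def differential_expression(
    rq: RQMatrix,
    groups: tuple | None = None,
    group_col: str = "group",
    q_cutoff: float = 0.05,
    equal_var: bool = False,
    fold_change_basis: str = "linear",
) -> pd.DataFrame:
    """Two-group differential expression on log2 relative quantities.

    Per gene: a two-tailed two-sample t-test (Welch by default) on log2 RQ,
    Benjamini-Hochberg q-values across the panel, and a fold change defined as
    the ratio of group means of *linear* RQ (group 1 / group 2); with
    ``fold_change_basis='log2'`` the fold change is 2^(difference of log2
    means) instead.  Genes with q <= ``q_cutoff`` are flagged significant.
    Genes that are constant and identical in both groups get p = 1.
    """
    labels = rq.metadata[group_col]
    if groups is None:
        uniq = list(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly two groups, found {uniq}")
        groups = tuple(uniq)
    g1 = rq.linear.loc[labels == groups[0]]
    g2 = rq.linear.loc[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least two cells in each group")
    log1, log2_ = np.log2(g1.to_numpy()), np.log2(g2.to_numpy())
    t, p = stats.ttest_ind(log1, log2_, axis=0, equal_var=equal_var)
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if fold_change_basis == "linear":
        fc = g1.mean(axis=0) / g2.mean(axis=0)
    elif fold_change_basis == "log2":
        fc = np.power(2.0, log1.mean(axis=0) - log2_.mean(axis=0))
    else:
        raise ValueError(f"unknown fold_change_basis {fold_change_basis!r}")
    out = pd.DataFrame(
        {
            "fold_change": np.asarray(fc, dtype=float),
            "t": t,
            "p_value": p,
            "q_value": q,
            "significant": q <= q_cutoff,
        },
        index=rq.linear.columns,
    )
    out.attrs["groups"] = groups
    return out


def classify_receptors(
    m: CqMatrix,
    gene_a: str = "Slc5a1",
    gene_b: str = "Tas1r3",
    mouse_col: str = "mouse_id",
) -> ReceptorClassSummary:
    """Classify each cell by detected expression of two receptor transcripts.

    A gene counts as expressed iff its transcript was detected (post-QC); the
    0.5 RQ substitution marks non-expression.  Class percentages are computed
    within each mouse and summarized across mice as mean +- s.e.m. (s.e.m. is
    undefined, and reported as None, with a single mouse).
    """
    for g in (gene_a, gene_b):
        if g not in m.cq.columns:
            raise ValueError(f"gene {g!r} not in the panel")
    if mouse_col not in m.metadata.columns:
        raise ValueError(f"metadata lacks a {mouse_col!r} column")
    a = m.cq[gene_a].notna()
    b = m.cq[gene_b].notna()
    labels = np.select(
        [a & b, a & ~b, ~a & b], ["both", "a_only", "b_only"], default="neither"
    )
    per_cell = pd.Series(labels, index=m.cq.index, name="receptor_class")
    order = ["neither", "a_only", "b_only", "both"]
    counts = (
        pd.crosstab(m.metadata[mouse_col], per_cell)
        .reindex(columns=order, fill_value=0)
    )
    per_mouse_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    mean_pct = per_mouse_pct.mean(axis=0)
    n_mice = per_mouse_pct.shape[0]
    sem_pct = per_mouse_pct.std(axis=0, ddof=1) / np.sqrt(n_mice) if n_mice > 1 else None
    return ReceptorClassSummary(
        gene_a=gene_a,
        gene_b=gene_b,
        per_cell=per_cell,
        per_mouse_pct=per_mouse_pct,
        mean_pct=mean_pct,
        sem_pct=sem_pct,
    )
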