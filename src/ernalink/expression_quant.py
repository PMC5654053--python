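"""Promoter annotation and CAGE expression quantification.

Covers summing per-position TSS counts into tag-cluster counts, assigning
clusters to protein-coding transcript promoters (500-bp same-strand rule),
TMM between-sample normalization, conversion to tags per million, low
expression filtering and promoter-to-gene aggregation.

TPM here is CAGE-style: tags scaled to an effective library size of one
million, with no feature-length normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome_model import CagePeak, GeneModel, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """Numeric thresholds of the analysis, in one place.

    Defaults are the study conditions: promoter window 500 bp, exon mask
    200 bp, divergent pairing gap 400 bp, 401-nt enhancer regions
    (halfwidth 200), directionality cutoff 0.8, >= 1 TPM in >= 10% of
    macrophage samples for expression, nonzero eRNA in >= 10% for
    transcription, link FDR 1e-4, z > 3 specificity with 10% (specific) and
    25% (responsive) sample fractions, 1000 Monte-Carlo trials at alpha
    0.01, TFBS summit FDR 1e-4.
    """

    promoter_window_bp: int = 500
    exon_mask_bp: int = 200
    divergent_gap_bp: int = 400
    enhancer_halfwidth_bp: int = 200
    directionality_max: float = 0.8
    tpm_min: float = 1.0
    expressed_frac: float = 0.10
    transcribed_frac: float = 0.10
    link_fdr: float = 1e-4
    z_threshold: float = 3.0
    specific_frac: float = 0.10
    responsive_frac: float = 0.25
    mc_trials: int = 1000
    mc_alpha: float = 0.01
    tfbs_summit_fdr: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("expressed_frac", "transcribed_frac", "specific_frac", "responsive_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("promoter_window_bp", "exon_mask_bp", "divergent_gap_bp",
                     "enhancer_halfwidth_bp", "mc_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ceil_fraction(frac: float, n: int) -> int:
    """ceil(frac * n) with guarding against binary float noise.

    "at least 10% of 184 samples" must mean 19 (= ceil(18.4)), and
    "10% of 40" must mean 4, not ceil(4.000000000000001) = 5.
    """
    return math.ceil(round(frac * n, 9))


@dataclass
class ExpressionMatrix:
    """Features x samples expression with an explicit normalization state."""

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    samples: list[SampleMetadata]
    state: str  # raw_counts | tpm

    def __post_init__(self) -> None:
        if self.state not in ("raw_counts", "tpm"):
            raise ValueError(f"unknown state {self.state!r}")
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise ValueError("matrix columns must match sample metadata order")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids_where(self, group: Optional[str] = None,
                         condition: Optional[str] = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (group is None or s.group == group)
            and (condition is None or s.condition == condition)
        ]

    def macrophage_ids(self) -> list[str]:
        return self.sample_ids_where(group="macrophage")

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(ids)], self.samples, self.state)


@dataclass(frozen=True)
class PromoterAssignment:
    peak_id: str
    transcript_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# TSS -> peak counts
# ---------------------------------------------------------------------------

def sum_tss_to_peaks(tss_counts: pd.DataFrame, peaks: Sequence[CagePeak],
                     samples: Sequence[SampleMetadata]) -> ExpressionMatrix:
    """Sum per-position TSS counts into per-peak counts, per sample.

    Positions not falling inside any same-strand peak are ignored (logged).
    """
    sample_ids = [s.sample_id for s in samples]
    df = tss_counts.reset_index(drop=True)
    counts_arr = df[sample_ids].to_numpy()
    mat = np.zeros((len(peaks), len(sample_ids)), dtype=np.int64)
    assigned = np.zeros(len(df), dtype=bool)
    # group positions by (chrom, strand) and assign via sorted peak starts
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
        sel = [
            (i, pk) for i, pk in enumerate(peaks)
            if pk.interval.chrom == chrom and pk.strand == strand
        ]
        if not sel:
            continue
        sel.sort(key=lambda t: t[1].interval.start)
        starts = np.array([pk.interval.start for _, pk in sel])
        ends = np.array([pk.interval.end for _, pk in sel])
        pos = grp["pos"].to_numpy()
        rows = grp.index.to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        assigned[rows[ok]] = True
        for j in np.unique(idx[ok]):
            member_rows = rows[ok & (idx == j)]
            mat[sel[j][0]] += counts_arr[member_rows].sum(axis=0).astype(np.int64)
    n_orphan = int((~assigned).sum())
    if n_orphan:
        logger.info("%d TSS positions outside any peak were ignored", n_orphan)
    values = pd.DataFrame(mat, index=[pk.id for pk in peaks], columns=sample_ids)
    return ExpressionMatrix(values, list(samples), "raw_counts")


# ---------------------------------------------------------------------------
# Promoter assignment
# ---------------------------------------------------------------------------

def assign_promoters(peaks: Sequence[CagePeak], genes: Sequence[GeneModel],
                     window: int = 500) -> list[PromoterAssignment]:
    """Assign a CAGE peak to every transcript whose TSS lies within
    ``window`` bp of the peak's 5' end on the same strand; gene ids are the
    union over the gene's transcripts."""
    if window <= 0:
        raise ValueError("window must be positive")
    out: list[PromoterAssignment] = []
    for pk in peaks:
        tx_ids: list[str] = []
        gene_ids: list[str] = []
        for gm in genes:
            if gm.chrom != pk.interval.chrom:
                continue
            hit = False
            for tx in gm.transcripts:
                if tx.strand == pk.strand and abs(pk.five_prime - tx.tss) <= window:
                    tx_ids.append(tx.transcript_id)
                    hit = True
            if hit:
                gene_ids.append(gm.gene_id)
        if tx_ids:
            out.append(PromoterAssignment(pk.id, tuple(tx_ids), tuple(gene_ids)))
    return out


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values, Robinson & Oshlack 2010)
# ---------------------------------------------------------------------------

def tmm_factors(matrix: ExpressionMatrix, logratio_trim: float = 0.3,
                abundance_trim: float = 0.05) -> np.ndarray:
    """Per-sample TMM scale factors, geometric mean rescaled to 1.

    The reference sample is the one whose upper quartile of nonzero relative
    counts is closest to the mean of those upper quartiles.  For each sample
    vs the reference, features with nonzero counts in both contribute
    M = log2 ratio of relative counts and A = mean log2 relative abundance;
    30% of each M tail and 5% of each A tail are trimmed (rank-based) and
    the factor is 2 to the inverse-variance weighted mean of retained M,
    with binomial delta-method weights.
    """
    if matrix.state != "raw_counts":
        raise ValueError("TMM factors are computed from raw counts")
    Y = matrix.values.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample {matrix.sample_ids[zero[0]]!r} has all-zero counts")
    rel = Y / lib

    uq = np.array([np.quantile(col[col > 0], 0.75) for col in rel.T])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(Y.shape[1])
    for k in range(Y.shape[1]):
        if k == ref:
            continue
        log_factors[k] = _tmm_pair(Y[:, k], Y[:, ref], lib[k], lib[ref],
                                   logratio_trim, abundance_trim)
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(y: np.ndarray, yr: np.ndarray, n: float, nr: float,
              logratio_trim: float, abundance_trim: float) -> float:
    both = (y > 0) & (yr > 0)
    y, yr = y[both], yr[both]
    if y.size == 0:
        return 0.0
    M = np.log2((y / n) / (yr / nr))
    A = 0.5 * np.log2((y / n) * (yr / nr))
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)  # delta-method variance of M
    if np.abs(M).max() < 1e-6:  # identical composition
        return 0.0
    m = M.size
    lo_m = np.floor(m * logratio_trim) + 1
    hi_m = m + 1 - lo_m
    lo_a = np.floor(m * abundance_trim) + 1
    hi_a = m + 1 - lo_a
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f)


def to_tpm(matrix: ExpressionMatrix, factors: np.ndarray,
           lib_sizes: Optional[np.ndarray] = None) -> ExpressionMatrix:
    """Convert raw counts to tags per million over TMM-effective library
    sizes: tpm = count / (lib * factor) * 1e6.

    ``lib_sizes`` overrides the matrix's own column sums; this supports
    normalizing a small feature set (e.g. enhancer eRNA) against library
    sizes of the full promoter matrix.
    """
    if matrix.state != "raw_counts":
        raise ValueError("to_tpm expects raw counts")
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    if lib_sizes is None:
        lib_sizes = matrix.values.to_numpy().sum(axis=0)
    eff = np.asarray(lib_sizes, dtype=float) * factors
    values = matrix.values / eff * 1e6
    return ExpressionMatrix(values, matrix.samples, "tpm")


# ---------------------------------------------------------------------------
# Filters and aggregation
# ---------------------------------------------------------------------------

def filter_expressed(matrix: ExpressionMatrix, sample_subset: Sequence[str],
                     min_tpm: float = 1.0, frac: float = 0.10) -> list[str]:
    """Feature ids with >= min_tpm in at least ceil(frac * |subset|)
    samples of the subset."""
    if not len(sample_subset):
        raise ValueError("sample subset must be non-empty")
    need = ceil_fraction(frac, len(sample_subset))
    sub = matrix.values[list(sample_subset)]
    n_ok = (sub >= min_tpm).sum(axis=1)
    return list(sub.index[n_ok >= need])


def gene_expression(matrix: ExpressionMatrix,
                    assignments: Sequence[PromoterAssignment]) -> ExpressionMatrix:
    """Gene-level expression: per-sample sum over the gene's assigned
    promoter peaks.  Genes without any assigned promoter are absent; a peak
    shared by two genes contributes to both."""
    per_gene: dict[str, list[str]] = {}
    present = set(matrix.values.index)
    for a in assignments:
        if a.peak_id not in present:
            continue
        for g in a.gene_ids:
            per_gene.setdefault(g, []).append(a.peak_id)
    gene_ids = sorted(per_gene)
    rows = [matrix.values.loc[sorted(set(per_gene[g]))].sum(axis=0) for g in gene_ids]
    values = pd.DataFrame(rows, index=gene_ids, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples, matrix.state)
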