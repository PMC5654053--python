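"""Bidirectional transcribed-enhancer calling from CAGE tag clusters.

The strategy: discard tag clusters near protein-coding transcript TSSs or
exons, pair a minus-strand cluster with a plus-strand cluster downstream of
it (divergent orientation, summits at most ``gap`` bp apart), anchor a
fixed-width region of 2*halfwidth+1 nt on the summit midpoint, require a
balanced directionality score |D| < dmax with D = (P - M)/(P + M), resolve
overlapping candidates by pooled tag support, then flag regions transcribed
in macrophages and supported by enhancer chromatin (H3K4me1/H3K27ac).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_quant import ExpressionMatrix, ceil_fraction
from .genome_model import CagePeak, GeneModel, GenomicInterval, SampleMetadata
from .genome_model import interval_distance, interval_point_distance, overlaps

logger = logging.getLogger(__name__)

CHIP_STATES = ("active", "poised", "none")


@dataclass
class EnhancerRegion:
    """A fixed-width bidirectionally transcribed candidate enhancer."""

    id: str
    interval: GenomicInterval  # unstranded, width 2*halfwidth + 1
    midpoint: int
    minus_peak_id: str
    plus_peak_id: str
    directionality: float
    pooled_tags: int
    counts: Optional[np.ndarray] = None  # per-sample eRNA counts
    transcribed: bool = False
    chip_supported: bool = False
    chip_state: str = "none"
    macrophage_specific: bool = False
    responsive_ifng: bool = False
    responsive_il4: bool = False
    marker_ifng: bool = False
    marker_il4: bool = False

    def __post_init__(self) -> None:
        if abs(self.directionality) > 1:
            raise ValueError("directionality must be in [-1, 1]")
        if self.chip_state not in CHIP_STATES:
            raise ValueError(f"unknown chip state {self.chip_state!r}")

    def validate_flags(self) -> None:
        if self.marker_ifng and not self.responsive_ifng:
            raise ValueError(f"{self.id}: marker_ifng requires responsive_ifng")
        if self.marker_il4 and not self.responsive_il4:
            raise ValueError(f"{self.id}: marker_il4 requires responsive_il4")


@dataclass
class ChipEnhancerSet:
    """ChIP-seq-derived enhancer intervals with a two-class chromatin state:
    active (H3K4me1 + H3K27ac) or poised (H3K4me1 only)."""

    intervals: list[GenomicInterval]
    states: list[str]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.states):
            raise ValueError("one state per interval required")
        bad = set(self.states) - {"active", "poised"}
        if bad:
            raise ValueError(f"unknown chromatin states: {sorted(bad)}")


# ---------------------------------------------------------------------------
# TSS clustering (distance-based stand-in for tag-cluster decomposition)
# ---------------------------------------------------------------------------

def cluster_tss(tss_counts: pd.DataFrame, sample_ids: Sequence[str],
                max_gap: int = 20) -> list[CagePeak]:
    """Single-linkage clustering of same-strand TSS positions.

    Positions on one chromosome and strand whose successive gaps are at most
    ``max_gap`` form one tag cluster; the summit is the position with the
    largest pooled count (leftmost on ties).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    peaks: list[CagePeak] = []
    df = tss_counts.sort_values(["chrom", "strand", "pos"], kind="stable")
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        counts = grp[list(sample_ids)].to_numpy()
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for block in np.split(np.arange(pos.size), breaks):
            p = pos[block]
            c = counts[block]
            pooled = c.sum(axis=1)
            summit = int(p[int(np.argmax(pooled))])  # argmax -> leftmost tie
            iv = GenomicInterval(chrom, int(p[0]), int(p[-1]) + 1, strand)
            peaks.append(
                CagePeak(f"tc_{chrom}_{strand}_{p[0]}", iv, summit, c.sum(axis=0))
            )
    return peaks


# ---------------------------------------------------------------------------
# Masking of gene-proximal clusters
# ---------------------------------------------------------------------------

def mask_peaks(peaks: Sequence[CagePeak], genes: Sequence[GeneModel],
               tss_window: int = 500, exon_window: int = 200) -> list[CagePeak]:
    """Remove tag clusters within ``tss_window`` bp of any protein-coding
    transcript TSS or within ``exon_window`` bp of any exon (strand-agnostic;
    overlap counts as distance 0)."""
    if tss_window <= 0 or exon_window <= 0:
        raise ValueError("windows must be positive")
    coding = [g for g in genes if g.biotype == "protein_coding"]
    retained: list[CagePeak] = []
    for pk in peaks:
        iv = pk.interval
        masked = False
        for gm in coding:
            if gm.chrom != iv.chrom:
                continue
            for tx in gm.transcripts:
                if interval_point_distance(iv, tx.tss, gm.chrom) <= tss_window:
                    masked = True
                    break
            if masked:
                break
            for exon in gm.exons:
                if interval_distance(iv, exon) <= exon_window:
                    masked = True
                    break
            if masked:
                break
        if not masked:
            retained.append(pk)
    return retained


# ---------------------------------------------------------------------------
# Divergent pairing
# ---------------------------------------------------------------------------

def call_bidirectional(peaks: Sequence[CagePeak], gap: int = 400,
                       halfwidth: int = 200, dmax: float = 0.8) -> list[EnhancerRegion]:
    """Pair divergent minus/plus tag clusters into fixed-width enhancer
    candidates.

    A candidate arises from a minus-strand cluster m and plus-strand cluster
    p on one chromosome with m.summit < p.summit and p.summit - m.summit <=
    gap.  The region is [mid - halfwidth, mid + halfwidth + 1) with
    mid = floor((m.summit + p.summit) / 2).  Pooled window tags (each
    cluster's total count attributed to its summit) give
    D = (P - M)/(P + M); candidates with P + M = 0 or |D| >= dmax are
    discarded.  Overlapping survivors are resolved by keeping the candidate
    with the largest P + M (ties: leftmost, then smaller midpoint).
    """
    candidates: list[EnhancerRegion] = []
    by_chrom: dict[str, tuple[list[CagePeak], list[CagePeak]]] = {}
    for pk in peaks:
        minus, plus = by_chrom.setdefault(pk.interval.chrom, ([], []))
        (minus if pk.strand == "-" else plus).append(pk)

    for chrom in sorted(by_chrom):
        minus, plus = by_chrom[chrom]
        if not minus or not plus:
            continue
        minus_summits = np.array([pk.summit for pk in minus])
        minus_tags = np.array([pk.total_count for pk in minus])
        plus_summits = np.array([pk.summit for pk in plus])
        plus_tags = np.array([pk.total_count for pk in plus])
        m_order = np.argsort(minus_summits, kind="stable")
        p_order = np.argsort(plus_summits, kind="stable")
        ms, mt = minus_summits[m_order], minus_tags[m_order]
        ps, pt = plus_summits[p_order], plus_tags[p_order]
        for i, m_idx in enumerate(m_order):
            m = minus[m_idx]
            lo = np.searchsorted(ps, m.summit, side="right")
            hi = np.searchsorted(ps, m.summit + gap, side="right")
            for j in range(lo, hi):
                p = plus[p_order[j]]
                mid = (m.summit + p.summit) // 2
                start = mid - halfwidth
                if start < 0:
                    continue
                end = mid + halfwidth + 1
                # window tag sums over summit-attributed pooled counts
                P = int(pt[(ps >= mid) & (ps < end)].sum())
                M = int(mt[(ms >= start) & (ms < mid)].sum())
                if P + M == 0:
                    logger.debug("candidate at %s:%d has no window tags", chrom, mid)
                    continue
                D = (P - M) / (P + M)
                if abs(D) >= dmax:
                    continue
                candidates.append(
                    EnhancerRegion(
                        id=f"enh_{chrom}_{start}_{end}",
                        interval=GenomicInterval(chrom, start, end),
                        midpoint=mid,
                        minus_peak_id=m.id,
                        plus_peak_id=p.id,
                        directionality=D,
                        pooled_tags=P + M,
                    )
                )
    return _resolve_overlaps(candidates)


def _resolve_overlaps(candidates: list[EnhancerRegion]) -> list[EnhancerRegion]:
    """Greedy strongest-first selection of non-overlapping candidates."""
    ranked = sorted(
        candidates,
        key=lambda e: (-e.pooled_tags, e.interval.chrom, e.interval.start, e.midpoint),
    )
    accepted: list[EnhancerRegion] = []
    for cand in ranked:
        if any(overlaps(cand.interval, acc.interval) for acc in accepted
               if acc.interval.chrom == cand.interval.chrom):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return accepted


# ---------------------------------------------------------------------------
# eRNA quantification and flags
# ---------------------------------------------------------------------------

def quantify_ernas(enhancers: Sequence[EnhancerRegion], tss_counts: pd.DataFrame,
                   samples: Sequence[SampleMetadata]) -> ExpressionMatrix:
    """Per-sample eRNA counts: minus-strand tags in [start, mid) plus
    plus-strand tags in [mid, end), the divergent configuration only.

    Also stores the count vector on each region (``region.counts``).
    """
    sample_ids = [s.sample_id for s in samples]
    mat = np.zeros((len(enhancers), len(sample_ids)), dtype=np.int64)
    for strand_sign, left in (("-", True), ("+", False)):
        sub = tss_counts[tss_counts["strand"] == strand_sign]
        for chrom, grp in sub.groupby("chrom", sort=False):
            grp = grp.sort_values("pos", kind="stable")
            pos = grp["pos"].to_numpy()
            counts = grp[sample_ids].to_numpy()
            csum = np.vstack([np.zeros(len(sample_ids)), np.cumsum(counts, axis=0)])
            for i, enh in enumerate(enhancers):
                if enh.interval.chrom != chrom:
                    continue
                if left:
                    lo, hi = enh.interval.start, enh.midpoint
                else:
                    lo, hi = enh.midpoint, enh.interval.end
                a = np.searchsorted(pos, lo, side="left")
                b = np.searchsorted(pos, hi, side="left")
                mat[i] += (csum[b] - csum[a]).astype(np.int64)
    for i, enh in enumerate(enhancers):
        enh.counts = mat[i]
    values = pd.DataFrame(mat, index=[e.id for e in enhancers], columns=sample_ids)
    return ExpressionMatrix(values, list(samples), "raw_counts")


def flag_transcribed(enhancers: Sequence[EnhancerRegion], counts: ExpressionMatrix,
                     macrophage_ids: Sequence[str], frac: float = 0.10) -> None:
    """Mark regions with nonzero eRNA in at least ceil(frac * N) macrophage
    samples as transcribed."""
    need = ceil_fraction(frac, len(macrophage_ids))
    sub = counts.values[list(macrophage_ids)]
    nonzero = (sub > 0).sum(axis=1)
    for enh in enhancers:
        enh.transcribed = bool(nonzero.loc[enh.id] >= need)


def chip_filter(enhancers: Sequence[EnhancerRegion], chip: ChipEnhancerSet) -> None:
    """Flag regions overlapping (>= 1 bp) a ChIP-derived enhancer interval;
    the state is active if any overlapped interval is active, else poised."""
    for enh in enhancers:
        hit_states = {
            st
            for iv, st in zip(chip.intervals, chip.states)
            if overlaps(enh.interval, iv)
        }
        enh.chip_supported = bool(hit_states)
        if "active" in hit_states:
            enh.chip_state = "active"
        elif hit_states:
            enh.chip_state = "poised"
        else:
            enh.chip_state = "none"
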