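"""Gene-set and TFBS over-representation analysis.

Gene sets are tested with the upper-tail hypergeometric probability of the
observed-or-larger overlap against a fixed gene universe, BH-corrected
across the collection.  TFBS enrichment uses the fraction of query regions
containing at least one ChIP summit, compared by Monte-Carlo resampling
against three backgrounds: the whole called enhancer set, the subset not
transcribed in macrophages, and width-matched random regions sampled
inside TADs away from excluded intervals (assembly gaps, repeats, coding
exons, called enhancers).  A factor is retained only when the empirical p
is below alpha for all three backgrounds and the factor itself is
expressed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

from .genome_model import GenomicInterval, NarrowPeak, TAD
from .interactome import bh_fdr


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe gene ids must be unique")


@dataclass
class TfbsPeakSet:
    """Retained ChIP summits (q < cutoff) for one transcription factor."""

    tf_name: str
    summits: pd.DataFrame  # columns: chrom, pos
    tf_expression: float  # mean TPM in the relevant samples


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_overlap: int
    n_query: int
    K_term: int
    N_universe: int
    p: float
    q: float = float("nan")


@dataclass(frozen=True)
class MonteCarloResult:
    tf_name: str
    observed_frac: float
    empirical_p: dict  # background name -> p
    significant: bool


# ---------------------------------------------------------------------------
# GMT I/O (name <tab> description <tab> gene...)
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike, universe: Sequence[str]) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets, list(universe))


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Hypergeometric gene-set tests
# ---------------------------------------------------------------------------

def hypergeom_test(query: Sequence[str], term: Sequence[str],
                   universe: Sequence[str]) -> EnrichmentResult:
    """Upper-tail hypergeometric p for the overlap between a query gene set
    and one term, both intersected with the universe first."""
    uni = set(universe)
    q = set(query) & uni
    t = set(term) & uni
    if len(q) > len(uni):
        raise ValueError("universe smaller than query")
    N, K, n = len(uni), len(t), len(q)
    k = len(q & t)
    p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    return EnrichmentResult("", k, n, K, N, min(p, 1.0))


def gene_set_enrichment(query: Sequence[str],
                        collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric test of a query against every term of the collection,
    BH-corrected across terms."""
    rows = []
    for name, genes in collection.sets.items():
        res = hypergeom_test(query, genes, collection.universe)
        rows.append({"term": name, "k": res.k_overlap, "n": res.n_query,
                     "K": res.K_term, "N": res.N_universe, "p": res.p})
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else np.array([])
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TFBS overlap statistic
# ---------------------------------------------------------------------------

def filter_summits(peaks: Sequence[NarrowPeak], q_max: float = 1e-4) -> pd.DataFrame:
    """Summit table (chrom, pos) of peaks with q below the cutoff."""
    rows = [
        {"chrom": pk.interval.chrom, "pos": pk.summit}
        for pk in peaks
        if pk.q_value < q_max
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def _summit_index(summits: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in summits.groupby("chrom", sort=False)
    }


def region_hits(regions: Sequence[GenomicInterval],
                summits: pd.DataFrame) -> np.ndarray:
    """Boolean per region: contains >= 1 summit (half-open: a summit at the
    start coordinate counts, at the end coordinate it does not)."""
    idx = _summit_index(summits)
    out = np.zeros(len(regions), dtype=bool)
    for i, iv in enumerate(regions):
        pos = idx.get(iv.chrom)
        if pos is None:
            continue
        a = np.searchsorted(pos, iv.start, side="left")
        b = np.searchsorted(pos, iv.end, side="left")
        out[i] = b > a
    return out


def tfbs_overlap_stat(regions: Sequence[GenomicInterval],
                      summits: pd.DataFrame) -> float:
    """Fraction of regions containing at least one summit."""
    if not len(regions):
        raise ValueError("empty query region set")
    return float(region_hits(regions, summits).mean())


# ---------------------------------------------------------------------------
# Random background regions
# ---------------------------------------------------------------------------

def _merge(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merged exclusion intervals per chromosome as an (n, 2) array."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged)
    return out


def _legal_segments(tads: Sequence[TAD],
                    exclusions: Sequence[GenomicInterval]) -> list[tuple[str, int, int]]:
    """Maximal exclusion-free sub-intervals of TADs as (chrom, start, end)."""
    excl = _merge(exclusions)
    segments: list[tuple[str, int, int]] = []
    for tad in tads:
        chrom = tad.interval.chrom
        cur = tad.interval.start
        for s, e in excl.get(chrom, np.empty((0, 2), dtype=int)):
            if e <= cur or s >= tad.interval.end:
                continue
            if s > cur:
                segments.append((chrom, cur, min(s, tad.interval.end)))
            cur = max(cur, e)
        if cur < tad.interval.end:
            segments.append((chrom, cur, tad.interval.end))
    return segments


def sample_background_regions(
    n: int,
    widths: Sequence[int],
    tads: Sequence[TAD],
    exclusions: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Sample ``n`` regions with the given widths (matched one-to-one),
    each entirely inside a TAD and intersecting no exclusion interval,
    uniformly over all legal start positions.

    Implemented by exact enumeration of exclusion-free segments, so no
    rejection sampling is needed; an unplaceable width is an error.
    """
    if len(widths) != n:
        raise ValueError("need one width per region")
    segments = _legal_segments(tads, exclusions)
    out: list[GenomicInterval] = []
    cache: dict[int, tuple[list[tuple[str, int]], np.ndarray]] = {}
    for w in widths:
        if w not in cache:
            anchors = []  # (chrom, segment start) with count of legal starts
            counts = []
            for chrom, s, e in segments:
                c = e - w - s + 1
                if c > 0:
                    anchors.append((chrom, s))
                    counts.append(c)
            if not anchors:
                raise ValueError(f"no legal placement for width {w}")
            cache[w] = (anchors, np.cumsum(counts))
        anchors, cum = cache[w]
        u = int(rng.integers(cum[-1]))
        seg = int(np.searchsorted(cum, u, side="right"))
        offset = u - (cum[seg - 1] if seg else 0)
        chrom, s = anchors[seg]
        out.append(GenomicInterval(chrom, s + offset, s + offset + w))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo enrichment
# ---------------------------------------------------------------------------

BackgroundSpec = Union[Sequence[GenomicInterval], Callable[[np.random.Generator], Sequence[GenomicInterval]]]


def monte_carlo_p(
    query_regions: Sequence[GenomicInterval],
    summits: pd.DataFrame,
    background: BackgroundSpec,
    trials: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Empirical over-representation p for one TF against one background.

    Each trial draws |query| regions -- without replacement from a region
    pool, or freshly from a callable background generator -- and computes
    the overlap fraction.  The plus-one estimator
    p = (1 + #{trial >= observed}) / (trials + 1) never returns 0.

    Returns (observed fraction, empirical p).
    """
    rng = rng if rng is not None else np.random.default_rng()
    observed = tfbs_overlap_stat(query_regions, summits)
    k = len(query_regions)
    n_ge = 0
    if callable(background):
        for _ in range(trials):
            stat = tfbs_overlap_stat(background(rng), summits)
            if stat >= observed:
                n_ge += 1
    else:
        pool = list(background)
        if len(pool) < k:
            raise ValueError("background pool smaller than query")
        hits = region_hits(pool, summits)
        for _ in range(trials):
            idx = rng.choice(len(pool), size=k, replace=False)
            if hits[idx].mean() >= observed:
                n_ge += 1
    return observed, (1 + n_ge) / (trials + 1)


def significant_tfbs(results: dict[str, dict[str, float]],
                     tf_expression: dict[str, float],
                     alpha: float = 0.01,
                     backgrounds: Sequence[str] = ("all_enhancers",
                                                   "non_macrophage_enhancers",
                                                   "random_regions")) -> list[str]:
    """TFs with empirical p < alpha against every background and nonzero
    expression."""
    retained = []
    for tf, per_bg in results.items():
        missing = [b for b in backgrounds if b not in per_bg]
        if missing:
            raise ValueError(f"{tf}: missing background results {missing}")
        if all(per_bg[b] < alpha for b in backgrounds) and tf_expression.get(tf, 0.0) > 0:
            retained.append(tf)
    return sorted(retained)


def tfbs_enrichment(
    query_regions: Sequence[GenomicInterval],
    tf_sets: Sequence[TfbsPeakSet],
    pools: dict[str, Sequence[GenomicInterval]],
    random_background: Callable[[np.random.Generator], Sequence[GenomicInterval]],
    trials: int = 1000,
    alpha: float = 0.01,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Monte-Carlo TFBS over-representation for many TFs at once.

    Trial region draws are shared across TFs (one set of resampled region
    sets per background), which matches drawing random region sets first
    and scoring every factor against them.
    """
    rng = rng if rng is not None else np.random.default_rng()
    k = len(query_regions)
    if k == 0:
        raise ValueError("empty query region set")
    # trial index sets per pool background
    pool_draws: dict[str, tuple[list[GenomicInterval], np.ndarray]] = {}
    for name, pool in pools.items():
        pool = list(pool)
        if len(pool) < k:
            raise ValueError(f"background pool {name!r} smaller than query")
        draws = np.stack([rng.choice(len(pool), size=k, replace=False)
                          for _ in range(trials)])
        pool_draws[name] = (pool, draws)
    random_sets = [list(random_background(rng)) for _ in range(trials)]
    flat = [iv for regions in random_sets for iv in regions]
    rand_chroms = np.array([iv.chrom for iv in flat])
    rand_starts = np.array([iv.start for iv in flat])
    rand_ends = np.array([iv.end for iv in flat])

    rows = []
    results: dict[str, dict[str, float]] = {}
    expr = {t.tf_name: t.tf_expression for t in tf_sets}
    for tf in tf_sets:
        observed = tfbs_overlap_stat(query_regions, tf.summits)
        per_bg: dict[str, float] = {}
        for name, (pool, draws) in pool_draws.items():
            hits = region_hits(pool, tf.summits)
            stats = hits[draws].mean(axis=1)
            per_bg[name] = float((1 + (stats >= observed).sum()) / (trials + 1))
        rand_hits = np.zeros(len(flat), dtype=bool)
        for chrom, pos in _summit_index(tf.summits).items():
            m = rand_chroms == chrom
            rand_hits[m] = (
                np.searchsorted(pos, rand_ends[m], side="left")
                > np.searchsorted(pos, rand_starts[m], side="left")
            )
        rand_stats = rand_hits.reshape(trials, k).mean(axis=1)
        per_bg["random_regions"] = float(
            (1 + (rand_stats >= observed).sum()) / (trials + 1)
        )
        results[tf.tf_name] = per_bg
        rows.append({"tf": tf.tf_name, "observed_frac": observed,
                     "tpm": tf.tf_expression, **{f"p_{k2}": v for k2, v in per_bg.items()}})
    retained = significant_tfbs(
        results, expr, alpha,
        backgrounds=tuple(list(pools) + ["random_regions"]),
    )
    df = pd.DataFrame(rows)
    df["significant"] = df["tf"].isin(retained)
    return df, retained
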