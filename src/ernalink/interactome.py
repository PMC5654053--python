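"""Enhancer-promoter-gene interactome within TADs.

Candidate pairs are enhancers and promoter tag clusters entirely contained
in the same TAD.  Each pair is scored by Spearman correlation of eRNA and
promoter expression across macrophage samples; Benjamini-Hochberg FDR is
applied once across all TAD-based pairs and links with positive rho below
the FDR threshold are retained, then collapsed to distinct (enhancer, gene)
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .enhancer_calling import EnhancerRegion
from .expression_quant import ExpressionMatrix, PromoterAssignment
from .genome_model import CagePeak, TAD, contained_within

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EPAssociation:
    enhancer_id: str
    promoter_id: str
    gene_id: str
    tad_id: str
    rho: float
    p_value: float
    q_value: float
    distance: int  # enhancer midpoint to promoter 5' end, bp


@dataclass(frozen=True)
class GeneEnhancerSummary:
    gene_id: str
    n_enhancers: int


def tad_pairs(enhancers: Sequence[EnhancerRegion], promoters: Sequence[CagePeak],
              tads: Sequence[TAD]) -> list[tuple[EnhancerRegion, CagePeak, TAD]]:
    """All (enhancer, promoter, TAD) triples where both features lie
    entirely within the TAD.  TADs may touch or nest; a feature straddling a
    TAD boundary yields no pair for that TAD."""
    out: list[tuple[EnhancerRegion, CagePeak, TAD]] = []
    for tad in tads:
        enh_in = [e for e in enhancers if contained_within(e.interval, tad.interval)]
        if not enh_in:
            continue
        prom_in = [p for p in promoters if contained_within(p.interval, tad.interval)]
        for e in enh_in:
            for p in prom_in:
                out.append((e, p, tad))
    return out


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with mean ranks for ties; two-sided p-value from
    the t-approximation.  Constant input is an error (callers drop the pair
    and log)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant vector")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_pairs(
    pairs: Sequence[tuple[EnhancerRegion, CagePeak, TAD]],
    enhancer_tpm: ExpressionMatrix,
    promoter_tpm: ExpressionMatrix,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Spearman rho/p for each TAD-based pair over the given samples.

    Returns a frame with one row per testable pair (constant-expression
    pairs are dropped and logged) and columns enhancer_id, promoter_id,
    tad_id, rho, p, distance.
    """
    cols = list(sample_ids)
    emat = enhancer_tpm.values[cols]
    pmat = promoter_tpm.values[cols]
    rows = []
    n_constant = 0
    for enh, prom, tad in pairs:
        x = emat.loc[enh.id].to_numpy()
        y = pmat.loc[prom.id].to_numpy()
        try:
            rho, p = spearman_rho(x, y)
        except ValueError:
            n_constant += 1
            continue
        rows.append(
            {
                "enhancer_id": enh.id,
                "promoter_id": prom.id,
                "tad_id": tad.id,
                "rho": rho,
                "p": p,
                "distance": abs(enh.midpoint - prom.five_prime),
            }
        )
    if n_constant:
        logger.info("dropped %d pairs with constant expression", n_constant)
    return pd.DataFrame(
        rows, columns=["enhancer_id", "promoter_id", "tad_id", "rho", "p", "distance"]
    )


def select_links(scored: pd.DataFrame, fdr_threshold: float = 1e-4,
                 require_positive: bool = True) -> pd.DataFrame:
    """BH over all tested pairs jointly, then keep rho > 0 (when required)
    and q < threshold."""
    out = scored.copy()
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.array([])
    keep = out["q"] < fdr_threshold
    if require_positive:
        keep &= out["rho"] > 0
    return out[keep].reset_index(drop=True)


def map_to_genes(
    links: pd.DataFrame,
    assignments: Sequence[PromoterAssignment],
    expressed_genes: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, list[GeneEnhancerSummary]]:
    """Collapse promoter-level links to distinct (enhancer, gene) pairs.

    ``expressed_genes`` lists genes that passed expression filters; those
    with no link are reported with n_enhancers = 0.
    """
    peak_to_genes: dict[str, tuple[str, ...]] = {a.peak_id: a.gene_ids for a in assignments}
    pairs: set[tuple[str, str]] = set()
    for row in links.itertuples(index=False):
        for g in peak_to_genes.get(row.promoter_id, ()):
            pairs.add((row.enhancer_id, g))
    gene_links = pd.DataFrame(
        sorted(pairs), columns=["enhancer_id", "gene_id"]
    )
    counts: dict[str, int] = {}
    for _, g in pairs:
        counts[g] = counts.get(g, 0) + 1
    genes = set(counts)
    if expressed_genes is not None:
        genes |= set(expressed_genes)
    summaries = [
        GeneEnhancerSummary(g, counts.get(g, 0)) for g in sorted(genes)
    ]
    return gene_links, summaries


def distance_stats(distances: Sequence[float],
                   other: Optional[Sequence[float]] = None) -> dict:
    """Median link distance; optional two-sided Wilcoxon rank-sum comparison
    against a second distance set."""
    d = np.asarray(distances, dtype=float)
    out = {"n": int(d.size), "median": float(np.median(d)) if d.size else float("nan")}
    if other is not None:
        o = np.asarray(other, dtype=float)
        stat, p = scipy.stats.ranksums(d, o)
        out["ranksum_stat"] = float(stat)
        out["ranksum_p"] = float(p)
    return out


def assert_no_cross_tad(links: pd.DataFrame, enhancers: Sequence[EnhancerRegion],
                        promoters: Sequence[CagePeak], tads: Sequence[TAD]) -> int:
    """Verify every selected link has both endpoints inside its TAD; returns
    the number of violations (0 on a correct run)."""
    enh_by_id = {e.id: e for e in enhancers}
    prom_by_id = {p.id: p for p in promoters}
    tad_by_id = {t.id: t for t in tads}
    bad = 0
    for row in links.itertuples(index=False):
        tad = tad_by_id[row.tad_id]
        if not contained_within(enh_by_id[row.enhancer_id].interval, tad.interval):
            bad += 1
        elif not contained_within(prom_by_id[row.promoter_id].interval, tad.interval):
            bad += 1
    return bad
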