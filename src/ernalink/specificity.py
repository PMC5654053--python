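"""z-score classification of macrophage-specific, stimulus-responsive and
marker features.

For each feature a per-target-sample z-score is computed against a
background sample set: z = (x - mean_bg) / sd_bg with the n-1 sd.  A
feature is macrophage-specific when z > 3 in at least 10% (ceiling) of
macrophage samples versus the non-macrophage background; it is responsive
to IFN-g or IL-4/IL-13 when z > 3 in strictly more than 25% of the
stimulated samples versus untreated macrophages.  Marker enhancers are
responsive in exactly one activation state, linked in-state to a known
marker gene, and over-expressed versus the opposite state by the same
z-score rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_quant import ExpressionMatrix, ceil_fraction
from .interactome import spearman_rho

logger = logging.getLogger(__name__)


@dataclass
class ZScoreResult:
    feature_id: str
    z: np.ndarray  # one value per target sample
    n_above: int
    classified: bool


@dataclass(frozen=True)
class MarkerCall:
    enhancer_id: str
    state: str  # ifng | il4il13
    marker_gene_ids: tuple[str, ...]


def zscores(matrix: ExpressionMatrix, target_samples: Sequence[str],
            background_samples: Sequence[str],
            threshold: float = 3.0) -> dict[str, ZScoreResult]:
    """Per-feature z-scores of target samples against a background set.

    sd uses the n-1 denominator.  A zero-variance background yields
    z = +inf where the target exceeds the background mean and z = 0
    otherwise (declared convention for silent features).
    ``classified`` is left False; threshold rules set it.
    """
    if len(background_samples) < 2:
        raise ValueError("background must contain >= 2 samples")
    bg = matrix.values[list(background_samples)].to_numpy(dtype=float)
    tg = matrix.values[list(target_samples)].to_numpy(dtype=float)
    mean = bg.mean(axis=1, keepdims=True)
    sd = bg.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (tg - mean) / sd
    flat = np.broadcast_to(sd == 0, z.shape)
    above_mean = tg > mean
    z = np.where(flat & above_mean, np.inf, z)
    z = np.where(flat & ~above_mean, 0.0, z)
    out: dict[str, ZScoreResult] = {}
    for i, fid in enumerate(matrix.feature_ids):
        n_above = int((z[i] > threshold).sum())
        out[fid] = ZScoreResult(fid, z[i], n_above, False)
    return out


def macrophage_specific(z_results: dict[str, ZScoreResult], n_target: int,
                        frac: float = 0.10, threshold: float = 3.0) -> list[str]:
    """Features with z strictly above ``threshold`` in at least
    ceil(frac * n_target) target samples."""
    need = ceil_fraction(frac, n_target)
    hits = []
    for res in z_results.values():
        res.classified = res.n_above >= need
        if res.classified:
            hits.append(res.feature_id)
    return sorted(hits)


def stimuli_responsive(matrix: ExpressionMatrix, stimulated_samples: Sequence[str],
                       unstimulated_samples: Sequence[str], frac: float = 0.25,
                       threshold: float = 3.0) -> list[str]:
    """Features up-regulated on stimulation: z > threshold versus untreated
    macrophages in strictly more than ``frac`` of the stimulated samples
    (16 stimulated samples -> at least 5)."""
    zres = zscores(matrix, stimulated_samples, unstimulated_samples, threshold)
    n = len(stimulated_samples)
    hits = []
    for res in zres.values():
        res.classified = res.n_above > frac * n
        if res.classified:
            hits.append(res.feature_id)
    return sorted(hits)


def condition_links(links: pd.DataFrame, enhancer_tpm: ExpressionMatrix,
                    promoter_tpm: ExpressionMatrix, state_samples: Sequence[str],
                    responsive_enhancers: Sequence[str],
                    responsive_promoters: Sequence[str]) -> pd.DataFrame:
    """Restrict links to one activation state: both endpoints responsive in
    that state and Spearman rho across the state's samples strictly
    positive (sign only, no p-value requirement)."""
    renh = set(responsive_enhancers)
    rprom = set(responsive_promoters)
    cols = list(state_samples)
    keep_rows = []
    n_constant = 0
    for idx, row in links.iterrows():
        if row["enhancer_id"] not in renh or row["promoter_id"] not in rprom:
            continue
        x = enhancer_tpm.values.loc[row["enhancer_id"], cols].to_numpy()
        y = promoter_tpm.values.loc[row["promoter_id"], cols].to_numpy()
        try:
            rho, _ = spearman_rho(x, y)
        except ValueError:
            n_constant += 1
            continue
        if rho > 0:
            keep_rows.append(idx)
    if n_constant:
        logger.info("condition_links: dropped %d constant-expression links", n_constant)
    return links.loc[keep_rows].reset_index(drop=True)


def load_marker_genes(path: Optional[str] = None) -> dict[str, list[str]]:
    """Known activation marker gene panels per state (ifng / il4il13).

    The packaged default lists classical and alternative activation markers
    for which stimulus-specific enhancer regulation has been described
    (Cxcl9/10/11, Nos2, Socs3, ... for IFN-g; Arg1, Egr2, Igf1, Mrc1, ...
    for IL-4/IL-13).  Users supply their own two-column TSV (gene, state)
    to substitute a panel.
    """
    if path is None:
        ref = resources.files("ernalink.data").joinpath("marker_genes.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {"ifng": [], "il4il13": []}
    for row in df.itertuples(index=False):
        if row.state not in out:
            raise ValueError(f"unknown marker state {row.state!r}")
        out[row.state].append(str(row.gene))
    return out


def marker_enhancers(
    responsive_sets: dict[str, Sequence[str]],
    state_gene_links: dict[str, pd.DataFrame],
    marker_genes: dict[str, Sequence[str]],
    enhancer_tpm: ExpressionMatrix,
    state_samples: dict[str, Sequence[str]],
    frac: float = 0.25,
    threshold: float = 3.0,
) -> list[MarkerCall]:
    """Activation marker enhancers per state.

    An enhancer is a marker for state S iff it is responsive in S and not in
    the other state, linked (within S's condition-restricted links) to at
    least one known marker gene of S, and shows z > threshold versus the
    opposite state's samples in strictly more than ``frac`` of S's samples.

    ``state_gene_links[state]`` must carry enhancer_id and gene_id columns.
    """
    states = ("ifng", "il4il13")
    calls: list[MarkerCall] = []
    for state in states:
        other = states[1 - states.index(state)]
        resp = set(responsive_sets.get(state, ()))
        resp_other = set(responsive_sets.get(other, ()))
        exclusive = resp - resp_other
        if not exclusive:
            continue
        links = state_gene_links[state]
        markers = set(marker_genes.get(state, ()))
        linked_markers: dict[str, set[str]] = {}
        for row in links.itertuples(index=False):
            if row.enhancer_id in exclusive and row.gene_id in markers:
                linked_markers.setdefault(row.enhancer_id, set()).add(row.gene_id)
        if not linked_markers:
            continue
        sub = enhancer_tpm.subset_features(sorted(linked_markers))
        zres = zscores(sub, list(state_samples[state]), list(state_samples[other]),
                       threshold)
        n = len(state_samples[state])
        for enh_id, res in zres.items():
            if res.n_above > frac * n:
                calls.append(
                    MarkerCall(enh_id, state, tuple(sorted(linked_markers[enh_id])))
                )
    calls.sort(key=lambda c: (c.state, c.enhancer_id))
    _assert_disjoint(calls)
    return calls


def _assert_disjoint(calls: Sequence[MarkerCall]) -> None:
    by_state: dict[str, set[str]] = {}
    for c in calls:
        by_state.setdefault(c.state, set()).add(c.enhancer_id)
    if len(by_state) == 2:
        overlap = by_state["ifng"] & by_state["il4il13"]
        if overlap:
            raise AssertionError(f"marker sets not disjoint: {sorted(overlap)}")
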