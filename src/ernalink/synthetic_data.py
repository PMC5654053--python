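"""Seeded generator of a miniature CAGE study with planted ground truth.

The generator emulates the structure of a stranded CAGE atlas over
macrophage and non-macrophage samples: a small genome tiled by TADs;
protein-coding genes with 1-3 transcripts and exons; planted enhancers
emitting divergent minus/plus tag clusters 100-300 bp apart whose eRNA
shares a latent log-normal activity with the target gene's promoter
(tuned so the realized Spearman correlation approximates a target);
decoy convergent or too-distant cluster pairs; negative-binomial tag
counts; condition-dependent up-regulation in stimulated samples;
chromatin-interval support for planted enhancers; and TF summits planted
inside a fraction of the enhancers next to uniformly scattered decoy
factors.

Every random draw flows from one ``numpy`` generator seeded by
``SimulationConfig.rng_seed``, so emitted datasets and truth tables are
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enhancer_calling import ChipEnhancerSet
from .enrichment import GeneSetCollection, write_gmt
from .genome_model import (
    BedRecord,
    GeneModel,
    GenomicInterval,
    NarrowPeak,
    SampleMetadata,
    TAD,
    Transcript,
    write_bed,
    write_narrowpeak,
    write_sample_metadata,
    write_tss_counts,
)

SLOT_SPACING = 6000  # bp between feature anchors; keeps masking windows clear
SLOT_MARGIN = 3000  # bp kept free at each TAD edge


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Sample structure mirrors the real design: 10 untreated, 16 IFN-g and
    16 IL-4/IL-13 stimulated macrophage samples (42 macrophages total)
    against a larger non-macrophage background panel.  Genome and feature
    counts are scaled down so a full run stays fast on one CPU.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_440_000
    n_tads_per_chrom: int = 8
    n_genes: int = 200
    n_planted_enhancers: int = 60
    n_nonmacrophage_enhancers: int = 80
    n_decoy_peak_pairs: int = 60
    n_untreated: int = 10
    n_ifng: int = 16
    n_il4il13: int = 16
    n_background_samples: int = 80
    nb_dispersion: float = 0.1
    baseline_mean_tags: float = 60.0
    link_rho_target: float = 0.8
    condition_effect_sd_units: float = 5.0
    n_responsive_ifng: int = 10
    n_responsive_il4: int = 10
    tad_shared_frac: float = 1.0
    chip_support_frac: float = 1.0
    chip_active_frac: float = 0.9
    tf_planting_frac: float = 0.5
    n_planted_tfs: int = 3
    n_decoy_tfs: int = 20
    n_decoy_summits: int = 30
    n_exclusion_intervals: int = 20
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_tads_per_chrom", "n_genes",
                     "n_planted_enhancers", "n_untreated", "n_ifng", "n_il4il13",
                     "n_background_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tad_shared_frac", "chip_support_frac", "chip_active_frac",
                     "tf_planting_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_planted_enhancers > self.n_genes:
            raise ValueError("each planted enhancer needs a distinct target gene")
        if self.n_responsive_ifng + self.n_responsive_il4 > self.n_planted_enhancers:
            raise ValueError("responsive links exceed planted links")

    @property
    def n_macrophage_samples(self) -> int:
        return self.n_untreated + self.n_ifng + self.n_il4il13

    def latent_sigma(self) -> float:
        """Log-scale sd of the shared activity factor chosen so the realized
        Spearman rho of a planted link approximates ``link_rho_target``.

        rho ~ sigma^2 / (sigma^2 + v) with v the log-count noise variance of
        a feature summed over its tag positions: splitting a feature's mean
        across several NB positions averages out part of the dispersion, so
        v is approximately dispersion/2 + 1/mean at the baseline.
        """
        rho = self.link_rho_target
        if rho <= 0:
            return 0.0
        v_noise = self.nb_dispersion / 2.0 + 1.0 / self.baseline_mean_tags
        return math.sqrt(rho / (1.0 - rho) * v_noise)


@dataclass
class SyntheticTruth:
    """Planted features and effects, keyed so downstream recovery can be
    scored against emitted data."""

    enhancers: pd.DataFrame  # truth_id, chrom, midpoint, start, end, kind, ...
    links: pd.DataFrame  # truth_id, gene_id, tad_id, responsive
    tfs: pd.DataFrame  # tf, planted, expression
    marker_genes: dict[str, list[str]]


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    tads: list[TAD]
    exclusions: list[GenomicInterval]
    gene_records: list[dict]
    enhancer_records: list[dict]
    decoy_records: list[dict]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: SyntheticGenome
    samples: list[SampleMetadata]
    tss: pd.DataFrame
    chip: ChipEnhancerSet
    tfbs: dict[str, list[NarrowPeak]]
    tf_expression: dict[str, float]
    genesets: GeneSetCollection
    truth: SyntheticTruth

    @property
    def genes(self) -> list[GeneModel]:
        return self.genome.genes

    @property
    def tads(self) -> list[TAD]:
        return self.genome.tads

    @property
    def exclusions(self) -> list[GenomicInterval]:
        return self.genome.exclusions


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> SyntheticGenome:
    """Lay out TADs, genes, planted/decoy enhancer anchors and exclusion
    intervals on the miniature genome.

    Features occupy slots spaced ``SLOT_SPACING`` bp apart so that enhancer
    anchors always stay clear of the TSS/exon masking windows.  Every
    planted enhancer shares a TAD with its distinct target gene (a
    configurable fraction may be placed across TADs for decoy studies).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    tad_width = config.chrom_length_bp // config.n_tads_per_chrom
    tads: list[TAD] = []
    slots_by_tad: list[list[int]] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for t in range(config.n_tads_per_chrom):
            start, end = t * tad_width, (t + 1) * tad_width
            tad = TAD(f"tad_{chrom}_{t:02d}", GenomicInterval(chrom, start, end))
            tads.append(tad)
            slots = list(range(start + SLOT_MARGIN, end - SLOT_MARGIN, SLOT_SPACING))
            rng.shuffle(slots)
            slots_by_tad.append(slots)

    n_slots_needed = (config.n_genes + config.n_planted_enhancers
                      + config.n_nonmacrophage_enhancers + config.n_decoy_peak_pairs
                      + config.n_exclusion_intervals)
    if sum(len(s) for s in slots_by_tad) < n_slots_needed:
        raise ValueError(
            f"infeasible packing: {n_slots_needed} features need more slots than "
            f"{sum(len(s) for s in slots_by_tad)} available; increase chrom_length_bp"
        )

    gene_records: list[dict] = []
    enhancer_records: list[dict] = []

    def chrom_of(tad_idx: int) -> str:
        return tads[tad_idx].interval.chrom

    def take_slot(tad_idx: int) -> int:
        if not slots_by_tad[tad_idx]:
            raise ValueError("infeasible packing: TAD ran out of slots")
        return slots_by_tad[tad_idx].pop()

    n_tads = len(tads)
    # planted enhancer + target gene pairs, round-robin over TADs
    for i in range(config.n_planted_enhancers):
        tad_idx = i % n_tads
        shared = rng.random() < config.tad_shared_frac
        gene_tad = tad_idx if shared else (tad_idx + 1) % n_tads
        gene_records.append(
            _make_gene(f"gene_{i:04d}", chrom_of(gene_tad), take_slot(gene_tad),
                       tads[gene_tad].id, rng)
        )
        enhancer_records.append(
            _make_enhancer(f"tenh_{i:04d}", chrom_of(tad_idx), take_slot(tad_idx),
                           tads[tad_idx].id, "macrophage", rng,
                           target_gene=f"gene_{i:04d}", shares_tad=shared)
        )

    remaining_tads = [i for i in range(n_tads) for _ in slots_by_tad[i]]
    rng.shuffle(remaining_tads)

    def next_free() -> int:
        while remaining_tads:
            idx = remaining_tads.pop()
            if slots_by_tad[idx]:
                return idx
        raise ValueError("infeasible packing: no free slots left")

    for i in range(config.n_planted_enhancers, config.n_genes):
        idx = next_free()
        gene_records.append(
            _make_gene(f"gene_{i:04d}", chrom_of(idx), take_slot(idx), tads[idx].id, rng)
        )
    for i in range(config.n_nonmacrophage_enhancers):
        idx = next_free()
        enhancer_records.append(
            _make_enhancer(f"tenh_nm_{i:04d}", chrom_of(idx), take_slot(idx),
                           tads[idx].id, "non_macrophage", rng)
        )
    decoy_records = []
    for i in range(config.n_decoy_peak_pairs):
        idx = next_free()
        decoy_records.append(
            _make_decoy(f"decoy_{i:04d}", chrom_of(idx), take_slot(idx), rng)
        )
    exclusions = []
    for i in range(config.n_exclusion_intervals):
        idx = next_free()
        center = take_slot(idx)
        exclusions.append(GenomicInterval(chrom_of(idx), center - 400, center + 400))

    genes = [_gene_model(rec) for rec in gene_records]
    return SyntheticGenome(genes, tads, exclusions, gene_records,
                           enhancer_records, decoy_records)


def _make_gene(gene_id: str, chrom: str, center: int, tad_id: str,
               rng: np.random.Generator) -> dict:
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(1, 4))
    sign = 1 if strand == "+" else -1
    tss_list = [center + sign * 20 * j for j in range(n_tx)]
    positions = sorted(center + sign * d for d in (0, 10, 20))
    return {
        "gene_id": gene_id,
        "chrom": chrom,
        "strand": strand,
        "center": center,
        "tad_id": tad_id,
        "tss_list": tss_list,
        "positions": positions,
    }


def _gene_model(rec: dict) -> GeneModel:
    chrom, strand = rec["chrom"], rec["strand"]
    transcripts = [
        Transcript(f"{rec['gene_id']}.t{j}", tss, strand)
        for j, tss in enumerate(rec["tss_list"])
    ]
    tss0 = rec["tss_list"][0]
    if strand == "+":
        exons = [
            GenomicInterval(chrom, tss0, tss0 + 200 + 20 * len(transcripts), strand),
            GenomicInterval(chrom, tss0 + 1400, tss0 + 2000, strand),
        ]
    else:
        exons = [
            GenomicInterval(chrom, tss0 - 200 - 20 * len(transcripts), tss0 + 1, strand),
            GenomicInterval(chrom, tss0 - 2000, tss0 - 1400, strand),
        ]
    return GeneModel(rec["gene_id"], chrom, "protein_coding", transcripts, exons)


def _make_enhancer(truth_id: str, chrom: str, center: int, tad_id: str, kind: str,
                   rng: np.random.Generator, target_gene: Optional[str] = None,
                   shares_tad: bool = True) -> dict:
    separation = int(rng.integers(50, 151)) * 2  # 100-300 bp, even
    minus_summit = center - separation // 2
    plus_summit = center + separation // 2
    return {
        "truth_id": truth_id,
        "chrom": chrom,
        "midpoint": center,
        "tad_id": tad_id,
        "kind": kind,
        "target_gene": target_gene,
        "shares_tad": shares_tad,
        "minus_positions": sorted(minus_summit + d for d in (-10, 0, 10)),
        "plus_positions": sorted(plus_summit + d for d in (-10, 0, 10)),
    }


def _make_decoy(truth_id: str, chrom: str, center: int,
                rng: np.random.Generator) -> dict:
    if rng.random() < 0.5:  # convergent: plus cluster left of minus cluster
        plus_c, minus_c = center - 75, center + 75
    else:  # divergent but beyond the pairing gap
        half = int(rng.integers(301, 501))
        minus_c, plus_c = center - half, center + half
    return {
        "truth_id": truth_id,
        "chrom": chrom,
        "minus_positions": sorted(minus_c + d for d in (-10, 0, 10)),
        "plus_positions": sorted(plus_c + d for d in (-10, 0, 10)),
    }


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _make_samples(config: SimulationConfig) -> list[SampleMetadata]:
    samples: list[SampleMetadata] = []
    times = [0.5, 1, 2, 4, 6, 12, 24, 48]
    for i in range(config.n_background_samples):
        samples.append(SampleMetadata(f"bg_{i:03d}", "non_macrophage", "none"))
    for i in range(config.n_untreated):
        samples.append(SampleMetadata(f"mac_u_{i:02d}", "macrophage", "untreated", 0.0))
    for i in range(config.n_ifng):
        samples.append(
            SampleMetadata(f"mac_ifng_{i:02d}", "macrophage", "ifng", times[i % len(times)])
        )
    for i in range(config.n_il4il13):
        samples.append(
            SampleMetadata(f"mac_il4_{i:02d}", "macrophage", "il4il13", times[i % len(times)])
        )
    return samples


def generate_expression(
    config: SimulationConfig,
    genome: SyntheticGenome,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, list[SampleMetadata], SyntheticTruth]:
    """Draw per-position stranded negative-binomial CAGE counts.

    Promoter positions carry gene-level means in every sample.  Planted
    enhancer positions carry eRNA means only in macrophage samples; each
    planted (enhancer, gene) pair shares a per-sample log-normal activity
    factor so their expression correlates near the configured target.
    Condition-responsive pairs are additionally up-scaled in the
    corresponding stimulated samples; non-macrophage enhancers are
    expressed only in background samples; decoy cluster pairs are
    expressed everywhere but are convergent or too far apart to pair.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    samples = _make_samples(config)
    sample_ids = [s.sample_id for s in samples]
    n_s = len(samples)
    is_mac = np.array([s.group == "macrophage" for s in samples])
    is_ifng = np.array([s.condition == "ifng" for s in samples])
    is_il4 = np.array([s.condition == "il4il13" for s in samples])

    sigma = config.latent_sigma()
    v_noise = config.nb_dispersion + 1.0 / config.baseline_mean_tags
    effect_factor = math.exp(
        config.condition_effect_sd_units * math.sqrt(sigma**2 + v_noise)
    )

    # responsive link assignment: disjoint subsets of planted links
    planted = [r for r in genome.enhancer_records if r["kind"] == "macrophage"]
    responsive_state = ["none"] * len(planted)
    order = rng.permutation(len(planted))
    for j in order[: config.n_responsive_ifng]:
        responsive_state[j] = "ifng"
    for j in order[config.n_responsive_ifng:
                   config.n_responsive_ifng + config.n_responsive_il4]:
        responsive_state[j] = "il4il13"

    rows: list[tuple[str, int, str]] = []
    means: list[np.ndarray] = []

    def add_positions(chrom: str, positions: Sequence[int], strand: str,
                      mu: np.ndarray) -> None:
        for pos in positions:
            rows.append((chrom, pos, strand))
            means.append(mu)

    gene_base: dict[str, float] = {}
    for rec in genome.gene_records:
        base = float(rng.lognormal(math.log(config.baseline_mean_tags), 0.6))
        gene_base[rec["gene_id"]] = base

    latents: dict[str, np.ndarray] = {}
    link_rows = []
    for rec, state in zip(planted, responsive_state):
        # activity factors saturate: clipping the log-latent at 2 sd keeps
        # the correlation structure while avoiding single-sample blowups
        z = np.clip(rng.standard_normal(int(is_mac.sum())), -2.0, 2.0)
        a = np.exp(sigma * z - 0.5 * sigma**2)
        factor = np.ones(n_s)
        factor[is_mac] = a
        latents[rec["truth_id"]] = factor
        link_rows.append(
            {
                "truth_id": rec["truth_id"],
                "gene_id": rec["target_gene"],
                "tad_id": rec["tad_id"],
                "shares_tad": rec["shares_tad"],
                "responsive": state,
            }
        )
    link_df = pd.DataFrame(
        link_rows, columns=["truth_id", "gene_id", "tad_id", "shares_tad", "responsive"]
    )

    gene_state = dict(zip(link_df["gene_id"], link_df["responsive"]))
    gene_latent = {
        row["gene_id"]: latents[row["truth_id"]] for row in link_rows
    }

    for rec in genome.gene_records:
        mu = np.full(n_s, gene_base[rec["gene_id"]] / 3.0)
        if rec["gene_id"] in gene_latent:
            mu = mu * gene_latent[rec["gene_id"]]
        state = gene_state.get(rec["gene_id"], "none")
        if state == "ifng":
            mu = np.where(is_ifng, mu * effect_factor, mu)
        elif state == "il4il13":
            mu = np.where(is_il4, mu * effect_factor, mu)
        add_positions(rec["chrom"], rec["positions"], rec["strand"], mu)

    state_by_truth_id = {
        rec["truth_id"]: st for rec, st in zip(planted, responsive_state)
    }
    enh_rows = []
    for idx, rec in enumerate(genome.enhancer_records):
        e_base = float(rng.lognormal(math.log(config.baseline_mean_tags * 0.8), 0.6))
        per_pos = e_base / 6.0  # two strands x three positions
        # off-state leak kept tiny so silent enhancers stay essentially
        # zero-count, as real eRNA is in inactive tissues
        mu = np.full(n_s, 0.002)
        if rec["kind"] == "macrophage":
            mu[is_mac] = per_pos
            mu = mu * latents[rec["truth_id"]]
            state = state_by_truth_id[rec["truth_id"]]
            if state == "ifng":
                mu = np.where(is_ifng, mu * effect_factor, mu)
            elif state == "il4il13":
                mu = np.where(is_il4, mu * effect_factor, mu)
        else:
            mu[~is_mac] = per_pos
            state = "none"
        add_positions(rec["chrom"], rec["minus_positions"], "-", mu)
        add_positions(rec["chrom"], rec["plus_positions"], "+", mu)
        enh_rows.append(
            {
                "truth_id": rec["truth_id"],
                "chrom": rec["chrom"],
                "midpoint": rec["midpoint"],
                "tad_id": rec["tad_id"],
                "kind": rec["kind"],
                "responsive": state,
                "macrophage_specific": rec["kind"] == "macrophage",
            }
        )

    for rec in genome.decoy_records:
        mu = np.full(n_s, config.baseline_mean_tags * 0.5 / 3.0)
        add_positions(rec["chrom"], rec["minus_positions"], "-", mu)
        add_positions(rec["chrom"], rec["plus_positions"], "+", mu)

    mu_mat = np.vstack(means)
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu_mat)
    counts = rng.negative_binomial(r, p)

    tss = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    tss = pd.concat(
        [tss, pd.DataFrame(counts, columns=sample_ids)], axis=1
    ).sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)

    # marker gene panels: responsive target genes per state
    marker_genes = {
        "ifng": sorted(link_df.loc[link_df["responsive"] == "ifng", "gene_id"]),
        "il4il13": sorted(link_df.loc[link_df["responsive"] == "il4il13", "gene_id"]),
    }
    enh_df = pd.DataFrame(enh_rows)
    truth = SyntheticTruth(enh_df, link_df, pd.DataFrame(), marker_genes)
    return tss, samples, truth


# ---------------------------------------------------------------------------
# ChIP intervals and TF summits
# ---------------------------------------------------------------------------

PLANTED_TF_NAMES = ("Spi1", "Cebpb", "Rela", "Irf1", "Stat1", "Junb")


def generate_chip_and_tfbs(
    config: SimulationConfig,
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ChipEnhancerSet, dict[str, list[NarrowPeak]], dict[str, float]]:
    """Chromatin support intervals and TF summit sets.

    ChIP intervals cover ``chip_support_frac`` of the planted macrophage
    enhancers (mostly active, some poised) plus decoy intervals elsewhere.
    Planted TFs receive low-q summits inside ``tf_planting_frac`` of the
    planted enhancers (plus a few above-cutoff summits that must be
    filtered out); decoy TFs receive uniform summits.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    planted = [r for r in genome.enhancer_records if r["kind"] == "macrophage"]

    intervals: list[GenomicInterval] = []
    states: list[str] = []
    chip_flags: dict[str, bool] = {}
    for rec in planted:
        supported = bool(rng.random() < config.chip_support_frac)
        chip_flags[rec["truth_id"]] = supported
        if supported:
            state = "active" if rng.random() < config.chip_active_frac else "poised"
            intervals.append(
                GenomicInterval(rec["chrom"], rec["midpoint"] - 500, rec["midpoint"] + 501)
            )
            states.append(state)
    # decoy chromatin intervals in gene-free space between slots
    for _ in range(20):
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        start = int(rng.integers(0, config.chrom_length_bp - 1000))
        intervals.append(GenomicInterval(chrom, start, start + 1000))
        states.append("poised" if rng.random() < 0.5 else "active")
    chip = ChipEnhancerSet(intervals, states)
    truth.enhancers["chip_supported"] = _chip_column(truth.enhancers, chip_flags)

    tfbs: dict[str, list[NarrowPeak]] = {}
    tf_expression: dict[str, float] = {}
    tf_rows = []
    planted_names = list(PLANTED_TF_NAMES[: config.n_planted_tfs])
    for tf in planted_names:
        peaks: list[NarrowPeak] = []
        chosen = rng.random(len(planted)) < config.tf_planting_frac
        for rec, hit in zip(planted, chosen):
            if not hit:
                continue
            summit = rec["midpoint"] + int(rng.integers(-100, 101))
            peaks.append(_tf_peak(rec["chrom"], summit, f"{tf}_pk{len(peaks)}", 1e-8))
        # above-cutoff summits that the q filter must drop
        for _ in range(5):
            chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            pos = int(rng.integers(500, config.chrom_length_bp - 500))
            peaks.append(_tf_peak(chrom, pos, f"{tf}_weak{len(peaks)}", 1e-2))
        tfbs[tf] = peaks
        tf_expression[tf] = 50.0
        tf_rows.append({"tf": tf, "planted": True, "expression": 50.0})
    for i in range(config.n_decoy_tfs):
        tf = f"DecoyTF{i:02d}"
        peaks = []
        for j in range(config.n_decoy_summits):
            chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            pos = int(rng.integers(500, config.chrom_length_bp - 500))
            peaks.append(_tf_peak(chrom, pos, f"{tf}_pk{j}", 1e-8))
        tfbs[tf] = peaks
        expr = 0.0 if i == config.n_decoy_tfs - 1 else 5.0
        tf_expression[tf] = expr
        tf_rows.append({"tf": tf, "planted": False, "expression": expr})
    truth.tfs = pd.DataFrame(tf_rows, columns=["tf", "planted", "expression"])
    return chip, tfbs, tf_expression


def _chip_column(enh_df: pd.DataFrame, flags: dict[str, bool]) -> list[bool]:
    return [bool(flags.get(tid, False)) for tid in enh_df["truth_id"]]


def _tf_peak(chrom: str, summit: int, name: str, q: float) -> NarrowPeak:
    iv = GenomicInterval(chrom, summit - 50, summit + 51)
    return NarrowPeak(iv, name, summit, q)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _gene_sets(config: SimulationConfig, genome: SyntheticGenome,
               truth: SyntheticTruth, rng: np.random.Generator) -> GeneSetCollection:
    universe = [rec["gene_id"] for rec in genome.gene_records]
    sets = {
        "IFNG_RESPONSE": truth.marker_genes["ifng"]
        + list(rng.choice(universe, size=5, replace=False)),
        "IL4_RESPONSE": truth.marker_genes["il4il13"]
        + list(rng.choice(universe, size=5, replace=False)),
    }
    for i in range(3):
        sets[f"HOUSEKEEPING_{i}"] = list(rng.choice(universe, size=30, replace=False))
    sets = {k: sorted(set(v)) for k, v in sets.items()}
    return GeneSetCollection(sets, universe)


def generate(config: Optional[SimulationConfig] = None,
             seed: Optional[int] = None) -> SyntheticDataset:
    """Generate the full synthetic study (genome, counts, chromatin, TFBS,
    gene sets, truth) from one seed."""
    config = config if config is not None else SimulationConfig()
    if seed is not None:
        config = replace(config, rng_seed=seed)
    rng = np.random.default_rng(config.rng_seed)
    genome = generate_genome(config, rng)
    tss, samples, truth = generate_expression(config, genome, rng)
    chip, tfbs, tf_expression = generate_chip_and_tfbs(config, genome, truth, rng)
    genesets = _gene_sets(config, genome, truth, rng)
    return SyntheticDataset(config, genome, samples, tss, chip, tfbs,
                            tf_expression, genesets, truth)


def realized_link_rho(ds: SyntheticDataset) -> pd.Series:
    """Generator self-check: realized Spearman rho of each planted link,
    computed directly from summed raw counts over macrophage samples."""
    from scipy.stats import spearmanr

    mac_ids = [s.sample_id for s in ds.samples if s.group == "macrophage"]
    enh_by_id = {r["truth_id"]: r for r in ds.genome.enhancer_records}
    gene_by_id = {r["gene_id"]: r for r in ds.genome.gene_records}
    tss = ds.tss
    out = {}
    for row in ds.truth.links.itertuples(index=False):
        erec = enh_by_id[row.truth_id]
        grec = gene_by_id[row.gene_id]
        e_pos = set(erec["minus_positions"]) | set(erec["plus_positions"])
        g_pos = set(grec["positions"])
        e = tss[(tss["chrom"] == erec["chrom"]) & tss["pos"].isin(e_pos)][mac_ids].sum()
        g = tss[(tss["chrom"] == grec["chrom"]) & tss["pos"].isin(g_pos)][mac_ids].sum()
        out[row.truth_id] = float(spearmanr(e, g).statistic)
    return pd.Series(out)


def score_against_truth(result, ds: SyntheticDataset,
                        midpoint_tolerance: int = 100) -> dict:
    """Score a pipeline run against the planted truth.

    Returns recovery fractions for planted enhancers (a planted enhancer is
    recovered when a transcribed, chromatin-supported called region has its
    midpoint within ``midpoint_tolerance`` bp of the planted midpoint),
    planted enhancer-gene links, cross-TAD link count, and planted/decoy TF
    retention.
    """
    planted = ds.truth.enhancers[ds.truth.enhancers["kind"] == "macrophage"]
    called = [e for e in result.enhancers if e.transcribed and e.chip_supported]
    match: dict[str, str] = {}  # truth_id -> called enhancer id
    for row in planted.itertuples(index=False):
        best = None
        for e in called:
            if e.interval.chrom != row.chrom:
                continue
            d = abs(e.midpoint - row.midpoint)
            if d <= midpoint_tolerance and (best is None or d < best[0]):
                best = (d, e.id)
        if best is not None:
            match[row.truth_id] = best[1]
    enh_recovery = len(match) / len(planted) if len(planted) else float("nan")

    gene_links = {
        (row.enhancer_id, row.gene_id)
        for row in result.gene_links.itertuples(index=False)
    }
    truth_links = ds.truth.links[ds.truth.links["shares_tad"]]
    n_rec = sum(
        (match.get(row.truth_id), row.gene_id) in gene_links
        for row in truth_links.itertuples(index=False)
    )
    link_recovery = n_rec / len(truth_links) if len(truth_links) else float("nan")

    from .interactome import assert_no_cross_tad

    promoters = [p for p in result.peaks]
    cross = assert_no_cross_tad(result.links, result.enhancers, promoters, ds.tads)

    planted_tfs = set(ds.truth.tfs.loc[ds.truth.tfs["planted"], "tf"])
    decoy_tfs = set(ds.truth.tfs.loc[~ds.truth.tfs["planted"], "tf"])
    retained = set(result.retained_tfs)
    tf_recall = (len(planted_tfs & retained) / len(planted_tfs)
                 if planted_tfs else float("nan"))
    decoy_rejection = (len(decoy_tfs - retained) / len(decoy_tfs)
                       if decoy_tfs else float("nan"))
    return {
        "enhancer_recovery": enh_recovery,
        "link_recovery": link_recovery,
        "n_cross_tad_links": cross,
        "tf_recall": tf_recall,
        "decoy_tf_rejection": decoy_rejection,
        "n_planted_enhancers": int(len(planted)),
        "n_planted_links": int(len(truth_links)),
    }


# ---------------------------------------------------------------------------
# File emission (the exact input formats the pipeline consumes)
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "tfbs"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)

    write_tss_counts(ds.tss, os.path.join(outdir, "tss_counts.tsv"))
    write_sample_metadata(ds.samples, os.path.join(outdir, "samples.tsv"))
    _write_gtf(ds.genes, os.path.join(outdir, "genes.gtf"))
    write_bed(
        [BedRecord(t.interval, t.id) for t in ds.tads],
        os.path.join(outdir, "tads.bed"), columns=4,
    )
    write_bed(
        [BedRecord(iv, st) for iv, st in zip(ds.chip.intervals, ds.chip.states)],
        os.path.join(outdir, "chip_enhancers.bed"), columns=4,
    )
    write_bed(
        [BedRecord(iv, "exclusion") for iv in ds.exclusions],
        os.path.join(outdir, "exclusions.bed"), columns=4,
    )
    for tf, peaks in ds.tfbs.items():
        write_narrowpeak(peaks, os.path.join(outdir, "tfbs", f"{tf}.narrowPeak"))
    pd.DataFrame(
        {"tf": list(ds.tf_expression), "tpm": list(ds.tf_expression.values())}
    ).to_csv(os.path.join(outdir, "tf_expression.tsv"), sep="\t", index=False)
    write_gmt(ds.genesets, os.path.join(outdir, "gene_sets.gmt"))
    rows = [
        {"gene": g, "state": state}
        for state, genes in ds.truth.marker_genes.items()
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene", "state"]).to_csv(
        os.path.join(outdir, "marker_genes.tsv"), sep="\t", index=False
    )
    ds.truth.enhancers.to_csv(
        os.path.join(outdir, "truth", "enhancers.tsv"), sep="\t", index=False
    )
    ds.truth.links.to_csv(
        os.path.join(outdir, "truth", "links.tsv"), sep="\t", index=False
    )
    ds.truth.tfs.to_csv(os.path.join(outdir, "truth", "tfs.tsv"), sep="\t", index=False)


def _write_gtf(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gm in genes:
            g_start = min(min(t.tss for t in gm.transcripts),
                          min(e.start for e in gm.exons))
            g_end = max(max(t.tss for t in gm.transcripts) + 1,
                        max(e.end for e in gm.exons))
            strand = gm.transcripts[0].strand
            attrs = f'gene_id "{gm.gene_id}"; gene_biotype "{gm.biotype}";'
            fh.write(
                "\t".join([gm.chrom, "sim", "gene", str(g_start + 1), str(g_end),
                           ".", strand, ".", attrs]) + "\n"
            )
            for tx in gm.transcripts:
                tx_exons = _transcript_exons(gm, tx)
                t_start = min(e.start for e in tx_exons)
                t_end = max(e.end for e in tx_exons)
                t_attrs = (f'gene_id "{gm.gene_id}"; transcript_id "{tx.transcript_id}"; '
                           f'gene_biotype "{gm.biotype}";')
                fh.write(
                    "\t".join([gm.chrom, "sim", "transcript", str(t_start + 1),
                               str(t_end), ".", tx.strand, ".", t_attrs]) + "\n"
                )
                for e in tx_exons:
                    fh.write(
                        "\t".join([gm.chrom, "sim", "exon", str(e.start + 1),
                                   str(e.end), ".", tx.strand, ".", t_attrs]) + "\n"
                    )


def _transcript_exons(gm: GeneModel, tx: Transcript) -> list[GenomicInterval]:
    """Exons attributed to one transcript, stretched so the transcript span
    starts exactly at its TSS (keeps the 5'-end definition exact on both
    strands)."""
    exons = []
    for e in gm.exons:
        start, end = e.start, e.end
        if tx.strand == "+":
            if e.start == min(x.start for x in gm.exons):
                start = tx.tss
        else:
            if e.end == max(x.end for x in gm.exons):
                end = tx.tss + 1
        if end > start:
            exons.append(GenomicInterval(gm.chrom, start, end, tx.strand))
    return exons
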