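"""End-to-end pipeline: quantify -> call -> chip-filter -> link -> classify
-> enrich -> report.

The pipeline runs either from in-memory objects (a
:class:`~ernalink.synthetic_data.SyntheticDataset` or
:class:`PipelineInputs`) or from a directory of standard-format files, and
optionally persists every stage's output as TSV/BED next to a JSON run
manifest (config snapshot, input checksums, stage timings, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .enhancer_calling import (
    ChipEnhancerSet,
    EnhancerRegion,
    call_bidirectional,
    chip_filter,
    cluster_tss,
    flag_transcribed,
    mask_peaks,
    quantify_ernas,
)
from .enrichment import (
    GeneSetCollection,
    TfbsPeakSet,
    filter_summits,
    gene_set_enrichment,
    read_gmt,
    sample_background_regions,
    tfbs_enrichment,
)
from .expression_quant import (
    Config,
    ExpressionMatrix,
    PromoterAssignment,
    assign_promoters,
    filter_expressed,
    gene_expression,
    sum_tss_to_peaks,
    tmm_factors,
    to_tpm,
)
from .genome_model import (
    BedRecord,
    CagePeak,
    GeneModel,
    GenomicInterval,
    NarrowPeak,
    SampleMetadata,
    TAD,
    read_bed,
    read_gene_models,
    read_narrowpeak,
    read_sample_metadata,
    read_tads,
    read_tss_counts,
    write_bed,
)
from .interactome import (
    assert_no_cross_tad,
    correlate_pairs,
    map_to_genes,
    select_links,
    tad_pairs,
)
from .specificity import (
    condition_links,
    load_marker_genes,
    macrophage_specific,
    marker_enhancers,
    stimuli_responsive,
    zscores,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    tss: pd.DataFrame
    samples: list[SampleMetadata]
    genes: list[GeneModel]
    tads: list[TAD]
    chip: ChipEnhancerSet
    tfbs: dict[str, list[NarrowPeak]]
    tf_expression: dict[str, float]
    genesets: Optional[GeneSetCollection] = None
    exclusions: list[GenomicInterval] = field(default_factory=list)
    marker_genes: Optional[dict[str, list[str]]] = None
    source_files: dict[str, str] = field(default_factory=dict)


INPUT_FILES = {
    "tss": "tss_counts.tsv",
    "samples": "samples.tsv",
    "genes": "genes.gtf",
    "tads": "tads.bed",
    "chip": "chip_enhancers.bed",
    "exclusions": "exclusions.bed",
    "tf_expression": "tf_expression.tsv",
    "gene_sets": "gene_sets.gmt",
    "marker_genes": "marker_genes.tsv",
}


def load_inputs(indir: str | os.PathLike) -> PipelineInputs:
    """Load pipeline inputs from a directory laid out as ``simulate`` writes
    them.  All required files are validated up front, before any
    computation."""
    indir = os.fspath(indir)
    paths = {k: os.path.join(indir, v) for k, v in INPUT_FILES.items()}
    missing = [p for k, p in paths.items()
               if k not in ("gene_sets", "marker_genes", "exclusions")
               and not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    tss = read_tss_counts(paths["tss"])
    samples = read_sample_metadata(paths["samples"])
    genes = read_gene_models(paths["genes"])
    tads = read_tads(paths["tads"])
    chip_recs = read_bed(paths["chip"], expected_columns=4)
    chip = ChipEnhancerSet([r.interval for r in chip_recs],
                           [r.name for r in chip_recs])
    exclusions = []
    if os.path.exists(paths["exclusions"]):
        exclusions = [r.interval for r in read_bed(paths["exclusions"])]
    tfbs: dict[str, list[NarrowPeak]] = {}
    tfbs_dir = os.path.join(indir, "tfbs")
    if os.path.isdir(tfbs_dir):
        for fn in sorted(os.listdir(tfbs_dir)):
            if fn.endswith(".narrowPeak"):
                tfbs[fn[: -len(".narrowPeak")]] = read_narrowpeak(
                    os.path.join(tfbs_dir, fn)
                )
    tf_expression = {}
    if os.path.exists(paths["tf_expression"]):
        df = pd.read_csv(paths["tf_expression"], sep="\t")
        tf_expression = dict(zip(df["tf"].astype(str), df["tpm"].astype(float)))
    genesets = None
    if os.path.exists(paths["gene_sets"]):
        genesets = read_gmt(paths["gene_sets"], [g.gene_id for g in genes])
    marker = None
    if os.path.exists(paths["marker_genes"]):
        marker = load_marker_genes(paths["marker_genes"])
    return PipelineInputs(
        tss, samples, genes, tads, chip, tfbs, tf_expression, genesets,
        exclusions, marker, source_files={k: p for k, p in paths.items()
                                          if os.path.exists(p)},
    )


@dataclass
class PipelineResult:
    config: Config
    seed: int
    peaks: list[CagePeak]
    assignments: list[PromoterAssignment]
    promoter_tpm: ExpressionMatrix  # expression-filtered promoters
    gene_tpm: ExpressionMatrix
    enhancers: list[EnhancerRegion]
    enhancer_tpm: ExpressionMatrix
    scored_pairs: pd.DataFrame
    links: pd.DataFrame
    gene_links: pd.DataFrame
    gene_summaries: pd.DataFrame  # gene_id, n_enhancers
    specific_enhancers: list[str]
    specific_genes: list[str]
    responsive_enhancers: dict[str, list[str]]
    responsive_genes: dict[str, list[str]]
    state_links: dict[str, pd.DataFrame]
    state_gene_links: dict[str, pd.DataFrame]
    markers: list
    gsea: pd.DataFrame
    tfbs_results: pd.DataFrame
    retained_tfs: list[str]
    report: dict
    manifest: dict


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100 * a / b rounded half-up to the requested number of decimals."""
    if denominator == 0:
        return float("nan")
    quantum = Decimal(1).scaleb(-decimals)
    val = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(val)


def run_pipeline(
    inputs: "PipelineInputs",
    config: Optional[Config] = None,
    seed: int = 0,
    outdir: Optional[str | os.PathLike] = None,
) -> PipelineResult:
    """Execute every stage in order on the given inputs.

    ``seed`` drives the Monte-Carlo enrichment resampling only; all other
    stages are deterministic.  With the same inputs and seed the outputs
    are identical.
    """
    from .synthetic_data import SyntheticDataset

    if isinstance(inputs, SyntheticDataset):
        inputs = PipelineInputs(
            inputs.tss, inputs.samples, inputs.genes, inputs.tads, inputs.chip,
            inputs.tfbs, inputs.tf_expression, inputs.genesets,
            inputs.exclusions, inputs.truth.marker_genes,
        )
    cfg = config if config is not None else Config()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 3)
        logger.info("stage %-14s %.2fs", stage, now - t0)
        t0 = now

    samples = inputs.samples
    sample_ids = [s.sample_id for s in samples]
    mac_ids = [s.sample_id for s in samples if s.group == "macrophage"]
    bg_ids = [s.sample_id for s in samples if s.group == "non_macrophage"]
    state_ids = {
        "ifng": [s.sample_id for s in samples if s.condition == "ifng"],
        "il4il13": [s.sample_id for s in samples if s.condition == "il4il13"],
    }
    untreated_ids = [s.sample_id for s in samples if s.condition == "untreated"]

    # --- quantify: peaks, promoters, normalization -------------------------
    peaks = cluster_tss(inputs.tss, sample_ids, max_gap=20)
    assignments = assign_promoters(peaks, inputs.genes, cfg.promoter_window_bp)
    assigned_ids = {a.peak_id for a in assignments}
    promoter_peaks = [pk for pk in peaks if pk.id in assigned_ids]
    promoter_counts = sum_tss_to_peaks(inputs.tss, promoter_peaks, samples)
    factors = tmm_factors(promoter_counts)
    lib_sizes = promoter_counts.values.to_numpy().sum(axis=0)
    promoter_tpm_all = to_tpm(promoter_counts, factors)
    expressed_promoters = filter_expressed(
        promoter_tpm_all, mac_ids, cfg.tpm_min, cfg.expressed_frac
    )
    promoter_tpm = promoter_tpm_all.subset_features(expressed_promoters)
    gene_tpm = gene_expression(promoter_tpm, assignments)
    tick("quantify")

    # --- call enhancers ----------------------------------------------------
    masked = mask_peaks(peaks, inputs.genes, cfg.promoter_window_bp, cfg.exon_mask_bp)
    enhancers = call_bidirectional(
        masked, cfg.divergent_gap_bp, cfg.enhancer_halfwidth_bp, cfg.directionality_max
    )
    enhancer_counts = quantify_ernas(enhancers, inputs.tss, samples)
    enhancer_tpm = to_tpm(enhancer_counts, factors, lib_sizes=lib_sizes)
    flag_transcribed(enhancers, enhancer_counts, mac_ids, cfg.transcribed_frac)
    chip_filter(enhancers, inputs.chip)
    tick("call")

    # --- link --------------------------------------------------------------
    active = [e for e in enhancers if e.transcribed and e.chip_supported]
    link_promoters = [pk for pk in promoter_peaks if pk.id in set(expressed_promoters)]
    pairs = tad_pairs(active, link_promoters, inputs.tads)
    scored = correlate_pairs(pairs, enhancer_tpm, promoter_tpm, mac_ids)
    links = select_links(scored, cfg.link_fdr)
    n_cross = assert_no_cross_tad(links, enhancers, link_promoters, inputs.tads)
    if n_cross:
        raise AssertionError(f"{n_cross} selected links cross a TAD boundary")
    gene_links, summaries = map_to_genes(
        links, assignments, expressed_genes=gene_tpm.feature_ids
    )
    summary_df = pd.DataFrame(
        [{"gene_id": s.gene_id, "n_enhancers": s.n_enhancers} for s in summaries]
    )
    tick("link")

    # --- classify ----------------------------------------------------------
    linked_enh = sorted(set(links["enhancer_id"])) if len(links) else []
    zres_enh = zscores(enhancer_tpm, mac_ids, bg_ids, cfg.z_threshold)
    specific_enh = macrophage_specific(
        zres_enh, len(mac_ids), cfg.specific_frac, cfg.z_threshold
    )
    zres_gene = zscores(gene_tpm, mac_ids, bg_ids, cfg.z_threshold)
    specific_genes = macrophage_specific(
        zres_gene, len(mac_ids), cfg.specific_frac, cfg.z_threshold
    )
    for e in enhancers:
        e.macrophage_specific = e.id in set(specific_enh)

    responsive_enh: dict[str, list[str]] = {}
    responsive_genes: dict[str, list[str]] = {}
    responsive_prom: dict[str, list[str]] = {}
    for state, ids in state_ids.items():
        responsive_enh[state] = stimuli_responsive(
            enhancer_tpm, ids, untreated_ids, cfg.responsive_frac, cfg.z_threshold
        )
        responsive_genes[state] = stimuli_responsive(
            gene_tpm, ids, untreated_ids, cfg.responsive_frac, cfg.z_threshold
        )
        responsive_prom[state] = stimuli_responsive(
            promoter_tpm, ids, untreated_ids, cfg.responsive_frac, cfg.z_threshold
        )
    for e in enhancers:
        e.responsive_ifng = e.id in set(responsive_enh["ifng"])
        e.responsive_il4 = e.id in set(responsive_enh["il4il13"])

    state_links: dict[str, pd.DataFrame] = {}
    state_gene_links: dict[str, pd.DataFrame] = {}
    for state, ids in state_ids.items():
        sl = condition_links(
            links, enhancer_tpm, promoter_tpm, ids,
            responsive_enh[state], responsive_prom[state],
        )
        state_links[state] = sl
        state_gene_links[state], _ = map_to_genes(sl, assignments)

    marker_genes = inputs.marker_genes if inputs.marker_genes is not None else load_marker_genes()
    markers = marker_enhancers(
        responsive_enh, state_gene_links, marker_genes, enhancer_tpm,
        state_ids, cfg.responsive_frac, cfg.z_threshold,
    )
    marker_ids = {(m.state, m.enhancer_id) for m in markers}
    for e in enhancers:
        e.marker_ifng = ("ifng", e.id) in marker_ids
        e.marker_il4 = ("il4il13", e.id) in marker_ids
        e.validate_flags()
    tick("classify")

    # --- enrich ------------------------------------------------------------
    rng = np.random.default_rng(seed)
    linked_genes = sorted(set(gene_links["gene_id"])) if len(gene_links) else []
    if inputs.genesets is not None and linked_genes:
        gsea = gene_set_enrichment(linked_genes, inputs.genesets)
    else:
        gsea = pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "q"])

    tf_sets = [
        TfbsPeakSet(tf, filter_summits(pks, cfg.tfbs_summit_fdr),
                    inputs.tf_expression.get(tf, 0.0))
        for tf, pks in sorted(inputs.tfbs.items())
    ]
    query = [e.interval for e in enhancers if e.macrophage_specific]
    all_pool = [e.interval for e in enhancers]
    non_mac_pool = [e.interval for e in enhancers if not e.transcribed]
    if query and tf_sets and len(non_mac_pool) >= len(query):
        exclusion_set = (
            list(inputs.exclusions)
            + [ex for g in inputs.genes for ex in g.exons]
            + all_pool
        )
        widths = [iv.width for iv in query]
        k = len(query)

        def random_bg(r: np.random.Generator) -> list[GenomicInterval]:
            return sample_background_regions(k, widths, inputs.tads, exclusion_set, r)

        tfbs_df, retained = tfbs_enrichment(
            query, tf_sets,
            {"all_enhancers": all_pool, "non_macrophage_enhancers": non_mac_pool},
            random_bg, trials=cfg.mc_trials, alpha=cfg.mc_alpha, rng=rng,
        )
    else:
        tfbs_df = pd.DataFrame()
        retained = []
    tick("enrich")

    # --- report ------------------------------------------------------------
    report = report_summary(
        enhancers, links, gene_links, summary_df, specific_enh, linked_enh,
        responsive_enh, responsive_genes, markers,
    )
    tick("report")

    manifest = {
        "tool": "ernalink",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "input_checksums": {
            k: _sha256(p) for k, p in inputs.source_files.items()
        },
        "stage_timings_s": timings,
    }
    result = PipelineResult(
        cfg, seed, peaks, assignments, promoter_tpm, gene_tpm, enhancers,
        enhancer_tpm, scored, links, gene_links, summary_df, specific_enh,
        specific_genes, responsive_enh, responsive_genes, state_links,
        state_gene_links, markers, gsea, tfbs_df, retained, report, manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def report_summary(
    enhancers: Sequence[EnhancerRegion],
    links: pd.DataFrame,
    gene_links: pd.DataFrame,
    gene_summaries: pd.DataFrame,
    specific_enhancers: Sequence[str],
    linked_enhancers: Sequence[str],
    responsive_enhancers: dict[str, Sequence[str]],
    responsive_genes: dict[str, Sequence[str]],
    markers: Sequence,
) -> dict:
    """Summary counts and percentages (half-up rounding at the printed
    precision; every percentage recomputes exactly from the numerator and
    denominator columns also present in the report)."""
    n_candidates = len(enhancers)
    n_transcribed = sum(e.transcribed for e in enhancers)
    n_chip = sum(e.transcribed and e.chip_supported for e in enhancers)
    n_active = len(set(linked_enhancers))
    n_specific_active = len(set(specific_enhancers) & set(linked_enhancers))
    bins = gene_summaries["n_enhancers"] if len(gene_summaries) else pd.Series(dtype=int)
    n_genes = int(len(bins))
    n_zero = int((bins == 0).sum())
    resp_i = set(responsive_enhancers.get("ifng", ()))
    resp_a = set(responsive_enhancers.get("il4il13", ()))
    report = {
        "rounding": "half-up at printed precision",
        "n_enhancer_candidates": n_candidates,
        "n_transcribed_enhancers": n_transcribed,
        "n_chip_supported_transcribed": n_chip,
        "pct_chip_supported_of_transcribed": percent(n_chip, n_transcribed, 0),
        "n_links": int(len(links)),
        "n_gene_links": int(len(gene_links)),
        "n_active_enhancers": n_active,
        "n_macrophage_specific_active": n_specific_active,
        "pct_macrophage_specific_of_active": percent(n_specific_active, n_active, 1),
        "n_genes_expressed": n_genes,
        "n_genes_without_enhancer": n_zero,
        "pct_genes_without_enhancer": percent(n_zero, n_genes, 1),
        "genes_by_enhancer_count": {
            str(k): int(v) for k, v in bins.value_counts().sort_index().items()
        },
        "n_responsive_ifng_enhancers": len(resp_i),
        "n_responsive_il4il13_enhancers": len(resp_a),
        "n_responsive_both_states": len(resp_i & resp_a),
        "n_responsive_ifng_genes": len(responsive_genes.get("ifng", ())),
        "n_responsive_il4il13_genes": len(responsive_genes.get("il4il13", ())),
        "n_marker_ifng": sum(1 for m in markers if m.state == "ifng"),
        "n_marker_il4il13": sum(1 for m in markers if m.state == "il4il13"),
    }
    return report


def write_outputs(result: PipelineResult, outdir: str | os.PathLike) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_bed(
        [
            BedRecord(e.interval, e.id, e.pooled_tags)
            for e in result.enhancers
        ],
        os.path.join(outdir, "enhancers.bed"), columns=5,
    )
    flags = pd.DataFrame(
        [
            {
                "enhancer_id": e.id,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "midpoint": e.midpoint,
                "directionality": e.directionality,
                "transcribed": e.transcribed,
                "chip_supported": e.chip_supported,
                "chip_state": e.chip_state,
                "macrophage_specific": e.macrophage_specific,
                "responsive_ifng": e.responsive_ifng,
                "responsive_il4il13": e.responsive_il4,
                "marker_ifng": e.marker_ifng,
                "marker_il4il13": e.marker_il4,
            }
            for e in result.enhancers
        ]
    )
    flags.to_csv(os.path.join(outdir, "enhancer_flags.tsv"), sep="\t", index=False)
    result.enhancer_tpm.values.to_csv(
        os.path.join(outdir, "enhancer_tpm.tsv"), sep="\t"
    )
    result.promoter_tpm.values.to_csv(
        os.path.join(outdir, "promoter_tpm.tsv"), sep="\t"
    )
    result.gene_tpm.values.to_csv(os.path.join(outdir, "gene_tpm.tsv"), sep="\t")
    pd.DataFrame(
        [
            {"peak_id": a.peak_id, "transcript_ids": ",".join(a.transcript_ids),
             "gene_ids": ",".join(a.gene_ids)}
            for a in result.assignments
        ]
    ).to_csv(os.path.join(outdir, "promoter_assignments.tsv"), sep="\t", index=False)
    result.links.to_csv(os.path.join(outdir, "links.tsv"), sep="\t", index=False)
    result.gene_links.to_csv(
        os.path.join(outdir, "gene_links.tsv"), sep="\t", index=False
    )
    result.gene_summaries.to_csv(
        os.path.join(outdir, "gene_enhancer_counts.tsv"), sep="\t", index=False
    )
    _write_bedpe(result, os.path.join(outdir, "links.bedpe"))
    pd.DataFrame(
        [
            {"enhancer_id": m.enhancer_id, "state": m.state,
             "marker_genes": ",".join(m.marker_gene_ids)}
            for m in result.markers
        ]
    ).to_csv(os.path.join(outdir, "marker_enhancers.tsv"), sep="\t", index=False)
    result.gsea.to_csv(os.path.join(outdir, "gsea.tsv"), sep="\t", index=False)
    result.tfbs_results.to_csv(
        os.path.join(outdir, "tfbs_enrichment.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def _write_bedpe(result: PipelineResult, path: str) -> None:
    enh = {e.id: e.interval for e in result.enhancers}
    prom = {p.id: p.interval for p in result.peaks}
    with open(path, "w") as fh:
        for row in result.links.itertuples(index=False):
            a = enh[row.enhancer_id]
            b = prom[row.promoter_id]
            fh.write(
                "\t".join(
                    [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start),
                     str(b.end), f"{row.enhancer_id}--{row.promoter_id}",
                     f"{row.rho:.4f}", ".", b.strand]
                )
                + "\n"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    try:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
    except OSError:
        return "unavailable"
    return h.hexdigest()
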