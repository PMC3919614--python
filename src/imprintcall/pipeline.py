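"""End-to-end orchestration: counts in, calls/extensions/vetting/QC out.

Stages run in a fixed order (counts -> candidate discovery -> strain-variant
exclusion -> Fisher/FDR testing -> annotation/aggregation -> extension
detection -> vetting -> catalogue bookkeeping), every exclusion carries a
reason code, and each run emits a machine-readable manifest with the record
count surviving each filter.  Identical inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotate_aggregate import summarize_catalogue
from .annotate_aggregate import aggregate_transcripts, annotate_snps
from .candidate_vetting import (
    VettingThresholds,
    read_paralog_bed,
    vet_prediction_set,
    vet_transcript,
)
from .counts_io import Cross, CrossDesign, read_annotation, read_counts, read_sites_vcf
from .errors import ImprintcallError, ValidationError
from .extension_detect import detect_extensions, extension_summary, extensions_to_bed
from .imprint_test import call_true_snps
from .snp_discovery import exclude_strain_variants, find_candidates
from .util import round_half_up


@dataclass
class RunConfig:
    counts_a: str
    counts_b: str
    annotation: str
    cross_a: str = "JXO"
    cross_b: str = "OXJ"
    mother_a: str = "JF1"
    father_a: str = "OG2"
    alt_strain: str = "JF1"
    catalogue: Optional[str] = None
    variant_vcf: Optional[str] = None
    paralog_bed: Optional[str] = None
    min_af: float = 0.80
    min_cov: int = 10
    both_af: float = 0.80
    fdr_max: float = 0.05
    recip_af_max: float = 0.20
    fdr_family: str = "pooled"
    exonic_only: bool = False
    max_gap: int = 10_000
    min_snps: int = 2
    max_reach: int = 100_000
    vetting: VettingThresholds = field(default_factory=VettingThresholds)
    outdir: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.min_af <= 1 or not 0 <= self.recip_af_max < self.min_af:
            raise ValidationError("need 0 <= recip_af_max < min_af <= 1")
        if not 0 < self.fdr_max <= 1:
            raise ValidationError("fdr_max must be in (0, 1]")

    def design(self) -> CrossDesign:
        return CrossDesign(
            crosses=(
                Cross(self.cross_a, self.mother_a, self.father_a),
                Cross(self.cross_b, self.father_a, self.mother_a),
            ),
            alt_strain=self.alt_strain,
        )


@dataclass
class PipelineResult:
    snp_tests: list
    excluded_sites: list
    annotated: list
    transcript_calls: list
    extensions: list
    unassigned_clusters: list
    vetting_reports: dict
    vetting_partition: Optional[object]
    catalogue_summary: Optional[object]
    manifest: dict


FUNNEL_STAGES = ("sites", "candidates", "post_strain_exclusion", "true_snps")


def filter_funnel(manifest: dict) -> list:
    """Ordered (stage, count) table of records surviving each filter.

    The funnel must be monotone non-increasing; any increase indicates an
    accounting bug and raises.
    """
    counts = manifest["stage_counts"]
    funnel = [(stage, counts[stage]) for stage in FUNNEL_STAGES]
    for (s1, c1), (s2, c2) in zip(funnel, funnel[1:]):
        if c2 > c1:
            raise AssertionError(f"funnel increased from {s1}={c1} to {s2}={c2}")
    return funnel


def run(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline for one reciprocal-cross dataset."""
    design = config.design()
    stage = "counts_io"
    try:
        counts_a = read_counts(config.counts_a, config.cross_a)
        counts_b = read_counts(config.counts_b, config.cross_b)
        models = read_annotation(config.annotation)
        restrict = read_sites_vcf(config.variant_vcf) if config.variant_vcf else None
        paralogs = read_paralog_bed(config.paralog_bed) if config.paralog_bed else None
        catalogue = (
            pd.read_csv(config.catalogue, sep="\t") if config.catalogue else None
        )

        stage = "snp_discovery"
        candidates = find_candidates(
            counts_a, counts_b, min_af=config.min_af, min_cov=config.min_cov,
            restrict_to=restrict,
        )
        kept, excluded = exclude_strain_variants(candidates, both_af=config.both_af)

        stage = "imprint_test"
        tests = call_true_snps(
            kept, design, fdr_max=config.fdr_max,
            recip_af_max=config.recip_af_max, fdr_family=config.fdr_family,
        )
        true_tests = [t for t in tests if t.is_true]

        stage = "annotate_aggregate"
        annotated = annotate_snps(tests, models, exonic_only=config.exonic_only)
        calls = aggregate_transcripts(annotated)
        clean_calls = [c for c in calls if c.consensus_origin != "CONFLICT"]

        stage = "extension_detect"
        extensions, unassigned = detect_extensions(
            annotated, clean_calls, models, max_gap=config.max_gap,
            min_snps=config.min_snps, max_reach=config.max_reach,
        )

        stage = "candidate_vetting"
        all_candidates = list(kept) + [e.candidate for e in excluded]
        true_keys = {t.candidate.key for t in true_tests}
        reports = {}
        for model in models:
            report = vet_transcript(
                model, all_candidates, true_keys, thresholds=config.vetting,
                excluded_intervals=paralogs,
            )
            if report is not None:
                reports[model.transcript_id] = report
        catalogue_genes = set(catalogue["gene"]) if catalogue is not None else set()
        novel_calls = [
            c for c in clean_calls
            if c.gene_name not in catalogue_genes
            and c.transcript_id not in catalogue_genes
        ]
        partition = vet_prediction_set(novel_calls, reports) if novel_calls else None

        stage = "catalogue_summary"
        cat_summary = (
            summarize_catalogue(clean_calls, catalogue)
            if catalogue is not None else None
        )
    except ImprintcallError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    site_keys = {r.key for r in counts_a} | {r.key for r in counts_b}
    manifest = {
        "tool": "imprintcall",
        "version": __version__,
        "inputs": {
            "counts_a": str(config.counts_a),
            "counts_b": str(config.counts_b),
            "annotation": str(config.annotation),
            "catalogue": str(config.catalogue) if config.catalogue else None,
        },
        "design": {
            "cross_a": config.cross_a, "cross_b": config.cross_b,
            "mother_a": config.mother_a, "father_a": config.father_a,
            "alt_strain": config.alt_strain,
        },
        "thresholds": {
            "min_af": config.min_af, "min_cov": config.min_cov,
            "both_af": config.both_af, "fdr_max": config.fdr_max,
            "recip_af_max": config.recip_af_max, "fdr_family": config.fdr_family,
            "max_gap": config.max_gap, "min_snps": config.min_snps,
            "max_reach": config.max_reach,
        },
        "stage_counts": {
            "sites": len(site_keys),
            "candidates": len(candidates),
            "strain_variants_excluded": len(excluded),
            "post_strain_exclusion": len(kept),
            "true_snps": len(true_tests),
            "false_snps": len(tests) - len(true_tests),
            "true_snps_by_cross": {
                c: sum(1 for t in true_tests if t.discovering_cross == c)
                for c in design.cross_ids
            },
            "transcript_calls": len(calls),
            "conflict_transcripts": len(calls) - len(clean_calls),
            "extensions": len(extensions),
            "unassigned_clusters": len(unassigned),
        },
    }

    result = PipelineResult(
        snp_tests=tests,
        excluded_sites=excluded,
        annotated=annotated,
        transcript_calls=clean_calls,
        extensions=extensions,
        unassigned_clusters=unassigned,
        vetting_reports=reports,
        vetting_partition=partition,
        catalogue_summary=cat_summary,
        manifest=manifest,
    )
    if config.outdir:
        write_result(result, config.outdir)
    return result


# ---------------------------------------------------------------------------
# output tables


def snp_table(result: PipelineResult) -> pd.DataFrame:
    """Per-SNP decision table mirroring the reported per-transcript rows."""
    rows = []
    for ann in result.annotated:
        t = ann.test
        cand = t.candidate
        ref_d, alt_d = cand.ref_alt(t.discovering_cross)
        ref_c, alt_c = cand.ref_alt(t.confirming_cross)
        af_d = cand.af(t.discovering_cross)
        af_c = cand.af(t.confirming_cross)
        rows.append(
            {
                "snp_id": cand.snp_id,
                "transcripts": ",".join(h.model.transcript_id for h in ann.hits)
                or "intergenic",
                "discovering_cross": t.discovering_cross,
                "alt_disc": alt_d, "ref_disc": ref_d,
                "ref_conf": ref_c, "alt_conf": alt_c,
                "af_disc": None if af_d is None else round_half_up(af_d, 2),
                "af_conf": None if af_c is None else round_half_up(af_c, 2),
                "p_value": t.p_value,
                "odds_ratio": t.odds_ratio,
                "odds_ratio_haldane": t.odds_ratio_haldane,
                "fdr": t.fdr,
                "status": t.status,
                "fail_reasons": ";".join(sorted(t.fail_reasons)),
                "origin": t.origin,
            }
        )
    return pd.DataFrame(rows)


def transcript_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for c in result.transcript_calls:
        row = {
            "transcript": c.transcript_id,
            "n_snps": c.n_true_snps,
            "avg_reads": c.mean_reads_per_snp,
            "strand": c.strand,
            "representative_snp": c.representative_snp,
            "origin": c.consensus_origin,
        }
        for cross, mean in sorted(c.mean_reads_by_cross.items()):
            row[f"avg_reads_{cross}"] = round_half_up(mean, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def extension_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "extension": f"{e.parent_transcript_id}_ext",
                "parent": e.parent_transcript_id,
                "chrom": e.chrom, "start": e.start, "end": e.end,
                "strand": e.strand, "origin": e.origin,
                "n_snps": e.n_snps, "avg_reads": e.mean_reads_per_snp,
                "representative_snp": e.representative_snp,
                "distance_to_parent": e.distance_to_parent,
            }
            for e in result.extensions
        ]
    )


def vetting_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript": r.transcript_id,
                "n_informative_snps": r.n_informative_snps,
                "n_true_snps": r.n_true_snps,
                "true_fraction": round_half_up(r.true_fraction, 3),
                "snp_density_per_kb": round_half_up(r.snp_density_per_kb, 2),
                "n_shared_alt_snps": r.n_shared_alt_snps,
                "flags": ";".join(sorted(r.flags)),
                "verdict": r.verdict,
            }
            for r in result.vetting_reports.values()
        ]
    )


def write_result(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snp_table(result).to_csv(outdir / "snp_tests.tsv", sep="\t", index=False)
    transcript_table(result).to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
    extension_table(result).to_csv(outdir / "extensions.tsv", sep="\t", index=False)
    vetting_table(result).to_csv(outdir / "vetting.tsv", sep="\t", index=False)
    (outdir / "extensions.bed").write_text(extensions_to_bed(result.extensions))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")
    funnel = filter_funnel(result.manifest)
    (outdir / "funnel.tsv").write_text(
        "stage\tcount\n" + "".join(f"{s}\t{c}\n" for s, c in funnel)
    )
    if result.catalogue_summary is not None:
        s = result.catalogue_summary
        payload = {
            k: getattr(s, k)
            for k in (
                "n_catalogue", "n_excluded_small_rna", "n_excluded_not_genuine",
                "n_excluded_duplicate", "n_evaluable", "n_found",
                "n_no_call_low_expression", "n_no_call_no_snp", "n_not_confirmed",
            )
        }
        payload["n_no_call"] = s.n_no_call
        (outdir / "catalogue_summary.json").write_text(
            json.dumps(payload, indent=2) + "\n"
        )
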