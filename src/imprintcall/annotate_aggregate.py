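"""Gene-model annotation, transcript-level aggregation and catalogue bookkeeping.

SNP-level imprinting calls are mapped onto transcript models, aggregated into
one call per transcript (number of supporting SNPs, mean read depth, consensus
parental origin, representative SNP), and compared against a catalogue of
previously known imprinted transcripts to produce the found / not-confirmed /
no-call bookkeeping.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .util import round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .imprint_test import SnpTest

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
CONFLICT = "CONFLICT"

#: catalogue categories excluded before evaluation
EXCLUSION_CATEGORIES = ("small_rna", "not_genuine", "duplicate")
VALID_CATEGORIES = ("ok",) + EXCLUSION_CATEGORIES


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with 0-based half-open genomic coordinates."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str = ""
    exons: tuple = ()
    known_label: Optional[str] = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"{self.transcript_id}: start must be < end ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s},{e}) outside transcript span"
                )

    @property
    def name(self) -> str:
        return self.gene_name or self.transcript_id

    def contains(self, pos: int, exonic_only: bool = False) -> bool:
        """Whether the 1-based point position falls inside the model."""
        p0 = pos - 1
        if not (self.start <= p0 < self.end):
            return False
        if exonic_only and self.exons:
            return any(s <= p0 < e for s, e in self.exons)
        return True

    def three_prime_end(self) -> int:
        """1-based coordinate of the annotated 3' end."""
        return self.end if self.strand == "+" else self.start + 1


@dataclass(frozen=True)
class TranscriptHit:
    model: GeneModel
    strand_concordant: Optional[bool]  # None when the SNP has no strand majority


@dataclass(frozen=True)
class AnnotatedSnp:
    """One tested SNP together with the transcripts overlapping it."""

    test: "SnpTest"
    hits: tuple
    majority_strand: Optional[str]

    @property
    def is_intergenic(self) -> bool:
        return not self.hits


@dataclass(frozen=True)
class TranscriptCall:
    """Transcript-level aggregate of its TRUE SNPs (one reported row)."""

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    n_true_snps: int
    mean_reads_per_snp: int
    mean_reads_by_cross: Mapping[str, float]
    consensus_origin: str
    representative_snp: str
    model: GeneModel

    @property
    def is_imprinted(self) -> bool:
        return self.consensus_origin in (MATERNAL, PATERNAL)


@dataclass
class CatalogueSummary:
    n_catalogue: int = 0
    n_excluded_small_rna: int = 0
    n_excluded_not_genuine: int = 0
    n_excluded_duplicate: int = 0
    n_evaluable: int = 0
    n_found: int = 0
    n_no_call_low_expression: int = 0
    n_no_call_no_snp: int = 0
    n_not_confirmed: int = 0
    found_genes: list = field(default_factory=list)
    not_confirmed_genes: list = field(default_factory=list)

    @property
    def n_no_call(self) -> int:
        return self.n_no_call_low_expression + self.n_no_call_no_snp

    def assert_identities(self) -> None:
        if self.n_evaluable != (
            self.n_catalogue
            - self.n_excluded_small_rna
            - self.n_excluded_not_genuine
            - self.n_excluded_duplicate
        ):
            raise AssertionError("catalogue exclusion identity violated")
        if self.n_found + self.n_no_call + self.n_not_confirmed != self.n_evaluable:
            raise AssertionError("catalogue evaluation identity violated")


def build_interval_index(gene_models: Iterable[GeneModel]) -> dict:
    """Per-chromosome interval tree over transcript spans."""
    index: dict = defaultdict(IntervalTree)
    for model in gene_models:
        index[model.chrom].addi(model.start, model.end, model)
    return dict(index)


def annotate_snps(
    snp_tests: Sequence["SnpTest"],
    gene_models: Sequence[GeneModel],
    exonic_only: bool = False,
) -> list:
    """Map each tested SNP onto every transcript whose span contains it.

    Overlap is point-in-interval on the transcript span by default; with
    ``exonic_only`` the SNP must additionally fall inside an exon block when
    blocks are present.  A SNP overlapping no transcript is intergenic.  The
    transcript strand is compared with the SNP's majority read strand and a
    mismatch is flagged on the hit.
    """
    index = build_interval_index(gene_models)
    out = []
    for test in snp_tests:
        cand = test.candidate
        strand = cand.majority_strand()
        hits = []
        tree = index.get(cand.chrom)
        if tree is not None:
            for iv in sorted(tree.at(cand.pos - 1)):
                model: GeneModel = iv.data
                if exonic_only and model.exons and not model.contains(
                    cand.pos, exonic_only=True
                ):
                    continue
                concordant = None if strand is None else (strand == model.strand)
                hits.append(TranscriptHit(model=model, strand_concordant=concordant))
        out.append(AnnotatedSnp(test=test, hits=tuple(hits), majority_strand=strand))
    return out


def aggregate_transcript(
    snp_tests: Sequence["SnpTest"], model: GeneModel
) -> Optional[TranscriptCall]:
    """Aggregate the TRUE SNPs of one transcript into a call.

    ``mean_reads_per_snp`` is the mean over TRUE SNPs of the per-SNP coverage
    averaged across the two crosses, rounded half-up to an integer; a per-cross
    breakdown is reported alongside.  The representative SNP is the TRUE SNP
    with the highest combined coverage (ties broken by position).  Returns
    ``None`` when the transcript has no TRUE SNP.
    """
    true_tests = [t for t in snp_tests if t.is_true]
    if not true_tests:
        return None
    cross_ids = sorted(true_tests[0].candidate.counts)
    combined = []
    by_cross: dict = {c: [] for c in cross_ids}
    for t in true_tests:
        covs = {c: t.candidate.coverage(c) for c in cross_ids}
        combined.append(sum(covs.values()) / len(covs))
        for c in cross_ids:
            by_cross[c].append(covs[c])
    origins = {t.origin for t in true_tests}
    consensus = origins.pop() if len(origins) == 1 else CONFLICT
    rep = max(
        true_tests,
        key=lambda t: (sum(t.candidate.coverage(c) for c in cross_ids), -t.candidate.pos),
    )
    return TranscriptCall(
        transcript_id=model.transcript_id,
        gene_name=model.name,
        chrom=model.chrom,
        strand=model.strand,
        n_true_snps=len(true_tests),
        mean_reads_per_snp=int(round_half_up(sum(combined) / len(combined))),
        mean_reads_by_cross={c: sum(v) / len(v) for c, v in by_cross.items()},
        consensus_origin=consensus,
        representative_snp=rep.candidate.snp_id,
        model=model,
    )


def aggregate_transcripts(annotated: Sequence[AnnotatedSnp]) -> list:
    """One TranscriptCall per transcript carrying at least one TRUE SNP."""
    per_transcript: dict = defaultdict(list)
    models: dict = {}
    for ann in annotated:
        for hit in ann.hits:
            per_transcript[hit.model.transcript_id].append(ann.test)
            models[hit.model.transcript_id] = hit.model
    calls = []
    for tid in sorted(per_transcript):
        call = aggregate_transcript(per_transcript[tid], models[tid])
        if call is not None:
            calls.append(call)
    return calls


def summarize_catalogue(
    transcript_calls: Sequence[TranscriptCall],
    catalogue: pd.DataFrame,
) -> CatalogueSummary:
    """Tally a known-imprinted-transcript catalogue against the pipeline calls.

    ``catalogue`` needs columns ``gene``, ``known_origin`` (MATERNAL/PATERNAL),
    ``category`` (ok / small_rna / not_genuine / duplicate), ``expressed`` and
    ``has_snp`` (yes/no).  A catalogue gene is *found* when a transcript call of
    matching parental origin exists; an expressed, SNP-covered gene without a
    matching call is *not confirmed* (biallelic in the data); the remainder are
    no-calls split by reason.
    """
    required = {"gene", "known_origin", "category", "expressed", "has_snp"}
    missing = required - set(catalogue.columns)
    if missing:
        raise ValidationError(f"catalogue missing columns: {sorted(missing)}")
    bad = set(catalogue["category"]) - set(VALID_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown catalogue categories: {sorted(bad)}")

    calls_by_gene: dict = defaultdict(list)
    for call in transcript_calls:
        calls_by_gene[call.gene_name].append(call)
        calls_by_gene[call.transcript_id].append(call)

    summary = CatalogueSummary(n_catalogue=len(catalogue))
    for row in catalogue.itertuples(index=False):
        if row.category == "small_rna":
            summary.n_excluded_small_rna += 1
            continue
        if row.category == "not_genuine":
            summary.n_excluded_not_genuine += 1
            continue
        if row.category == "duplicate":
            summary.n_excluded_duplicate += 1
            continue
        summary.n_evaluable += 1
        matching = [
            c
            for c in calls_by_gene.get(row.gene, [])
            if c.consensus_origin == row.known_origin
        ]
        if matching:
            summary.n_found += 1
            summary.found_genes.append(row.gene)
        elif str(row.expressed).lower() in ("no", "false", "0"):
            summary.n_no_call_low_expression += 1
        elif str(row.has_snp).lower() in ("no", "false", "0"):
            summary.n_no_call_no_snp += 1
        else:
            summary.n_not_confirmed += 1
            summary.not_confirmed_genes.append(row.gene)
    summary.assert_identities()
    return summary
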