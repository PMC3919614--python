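"""Artifact vetting of novel imprinted-gene predictions.

Three failure modes mark a predicted transcript as suspect: (i) the TRUE SNPs
are a minority of the informative SNPs along the transcript (the rest being
biallelic — the hallmark of an aberrant site on a biallelic gene); (ii) the
SNP density is implausibly high for a true strain polymorphism rate (the
pseudogene read-misassignment pattern); (iii) most informative SNPs show high
alternative AF in *both* crosses, i.e. the reads carry shared paralog
variants rather than cross-specific alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotate_aggregate import GeneModel, TranscriptCall
from .errors import ValidationError
from .snp_discovery import CandidateSnp

FLAG_MINORITY_TRUE = "minority_true"
FLAG_HIGH_DENSITY = "high_density"
FLAG_SHARED_ALT = "shared_alt_paralog"


@dataclass(frozen=True)
class VettingThresholds:
    minority_cutoff: float = 0.5   # TRUE fraction below this -> minority_true
    density_cutoff: float = 10.0   # informative SNPs per kb above this -> high_density
    shared_cutoff: float = 0.5     # fraction of shared-alt SNPs above this -> paralog
    shared_af: float = 0.80        # AF-in-both-crosses threshold defining "shared"


@dataclass(frozen=True)
class VettingReport:
    transcript_id: str
    n_informative_snps: int
    n_true_snps: int
    true_fraction: float
    snp_density_per_kb: float
    n_shared_alt_snps: int
    flags: frozenset

    @property
    def verdict(self) -> str:
        return "suspect" if self.flags else "pass"


def vet_transcript(
    model: GeneModel,
    candidates: Sequence[CandidateSnp],
    true_keys: set,
    thresholds: VettingThresholds = VettingThresholds(),
    excluded_intervals: Optional[Sequence] = None,
) -> Optional[VettingReport]:
    """Vet one transcript given *all* SNPs overlapping it.

    ``candidates`` should include sites later excluded as strain variants
    (the shared-alt paralog signal lives in those), and ``true_keys`` is the
    set of (chrom, pos) of TRUE SNPs.  Informative SNPs are those covered in
    both crosses.  ``excluded_intervals`` optionally lists (chrom, start, end)
    0-based half-open paralog regions (e.g. user-supplied mitochondrial
    homology intervals); a transcript intersecting one is flagged
    shared_alt_paralog outright.  Returns None when no SNP is informative.
    """
    informative = [
        c for c in candidates
        if model.contains(c.pos) and all(c.coverage(x) > 0 for x in c.counts)
    ]
    if not informative:
        return None
    n_true = sum(1 for c in informative if c.key in true_keys)
    true_fraction = n_true / len(informative)
    density = len(informative) / ((model.end - model.start) / 1000.0)
    n_shared = sum(
        1
        for c in informative
        if all((c.af(x) or 0.0) >= thresholds.shared_af for x in c.counts)
    )
    flags = set()
    if true_fraction < thresholds.minority_cutoff:
        flags.add(FLAG_MINORITY_TRUE)
    if density > thresholds.density_cutoff:
        flags.add(FLAG_HIGH_DENSITY)
    if n_shared / len(informative) > thresholds.shared_cutoff:
        flags.add(FLAG_SHARED_ALT)
    if excluded_intervals:
        for chrom, start, end in excluded_intervals:
            if chrom == model.chrom and start < model.end and end > model.start:
                flags.add(FLAG_SHARED_ALT)
    return VettingReport(
        transcript_id=model.transcript_id,
        n_informative_snps=len(informative),
        n_true_snps=n_true,
        true_fraction=true_fraction,
        snp_density_per_kb=density,
        n_shared_alt_snps=n_shared,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class VettingPartition:
    retained: tuple
    rejected: tuple  # of (TranscriptCall, flags)


def vet_prediction_set(
    novel_calls: Sequence[TranscriptCall],
    reports: Mapping[str, VettingReport],
) -> VettingPartition:
    """Partition novel transcript calls by their vetting verdicts."""
    retained, rejected = [], []
    for call in novel_calls:
        report = reports.get(call.transcript_id)
        if report is None:
            raise ValidationError(f"no vetting report for {call.transcript_id}")
        if report.verdict == "pass":
            retained.append(call)
        else:
            rejected.append((call, report.flags))
    return VettingPartition(retained=tuple(retained), rejected=tuple(rejected))


def read_paralog_bed(path) -> list:
    """(chrom, start, end) triples from a BED file of paralog intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(f"paralog BED needs >= 3 columns: {line!r}")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out
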