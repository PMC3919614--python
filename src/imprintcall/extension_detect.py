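"""Detection of parental-allele-specific transcript extensions.

Intergenic TRUE SNPs are clustered per (chromosome, parental origin, read
strand) by single-linkage with a maximum inter-SNP gap; a cluster becomes an
extension call when the nearest annotated imprinted transcript immediately
upstream in transcription direction (within ``max_reach``) matches the
cluster's origin and strand.  Clusters are additionally split wherever an
annotated same-strand transcript lies between two consecutive SNPs, so that
an extension never reads through another gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotate_aggregate import (
    AnnotatedSnp,
    GeneModel,
    TranscriptCall,
    build_interval_index,
)
from .errors import ValidationError
from .util import round_half_up

DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_SNPS = 2
DEFAULT_MAX_REACH = 100_000


@dataclass(frozen=True)
class ExtensionCall:
    """An imprinted transcript extension (reported 1-based inclusive span)."""

    parent_transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    origin: str
    n_snps: int
    mean_reads_per_snp: int
    representative_snp: str
    distance_to_parent: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("extension start must be <= end")


@dataclass(frozen=True)
class UnassignedCluster:
    chrom: str
    start: int
    end: int
    strand: Optional[str]
    origin: str
    n_snps: int
    reason: str


@dataclass(frozen=True)
class ExtensionSummary:
    n_extensions: int
    by_parent: dict


def _mean_combined_coverage(tests) -> int:
    vals = []
    for t in tests:
        covs = [t.candidate.coverage(c) for c in t.candidate.counts]
        vals.append(sum(covs) / len(covs))
    return int(round_half_up(sum(vals) / len(vals)))


def _nearest_upstream_parent(
    cluster_tests,
    strand: str,
    chrom: str,
    parents: Sequence[TranscriptCall],
    max_reach: int,
):
    """Nearest same-origin, same-strand transcript 3' end upstream of the cluster.

    For a plus-strand cluster the parent's annotated end must lie at or before
    the cluster's 5'-most (leftmost) SNP; for minus strand, the parent's start
    at or after the rightmost SNP.  Distance is measured from the parent's 3'
    end to that 5'-most SNP and must not exceed ``max_reach``.
    """
    positions = [t.candidate.pos for t in cluster_tests]
    best = None
    for call in parents:
        model = call.model
        if model.chrom != chrom or model.strand != strand:
            continue
        if strand == "+":
            five_prime = min(positions)
            dist = five_prime - model.three_prime_end()
        else:
            five_prime = max(positions)
            dist = model.three_prime_end() - five_prime
        if dist < 0 or dist > max_reach:
            continue
        if best is None or dist < best[1]:
            best = (call, dist)
    return best


def detect_extensions(
    annotated: Sequence[AnnotatedSnp],
    transcript_calls: Sequence[TranscriptCall],
    gene_models: Sequence[GeneModel],
    max_gap: int = DEFAULT_MAX_GAP,
    min_snps: int = DEFAULT_MIN_SNPS,
    max_reach: int = DEFAULT_MAX_REACH,
) -> tuple:
    """Cluster intergenic TRUE SNPs and assign clusters to parent transcripts.

    Returns ``(extensions, unassigned)``.  Any transcript with an imprinted
    TranscriptCall is parent-eligible, so extensions can chain off earlier
    extensions' parents.  Orphan clusters (no concordant parent in reach) and
    undersized clusters are reported as UnassignedCluster diagnostics.
    """
    parents = [c for c in transcript_calls if c.is_imprinted]
    model_index = build_interval_index(gene_models)

    groups: dict = defaultdict(list)
    for ann in annotated:
        if not ann.test.is_true or not ann.is_intergenic:
            continue
        if ann.majority_strand is None:
            continue
        key = (ann.test.candidate.chrom, ann.test.origin, ann.majority_strand)
        groups[key].append(ann.test)

    extensions, unassigned = [], []
    for (chrom, origin, strand), tests in sorted(groups.items()):
        tests.sort(key=lambda t: t.candidate.pos)
        tree = model_index.get(chrom)
        clusters = [[tests[0]]]
        for prev, cur in zip(tests, tests[1:]):
            gap = cur.candidate.pos - prev.candidate.pos
            blocked = False
            if tree is not None and cur.candidate.pos - prev.candidate.pos > 1:
                # split when an annotated same-strand transcript separates them
                between = tree.overlap(prev.candidate.pos, cur.candidate.pos - 1)
                blocked = any(iv.data.strand == strand for iv in between)
            if gap <= max_gap and not blocked:
                clusters[-1].append(cur)
            else:
                clusters.append([cur])
        for cluster in clusters:
            positions = [t.candidate.pos for t in cluster]
            start, end = min(positions), max(positions)
            if len(cluster) < min_snps:
                unassigned.append(
                    UnassignedCluster(chrom, start, end, strand, origin,
                                      len(cluster), "too_few_snps")
                )
                continue
            found = _nearest_upstream_parent(cluster, strand, chrom, parents, max_reach)
            if found is None:
                unassigned.append(
                    UnassignedCluster(chrom, start, end, strand, origin,
                                      len(cluster), "unassigned_cluster")
                )
                continue
            parent, dist = found
            if parent.consensus_origin != origin:
                unassigned.append(
                    UnassignedCluster(chrom, start, end, strand, origin,
                                      len(cluster), "unassigned_cluster")
                )
                continue
            rep = max(
                cluster,
                key=lambda t: (
                    sum(t.candidate.coverage(c) for c in t.candidate.counts),
                    -t.candidate.pos,
                ),
            )
            extensions.append(
                ExtensionCall(
                    parent_transcript_id=parent.transcript_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    origin=origin,
                    n_snps=len(cluster),
                    mean_reads_per_snp=_mean_combined_coverage(cluster),
                    representative_snp=rep.candidate.snp_id,
                    distance_to_parent=dist,
                )
            )
    extensions.sort(key=lambda e: (e.chrom, e.start))
    return extensions, unassigned


def extension_summary(extensions: Sequence[ExtensionCall]) -> ExtensionSummary:
    """Total count and per-parent grouping of extension calls."""
    by_parent: dict = defaultdict(list)
    for ext in extensions:
        by_parent[ext.parent_transcript_id].append(ext)
    return ExtensionSummary(n_extensions=len(extensions), by_parent=dict(by_parent))


def extensions_to_bed(extensions: Sequence[ExtensionCall]) -> str:
    """BED6 text (0-based half-open) for the extension intervals."""
    lines = []
    for e in extensions:
        lines.append(
            "\t".join(
                [
                    e.chrom,
                    str(e.start - 1),
                    str(e.end),
                    f"{e.parent_transcript_id}_ext",
                    str(e.n_snps),
                    e.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
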