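"""Candidate SNP discovery from reciprocal-cross allele counts.

A site is a candidate allele-specific SNP when, in at least one cross, the
alternative allele fraction (AF) is at or above ``min_af`` (default 0.80) with
total ref+alt coverage at or above ``min_cov`` (default 10).  Sites with high
AF in *both* crosses are homozygous strain variants, not imprinting signals,
and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .counts_io import AlleleCount
from .errors import UndefinedStatisticError, ValidationError

DEFAULT_MIN_AF = 0.80
DEFAULT_MIN_COV = 10

FLAG_UNCONFIRMED = "unconfirmed_low_coverage"
REASON_STRAIN_VARIANT = "strain_variant"


def allele_fraction(ref_count: int, alt_count: int) -> float:
    """Alternative allele fraction alt/(ref+alt)."""
    if ref_count < 0 or alt_count < 0:
        raise ValidationError("counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise UndefinedStatisticError("allele fraction undefined at zero coverage")
    return alt_count / total


@dataclass(frozen=True)
class CandidateSnp:
    """One site with counts attached for both crosses.

    ``counts`` maps each cross id to its AlleleCount (or None when the site
    was not observed in that cross).  ``discovering_crosses`` are the crosses
    in which the candidate criteria were met; after strain-variant exclusion
    exactly one remains.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: Optional[str]
    counts: Mapping[str, Optional[AlleleCount]]
    discovering_crosses: tuple
    flags: frozenset = frozenset()

    @property
    def key(self):
        return (self.chrom, self.pos)

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    @property
    def discovering_cross(self) -> str:
        if len(self.discovering_crosses) != 1:
            raise ValidationError(
                f"{self.snp_id}: {len(self.discovering_crosses)} discovering crosses"
            )
        return self.discovering_crosses[0]

    def confirming_cross(self) -> str:
        other = [c for c in self.counts if c != self.discovering_cross]
        return other[0]

    def coverage(self, cross_id: str) -> int:
        rec = self.counts.get(cross_id)
        return 0 if rec is None else rec.coverage

    def af(self, cross_id: str) -> Optional[float]:
        """AF in one cross, or None when that cross has zero coverage."""
        rec = self.counts.get(cross_id)
        if rec is None or rec.coverage == 0:
            return None
        return rec.allele_fraction()

    def ref_alt(self, cross_id: str) -> tuple:
        rec = self.counts.get(cross_id)
        return (0, 0) if rec is None else (rec.ref_count, rec.alt_count)

    def majority_strand(self) -> Optional[str]:
        """'+'/'-' by summed read-strand counts across crosses; None on tie."""
        plus = sum(r.plus_count for r in self.counts.values() if r is not None)
        minus = sum(r.minus_count for r in self.counts.values() if r is not None)
        if plus == minus:
            return None
        return "+" if plus > minus else "-"


@dataclass(frozen=True)
class ExcludedSite:
    candidate: CandidateSnp
    reason: str


def _merge_site(records: Sequence[Optional[AlleleCount]]):
    """Reconcile ref/alt alleles of the same site seen in different crosses."""
    present = [r for r in records if r is not None]
    refs = {r.ref_base for r in present}
    if len(refs) != 1:
        raise ValidationError(
            f"{present[0].snp_id}: reference base differs between crosses"
        )
    alts = {r.alt_base for r in present if r.alt_base is not None}
    if len(alts) > 1:
        raise ValidationError(
            f"{present[0].snp_id}: alternative base differs between crosses"
        )
    return refs.pop(), (alts.pop() if alts else None)


def find_candidates(
    counts_a: Iterable[AlleleCount],
    counts_b: Iterable[AlleleCount],
    min_af: float = DEFAULT_MIN_AF,
    min_cov: int = DEFAULT_MIN_COV,
    restrict_to: Optional[set] = None,
) -> list:
    """Candidate SNPs present in either cross at AF >= min_af, coverage >= min_cov.

    The non-discovering cross's counts are attached even when its coverage is
    below ``min_cov``; a candidate whose other cross has no reads at all is
    flagged ``unconfirmed_low_coverage`` (it can never become TRUE).  If both
    crosses qualify, both are recorded as discovering (such sites are strain
    variants and are resolved by :func:`exclude_strain_variants`).
    ``restrict_to`` optionally limits testing to a set of (chrom, pos) keys
    (e.g. from a known-variant VCF).
    """
    if not 0 < min_af <= 1:
        raise ValidationError("min_af must be in (0, 1]")
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    counts_a = list(counts_a)
    counts_b = list(counts_b)
    if not counts_a and not counts_b:
        return []
    cross_a = next((r.cross_id for r in counts_a), None)
    cross_b = next((r.cross_id for r in counts_b), None)
    if cross_a is None:
        cross_a = "A" if cross_b != "A" else "B"
    if cross_b is None:
        cross_b = "B" if cross_a != "B" else "A"
    if cross_a == cross_b:
        raise ValidationError("the two count sets carry the same cross_id")

    by_site: dict = {}
    for rec in counts_a:
        by_site.setdefault(rec.key, [None, None])[0] = rec
    for rec in counts_b:
        slot = by_site.setdefault(rec.key, [None, None])
        slot[1] = rec

    candidates = []
    for key in sorted(by_site):
        if restrict_to is not None and key not in restrict_to:
            continue
        rec_a, rec_b = by_site[key]
        ref_base, alt_base = _merge_site([rec_a, rec_b])
        discovering = []
        for cross_id, rec in ((cross_a, rec_a), (cross_b, rec_b)):
            if rec is None or rec.coverage < min_cov:
                continue
            if rec.allele_fraction() >= min_af:
                discovering.append(cross_id)
        if not discovering:
            continue
        flags = set()
        for cross_id, rec in ((cross_a, rec_a), (cross_b, rec_b)):
            if cross_id not in discovering and (rec is None or rec.coverage == 0):
                flags.add(FLAG_UNCONFIRMED)
        candidates.append(
            CandidateSnp(
                chrom=key[0],
                pos=key[1],
                ref_base=ref_base,
                alt_base=alt_base,
                counts={cross_a: rec_a, cross_b: rec_b},
                discovering_crosses=tuple(discovering),
                flags=frozenset(flags),
            )
        )
    return candidates


def exclude_strain_variants(
    candidates: Sequence[CandidateSnp], both_af: float = DEFAULT_MIN_AF
) -> tuple:
    """Split candidates into (kept, excluded strain variants).

    A site with AF >= ``both_af`` in both crosses (each with coverage > 0) is a
    strain-homozygous variant: the alternative allele is expressed regardless
    of parent, so it carries no imprinting information.
    """
    kept, excluded = [], []
    for cand in candidates:
        afs = [cand.af(c) for c in cand.counts]
        if all(a is not None and a >= both_af for a in afs):
            excluded.append(ExcludedSite(candidate=cand, reason=REASON_STRAIN_VARIANT))
            continue
        if len(cand.discovering_crosses) > 1:
            # qualified in both crosses but the reciprocal AF is below both_af
            # there; keep the higher-AF cross as the discovering one
            best = max(
                cand.discovering_crosses,
                key=lambda c: (cand.af(c) or 0.0, c),
            )
            cand = replace(cand, discovering_crosses=(best,))
        kept.append(cand)
    return kept, excluded
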