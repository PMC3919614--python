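"""Reading and writing allele counts, annotations and library-level QC.

The primary input is a per-cross counts-TSV with one row per variant site
(columns ``chrom pos ref alt ref_count alt_count plus_count minus_count``).
A converter from samtools-mpileup-style text is provided, applying the
base-quality filter before counting.  Annotation is read from BED6/BED12 or
GTF into :class:`~imprintcall.annotate_aggregate.GeneModel` records.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .annotate_aggregate import GeneModel
from .errors import ParseError, UndefinedStatisticError, ValidationError
from .util import percent

BASES = ("A", "C", "G", "T")
COUNTS_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "plus_count",
    "minus_count",
)

#: read-pair orientation -> transcript strand of the dUTP protocol.
#: Read 1 comes from the surviving first-strand cDNA and reports the
#: antisense strand; read 2 reports the sense strand.
ORIENTATION_STRAND = {
    "F2R1": "antisense",
    "R1F2": "antisense",
    "F1R2": "sense",
    "R2F1": "sense",
}

PHRED_OFFSET = 33
DEFAULT_MIN_BASE_QUALITY = 13


@dataclass(frozen=True)
class AlleleCount:
    """Reference/alternative read counts at one site in one cross."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: Optional[str]  # None when no alternative read was observed
    ref_count: int
    alt_count: int
    plus_count: int = 0
    minus_count: int = 0
    cross_id: str = ""
    other_count: int = 0  # reads showing a base other than ref/alt (logged only)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.ref_base not in BASES:
            raise ValidationError(f"{self.chrom}:{self.pos}: bad ref base {self.ref_base!r}")
        if self.alt_base is not None:
            if self.alt_base not in BASES:
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: bad alt base {self.alt_base!r}"
                )
            if self.alt_base == self.ref_base:
                raise ValidationError(f"{self.chrom}:{self.pos}: alt equals ref")
        elif self.alt_count:
            raise ValidationError(f"{self.chrom}:{self.pos}: alt reads without alt base")
        for name in ("ref_count", "alt_count", "plus_count", "minus_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.chrom}:{self.pos}: negative {name}")
        if (self.plus_count or self.minus_count) and (
            self.plus_count + self.minus_count != self.coverage
        ):
            raise ValidationError(
                f"{self.chrom}:{self.pos}: strand counts do not sum to coverage"
            )

    @property
    def coverage(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def key(self):
        return (self.chrom, self.pos)

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    def allele_fraction(self) -> float:
        if self.coverage == 0:
            raise UndefinedStatisticError(f"{self.snp_id}: zero coverage")
        return self.alt_count / self.coverage


@dataclass(frozen=True)
class Cross:
    cross_id: str
    mother_strain: str
    father_strain: str


@dataclass(frozen=True)
class CrossDesign:
    """Two reciprocal crosses plus the strain assumed to carry the alt allele."""

    crosses: tuple
    alt_strain: str

    def __post_init__(self):
        if len(self.crosses) != 2:
            raise ValidationError("a reciprocal design has exactly two crosses")
        a, b = self.crosses
        if not (a.mother_strain == b.father_strain and a.father_strain == b.mother_strain):
            raise ValidationError("the two crosses must have swapped parents")
        if self.alt_strain not in (a.mother_strain, a.father_strain):
            raise ValidationError(f"alt_strain {self.alt_strain!r} not in the design")

    @property
    def cross_ids(self) -> tuple:
        return tuple(c.cross_id for c in self.crosses)

    def cross(self, cross_id: str) -> Cross:
        for c in self.crosses:
            if c.cross_id == cross_id:
                return c
        raise ValidationError(f"unknown cross {cross_id!r}")

    def swapped_labels(self) -> "CrossDesign":
        """The same matings with the two cross identifiers exchanged."""
        a, b = self.crosses
        return CrossDesign(
            crosses=(replace(a, cross_id=b.cross_id), replace(b, cross_id=a.cross_id)),
            alt_strain=self.alt_strain,
        )


@dataclass(frozen=True)
class LibraryStats:
    total_reads: int
    aligned_reads: int
    sense_reads: Optional[int]
    aligned_fraction: float
    sense_fraction: Optional[float]

    @property
    def aligned_percent(self) -> float:
        """Aligned fraction as a one-decimal half-up percentage."""
        return percent(self.aligned_reads, self.total_reads, 1)

    @property
    def sense_percent(self) -> Optional[float]:
        if self.sense_reads is None:
            return None
        return percent(self.sense_reads, self.aligned_reads, 1)


def library_stats(
    total_reads: int, aligned_reads: int, sense_reads: Optional[int] = None
) -> LibraryStats:
    """Alignment and sense-orientation rates of one sequencing library."""
    if total_reads == 0:
        raise UndefinedStatisticError("alignment rate undefined for zero total reads")
    if not 0 <= aligned_reads <= total_reads:
        raise ValidationError("need 0 <= aligned_reads <= total_reads")
    if sense_reads is not None and not 0 <= sense_reads <= aligned_reads:
        raise ValidationError("need 0 <= sense_reads <= aligned_reads")
    return LibraryStats(
        total_reads=total_reads,
        aligned_reads=aligned_reads,
        sense_reads=sense_reads,
        aligned_fraction=aligned_reads / total_reads,
        sense_fraction=None if sense_reads is None else sense_reads / aligned_reads,
    )


def strand_from_orientation(orientation_code: str) -> str:
    """Transcript strand ('sense'/'antisense') from a read-pair orientation code."""
    try:
        return ORIENTATION_STRAND[orientation_code]
    except KeyError:
        raise ValidationError(
            f"unknown orientation code {orientation_code!r}; "
            f"expected one of {sorted(ORIENTATION_STRAND)}"
        ) from None


# ---------------------------------------------------------------------------
# counts-TSV


def read_counts(path, cross_id: str) -> list:
    """Read one cross's counts-TSV into AlleleCount records sorted by site.

    Duplicate (chrom, pos) rows and malformed lines raise with the line number.
    """
    path = Path(path)
    records = []
    seen = set()
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if tuple(header) != COUNTS_COLUMNS:
            raise ParseError(
                f"{path}:1: bad header {header!r}; expected {list(COUNTS_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(COUNTS_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(COUNTS_COLUMNS)} columns")
            try:
                rec = AlleleCount(
                    chrom=row[0],
                    pos=int(row[1]),
                    ref_base=row[2],
                    alt_base=None if row[3] in (".", "") else row[3],
                    ref_count=int(row[4]),
                    alt_count=int(row[5]),
                    plus_count=int(row[6]),
                    minus_count=int(row[7]),
                    cross_id=cross_id,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if rec.key in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate site {rec.snp_id}")
            seen.add(rec.key)
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_counts(records: Iterable[AlleleCount], path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COUNTS_COLUMNS)
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            writer.writerow(
                [
                    r.chrom,
                    r.pos,
                    r.ref_base,
                    r.alt_base or ".",
                    r.ref_count,
                    r.alt_count,
                    r.plus_count,
                    r.minus_count,
                ]
            )


# ---------------------------------------------------------------------------
# samtools-mpileup-style text


@dataclass(frozen=True)
class PileupSite:
    """One pileup row: per-read observed bases with qualities and strands."""

    chrom: str
    pos: int
    ref_base: str
    observations: tuple  # of (base, phred_quality, strand '+'/'-')


def filter_base_quality(
    pileup_record: PileupSite,
    min_quality: int = DEFAULT_MIN_BASE_QUALITY,
    cross_id: str = "",
) -> AlleleCount:
    """Count ref/alt reads at a pileup site, keeping only bases at or above
    ``min_quality`` (Phred).

    The alternative allele is the most frequent non-reference base among the
    retained reads (ties broken alphabetically); remaining non-ref/alt bases
    are excluded from counts but tallied in ``other_count``.
    """
    kept = [
        (base.upper(), strand)
        for base, q, strand in pileup_record.observations
        if q >= min_quality and base.upper() in BASES
    ]
    non_ref = Counter(b for b, _ in kept if b != pileup_record.ref_base)
    alt_base = None
    if non_ref:
        top = max(non_ref.values())
        alt_base = min(b for b, n in non_ref.items() if n == top)
    ref_count = alt_count = plus = minus = 0
    other = 0
    for base, strand in kept:
        if base == pileup_record.ref_base:
            ref_count += 1
        elif base == alt_base:
            alt_count += 1
        else:
            other += 1
            continue
        if strand == "+":
            plus += 1
        else:
            minus += 1
    return AlleleCount(
        chrom=pileup_record.chrom,
        pos=pileup_record.pos,
        ref_base=pileup_record.ref_base,
        alt_base=alt_base,
        ref_count=ref_count,
        alt_count=alt_count,
        plus_count=plus,
        minus_count=minus,
        cross_id=cross_id,
        other_count=other,
    )


def _parse_pileup_bases(bases: str, quals: str, lineno: int, path) -> list:
    """Expand an mpileup base string into (base, quality, strand) triples.

    Handles read starts (``^`` + mapping quality), read ends (``$``), indels
    (``+n``/``-n`` followed by the inserted/deleted sequence) and deletion
    placeholders (``*``, which consume a quality but are not counted).
    """
    out = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise ParseError(f"{path}:{lineno}: malformed indel in pileup bases")
            i += int(num)
            continue
        if qi >= len(quals):
            raise ParseError(f"{path}:{lineno}: base/quality length mismatch")
        q = ord(quals[qi]) - PHRED_OFFSET
        qi += 1
        i += 1
        if c == "*":
            continue  # deletion placeholder
        if c in ".":
            out.append((None, q, "+"))
        elif c == ",":
            out.append((None, q, "-"))
        elif c.upper() in BASES or c.upper() == "N":
            out.append((c, q, "+" if c.isupper() else "-"))
        # anything else (e.g. '<', '>') is skipped but consumed a quality
    return out


def read_mpileup(
    path,
    cross_id: str,
    min_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list:
    """Convert samtools-mpileup-style text to quality-filtered AlleleCounts.

    Sites where every read is filtered out, or with no retained alternative
    read, are still returned (with zero/ref-only counts) and are dropped by
    downstream coverage rules.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 pileup columns")
            chrom, pos_s, ref, _depth, bases, quals = cols[:6]
            ref = ref.upper()
            if ref not in BASES:
                continue  # N reference: uninformative
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            triples = _parse_pileup_bases(bases, quals, lineno, path)
            obs = tuple(
                (ref if b is None else b, q, s) for b, q, s in triples if b is None or b.upper() in BASES
            )
            site = PileupSite(chrom=chrom, pos=pos, ref_base=ref, observations=obs)
            records.append(filter_base_quality(site, min_quality, cross_id))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


# ---------------------------------------------------------------------------
# annotation (BED6/BED12, GTF)


def _read_bed(path) -> list:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValidationError(
                    f"{path}:{lineno}: BED record has no strand column "
                    "(strand is required; use BED6 or BED12)"
                )
            chrom, start_s, end_s, name, _score, strand = cols[:6]
            start, end = int(start_s), int(end_s)
            exons = ()
            if len(cols) >= 12:
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                if len(sizes) != len(offsets):
                    raise ParseError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
                exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                models.append(
                    GeneModel(
                        transcript_id=name,
                        gene_name=name,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        exons=exons,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return models


def _read_gtf(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValidationError(f"{path}: exon without transcript_id attribute")
        if exon.strand not in ("+", "-"):
            raise ValidationError(f"{path}: transcript {tid} lacks a strand")
        gname = exon.attributes.get("gene_name", exon.attributes.get("gene_id", [tid]))[0]
        entry = grouped.setdefault(tid, {"chrom": exon.seqid, "strand": exon.strand,
                                         "gene": gname, "exons": []})
        # GTF is 1-based inclusive; convert to 0-based half-open
        entry["exons"].append((exon.start - 1, exon.end))
    models = []
    for tid, entry in grouped.items():
        exons = tuple(sorted(entry["exons"]))
        models.append(
            GeneModel(
                transcript_id=tid,
                gene_name=entry["gene"],
                chrom=entry["chrom"],
                start=exons[0][0],
                end=exons[-1][1],
                strand=entry["strand"],
                exons=exons,
            )
        )
    return models


def read_annotation(path) -> list:
    """Read gene models from BED6/BED12 or GTF (chosen by file extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path)
    return _read_bed(path)


def read_sites_vcf(path) -> set:
    """(chrom, pos) site keys from a sites-only VCF, for pre-restricting tests."""
    keys = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 VCF columns")
            keys.add((cols[0], int(cols[1])))
    return keys
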