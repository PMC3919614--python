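"""Reciprocal-cross allelic-asymmetry testing and parental-origin assignment.

Each candidate SNP is tested with a two-sided Fisher exact test on the 2x2
table of (alt, ref) counts in the two crosses, p-values are adjusted with the
Benjamini-Hochberg step-up over the whole candidate family, and a SNP is
called TRUE when its FDR is at or below ``fdr_max`` and the confirming
(reciprocal) cross shows alternative AF at or below ``recip_af_max``.  The
parental origin of a TRUE SNP follows from which cross discovered it: if the
alternative-carrying strain is the mother in the discovering cross the SNP
marks maternal expression, otherwise paternal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts_io import CrossDesign
from .errors import UndefinedStatisticError, ValidationError
from .snp_discovery import CandidateSnp
from .util import round_half_up

DEFAULT_FDR_MAX = 0.05
DEFAULT_RECIP_AF_MAX = 0.20

MATERNAL = "MATERNAL"
PATERNAL = "PATERNAL"
UNASSIGNED = "UNASSIGNED"

FAIL_LOW_FDR = "low_fdr_fail"
FAIL_RECIP_AF = "reciprocal_af_fail"
FAIL_UNCONFIRMED = "unconfirmed_low_coverage"


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    odds_ratio_haldane: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test of the table ((a, b), (c, d)).

    Rows are (alt, ref) in the two crosses.  The two-sided p-value is the sum
    of hypergeometric point probabilities, over all tables with the observed
    margins, that do not exceed the observed table's point probability
    (minimum-likelihood definition).  The odds ratio is the sample estimate
    a*d / (b*c), +inf or 0 when a zero cell makes it degenerate; a
    Haldane-Anscombe (+0.5) corrected estimate is reported alongside.
    """
    cells = (a, b, c, d)
    if any(not isinstance(x, (int, np.integer)) or x < 0 for x in cells):
        raise ValidationError(f"cells must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise UndefinedStatisticError("Fisher test undefined for the all-zero table")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c > 0:
        oratio = (a * d) / (b * c)
    elif a * d > 0:
        oratio = math.inf
    else:
        oratio = 0.0
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return FisherResult(p_value=p, odds_ratio=oratio, odds_ratio_haldane=haldane)


def bh_adjust(p_values: Sequence[float]):
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SnpTest:
    """Full decision record for one candidate SNP."""

    candidate: CandidateSnp
    discovering_cross: str
    confirming_cross: str
    p_value: float
    odds_ratio: float
    odds_ratio_haldane: float
    fdr: float
    is_true: bool
    fail_reasons: frozenset
    origin: str

    @property
    def status(self) -> str:
        return "TRUE" if self.is_true else "FALSE"


def assign_origin(discovering_cross: str, design: CrossDesign) -> str:
    """Parental origin implied by the cross that discovered the SNP.

    The discovering cross is the one where the alternative allele dominates,
    i.e. where the alt-carrying strain's allele is expressed.  If that strain
    is the mother there, expression is maternal; if the father, paternal.
    """
    cross = design.cross(discovering_cross)
    if design.alt_strain == cross.mother_strain:
        return MATERNAL
    if design.alt_strain == cross.father_strain:
        return PATERNAL
    raise ValidationError(
        f"alt strain {design.alt_strain!r} is not a parent in cross {discovering_cross!r}"
    )


def call_true_snps(
    candidates: Sequence[CandidateSnp],
    design: CrossDesign,
    fdr_max: float = DEFAULT_FDR_MAX,
    recip_af_max: float = DEFAULT_RECIP_AF_MAX,
    fdr_family: str = "pooled",
) -> list:
    """Fisher-test every candidate, BH-adjust, and apply the TRUE-SNP rule.

    ``fdr_family`` is "pooled" (one BH family over all candidates, the
    default) or "per_cross" (separate families per discovering cross).  FALSE
    records are retained with their failure reasons.
    """
    if fdr_family not in ("pooled", "per_cross"):
        raise ValidationError(f"unknown fdr_family {fdr_family!r}")
    rows = []
    for cand in candidates:
        disc = cand.discovering_cross
        conf = cand.confirming_cross()
        ref_d, alt_d = cand.ref_alt(disc)
        ref_c, alt_c = cand.ref_alt(conf)
        if alt_d + ref_d + alt_c + ref_c == 0:
            raise UndefinedStatisticError(f"{cand.snp_id}: no reads in either cross")
        fisher = fisher_exact_2x2(alt_d, ref_d, alt_c, ref_c)
        rows.append((cand, disc, conf, fisher))

    pvals = np.array([r[3].p_value for r in rows]) if rows else np.array([])
    if fdr_family == "pooled" or not rows:
        fdrs = bh_adjust(pvals)
    else:
        fdrs = np.empty(len(rows))
        for cross_id in {r[1] for r in rows}:
            idx = [i for i, r in enumerate(rows) if r[1] == cross_id]
            fdrs[idx] = bh_adjust(pvals[idx])

    tests = []
    for (cand, disc, conf, fisher), fdr in zip(rows, fdrs):
        reasons = set()
        conf_af = cand.af(conf)
        if fdr > fdr_max:
            reasons.add(FAIL_LOW_FDR)
        if conf_af is None:
            reasons.add(FAIL_UNCONFIRMED)
        elif conf_af > recip_af_max:
            reasons.add(FAIL_RECIP_AF)
        is_true = not reasons
        tests.append(
            SnpTest(
                candidate=cand,
                discovering_cross=disc,
                confirming_cross=conf,
                p_value=fisher.p_value,
                odds_ratio=fisher.odds_ratio,
                odds_ratio_haldane=fisher.odds_ratio_haldane,
                fdr=float(fdr),
                is_true=is_true,
                fail_reasons=frozenset(reasons),
                origin=assign_origin(disc, design) if is_true else UNASSIGNED,
            )
        )
    return tests


@dataclass(frozen=True)
class ConcordanceResult:
    n_match: int
    n_total: int

    @property
    def percent(self) -> int:
        """Integer half-up percentage of concordant SNPs."""
        if self.n_total == 0:
            raise UndefinedStatisticError("concordance undefined for empty group")
        return int(round_half_up(100.0 * self.n_match / self.n_total))


def alt_strain_concordance(
    true_snps: Sequence[SnpTest],
    design: CrossDesign,
    known_origin: str,
) -> ConcordanceResult:
    """How often the discovering cross matches the default alt-strain expectation.

    For a group of TRUE SNPs in genes of known parental origin, the expected
    discovering cross is the one where the default alternative-carrying strain
    plays that parental role (e.g. for maternally expressed genes, the cross
    whose mother is the alt strain).  The complement are SNPs whose
    alternative allele belongs to the other strain.
    """
    expected = [
        c.cross_id
        for c in design.crosses
        if assign_origin(c.cross_id, design) == known_origin
    ]
    if len(expected) != 1:
        raise ValidationError(f"no unique cross implies origin {known_origin!r}")
    tests = list(true_snps)
    if not tests:
        raise UndefinedStatisticError("concordance undefined for empty group")
    n_match = sum(1 for t in tests if t.discovering_cross == expected[0])
    return ConcordanceResult(n_match=n_match, n_total=len(tests))
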