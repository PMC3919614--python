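"""Synthetic reciprocal-cross allele-count generator with known ground truth.

The generator emulates the data model underlying allele-specific RNA-seq of
two reciprocal crosses: SNPs placed along genes by a Poisson process,
negative-binomial per-SNP coverage, and binomial alternative-allele counts
whose success probability depends on the gene's expression state.  With the
alternative allele carried by the maternal strain in cross A and the paternal
strain in cross B (the reciprocal flip):

========================  =================  =================
state                     alt fraction, A    alt fraction, B
========================  =================  =================
MAT (maternal expr.)      1 - eps            eps
PAT (paternal expr.)      eps                1 - eps
BIALLELIC                 0.5                0.5
LEAKY (paternal, leak t)  t                  1 - t
STRAIN_VARIANT            1 - eps            1 - eps
========================  =================  =================

Pseudogene decoys mix mostly shared-alt SNPs (high AF in both crosses) at
high density with a couple of uniparental SNPs — the read-misassignment
pattern of a silent pseudogene of an imprinted gene.  Optional extensions
reuse the parent gene's state at scaled coverage downstream of its 3' end.
Generation is deterministic per (config, seed), with independent per-gene
substreams so adding genes does not perturb existing genes' draws.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .annotate_aggregate import GeneModel, MATERNAL, PATERNAL
from .counts_io import AlleleCount, Cross, CrossDesign, write_counts
from .errors import ValidationError

MAT = "MAT"
PAT = "PAT"
BIALLELIC = "BIALLELIC"
LEAKY = "LEAKY"
PSEUDOGENE_DECOY = "PSEUDOGENE_DECOY"
STRAIN_VARIANT = "STRAIN_VARIANT"

IMPRINTED_STATES = (MAT, PAT)
ORIGIN_OF_STATE = {MAT: MATERNAL, PAT: PATERNAL}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class ExtensionSpec:
    """A downstream extension attached to one imprinted gene.

    ``parent_index`` indexes the imprinted genes (maternal first, then
    paternal) in generation order.
    """

    parent_index: int
    length: int = 10_000
    coverage_scale: float = 0.25
    gap: int = 1_000


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 500
    fraction_maternal: float = 0.04   # 20 of 500
    fraction_paternal: float = 0.04   # 20 of 500
    fraction_leaky: float = 0.01      # 5 of 500
    leak_range: tuple = (0.21, 0.25)  # maternal leak of the leaky (Dlk1-like) state
    gene_length: int = 2_000
    intergene_gap: int = 8_000
    snp_rate_per_kb: float = 2.0
    min_snps_imprinted: int = 3
    coverage_mean: float = 30.0
    nb_dispersion: float = 10.0       # negative-binomial size; inf -> Poisson
    coverage_fixed: bool = False      # every SNP at exactly round(coverage_mean)
    sequencing_error: float = 0.01
    sense_fraction: float = 0.9
    n_strain_variant_sites: int = 50
    n_pseudogene_decoys: int = 2
    decoy_length: int = 1_100
    decoy_snp_rate_per_kb: float = 27.0
    decoy_true_snps: int = 2
    extensions: tuple = ()
    chrom: str = "chrS1"
    cross_a: str = "JXO"
    cross_b: str = "OXJ"
    mother_a: str = "JF1"
    father_a: str = "OG2"
    alt_strain: str = "JF1"

    def __post_init__(self):
        fsum = self.fraction_maternal + self.fraction_paternal + self.fraction_leaky
        if fsum > 1:
            raise ValidationError("gene state fractions must sum to <= 1")
        if not 0 <= self.sequencing_error <= 0.1:
            raise ValidationError("sequencing_error must be in [0, 0.1]")
        if self.coverage_mean <= 0:
            raise ValidationError("coverage_mean must be positive")
        lo, hi = self.leak_range
        if not 0 < lo <= hi < 0.5:
            raise ValidationError("leak_range must satisfy 0 < lo <= hi < 0.5")

    def design(self) -> CrossDesign:
        return CrossDesign(
            crosses=(
                Cross(self.cross_a, self.mother_a, self.father_a),
                Cross(self.cross_b, self.father_a, self.mother_a),
            ),
            alt_strain=self.alt_strain,
        )

    def state_counts(self) -> dict:
        nm = round(self.n_genes * self.fraction_maternal)
        np_ = round(self.n_genes * self.fraction_paternal)
        nl = round(self.n_genes * self.fraction_leaky)
        return {MAT: nm, PAT: np_, LEAKY: nl, BIALLELIC: self.n_genes - nm - np_ - nl}


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    status: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    theta: Optional[float] = None


@dataclass(frozen=True)
class SnpTruth:
    label: str
    gene_id: Optional[str]
    f_alt: dict  # cross_id -> true alternative-allele fraction


@dataclass(frozen=True)
class ExtensionTruth:
    parent_gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    origin: str


@dataclass
class SyntheticTruth:
    genes: dict = field(default_factory=dict)       # gene_id -> GeneTruth
    snps: dict = field(default_factory=dict)        # (chrom, pos) -> SnpTruth
    extensions: list = field(default_factory=list)  # ExtensionTruth


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    seed: int
    counts: dict            # cross_id -> list[AlleleCount]
    gene_models: list
    truth: SyntheticTruth

    @property
    def design(self) -> CrossDesign:
        return self.config.design()


def _nb_coverage(rng, mean: float, dispersion: float, size: int, fixed: bool = False):
    if fixed:
        return np.full(size, int(round(mean)), dtype=int)
    if math.isinf(dispersion):
        return rng.poisson(mean, size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def _state_fractions(state: str, eps: float, theta: Optional[float]) -> tuple:
    """(f_alt in cross A, f_alt in cross B) for a gene state."""
    if state == MAT:
        return 1 - eps, eps
    if state == PAT:
        return eps, 1 - eps
    if state == BIALLELIC:
        return 0.5, 0.5
    if state == LEAKY:
        return theta, 1 - theta
    if state == STRAIN_VARIANT:
        return 1 - eps, 1 - eps
    raise ValidationError(f"unknown state {state!r}")


def _emit_snp(rng, cfg, chrom, pos, f_a, f_b, strand, cov_a, cov_b, out_a, out_b):
    ref, alt = rng.choice(4, size=2, replace=False)
    alt_a = rng.binomial(cov_a, f_a) if cov_a else 0
    alt_b = rng.binomial(cov_b, f_b) if cov_b else 0
    for cov, alt_n, cross, out in (
        (cov_a, alt_a, cfg.cross_a, out_a),
        (cov_b, alt_b, cfg.cross_b, out_b),
    ):
        sense = rng.binomial(cov, cfg.sense_fraction) if cov else 0
        plus = sense if strand == "+" else cov - sense
        out.append(
            AlleleCount(
                chrom=chrom,
                pos=int(pos),
                ref_base=str(_BASES[ref]),
                alt_base=str(_BASES[alt]),
                ref_count=int(cov - alt_n),
                alt_count=int(alt_n),
                plus_count=int(plus),
                minus_count=int(cov - plus),
                cross_id=cross,
            )
        )


def _snp_positions(rng, start0: int, length: int, rate_per_kb: float, n_min: int = 0):
    n = int(rng.poisson(rate_per_kb * length / 1000.0))
    n = max(n, n_min)
    n = min(n, length)
    if n == 0:
        return np.array([], dtype=int)
    offsets = rng.choice(length, size=n, replace=False)
    return np.sort(offsets) + start0 + 1  # 1-based


def generate(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Generate one reciprocal-cross dataset with truth labels.

    Deterministic: identical (config, seed) yield identical datasets.  Genes
    are laid out on one synthetic chromosome with enough intergenic space
    reserved around genes that carry extensions.
    """
    cfg = config
    eps = cfg.sequencing_error
    counts = cfg.state_counts()
    states = (
        [MAT] * counts[MAT] + [PAT] * counts[PAT]
        + [LEAKY] * counts[LEAKY] + [BIALLELIC] * counts[BIALLELIC]
    )
    ext_by_gene: dict = {}
    n_imprinted = counts[MAT] + counts[PAT]
    for spec in cfg.extensions:
        if not 0 <= spec.parent_index < n_imprinted:
            raise ValidationError(
                f"extension parent_index {spec.parent_index} out of range "
                f"(have {n_imprinted} imprinted genes)"
            )
        ext_by_gene[spec.parent_index] = spec

    out_a: list = []
    out_b: list = []
    truth = SyntheticTruth()
    gene_models = []

    cursor = 1_000
    for i, state in enumerate(states):
        rng = np.random.default_rng([seed, i])
        spec = ext_by_gene.get(i)
        ext_extra = (spec.gap + spec.length + 500) if spec else 0
        start0 = cursor + ext_extra
        end0 = start0 + cfg.gene_length
        cursor = end0 + cfg.intergene_gap + ext_extra

        strand = "+" if rng.random() < 0.5 else "-"
        theta = float(rng.uniform(*cfg.leak_range)) if state == LEAKY else None
        n_min = cfg.min_snps_imprinted if state in IMPRINTED_STATES else (
            1 if state == LEAKY else 0
        )
        positions = _snp_positions(rng, start0, cfg.gene_length, cfg.snp_rate_per_kb, n_min)
        f_a, f_b = _state_fractions(state, eps, theta)
        gene_id = f"gene{i:04d}"
        covs_a = _nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, len(positions), cfg.coverage_fixed)
        covs_b = _nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, len(positions), cfg.coverage_fixed)
        for pos, cov_a, cov_b in zip(positions, covs_a, covs_b):
            _emit_snp(rng, cfg, cfg.chrom, pos, f_a, f_b, strand,
                      int(cov_a), int(cov_b), out_a, out_b)
            truth.snps[(cfg.chrom, int(pos))] = SnpTruth(
                label=state, gene_id=gene_id, f_alt={cfg.cross_a: f_a, cfg.cross_b: f_b}
            )
        truth.genes[gene_id] = GeneTruth(
            gene_id=gene_id, status=state, chrom=cfg.chrom,
            start=start0, end=end0, strand=strand, theta=theta,
        )
        gene_models.append(
            GeneModel(transcript_id=gene_id, gene_name=gene_id, chrom=cfg.chrom,
                      start=start0, end=end0, strand=strand)
        )

        if spec is not None:
            # extension: parent state at scaled coverage, downstream of the 3' end
            if strand == "+":
                ext_start0 = end0 + spec.gap
            else:
                ext_start0 = start0 - spec.gap - spec.length
            ext_positions = _snp_positions(
                rng, ext_start0, spec.length, cfg.snp_rate_per_kb, n_min=2
            )
            ext_mean = max(cfg.coverage_mean * spec.coverage_scale, 1.0)
            ecov_a = _nb_coverage(rng, ext_mean, cfg.nb_dispersion, len(ext_positions), cfg.coverage_fixed)
            ecov_b = _nb_coverage(rng, ext_mean, cfg.nb_dispersion, len(ext_positions), cfg.coverage_fixed)
            for pos, cov_a, cov_b in zip(ext_positions, ecov_a, ecov_b):
                _emit_snp(rng, cfg, cfg.chrom, pos, f_a, f_b, strand,
                          int(cov_a), int(cov_b), out_a, out_b)
                truth.snps[(cfg.chrom, int(pos))] = SnpTruth(
                    label=state, gene_id=f"{gene_id}_ext",
                    f_alt={cfg.cross_a: f_a, cfg.cross_b: f_b},
                )
            truth.extensions.append(
                ExtensionTruth(
                    parent_gene_id=gene_id, chrom=cfg.chrom,
                    start=ext_start0, end=ext_start0 + spec.length,
                    strand=strand, origin=ORIGIN_OF_STATE[state],
                )
            )

    # pseudogene decoys: dense shared-alt SNPs plus a few uniparental ones
    for d in range(cfg.n_pseudogene_decoys):
        rng = np.random.default_rng([seed, 10_000_000 + d])
        start0 = cursor
        end0 = start0 + cfg.decoy_length
        cursor = end0 + cfg.intergene_gap
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"decoy{d:02d}"
        positions = _snp_positions(
            rng, start0, cfg.decoy_length, cfg.decoy_snp_rate_per_kb,
            n_min=cfg.decoy_true_snps + 1,
        )
        n_uni = min(cfg.decoy_true_snps, len(positions))
        uni_idx = set(rng.choice(len(positions), size=n_uni, replace=False).tolist())
        covs_a = _nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, len(positions), cfg.coverage_fixed)
        covs_b = _nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, len(positions), cfg.coverage_fixed)
        for j, (pos, cov_a, cov_b) in enumerate(zip(positions, covs_a, covs_b)):
            if j in uni_idx:
                f_a, f_b = _state_fractions(MAT, eps, None)  # contaminant is uniparental
            else:
                f_a, f_b = _state_fractions(STRAIN_VARIANT, eps, None)
            _emit_snp(rng, cfg, cfg.chrom, pos, f_a, f_b, strand,
                      int(cov_a), int(cov_b), out_a, out_b)
            truth.snps[(cfg.chrom, int(pos))] = SnpTruth(
                label=PSEUDOGENE_DECOY, gene_id=gene_id,
                f_alt={cfg.cross_a: f_a, cfg.cross_b: f_b},
            )
        truth.genes[gene_id] = GeneTruth(
            gene_id=gene_id, status=PSEUDOGENE_DECOY, chrom=cfg.chrom,
            start=start0, end=end0, strand=strand,
        )
        gene_models.append(
            GeneModel(transcript_id=gene_id, gene_name=gene_id, chrom=cfg.chrom,
                      start=start0, end=end0, strand=strand)
        )

    # intergenic strain-homozygous variant sites
    rng = np.random.default_rng([seed, 20_000_000])
    for s in range(cfg.n_strain_variant_sites):
        pos = cursor + 1 + s * 200 + int(rng.integers(0, 100))
        strand = "+" if rng.random() < 0.5 else "-"
        f_a, f_b = _state_fractions(STRAIN_VARIANT, eps, None)
        cov_a = int(_nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, 1, cfg.coverage_fixed)[0])
        cov_b = int(_nb_coverage(rng, cfg.coverage_mean, cfg.nb_dispersion, 1, cfg.coverage_fixed)[0])
        _emit_snp(rng, cfg, cfg.chrom, pos, f_a, f_b, strand, cov_a, cov_b, out_a, out_b)
        truth.snps[(cfg.chrom, pos)] = SnpTruth(
            label=STRAIN_VARIANT, gene_id=None,
            f_alt={cfg.cross_a: f_a, cfg.cross_b: f_b},
        )

    out_a.sort(key=lambda r: (r.chrom, r.pos))
    out_b.sort(key=lambda r: (r.chrom, r.pos))
    return SyntheticDataset(
        config=cfg, seed=seed,
        counts={cfg.cross_a: out_a, cfg.cross_b: out_b},
        gene_models=gene_models, truth=truth,
    )


# ---------------------------------------------------------------------------
# evaluation against truth


@dataclass(frozen=True)
class EvalMetrics:
    snp_sensitivity: Optional[float]
    snp_specificity: Optional[float]
    snp_fdp: Optional[float]
    gene_sensitivity: Optional[float]
    origin_accuracy: Optional[float]
    n_true_calls: int
    n_positive_snps: int
    n_imprinted_genes: int
    n_detected_genes: int


def evaluate_calls(
    snp_tests: Sequence,
    truth: SyntheticTruth,
    transcript_calls: Optional[Sequence] = None,
) -> EvalMetrics:
    """Confusion-matrix metrics of pipeline calls against generator truth.

    Positives are SNPs of genuinely imprinted loci (states MAT/PAT, including
    extension SNPs); LEAKY, BIALLELIC, STRAIN_VARIANT and PSEUDOGENE_DECOY
    sites all count as negatives — a leaky gene called FALSE is a correct
    rejection.  Per-gene sensitivity asks whether each imprinted gene received
    at least one TRUE SNP (via ``transcript_calls`` when given, else from the
    SNP tests grouped by the truth's gene assignment); origin accuracy is
    evaluated among the detected imprinted genes.
    """
    tp = fp = tn = fn = 0
    true_by_gene: dict = {}
    for t in snp_tests:
        key = (t.candidate.chrom, t.candidate.pos)
        if key not in truth.snps:
            raise ValidationError(f"called site {key} absent from truth")
        st = truth.snps[key]
        positive = st.label in IMPRINTED_STATES
        if t.is_true:
            if positive:
                tp += 1
            else:
                fp += 1
            if st.gene_id is not None:
                true_by_gene.setdefault(st.gene_id, []).append(t)
        else:
            if positive:
                fn += 1
            else:
                tn += 1

    imprinted_genes = [g for g in truth.genes.values() if g.status in IMPRINTED_STATES]
    detected = 0
    origin_ok = 0
    calls_by_gene = {}
    if transcript_calls is not None:
        for c in transcript_calls:
            calls_by_gene[c.transcript_id] = c
    for g in imprinted_genes:
        expected = ORIGIN_OF_STATE[g.status]
        if transcript_calls is not None:
            call = calls_by_gene.get(g.gene_id)
            if call is None or not call.is_imprinted:
                continue
            detected += 1
            origin_ok += int(call.consensus_origin == expected)
        else:
            tests = true_by_gene.get(g.gene_id, [])
            if not tests:
                continue
            detected += 1
            origins = {t.origin for t in tests}
            origin_ok += int(origins == {expected})

    n_called = tp + fp
    n_pos = tp + fn
    n_neg = tn + fp
    return EvalMetrics(
        snp_sensitivity=tp / n_pos if n_pos else None,
        snp_specificity=tn / n_neg if n_neg else None,
        snp_fdp=fp / n_called if n_called else None,
        gene_sensitivity=detected / len(imprinted_genes) if imprinted_genes else None,
        origin_accuracy=origin_ok / detected if detected else None,
        n_true_calls=n_called,
        n_positive_snps=n_pos,
        n_imprinted_genes=len(imprinted_genes),
        n_detected_genes=detected,
    )


def load_truth(truth_genes_path, truth_snps_path, cross_a: str, cross_b: str) -> SyntheticTruth:
    """Re-read truth tables written by :func:`write_dataset`."""
    truth = SyntheticTruth()
    with open(truth_genes_path) as fh:
        header = fh.readline()
        for line in fh:
            gid, status, chrom, start, end, strand, theta = line.rstrip("\n").split("\t")
            truth.genes[gid] = GeneTruth(
                gene_id=gid, status=status, chrom=chrom, start=int(start),
                end=int(end), strand=strand, theta=float(theta) if theta else None,
            )
    with open(truth_snps_path) as fh:
        header = fh.readline()  # noqa: F841
        for line in fh:
            chrom, pos, label, gid, fa, fb = line.rstrip("\n").split("\t")
            truth.snps[(chrom, int(pos))] = SnpTruth(
                label=label, gene_id=gid or None,
                f_alt={cross_a: float(fa), cross_b: float(fb)},
            )
    return truth


# ---------------------------------------------------------------------------
# on-disk provenance


def _models_to_bed(models: Sequence[GeneModel]) -> str:
    lines = [
        "\t".join([m.chrom, str(m.start), str(m.end), m.transcript_id, "0", m.strand])
        for m in models
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write counts-TSV x2, BED annotation, truth tables and the exact config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    paths = {
        "counts_a": outdir / f"counts_{cfg.cross_a}.tsv",
        "counts_b": outdir / f"counts_{cfg.cross_b}.tsv",
        "annotation": outdir / "genes.bed",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_snps": outdir / "truth_snps.tsv",
        "config": outdir / "config.yaml",
    }
    write_counts(dataset.counts[cfg.cross_a], paths["counts_a"])
    write_counts(dataset.counts[cfg.cross_b], paths["counts_b"])
    paths["annotation"].write_text(_models_to_bed(dataset.gene_models))
    with paths["truth_genes"].open("w") as fh:
        fh.write("gene_id\tstatus\tchrom\tstart\tend\tstrand\ttheta\n")
        for g in dataset.truth.genes.values():
            fh.write(
                f"{g.gene_id}\t{g.status}\t{g.chrom}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{'' if g.theta is None else g.theta}\n"
            )
    with paths["truth_snps"].open("w") as fh:
        fh.write("chrom\tpos\tlabel\tgene_id\tf_alt_a\tf_alt_b\n")
        for (chrom, pos), s in sorted(dataset.truth.snps.items()):
            fh.write(
                f"{chrom}\t{pos}\t{s.label}\t{s.gene_id or ''}\t"
                f"{s.f_alt[cfg.cross_a]}\t{s.f_alt[cfg.cross_b]}\n"
            )
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["leak_range"] = list(cfg.leak_range)
    cfg_dict["extensions"] = [dataclasses.asdict(e) for e in cfg.extensions]
    cfg_dict["seed"] = dataset.seed
    paths["config"].write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return paths
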