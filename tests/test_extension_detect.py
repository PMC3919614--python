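import pytest

from conftest import run_synthetic

from imprintcall.annotate_aggregate import (
    GeneModel,
    MATERNAL,
    PATERNAL,
    aggregate_transcripts,
    annotate_snps,
)
from imprintcall.extension_detect import (
    detect_extensions,
    extension_summary,
    extensions_to_bed,
)
from imprintcall.synthetic_data import ExtensionSpec, SyntheticConfig, generate
from test_annotate_aggregate import make_test


def scenario(origins_positions, gene, strand="+", chrom="chr12"):
    """Annotate/aggregate a parent gene plus intergenic SNPs and detect."""
    tests = [
        make_test(pos, 20, 20, origin=origin, strand=strand, chrom=chrom)
        for pos, origin in origins_positions
    ]
    annotated = annotate_snps(tests, [gene])
    calls = aggregate_transcripts(annotated)
    return detect_extensions(annotated, calls, [gene])


RIAN = GeneModel("Rian", "chr12", 110_877_000, 110_885_000, "+")


class TestDetectExtensions:
    def test_concordant_downstream_cluster_assigned(self):
        inside = [(110_880_000, MATERNAL)]
        downstream = [(110_900_000 + i * 5_000, MATERNAL) for i in range(14)]
        extensions, unassigned = scenario(inside + downstream, RIAN)
        assert len(extensions) == 1 and not unassigned
        ext = extensions[0]
        assert ext.parent_transcript_id == "Rian"
        assert (ext.start, ext.end) == (110_900_000, 110_965_000)
        assert ext.origin == MATERNAL and ext.strand == "+"
        assert ext.n_snps == 14

    def test_no_intergenic_true_snps(self):
        extensions, unassigned = scenario([(110_880_000, MATERNAL)], RIAN)
        assert extensions == [] and unassigned == []

    def test_discordant_origin_is_unassigned(self):
        inside = [(110_880_000, MATERNAL)]
        downstream = [(110_900_000, PATERNAL), (110_901_000, PATERNAL)]
        extensions, unassigned = scenario(inside + downstream, RIAN)
        assert extensions == []
        assert len(unassigned) == 1
        assert unassigned[0].reason == "unassigned_cluster"

    def test_upstream_cluster_not_an_extension(self):
        inside = [(110_880_000, MATERNAL)]
        upstream = [(110_850_000, MATERNAL), (110_852_000, MATERNAL)]
        extensions, unassigned = scenario(inside + upstream, RIAN)
        assert extensions == []

    def test_minus_strand_extension_runs_leftward(self):
        grb10 = GeneModel("Grb10", "chr11", 11_831_000, 11_860_000, "-")
        inside = [(11_840_000, MATERNAL)]
        downstream = [(11_824_747, MATERNAL), (11_828_159, MATERNAL)]
        tests = [make_test(p, 10, 12, origin=o, strand="-", chrom="chr11")
                 for p, o in inside + downstream]
        annotated = annotate_snps(tests, [grb10])
        calls = aggregate_transcripts(annotated)
        extensions, _ = detect_extensions(annotated, calls, [grb10])
        (ext,) = extensions
        assert (ext.start, ext.end) == (11_824_747, 11_828_159)
        assert ext.distance_to_parent == 11_831_001 - 11_828_159

    def test_beyond_max_reach_unassigned(self):
        inside = [(110_880_000, MATERNAL)]
        far = [(111_100_000, MATERNAL), (111_101_000, MATERNAL)]
        extensions, unassigned = scenario(inside + far, RIAN)
        assert extensions == []
        assert unassigned[0].reason == "unassigned_cluster"

    def test_small_cluster_diagnosed(self):
        inside = [(110_880_000, MATERNAL)]
        single = [(110_900_000, MATERNAL)]
        extensions, unassigned = scenario(inside + single, RIAN)
        assert extensions == []
        assert unassigned[0].reason == "too_few_snps"

    def test_cluster_split_at_intervening_gene(self):
        """Clusters never read through an annotated same-strand transcript."""
        other = GeneModel("Mid", "chr12", 110_910_000, 110_912_000, "+")
        inside = [(110_880_000, MATERNAL)]
        cluster = [(110_900_000, MATERNAL), (110_905_000, MATERNAL),
                   (110_915_000, MATERNAL), (110_918_000, MATERNAL)]
        tests = [make_test(p, 20, 20, origin=o, chrom="chr12")
                 for p, o in inside + cluster]
        annotated = annotate_snps(tests, [RIAN, other])
        calls = aggregate_transcripts(annotated)
        extensions, unassigned = detect_extensions(annotated, calls, [RIAN, other])
        spans = {(e.start, e.end) for e in extensions}
        assert (110_900_000, 110_905_000) in spans
        assert not any(s <= 110_910_000 <= e for s, e in spans)

    def test_shrinking_max_gap_never_merges(self):
        inside = [(110_880_000, MATERNAL)]
        downstream = [(110_900_000 + i * 4_000, MATERNAL) for i in range(10)]
        tests = [make_test(p, 20, 20, origin=o, chrom="chr12")
                 for p, o in inside + downstream]
        annotated = annotate_snps(tests, [RIAN])
        calls = aggregate_transcripts(annotated)
        wide, _ = detect_extensions(annotated, calls, [RIAN], max_gap=10_000)
        narrow, narrow_un = detect_extensions(annotated, calls, [RIAN], max_gap=3_000)
        # narrow clusters are subsets of wide clusters, never merges
        assert len(narrow) + len(narrow_un) >= len(wide)
        for n in narrow:
            assert any(w.start <= n.start and n.end <= w.end for w in wide)

    def test_deterministic_and_order_invariant(self):
        inside = [(110_880_000, MATERNAL)]
        downstream = [(110_900_000 + i * 5_000, MATERNAL) for i in range(5)]
        pairs = inside + downstream
        first = scenario(pairs, RIAN)
        second = scenario(list(reversed(pairs)), RIAN)
        assert first == second


class TestInvariantsOnSyntheticGenomes:
    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_emitted_extensions_satisfy_invariants(self, seed):
        cfg = SyntheticConfig(
            n_genes=40, fraction_maternal=0.15, fraction_paternal=0.15,
            n_strain_variant_sites=5, n_pseudogene_decoys=1,
            extensions=(ExtensionSpec(0), ExtensionSpec(5), ExtensionSpec(9)),
        )
        ds = generate(cfg, seed)
        run = run_synthetic(ds)
        extensions, _ = detect_extensions(run.annotated, run.calls, ds.gene_models)
        calls_by_id = {c.transcript_id: c for c in run.calls}
        truth_parents = {e.parent_gene_id for e in ds.truth.extensions}
        assert extensions, "expected at least one detected extension"
        for ext in extensions:
            parent = calls_by_id[ext.parent_transcript_id]
            assert ext.origin == parent.consensus_origin
            assert ext.strand == parent.strand
            assert ext.start <= ext.end
            assert ext.n_snps >= 2
            if parent.strand == "+":
                assert ext.start > parent.model.end
            else:
                assert ext.end < parent.model.start + 1
            assert ext.parent_transcript_id in truth_parents

    def test_summary_and_bed_export(self, small_dataset, small_run):
        extensions, _ = detect_extensions(
            small_run.annotated, small_run.calls, small_dataset.gene_models
        )
        summary = extension_summary(extensions)
        assert summary.n_extensions == len(extensions)
        bed = extensions_to_bed(extensions)
        assert bed.count("\n") == len(extensions)
        for line, ext in zip(bed.splitlines(), extensions):
            chrom, start, end, name, score, strand = line.split("\t")
            assert int(start) == ext.start - 1 and int(end) == ext.end
            assert name.endswith("_ext")
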