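from types import SimpleNamespace

import pytest

from imprintcall.annotate_aggregate import aggregate_transcripts, annotate_snps
from imprintcall.imprint_test import call_true_snps
from imprintcall.snp_discovery import exclude_strain_variants, find_candidates
from imprintcall.synthetic_data import ExtensionSpec, SyntheticConfig, generate
from imprintcall.worked_examples import jxo_oxj_design


@pytest.fixture(scope="session")
def design():
    return jxo_oxj_design()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator configuration used across unit tests."""
    return SyntheticConfig(
        n_genes=60,
        fraction_maternal=0.10,
        fraction_paternal=0.10,
        fraction_leaky=0.05,
        n_strain_variant_sites=10,
        n_pseudogene_decoys=1,
        extensions=(ExtensionSpec(parent_index=0), ExtensionSpec(parent_index=7)),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config, seed=7)


def run_synthetic(dataset, **call_kwargs):
    """Run the in-memory pipeline stages on a synthetic dataset."""
    cross_a, cross_b = dataset.config.cross_a, dataset.config.cross_b
    candidates = find_candidates(dataset.counts[cross_a], dataset.counts[cross_b])
    kept, excluded = exclude_strain_variants(candidates)
    tests = call_true_snps(kept, dataset.design, **call_kwargs)
    annotated = annotate_snps(tests, dataset.gene_models)
    calls = aggregate_transcripts(annotated)
    return SimpleNamespace(
        candidates=candidates,
        kept=kept,
        excluded=excluded,
        tests=tests,
        annotated=annotated,
        calls=calls,
    )


@pytest.fixture(scope="session")
def small_run(small_dataset):
    return run_synthetic(small_dataset)
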