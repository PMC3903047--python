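import numpy as np
import pytest

import sixmeth as sm


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free, all-methylated corpus: exact round trips attainable."""
    spec = sm.FixtureSpec(
        n_genes=400, noise_sd_expression=0.0, noise_sd_methylation=0.0,
        bimodal_fraction_unmethylated=0.0, seed=3)
    return sm.generate_corpus(spec)


@pytest.fixture(scope="session")
def default_corpus():
    """The default study conditions: 2,000 genes, 30 experiments, 5% noise,
    30% silenced genes, seed 7."""
    return sm.generate_corpus(sm.FixtureSpec())


def make_dataset(corpus):
    summary = sm.summarize_expression(corpus.expression)
    return sm.Dataset(
        decomps=corpus.decompositions,
        lengths=corpus.lengths,
        ge_cv=summary["GE_CV"],
        met=corpus.methylation,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_corpus):
    return make_dataset(clean_corpus)


@pytest.fixture(scope="session")
def default_dataset(default_corpus):
    return make_dataset(default_corpus)


def random_codon_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=3 * n_codons))
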