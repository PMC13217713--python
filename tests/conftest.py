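import numpy as np
import pytest

from molfuse import FixtureSpec, gen_dti_dataset, gen_molecule_dataset, gen_regression_dataset, train_bpe


@pytest.fixture(scope="session")
def clf_records():
    recs, manifest = gen_molecule_dataset(
        FixtureSpec(n=300, n_endpoints=3, positive_rates=(0.5, 0.4, 0.6),
                    missing_rate=0.3, noise=0.05, seed=11))
    return recs, manifest


@pytest.fixture(scope="session")
def reg_records():
    return gen_regression_dataset(300, seed=12, noise=0.1)


@pytest.fixture(scope="session")
def dti_records():
    return gen_dti_dataset(200, seed=13, noise=0.15, frac_long=0.25,
                           short_length=(30, 80), long_length=(90, 150))


@pytest.fixture(scope="session")
def mol_tokenizer(clf_records, reg_records, dti_records):
    corpus = [r.smiles for r in clf_records[0] + reg_records[0] + dti_records[0]]
    return train_bpe(corpus, vocab_limit=300, min_pair_freq=2)


@pytest.fixture(scope="session")
def prot_tokenizer(dti_records):
    return train_bpe([r.protein for r in dti_records[0]], vocab_limit=300, min_pair_freq=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
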