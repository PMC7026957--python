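import numpy as np
import pytest

from molcycle import corpus as corpus_mod
from molcycle.cycle import CycleConfig, run_cycle
from molcycle.fixtures import FixtureSpec, generate_fixture_corpus, write_corpus
from molcycle.generator import GeneratorConfig, GeneratorModel


@pytest.fixture(scope="session")
def small_corpus():
    """800 synthetic molecules: enough grammar to train a toy model on."""
    return generate_fixture_corpus(FixtureSpec(n_molecules=800, seed=3))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return corpus_mod.build_vocabulary(small_corpus)


@pytest.fixture(scope="session")
def small_encoded(small_corpus, small_vocab):
    return corpus_mod.encode(small_corpus, small_vocab, window_length=40)


@pytest.fixture(scope="session")
def trained_small_model(small_encoded, small_vocab):
    """A briefly trained toy generator shared across read-only tests.

    Tests that mutate the model (fine-tuning) must work on a copy.
    """
    cfg = GeneratorConfig.desk(
        small_vocab.size, window_length=40, n_epochs=4, seed=11
    )
    model = GeneratorModel(cfg, small_vocab)
    model.train(small_encoded)
    return model


@pytest.fixture(scope="session")
def default_corpus_file(tmp_path_factory):
    """The default study corpus: 5,000 molecules, ~10% inside the RO3 region."""
    path = tmp_path_factory.mktemp("corpus") / "corpus.smi"
    write_corpus(generate_fixture_corpus(FixtureSpec()), path)
    return path


@pytest.fixture(scope="session")
def desk_cycle_run(default_corpus_file, tmp_path_factory):
    """One full desk-scale cycle run under the default seed.

    Session-scoped because the run takes a couple of minutes; every
    acceptance property reads from this single execution.
    """
    outdir = tmp_path_factory.mktemp("cycle_run")
    molecules = corpus_mod.load_corpus(default_corpus_file)
    vocab_size = corpus_mod.build_vocabulary(molecules).size
    config = CycleConfig.desk(vocab_size=vocab_size, seed=0)
    reports, model, archive = run_cycle(default_corpus_file, config, outdir=outdir)
    return {
        "reports": reports,
        "model": model,
        "archive": archive,
        "outdir": outdir,
        "config": config,
    }
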