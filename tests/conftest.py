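import numpy as np
import pytest

from secribo.simulate import SimulationConfig, make_transcript


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def toy_transcript(rng):
    """202-codon selenoprotein-like transcript, UGA-Sec at codon 46."""
    return make_transcript(rng, "TOY_001.1", "ToySel", 202, (46,),
                           utr5=60, utr3=80)


@pytest.fixture()
def toy_no_sec(rng):
    return make_transcript(rng, "TOY_002.1", "ToyHk", 150, (), 60, 60)


def two_gene_config(seed=5, library_size=20_000, **kw):
    """Small two-gene simulation used across test modules."""
    r = np.random.default_rng(999)
    t1 = make_transcript(r, "T1.1", "SelA", 200, (60,), 60, 80)
    t2 = make_transcript(r, "T2.1", "HkB", 250, (), 60, 80)
    defaults = dict(
        transcripts=[t1, t2],
        abundance={"SelA": {"0Se": 1.0, "0.1Se": 2.0},
                   "HkB": {"0Se": 3.0, "0.1Se": 3.0}},
        readthrough={"SelA": {"0Se": 0.3, "0.1Se": 0.8}},
        seed=seed,
        library_size=library_size,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture()
def small_config():
    return two_gene_config()
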