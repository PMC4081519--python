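import numpy as np
import pytest

from rgkscan import motif_engine as me
from rgkscan import synthetic_data as sd


@pytest.fixture(scope="session")
def signature():
    return me.rgk_signature()


@pytest.fixture(scope="session")
def catalog():
    return me.default_g_motif_catalog()


@pytest.fixture(scope="session")
def small_benchmark():
    """A small seeded benchmark shared by fast tests."""
    spec = sd.BenchmarkSpec(n_rgk=30, n_decoy=20, n_background=30, seed=42)
    records, truth = sd.generate_benchmark(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def clean_rgk_records():
    """Five noise-free RGK-like records with their truth rows."""
    spec = sd.BenchmarkSpec(n_rgk=5, n_decoy=0, n_background=0, seed=7, tail_noise=0.0)
    return sd.generate_rgk_like(5, spec)


def plant(motif: str, at: int, length: int, fill: str = "A") -> str:
    """A filler sequence with one motif planted at a given offset."""
    assert at + len(motif) <= length
    seq = list(fill * length)
    seq[at : at + len(motif)] = motif
    return "".join(seq)
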