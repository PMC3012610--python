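import numpy as np
import pandas as pd
import pytest

from cypwaves.preprocess import average_duplicates, floor_signal
from cypwaves.registry import load_registry
from cypwaves.simulate import ArchetypeSpec, ArrayDesign, generate_timecourse


@pytest.fixture(scope="session")
def registry():
    """The packaged zebrafish CYP registry (96 rows, 94 distinct genes)."""
    return load_registry()


@pytest.fixture(scope="session")
def four_archetype_mix():
    """Four mutually separable temporal patterns for recovery benchmarks.

    Maternal decay, waves centered at 24 and 36 hpf, and bimodal; all
    pairwise profile affinities are below the 0.7 clustering threshold.
    """
    return {
        ArchetypeSpec("maternal_decay"): 0.25,
        ArchetypeSpec("unimodal_wave", center=24.0): 0.25,
        ArchetypeSpec("unimodal_wave", center=36.0): 0.25,
        ArchetypeSpec("bimodal"): 0.25,
    }


@pytest.fixture(scope="session")
def small_timecourse():
    """A small mixed time course with warps and full noise, plus its truth."""
    design = ArrayDesign(n_probes=300)
    return generate_timecourse(design=design, seed=42)


def averaged_matrix(table: pd.DataFrame, floor: bool = True) -> pd.DataFrame:
    """Floor (optionally) and duplicate-average a raw table to probe x array."""
    if floor:
        table = floor_signal(table)
    return average_duplicates(table).values


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
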