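"""Shared fixtures: small synthetic datasets with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from dapregulon.genome import MarkovBackground, fit_markov_background
from dapregulon.peaks import call_peaks, coverage_from_fragments, peak_sequences
from dapregulon.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def uniform_bg() -> MarkovBackground:
    return MarkovBackground.uniform(0)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic study: 120 kb, 48 operons, 8 planted sites."""
    cfg = SimulationConfig(seed=0, genome_length=120_000, n_operons=48,
                           n_planted_sites=8)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_tracks(small_dataset):
    ds = small_dataset
    tf = coverage_from_fragments(ds.tf_fragments, ds.genome, sample_id="synTF")
    ctrl = coverage_from_fragments(ds.control_fragments, ds.genome,
                                   sample_id="control")
    return tf, ctrl


@pytest.fixture(scope="session")
def small_peaks(small_dataset, small_tracks):
    tf, ctrl = small_tracks
    return call_peaks(tf, ctrl)


@pytest.fixture(scope="session")
def small_background(small_dataset):
    return fit_markov_background(small_dataset.genome, order=2)


@pytest.fixture(scope="session")
def small_peak_sequences(small_dataset, small_peaks):
    return peak_sequences(small_peaks, small_dataset.genome, width=500)


def random_pssm(rng: np.random.Generator, width: int, nsites: float = 20.0,
                alpha: float = 1.0):
    """A random PSSM with Dirichlet column frequencies (test helper)."""
    from dapregulon.motifs import PSSM

    freqs = rng.dirichlet(np.full(4, alpha), size=width)
    return PSSM(freqs * nsites, pseudocount=0.0)
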