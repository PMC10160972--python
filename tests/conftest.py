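"""Shared fixtures: small hand-built regions and a reduced simulated sort.

The reduced experiment (a 6-residue sub-domain, 114 substitutions,
2x10^5 cells, 10^4 reads per bin) is session-scoped because the
Gaussian deconvolution of even a small library dominates test runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from hkscan import deconvolve as dec
from hkscan import simulate as sim


@pytest.fixture(scope="session")
def region():
    """The default synthetic 60-residue reference domain (positions 230-289)."""
    return sim.default_reference_region()


@pytest.fixture(scope="session")
def small_region(region):
    """A 6-residue sub-domain (positions 230-235) with coding sequence."""
    from hkscan.library import DomainRegion

    aa = region.aa_sequence[:6]
    nt = region.nt_sequence[:18]
    return DomainRegion(
        protein_id="EnvZ_synthetic", start=230, end=235, aa_sequence=aa, nt_sequence=nt
    )


@pytest.fixture(scope="session")
def small_truth(small_region):
    return sim.generate_ground_truth(
        small_region,
        class_fractions={
            "neutral": 0.60,
            "loss_of_function": 0.15,
            "constitutive": 0.05,
            "crosstalk_gain_R1": 0.05,
            "crosstalk_gain_R2": 0.10,
            "crosstalk_gain_both": 0.05,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sort_config():
    return sim.SortConfig(n_cells_total=200_000, reads_per_bin=10_000, seed=11)


@pytest.fixture(scope="session")
def small_table(small_truth, small_sort_config):
    return sim.simulate_sort_experiment(small_truth, small_sort_config)


@pytest.fixture(scope="session")
def small_measurements(small_table):
    return dec.deconvolve(small_table)
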