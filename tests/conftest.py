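"""Shared fixtures: small seeded plates, frames and matrices."""

import dataclasses

import numpy as np
import pytest

from aggrescreen import flowfret as ff
from aggrescreen.synthdata import (
    ImageSimConfig,
    PlateSimConfig,
    simulate_image,
    simulate_plate,
    with_planted_inhibitors,
)

#: gates matched to the generator's default channel models
BASE_GATES = ff.GateSpec(
    fret_threshold=np.inf, viability_cutoff=1000.0, donor_min=200.0, acceptor_min=200.0
)


def gates_with_threshold(threshold: float) -> ff.GateSpec:
    return dataclasses.replace(BASE_GATES, fret_threshold=threshold)


def auto_gates(plate, layout) -> ff.GateSpec:
    negatives = [plate[w] for w in layout.loc[layout.role == "negative-control", "well"]]
    return gates_with_threshold(ff.auto_fret_threshold(negatives, gates=BASE_GATES))


@pytest.fixture(scope="session")
def small_plate():
    """8-compound plate with one planted inhibitor; 2000 events/well."""
    config = with_planted_inhibitors(
        PlateSimConfig(n_compounds=8, n_events_per_well=2000, seed=11), ["C001"], 0.1
    )
    return simulate_plate(config)


@pytest.fixture(scope="session")
def standard_frame():
    """Default synthetic frame: 10 spots, 6 cells, rho 0.8, N:C ratio 2."""
    return simulate_image(ImageSimConfig(seed=7))
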