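import datetime as dt

import numpy as np
import pytest

from underice.ao_rates import DeltaCalibration, IncubationRecord, atom_fraction_to_delta, delta_to_atom_fraction


@pytest.fixture
def identity_calib():
    return DeltaCalibration.identity()


def record_with_excess(
    excess_n2o: float,
    no2_initial: float = 0.3,
    nh4_ambient: float = 1.9,
    spike: float = 0.1,
    t_hours: float = 4.0,
    baseline_delta: float = 0.0,
) -> IncubationRecord:
    """Build a bottle record whose mean N₂O-scale atom-fraction difference
    (t_f − t₀) is exactly ``excess_n2o``."""
    af0 = delta_to_atom_fraction(baseline_delta)
    return IncubationRecord(
        sample_id="t",
        date=dt.date(2012, 2, 1),
        depth_label="top",
        diel="day",
        nh4_ambient=nh4_ambient,
        no2_initial=no2_initial,
        spike_15n=spike,
        carrier_no2=0.25,
        t_incubation=t_hours,
        d15n_t0=[atom_fraction_to_delta(af0)],
        d15n_tf=[atom_fraction_to_delta(af0 + excess_n2o)],
    )


def random_incubation(rng: np.random.Generator) -> IncubationRecord:
    """A random but physically valid bottle record."""
    return record_with_excess(
        excess_n2o=rng.uniform(-2e-4, 1e-3),
        no2_initial=rng.uniform(0.26, 1.0),
        nh4_ambient=rng.uniform(0.0, 3.4),
        spike=rng.uniform(0.05, 0.3),
        t_hours=rng.uniform(1.0, 24.0),
        baseline_delta=rng.uniform(-30.0, 30.0),
    )
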