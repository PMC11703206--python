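import numpy as np
import pytest

import pepbound as pb


@pytest.fixture
def x5yx5_design():
    return pb.LibraryDesign(var_len_aa=11, fixed_positions={5: "Y"})


@pytest.fixture
def x11_design():
    return pb.LibraryDesign(var_len_aa=11, fixed_positions={})


@pytest.fixture
def constrained_model():
    """Central-Y constrained model, all other coefficients zero."""
    spec = pb.apply_central_constraint(pb.EnergyMatrix(11), "Y")
    ns = pb.NonSpecificMode(pb.EnergyMatrix(3), np.zeros(9))
    return pb.BindingModel(
        spec, ns, activities=[(1.0, 1.0)], depth_params=[(1.0, 1.0)]
    )


@pytest.fixture
def small_design():
    """A 5-residue design with a central fixed tyrosine, for fast fits."""
    return pb.LibraryDesign(var_len_aa=5, fixed_positions={2: "Y"})


def tiny_tables(design, seed=3, n_unique=50, reads=500, rounds=1, w_ns=1):
    sim = pb.SimulationConfig(
        design=design, n_unique=n_unique, rounds=rounds,
        reads_per_column=reads, seed=seed, w_ns=w_ns,
    )
    return pb.simulate_experiment(sim)
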