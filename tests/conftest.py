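import numpy as np
import pytest

from lipidtherm import CycleDesign, EventThermo, GroundTruth, NoiseModel

#: Stepwise K_D values (uM) for wild-type MsbA binding KDL at 298 K.
WT_KD_298 = (0.68, 2.53, 6.01)


@pytest.fixture
def wt_ka():
    """Stepwise association constants (per uM) for the 298 K wild type."""
    return 1.0 / np.asarray(WT_KD_298)


@pytest.fixture
def wt_truth():
    """Three-event ground truth matching the wild-type 298 K signature."""
    return GroundTruth(
        t0=298.0,
        variants={
            "WT": [
                EventThermo(dg_t0=-35.2, dh_t0=45.0, dcp=8.9),
                EventThermo(dg_t0=-32.0, dh_t0=59.9, dcp=11.7),
                EventThermo(dg_t0=-29.8, dh_t0=59.1, dcp=10.7),
            ]
        },
    )


@pytest.fixture
def double_design():
    """Single-event double-mutant-cycle design with a known coupling."""
    return CycleDesign(
        wild_type=[EventThermo(dg_t0=-35.2, dh_t0=45.0, dcp=8.9)],
        mutations={
            "X": [EventThermo(dg_t0=2.7, dh_t0=-60.0, dcp=-2.0)],
            "Y": [EventThermo(dg_t0=2.8, dh_t0=-2.0, dcp=1.0)],
        },
        couplings={frozenset(("X", "Y")): [(1.7, -26.0)]},
    )


@pytest.fixture
def noiseless():
    return NoiseModel(fraction_noise_sd=0.0, n_replicates=1, seed=0)
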