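import numpy as np
import pytest

from lbdens.synthetic import (
    BondSchedule,
    BoostSpec,
    LandscapeSpec,
    WellSpec,
    gen_amd_ensemble,
    gen_mini_protein_trajectory,
    gen_titration,
)

# study conditions used across tests: a two-well surface 1 kcal/mol apart,
# and a 12-point 2-fold titration of a 50 nM probe spanning Kd = 100 nM
TWO_WELL_CENTERS = ((1.0, 3.0), (3.0, 1.0))
TWO_WELL_DEPTH = 1.0
TITRATION_RT = [5000.0 / 2**i for i in range(12)]
TITRATION_TRUTH = dict(Kd_nM=100.0, Ab=0.35, Af=0.05, Lst_nM=50.0)


@pytest.fixture(scope="session")
def two_well_spec():
    return LandscapeSpec(
        wells=[
            WellSpec(center=TWO_WELL_CENTERS[0], depth=0.0),
            WellSpec(center=TWO_WELL_CENTERS[1], depth=TWO_WELL_DEPTH),
        ]
    )


@pytest.fixture(scope="session")
def two_well_boosted_spec():
    return LandscapeSpec(
        wells=[
            WellSpec(center=TWO_WELL_CENTERS[0], depth=0.0),
            WellSpec(center=TWO_WELL_CENTERS[1], depth=TWO_WELL_DEPTH),
        ],
        boost=BoostSpec(),
    )


@pytest.fixture(scope="session")
def unbiased_ensemble(two_well_spec):
    return gen_amd_ensemble(two_well_spec, 100_000, seed=11)


@pytest.fixture(scope="session")
def boosted_ensemble(two_well_boosted_spec):
    return gen_amd_ensemble(two_well_boosted_spec, 100_000, seed=12)


@pytest.fixture(scope="session")
def half_bonded_trajectory():
    """12-residue peptide whose 3->8 pair is bonded in exactly half the frames."""
    schedule = BondSchedule(
        pairs=[(3, 8)], states=[np.tile([True, False], 5)]
    )
    return gen_mini_protein_trajectory(12, schedule=schedule)


@pytest.fixture()
def clean_titration():
    t, flags = gen_titration(
        **TITRATION_TRUTH,
        Rt_series_nM=TITRATION_RT,
        noise_sd=0.0,
        outlier_frac=0.0,
        seed=0,
    )
    assert not flags.any()
    return t
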