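import dataclasses

import pytest

from skinstrain.synthetic import default_profiles, generate_dataset


@pytest.fixture(scope="session")
def profiles():
    """The two default cultivar profiles, seeded."""
    return default_profiles(seed=1)


@pytest.fixture(scope="session")
def bundles(profiles):
    """One generated dataset per default profile (full default sizes)."""
    apple, tommy = profiles
    return generate_dataset(apple), generate_dataset(tommy)


@pytest.fixture(scope="session")
def noiseless_bundle(profiles):
    """Apple-like dataset with every noise CV forced to zero."""
    apple, _ = profiles
    silent = dataclasses.replace(
        apple, cv_area=0.0, cv_disc=0.0, cv_mass=0.0, cv_force=0.0, cv_lenticel_area=0.0
    )
    return generate_dataset(silent)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, bundles):
    """Both generated datasets written out as CSV directories."""
    root = tmp_path_factory.mktemp("simdata")
    for bundle in bundles:
        bundle.write(root / bundle.profile.name)
    return root
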