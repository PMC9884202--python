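import numpy as np
import pytest

from sarcseg.simulate import DoubleLineSpec, NoiseSpec, simulate_double_lines, simulate_field


@pytest.fixture(scope="session")
def small_line_spec():
    """Three pairs on a short strand — fast fixture for geometry tests."""
    return DoubleLineSpec(
        n_pairs=3,
        epitope_density=20.0,
        labels_per_epitope_mean=3.0,
        labels_per_epitope_var=1.0,
        blinks_per_label_mean=1.2,
    )


@pytest.fixture(scope="session")
def small_noise_spec():
    return NoiseSpec(field_width=12000.0, field_height=8000.0)


@pytest.fixture(scope="session")
def small_field(small_line_spec, small_noise_spec):
    return simulate_field(small_line_spec, small_noise_spec, rng_seed=11)


@pytest.fixture(scope="session")
def object_cloud():
    """Localizations of a single clean double-line object (d=120 nm)."""
    spec = DoubleLineSpec(
        n_pairs=1,
        d=120.0,
        epitope_density=30.0,
        labels_per_epitope_mean=4.0,
        loc_precision_mean=10.0,
        loc_precision_sd=0.0,
        linker_length=0.0,
        blinks_per_label_mean=1.0,
    )
    df = simulate_double_lines(spec, rng_seed=5)
    return df[["x_nm", "y_nm"]].to_numpy(float)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
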