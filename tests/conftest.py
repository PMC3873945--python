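import pytest

from ecogdecode import (
    DecodingConfig,
    GeneratorConfig,
    GroundTruth,
    make_dataset,
    prepare_decoding,
)

# A small planted session shared across test modules: 8 electrodes on a
# 2 x 4 grid, 90 s at 500 Hz, three informative channels coupled through
# the wide gamma bands at comfortable SNR.
PLANTED_CHANNELS = frozenset({2, 5, 7})


@pytest.fixture(scope="session")
def planted_channels():
    return PLANTED_CHANNELS


@pytest.fixture(scope="session")
def planted_dataset():
    cfg = GeneratorConfig(
        duration_s=90.0,
        fs=500.0,
        n_rows=2,
        n_cols=4,
        seed=202,
        truth=GroundTruth(
            informative_channels=PLANTED_CHANNELS,
            band_weights={"gamma2": 1.0, "gamma3": 1.0, "gamma4": 1.0},
            snr=25.0,
        ),
    )
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def small_decoding():
    return DecodingConfig(train_s=50.0, test_s=30.0)


@pytest.fixture(scope="session")
def prepared(planted_dataset, small_decoding):
    return prepare_decoding(planted_dataset, small_decoding)
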