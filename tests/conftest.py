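import numpy as np
import pytest

from predann.experiments import (
    HIGH_SNR_DB,
    LOW_SNR_DB,
    delay_sweep,
    lambda_contrast,
    length_curve,
    run_analogue_cached,
)

ANALOGUE_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def high_snr_run():
    """End-to-end run at high SNR (the noise-free sanity regime)."""
    return run_analogue_cached(0, snr_db=HIGH_SNR_DB, lambda_predann=0.05)


@pytest.fixture(scope="session")
def lambda_results():
    """Paired low-SNR comparison of contrastive weight 0.05 vs 0, 3 seeds."""
    return lambda_contrast(seeds=ANALOGUE_SEEDS, snr_db=LOW_SNR_DB)


@pytest.fixture(scope="session")
def low_snr_runs():
    """The contrastive low-SNR runs, one per seed."""
    return [
        run_analogue_cached(s, snr_db=LOW_SNR_DB, lambda_predann=0.05)
        for s in ANALOGUE_SEEDS
    ]


@pytest.fixture(scope="session")
def length_tables(low_snr_runs):
    """Length-by-method accuracy tables for each low-SNR run."""
    return [length_curve(run)[0] for run in low_snr_runs]


@pytest.fixture(scope="session")
def sweep_results():
    """Training-delay sweep on the {0, 100, 200, 400} ms grid."""
    return delay_sweep(seeds=ANALOGUE_SEEDS, snr_db=LOW_SNR_DB)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
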