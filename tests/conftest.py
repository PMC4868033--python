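import numpy as np
import pandas as pd
import pytest

from heatmort import SeriesSpec, lag_mean_exposure, simulate_daily_series


@pytest.fixture(scope="session")
def default_series():
    """One synthetic 5-summer series at the default generating truths."""
    return simulate_daily_series(SeriesSpec(seed=1234))


@pytest.fixture(scope="session")
def default_exposure(default_series):
    return lag_mean_exposure(
        default_series.set_index("date")["tmean_c"], policy="partial"
    )


def make_noise_free_records(
    t0=20.0, beta1=-0.04, beta2=0.017, alpha=np.log(150.0), n_summers=3, seed=7
):
    """Deterministic records whose deaths equal the exact Poisson means.

    Temperatures are a fixed quasi-random scan of the exposure range;
    confounder effects are zero, so the two-segment model fits exactly and
    the profile likelihood has a unique kink-free optimum at ``t0``.
    The large alpha keeps all means >= 100.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_summers):
        dates = pd.date_range(f"{2007 + k}-05-01", f"{2007 + k}-09-30", freq="D")
        temps = rng.uniform(12.0, 30.0, size=len(dates))
        expo = (
            pd.Series(temps, index=dates)
            .rolling(4, min_periods=1)
            .mean()
            .to_numpy()
        )
        lp = alpha + np.where(
            expo <= t0, beta1 * (expo - t0), beta2 * (expo - t0)
        )
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "deaths": np.exp(lp),  # exact means, no Poisson noise
                    "tmean_c": temps,
                    "dewpoint_c": np.zeros(len(dates)),
                    "pm10": np.full(len(dates), 40.0),
                    "holiday": 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
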