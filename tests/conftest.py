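import numpy as np
import pytest

import dfcstates as d


@pytest.fixture(scope="session")
def taper22() -> d.TaperedWindow:
    return d.make_taper(22, 3.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def series_from_vectors(vectors, n_regions, subject_id="s"):
    """Build a WindowedConnectivitySeries whose upper-triangle vectors are
    the given rows (test helper for clustering on known geometry)."""
    from dfcstates.clustering import vec_to_matrix

    mats = np.stack([vec_to_matrix(v, n_regions) for v in np.atleast_2d(vectors)])
    return d.WindowedConnectivitySeries(
        matrices=mats,
        kind="correlation",
        window_starts=np.arange(mats.shape[0]),
        subject_id=subject_id,
    )


@pytest.fixture(scope="session")
def small_three_state_dataset():
    """12 subjects, 12 regions, 3 latent states, low noise — a compact
    scenario whose windowed series and truth labels several tests share."""
    sc = d.make_paper_like_scenario(
        k_states=3,
        weak_fraction_shift=0.0,
        dwell_ratio=1.0,
        seed=5,
        n_regions=12,
        n_timepoints=120,
        n_subjects=(6, 6),
        noise_sd=0.05,
    )
    tcs, truth = d.generate_dataset(sc)
    taper = d.make_taper(22, 3.0)
    series = [d.windowed_correlation(tc, taper) for tc in tcs]
    return sc, series, truth
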