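import numpy as np
import pytest

from irlego import lineage as lin
from irlego import synthetic as syn
from irlego import thermometry as th


def theta_grid(resolution=0.01):
    n = int(round(1.0 / resolution))
    grid = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                grid.append((a, b, c, n - a - b - c))
    return np.asarray(grid, dtype=float) / n


def grid_search_mle(counts, resolution=0.01):
    """Brute-force maximum of the joint log-likelihood on a parameter grid.

    Independent of the optimizer: enumerates the theta simplex and both
    background rates at the given resolution.
    """
    thetas = theta_grid(resolution)
    betas = np.arange(0.0, 1.0 + resolution / 2, resolution)
    n_lab = counts.labeled.astype(float)
    n_ctl = counts.control.astype(float)
    best = -np.inf
    tiny = 1e-300
    for bt in betas:
        for bm in betas:
            m = np.array(
                [
                    [1, bt, bm, bt * bm],
                    [0, 0, 1 - bm, bt * (1 - bm)],
                    [0, 1 - bt, 0, (1 - bt) * bm],
                    [0, 0, 0, (1 - bt) * (1 - bm)],
                ]
            )
            ll = np.log(np.clip(thetas @ m.T, tiny, None)) @ n_lab
            p_ctl = np.array(
                [bt * bm, bt * (1 - bm), (1 - bt) * bm, (1 - bt) * (1 - bm)]
            )
            ll_ctl = float(n_ctl @ np.log(np.clip(p_ctl, tiny, None)))
            top = float(ll.max()) + ll_ctl
            if top > best:
                best = top
    return best


@pytest.fixture(scope="session")
def small_table_grid_oracle():
    """A small category table and its brute-force joint-loglik maximum."""
    counts = lin.CohortCounts(
        labeled=np.array([3, 1, 1, 1]), control=np.array([0, 1, 1, 8])
    )
    return counts, grid_search_mle(counts, resolution=0.01)


@pytest.fixture(scope="session")
def bootstrap_coverage_rate():
    """Fraction of 250 synthetic cohorts (n = 200 per group) whose 95%
    bootstrap interval for theta_TM covers the simulation truth."""
    theta_true = 0.4
    cover = 0
    n_cohorts = 250
    for rep in range(n_cohorts):
        cfg = syn.CohortGenConfig(
            theta=(0.4, 0.3, 0.1, 0.2), beta_t=0.05, beta_m=0.10,
            n_labeled=200, n_control=200, seed=50_000 + rep,
        )
        df = syn.generate_cohort(cfg)
        _, ci = lin.bootstrap_ci(df, B=120, seed=rep, n_starts_per_fit=1)
        lo, hi = ci["theta_tm"]
        cover += lo <= theta_true <= hi
    return cover / n_cohorts


@pytest.fixture(scope="session")
def noiseless_cfg() -> syn.SpectraGenConfig:
    return syn.SpectraGenConfig(noise_cv=0.0)


@pytest.fixture(scope="session")
def default_basis(noiseless_cfg) -> th.DyeBasis:
    fitc, tamra = syn.generate_basis_spectra(noiseless_cfg)
    return th.DyeBasis(fitc, tamra)


@pytest.fixture(scope="session")
def calibration_noiseless(noiseless_cfg, default_basis) -> th.RatioCalibration:
    """Noise-free ratio calibration over the 25-38 degC ramp."""
    series = syn.generate_calibration_series(
        np.arange(25.0, 38.5, 1.0), 1, noiseless_cfg
    )
    unmixed = [(t, th.unmix_spectrum(s, default_basis)) for t, s in series]
    return th.fit_ratio_calibration(
        unmixed, medium="water", reference_temperature=noiseless_cfg.ref_temperature
    )
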