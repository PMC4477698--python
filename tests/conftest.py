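import numpy as np
import pytest

from bayspar.calibration import McmcSettings, PosteriorEnsemble
from bayspar.spatial import GridSpec


@pytest.fixture
def grid():
    return GridSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_point_mass_ensemble(
    box_ids, alpha, beta, tau2=1e-12, n_draws=1, grid=None, jitter_sd=0.0, seed=0
) -> PosteriorEnsemble:
    """Ensemble with (near-)degenerate draws, for deterministic-limit tests."""
    grid = grid or GridSpec()
    box_ids = np.asarray(box_ids, dtype=int)
    nb = len(box_ids)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (nb,))
    beta = np.broadcast_to(np.asarray(beta, dtype=float), (nb,))
    g = np.random.default_rng(seed)
    a = np.tile(alpha, (n_draws, 1)) + jitter_sd * g.standard_normal((n_draws, nb))
    b = np.tile(beta, (n_draws, 1)) + jitter_sd * g.standard_normal((n_draws, nb))
    b = np.maximum(b, 1e-6)
    settings = McmcSettings(n_chains=1, n_iter=n_draws + 1, n_warmup=1, thin=1)
    return PosteriorEnsemble(
        alpha=a,
        beta=b,
        tau2=np.full(n_draws, tau2),
        mu_alpha=np.full(n_draws, alpha.mean()),
        mu_beta=np.full(n_draws, beta.mean()),
        sigma2_alpha=np.full(n_draws, 1e-6),
        sigma2_beta=np.full(n_draws, 1e-8),
        phi=np.full(n_draws, 5e-4),
        chain=np.zeros(n_draws, dtype=int),
        box_ids=box_ids,
        target_kind="SST",
        seed=seed,
        settings=settings,
        grid=grid,
        box_mean_tex=np.full(nb, 0.5),
        box_mean_temp=np.full(nb, 15.0),
        box_n_obs=np.ones(nb, dtype=int),
    )
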