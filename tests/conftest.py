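import numpy as np
import pytest

import uncertime as ut


@pytest.fixture(scope="session")
def low_noise_ds() -> ut.SyntheticDataset:
    """80 cells on a tight trajectory, 40 genes (10 sigmoidal switches)."""
    cfg = ut.SimulationConfig(
        n_cells=80,
        n_genes=40,
        frac_switch=0.25,
        noise_sd_embedding=0.03,
        noise_sd_expression=0.3,
        seed=11,
    )
    return ut.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def posterior_low_noise(low_noise_ds) -> ut.PseudotimePosterior:
    """One shared 2-chain posterior on the low-noise fixture (unoriented)."""
    Xs = ut.standardize(low_noise_ds.embedding)
    settings = ut.MCMCSettings(chains=2, warmup=600, samples=600, seed=5)
    return ut.sample_posterior(Xs, ut.GPLVMHyperparams(), settings)


@pytest.fixture(scope="session")
def oriented_posterior(posterior_low_noise, low_noise_ds) -> ut.PseudotimePosterior:
    """The shared posterior oriented against the true pseudotimes."""
    return ut.orient_and_map(posterior_low_noise, low_noise_ds.truth_pseudotimes)


@pytest.fixture(scope="session")
def posterior_high_noise():
    """Posterior on a noisy trajectory (for predictive-overlap contrasts)."""
    cfg = ut.SimulationConfig(
        n_cells=60, n_genes=10, noise_sd_embedding=0.25, seed=21
    )
    ds = ut.simulate_dataset(cfg)
    Xs = ut.standardize(ds.embedding)
    settings = ut.MCMCSettings(chains=1, warmup=400, samples=400, seed=7)
    return ds, ut.sample_posterior(Xs, ut.GPLVMHyperparams(), settings)


def make_posterior(t_draws, cell_ids=None, lam=5.0, sigma_sq=0.1, gamma=6.0):
    """Hand-build a PseudotimePosterior from given pseudotime draws (for
    tests of the downstream sweeps that do not need a real MCMC run)."""
    t_draws = np.atleast_2d(np.asarray(t_draws, dtype=float))
    S, N = t_draws.shape
    if cell_ids is None:
        cell_ids = tuple(f"cell_{i:04d}" for i in range(N))
    return ut.PseudotimePosterior(
        t=t_draws,
        lam=np.full((S, 2), lam),
        sigma_sq=np.full((S, 2), sigma_sq),
        gamma=np.full(S, gamma),
        chain_id=np.zeros(S, dtype=int),
        log_posterior=np.zeros(S),
        map_index=0,
        cell_ids=tuple(cell_ids),
        hyperparams=ut.GPLVMHyperparams(),
    )
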