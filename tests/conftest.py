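"""Shared fixtures: small synthetic datasets with known ground truth."""

from __future__ import annotations

import pytest

from paleodiv.synthetic import (SimulationConfig, emit_occurrence_table,
                                simulate_bd, simulate_preservation)

WINDOW = (254.0, 237.0)


def constant_config(seed=0, lam=0.2, mu=0.1, q=1.0, n_seed=30, **kw):
    return SimulationConfig(
        t_start=WINDOW[0], t_end=WINDOW[1],
        lambda_episodes=[(WINDOW[0], WINDOW[1], lam)],
        mu_episodes=[(WINDOW[0], WINDOW[1], mu)],
        q_bins=[(WINDOW[0], WINDOW[1], q)],
        n_seed_lineages=n_seed, rng_seed=seed, **kw)


@pytest.fixture(scope="session")
def small_history():
    return simulate_bd(constant_config(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = constant_config(seed=7)
    history = simulate_bd(cfg)
    occs = simulate_preservation(history, cfg)
    table, truth = emit_occurrence_table(history, occs, cfg)
    return cfg, history, occs, table, truth


@pytest.fixture(scope="session")
def noisy_dataset():
    cfg = constant_config(seed=11, qualifier_noise_p=0.08, terrestrial_p=0.05,
                          subgenus_p=0.15, outlier_p=0.2, coarse_dating_p=0.1)
    history = simulate_bd(cfg)
    occs = simulate_preservation(history, cfg)
    table, truth = emit_occurrence_table(history, occs, cfg)
    return cfg, history, occs, table, truth
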