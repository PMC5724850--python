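"""Shared fixtures: small phantoms and simulated cohorts, generated at test
time (no stored binary data)."""

from __future__ import annotations

import numpy as np
import pytest

from normes import PhantomSpec, QuantConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small but anatomically complete phantom: clean volume, true lung
    mask, true emphysema grid, and the spec that produced them."""
    spec = PhantomSpec(shape=(32, 64, 64), spacing=(1.25, 1.0, 1.0),
                       n_clusters=6, cluster_radius_mm=(2.5, 5.0), seed=42)
    clean, mask, emph = generate_phantom(spec)
    return clean, mask, emph, spec


@pytest.fixture(scope="session")
def quant_config():
    return QuantConfig()


def make_survival_data(n: int, seed: int, censor_frac: float = 0.3,
                       beta: float = 0.0):
    """Simple exponential survival sample with a standard-normal marker and
    uniform censoring; returns (time, event, weight, marker)."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=n)
    lam = 1e-3 * np.exp(beta * m)
    death = rng.exponential(1.0 / lam)
    cens = np.where(rng.random(n) < censor_frac,
                    rng.uniform(1, 3000, n), 3000.0)
    time = np.minimum(death, cens)
    event = (death <= cens).astype(int)
    return np.maximum(time, 1.0), event, np.ones(n), m
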