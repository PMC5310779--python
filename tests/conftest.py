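"""Shared fixtures: one reusable simulated dataset and an independent
site-wise pair simulator for distance-estimator recovery tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from rge import evolution_metrics as em
from rge import synthetic_data as sd

BASES = "ACGT"


def hky_pair(t: float, kappa: float, gc: float, length: int, seed: int):
    """Simulate an (ancestor, descendant) pair site-independently.

    Deliberately separate from the package's Gillespie machinery: the
    ancestor is drawn from the HKY equilibrium and each site's descendant
    base is sampled from the matrix exponential of the rate matrix, so
    estimator-recovery tests do not share a code path with the simulator
    under test.
    """
    rng = np.random.default_rng(seed)
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = (kappa if (i, j) in transitions else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    P = expm(Q * t)
    cumP = np.cumsum(P, axis=1)
    anc = rng.choice(4, size=length, p=pi)
    dec = np.empty(length, dtype=int)
    for x in range(4):
        idx = np.flatnonzero(anc == x)
        dec[idx] = np.searchsorted(cumP[x], rng.random(len(idx)), side="right")
    dec = np.minimum(dec, 3)
    to_str = np.array(list(BASES))
    return "".join(to_str[anc]), "".join(to_str[dec])


def exact_mwu_p(x, y):
    """Exhaustive two-sided exact Mann-Whitney oracle (assumes no ties)."""
    import itertools

    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b)

    u_obs = u_stat(x, y)
    n1n2 = n1 * len(y)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        chosen = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = u_stat(xs, ys)
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return extreme / total


@pytest.fixture(scope="session")
def default_dataset() -> sd.SimulationResult:
    """One default-condition simulated dataset shared across tests."""
    return sd.simulate_dataset(sd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_alignments(default_dataset):
    return {
        gene: em.pairwise_vs_outgroup(rows, sd.OUTGROUP_ID)
        for gene, rows in default_dataset.alignments.items()
    }
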