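"""Shared fixtures and the independent fixed-step Euler oracle.

The oracle integrates the same mass-action network with explicit Euler at
a small fixed step, sharing no code with the adaptive solve_ivp path in
:mod:`rascycle.kinetics`.  Oracle scenarios use a reduced nucleotide pool
so the fast bimolecular binding mode stays within Euler's stability limit
at a tractable step size.
"""

from __future__ import annotations

import numpy as np
import pytest
from numba import njit

from rascycle.kinetics import ReactionNetwork


@njit(cache=False)
def _euler_loop(x, n_steps, dt, ri, ks, stoich, sample_every, out):
    n_species = x.shape[0]
    n_flux = ks.shape[0]
    dx = np.zeros(n_species)
    out[:, 0] = x
    s = 0
    for step in range(1, n_steps + 1):
        for i in range(n_species):
            dx[i] = 0.0
        for j in range(n_flux):
            v = ks[j]
            a, b = ri[j, 0], ri[j, 1]
            if a >= 0:
                v *= x[a]
            if b >= 0:
                v *= x[b]
            if v != 0.0:
                for i in range(n_species):
                    if stoich[i, j] != 0.0:
                        dx[i] += stoich[i, j] * v
        for i in range(n_species):
            x[i] += dx[i] * dt
        if step % sample_every == 0:
            s += 1
            out[:, s] = x


def euler_simulate(
    net: ReactionNetwork,
    ic: dict[str, float],
    t_end: float,
    dt: float,
    sample_dt: float,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Fixed-step explicit-Euler integration of a mass-action network."""
    idx = {s: i for i, s in enumerate(net.species)}
    n = len(net.species)
    ri_rows, ks, cols = [], [], []
    for r in net.reactions:
        if r.modifier is not None:
            raise ValueError("oracle only supports pure mass-action networks")
        col = np.zeros(n)
        for s in r.reactants:
            col[idx[s]] -= 1
        for s in r.products:
            col[idx[s]] += 1
        pad = [idx[s] for s in r.reactants] + [-1, -1]
        ri_rows.append(pad[:2])
        ks.append(r.k_fwd)
        cols.append(col)
        if r.k_rev > 0:
            pad = [idx[s] for s in r.products] + [-1, -1]
            ri_rows.append(pad[:2])
            ks.append(r.k_rev)
            cols.append(-col)
    sample_every = int(round(sample_dt / dt))
    n_samples = int(round(t_end / sample_dt))
    n_steps = n_samples * sample_every
    x = np.zeros(n)
    for s, c in ic.items():
        x[idx[s]] = c
    out = np.zeros((n, n_samples + 1))
    _euler_loop(
        x, n_steps, dt,
        np.asarray(ri_rows, dtype=np.int64),
        np.asarray(ks, dtype=np.float64),
        np.column_stack(cols).astype(np.float64),
        sample_every, out,
    )
    times = np.arange(n_samples + 1) * sample_dt
    return times, {s: out[idx[s]] for s in net.species}


@pytest.fixture(scope="session")
def canonical_ic():
    from rascycle.kinetics import CANONICAL_INITIAL_STATE

    return dict(CANONICAL_INITIAL_STATE)
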