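"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from stroopeffort.engine import LevelModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_level_model(rng: np.random.Generator, n_states=(2, 3),
                       n_outcomes=(2, 4), T: int = 3,
                       n_actions=(1, 2), n_policies: int = 2,
                       preferences: bool = False) -> LevelModel:
    """A fully random (dense, well-conditioned) small model."""
    A = []
    for no in n_outcomes:
        a = rng.random((no,) + tuple(n_states)) + 0.1
        A.append(a / a.sum(axis=0, keepdims=True))
    B = []
    for f, na in enumerate(n_actions):
        b = rng.random((na, n_states[f], n_states[f])) + 0.1
        B.append(b / b.sum(axis=1, keepdims=True))
    D = [rng.dirichlet(np.ones(n) * 2) for n in n_states]
    C = [rng.normal(size=no) if preferences else np.zeros(no)
         for no in n_outcomes]
    policies = np.stack([
        np.stack([[rng.integers(n_actions[f]) for f in range(len(n_states))]
                  for _ in range(T)])
        for _ in range(n_policies)])
    return LevelModel(A=A, B=B, C=C, D=D, E=rng.normal(size=n_policies),
                      policies=policies, T=T)


def enumerate_posterior(model: LevelModel, observations, policy: int) -> np.ndarray:
    """Exact smoothing marginals by summation over all joint state sequences.

    Returns an array ``(T, *n_states)`` of per-time-step joint marginals.
    Deliberately naive (independent of the package's message passing).
    """
    ns = model.n_states
    n_joint = int(np.prod(ns))
    post = np.zeros((model.T,) + ns)
    for seq in product(range(n_joint), repeat=model.T):
        p = 1.0
        prev = None
        for t, j in enumerate(seq):
            idx = np.unravel_index(j, ns)
            if t == 0:
                for f, i in enumerate(idx):
                    p *= model.D[f][i]
            else:
                pidx = np.unravel_index(prev, ns)
                acts = model.policy_actions(policy, t - 1)
                for f in range(model.n_factors):
                    p *= model.B[f][acts[f], idx[f], pidx[f]]
            if t < len(observations) and observations[t] is not None:
                for m, o in enumerate(observations[t]):
                    if o is not None:
                        p *= model.A[m][(o,) + idx]
            prev = j
        for t, j in enumerate(seq):
            post[t][np.unravel_index(j, ns)] += p
    return post / post.sum(axis=tuple(range(1, model.n_factors + 1)),
                           keepdims=True)


@pytest.fixture
def baseline_params():
    from stroopeffort.stroop import StroopParams

    return StroopParams(seed=0, condition="colour-naming")
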