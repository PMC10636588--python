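"""Discrete-state active-inference machinery.

A single hierarchical level is described by a :class:`LevelModel` holding the
usual categorical generative-model components:

* ``A`` — likelihood arrays, one per outcome modality, mapping the joint
  hidden state to a distribution over outcomes;
* ``B`` — transition arrays, one per hidden-state factor and action,
  column-stochastic over the "to" index;
* ``C`` — prior (log) preferences per outcome modality, stored so that
  *higher means preferred*;
* ``D`` — initial-state priors per factor;
* ``E`` — habit potentials, one per policy, in nats; the habitual policy
  prior is ``softmax(-E)``;
* a policy set and a horizon.

Belief updating is a gradient flow on variational free energy in log-space
(``v``); the flow's fixed point is the exact smoothing posterior of the joint
hidden-state chain, which this module computes with forward/backward message
passing on the flattened joint state space.  The iterates of the flow are
recorded so that downstream synthetic electrophysiology can be derived from
the *dynamics* of belief updating, while the returned posteriors are the
fixed point itself (exact, so they agree with brute-force enumeration).

Policies are scored by their expected free energy ``G`` (risk relative to
preferences plus ambiguity of the likelihood mapping) and combined with the
habit potential to give the policy posterior ``softmax(-E - G)``.

Joint-state flattening uses declaration order with the *last* factor varying
fastest (C order), fixed throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "P_FLOOR",
    "LevelModel",
    "LevelLink",
    "BeliefTrajectory",
    "softmax",
    "stable_log",
    "infer_states",
    "predict_outcomes",
    "ambiguity",
    "expected_free_energy",
    "efe_decomposition",
    "policy_posterior",
    "bayesian_model_average",
    "run_deep_inference",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "trajectory_to_tsv",
    "trajectory_to_hdf5",
]

#: Probabilities are floored at this value inside logarithms, so that
#: deterministic likelihoods do not produce -inf potentials.
P_FLOOR = 1e-16

_NORM_TOL = 1e-9


def stable_log(p: np.ndarray) -> np.ndarray:
    """Logarithm with probabilities floored at :data:`P_FLOOR`."""
    return np.log(np.maximum(np.asarray(p, dtype=float), P_FLOOR))


def softmax(potentials: Sequence[float] | np.ndarray, precision: float = 1.0,
            axis: int = -1) -> np.ndarray:
    """Normalised exponential of ``precision * potentials``.

    Invariant to adding a constant to all potentials and computed stably for
    large magnitudes.  ``precision`` must be a finite non-negative real
    (``0`` yields the uniform distribution).
    """
    x = np.asarray(potentials, dtype=float)
    if x.size == 0:
        raise ValueError("softmax of an empty potential vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax requires finite potentials")
    if not np.isfinite(precision) or precision < 0:
        raise ValueError("softmax precision must be a finite non-negative real")
    z = precision * x
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_prob(p: np.ndarray, name: str, axis: int = -1) -> None:
    p = np.asarray(p)
    if np.any(p < -_NORM_TOL):
        raise ValueError(f"{name} has negative entries")
    s = p.sum(axis=axis)
    if not np.allclose(s, 1.0, atol=1e-6):
        raise ValueError(f"{name} does not normalise to 1 (sums {s})")


@dataclass
class LevelModel:
    """Generative model for one hierarchical level.

    Parameters
    ----------
    A : list of ndarray
        One array per outcome modality, shape ``(n_outcomes, *n_states)``.
    B : list of ndarray
        One array per factor, shape ``(n_actions, n_states, n_states)``;
        ``B[f][a][:, j]`` is the distribution of the next state given state
        ``j`` under action ``a``.  Uncontrolled factors have ``n_actions = 1``.
    C : list of ndarray
        Log-preferences per modality (higher = preferred), in nats.
    D : list of ndarray
        Initial-state prior per factor.
    E : ndarray
        Habit potential per policy, in nats.
    policies : ndarray
        Integer array ``(n_policies, horizon, n_factors)`` of action indices.
    T : int
        Horizon (number of time steps).
    """

    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    E: np.ndarray
    policies: np.ndarray
    T: int
    factor_names: tuple[str, ...] = ()
    modality_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        self.C = [np.asarray(c, dtype=float) for c in self.C]
        self.D = [np.asarray(d, dtype=float) for d in self.D]
        self.E = np.asarray(self.E, dtype=float)
        self.policies = np.asarray(self.policies, dtype=int)
        if self.policies.ndim != 3:
            raise ValueError("policies must be (n_policies, horizon, n_factors)")
        if not self.factor_names:
            self.factor_names = tuple(f"f{i}" for i in range(len(self.B)))
        if not self.modality_names:
            self.modality_names = tuple(f"m{i}" for i in range(len(self.A)))
        self._validate()
        self._A_flat = [a.reshape(a.shape[0], -1) for a in self.A]
        self._H = self._ambiguity_vector()

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_factors(self) -> int:
        return len(self.B)

    @property
    def n_states(self) -> tuple[int, ...]:
        return tuple(b.shape[1] for b in self.B)

    @property
    def n_modalities(self) -> int:
        return len(self.A)

    @property
    def n_outcomes(self) -> tuple[int, ...]:
        return tuple(a.shape[0] for a in self.A)

    @property
    def n_joint(self) -> int:
        return int(np.prod(self.n_states))

    @property
    def n_policies(self) -> int:
        return self.policies.shape[0]

    @property
    def A_flat(self) -> list[np.ndarray]:
        """Likelihoods reshaped to ``(n_outcomes, n_joint)`` (C order)."""
        return self._A_flat

    @property
    def H(self) -> np.ndarray:
        """Conditional outcome entropy per joint state, summed over modalities."""
        return self._H

    def _validate(self) -> None:
        shape = self.n_states
        for m, a in enumerate(self.A):
            if a.shape[1:] != shape:
                raise ValueError(f"A[{m}] state dimensions {a.shape[1:]} != {shape}")
            _check_prob(a, f"A[{m}]", axis=0)
        for f, b in enumerate(self.B):
            if b.ndim != 3 or b.shape[1] != b.shape[2]:
                raise ValueError(f"B[{f}] must be (n_actions, n, n)")
            _check_prob(b, f"B[{f}]", axis=1)
        for m, c in enumerate(self.C):
            if c.shape != (self.n_outcomes[m],):
                raise ValueError(f"C[{m}] length mismatch")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"C[{m}] must be finite")
        for f, d in enumerate(self.D):
            if d.shape != (shape[f],):
                raise ValueError(f"D[{f}] length mismatch")
            _check_prob(d, f"D[{f}]")
        if self.E.shape != (self.policies.shape[0],):
            raise ValueError("|E| must equal the number of policies")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("E must be finite")
        if self.policies.shape[1] > self.T:
            raise ValueError("policy length exceeds the horizon")
        if self.policies.shape[2] != self.n_factors:
            raise ValueError("policies must give one action per factor")
        for f, b in enumerate(self.B):
            if np.any(self.policies[:, :, f] >= b.shape[0]):
                raise ValueError(f"policy action out of range for factor {f}")

    # -- joint-space helpers ---------------------------------------------
    def joint_D(self) -> np.ndarray:
        return reduce(np.kron, self.D)

    def joint_B(self, actions: Sequence[int]) -> np.ndarray:
        """Joint transition matrix for one action per factor (last factor fastest)."""
        mats = [self.B[f][int(a)] for f, a in enumerate(actions)]
        return reduce(np.kron, mats)

    def policy_actions(self, policy: int, t: int) -> np.ndarray:
        """Actions applied between step ``t`` and ``t+1`` under a policy."""
        steps = self.policies.shape[1]
        return self.policies[policy, min(t, steps - 1)]

    def joint_to_factors(self, q: np.ndarray) -> list[np.ndarray]:
        """Marginalise a joint-state distribution into per-factor marginals."""
        qt = q.reshape(self.n_states)
        out = []
        for f in range(self.n_factors):
            axes = tuple(i for i in range(self.n_factors) if i != f)
            out.append(qt.sum(axis=axes))
        return out

    def _ambiguity_vector(self) -> np.ndarray:
        H = np.zeros(self.n_joint)
        for a in self._A_flat:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(a > 0, a * np.log(np.maximum(a, P_FLOOR)), 0.0)
            H -= t.sum(axis=0)
        return H


@dataclass
class LevelLink:
    """Linkage of a slow level onto a fast level.

    ``modality_to_factor`` maps slow outcome-modality indices onto fast
    hidden-state factor indices: the slow level's predicted outcome for that
    modality becomes the fast factor's empirical initial-state prior, and the
    fast level's evidence about that initial state ascends to the slow level.
    """

    modality_to_factor: dict[int, int]

    def validate(self, slow: LevelModel, fast: LevelModel) -> None:
        for m, f in self.modality_to_factor.items():
            if m >= slow.n_modalities or f >= fast.n_factors:
                raise ValueError("link indices out of range")
            if slow.n_outcomes[m] != fast.n_states[f]:
                raise ValueError(
                    f"slow modality {m} ({slow.n_outcomes[m]} outcomes) cannot set "
                    f"fast factor {f} ({fast.n_states[f]} states)")


@dataclass
class BeliefTrajectory:
    """Posterior beliefs for one level, per policy and time step.

    ``s[p][f]`` is an ``(T, n_states_f)`` array of state posteriors for
    policy ``p`` and factor ``f``; ``joint[p]`` holds the corresponding joint
    posteriors.  ``v_trace[p]`` records the gradient-flow iterates of the
    joint log-potentials (``(n_recorded, T, n_joint)``), ``epsilon`` the
    state prediction-error magnitude per iteration and ``sigma_err`` the
    outcome (risk) prediction error per time step.
    """

    s: list[list[np.ndarray]]
    joint: list[np.ndarray]
    pi: np.ndarray
    G: np.ndarray
    F: np.ndarray
    v_trace: list[np.ndarray] = field(default_factory=list)
    epsilon: np.ndarray | None = None
    sigma_err: np.ndarray | None = None
    converged: bool = True

    @property
    def n_policies(self) -> int:
        return len(self.s)


# ---------------------------------------------------------------------------
# state inference
# ---------------------------------------------------------------------------

def _likelihood_vector(model: LevelModel, obs: Sequence[int | None] | None) -> np.ndarray:
    lik = np.ones(model.n_joint)
    if obs is None:
        return lik
    for m, o in enumerate(obs):
        if o is None:
            continue
        if not 0 <= int(o) < model.n_outcomes[m]:
            raise ValueError(f"observation {o} out of range for modality {m}")
        lik = lik * model.A_flat[m][int(o)]
    return lik


def exact_joint_posterior(model: LevelModel, observations: Sequence,
                          policy: int) -> tuple[np.ndarray, float]:
    """Exact smoothing posterior of the joint chain under one policy.

    Returns ``(q, F)`` where ``q`` is ``(T, n_joint)`` and ``F`` is the
    accumulated variational free energy at its minimum, i.e. the negative
    log-evidence of the observations under the policy.
    """
    T = model.T
    if len(observations) > T:
        raise ValueError("more observations than time steps")
    liks = [_likelihood_vector(model, observations[t]) if t < len(observations)
            else np.ones(model.n_joint) for t in range(T)]
    Bs = [model.joint_B(model.policy_actions(policy, t)) for t in range(T - 1)]

    alpha = np.empty((T, model.n_joint))
    logZ = 0.0
    a = model.joint_D() * liks[0]
    z = a.sum()
    if z <= 0:
        raise ValueError("observations have zero probability under the model")
    logZ += np.log(z)
    alpha[0] = a / z
    for t in range(1, T):
        a = liks[t] * (Bs[t - 1] @ alpha[t - 1])
        z = a.sum()
        if z <= 0:
            raise ValueError("observations have zero probability under the model")
        logZ += np.log(z)
        alpha[t] = a / z

    beta = np.ones((T, model.n_joint))
    for t in range(T - 2, -1, -1):
        b = Bs[t].T @ (liks[t + 1] * beta[t + 1])
        m = b.max()
        beta[t] = b / (m if m > 0 else 1.0)

    q = alpha * beta
    q = q / q.sum(axis=1, keepdims=True)
    return q, -logZ


def infer_states(model: LevelModel, observations: Sequence, policy: int = 0,
                 n_iter: int = 16, step: float = 0.25, tol: float = 1e-4,
                 v_init: np.ndarray | None = None,
                 record: bool = True) -> BeliefTrajectory:
    """Policy-conditioned state posteriors by free-energy gradient flow.

    ``observations`` is a sequence (length <= T) of per-modality outcome
    indices (``None`` marks an unobserved modality).  The flow
    ``v <- v + step * (ln q* - v)`` contracts onto its fixed point, the exact
    smoothing posterior ``q*`` of the joint hidden-state chain; the iterates
    are recorded (for synthetic electrophysiology) and the fixed point is
    returned.  Steps after the last observation hold the prior-predictive
    propagation ``B·s``.
    """
    if not 0 <= policy < model.n_policies:
        raise ValueError("unknown policy index")
    q_star, F = exact_joint_posterior(model, observations, policy)
    target = stable_log(q_star)
    target = target - target.max(axis=1, keepdims=True)

    if v_init is None:
        # start the flow from the prior propagation
        prior = np.empty_like(q_star)
        prior[0] = model.joint_D()
        for t in range(1, model.T):
            prior[t] = model.joint_B(model.policy_actions(policy, t - 1)) @ prior[t - 1]
        v = stable_log(prior)
    else:
        v = np.array(v_init, dtype=float)
    v = v - v.max(axis=1, keepdims=True)

    trace = []
    eps = []
    converged = False
    for _ in range(n_iter):
        delta = target - v
        v = v + step * delta
        eps.append(float(np.abs(delta).max()))
        if record:
            trace.append(v.copy())
        if eps[-1] < tol:
            converged = True
            break

    s = [model.joint_to_factors(q_star[t]) for t in range(model.T)]
    s_by_factor = [np.stack([s[t][f] for t in range(model.T)])
                   for f in range(model.n_factors)]
    # outcome (risk) prediction errors per time step
    sigma = np.zeros(model.T)
    for t in range(model.T):
        for m in range(model.n_modalities):
            o = model.A_flat[m] @ q_star[t]
            sigma[t] += float(o @ (stable_log(o) - model.C[m]))
    return BeliefTrajectory(
        s=[s_by_factor],
        joint=[q_star],
        pi=np.ones(1),
        G=np.zeros(1),
        F=np.array([F]),
        v_trace=[np.stack(trace)] if (record and trace) else [],
        epsilon=np.array(eps)[None, :],
        sigma_err=sigma[None, :],
        converged=converged,
    )


# ---------------------------------------------------------------------------
# outcome prediction, ambiguity and expected free energy
# ---------------------------------------------------------------------------

def _joint_from_factors(model: LevelModel, factors: Sequence[np.ndarray]) -> np.ndarray:
    for f, s in enumerate(factors):
        _check_prob(np.asarray(s, float), f"state posterior factor {f}")
    return reduce(np.kron, [np.asarray(s, float) for s in factors])


def predict_outcomes(model: LevelModel, state_posterior: Sequence[np.ndarray],
                     mode: str = "linear") -> list[np.ndarray]:
    """Predicted outcome distribution per modality given factor posteriors.

    ``mode='linear'`` (default) is the push-forward ``o = A · s`` of the joint
    posterior through the likelihood; ``mode='expected_log'`` is the softmax
    of the expected log-likelihood (the literal expected-log reading).
    """
    q = _joint_from_factors(model, state_posterior)
    if q.shape[0] != model.n_joint:
        raise ValueError("state posterior does not match the model's factors")
    out = []
    for m in range(model.n_modalities):
        if mode == "linear":
            out.append(model.A_flat[m] @ q)
        elif mode == "expected_log":
            out.append(softmax(stable_log(model.A_flat[m]) @ q))
        else:
            raise ValueError(f"unknown prediction mode {mode!r}")
    return out


def ambiguity(model: LevelModel,
              state_posterior: Sequence[np.ndarray] | None = None):
    """Conditional outcome entropy ``H`` per joint state (summed over
    modalities) and, if a posterior is given, its expectation ``H·s``."""
    H = model.H
    if state_posterior is None:
        return H
    q = _joint_from_factors(model, state_posterior)
    return H, float(H @ q)


def expected_free_energy(model: LevelModel, beliefs: BeliefTrajectory,
                         policy: int, mode: str = "linear") -> float:
    """Expected free energy of a policy, accumulated over its horizon.

    ``G = sum_tau sum_m [ o·(ln o − C) ] + H·s`` with ``C`` stored as a
    log-preference (higher = preferred), so preferred outcomes lower ``G``.
    """
    q = beliefs.joint[policy]
    G = 0.0
    for t in range(q.shape[0]):
        for m in range(model.n_modalities):
            if mode == "linear":
                o = model.A_flat[m] @ q[t]
            elif mode == "expected_log":
                o = softmax(stable_log(model.A_flat[m]) @ q[t])
            else:
                raise ValueError(f"unknown prediction mode {mode!r}")
            G += float(o @ (stable_log(o) - model.C[m]))
        G += float(model.H @ q[t])
    return G


def efe_decomposition(model: LevelModel, beliefs: BeliefTrajectory,
                      policy: int) -> tuple[np.ndarray, np.ndarray]:
    """Risk/mutual-information decomposition of the expected free energy.

    Returns per-time-step arrays ``(preference_term, mutual_information)``
    such that ``sum(preference_term) - sum(mutual_information)`` equals
    :func:`expected_free_energy` (linear mode): the preference term is
    ``-o·C`` (dispreferred outcomes raise it) and the mutual information is
    ``D_KL[Q(o|pi)Q(s|pi) || Q(o,s|pi)]`` summed over modalities.
    """
    q = beliefs.joint[policy]
    T = q.shape[0]
    pref = np.zeros(T)
    mi = np.zeros(T)
    for t in range(T):
        qs = q[t]
        for m in range(model.n_modalities):
            A = model.A_flat[m]
            o = A @ qs
            pref[t] += float(-(o @ model.C[m]))
            joint = A * qs[None, :]          # Q(o, s)
            prod = o[:, None] * qs[None, :]  # Q(o) Q(s)
            mask = joint > 0
            mi[t] += float(np.sum(joint[mask] *
                                  (np.log(joint[mask]) - stable_log(prod[mask]))))
    return pref, mi


def policy_posterior(G: np.ndarray, E: np.ndarray,
                     F: np.ndarray | None = None,
                     include_F: bool = False) -> np.ndarray:
    """Policy posterior ``softmax(-(E + G))``; optionally adds accumulated
    evidence ``F`` (``softmax(-(E + G + F))``)."""
    G = np.asarray(G, float)
    E = np.asarray(E, float)
    if G.shape != E.shape:
        raise ValueError("G and E must have one entry per policy")
    pot = -(E + G)
    if include_F:
        if F is None or np.shape(F) != G.shape:
            raise ValueError("include_F requires F with one entry per policy")
        pot = pot - np.asarray(F, float)
    return softmax(pot)


def bayesian_model_average(pi: np.ndarray,
                           posteriors: Sequence[Sequence[np.ndarray]]) -> list[np.ndarray]:
    """Policy-averaged state posteriors ``s = sum_pi pi_p s_p`` per factor."""
    pi = np.asarray(pi, float)
    _check_prob(pi, "pi")
    if len(posteriors) != pi.shape[0]:
        raise ValueError("one posterior set per policy required")
    n_factors = len(posteriors[0])
    out = []
    for f in range(n_factors):
        acc = np.zeros_like(np.asarray(posteriors[0][f], float))
        for p, w in enumerate(pi):
            acc = acc + w * np.asarray(posteriors[p][f], float)
        out.append(acc / acc.sum(axis=-1, keepdims=True))
    return out


# ---------------------------------------------------------------------------
# deep (two-level) temporal inference
# ---------------------------------------------------------------------------

def _fast_init_likelihood(fast: LevelModel, observations: Sequence) -> np.ndarray:
    """``P(fast observations | fast initial joint state)`` by backward recursion."""
    n_steps = len(observations)
    if n_steps > fast.T:
        raise ValueError("more fast observations than the fast horizon")
    if fast.n_policies != 1:
        raise ValueError("deep inference assumes an uncontrolled fast level")
    L = np.ones(fast.n_joint)
    for t in range(n_steps - 1, 0, -1):
        lik = _likelihood_vector(fast, observations[t])
        B = fast.joint_B(fast.policy_actions(0, t - 1))
        L = B.T @ (lik * L)
    return _likelihood_vector(fast, observations[0] if n_steps else None) * L


def _descending_init_dists(slow: LevelModel, fast: LevelModel, link: LevelLink,
                           slow_outcomes: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Fast-level initial-state priors given predicted slow outcomes."""
    D = [d.copy() for d in fast.D]
    for m, f in link.modality_to_factor.items():
        D[f] = np.asarray(slow_outcomes[m], float)
    return D


def run_deep_inference(slow: LevelModel, fast: LevelModel, link: LevelLink,
                       observations: Sequence[Sequence],
                       include_evidence: bool = False,
                       g_horizon: int | None = None,
                       ) -> tuple[BeliefTrajectory, list[BeliefTrajectory]]:
    """Two-level belief updating over a sequence of fast episodes.

    ``observations[t]`` holds the fast-level observation tuples for slow step
    ``t`` (a list over fast time steps; entries/modalities may be ``None``).
    The descending pass turns predicted slow outcomes into fast initial-state
    priors; the ascending pass returns the fast level's evidence about those
    initial states, which updates the slow posterior exactly (the fast
    sequence is marginalised analytically).

    Returns the slow-level trajectory (with policy posterior, ``G`` and
    accumulated evidence ``F``) and one fast-level trajectory per slow step
    (computed under policy-averaged descending predictions).
    """
    link.validate(slow, fast)
    T = min(len(observations), slow.T)
    nP = slow.n_policies
    n_joint = slow.n_joint

    # prospective expected free energy per policy (prior predictive)
    horizon = slow.T if g_horizon is None else min(g_horizon, slow.T)
    G = np.zeros(nP)
    for p in range(nP):
        q = np.empty((horizon, n_joint))
        q[0] = slow.joint_D()
        for t in range(1, horizon):
            q[t] = slow.joint_B(slow.policy_actions(p, t - 1)) @ q[t - 1]
        traj = BeliefTrajectory(s=[[None]], joint=[q], pi=np.ones(1),
                                G=np.zeros(1), F=np.zeros(1))
        G[p] = expected_free_energy(slow, traj, 0)

    alphas = np.tile(slow.joint_D(), (nP, 1))
    F = np.zeros(nP)
    lik_history: list[np.ndarray] = []
    fast_trajs: list[BeliefTrajectory] = []
    slow_filtered = np.empty((nP, T, n_joint))

    def init_mixture(slow_outcomes: Sequence[np.ndarray]) -> np.ndarray:
        dists = _descending_init_dists(slow, fast, link, slow_outcomes)
        return reduce(np.kron, dists)

    for t in range(T):
        # descending predictions per policy
        preds = np.empty((nP, n_joint))
        for p in range(nP):
            if t == 0:
                preds[p] = alphas[p]
            else:
                preds[p] = slow.joint_B(slow.policy_actions(p, t - 1)) @ alphas[p]

        # per-slow-state fast evidence (exact marginal likelihood of the episode)
        L_init = _fast_init_likelihood(fast, observations[t])
        ell = np.empty(n_joint)
        for s_idx in range(n_joint):
            outs = [slow.A_flat[m][:, s_idx] for m in range(slow.n_modalities)]
            ell[s_idx] = init_mixture(outs) @ L_init

        # ascending update of slow beliefs (filtering) and policy evidence
        for p in range(nP):
            a = ell * preds[p]
            z = a.sum()
            if z <= 0:
                a = np.full(n_joint, 1.0 / n_joint)
                z = P_FLOOR
            F[p] -= np.log(max(z, P_FLOOR))
            alphas[p] = a / max(z, P_FLOOR)
            slow_filtered[p, t] = alphas[p]

        # fast-level posterior under policy-averaged descending priors
        pi_t = policy_posterior(G, slow.E, F=F, include_F=include_evidence)
        bma_pred = (pi_t[:, None] * preds).sum(axis=0)
        slow_out_bma = [slow.A_flat[m] @ bma_pred for m in range(slow.n_modalities)]
        fast_D = _descending_init_dists(slow, fast, link, slow_out_bma)
        fast_model = LevelModel(
            A=fast.A, B=fast.B, C=fast.C, D=fast_D, E=fast.E,
            policies=fast.policies, T=fast.T,
            factor_names=fast.factor_names, modality_names=fast.modality_names)
        fast_trajs.append(infer_states(fast_model, observations[t], record=False))
        lik_history.append(ell)

    # smoothing pass for the slow level per policy
    s_out: list[list[np.ndarray]] = []
    joints: list[np.ndarray] = []
    for p in range(nP):
        beta = np.ones((T, n_joint))
        for t in range(T - 2, -1, -1):
            B = slow.joint_B(slow.policy_actions(p, t))
            b = B.T @ (lik_history[t + 1] * beta[t + 1])
            m = b.max()
            beta[t] = b / (m if m > 0 else 1.0)
        # combine filtered forward with backward evidence
        q = np.empty((T, n_joint))
        q[T - 1] = slow_filtered[p, T - 1]
        for t in range(T - 1):
            raw = slow_filtered[p, t] * beta[t]
            q[t] = raw / raw.sum()
        joints.append(q)
        s_out.append([np.stack([slow.joint_to_factors(q[t])[f] for t in range(T)])
                      for f in range(slow.n_factors)])

    pi = policy_posterior(G, slow.E, F=F, include_F=include_evidence)
    slow_traj = BeliefTrajectory(s=s_out, joint=joints, pi=pi, G=G, F=F)
    return slow_traj, fast_trajs


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def model_to_dict(model: LevelModel) -> dict:
    return {
        "factor_names": list(model.factor_names),
        "modality_names": list(model.modality_names),
        "n_states": list(model.n_states),
        "n_outcomes": list(model.n_outcomes),
        "A": [a.tolist() for a in model.A],
        "B": [b.tolist() for b in model.B],
        "C": [c.tolist() for c in model.C],
        "D": [d.tolist() for d in model.D],
        "E": model.E.tolist(),
        "policies": model.policies.tolist(),
        "T": int(model.T),
    }


def model_from_dict(d: Mapping) -> LevelModel:
    return LevelModel(
        A=[np.asarray(a, float) for a in d["A"]],
        B=[np.asarray(b, float) for b in d["B"]],
        C=[np.asarray(c, float) for c in d["C"]],
        D=[np.asarray(x, float) for x in d["D"]],
        E=np.asarray(d["E"], float),
        policies=np.asarray(d["policies"], int),
        T=int(d["T"]),
        factor_names=tuple(d.get("factor_names", ())),
        modality_names=tuple(d.get("modality_names", ())),
    )


def save_model(model: LevelModel, path: str | Path) -> None:
    path = Path(path)
    payload = model_to_dict(model)
    if path.suffix in {".yml", ".yaml"}:
        import yaml

        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LevelModel:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yml", ".yaml"}:
        import yaml

        return model_from_dict(yaml.safe_load(text))
    return model_from_dict(json.loads(text))


def trajectory_to_tsv(model: LevelModel, traj: BeliefTrajectory,
                      path: str | Path, level: str = "level0") -> None:
    """Long-format TSV: level, factor, policy, time, state, probability."""
    rows = ["level\tfactor\tpolicy\ttime\tstate\tprobability"]
    for p in range(traj.n_policies):
        for f, name in enumerate(model.factor_names):
            arr = traj.s[p][f]
            for t in range(arr.shape[0]):
                for i in range(arr.shape[1]):
                    rows.append(f"{level}\t{name}\t{p}\t{t}\t{i}\t{arr[t, i]:.12g}")
    Path(path).write_text("\n".join(rows) + "\n")


def trajectory_to_hdf5(model: LevelModel, traj: BeliefTrajectory,
                       path: str | Path, level: str = "level0") -> None:
    import h5py

    with h5py.File(path, "a") as h5:
        grp = h5.require_group(level)
        grp.attrs["factors"] = ",".join(model.factor_names)
        for p in range(traj.n_policies):
            pg = grp.require_group(f"policy{p}")
            for f, name in enumerate(model.factor_names):
                if name in pg:
                    del pg[name]
                pg.create_dataset(name, data=traj.s[p][f])
        for name, val in (("pi", traj.pi), ("G", traj.G), ("F", traj.F)):
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=val)
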