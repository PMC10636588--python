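"""Cognitive effort as a divergence between policy beliefs.

Effort (``xi``) is the Kullback-Leibler divergence from the habit-only
policy prior ``P_E = Cat(softmax(-E))`` to the context-sensitive policy
belief ``P_G = Cat(softmax(-G - E))``:

    xi = D_KL[ P_G || P_E ]   (nats)

It vanishes when the expected free energy ``G`` is constant across policies
(no context to take into account) and grows when goal-directed evaluation
must overcome a habit.  The module also computes the demand-by-preference
effort surface for a single binary decision in which the habitually
favoured policy is the one that does *not* fulfil preferences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import softmax

__all__ = ["EffortReport", "cognitive_effort", "effort_surface",
           "session_effort", "kl_divergence"]


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """``D_KL[p || q]`` for categorical distributions, in nats."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


@dataclass
class EffortReport:
    """Effort of one decision and the quantities it was computed from."""

    xi: float
    G: np.ndarray
    E: np.ndarray
    P_G: np.ndarray
    P_E: np.ndarray


def cognitive_effort(G: Sequence[float] | np.ndarray,
                     E: Sequence[float] | np.ndarray) -> EffortReport:
    """Effort of a single decision given expected free energies and habits."""
    G = np.asarray(G, float)
    E = np.asarray(E, float)
    if G.shape != E.shape or G.ndim != 1:
        raise ValueError("G and E must be vectors with one entry per policy")
    P_E = softmax(-E)
    P_G = softmax(-(G + E))
    xi = kl_divergence(P_G, P_E)
    return EffortReport(xi=max(xi, 0.0), G=G, E=E, P_G=P_G, P_E=P_E)


def effort_surface(demand_grid: Sequence[float],
                   preference_grid: Sequence[float],
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Effort and success probability over demand and preference strength.

    A binary decision: cognitive demand ``d`` is the prior probability of
    the policy that does not fulfil preferences (the habit), so
    ``P_E = (d, 1 - d)`` with the preferred policy second; preference
    strength ``psi`` separates the expected free energies by ``2 * psi``
    in favour of the preferred policy.

    Returns ``(xi, success)`` matrices of shape
    ``(len(demand_grid), len(preference_grid))`` where ``success`` is the
    probability ``P_G`` of the preferred policy.
    """
    d = np.asarray(demand_grid, float)
    psi = np.asarray(preference_grid, float)
    if np.any(~np.isfinite(d)) or np.any(~np.isfinite(psi)):
        raise ValueError("grids must be finite")
    if np.any((d <= 0) | (d >= 1)):
        raise ValueError("demand must lie strictly inside (0, 1)")
    if np.any(psi < 0):
        raise ValueError("preference strength must be non-negative")
    xi = np.empty((d.size, psi.size))
    success = np.empty_like(xi)
    for i, dd in enumerate(d):
        E = -np.log([dd, 1.0 - dd])
        for j, pp in enumerate(psi):
            G = np.array([pp, -pp])
            rep = cognitive_effort(G, E)
            xi[i, j] = rep.xi
            success[i, j] = rep.P_G[1]
    return xi, success


def session_effort(G_list: Sequence[np.ndarray],
                   E: np.ndarray) -> tuple[list[EffortReport], float]:
    """Per-decision effort for a session plus its mean.

    ``G_list`` holds the expected-free-energy vector of each decision epoch;
    ``E`` is the session's habit potential.
    """
    if len(G_list) == 0:
        raise ValueError("session contains no decisions")
    reports = [cognitive_effort(G, E) for G in G_list]
    mean_xi = float(np.mean([r.xi for r in reports]))
    return reports, mean_xi


def surface_to_csv(demand_grid: Sequence[float], preference_grid: Sequence[float],
                   matrix: np.ndarray, path: str | Path) -> None:
    """CSV matrix with header row/column giving the grid values."""
    lines = ["demand\\preference," + ",".join(f"{p:g}" for p in preference_grid)]
    for d, row in zip(demand_grid, matrix):
        lines.append(f"{d:g}," + ",".join(f"{x:.10g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
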