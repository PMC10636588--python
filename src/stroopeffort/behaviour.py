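"""Overt behaviour: response sampling, reaction times and session execution.

Responses are sampled from a softmax of the log predicted verbal outcome,

    u = softmax( lambda * ln(A) s ),    o ~ Cat(u),

where ``s`` is the Bayesian model average of policy-conditioned state
predictions and ``lambda`` (default 1/4) is an action precision: small
``lambda`` makes responding more random.  Reaction times are a lognormal
function of the entropy of the predicted response,

    r = 1/2 * exp( n + H[u] ),    n ~ N(0, 1/256),

so confident predictions are answered quickly (H = 0 gives r = 0.5 time
units) and uncertain ones slowly.

Session execution couples the slow (mental-policy) and fast (stimulus)
levels of the Stroop model.  The Stroop likelihoods are deterministic, so
the deep belief updates have closed form and the simulator evaluates them
directly: the instruction cue pins the slow instruction belief, each
stimulus is identified at the viewing step, and the policy posterior is

    pi_t = softmax( -E - G_t - F_t ),

with ``G_t`` the one-presentation-ahead expected free energy (the risk of
being incorrect under each mental action) and ``F_t`` a *leaky* accumulator
of response evidence: each observed response is scored under each policy
with the same precision-``lambda`` likelihood that generated it, and the
accumulator retains a fraction ``evidence_decay`` of its value from one
presentation to the next.  The leak is what lets beliefs relax toward the
habit across uninformative (congruent) stretches, producing the congruency
sequence effect.  Per-decision effort is computed from ``(G_t, E)`` alone,
per its definition, and is therefore identical for congruent and
incongruent decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import effort as effort_mod
from .engine import P_FLOOR, softmax, stable_log
from .stroop import (COLOURS, CONDITIONS, StimulusSequence, StroopParams,
                     generate_stimuli, HABIT_SPACING, PREFERENCE_SPACING)

__all__ = [
    "SessionRecord",
    "SessionTrace",
    "action_distribution",
    "sample_response",
    "reaction_time",
    "predicted_entropy",
    "run_session",
    "summarize_sessions",
]

RT_NOISE_SD = 1.0 / 16.0  # Eq: n ~ N(0, 1/256)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def action_distribution(predicted_state: Sequence[np.ndarray],
                        A_response: np.ndarray, lam: float,
                        null_outcome: int | None = -1) -> np.ndarray:
    """Predicted-response distribution ``softmax(lambda * ln(A) s)``.

    ``predicted_state`` holds one posterior per hidden-state factor (their
    Kronecker product is the joint), ``A_response`` the response likelihood
    with outcomes on the first axis.  The ``null_outcome`` row (default: the
    last) is excluded, as no-response is not an available overt action at a
    response step.  ``lam = 0`` yields uniform responding; negative values
    are rejected.
    """
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("action precision lambda must be non-negative")
    A = np.asarray(A_response, float)
    A_flat = A.reshape(A.shape[0], -1)
    joint = reduce(np.kron, [np.asarray(s, float) for s in predicted_state])
    if joint.shape[0] != A_flat.shape[1]:
        raise ValueError("state posterior does not match the likelihood array")
    a = A_flat @ joint
    if null_outcome is not None:
        keep = np.ones(a.shape[0], bool)
        keep[null_outcome] = False
        a = a[keep]
    return softmax(lam * stable_log(a))


def sample_response(u: np.ndarray, rng: np.random.Generator) -> int:
    """Categorical draw from the predicted-response distribution."""
    u = np.asarray(u, float)
    if abs(u.sum() - 1.0) > 1e-6 or np.any(u < 0):
        raise ValueError("u must be a probability vector")
    return int(rng.choice(u.shape[0], p=u / u.sum()))


def predicted_entropy(u: np.ndarray) -> float:
    """Entropy ``H[u] = -u . ln u`` of the predicted response, in nats."""
    u = np.asarray(u, float)
    mask = u > 0
    return float(-np.sum(u[mask] * np.log(u[mask])))


def reaction_time(u: np.ndarray, rng: np.random.Generator) -> float:
    """Sample a reaction time ``r = 1/2 exp(n + H[u])``, ``n ~ N(0, 1/256)``."""
    n = rng.normal(0.0, RT_NOISE_SD)
    return float(0.5 * np.exp(n + predicted_entropy(u)))


# ---------------------------------------------------------------------------
# session dynamics
# ---------------------------------------------------------------------------

class StroopDynamics:
    """Closed-form deep belief updating for one Stroop session.

    Exposes the per-presentation quantities (policy posterior, predicted
    response distribution, effort) both for forward simulation and for
    likelihood replay with forced responses (used by phenotyping).
    """

    def __init__(self, params: StroopParams):
        self.params = params
        self.E = np.exp(params.e) * np.array([-HABIT_SPACING, HABIT_SPACING])
        self.C = np.exp(params.c) * np.array([PREFERENCE_SPACING,
                                              -PREFERENCE_SPACING])
        self.lam = params.lam
        self.decay = params.evidence_decay
        self.b_instr = np.full(2, 0.5)   # belief that instruction = word / colour
        self.F = np.zeros(2)             # leaky policy-evidence accumulator

    # -- slow level -------------------------------------------------------
    def observe_instruction(self, condition: str) -> None:
        """The instruction cue pins the slow-level instruction belief."""
        idx = CONDITIONS.index(condition)
        self.b_instr = np.eye(2)[idx]

    def expected_free_energy(self) -> np.ndarray:
        """EFE per policy over the next ``planning_horizon`` presentations.

        Each mental policy holds the response modality fixed, so every
        planned presentation contributes the same correctness risk; the
        risk of one presentation is accumulated over the planning depth.
        """
        G = np.empty(2)
        for p in range(2):
            p_correct = float(self.b_instr[p])  # policy p holds modality p
            o = np.array([p_correct, 1.0 - p_correct])
            G[p] = float(o @ (stable_log(o) - self.C))
        return self.params.planning_horizon * G

    def policy_posterior(self, G: np.ndarray) -> np.ndarray:
        return softmax(-(self.E + G + self.F))

    # -- fast level -------------------------------------------------------
    def response_distribution(self, pi: np.ndarray, word_idx: int,
                              colour_idx: int) -> np.ndarray:
        """``softmax(lambda ln(A s))`` with the BMA predicted state."""
        a = np.full(len(COLOURS), P_FLOOR)
        a[word_idx] += pi[0]
        a[colour_idx] += pi[1]
        return softmax(self.lam * np.log(a))

    def policy_likelihoods(self, word_idx: int, colour_idx: int) -> np.ndarray:
        """Per-policy response likelihood ``u_p`` (rows: policy)."""
        out = np.empty((2, len(COLOURS)))
        for p, idx in enumerate((word_idx, colour_idx)):
            a = np.full(len(COLOURS), P_FLOOR)
            a[idx] += 1.0
            out[p] = softmax(self.lam * np.log(a))
        return out

    # -- one presentation -------------------------------------------------
    def decision(self, word_idx: int, colour_idx: int) -> dict:
        """Advance to a new stimulus presentation and form the decision."""
        self.F = self.decay * self.F
        G = self.expected_free_energy()
        pi = self.policy_posterior(G)
        u = self.response_distribution(pi, word_idx, colour_idx)
        xi = effort_mod.cognitive_effort(G, self.E).xi
        return {"G": G, "pi": pi, "u": u, "xi": xi}

    def assimilate(self, word_idx: int, colour_idx: int,
                   response_idx: int) -> np.ndarray:
        """Score the observed response under each policy; update evidence."""
        u_p = self.policy_likelihoods(word_idx, colour_idx)
        self.F = self.F - np.log(np.maximum(u_p[:, response_idx], P_FLOOR))
        return softmax(-(self.E + self.expected_free_energy() + self.F))


# ---------------------------------------------------------------------------
# belief traces for synthetic electrophysiology
# ---------------------------------------------------------------------------

UNIT_GROUPS: tuple[tuple[str, str, int], ...] = (
    ("fast", "word", 4), ("fast", "colour", 4), ("fast", "task_sequence", 3),
    ("fast", "instruction", 2), ("fast", "modality", 2),
    ("fast", "correctness", 2),
    ("slow", "narrative", 2), ("slow", "instruction", 2),
    ("slow", "modality", 2), ("slow", "policy", 2),
)

ITERS_PER_EPOCH = 16
FLOW_STEP = 0.25


@dataclass
class SessionTrace:
    """Iteration-resolved beliefs of every represented population.

    ``probs`` is ``(n_units, n_bins)``; each observation epoch contributes
    :data:`ITERS_PER_EPOCH` bins of the free-energy gradient flow.
    ``unit_labels`` maps rows to ``(level, factor, state)``;
    ``presentation_of_bin`` and ``epoch_of_bin`` index bins back onto the
    session, and ``trial_windows`` holds ``(start, stop)`` bin ranges per
    stimulus presentation.
    """

    probs: np.ndarray
    unit_labels: list[tuple[str, str, int]]
    presentation_of_bin: np.ndarray
    epoch_of_bin: np.ndarray
    trial_windows: list[tuple[int, int]]

    def unit_index(self, level: str, factor: str) -> np.ndarray:
        return np.array([i for i, (lv, f, _) in enumerate(self.unit_labels)
                         if lv == level and f == factor])


class _TraceRecorder:
    def __init__(self) -> None:
        self.labels: list[tuple[str, str, int]] = []
        for level, factor, n in UNIT_GROUPS:
            self.labels += [(level, factor, i) for i in range(n)]
        self.n_units = len(self.labels)
        self._slices: dict[tuple[str, str], slice] = {}
        off = 0
        for level, factor, n in UNIT_GROUPS:
            self._slices[(level, factor)] = slice(off, off + n)
            off += n
        self.v = np.zeros(self.n_units)  # uniform within each group
        self.bins: list[np.ndarray] = []
        self.pres: list[int] = []
        self.epoch: list[int] = []

    def _targets_to_v(self, targets: dict[tuple[str, str], np.ndarray]) -> np.ndarray:
        t = np.empty(self.n_units)
        for key, sl in self._slices.items():
            t[sl] = stable_log(targets[key])
        return t

    def epoch_flow(self, targets: dict, presentation: int, epoch: int) -> None:
        tv = self._targets_to_v(targets)
        for _ in range(ITERS_PER_EPOCH):
            self.v = self.v + FLOW_STEP * (tv - self.v)
            probs = np.empty(self.n_units)
            for sl in self._slices.values():
                probs[sl] = softmax(self.v[sl])
            self.bins.append(probs)
            self.pres.append(presentation)
            self.epoch.append(epoch)

    def finish(self, trial_windows: list[tuple[int, int]]) -> SessionTrace:
        return SessionTrace(
            probs=np.stack(self.bins, axis=1),
            unit_labels=self.labels,
            presentation_of_bin=np.asarray(self.pres),
            epoch_of_bin=np.asarray(self.epoch),
            trial_windows=trial_windows,
        )


# ---------------------------------------------------------------------------
# session execution
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    """One simulated session: behaviour table plus model quantities.

    ``data`` has one row per presentation (columns: presentation, phase,
    word, colour, congruent, condition, response, correct, rt, entropy, xi);
    ``G`` stacks the per-decision expected-free-energy vectors and ``E`` is
    the session's habit potential, so effort can be recomputed.
    """

    data: pd.DataFrame
    params: StroopParams
    stimuli: StimulusSequence
    G: np.ndarray
    E: np.ndarray
    trace: SessionTrace | None = None

    @property
    def condition(self) -> str:
        return self.params.condition

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def table_from_tsv(cls, path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")


def run_session(params: StroopParams,
                stimuli: StimulusSequence | None = None,
                rng: np.random.Generator | None = None,
                record_trace: bool = True) -> SessionRecord:
    """Simulate one full session.

    One seed stream drives stimulus generation and an independent derived
    stream drives response/reaction-time sampling, so the same stimuli can
    be replayed across parameter settings.  Sampled responses are fed back
    as observations, which is what makes behaviour history-dependent.
    Correctness is scored against the generating process's instruction.
    """
    ss = np.random.SeedSequence(params.seed)
    stim_rng, act_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    if stimuli is None:
        stimuli = generate_stimuli(params, stim_rng)
    if rng is not None:
        act_rng = rng
    if stimuli.condition != params.condition:
        raise ValueError("stimulus sequence condition does not match params")
    if stimuli.n_presentations != params.n_presentations:
        raise ValueError("stimulus sequence length does not match params")

    dyn = StroopDynamics(params)
    rec = _TraceRecorder() if record_trace else None
    cond_idx = CONDITIONS.index(params.condition)

    rows = []
    G_list = []
    windows: list[tuple[int, int]] = []

    # presentation 0: the instruction
    pi0 = dyn.policy_posterior(dyn.expected_free_energy())
    dyn.observe_instruction(params.condition)
    if rec is not None:
        rec.epoch_flow(_targets(dyn, pi0, None, None), presentation=0, epoch=0)
    rows.append({"presentation": 0, "phase": "instruction", "word": "none",
                 "colour": "none", "congruent": "", "condition": params.condition,
                 "response": "none", "correct": "", "rt": np.nan,
                 "entropy": np.nan, "xi": np.nan})

    for i, (w, k, cong) in enumerate(zip(stimuli.words, stimuli.colours,
                                         stimuli.congruent), start=1):
        wi, ki = COLOURS.index(w), COLOURS.index(k)
        dec = dyn.decision(wi, ki)
        start_bin = len(rec.bins) if rec is not None else 0
        if rec is not None:  # viewing epoch
            rec.epoch_flow(_targets(dyn, dec["pi"], wi, ki), presentation=i, epoch=0)
        u = dec["u"]
        resp = sample_response(u, act_rng)
        rt = reaction_time(u, act_rng)
        pi_post = dyn.assimilate(wi, ki, resp)
        if rec is not None:  # response epoch
            rec.epoch_flow(_targets(dyn, pi_post, wi, ki, responded=True),
                           presentation=i, epoch=1)
            windows.append((start_bin, len(rec.bins)))
        truth = wi if cond_idx == 0 else ki
        rows.append({"presentation": i, "phase": "stimulus", "word": w,
                     "colour": k, "congruent": bool(cong),
                     "condition": params.condition,
                     "response": COLOURS[resp], "correct": bool(resp == truth),
                     "rt": rt, "entropy": predicted_entropy(u),
                     "xi": dec["xi"]})
        G_list.append(dec["G"])

    trace = rec.finish(windows) if rec is not None else None
    return SessionRecord(data=pd.DataFrame(rows), params=params,
                         stimuli=stimuli, G=np.stack(G_list), E=dyn.E.copy(),
                         trace=trace)


def _targets(dyn: StroopDynamics, pi: np.ndarray, word_idx: int | None,
             colour_idx: int | None, responded: bool = False) -> dict:
    """Fixed points of the belief flow for every recorded population."""
    uniform4 = np.full(4, 0.25)
    onehot = np.eye(4)
    in_instruction = word_idx is None
    b = dyn.b_instr
    p_correct = float(pi @ b)
    task = np.zeros(3)
    task[0 if in_instruction else (2 if responded else 1)] = 1.0
    return {
        ("fast", "word"): uniform4 if in_instruction else onehot[word_idx],
        ("fast", "colour"): uniform4 if in_instruction else onehot[colour_idx],
        ("fast", "task_sequence"): task,
        ("fast", "instruction"): b,
        ("fast", "modality"): pi,
        ("fast", "correctness"): np.array([p_correct, 1 - p_correct]),
        ("slow", "narrative"): np.array([1.0, 0.0]) if in_instruction
        else np.array([0.0, 1.0]),
        ("slow", "instruction"): b,
        ("slow", "modality"): pi,
        ("slow", "policy"): pi,
    }


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_sessions(records: Sequence[SessionRecord]) -> pd.DataFrame:
    """Condition x congruency table of accuracy and reaction-time statistics.

    Cells with no observations are reported as missing (NaN), not zero.
    """
    if len(records) == 0:
        raise ValueError("no sessions to summarise")
    df = pd.concat([r.data for r in records], ignore_index=True)
    df = df[df["phase"] == "stimulus"].copy()
    df["correct"] = df["correct"].astype(bool)
    df["congruent"] = df["congruent"].astype(bool)

    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "n": len(g),
            "percent_correct": 100.0 * g["correct"].mean(),
            "mean_rt": g["rt"].mean(),
            "median_rt": g["rt"].median(),
            "rt_q10": g["rt"].quantile(0.10),
            "rt_q90": g["rt"].quantile(0.90),
        })

    table = (df.groupby(["condition", "congruent"])
               .apply(agg, include_groups=False))
    idx = pd.MultiIndex.from_product(
        [sorted(df["condition"].unique()), [False, True]],
        names=["condition", "congruent"])
    return table.reindex(idx)
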