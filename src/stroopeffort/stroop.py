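"""Two-level generative model of the Stroop task.

The task: a participant sees colour words (red, green, blue, yellow) printed
in coloured fonts and must either read the word or name the font colour,
depending on an instruction given at the start of the session.  The model
separates a *slow* level — the narrative of the session, the instruction in
force and the covert choice of response modality (the only thing the agent
controls, a "mental action") — from a *fast* level that unfolds within each
stimulus presentation (viewing then responding).

Two log-scaled parameters shape behaviour:

* ``e`` (cognitive demand) scales the habit potential over the two mental
  policies, ``E = exp(e) * (-0.85, +0.85)``, so at ``e = 0`` the habitual
  prior expects word-reading 85% of the time;
* ``c`` (motivation) scales the preference for being correct,
  ``C = exp(c) * (+1, -1)`` over the correctness channel, so at ``c = 0``
  being correct is ``e^2`` (~7.4) times more probable a priori than being
  incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import LevelLink, LevelModel

__all__ = [
    "COLOURS",
    "CONDITIONS",
    "StroopParams",
    "StimulusSequence",
    "build_fast_level",
    "build_slow_level",
    "link_levels",
    "generate_stimuli",
]

COLOURS: tuple[str, ...] = ("red", "green", "blue", "yellow")
CONDITIONS: tuple[str, ...] = ("word-reading", "colour-naming")

# fast-level factor order (declaration order fixes joint flattening)
FAST_FACTORS = ("word", "colour", "task_sequence", "instruction",
                "modality", "correctness")
FAST_MODALITIES = ("instruction_cue", "word_text", "font_colour",
                   "verbal_response")
SLOW_FACTORS = ("narrative", "instruction", "modality")
SLOW_MODALITIES = ("task_sequence_init", "instruction_init",
                   "modality_init", "correctness")

#: habit-potential spacing at e = 0 (habitual prior ~ 85/15)
HABIT_SPACING = 0.85
#: log-preference spacing at c = 0 (correct:incorrect prior ratio e^2)
PREFERENCE_SPACING = 1.0


@dataclass(frozen=True)
class StroopParams:
    """Configuration of one simulated Stroop session.

    Parameters
    ----------
    c, e : float
        Log-scaled motivation (preference strength) and cognitive demand
        (habit strength).
    lam : float
        Action precision (inverse temperature) of overt response sampling.
    n_presentations : int
        Presentations including the initial instruction (64 -> 63 stimuli).
    congruency : float or sequence of bool
        Probability that a stimulus is congruent, or an explicit per-stimulus
        schedule of length ``n_presentations - 1``.
    condition : str
        ``"word-reading"`` or ``"colour-naming"``.
    evidence_decay : float
        Retention factor of the leaky policy-evidence accumulator
        (0 = no memory of previous responses, 1 = perfect accumulation).
    planning_horizon : int
        Number of upcoming presentations over which the expected free
        energy of each mental policy is accumulated when the decision is
        formed (a receding planning depth).
    seed : int
        Seed of the session's random streams.
    """

    c: float = 0.0
    e: float = 0.0
    lam: float = 0.25
    n_presentations: int = 64
    congruency: float | tuple[bool, ...] = 0.5
    condition: str = "colour-naming"
    evidence_decay: float = 0.5
    planning_horizon: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presentations < 2:
            raise ValueError("need at least an instruction and one stimulus")
        if not self.lam > 0:
            raise ValueError("action precision lambda must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not 0.0 <= self.evidence_decay <= 1.0:
            raise ValueError("evidence_decay must lie in [0, 1]")
        if self.planning_horizon < 1:
            raise ValueError("planning_horizon must be a positive integer")
        if isinstance(self.congruency, (tuple, list)):
            if len(self.congruency) != self.n_presentations - 1:
                raise ValueError("explicit congruency schedule must cover "
                                 "every stimulus presentation")
            object.__setattr__(self, "congruency", tuple(bool(x) for x in self.congruency))
        else:
            p = float(self.congruency)
            if not 0.0 <= p <= 1.0:
                raise ValueError("congruency probability must lie in [0, 1]")


@dataclass
class StimulusSequence:
    """A session's stimulus stream: one instruction then word/colour stimuli."""

    condition: str
    words: tuple[str, ...]
    colours: tuple[str, ...]
    congruent: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        n = len(self.words)
        if len(self.colours) != n or len(self.congruent) != n:
            raise ValueError("words, colours and congruency must align")
        for w, col, cong in zip(self.words, self.colours, self.congruent):
            if w not in COLOURS or col not in COLOURS:
                raise ValueError("unknown colour word")
            if cong != (w == col):
                raise ValueError("congruency flag inconsistent with stimulus")

    @property
    def n_presentations(self) -> int:
        """Stimuli plus the initial instruction."""
        return len(self.words) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [{"presentation": 0, "phase": "instruction", "word": "none",
                 "colour": "none", "congruent": "", "condition": self.condition}]
        for i, (w, col, cong) in enumerate(zip(self.words, self.colours,
                                               self.congruent), start=1):
            rows.append({"presentation": i, "phase": "stimulus", "word": w,
                         "colour": col, "congruent": bool(cong),
                         "condition": self.condition})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StimulusSequence":
        df = pd.read_csv(path, sep="\t")
        stim = df[df["phase"] == "stimulus"]
        return cls(condition=str(df["condition"].iloc[0]),
                   words=tuple(stim["word"]),
                   colours=tuple(stim["colour"]),
                   congruent=tuple(s in (True, "True") for s in stim["congruent"]))


def generate_stimuli(params: StroopParams,
                     rng: np.random.Generator) -> StimulusSequence:
    """Draw a stimulus sequence honouring the congruency schedule.

    Word identities are uniform over the four colours; on congruent trials
    the font colour equals the word, otherwise it is uniform over the
    remaining three colours.
    """
    n_stim = params.n_presentations - 1
    if isinstance(params.congruency, tuple):
        flags = list(params.congruency)
    else:
        flags = list(rng.random(n_stim) < params.congruency)
    if len(COLOURS) < 2 and any(not f for f in flags):
        raise ValueError("incongruent stimuli impossible with fewer than 2 colours")
    words, colours = [], []
    for cong in flags:
        w = COLOURS[rng.integers(len(COLOURS))]
        if cong:
            col = w
        else:
            others = [x for x in COLOURS if x != w]
            col = others[rng.integers(len(others))]
        words.append(w)
        colours.append(col)
    return StimulusSequence(condition=params.condition, words=tuple(words),
                            colours=tuple(colours),
                            congruent=tuple(bool(f) for f in flags))


# ---------------------------------------------------------------------------
# fast level
# ---------------------------------------------------------------------------

def build_fast_level(params: StroopParams) -> LevelModel:
    """Within-presentation model: viewing and responding to one stimulus.

    Factors: written word (4), font colour (4), task sequence
    (instruction / viewing / response), instruction (2), response modality
    (2) and correctness (2).  Outcome modalities carry an explicit ``null``
    level for phases in which they are not generated.  The correctness
    factor influences no outcome; it is inferred from empirical priors only.
    """
    nW, nC = len(COLOURS), len(COLOURS)
    nT, nI, nM, nK = 3, 2, 2, 2  # task-sequence, instruction, modality, correct
    shape = (nW, nC, nT, nI, nM, nK)

    def blank(n_out: int) -> np.ndarray:
        return np.zeros((n_out,) + shape)

    # instruction cue: word/colour instruction + null; emitted only during
    # the instruction phase
    A_cue = blank(nI + 1)
    for i in range(nI):
        A_cue[i, :, :, 0, i, :, :] = 1.0
    A_cue[nI, :, :, 1:, :, :, :] = 1.0

    # word text and font colour: shown during viewing and response
    A_word = blank(nW + 1)
    for w in range(nW):
        A_word[w, w, :, 1:, :, :, :] = 1.0
    A_word[nW, :, :, 0, :, :, :] = 1.0

    A_col = blank(nC + 1)
    for c in range(nC):
        A_col[c, :, c, 1:, :, :, :] = 1.0
    A_col[nC, :, :, 0, :, :, :] = 1.0

    # verbal response: only in the response phase; reports the written word
    # when modality = word, the font colour when modality = colour
    A_resp = blank(nW + 1)
    for w in range(nW):
        A_resp[w, w, :, 2, :, 0, :] = 1.0   # modality 0 = word
    for c in range(nC):
        A_resp[c, :, c, 2, :, 1, :] = 1.0   # modality 1 = colour
    A_resp[nW, :, :, :2, :, :, :] = 1.0

    def identity_B(n: int) -> np.ndarray:
        return np.eye(n)[None, :, :]

    B_task = np.zeros((1, nT, nT))
    B_task[0, 0, 0] = 1.0  # instruction -> instruction
    B_task[0, 2, 1] = 1.0  # viewing -> response
    B_task[0, 2, 2] = 1.0  # response absorbs

    B = [identity_B(nW), identity_B(nC), B_task, identity_B(nI),
         identity_B(nM), identity_B(nK)]
    A = [A_cue, A_word, A_col, A_resp]
    C = [np.zeros(a.shape[0]) for a in A]
    D = [np.full(nW, 1 / nW), np.full(nC, 1 / nC),
         np.array([0.0, 1.0, 0.0]), np.full(nI, 1 / nI),
         np.full(nM, 1 / nM), np.full(nK, 1 / nK)]
    policies = np.zeros((1, 1, len(B)), dtype=int)
    return LevelModel(A=A, B=B, C=C, D=D, E=np.zeros(1), policies=policies,
                      T=2, factor_names=FAST_FACTORS,
                      modality_names=FAST_MODALITIES)


# ---------------------------------------------------------------------------
# slow level
# ---------------------------------------------------------------------------

def build_slow_level(params: StroopParams) -> LevelModel:
    """Across-presentation model: narrative, instruction and mental policy.

    The response modality is the only policy-dependent factor; the two
    policies hold it at "word" or at "colour" for the session.  Habit
    potentials and correctness preferences are scaled by ``exp(e)`` and
    ``exp(c)`` respectively.
    """
    nN, nI, nM = 2, 2, 2
    shape = (nN, nI, nM)

    def blank(n_out: int) -> np.ndarray:
        return np.zeros((n_out,) + shape)

    # predicted initial task-sequence of the fast level: instruction phase
    # in the instructional context, viewing phase in the response context
    A_task = blank(3)
    A_task[0, 0, :, :] = 1.0
    A_task[1, 1, :, :] = 1.0

    A_instr = blank(nI)
    for i in range(nI):
        A_instr[i, :, i, :] = 1.0

    A_mod = blank(nM)
    for m in range(nM):
        A_mod[m, :, :, m] = 1.0

    # correctness: correct when instruction and modality agree
    A_corr = blank(2)
    for i in range(nI):
        for m in range(nM):
            A_corr[0 if i == m else 1, :, i, m] = 1.0

    B_narr = np.zeros((1, nN, nN))
    B_narr[0, 1, 0] = 1.0  # instructional context -> response context
    B_narr[0, 1, 1] = 1.0
    B_instr = np.eye(nI)[None]
    # modality is controlled: action 0 sets word, action 1 sets colour
    B_mod = np.zeros((2, nM, nM))
    B_mod[0, 0, :] = 1.0
    B_mod[1, 1, :] = 1.0

    A = [A_task, A_instr, A_mod, A_corr]
    C = [np.zeros(3), np.zeros(nI), np.zeros(nM),
         np.exp(params.c) * np.array([PREFERENCE_SPACING, -PREFERENCE_SPACING])]
    D = [np.array([1.0, 0.0]), np.full(nI, 1 / nI), np.full(nM, 1 / nM)]
    T = params.n_presentations
    # two constant mental actions over the session
    policies = np.zeros((2, T, 3), dtype=int)
    policies[1, :, 2] = 1
    policies[0, :, 2] = 0
    E = np.exp(params.e) * np.array([-HABIT_SPACING, HABIT_SPACING])
    return LevelModel(A=A, B=[B_narr, B_instr, B_mod], C=C, D=D, E=E,
                      policies=policies, T=T, factor_names=SLOW_FACTORS,
                      modality_names=SLOW_MODALITIES)


def link_levels(slow: LevelModel, fast: LevelModel) -> LevelLink:
    """Map slow outcomes onto fast initial states.

    The slow level's predicted task-sequence, instruction, modality and
    correctness outcomes become the corresponding fast factors' initial
    states; the correctness channel is the only preference-bearing one.
    """
    if tuple(slow.factor_names) != SLOW_FACTORS or \
            tuple(fast.factor_names) != FAST_FACTORS:
        raise ValueError("link_levels expects models built by this module")
    link = LevelLink(modality_to_factor={
        SLOW_MODALITIES.index("task_sequence_init"): FAST_FACTORS.index("task_sequence"),
        SLOW_MODALITIES.index("instruction_init"): FAST_FACTORS.index("instruction"),
        SLOW_MODALITIES.index("modality_init"): FAST_FACTORS.index("modality"),
        SLOW_MODALITIES.index("correctness"): FAST_FACTORS.index("correctness"),
    })
    link.validate(slow, fast)
    return link


def habitual_prior(e: float) -> np.ndarray:
    """Habitual policy prior softmax(-E) as a function of demand ``e``."""
    E = np.exp(e) * np.array([-HABIT_SPACING, HABIT_SPACING])
    x = np.exp(-E - (-E).max())
    return x / x.sum()


def preference_ratio(c: float) -> float:
    """Prior correct:incorrect probability ratio as a function of ``c``."""
    return float(np.exp(2 * PREFERENCE_SPACING * np.exp(c)))
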