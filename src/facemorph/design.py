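"""Trial schedules and the generative observer model.

Two experimental designs are supported:

* Experiment 1 (masking): whole face, upper half or lower half visible.
  Each participant sees every (condition x identity x morph) cell once per
  run; two runs give 40 trials per morph x condition cell.
* Experiment 2 (composite faces): a morphed target half is combined with a
  full-blown (100%) fearful or angry distractor half.  Trials are blocked
  by judged half; within a block every (identity x morph x distractor
  emotion) combination occurs ``n_runs`` times.

Responses are simulated from a guess/lapse-contaminated logistic observer
whose category boundary is perturbed per face identity and per participant,
with an optional featural-interference mixture that pulls composite-face
responses toward the distractor expression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Morph fractions of the default stimulus continuum: the two originals plus
#: nine equal interpolation steps, 0 = 100% fear, 1 = 100% anger.
DEFAULT_GRID_LEVELS = 11

EXP1_CONDITIONS = ("whole", "upper", "lower")
#: Experiment 2 condition labels are ``<judged half>_<distractor emotion>``:
#: ``upper_anger`` means the participant judges the upper half while the
#: lower half shows full-blown anger.
EXP2_CONDITIONS = ("upper_anger", "upper_fear", "lower_anger", "lower_fear")

DISTRACTOR_NONE = "none"


class ConfigError(ValueError):
    """An observer/world configuration violates its invariants."""


@dataclass(frozen=True)
class MorphGrid:
    """Ordered morph fractions in [0, 1] (0 = original fear, 1 = original anger)."""

    levels: tuple = tuple(np.round(np.linspace(0.0, 1.0, DEFAULT_GRID_LEVELS), 10))

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 2:
            raise ConfigError("morph grid needs at least 2 levels")
        if not np.all(np.diff(lv) > 0):
            raise ConfigError("morph grid levels must be strictly increasing")
        if lv[0] != 0.0 or lv[-1] != 1.0:
            raise ConfigError("morph grid must include the endpoints 0 and 1")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=float)


@dataclass
class SimConfig:
    """Generative observer/world parameters.

    Parameters
    ----------
    alpha : mapping
        Per-condition category boundary (morph fraction) of the latent
        logistic.
    beta : mapping
        Per-condition steepness (per unit morph fraction); must be >= 0.
    sigma_identity, sigma_participant : float
        SDs of Gaussian offsets added to alpha per face identity and per
        participant (shared across that participant's conditions).
    sigma_participant_condition : float or mapping
        SD of an additional boundary offset drawn per participant x
        condition: stable individual idiosyncrasies in how each viewing
        condition is handled, which make a participant's two experiment
        halves more similar to each other than to another condition.
    slope_cv : float or mapping
        Coefficient of variation of a per-participant x condition
        multiplicative steepness factor, lognormal with mean exactly 1
        (individual differences in category-boundary sharpness).
    sigma_bias : float or mapping
        SD of a stable per-participant x condition vertical response bias:
        a draw delta shifts the guess floor up and the lapse ceiling down
        by the same amount (floored at 0), moving the whole curve toward
        "angry" or "fearful" without changing its span.
    guess, lapse : float or mapping
        Stimulus-independent "angry" floor and "fearful" ceiling; the
        asymptotes of the generated curves are ``guess`` and ``1 - lapse``.
        A per-condition mapping captures masking conditions whose responses
        stay farther from 0/1 (harder conditions compress the whole curve,
        not just its midpoint region).
    w_eye, w_mouth : float
        Interference weights in [0, 1]: how strongly the to-be-ignored half
        pulls the response when judging the upper (``w_eye``) or lower
        (``w_mouth``) half of a composite face.
    anger_bias : float
        Constant boundary shift (morph-fraction units) toward fear, i.e. a
        positive value produces more "angry" responses overall.
    seed : int
        Seed for offset draws and Bernoulli responses.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    sigma_identity: float = 0.08
    sigma_participant: float = 0.03
    sigma_participant_condition: float | Mapping[str, float] = 0.03
    slope_cv: float | Mapping[str, float] = 0.25
    sigma_bias: float | Mapping[str, float] = 0.0
    guess: float | Mapping[str, float] = 0.02
    lapse: float | Mapping[str, float] = 0.02
    w_eye: float = 0.0
    w_mouth: float = 0.0
    anger_bias: float = 0.0
    seed: int = 0

    def _per_condition(self, value, condition: str, name: str) -> float:
        try:
            return value[condition] if isinstance(value, Mapping) else value
        except KeyError:
            raise ConfigError(f"no {name} for condition {condition!r}") from None

    def guess_for(self, condition: str) -> float:
        return self._per_condition(self.guess, condition, "guess rate")

    def lapse_for(self, condition: str) -> float:
        return self._per_condition(self.lapse, condition, "lapse rate")

    def __post_init__(self):
        for c in self.alpha:
            g, l = self.guess_for(c), self.lapse_for(c)
            if g < 0 or l < 0 or g + l >= 1:
                raise ConfigError(
                    f"guess and lapse must be >= 0 with guess + lapse < 1 ({c!r})")
            for val, name in ((self.sigma_participant_condition, "condition offset SD"),
                              (self.slope_cv, "slope CV"),
                              (self.sigma_bias, "bias SD")):
                if self._per_condition(val, c, name) < 0:
                    raise ConfigError(f"{name} must be >= 0")
        for w in (self.w_eye, self.w_mouth):
            if not 0.0 <= w <= 1.0:
                raise ConfigError("interference weights must lie in [0, 1]")
        if self.sigma_identity < 0 or self.sigma_participant < 0:
            raise ConfigError("offset SDs must be >= 0")
        if set(self.alpha) != set(self.beta):
            raise ConfigError("alpha and beta must cover the same conditions")
        for c, b in self.beta.items():
            if b < 0:
                raise ConfigError(f"beta must be >= 0 (condition {c!r})")

    @classmethod
    def exp1_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Masking-experiment observer: a shared boundary at the mid morph and
        condition-ordered steepness (whole > upper > lower)."""
        kw = dict(
            alpha={c: 0.5 for c in EXP1_CONDITIONS},
            beta={"whole": 10.3, "upper": 7.8, "lower": 4.4},
            guess={"whole": 0.02, "upper": 0.05, "lower": 0.10},
            lapse={"whole": 0.02, "upper": 0.05, "lower": 0.10},
            sigma_participant_condition={"whole": 0.026, "upper": 0.052, "lower": 0.074},
            slope_cv={"whole": 0.29, "upper": 0.38, "lower": 0.35},
            sigma_bias={"whole": 0.09, "upper": 0.045, "lower": 0.13},
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def exp1_recovery(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Idealized observer for parameter-recovery studies: the response
        curve IS the anchored logistic with known (alpha, beta) per
        condition, a small global guess/lapse, and only mean-zero
        participant boundary offsets on top of binomial trial noise (no
        identity blur, steepness heterogeneity or response bias, so the
        generative closed-form threshold and slope are the recovery
        targets)."""
        kw = dict(
            alpha={c: 0.5 for c in EXP1_CONDITIONS},
            beta={"whole": 9.0, "upper": 6.8, "lower": 4.0},
            guess=0.02, lapse=0.02,
            sigma_identity=0.0, sigma_participant=0.03,
            sigma_participant_condition=0.0, slope_cv=0.0, sigma_bias=0.0,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def exp2_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Composite-face observer: upper-half judgements are steeper and less
        interfered with than lower-half judgements (w_eye < w_mouth)."""
        upper = {"upper_anger", "upper_fear"}
        kw = dict(
            alpha={c: 0.5 for c in EXP2_CONDITIONS},
            beta={c: (6.4 if c in upper else 2.8) for c in EXP2_CONDITIONS},
            guess={c: (0.04 if c in upper else 0.10) for c in EXP2_CONDITIONS},
            lapse={c: (0.04 if c in upper else 0.10) for c in EXP2_CONDITIONS},
            sigma_participant_condition={c: (0.052 if c in upper else 0.10)
                                         for c in EXP2_CONDITIONS},
            slope_cv={c: (0.40 if c in upper else 0.50) for c in EXP2_CONDITIONS},
            sigma_bias={c: (0.05 if c in upper else 0.12) for c in EXP2_CONDITIONS},
            w_eye=0.10,
            w_mouth=0.37,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def interference_weight(self, condition: str) -> float:
        if condition.startswith("upper"):
            return self.w_eye
        if condition.startswith("lower"):
            return self.w_mouth
        return 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _shuffle_no_repeat(frame: pd.DataFrame, rng: np.random.Generator,
                       max_restarts: int = 50) -> pd.DataFrame:
    """Random order with no two consecutive rows sharing ``identity``.

    Shuffle, then repair adjacent identity repeats by swapping each offender
    with a random position where neither row creates a new conflict; restart
    from a fresh shuffle in the (rare) event repair stalls.
    """
    ids = frame["identity"].to_numpy()
    n = len(ids)
    for _ in range(max_restarts):
        order = rng.permutation(n)
        for _ in range(200):  # repair passes
            perm_ids = ids[order]
            bad = np.nonzero(perm_ids[1:] == perm_ids[:-1])[0] + 1
            if bad.size == 0:
                return frame.iloc[order].reset_index(drop=True)
            for i in bad:
                perm_ids = ids[order]
                if perm_ids[i] != perm_ids[i - 1]:
                    continue  # fixed by an earlier swap
                for j in rng.permutation(n):
                    if _swap_ok(perm_ids, i, j):
                        order[i], order[j] = order[j], order[i]
                        break
    raise RuntimeError("could not satisfy the no-identity-repeat constraint")


def _swap_ok(ids: np.ndarray, i: int, j: int) -> bool:
    if i == j:
        return False
    n = len(ids)
    # evaluate both positions with the swap virtually applied
    tmp = ids.copy()
    tmp[i], tmp[j] = ids[j], ids[i]
    for pos in (i, j):
        if pos > 0 and tmp[pos - 1] == tmp[pos]:
            return False
        if pos < n - 1 and tmp[pos + 1] == tmp[pos]:
            return False
    return True


def build_schedule(experiment: int, n_participants: int = 28, n_runs: int | None = None,
                   n_identities: int = 20, grid: MorphGrid | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Build a randomized trial schedule for one experiment.

    Returns a DataFrame with columns ``participant, experiment, run, block,
    condition, identity, morph, distractor`` (block and distractor are only
    meaningful for experiment 2).  Within each run (experiment 1) or each
    run-within-block (experiment 2) no two consecutive trials share a face
    identity, mirroring the constraint used when the stimulus order was
    randomized for human observers.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    if n_participants < 1 or (n_runs is not None and n_runs < 1):
        raise ValueError("n_participants and n_runs must be >= 1")
    if n_runs is None:
        n_runs = 2 if experiment == 1 else 1
    grid = grid or MorphGrid()
    rng = np.random.default_rng(seed)
    identities = np.arange(1, n_identities + 1)
    morphs = grid.as_array()

    pieces = []
    for p in range(1, n_participants + 1):
        if experiment == 1:
            base = pd.DataFrame(
                [(c, i, m) for c in EXP1_CONDITIONS for i in identities for m in morphs],
                columns=["condition", "identity", "morph"],
            )
            for run in range(1, n_runs + 1):
                t = _shuffle_no_repeat(base, rng)
                t.insert(0, "participant", p)
                t.insert(1, "experiment", 1)
                t.insert(2, "run", run)
                t.insert(3, "block", "")
                t["distractor"] = DISTRACTOR_NONE
                pieces.append(t)
        else:
            blocks = ["upper", "lower"] if p % 2 == 1 else ["lower", "upper"]
            for block in blocks:
                base = pd.DataFrame(
                    [(f"{block}_{e}", i, m, e)
                     for e in ("anger", "fear") for i in identities for m in morphs],
                    columns=["condition", "identity", "morph", "distractor"],
                )
                for run in range(1, n_runs + 1):
                    t = _shuffle_no_repeat(base, rng)
                    t.insert(0, "participant", p)
                    t.insert(1, "experiment", 2)
                    t.insert(2, "run", run)
                    t.insert(3, "block", block)
                    pieces.append(t)
    out = pd.concat(pieces, ignore_index=True)
    return out[["participant", "experiment", "run", "block", "condition",
                "identity", "morph", "distractor"]]


def logistic(x, alpha, beta):
    """Plain logistic F(x; alpha, beta) = 1 / (1 + exp(-beta (x - alpha)))."""
    z = np.asarray(beta, dtype=float) * (np.asarray(x, dtype=float) - alpha)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def response_probability(x, alpha, beta, distractor=DISTRACTOR_NONE, w=0.0,
                         guess=0.0, lapse=0.0):
    """Probability of an "angry" response under the generative observer.

    ``P = guess + (1 - guess - lapse) * [(1 - w) F(x; alpha, beta) + w d]``
    where ``d`` is 1 for an angry distractor, 0 for a fearful one, and the
    mixture collapses to ``F`` alone when there is no distractor.
    """
    if guess < 0 or lapse < 0 or guess + lapse >= 1:
        raise ConfigError("guess and lapse must satisfy guess + lapse < 1")
    if not 0.0 <= w <= 1.0:
        raise ConfigError("interference weight must lie in [0, 1]")
    f = logistic(x, alpha, beta)
    if isinstance(distractor, str):
        if distractor == DISTRACTOR_NONE:
            core = f
        else:
            d = 1.0 if distractor == "anger" else 0.0
            core = (1.0 - w) * f + w * d
    else:
        d = np.asarray([{"anger": 1.0, "fear": 0.0, DISTRACTOR_NONE: np.nan}[s]
                        for s in distractor])
        core = np.where(np.isnan(d), f, (1.0 - w) * f + w * np.nan_to_num(d))
    return guess + (1.0 - guess - lapse) * core


def simulate(schedule: pd.DataFrame, config: SimConfig,
             emit_rt: bool = False) -> pd.DataFrame:
    """Draw one Bernoulli response per schedule slot.

    Identity offsets ``a_j ~ N(0, sigma_identity^2)`` and participant offsets
    ``u_i ~ N(0, sigma_participant^2)`` are drawn once and added to the
    condition boundary for all of that unit's trials.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    identities = np.sort(schedule["identity"].unique())
    participants = np.sort(schedule["participant"].unique())
    conditions = sorted(config.alpha)
    a_id = dict(zip(identities, rng.normal(0.0, config.sigma_identity, len(identities))))
    u_p = dict(zip(participants, rng.normal(0.0, config.sigma_participant, len(participants))))
    v_pc, s_pc, b_pc = {}, {}, {}
    for p in participants:
        for c in conditions:
            v_pc[(p, c)] = rng.normal(
                0.0, config._per_condition(config.sigma_participant_condition, c, "sd"))
            cv = config._per_condition(config.slope_cv, c, "cv")
            if cv > 0:
                sig = np.sqrt(np.log1p(cv ** 2))  # lognormal with mean exactly 1
                s_pc[(p, c)] = rng.lognormal(-sig ** 2 / 2.0, sig)
            else:
                s_pc[(p, c)] = 1.0
            b_pc[(p, c)] = rng.normal(
                0.0, config._per_condition(config.sigma_bias, c, "sd"))

    cond = schedule["condition"].to_numpy()
    unknown = set(cond) - set(config.alpha)
    if unknown:
        raise ConfigError(f"config lacks parameters for conditions {sorted(unknown)}")
    pc = list(zip(schedule["participant"], cond))
    alpha = np.array([config.alpha[c] for c in cond])
    alpha += schedule["identity"].map(a_id).to_numpy()
    alpha += schedule["participant"].map(u_p).to_numpy()
    alpha += np.array([v_pc[k] for k in pc])
    alpha -= config.anger_bias
    beta = np.array([config.beta[c] for c in cond]) * np.array([s_pc[k] for k in pc])
    w = np.array([config.interference_weight(c) if d != DISTRACTOR_NONE else 0.0
                  for c, d in zip(cond, schedule["distractor"])])
    d = schedule["distractor"].map({"anger": 1.0, "fear": 0.0, DISTRACTOR_NONE: np.nan}).to_numpy()

    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(-beta * (schedule["morph"].to_numpy() - alpha)))
    core = np.where(np.isnan(d), f, (1.0 - w) * f + w * np.nan_to_num(d))
    guess = np.array([config.guess_for(c) for c in cond])
    lapse = np.array([config.lapse_for(c) for c in cond])
    delta = np.array([b_pc[k] for k in pc])
    guess = np.clip(guess + delta, 0.0, None)
    lapse = np.clip(lapse - delta, 0.0, None)
    p = np.clip(guess + (1.0 - guess - lapse) * core, 0.0, 1.0)

    trials = schedule.copy()
    trials["response"] = (rng.random(len(p)) < p).astype(int)
    if emit_rt:
        # constant-plus-noise RT (ms); for screening tests only, not a model
        trials["rt"] = np.clip(rng.normal(650.0, 150.0, len(p)), 200.0, None).round(1)
    return trials
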