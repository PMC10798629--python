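"""Experiment designs and trial generation for the coin-catching task.

The task: on each trial a hidden coin position is drawn from a zero-mean
Gaussian prior, and five "splash" dots are scattered around it with Gaussian
likelihood noise.  The observer places a net at the estimated coin position.
Screen coordinates run from -0.5 (left edge) to 0.5 (right edge).

Two experiments are supported:

* ``exp1`` -- two priors (Pn sigma=0.025, Pw sigma=0.085) crossed orthogonally
  with two likelihoods (Ln sigma=0.06, Lw sigma=0.15); 400 learning trials
  (200 per trained combo, block-wise for the *serial* group, interleaved for
  the *parallel* group) and 180 transfer trials (one prior with both
  likelihoods, 90 each).
* ``exp2`` -- one prior (Pw sigma=0.085) and three likelihoods
  (Ln sigma=0.024, Lm sigma=0.06, Lw sigma=0.15); 200 learning trials
  (100 + 100 of the group's two trained combos) and 225 transfer trials
  (75 per combo).  The *interpolation* group trains on Ln and Lw (novel
  combo: Lm); the *extrapolation* group trains on Ln and Lm (novel: Lw).

A likelihood-only pre-task (centroid estimation without prior information)
measures the observer's evidence precision: 80 trials (40 per likelihood) in
exp1, 90 trials (30 per likelihood over three 30-trial blocks) in exp2.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

PHASE_LEARNING = "learning"
PHASE_TRANSFER = "transfer"
TASK_COIN = "coin"
TASK_LIKELIHOOD_ONLY = "likelihood_only"

EXP1 = "exp1"
EXP2 = "exp2"
EXP1_GROUPS = ("serial", "parallel")
EXP2_GROUPS = ("interpolation", "extrapolation")

#: column order of the trial-table CSV dialect
TRIAL_TABLE_COLUMNS = [
    "participant_id", "experiment", "group", "phase", "novelty", "trial_index",
    "prior_label", "likelihood_label", "sigma_P", "sigma_L", "coin_x",
    "dot_x1", "dot_x2", "dot_x3", "dot_x4", "dot_x5", "response_x", "hit",
]


class DesignError(ValueError):
    """Raised for invalid task-design parameters or experiment/group combos."""


@dataclass(frozen=True)
class TaskDesign:
    """Generative parameters of a coin-task experiment.

    ``priors`` and ``likelihoods`` map condition labels (e.g. ``"Pw"``,
    ``"Ln"``) to standard deviations in screen units.  Prior means are fixed
    at zero (the screen centre).  The scoring window ``hit_window`` is the
    net width plus the coin diameter: a response within half of it catches
    the coin.
    """

    priors: Mapping[str, float]
    likelihoods: Mapping[str, float]
    screen_halfwidth: float = 0.5
    n_dots: int = 5
    net_width: float = 0.02
    coin_diameter: float = 0.01

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise DesignError("n_dots must be >= 1")
        for label, sigma in {**dict(self.priors), **dict(self.likelihoods)}.items():
            if not sigma > 0:
                raise DesignError(f"sigma for {label!r} must be > 0, got {sigma}")

    @property
    def hit_window(self) -> float:
        """Total catch window L = net width l + coin diameter d."""
        return self.net_width + self.coin_diameter

    @classmethod
    def exp1(cls) -> "TaskDesign":
        return cls(priors={"Pn": 0.025, "Pw": 0.085},
                   likelihoods={"Ln": 0.06, "Lw": 0.15})

    @classmethod
    def exp2(cls, narrow_sigma: float = 0.024) -> "TaskDesign":
        # narrow_sigma is config-exposed; 0.024 is the default reading of the
        # design (the alternative 0.0024 appears once as a likely typo).
        return cls(priors={"Pw": 0.085},
                   likelihoods={"Ln": narrow_sigma, "Lm": 0.06, "Lw": 0.15})

    @classmethod
    def for_experiment(cls, experiment: str) -> "TaskDesign":
        if experiment == EXP1:
            return cls.exp1()
        if experiment == EXP2:
            return cls.exp2()
        raise DesignError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class Condition:
    """A prior/likelihood pairing within a phase.

    ``novelty`` is ``"new"`` only for transfer-phase combos the participant
    never saw during learning; ``None`` for likelihood-only trials (no prior).
    """

    prior_label: Optional[str]
    likelihood_label: str
    phase: str
    novelty: Optional[str] = None

    def __post_init__(self) -> None:
        if self.novelty == "new" and self.phase != PHASE_TRANSFER:
            raise DesignError("novelty='new' is only valid in the transfer phase")

    @property
    def combo(self) -> str:
        return f"{self.prior_label or ''}{self.likelihood_label}"


@dataclass(frozen=True)
class Trial:
    """One splash display with its hidden coin position."""

    trial_index: int
    condition: Condition
    coin_x: float
    dot_xs: tuple
    task: str = TASK_COIN

    @property
    def mu_l(self) -> float:
        """Centroid of the splash dots (the trial's likelihood mean)."""
        return statistics.fmean(self.dot_xs)


@dataclass
class Schedule:
    experiment: str
    group: str
    trials: list
    counterbalance: int = 0
    design: TaskDesign = field(default_factory=TaskDesign.exp1)

    def counts(self) -> dict:
        """Trial counts keyed by (phase, combo, novelty)."""
        out: dict = {}
        for t in self.trials:
            key = (t.condition.phase, t.condition.combo, t.condition.novelty)
            out[key] = out.get(key, 0) + 1
        return out


def sample_trial(prior, likelihood_sigma: float, rng: np.random.Generator, *,
                 n_dots: int = 5, condition: Optional[Condition] = None,
                 trial_index: int = 0, task: str = TASK_COIN) -> Trial:
    """Draw one trial: coin ~ N(mu_P, sigma_P^2), dots i.i.d. N(coin, sigma_L^2).

    ``prior`` is a ``(mu_P, sigma_P)`` pair.  Positions are not clipped to the
    screen; the design sigmas make excursions beyond the edges negligible and
    clipping would distort the Gaussian assumptions of the analysis.
    """
    mu_p, sigma_p = prior
    if not sigma_p > 0:
        raise DesignError(f"prior sigma must be > 0, got {sigma_p}")
    if likelihood_sigma < 0:
        raise DesignError(f"likelihood sigma must be >= 0, got {likelihood_sigma}")
    coin_x = float(rng.normal(mu_p, sigma_p))
    dots = coin_x + likelihood_sigma * rng.standard_normal(n_dots)
    if condition is None:
        condition = Condition(None, "", PHASE_LEARNING)
    return Trial(trial_index=trial_index, condition=condition, coin_x=coin_x,
                 dot_xs=tuple(float(d) for d in dots), task=task)


def _interleave(counts: Mapping[str, int], rng: np.random.Generator,
                max_run: int = 6) -> list:
    """Pseudorandom order of condition labels with no run longer than max_run.

    Labels are drawn proportionally to their remaining counts, excluding any
    label that would extend a run past ``max_run``; the rare dead ends at the
    tail are resolved by restarting.
    """
    labels = list(counts)
    if len(labels) == 1:
        return labels * counts[labels[0]]
    total = sum(counts.values())
    for _attempt in range(10_000):
        remaining = dict(counts)
        out: list = []
        run_label, run_len = None, 0
        for _ in range(total):
            avail = [l for l in labels
                     if remaining[l] > 0 and not (l == run_label and run_len >= max_run)]
            if not avail:
                break
            weights = np.array([remaining[l] for l in avail], dtype=float)
            pick = avail[int(rng.choice(len(avail), p=weights / weights.sum()))]
            out.append(pick)
            remaining[pick] -= 1
            if pick == run_label:
                run_len += 1
            else:
                run_label, run_len = pick, 1
        if len(out) == total:
            return out
    raise RuntimeError("could not build a constrained interleaving")  # pragma: no cover


def exp1_combos(counterbalance: int) -> tuple:
    """Counterbalance assignment for exp1.

    Bit 0 selects the orthogonal learning pairing (Pn-Ln/Pw-Lw or Pn-Lw/Pw-Ln);
    bit 1 selects which prior carries over into the transfer phase.  Returns
    ``(learning_pairs, transfer_prior, new_pair, old_pair)``.
    """
    if counterbalance not in (0, 1, 2, 3):
        raise DesignError(f"exp1 counterbalance must be 0..3, got {counterbalance}")
    pairing = ({"Pn": "Ln", "Pw": "Lw"}, {"Pn": "Lw", "Pw": "Ln"})[counterbalance & 1]
    transfer_prior = ("Pn", "Pw")[(counterbalance >> 1) & 1]
    learning_pairs = [(p, l) for p, l in pairing.items()]
    old_pair = (transfer_prior, pairing[transfer_prior])
    new_lik = "Lw" if pairing[transfer_prior] == "Ln" else "Ln"
    new_pair = (transfer_prior, new_lik)
    return learning_pairs, transfer_prior, new_pair, old_pair


def exp2_combos(group: str) -> tuple:
    """Trained and novel likelihoods for an exp2 group: (trained, new)."""
    if group == "interpolation":
        return ["Ln", "Lw"], "Lm"
    if group == "extrapolation":
        return ["Ln", "Lm"], "Lw"
    raise DesignError(f"unknown exp2 group {group!r}")


def build_schedule(experiment: str, group: str, counterbalance: int,
                   rng: np.random.Generator,
                   design: Optional[TaskDesign] = None) -> Schedule:
    """Build the full coin-task schedule (learning followed by transfer)."""
    if design is None:
        design = TaskDesign.for_experiment(experiment)

    trials: list = []
    index = 0

    def emit(prior_label: str, lik_label: str, phase: str, novelty: str) -> None:
        nonlocal index
        cond = Condition(prior_label, lik_label, phase, novelty)
        trial = sample_trial((0.0, design.priors[prior_label]),
                             design.likelihoods[lik_label], rng,
                             n_dots=design.n_dots, condition=cond,
                             trial_index=index, task=TASK_COIN)
        trials.append(trial)
        index += 1

    if experiment == EXP1:
        if group not in EXP1_GROUPS:
            raise DesignError(f"exp1 groups are {EXP1_GROUPS}, got {group!r}")
        learning_pairs, _, new_pair, old_pair = exp1_combos(counterbalance)
        combo_of = {f"{p}{l}": (p, l) for p, l in learning_pairs}
        if group == "serial":
            order = [f"{p}{l}" for p, l in learning_pairs for _ in range(200)]
        else:
            order = _interleave({f"{p}{l}": 200 for p, l in learning_pairs}, rng)
        for combo in order:
            p, l = combo_of[combo]
            emit(p, l, PHASE_LEARNING, "old")
        transfer_pairs = {f"{p}{l}": (p, l) for p, l in (old_pair, new_pair)}
        t_order = _interleave({c: 90 for c in transfer_pairs}, rng)
        for combo in t_order:
            p, l = transfer_pairs[combo]
            novelty = "new" if (p, l) == new_pair else "old"
            emit(p, l, PHASE_TRANSFER, novelty)
    elif experiment == EXP2:
        trained, new_lik = exp2_combos(group)
        prior = "Pw"
        order = _interleave({l: 100 for l in trained}, rng)
        for l in order:
            emit(prior, l, PHASE_LEARNING, "old")
        t_order = _interleave({l: 75 for l in ("Ln", "Lm", "Lw")}, rng)
        for l in t_order:
            emit(prior, l, PHASE_TRANSFER, "new" if l == new_lik else "old")
    else:
        raise DesignError(f"unknown experiment {experiment!r}")

    return Schedule(experiment=experiment, group=group, trials=trials,
                    counterbalance=counterbalance, design=design)


def build_likelihood_only_schedule(experiment: str, rng: np.random.Generator,
                                   design: Optional[TaskDesign] = None) -> Schedule:
    """Build the centroid-estimation pre-task schedule.

    The generative centre of each dot cloud is drawn from a zero-mean Gaussian
    with the design's widest prior sigma; scoring never references it directly
    (responses are judged against the splash centre), so its spread is a
    presentation choice only.
    """
    if design is None:
        design = TaskDesign.for_experiment(experiment)
    centre_sigma = max(design.priors.values())

    if experiment == EXP1:
        blocks = [_interleave({"Ln": 40, "Lw": 40}, rng)]
    elif experiment == EXP2:
        # 30 trials of each likelihood, interspersed over three 30-trial blocks
        blocks = [_interleave({"Ln": 10, "Lm": 10, "Lw": 10}, rng) for _ in range(3)]
    else:
        raise DesignError(f"unknown experiment {experiment!r}")

    trials: list = []
    index = 0
    for block in blocks:
        for lik_label in block:
            cond = Condition(None, lik_label, PHASE_LEARNING)
            trials.append(sample_trial((0.0, centre_sigma),
                                       design.likelihoods[lik_label], rng,
                                       n_dots=design.n_dots, condition=cond,
                                       trial_index=index,
                                       task=TASK_LIKELIHOOD_ONLY))
            index += 1
    return Schedule(experiment=experiment, group=TASK_LIKELIHOOD_ONLY,
                    trials=trials, design=design)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table in the CSV dialect (fixed column order, header)."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    df[TRIAL_TABLE_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the dialect."""
    df = pd.read_csv(path, dtype={"participant_id": str, "novelty": str,
                                  "prior_label": str, "likelihood_label": str})
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    for col in ("novelty", "prior_label"):
        df[col] = df[col].fillna("")
    return df
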