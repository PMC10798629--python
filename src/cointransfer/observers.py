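"""Simulated participants for the coin task.

Each observer carries *internal* prior and likelihood dispersions which may be
miscalibrated relative to the generative design (human participants reliably
over-weight the likelihood, which corresponds to internally shrunken
likelihood sigmas).  Strategy classes:

``bayes``
    weights the splash centroid by w = sigma_P^2 / (sigma_P^2 + sigma_L^2/n)
    computed from the internal dispersions.
``likelihood_only`` / ``prior_only``
    respond at the splash centroid / the prior mean.
``linear_map``
    a heuristic linear mapping from precisions to the weight,
    w = b0 + b1/sigma_P^2 + b2/sigma_L^2, clipped to [0, 1].
``exemplar``
    stores coin-position feedback from the learning phase and, per trial,
    resamples N exemplars and takes their likelihood-weighted mean
    (a sampling approximation to the posterior mean).
``rote``
    learns weights like ``bayes`` during training but re-uses the trained
    weight unchanged when the likelihood changes in transfer -- the
    zero-transfer baseline.

Motor noise is additive Gaussian on the response, identical across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import task_protocol as tp
from .estimation import optimal_slope

STRATEGIES = ("bayes", "likelihood_only", "prior_only", "linear_map",
              "exemplar", "rote")


class ObserverError(ValueError):
    pass


@dataclass
class ObserverSpec:
    """A simulated participant: strategy plus internal (possibly
    miscalibrated) dispersions and motor noise, all in screen units."""

    strategy: str
    internal_sigma_p: Dict[str, float] = field(default_factory=dict)
    internal_sigma_l: Dict[str, float] = field(default_factory=dict)
    motor_sd: float = 0.0
    linear_coeffs: Optional[tuple] = None
    exemplar_n: int = 5
    exemplar_weighting: str = "single_dot"  # or "centroid"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ObserverError(f"unknown strategy {self.strategy!r}")
        for sigma in (*self.internal_sigma_p.values(),
                      *self.internal_sigma_l.values()):
            if sigma < 0:
                raise ObserverError("internal sigmas must be >= 0")
        if self.strategy == "exemplar" and self.exemplar_n < 1:
            raise ObserverError("exemplar_n must be >= 1")
        if self.strategy == "linear_map" and self.linear_coeffs is None:
            raise ObserverError("linear_map observers need linear_coeffs")

    @classmethod
    def ideal(cls, design: tp.TaskDesign, strategy: str = "bayes",
              motor_sd: float = 0.0, **kwargs) -> "ObserverSpec":
        """Observer whose internal dispersions equal the generative ones."""
        return cls(strategy=strategy,
                   internal_sigma_p=dict(design.priors),
                   internal_sigma_l=dict(design.likelihoods),
                   motor_sd=motor_sd, **kwargs)

    def weight(self, prior_label: str, lik_label: str, n_dots: int) -> float:
        """Internal likelihood weight for a combo (bayes/rote/linear_map)."""
        sp = self.internal_sigma_p[prior_label]
        sl = self.internal_sigma_l[lik_label]
        if self.strategy == "linear_map":
            b0, b1, b2 = self.linear_coeffs
            w = b0 + b1 / sp ** 2 + b2 / sl ** 2
            return float(np.clip(w, 0.0, 1.0))
        return optimal_slope(sp, sl, n_dots)

    def weighting_sigma(self, lik_label: str, n_dots: int) -> float:
        sl = self.internal_sigma_l[lik_label]
        if self.exemplar_weighting == "centroid":
            return sl / np.sqrt(n_dots)
        return sl


def respond_likelihood_only(obs: ObserverSpec, trial: tp.Trial,
                            rng: np.random.Generator) -> float:
    """Centroid estimation is strategy-independent: splash mean plus noise."""
    if trial.task != tp.TASK_LIKELIHOOD_ONLY:
        raise ObserverError("trial is not a likelihood-only trial")
    return trial.mu_l + float(rng.normal(0.0, obs.motor_sd)) \
        if obs.motor_sd > 0 else trial.mu_l


def exemplar_estimate(memory, mu_l: float, weighting_sigma: float, n: int,
                      rng: np.random.Generator) -> float:
    """Likelihood-weighted mean of N exemplars resampled from memory.

    Draws ``n`` stored coin positions uniformly with replacement and weights
    each by the Gaussian likelihood density at ``mu_l`` with scale
    ``weighting_sigma`` (self-normalized importance sampling).  If every
    weight underflows to zero, falls back to the unweighted sample mean.
    """
    memory = np.asarray(memory, dtype=float)
    if memory.size == 0:
        raise ObserverError("exemplar memory is empty")
    if n < 1:
        raise ObserverError("n must be >= 1")
    if not weighting_sigma > 0:
        raise ObserverError("weighting_sigma must be > 0")
    draws = memory[rng.integers(0, memory.size, size=n)]
    w = np.exp(-0.5 * ((draws - mu_l) / weighting_sigma) ** 2)
    tot = w.sum()
    if not np.isfinite(tot) or tot <= 0.0:
        return float(draws.mean())
    return float((w * draws).sum() / tot)


def exemplar_estimate_batch(memory, mu_ls, weighting_sigmas, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`exemplar_estimate` over many trials."""
    memory = np.asarray(memory, dtype=float)
    if memory.size == 0:
        raise ObserverError("exemplar memory is empty")
    mu_ls = np.asarray(mu_ls, dtype=float)
    sig = np.broadcast_to(np.asarray(weighting_sigmas, dtype=float), mu_ls.shape)
    draws = memory[rng.integers(0, memory.size, size=(mu_ls.size, n))]
    w = np.exp(-0.5 * ((draws - mu_ls[:, None]) / sig[:, None]) ** 2)
    tot = w.sum(axis=1)
    est = np.where(tot > 0.0, (w * draws).sum(axis=1) / np.where(tot > 0, tot, 1.0),
                   draws.mean(axis=1))
    return est


def respond_coin(obs: ObserverSpec, trial: tp.Trial, rng: np.random.Generator,
                 *, memory=None, rote_weights: Optional[Mapping] = None,
                 n_dots: int = 5, mu_p: float = 0.0) -> float:
    """One coin-task response (before-noise estimate plus motor noise)."""
    if trial.task != tp.TASK_COIN:
        raise ObserverError("trial is not a coin trial")
    cond = trial.condition
    mu_l = trial.mu_l
    if obs.strategy == "likelihood_only":
        x = mu_l
    elif obs.strategy == "prior_only":
        x = mu_p
    elif obs.strategy in ("bayes", "linear_map"):
        w = obs.weight(cond.prior_label, cond.likelihood_label, n_dots)
        x = w * mu_l + (1.0 - w) * mu_p
    elif obs.strategy == "exemplar":
        if memory is None or len(memory) == 0:
            x = mu_l  # nothing stored yet: evidence is all there is
        else:
            x = exemplar_estimate(memory, mu_l,
                                  obs.weighting_sigma(cond.likelihood_label, n_dots),
                                  obs.exemplar_n, rng)
    elif obs.strategy == "rote":
        if rote_weights is None:
            raise ObserverError("rote observer needs its learned weights")
        w = _rote_weight(obs, rote_weights, cond.prior_label,
                         cond.likelihood_label)
        x = w * mu_l + (1.0 - w) * mu_p
    else:  # pragma: no cover
        raise ObserverError(f"unknown strategy {obs.strategy!r}")
    if obs.motor_sd > 0:
        x += float(rng.normal(0.0, obs.motor_sd))
    return float(x)


def _rote_weight(obs: ObserverSpec, rote_weights: Mapping, prior_label: str,
                 lik_label: str) -> float:
    """Learned weight lookup: exact combo if trained, else the trained combo
    with the same prior whose likelihood sigma is nearest to the novel one."""
    if (prior_label, lik_label) in rote_weights:
        return rote_weights[(prior_label, lik_label)]
    same_prior = [(p, l) for (p, l) in rote_weights if p == prior_label]
    if not same_prior:
        raise ObserverError(f"rote observer never trained prior {prior_label!r}")
    target = obs.internal_sigma_l[lik_label]
    nearest = min(same_prior,
                  key=lambda pl: abs(obs.internal_sigma_l[pl[1]] - target))
    return rote_weights[nearest]


def simulate_participant(obs: ObserverSpec,
                         likelihood_only_schedule: tp.Schedule,
                         coin_schedule: tp.Schedule,
                         rng: np.random.Generator,
                         participant_id: str = "p000") -> pd.DataFrame:
    """Simulate one participant through both tasks and return trial-table rows.

    Exemplar memory and rote weights accumulate from learning-phase trials
    only; the transfer phase provides no coin feedback, so both stay frozen
    there.  ``hit`` marks responses within half the catch window of the coin.
    """
    design = coin_schedule.design
    half_window = design.hit_window / 2.0
    rows = []

    def base_row(schedule: tp.Schedule, trial: tp.Trial, response: float,
                 hit_target: float) -> dict:
        cond = trial.condition
        dots = trial.dot_xs
        return {
            "participant_id": participant_id,
            "experiment": schedule.experiment,
            "group": schedule.group,
            "phase": (tp.TASK_LIKELIHOOD_ONLY
                      if trial.task == tp.TASK_LIKELIHOOD_ONLY else cond.phase),
            "novelty": cond.novelty or "",
            "trial_index": trial.trial_index,
            "prior_label": cond.prior_label or "",
            "likelihood_label": cond.likelihood_label,
            "sigma_P": (design.priors[cond.prior_label]
                        if cond.prior_label else float("nan")),
            "sigma_L": design.likelihoods[cond.likelihood_label],
            "coin_x": trial.coin_x,
            **{f"dot_x{i + 1}": dots[i] for i in range(len(dots))},
            "response_x": response,
            "hit": bool(abs(response - hit_target) <= half_window),
        }

    for trial in likelihood_only_schedule.trials:
        resp = respond_likelihood_only(obs, trial, rng)
        rows.append(base_row(likelihood_only_schedule, trial, resp, trial.mu_l))

    memory: list = []
    rote_weights: dict = {}
    for trial in coin_schedule.trials:
        cond = trial.condition
        learning = cond.phase == tp.PHASE_LEARNING
        if obs.strategy == "rote" and learning:
            key = (cond.prior_label, cond.likelihood_label)
            if key not in rote_weights:
                rote_weights[key] = obs.weight(*key, design.n_dots)
        resp = respond_coin(obs, trial, rng, memory=memory,
                            rote_weights=rote_weights, n_dots=design.n_dots)
        rows.append(base_row(coin_schedule, trial, resp, trial.coin_x))
        if obs.strategy == "exemplar" and learning:
            memory.append(trial.coin_x)  # coin feedback shown during learning

    return pd.DataFrame(rows, columns=tp.TRIAL_TABLE_COLUMNS)


@dataclass
class CohortConfig:
    """A simulated cohort: strategy mix, miscalibration model and noise.

    Internal dispersions are drawn per participant and label as
    ``true_sigma * bias * exp(tau * z)`` with z standard normal, i.e.
    log-normal multiplicative miscalibration around a systematic bias.  The
    default ``bias_l = 0.7`` shrinks internal likelihood sigmas, reproducing
    the characteristic over-weighting of sensory evidence; pass ``bias_l=1``
    for ideal observers.  ``counterbalance=None`` cycles assignments across
    participants (exp1).
    """

    n_participants: int
    experiment: str = tp.EXP1
    group: str = "serial"
    strategy: Union[str, Mapping[str, float]] = "bayes"
    bias_p: float = 1.0
    bias_l: float = 0.7
    tau_p: float = 0.0
    tau_l: float = 0.0
    motor_sd: float = 0.01
    linear_coeffs: Optional[tuple] = None
    exemplar_n: int = 5
    exemplar_weighting: str = "single_dot"
    counterbalance: Optional[int] = None
    seed: int = 0
    design: Optional[tp.TaskDesign] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ObserverError("n_participants must be >= 1")
        if min(self.tau_p, self.tau_l) < 0:
            raise ObserverError("tau must be >= 0")

    def strategy_for(self, idx: int) -> str:
        if isinstance(self.strategy, str):
            return self.strategy
        # deterministic proportional assignment of a strategy mix
        items = sorted(self.strategy.items())
        total = sum(frac for _, frac in items)
        cum, point = 0.0, (idx + 0.5) / self.n_participants
        for name, frac in items:
            cum += frac / total
            if point <= cum:
                return name
        return items[-1][0]



def simulate_cohort(config: CohortConfig):
    """Simulate a cohort; returns ``(trials, truth)`` DataFrames.

    ``truth`` is the ground-truth sidecar (one row per participant) holding
    the strategy, motor noise and every internal sigma, for
    parameter-recovery checks.  The master seed fixes everything.
    """
    design = config.design or tp.TaskDesign.for_experiment(config.experiment)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)

    trial_frames = []
    truth_rows = []
    for idx in range(config.n_participants):
        rng = np.random.default_rng(children[idx])
        pid = f"p{idx:03d}"
        strategy = config.strategy_for(idx)

        internal_p = {lab: sig * config.bias_p * np.exp(config.tau_p * rng.standard_normal())
                      for lab, sig in design.priors.items()}
        internal_l = {lab: sig * config.bias_l * np.exp(config.tau_l * rng.standard_normal())
                      for lab, sig in design.likelihoods.items()}
        obs = ObserverSpec(strategy=strategy,
                           internal_sigma_p=internal_p,
                           internal_sigma_l=internal_l,
                           motor_sd=config.motor_sd,
                           linear_coeffs=config.linear_coeffs,
                           exemplar_n=config.exemplar_n,
                           exemplar_weighting=config.exemplar_weighting)

        if config.experiment == tp.EXP1:
            cb = (config.counterbalance if config.counterbalance is not None
                  else idx % 4)
        else:
            cb = config.counterbalance or 0
        lik_only = tp.build_likelihood_only_schedule(config.experiment, rng,
                                                     design=design)
        coin = tp.build_schedule(config.experiment, config.group, cb, rng,
                                 design=design)
        trial_frames.append(simulate_participant(obs, lik_only, coin, rng,
                                                 participant_id=pid))
        truth_rows.append({
            "participant_id": pid, "strategy": strategy,
            "motor_sd": config.motor_sd, "counterbalance": cb,
            **{f"sigma_P_{lab}": sig for lab, sig in internal_p.items()},
            **{f"sigma_L_{lab}": sig for lab, sig in internal_l.items()},
        })

    trials = pd.concat(trial_frames, ignore_index=True)
    return trials, pd.DataFrame(truth_rows)
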