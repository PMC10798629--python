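"""Per-participant estimation: weighting slopes and variance proxies.

The analysis chain recovers, for each participant,

* ``sigma_Li^2`` -- the effective evidence variance per likelihood level,
  measured in the likelihood-only task as the mean squared deviation of
  centroid responses from the generative cloud centre (population divisor n).
  For a noiseless centroid estimator this equals sigma_L^2 / n_dots; motor
  and computation errors add to it, which is exactly what makes it a
  subject-specific proxy.
* sensory-weighting slopes -- ordinary least squares of net placements on
  splash centroids, per prior/likelihood combo, in presentation order, after
  discarding the first ``discard`` trials of that combo (50 in exp1, 25 in
  exp2) to skip the initial prior-acquisition period.
* ``sigma_Pi^2 = sigma_Li^2 * slope / (1 - slope)`` -- the implied internal
  prior variance, obtained by inverting the optimal-weighting relation
  ``slope = sigma_P^2 / (sigma_P^2 + sigma_L^2)``.  Slopes at or above
  ``slope_cap`` (default 0.99) make this proxy arbitrarily large and are
  flagged unreliable rather than propagated.
* predicted transfer slopes -- the optimal-weighting relation re-applied with
  the participant's own proxies and the novel likelihood's evidence variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .task_protocol import (PHASE_LEARNING, PHASE_TRANSFER,
                            TASK_LIKELIHOOD_ONLY)

DEFAULT_SLOPE_CAP = 0.99
DEFAULT_DISCARD = {"exp1": 50, "exp2": 25}
DOT_COLUMNS = ["dot_x1", "dot_x2", "dot_x3", "dot_x4", "dot_x5"]


class EstimationError(ValueError):
    pass


class UnreliableSlopeError(EstimationError):
    """Slope outside (0, slope_cap): the implied prior variance is unusable."""


def optimal_slope(sigma_p: float, sigma_l: float, n_dots: int = 5) -> float:
    """Ideal-observer likelihood weight sigma_P^2 / (sigma_P^2 + sigma_L^2/n).

    ``sigma_l`` is the single-dot dispersion; the centroid of ``n_dots`` dots
    carries evidence variance sigma_L^2 / n_dots.
    """
    if sigma_p < 0 or sigma_l < 0:
        raise EstimationError("sigmas must be non-negative")
    if sigma_p == 0 and sigma_l == 0:
        raise EstimationError("prior and likelihood sigma cannot both be zero")
    vp = sigma_p ** 2
    vl = sigma_l ** 2 / n_dots
    return vp / (vp + vl)


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of responses on splash centroids for one condition."""

    slope: float
    intercept: float
    n_used: int
    discarded: int
    zero_intercept: bool = False
    condition: str = ""


def fit_slope(mu_l, responses, discard: int = 0, zero_intercept: bool = False,
              condition: str = "") -> SlopeFit:
    """Regress responses on likelihood means, in presentation order.

    The first ``discard`` trials of the condition are dropped before fitting.
    ``zero_intercept`` forces the line through the origin (closed form
    beta = sum(xy)/sum(x^2)).
    """
    x = np.asarray(mu_l, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EstimationError("mu_l and responses must be equal-length 1-D arrays")
    if x.size < discard + 2:
        raise EstimationError(
            f"condition {condition or '<unnamed>'}: need at least {discard + 2} "
            f"trials, got {x.size}")
    x, y = x[discard:], y[discard:]
    if zero_intercept:
        beta = float(x @ y / (x @ x))
        inter = 0.0
    else:
        beta, inter = (float(v) for v in np.polyfit(x, y, 1))
    if not math.isfinite(beta):
        raise EstimationError(f"condition {condition}: non-finite slope")
    return SlopeFit(slope=beta, intercept=inter, n_used=int(x.size),
                    discarded=discard, zero_intercept=zero_intercept,
                    condition=condition)


def sigma_li_sq(estimates, truths) -> float:
    """Evidence-variance proxy: mean squared deviation of centroid estimates
    from the true cloud centres (population divisor n)."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.ndim != 1:
        raise EstimationError("estimates and truths must be equal-length 1-D arrays")
    if est.size < 2:
        raise EstimationError("need at least 2 paired estimates")
    return float(np.mean((est - tru) ** 2))


def sigma_pi_sq(sigma_li_sq_value: float, slope: float,
                slope_cap: float = DEFAULT_SLOPE_CAP) -> float:
    """Internal prior-variance proxy sigma_Li^2 * slope / (1 - slope).

    Raises :class:`UnreliableSlopeError` when the slope leaves (0, slope_cap):
    near 1 the proxy diverges, at or below 0 it is non-positive; both mark the
    (participant, prior) for exclusion rather than silent computation.
    """
    if not sigma_li_sq_value > 0:
        raise EstimationError(f"sigma_Li^2 must be > 0, got {sigma_li_sq_value}")
    if not 0.0 < slope < slope_cap:
        raise UnreliableSlopeError(
            f"slope {slope:.4f} outside (0, {slope_cap}): prior proxy unreliable")
    return sigma_li_sq_value * slope / (1.0 - slope)


def predicted_transfer_slope(sigma_pi_sq_value: float,
                             sigma_li_sq_new: float) -> float:
    """Predicted weighting for a novel likelihood from the subject's proxies."""
    if not (sigma_pi_sq_value > 0 and sigma_li_sq_new > 0):
        raise EstimationError("variance proxies must be > 0")
    return sigma_pi_sq_value / (sigma_pi_sq_value + sigma_li_sq_new)


def logistic_pool(slopes) -> float:
    """Average slopes on the log-odds scale and back-transform.

    Alternative to hard exclusion for slopes near 0/1; exposed for cohort
    summaries, not used in the default chain.
    """
    s = np.clip(np.asarray(slopes, dtype=float), 1e-12, 1 - 1e-12)
    z = np.log(s / (1 - s))
    return float(1.0 / (1.0 + np.exp(-np.mean(z))))


@dataclass
class SubjectEstimates:
    """Everything the downstream metrics need about one participant."""

    participant_id: str
    experiment: str
    group: str
    sigma_li_sq: Dict[str, float] = field(default_factory=dict)
    learning_slopes: Dict[str, SlopeFit] = field(default_factory=dict)
    transfer_slopes: Dict[str, SlopeFit] = field(default_factory=dict)
    new_combo: str = ""
    new_likelihood: str = ""
    sigma_pi_sq: Dict[str, float] = field(default_factory=dict)
    predicted_new_slope: Dict[str, float] = field(default_factory=dict)
    unreliable: Dict[str, str] = field(default_factory=dict)
    combo_prior: Dict[str, str] = field(default_factory=dict)
    combo_lik: Dict[str, str] = field(default_factory=dict)


def _combo_frame(df: pd.DataFrame) -> pd.Series:
    return df["prior_label"].astype(str) + df["likelihood_label"].astype(str)


def estimate_subject(df: pd.DataFrame, *, discard: Optional[int] = None,
                     zero_intercept: bool = False,
                     slope_cap: float = DEFAULT_SLOPE_CAP) -> SubjectEstimates:
    """Run the full estimation chain on one participant's trial table."""
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise EstimationError("estimate_subject expects a single participant")
    experiment = str(df["experiment"].iloc[0])
    group = str(df.loc[df["phase"] != TASK_LIKELIHOOD_ONLY, "group"].iloc[0]
                if (df["phase"] != TASK_LIKELIHOOD_ONLY).any()
                else df["group"].iloc[0])
    if discard is None:
        discard = DEFAULT_DISCARD.get(experiment, 0)

    est = SubjectEstimates(participant_id=str(pids[0]), experiment=experiment,
                           group=group)
    df = df.sort_values("trial_index", kind="stable")
    mu_l = df[DOT_COLUMNS].mean(axis=1)

    lik_only = df[df["phase"] == TASK_LIKELIHOOD_ONLY]
    for label, sub in lik_only.groupby("likelihood_label"):
        est.sigma_li_sq[str(label)] = sigma_li_sq(
            sub["response_x"].to_numpy(), sub["coin_x"].to_numpy())

    combo_prior = est.combo_prior
    combo_lik = est.combo_lik

    learning = df[df["phase"] == PHASE_LEARNING]
    for combo, sub in learning.groupby(_combo_frame(learning)):
        combo_prior[str(combo)] = str(sub["prior_label"].iloc[0])
        combo_lik[str(combo)] = str(sub["likelihood_label"].iloc[0])
        est.learning_slopes[str(combo)] = fit_slope(
            mu_l.loc[sub.index], sub["response_x"], discard=discard,
            zero_intercept=zero_intercept, condition=f"learning/{combo}")

    new_prior = ""
    transfer = df[df["phase"] == PHASE_TRANSFER]
    for combo, sub in transfer.groupby(_combo_frame(transfer)):
        est.transfer_slopes[str(combo)] = fit_slope(
            mu_l.loc[sub.index], sub["response_x"], discard=0,
            zero_intercept=zero_intercept, condition=f"transfer/{combo}")
        if (sub["novelty"] == "new").any():
            est.new_combo = str(combo)
            est.new_likelihood = str(sub["likelihood_label"].iloc[0])
            new_prior = str(sub["prior_label"].iloc[0])

    # prior-variance proxies for every trained combo (model features), and
    # predicted transfer slopes from the combos sharing the novel combo's prior
    for combo, fit in est.learning_slopes.items():
        lik_label = combo_lik[combo]
        if lik_label not in est.sigma_li_sq:
            est.unreliable[combo] = f"no likelihood-only data for {lik_label}"
            continue
        try:
            vp = sigma_pi_sq(est.sigma_li_sq[lik_label], fit.slope,
                             slope_cap=slope_cap)
        except UnreliableSlopeError as err:
            est.unreliable[combo] = str(err)
            est.sigma_pi_sq[combo] = float("nan")
            continue
        est.sigma_pi_sq[combo] = vp
        if est.new_combo and combo_prior[combo] == new_prior:
            if est.new_likelihood in est.sigma_li_sq:
                est.predicted_new_slope[combo] = predicted_transfer_slope(
                    vp, est.sigma_li_sq[est.new_likelihood])
    return est


def estimate_cohort(df: pd.DataFrame, **kwargs) -> list:
    """Estimate every participant in a cohort trial table."""
    return [estimate_subject(sub, **kwargs)
            for _, sub in df.groupby("participant_id", sort=True)]


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Per-participant estimates in long CSV form (one row per condition)."""
    rows = []
    for est in estimates:
        for combo, fit in est.learning_slopes.items():
            rows.append({
                "participant_id": est.participant_id, "phase": PHASE_LEARNING,
                "condition": combo, "slope": fit.slope,
                "intercept": fit.intercept, "n_used": fit.n_used,
                "sigma_Li_sq": est.sigma_li_sq.get(est.combo_lik.get(combo, ""), float("nan")),
                "sigma_Pi_sq": est.sigma_pi_sq.get(combo, float("nan")),
                "predicted_slope": est.predicted_new_slope.get(combo, float("nan")),
                "unreliable": est.unreliable.get(combo, ""),
            })
        for combo, fit in est.transfer_slopes.items():
            rows.append({
                "participant_id": est.participant_id, "phase": PHASE_TRANSFER,
                "condition": combo, "slope": fit.slope,
                "intercept": fit.intercept, "n_used": fit.n_used,
                "sigma_Li_sq": float("nan"),
                "sigma_Pi_sq": float("nan"), "predicted_slope": float("nan"),
                "unreliable": "",
            })
    return pd.DataFrame(rows)
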