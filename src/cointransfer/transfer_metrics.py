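"""Transfer scores, the optimality index, and robust outlier screening.

The transfer score normalises the measured slope change on a novel
prior/likelihood pairing by the change an optimal Bayesian observer with the
*participant's own* variance proxies would show:

    ts = (measured_new - learned) / (predicted_new - learned)

1 means fully Bayesian transfer, <= 0 means none; the normalisation makes the
score invariant to subject-specific miscalibration of prior and likelihood
uncertainty.  In the two-trained-combo protocol (exp2) one score is computed
against each trained combo and the two are averaged.

The optimality index tracks per-trial performance: the probability of
catching the coin at the chosen net position, divided by the maximum
achievable probability under the true posterior.

Outlier screening follows staged 3-MAD exclusion (scaled MAD, normal
consistency constant 1.4826) applied in order to slopes, prior-variance
proxies, predicted slopes and transfer scores; a participant flagged at any
stage is excluded from the later stages and the pooled statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import DOT_COLUMNS, SubjectEstimates, optimal_slope
from .task_protocol import PHASE_TRANSFER, TaskDesign

MAD_SCALE = 1.4826  # normal-consistency constant for the scaled MAD


class UndefinedTransferScore(ValueError):
    """Predicted and learned slopes coincide: the score is undefined."""


def transfer_score(measured_new: float, slope_learned: float,
                   predicted_new: float, tol: float = 1e-6) -> float:
    """Measured slope change over predicted slope change."""
    denom = predicted_new - slope_learned
    if abs(denom) < tol:
        raise UndefinedTransferScore(
            f"predicted slope change {denom:.2e} below tolerance {tol:.0e}")
    return (measured_new - slope_learned) / denom


@dataclass
class TransferResult:
    participant_id: str
    per_baseline: Dict[str, float] = field(default_factory=dict)
    pooled: float = float("nan")
    excluded: Optional[str] = None  # exclusion stage/reason, None if included


def participant_transfer(est: SubjectEstimates) -> TransferResult:
    """Transfer score(s) for one participant, pooled across trained combos."""
    res = TransferResult(participant_id=est.participant_id)
    reasons = []
    for baseline, predicted in est.predicted_new_slope.items():
        if baseline in est.unreliable or not math.isfinite(predicted):
            continue
        measured = est.transfer_slopes[est.new_combo].slope
        learned = est.learning_slopes[baseline].slope
        try:
            res.per_baseline[baseline] = transfer_score(measured, learned,
                                                        predicted)
        except UndefinedTransferScore as err:
            reasons.append(f"{baseline}: {err}")
    if res.per_baseline:
        res.pooled = float(np.mean(list(res.per_baseline.values())))
    else:
        res.excluded = ("undefined ts: " + "; ".join(reasons) if reasons
                        else "unreliable: " + "; ".join(est.unreliable.values()))
    return res


def posterior_params(mu_l: float, sigma_p: float, sigma_l: float,
                     n_dots: int = 5):
    """Posterior mean and sd for a trial (zero-mean prior).

    sigma^2 = (1/sigma_P^2 + n/sigma_L^2)^-1 and mu = w * mu_L with w the
    optimal weight.
    """
    if not (sigma_p > 0 and sigma_l > 0):
        raise ValueError("sigma_p and sigma_l must be > 0")
    var = 1.0 / (1.0 / sigma_p ** 2 + n_dots / sigma_l ** 2)
    mu = optimal_slope(sigma_p, sigma_l, n_dots) * mu_l
    return float(mu), float(math.sqrt(var))


def p_hit(x, mu, sigma, window):
    """Probability that the coin lands within the net at position x.

    Integrates the posterior density over [x - L/2, x + L/2] via the normal
    CDF; symmetric in (x - mu) and maximal at x = mu.
    """
    if np.any(np.asarray(sigma) <= 0) or window <= 0:
        raise ValueError("sigma and window must be > 0")
    x = np.asarray(x, dtype=float)
    upper = norm.cdf((x + window / 2 - mu) / sigma)
    lower = norm.cdf((x - window / 2 - mu) / sigma)
    out = upper - lower
    return float(out) if out.ndim == 0 else out


def optimality_index(x_net, mu, sigma, window):
    """p_hit at the response normalised by p_hit at the posterior mean."""
    return p_hit(x_net, mu, sigma, window) / p_hit(mu, mu, sigma, window)


def trial_optimality(df: pd.DataFrame, design: TaskDesign) -> pd.Series:
    """Optimality index for every coin-task row of a trial table.

    Uses the true generative posterior of each trial's prior/likelihood
    combination, per the design parameters.
    """
    coin = df[df["phase"].isin(("learning", "transfer"))]
    mu_l = coin[DOT_COLUMNS].mean(axis=1).to_numpy()
    sig_p = coin["sigma_P"].to_numpy()
    sig_l = coin["sigma_L"].to_numpy()
    w = sig_p ** 2 / (sig_p ** 2 + sig_l ** 2 / design.n_dots)
    mu = w * mu_l
    sd = np.sqrt(1.0 / (1.0 / sig_p ** 2 + design.n_dots / sig_l ** 2))
    idx = (p_hit(coin["response_x"].to_numpy(), mu, sd, design.hit_window)
           / p_hit(mu, mu, sd, design.hit_window))
    return pd.Series(idx, index=coin.index, name="optimality_index")


def first_last_optimality(df: pd.DataFrame, design: TaskDesign,
                          novelty: str = "new", k: int = 10) -> pd.DataFrame:
    """Mean optimality of the first vs last ``k`` transfer trials per
    participant (the no-incremental-learning diagnostic)."""
    oi = trial_optimality(df, design)
    rows = []
    sel = df[(df["phase"] == PHASE_TRANSFER) & (df["novelty"] == novelty)]
    for pid, sub in sel.groupby("participant_id"):
        sub = sub.sort_values("trial_index")
        rows.append({"participant_id": pid,
                     "first_mean": float(oi.loc[sub.index[:k]].mean()),
                     "last_mean": float(oi.loc[sub.index[-k:]].mean())})
    return pd.DataFrame(rows)


def mad_filter(values, k: float = 3.0, scale: float = MAD_SCALE) -> np.ndarray:
    """Inclusion mask: keep values within k scaled-MADs of the median.

    With MAD = 0 (e.g. all values identical) only exact deviants from the
    median are excluded.  NaNs are excluded.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to screen outliers")
    finite = np.isfinite(v)
    med = np.median(v[finite]) if finite.any() else float("nan")
    mad = scale * np.median(np.abs(v[finite] - med)) if finite.any() else 0.0
    if mad == 0.0:
        keep = v == med
    else:
        keep = np.abs(v - med) <= k * mad
    return keep & finite


@dataclass
class CohortTransfer:
    """Pooled transfer-score statistics with the staged exclusion tally."""

    results: List[TransferResult]
    included_ids: List[str]
    ts_values: np.ndarray
    mean_ts: float
    median_ts: float
    iqr_ts: float
    exclusions: Dict[str, int]
    exclusion_reasons: Dict[str, str]


def cohort_transfer(estimates: List[SubjectEstimates], mad_k: float = 3.0,
                    screen: bool = True) -> CohortTransfer:
    """Pool participant transfer scores with staged outlier screening.

    Stages, in order: unreliable slope flags (slope cap / undefined score),
    then 3-MAD screening of (1) learning and transfer-new slopes per combo,
    (2) prior-variance proxies per combo, (3) predicted transfer slopes,
    (4) pooled transfer scores.  Each stage only sees survivors of the
    previous ones.
    """
    results = {e.participant_id: participant_transfer(e) for e in estimates}
    excluded: Dict[str, str] = {}
    tally = {"unreliable": 0, "slope": 0, "sigma_pi_sq": 0,
             "predicted": 0, "ts": 0}

    for e in estimates:
        r = results[e.participant_id]
        if r.excluded is not None:
            excluded[e.participant_id] = r.excluded
            tally["unreliable"] += 1

    def survivors():
        return [e for e in estimates if e.participant_id not in excluded]

    def screen_stage(stage: str, value_maps: Dict[str, Dict[str, float]]):
        # value_maps: series label -> {participant_id -> value}
        if not screen:
            return
        for label, mapping in value_maps.items():
            ids = [pid for pid in mapping if pid not in excluded]
            if len(ids) < 3:
                continue
            keep = mad_filter([mapping[pid] for pid in ids], k=mad_k)
            for pid, ok in zip(ids, keep):
                if not ok and pid not in excluded:
                    excluded[pid] = f"{stage} outlier ({label})"
                    tally[stage] += 1

    slope_maps: Dict[str, Dict[str, float]] = {}
    for e in survivors():
        for combo, fit in e.learning_slopes.items():
            slope_maps.setdefault(f"learning/{combo}", {})[e.participant_id] = fit.slope
        if e.new_combo:
            slope_maps.setdefault(f"transfer-new/{e.new_combo}", {})[
                e.participant_id] = e.transfer_slopes[e.new_combo].slope
    screen_stage("slope", slope_maps)

    vp_maps: Dict[str, Dict[str, float]] = {}
    for e in survivors():
        for combo, vp in e.sigma_pi_sq.items():
            if math.isfinite(vp):
                vp_maps.setdefault(combo, {})[e.participant_id] = vp
    screen_stage("sigma_pi_sq", vp_maps)

    pred_maps: Dict[str, Dict[str, float]] = {}
    for e in survivors():
        for baseline, pred in e.predicted_new_slope.items():
            pred_maps.setdefault(baseline, {})[e.participant_id] = pred
    screen_stage("predicted", pred_maps)

    ts_map = {e.participant_id: results[e.participant_id].pooled
              for e in survivors()}
    screen_stage("ts", {"pooled": ts_map})

    included = [e.participant_id for e in survivors()]
    for pid, reason in excluded.items():
        results[pid].excluded = reason
    values = np.array([results[pid].pooled for pid in included], dtype=float)
    q75, q25 = (np.percentile(values, [75, 25]) if values.size
                else (float("nan"), float("nan")))
    return CohortTransfer(
        results=list(results.values()),
        included_ids=included,
        ts_values=values,
        mean_ts=float(values.mean()) if values.size else float("nan"),
        median_ts=float(np.median(values)) if values.size else float("nan"),
        iqr_ts=float(q75 - q25),
        exclusions=tally,
        exclusion_reasons=excluded,
    )


def transfer_to_frame(cohort: CohortTransfer, group: str = "") -> pd.DataFrame:
    """Per-participant metrics in CSV form."""
    rows = []
    for r in cohort.results:
        for baseline, ts in r.per_baseline.items():
            rows.append({"participant_id": r.participant_id, "group": group,
                         "baseline_combo": baseline, "ts": ts,
                         "pooled_ts": r.pooled,
                         "excluded": r.excluded or ""})
        if not r.per_baseline:
            rows.append({"participant_id": r.participant_id, "group": group,
                         "baseline_combo": "", "ts": float("nan"),
                         "pooled_ts": r.pooled, "excluded": r.excluded or ""})
    return pd.DataFrame(rows)
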