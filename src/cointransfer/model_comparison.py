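"""Strategy-model fits and BIC comparison on transfer scores.

Candidate models of the transfer-phase behaviour, all conditioned on the
learning phase only:

``bayes``
    the ideal-transfer reference: the modelled transfer slope equals the
    subject-proxy prediction, so the modelled transfer score is exactly 1
    (no free parameters beyond the shared estimation stage, k = 0).
``linear``
    a per-participant linear mapping from precisions to slopes,
    slope = b0 + b1/sigma_Pi^2 + b2/sigma_Li^2, fitted to the learning
    combos (k = 3).  With two learning combos the system is rank-deficient
    and the minimum-norm least-squares solution is used (flagged in output).
``likelihood_only``
    the b1 = 0 special case: slope depends on likelihood precision alone
    (k = 2); exactly determined by two learning combos.
``exemplar_N5`` / ``exemplar_N20``
    resampling models: the stored learning-phase coin positions are
    resampled (N = 5 or 20) and likelihood-weighted to simulate transfer
    responses, whose refitted slope yields the modelled score (k = 1).

Each model's predicted transfer-new slope is pushed through the transfer
score with the participant's own learned slope and Bayes-predicted slope;
models are ranked by the Gaussian-residual BIC n*ln(RSS/n) + k*ln(n) over
participant-level (measured - modelled) score residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .estimation import DOT_COLUMNS, SubjectEstimates
from .observers import exemplar_estimate_batch
from .task_protocol import PHASE_LEARNING, PHASE_TRANSFER, TaskDesign
from .transfer_metrics import CohortTransfer, UndefinedTransferScore, transfer_score

log = logging.getLogger(__name__)

MODEL_K = {"bayes": 0, "linear": 3, "likelihood_only": 2,
           "exemplar_N5": 1, "exemplar_N20": 1}
DEFAULT_MODELS = ("bayes", "linear", "likelihood_only",
                  "exemplar_N5", "exemplar_N20")


class ModelError(ValueError):
    pass


def fit_linear_mapping(inv_sigma_p2, inv_sigma_l2, slopes,
                       variant: str = "full"):
    """Least-squares coefficients (b0, b1, b2) of the precision-to-slope map.

    ``variant="likelihood_only"`` fixes b1 = 0.  Rank-deficient systems (two
    learning combos against three coefficients) fall back to the minimum-norm
    solution; the returned ``rank_deficient`` flag records it.
    """
    isp = np.asarray(inv_sigma_p2, dtype=float)
    isl = np.asarray(inv_sigma_l2, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if not (isp.shape == isl.shape == s.shape) or s.ndim != 1:
        raise ModelError("feature and slope arrays must be equal-length 1-D")
    if variant == "full":
        a = np.column_stack([np.ones_like(s), isp, isl])
    elif variant == "likelihood_only":
        a = np.column_stack([np.ones_like(s), isl])
    else:
        raise ModelError(f"unknown variant {variant!r}")
    coef, _, rank, _ = np.linalg.lstsq(a, s, rcond=None)
    rank_deficient = rank < a.shape[1]
    if rank_deficient and not getattr(fit_linear_mapping, "_warned", False):
        fit_linear_mapping._warned = True  # warn once per process
        log.warning("linear mapping fit is rank-deficient "
                    "(%d observations for %d coefficients): minimum-norm "
                    "solution used", s.size, a.shape[1])
    if variant == "likelihood_only":
        coef = np.array([coef[0], 0.0, coef[1]])
    return tuple(float(c) for c in coef), rank_deficient


def _linear_predicted_slope(est: SubjectEstimates, variant: str):
    combos = [c for c in est.learning_slopes
              if c in est.sigma_pi_sq and math.isfinite(est.sigma_pi_sq[c])]
    if len(combos) < 2:
        return None
    isp = [1.0 / est.sigma_pi_sq[c] for c in combos]
    isl = [1.0 / est.sigma_li_sq[est.combo_lik[c]] for c in combos]
    s = [est.learning_slopes[c].slope for c in combos]
    (b0, b1, b2), _ = fit_linear_mapping(isp, isl, s, variant=variant)
    # features of the novel combo: the trained prior's proxy and the novel
    # likelihood's proxy
    new_prior = est.combo_prior.get(est.new_combo)
    if new_prior is None and est.new_combo:
        # novel combo never trained; find a trained combo sharing its prior
        for c in combos:
            if est.new_combo.startswith(est.combo_prior[c]):
                new_prior = est.combo_prior[c]
                break
    prior_combo = next((c for c in combos if est.combo_prior[c] == new_prior),
                       None)
    if prior_combo is None or est.new_likelihood not in est.sigma_li_sq:
        return None
    isp_new = 1.0 / est.sigma_pi_sq[prior_combo]
    isl_new = 1.0 / est.sigma_li_sq[est.new_likelihood]
    return b0 + b1 * isp_new + b2 * isl_new


def _exemplar_predicted_slope(est: SubjectEstimates, trials: pd.DataFrame,
                              design: TaskDesign, n_samples: int,
                              rng: np.random.Generator,
                              n_reps: int = 20) -> Optional[float]:
    """Simulate transfer-new responses from resampled learning-phase coin
    positions and return the mean refitted slope over repetitions."""
    learning = trials[trials["phase"] == PHASE_LEARNING]
    memory = learning["coin_x"].to_numpy()
    new = trials[(trials["phase"] == PHASE_TRANSFER)
                 & (trials["novelty"] == "new")].sort_values("trial_index")
    if memory.size == 0 or len(new) < 3:
        return None
    mu_l = new[DOT_COLUMNS].mean(axis=1).to_numpy()
    sigma_w = new["sigma_L"].to_numpy()  # single-dot likelihood dispersion
    slopes = []
    for _ in range(n_reps):
        sim = exemplar_estimate_batch(memory, mu_l, sigma_w, n_samples, rng)
        beta = np.polyfit(mu_l, sim, 1)[0]
        slopes.append(float(beta))
    return float(np.mean(slopes))


def predict_model_ts(model_id: str, est: SubjectEstimates,
                     trials: Optional[pd.DataFrame] = None,
                     design: Optional[TaskDesign] = None,
                     rng: Optional[np.random.Generator] = None,
                     n_reps: int = 20) -> Optional[float]:
    """Pooled modelled transfer score for one participant, or None when the
    model (or the participant's estimation chain) is undefined."""
    if not est.predicted_new_slope:
        return None
    if model_id == "bayes":
        # modelled transfer slope == proxy prediction, score 1 by construction
        return 1.0

    if model_id in ("linear", "likelihood_only"):
        modelled_slope = _linear_predicted_slope(
            est, "full" if model_id == "linear" else "likelihood_only")
    elif model_id in ("exemplar_N5", "exemplar_N20"):
        if trials is None or design is None or rng is None:
            raise ModelError("exemplar models need trials, design and rng")
        n_samples = 5 if model_id == "exemplar_N5" else 20
        modelled_slope = _exemplar_predicted_slope(est, trials, design,
                                                   n_samples, rng,
                                                   n_reps=n_reps)
    else:
        raise ModelError(f"unknown model {model_id!r}")
    if modelled_slope is None:
        return None

    scores = []
    for baseline, predicted in est.predicted_new_slope.items():
        learned = est.learning_slopes[baseline].slope
        try:
            scores.append(transfer_score(modelled_slope, learned, predicted))
        except UndefinedTransferScore:
            continue
    return float(np.mean(scores)) if scores else None


def bic(residuals, k: int) -> float:
    """Gaussian-residual Bayesian Information Criterion.

    n*ln(RSS/n) + k*ln(n); an exact fit (RSS = 0) returns -inf, reported as a
    perfect fit by callers.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n == 0:
        raise ModelError("no residuals")
    rss = float(r @ r)
    if rss == 0.0:
        return float("-inf")
    return n * math.log(rss / n) + k * math.log(n)


@dataclass
class ModelFit:
    model_id: str
    k: int
    n: int
    rss: float
    bic: float
    modelled_ts: Dict[str, float]


def compare_models(trials: pd.DataFrame, estimates: List[SubjectEstimates],
                   cohort: CohortTransfer, design: TaskDesign,
                   rng: np.random.Generator,
                   models=DEFAULT_MODELS, n_reps: int = 20,
                   min_participants: int = 5):
    """Rank strategy models by BIC over participant-level score residuals.

    Only participants surviving the cohort's outlier screening and for whom
    every candidate model yields a defined score enter the comparison (each
    model is judged on the same residual set).  Returns ``(summary, per_ts)``
    DataFrames; the summary is sorted ascending by BIC, so its first row is
    the winning model.
    """
    measured = {r.participant_id: r.pooled for r in cohort.results
                if r.participant_id in cohort.included_ids}
    est_by_id = {e.participant_id: e for e in estimates}
    by_pid = dict(tuple(trials.groupby("participant_id")))

    fits: List[ModelFit] = []
    modelled: Dict[str, Dict[str, float]] = {m: {} for m in models}
    for model_id in models:
        for pid in sorted(measured):
            val = predict_model_ts(model_id, est_by_id[pid],
                                   trials=by_pid.get(pid), design=design,
                                   rng=rng, n_reps=n_reps)
            if val is not None and math.isfinite(val):
                modelled[model_id][pid] = val

    common = sorted(set(measured)
                    & set.intersection(*(set(modelled[m]) for m in models)))
    if len(common) < min_participants:
        raise ModelError(
            f"only {len(common)} participants usable; need {min_participants}")

    for model_id in models:
        resid = np.array([measured[pid] - modelled[model_id][pid]
                          for pid in common])
        fits.append(ModelFit(model_id=model_id, k=MODEL_K[model_id],
                             n=len(common), rss=float(resid @ resid),
                             bic=bic(resid, MODEL_K[model_id]),
                             modelled_ts=modelled[model_id]))

    summary = pd.DataFrame(
        [{"model_id": f.model_id, "k": f.k, "n": f.n, "RSS": f.rss,
          "BIC": f.bic} for f in fits]).sort_values(
              "BIC", kind="stable").reset_index(drop=True)
    summary["delta_BIC"] = summary["BIC"] - summary["BIC"].iloc[0]
    per_ts = pd.DataFrame(
        [{"participant_id": pid, "model_id": m,
          "measured_ts": measured[pid], "modelled_ts": modelled[m][pid]}
         for m in models for pid in common])
    return summary, per_ts
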