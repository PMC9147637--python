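"""Binder / nonbinder classification of probe depletion.

Three statistical routes are implemented, mirroring the assay's design:

1. a frequentist test of the four-group contrast
   D = (NC_mean - blank_mean) - (TC_mean - TCblank_mean)
   using T = D / sqrt(s_NC^2/n_NC + s_blank^2/n_blank + s_TC^2/n_TC +
   s_TCb^2/n_TCb) referred to a Student t distribution with
   Welch-Satterthwaite degrees of freedom
   df = (sum of s^2/n terms)^2 / sum of (s^2/n)^2 / (n - 1);
2. a Bayesian normal model with Gaussian priors on the four group means and
   Gamma priors on the precisions, sampled by Gibbs; a chemical is a binder
   when the lower bound of the equal-tailed credible interval on D exceeds 0;
3. a simple screening rule: binder when the percent depletion exceeds a
   factor (default 5) times the SD of the per-well NC percent depletions.

Assay-level calls are combined into run calls (a run is positive if any of
the three read-outs is positive) and run calls into chemical calls by
majority vote across repeated runs, with ties reported as inconclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .depletion import DepletionEstimate, GroupSummary, tc_depletion
from .errors import (
    DegenerateVarianceError,
    InsufficientReplicatesError,
    NotEvaluableError,
)


class Call(str, Enum):
    BINDER = "binder"
    NONBINDER = "nonbinder"
    INCONCLUSIVE = "inconclusive"
    NOT_AVAILABLE = "not_available"


@dataclass
class MCMCConfig:
    iterations: int = 20_000
    burn_in: int = 5_000
    chains: int = 2
    seed: int = 0
    prior_mean_sd_scale: float = 1e3  # prior SD on means = scale x signal scale
    gamma_shape: float = 0.001  # vague Gamma prior on precisions
    gamma_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


@dataclass
class InferenceConfig:
    """Knobs of the classification step.

    alpha is the tolerated type-I error (binder call on a true nonbinder);
    the credible-interval level of the Bayesian route is 1 - alpha,
    equal-tailed, with the binder rule applied to the lower endpoint.
    """

    alpha: float = 0.005
    sidedness: str = "one_sided_greater"  # or "two_sided"
    ksd_factor: float = 5.0
    borderline_pos_pct: float = 10.0  # binder below this pct -> potential type I
    borderline_neg_pct: float = 3.0  # nonbinder above this pct -> potential type II
    neg_depletion_anomaly_pct: float = -20.0  # below this -> inconclusive
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.sidedness not in ("one_sided_greater", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class AssayCall:
    call: Call
    pct_depletion: Optional[float] = None
    estimate: Optional[DepletionEstimate] = None
    borderline_type1: bool = False  # positive with < 10 % depletion
    borderline_type2: bool = False  # negative with > 3 % depletion
    anomalous_negative: bool = False  # large signal gain; forces inconclusive
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# frequentist route


def welch_t(groups: Mapping) -> tuple[float, float]:
    """T statistic and Welch-Satterthwaite df for the four-group contrast.

    Expects the slot-resolved view: keys ``blank``, ``nc``, ``tc``,
    ``tc_blank``.  The variance-of-mean terms divide each sample variance by
    the number of included wells (15/8/4/3 on a full plate).
    """
    parts = []
    for key in ("nc", "blank", "tc", "tc_blank"):
        g: GroupSummary = groups[key]
        if g.n < 2 or g.sd is None:
            raise InsufficientReplicatesError(
                f"group {key} needs >= 2 wells for inference, has {g.n}"
            )
        parts.append((g.sd**2 / g.n, g.n))
    var_sum = sum(v for v, _ in parts)
    if var_sum == 0.0:
        raise DegenerateVarianceError("all group variances are zero")
    d = (groups["nc"].mean - groups["blank"].mean) - (
        groups["tc"].mean - groups["tc_blank"].mean
    )
    t = d / math.sqrt(var_sum)
    df = var_sum**2 / sum(v**2 / (n - 1) for v, n in parts)
    return t, df


def _slot_view(groups: Mapping, slot: int) -> dict:
    return {
        "blank": groups["blank"],
        "nc": groups["nc"],
        "tc": groups[("tc", slot)],
        "tc_blank": groups[("tc_blank", slot)],
    }


def frequentist_call(groups: Mapping, cfg: InferenceConfig, slot: int = None) -> AssayCall:
    """Classify one chemical slot with the t-based route."""
    view = _slot_view(groups, slot) if slot is not None else dict(groups)
    t, df = welch_t(view)
    if cfg.sidedness == "one_sided_greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    est = tc_depletion(groups, slot) if slot is not None else _depletion_of(view)
    est.T, est.df, est.p_value, est.method = t, df, p, "frequentist"
    # CI on the percent-depletion scale from the t quantile
    window = view["nc"].mean - view["blank"].mean
    se_pct = 100.0 * math.sqrt(sum(g.sd**2 / g.n for g in view.values())) / window
    q = stats.t.ppf(1 - cfg.alpha / 2, df)
    est.ci_low = est.pct_depletion - q * se_pct
    est.ci_high = est.pct_depletion + q * se_pct
    call = Call.BINDER if p < cfg.alpha else Call.NONBINDER
    return flag_borderline(
        AssayCall(call=call, pct_depletion=est.pct_depletion, estimate=est), cfg
    )


def _depletion_of(view: Mapping) -> DepletionEstimate:
    window = view["nc"].mean - view["blank"].mean
    d = window - (view["tc"].mean - view["tc_blank"].mean)
    return DepletionEstimate(depletion_abs=d, pct_depletion=100.0 * d / window)


# ---------------------------------------------------------------------------
# Bayesian route (normal-gamma Gibbs sampler)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an (n_chains, n_draws) array."""
    n = chains.shape[1] // 2
    segs = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _gibbs_group_means(
    values: Sequence[np.ndarray], mcmc: MCMCConfig, rng: np.random.Generator
) -> np.ndarray:
    """Posterior draws of the group means.

    Returns an array of shape (n_groups, chains, kept_draws).  Each group is
    modelled as iid Gaussian with a vague Gaussian prior on its mean and a
    Gamma(shape, rate) prior on its precision; the two full conditionals are
    conjugate, so the sampler alternates exact draws.  Groups and chains are
    updated in a single vectorized step per iteration.

    A Gamma(eps, eps) prior is only uninformative when the residual scale is
    O(1), so the data are standardized by the pooled within-group SD before
    sampling and the mean draws mapped back; this makes the posterior (and
    the binder call) invariant to the instrument's signal units.
    """
    ys = [np.asarray(v, dtype=float) for v in values]
    pooled = float(np.sqrt(np.mean([y.var(ddof=1) for y in ys])))
    unit = pooled if pooled > 0 else max(float(np.max(np.abs(np.concatenate(ys)))), 1.0)
    ys = [y / unit for y in ys]
    n = np.array([y.size for y in ys], dtype=float)[:, None]
    ybar = np.array([y.mean() for y in ys])[:, None]
    ss = np.array([((y - y.mean()) ** 2).sum() for y in ys])[:, None]
    scale = max(float(np.max(np.abs(ybar))), 1.0)
    prior_var = (mcmc.prior_mean_sd_scale * scale) ** 2

    shape_post = mcmc.gamma_shape + n / 2.0
    g, c = len(ys), mcmc.chains
    mu = np.tile(ybar, (1, c))
    kept = np.empty((g, c, mcmc.iterations - mcmc.burn_in))
    for it in range(mcmc.iterations):
        # tau | mu : Gamma(shape + n/2, rate + sum (y - mu)^2 / 2)
        resid = ss + n * (mu - ybar) ** 2
        tau = rng.gamma(shape_post, 1.0 / (mcmc.gamma_rate + resid / 2.0))
        # mu | tau : normal with precision 1/prior_var + n tau
        prec = 1.0 / prior_var + n * tau
        mean = (n * tau * ybar) / prec  # prior mean 0 contributes ~nothing
        mu = rng.normal(mean, 1.0 / np.sqrt(prec))
        if it >= mcmc.burn_in:
            kept[:, :, it - mcmc.burn_in] = mu
    return kept * unit


def bayesian_call(
    group_values: Mapping[str, Sequence[float]],
    cfg: InferenceConfig,
    seed: Optional[int] = None,
) -> AssayCall:
    """Classify one chemical from raw (post-QC) well values.

    ``group_values`` maps ``blank`` / ``nc`` / ``tc`` / ``tc_blank`` to their
    well values.  The binder rule is: lower bound of the equal-tailed
    (1 - alpha) credible interval on the absolute depletion > 0.
    """
    order = ("nc", "blank", "tc", "tc_blank")
    values = [np.asarray(group_values[k], dtype=float) for k in order]
    for k, v in zip(order, values):
        if v.size < 2:
            raise InsufficientReplicatesError(f"group {k} needs >= 2 wells, has {v.size}")
    rng = np.random.default_rng(cfg.mcmc.seed if seed is None else seed)
    draws = _gibbs_group_means(values, cfg.mcmc, rng)  # (4, chains, draws)
    mu_nc, mu_blank, mu_tc, mu_tcb = draws
    depletion = (mu_nc - mu_blank) - (mu_tc - mu_tcb)
    window = mu_nc - mu_blank
    pct = 100.0 * depletion / window

    rhat = _split_rhat(depletion)
    flat_d = depletion.reshape(-1)
    flat_pct = pct.reshape(-1)
    lo_q, hi_q = cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0
    d_lo, d_hi = np.quantile(flat_d, [lo_q, hi_q])
    pct_lo, pct_hi = np.quantile(flat_pct, [lo_q, hi_q])

    est = DepletionEstimate(
        depletion_abs=float(flat_d.mean()),
        pct_depletion=float(flat_pct.mean()),
        ci_low=float(pct_lo),
        ci_high=float(pct_hi),
        method="bayesian",
    )
    call = Call.BINDER if d_lo > 0 else Call.NONBINDER
    diagnostics = {"split_rhat": rhat, "depletion_ci": (float(d_lo), float(d_hi))}
    if rhat > 1.05:
        diagnostics["convergence_warning"] = True
    return flag_borderline(
        AssayCall(
            call=call,
            pct_depletion=est.pct_depletion,
            estimate=est,
            diagnostics=diagnostics,
        ),
        cfg,
    )


# ---------------------------------------------------------------------------
# k x SD screening rule


def ksd_call(
    pct_depletion: float,
    nc_pct_sd: float,
    cfg: InferenceConfig,
    depletion_abs: Optional[float] = None,
) -> AssayCall:
    """Binder iff percent depletion strictly exceeds factor x NC percent SD."""
    threshold = cfg.ksd_factor * nc_pct_sd
    call = Call.BINDER if pct_depletion > threshold else Call.NONBINDER
    est = DepletionEstimate(
        depletion_abs=0.0 if depletion_abs is None else depletion_abs,
        pct_depletion=pct_depletion,
        method="ksd",
    )
    return flag_borderline(
        AssayCall(
            call=call,
            pct_depletion=pct_depletion,
            estimate=est,
            diagnostics={"threshold_pct": threshold},
        ),
        cfg,
    )


# ---------------------------------------------------------------------------
# borderline / anomaly flags and call combination


def flag_borderline(call: AssayCall, cfg: InferenceConfig) -> AssayCall:
    """Attach borderline flags; large signal gain forces an inconclusive call.

    A positive below 10 % depletion is a potential type I error; a negative
    above 3 % depletion is a potential type II error; a percent depletion
    below the anomaly threshold (default -20 %) indicates a signal gain
    (e.g. coloured reaction products) and the result is not interpretable.
    """
    if call.pct_depletion is None or call.call not in (Call.BINDER, Call.NONBINDER):
        return call
    pct = call.pct_depletion
    if pct < cfg.neg_depletion_anomaly_pct:
        return replace(call, call=Call.INCONCLUSIVE, anomalous_negative=True,
                       borderline_type1=False, borderline_type2=False)
    t1 = call.call is Call.BINDER and pct < cfg.borderline_pos_pct
    t2 = call.call is Call.NONBINDER and pct > cfg.borderline_neg_pct
    return replace(call, borderline_type1=t1, borderline_type2=t2)


def run_call(modality_calls: Mapping[str, AssayCall]) -> Call:
    """Combine the (up to three) assay calls of one run.

    Positive if any read-out is positive.  A clean negative requires at
    least one conclusive negative and no inconclusive/anomalous read-out;
    otherwise the run is inconclusive.
    """
    calls = [c.call for c in modality_calls.values()]
    if all(c is Call.NOT_AVAILABLE for c in calls):
        raise NotEvaluableError("all assay read-outs unavailable for this run")
    if any(c is Call.BINDER for c in calls):
        return Call.BINDER
    if any(c is Call.INCONCLUSIVE for c in calls):
        return Call.INCONCLUSIVE
    return Call.NONBINDER  # >= 1 nonbinder, rest NA


def chemical_call(run_calls: Sequence[Call]) -> tuple[Call, int]:
    """Majority vote over runs; inconclusive runs drop out of the tally.

    Returns (call, number of evaluable runs).  An exact binder/nonbinder
    tie is inconclusive.
    """
    if not run_calls:
        raise NotEvaluableError("no runs to combine")
    pos = sum(1 for c in run_calls if c is Call.BINDER)
    neg = sum(1 for c in run_calls if c is Call.NONBINDER)
    if pos + neg == 0:
        raise NotEvaluableError("no conclusive runs to combine")
    if pos > neg:
        return Call.BINDER, pos + neg
    if neg > pos:
        return Call.NONBINDER, pos + neg
    return Call.INCONCLUSIVE, pos + neg
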