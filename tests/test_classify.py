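import math

import numpy as np
import pytest
from scipy import stats

from easa96.classify import (
    AssayCall,
    Call,
    InferenceConfig,
    MCMCConfig,
    bayesian_call,
    chemical_call,
    flag_borderline,
    frequentist_call,
    ksd_call,
    run_call,
    welch_t,
)
from easa96.depletion import GroupSummary
from easa96.errors import (
    DegenerateVarianceError,
    InsufficientReplicatesError,
    NotEvaluableError,
)

FAST_MCMC = MCMCConfig(iterations=4000, burn_in=1000)


def groups_from(nc, blank, tc, tcb):
    return {
        "nc": GroupSummary.from_values(nc),
        "blank": GroupSummary.from_values(blank),
        "tc": GroupSummary.from_values(tc),
        "tc_blank": GroupSummary.from_values(tcb),
    }


def summaries(means, sds, ns=(15, 8, 4, 3)):
    keys = ("nc", "blank", "tc", "tc_blank")
    return {
        k: GroupSummary(mean=m, sd=s, n=n) for k, m, s, n in zip(keys, means, sds, ns)
    }


# ---------------------------------------------------------------------------
# Welch T and Satterthwaite df


def printed_formulas(means, sds, ns):
    """Brute-force evaluation of the printed T and df expressions."""
    nc, blank, tc, tcb = means
    s = sds
    u = s[0] ** 2 / ns[0] + s[1] ** 2 / ns[1] + s[2] ** 2 / ns[2] + s[3] ** 2 / ns[3]
    T = ((nc - blank) - (tc - tcb)) / math.sqrt(u)
    df = u**2 / (
        (s[0] ** 2 / ns[0]) ** 2 / (ns[0] - 1)
        + (s[1] ** 2 / ns[1]) ** 2 / (ns[1] - 1)
        + (s[2] ** 2 / ns[2]) ** 2 / (ns[2] - 1)
        + (s[3] ** 2 / ns[3]) ** 2 / (ns[3] - 1)
    )
    return T, df


def test_welch_matches_brute_force_on_random_inputs():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        means = rng.uniform(0.05, 2.0, 4)
        sds = rng.uniform(1e-4, 0.3, 4)
        ns = rng.integers(2, 30, 4)
        g = summaries(means, sds, ns)
        t, df = welch_t(g)
        t_ref, df_ref = printed_formulas(means, sds, ns)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == pytest.approx(df_ref, rel=1e-12)


def test_welch_zero_depletion_symmetric_variances():
    g = summaries((1.1, 0.1, 1.1, 0.1), (0.01, 0.01, 0.01, 0.01))
    t, df = welch_t(g)
    assert t == 0.0
    assert df >= 1.0


def test_welch_two_group_limit_matches_scipy():
    """When the blank groups carry ~no variance the statistic reduces to a
    classical two-sample Welch test between NC and TC wells."""
    rng = np.random.default_rng(5)
    nc = rng.normal(1.1, 0.02, 15)
    tc = rng.normal(0.9, 0.05, 4)
    big = 10_000
    g = {
        "nc": GroupSummary.from_values(nc),
        "tc": GroupSummary.from_values(tc),
        "blank": GroupSummary(mean=0.0, sd=1e-12, n=big),
        "tc_blank": GroupSummary(mean=0.0, sd=1e-12, n=big),
    }
    t, df = welch_t(g)
    ref = stats.ttest_ind(nc, tc, equal_var=False)
    assert t == pytest.approx(ref.statistic, rel=1e-6)
    assert df == pytest.approx(ref.df, rel=1e-6)


def test_welch_error_conditions():
    with pytest.raises(InsufficientReplicatesError):
        welch_t(summaries((1, 0, 1, 0), (0.1, 0.1, 0.1, None), ns=(15, 8, 4, 1)))
    with pytest.raises(DegenerateVarianceError):
        welch_t(summaries((1, 0, 1, 0), (0.0, 0.0, 0.0, 0.0)))


# ---------------------------------------------------------------------------
# frequentist calls


def test_strong_depletion_is_binder_at_any_alpha():
    g = summaries((1.1, 0.1, 0.55, 0.05), (0.01, 0.005, 0.01, 0.005))
    for alpha in (0.05, 0.01, 0.005, 0.001):
        call = frequentist_call(g, InferenceConfig(alpha=alpha))
        assert call.call is Call.BINDER
        assert call.estimate.p_value < alpha


def test_zero_depletion_is_nonbinder():
    g = summaries((1.1, 0.1, 1.1, 0.1), (0.012, 0.002, 0.012, 0.002))
    call = frequentist_call(g, InferenceConfig())
    assert call.call is Call.NONBINDER
    assert call.pct_depletion == pytest.approx(0.0)


def test_monotone_in_depletion():
    """Raising depletion with variances fixed never un-calls a binder."""
    cfg = InferenceConfig(alpha=0.005)
    previous_binder = False
    for pct in np.linspace(0, 60, 30):
        tc_mean = 0.1 + (1 - pct / 100.0)
        g = summaries((1.1, 0.1, tc_mean, 0.1), (0.013, 0.002, 0.013, 0.002))
        is_binder = frequentist_call(g, cfg).call is Call.BINDER
        assert is_binder or not previous_binder
        previous_binder = previous_binder or is_binder
    assert previous_binder  # strong depletion did get called


def test_alpha_monotonicity_on_fixed_dataset():
    rng = np.random.default_rng(21)
    dataset = []
    for _ in range(300):
        pct = rng.uniform(0, 30)
        tc_mean = 0.1 + (1 - pct / 100.0)
        dataset.append(
            summaries(
                (1.1, 0.1, tc_mean + rng.normal(0, 0.01), 0.1),
                (0.013, 0.002, 0.013, 0.002),
            )
        )
    counts = []
    for alpha in (0.05, 0.01, 0.005, 0.001):
        cfg = InferenceConfig(alpha=alpha)
        counts.append(
            sum(frequentist_call(g, cfg).call is Call.BINDER for g in dataset)
        )
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# k x SD rule


@pytest.mark.parametrize(
    "pct, nc_sd, expected",
    [
        (10.0, 1.3, Call.BINDER),  # 10 > 5 x 1.3
        (0.0, 1.3, Call.NONBINDER),
        (6.5, 1.3, Call.NONBINDER),  # exact tie -> strict inequality
    ],
)
def test_ksd_rule(pct, nc_sd, expected):
    call = ksd_call(pct, nc_sd, InferenceConfig(ksd_factor=5.0))
    assert call.call is expected


# ---------------------------------------------------------------------------
# borderline / anomaly flags


@pytest.mark.parametrize(
    "call_in, pct, t1, t2, final",
    [
        (Call.BINDER, 7.0, True, False, Call.BINDER),
        (Call.BINDER, 50.0, False, False, Call.BINDER),
        (Call.NONBINDER, 5.0, False, True, Call.NONBINDER),
        (Call.NONBINDER, 1.0, False, False, Call.NONBINDER),
        (Call.NONBINDER, -176.0, False, False, Call.INCONCLUSIVE),
    ],
)
def test_borderline_flags(call_in, pct, t1, t2, final):
    cfg = InferenceConfig()
    out = flag_borderline(AssayCall(call=call_in, pct_depletion=pct), cfg)
    assert out.call is final
    assert out.borderline_type1 is t1
    assert out.borderline_type2 is t2
    assert out.anomalous_negative is (final is Call.INCONCLUSIVE)


# ---------------------------------------------------------------------------
# run- and chemical-level combination


def _ac(call):
    return AssayCall(call=call, pct_depletion=0.0)


@pytest.mark.parametrize(
    "calls, expected",
    [
        ((Call.NONBINDER, Call.NONBINDER, Call.BINDER), Call.BINDER),
        ((Call.NONBINDER, Call.NONBINDER, Call.NONBINDER), Call.NONBINDER),
        ((Call.NONBINDER, Call.INCONCLUSIVE, Call.NONBINDER), Call.INCONCLUSIVE),
        ((Call.BINDER, Call.INCONCLUSIVE, Call.NOT_AVAILABLE), Call.BINDER),
        ((Call.NONBINDER, Call.NOT_AVAILABLE, Call.NOT_AVAILABLE), Call.NONBINDER),
    ],
)
def test_run_call_combination(calls, expected):
    modal = {m: _ac(c) for m, c in zip(("nbt", "pda_a", "pda_f"), calls)}
    assert run_call(modal) is expected


def test_run_call_all_unavailable_raises():
    modal = {m: _ac(Call.NOT_AVAILABLE) for m in ("a", "b", "c")}
    with pytest.raises(NotEvaluableError):
        run_call(modal)


@pytest.mark.parametrize(
    "runs, expected, n_eval",
    [
        ([Call.BINDER], Call.BINDER, 1),
        ([Call.BINDER, Call.NONBINDER, Call.BINDER, Call.NONBINDER], Call.INCONCLUSIVE, 4),
        ([Call.BINDER, Call.BINDER, Call.NONBINDER], Call.BINDER, 3),
        ([Call.INCONCLUSIVE, Call.NONBINDER], Call.NONBINDER, 1),
    ],
)
def test_chemical_call_majority(runs, expected, n_eval):
    call, n = chemical_call(runs)
    assert call is expected
    assert n == n_eval


def test_chemical_call_requires_conclusive_run():
    with pytest.raises(NotEvaluableError):
        chemical_call([Call.INCONCLUSIVE, Call.INCONCLUSIVE])
    with pytest.raises(NotEvaluableError):
        chemical_call([])


# ---------------------------------------------------------------------------
# Bayesian route


def _draw_groups(rng, true_pct, cv=0.012, blank=0.1, nc=1.1):
    tcm = blank + (1 - true_pct / 100.0) * (nc - blank)
    return {
        "nc": rng.normal(nc, cv * nc, 15),
        "blank": rng.normal(blank, cv * blank, 8),
        "tc": rng.normal(tcm, cv * tcm, 4),
        "tc_blank": rng.normal(blank, cv * blank, 3),
    }


def test_bayesian_separated_groups_recover_truth():
    cfg = InferenceConfig(alpha=0.005, mcmc=FAST_MCMC)
    rng = np.random.default_rng(31)
    errors = []
    for i in range(10):
        call = bayesian_call(_draw_groups(rng, 50.0, cv=0.01), cfg, seed=i)
        assert call.call is Call.BINDER
        errors.append(call.pct_depletion - 50.0)
    assert max(abs(e) for e in errors) < 2.0


def test_bayesian_null_covers_zero():
    cfg = InferenceConfig(alpha=0.05, mcmc=FAST_MCMC)
    rng = np.random.default_rng(32)
    call = bayesian_call(_draw_groups(rng, 0.0), cfg, seed=0)
    assert call.call is Call.NONBINDER
    lo, hi = call.diagnostics["depletion_ci"]
    assert lo < 0 < hi
    assert call.diagnostics["split_rhat"] < 1.05


def test_bayesian_reproducible_for_fixed_seed():
    cfg = InferenceConfig(mcmc=FAST_MCMC)
    rng = np.random.default_rng(33)
    vals = _draw_groups(rng, 25.0)
    a = bayesian_call(vals, cfg, seed=7)
    b = bayesian_call(vals, cfg, seed=7)
    assert a.pct_depletion == b.pct_depletion
    assert a.diagnostics["depletion_ci"] == b.diagnostics["depletion_ci"]


def test_bayesian_scale_invariant_call():
    """The binder decision does not depend on the instrument's units."""
    cfg = InferenceConfig(mcmc=FAST_MCMC)
    rng = np.random.default_rng(34)
    vals = _draw_groups(rng, 30.0)
    scaled = {k: np.asarray(v) * 5e4 for k, v in vals.items()}
    a = bayesian_call(vals, cfg, seed=9)
    b = bayesian_call(scaled, cfg, seed=9)
    assert a.call is b.call
    assert a.pct_depletion == pytest.approx(b.pct_depletion, rel=1e-9)
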