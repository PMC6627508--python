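import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from metacohort import (hedges_g, cox_association, pearson_fisherz,
                        standardize_expression, smd_table, cox_table)
from metacohort.effects import DegenerateInputError, CoxDivergenceError


# ---------------------------------------------------------------- Hedges g

def _hedges_oracle(x1, x2):
    """Textbook formula, written independently of the implementation."""
    n1, n2 = len(x1), len(x2)
    s1 = sum((v - sum(x1) / n1) ** 2 for v in x1) / (n1 - 1)
    s2 = sum((v - sum(x2) / n2) ** 2 for v in x2) / (n2 - 1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    d = (sum(x1) / n1 - sum(x2) / n2) / sp ** 0.5
    J = 1 - 3 / (4 * (n1 + n2 - 2) - 1)
    g = J * d
    return g, (n1 + n2) / (n1 * n2) + g ** 2 / (2 * (n1 + n2))


def test_hedges_matches_textbook_formula():
    est = hedges_g([3, 4, 5, 6], [1, 2, 3, 4])
    g, v = _hedges_oracle([3, 4, 5, 6], [1, 2, 3, 4])
    assert est.estimate == pytest.approx(g, abs=1e-12)
    assert est.variance == pytest.approx(v, abs=1e-12)


def test_hedges_null_and_antisymmetry():
    est = hedges_g([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
    assert est.estimate == pytest.approx(0.0, abs=1e-12)
    assert est.variance == pytest.approx(6 / 9, abs=1e-12)
    a = hedges_g([3, 4, 5, 9], [1, 2, 3, 4])
    b = hedges_g([1, 2, 3, 4], [3, 4, 5, 9])
    assert a.estimate == pytest.approx(-b.estimate, abs=1e-12)
    assert a.variance == pytest.approx(b.variance, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(a=st.floats(0.1, 50), b=st.floats(-100, 100),
       seed=st.integers(0, 10_000))
def test_hedges_invariant_under_common_affine_map(a, b, seed):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(1, 1, 8), rng.normal(0, 1, 10)
    g0 = hedges_g(x1, x2).estimate
    g1 = hedges_g(a * x1 + b, a * x2 + b).estimate
    assert g1 == pytest.approx(g0, rel=1e-9, abs=1e-9)


def test_hedges_degenerate_inputs():
    with pytest.raises(DegenerateInputError, match="zero pooled SD"):
        hedges_g([2.0, 2.0, 2.0], [2.0, 2.0], gene_id="flatgene")
    with pytest.raises(DegenerateInputError):
        hedges_g([1.0], [1.0, 2.0])


def test_smd_table_matches_scalar_and_masks(tiny_bundle):
    tab = smd_table(tiny_bundle).set_index("gene_id")
    assert "gConst" not in tab.index  # zero pooled SD masked
    ref = hedges_g(tiny_bundle.expr.loc["gA", ["s0", "s1", "s2", "s3"]],
                   tiny_bundle.expr.loc["gA", ["s4", "s5"]])
    assert tab.loc["gA", "estimate"] == pytest.approx(ref.estimate, abs=1e-12)
    assert tab.loc["gA", "variance"] == pytest.approx(ref.variance, abs=1e-12)


# ---------------------------------------------------------- standardization

def test_standardize_definition_and_idempotence(signal_cohort):
    _, bundles, _ = signal_cohort
    z1 = standardize_expression(bundles[0], scope="tumor_only")
    sub = z1.expr.loc[:, z1.tumor_ids()]
    assert np.abs(sub.mean(axis=1)).max() < 1e-12
    assert np.abs(sub.std(axis=1, ddof=1) - 1).max() < 1e-12
    z2 = standardize_expression(z1, scope="tumor_only")
    assert np.abs(z2.expr - z1.expr).to_numpy().max() < 1e-12


def test_standardize_masks_constant_gene(tiny_bundle):
    z = standardize_expression(tiny_bundle, scope="all")
    assert "gConst" not in z.genes
    assert {"gA", "gB"} <= set(z.genes)


# ------------------------------------------------------------------- Cox

def _efron_partial_loglik(beta, z, time, event):
    """Hand-written Efron partial likelihood, brute-force style."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = [i for i in range(len(z)) if time[i] == t and event[i] == 1]
        R = [i for i in range(len(z)) if time[i] >= t]
        d = len(D)
        ll += sum(beta * z[i] for i in D)
        sR = sum(np.exp(beta * z[i]) for i in R)
        sD = sum(np.exp(beta * z[i]) for i in D)
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


def test_cox_matches_bruteforce_maximizer():
    z = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
    t = np.arange(1.0, 7.0)
    e = np.ones(6)
    est = cox_association(z, t, e)
    res = optimize.minimize_scalar(
        lambda b: -_efron_partial_loglik(b, z, t, e),
        bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10})
    assert est.estimate == pytest.approx(res.x, abs=1e-6)


def test_cox_matches_bruteforce_with_ties():
    z = np.array([0.5, -0.3, 1.2, -1.0, 0.1, 0.9, -0.7, 0.2])
    t = np.array([2.0, 2.0, 3.0, 3.0, 3.0, 5.0, 7.0, 7.0])
    e = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    est = cox_association(z, t, e)
    res = optimize.minimize_scalar(
        lambda b: -_efron_partial_loglik(b, z, t, e),
        bounds=(-5, 5), method="bounded", options={"xatol": 1e-10})
    assert est.estimate == pytest.approx(res.x, abs=1e-6)


def test_cox_agrees_with_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    n = 120
    z = rng.standard_normal(n)
    t = np.round(rng.exponential(1 / (0.1 * np.exp(0.4 * z))), 1) + 0.05
    e = (rng.random(n) > 0.3).astype(float)
    est = cox_association(z, t, e)
    cph = lifelines.CoxPHFitter().fit(
        pd.DataFrame({"z": z, "t": t, "e": e}), "t", "e")
    assert est.estimate == pytest.approx(cph.params_["z"], abs=1e-6)
    assert est.variance == pytest.approx(cph.variance_matrix_.iloc[0, 0],
                                         rel=1e-5)


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.01, 100), seed=st.integers(0, 1000))
def test_cox_invariant_to_time_rescaling(scale, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(30)
    t = rng.exponential(10, 30) + 0.01
    e = (rng.random(30) > 0.3).astype(float)
    if e.sum() < 2:
        return
    a = cox_association(z, t, e)
    b = cox_association(z, t * scale, e)
    assert a.estimate == pytest.approx(b.estimate, rel=1e-8, abs=1e-10)


def test_cox_degenerate_inputs():
    t = np.arange(1.0, 7.0)
    with pytest.raises(DegenerateInputError, match="constant"):
        cox_association(np.ones(6), t, np.ones(6))
    with pytest.raises(DegenerateInputError, match="events"):
        cox_association(np.arange(6.0), t, np.zeros(6))


def test_cox_separation_flagged():
    # expression perfectly orders the event times: no finite maximizer
    z = np.array([3.0, 2.5, 2.0, -2.0, -2.5, -3.0])
    t = np.array([1.0, 2.0, 3.0, 50.0, 60.0, 70.0])
    e = np.ones(6)
    with pytest.raises(CoxDivergenceError):
        cox_association(z, t, e)


def test_cox_table_matches_scalar(signal_cohort):
    _, bundles, _ = signal_cohort
    b = bundles[0]
    tab = cox_table(b).set_index("gene_id")
    ids = b.survival_ids()
    x = b.expr.loc["G000", ids].to_numpy()
    zx = (x - x.mean()) / x.std(ddof=1)
    ref = cox_association(zx,
                          pd.to_numeric(b.samples.loc[ids, "os_time"]),
                          pd.to_numeric(b.samples.loc[ids, "os_event"]))
    assert tab.loc["G000", "estimate"] == pytest.approx(ref.estimate,
                                                        abs=1e-8)


# --------------------------------------------------------------- Fisher z

def test_fisherz_clamps_perfect_correlation():
    x = np.arange(10.0)
    est = pearson_fisherz(x, x)
    assert np.isfinite(est.estimate) and est.estimate > 10
    assert np.tanh(est.estimate) > 0.999999


def test_fisherz_sign_and_variance():
    rng = np.random.default_rng(1)
    x = np.arange(20.0)
    est = pearson_fisherz(x, -x + rng.normal(0, 0.1, 20))
    assert est.estimate < 0
    assert est.variance == pytest.approx(1 / 17)


def test_fisherz_sampling_variance_matches_theory():
    # atanh(r) at n=10 has variance ~ 1/(n-3) = 1/7 regardless of rho
    rng = np.random.default_rng(2)
    rho, n, reps = 0.6, 10, 10_000
    x = rng.standard_normal((reps, n))
    y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal((reps, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
    v = np.arctanh(r).var(ddof=1)
    assert abs(v - 1 / 7) / (1 / 7) < 0.10


def test_fisherz_rejects_constant_and_short():
    with pytest.raises(DegenerateInputError):
        pearson_fisherz(np.ones(10), np.arange(10.0))
    with pytest.raises(DegenerateInputError):
        pearson_fisherz(np.arange(3.0), np.arange(3.0))


def test_smd_z_calibrated_on_null_genes(null_cohort):
    # hedges_g / sqrt(var) ~ N(0,1) on null genes: type-I near 0.05
    _, bundles, _ = null_cohort
    est = pd.concat([smd_table(b) for b in bundles], ignore_index=True)
    z = est["estimate"] / np.sqrt(est["variance"])
    reject = (np.abs(z) > 1.96).mean()
    assert 0.035 <= reject <= 0.065
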