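import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from oracles import ols_normal_equations
from pondnet.stats import (
    CommunityMatrix,
    abundance,
    fit_glm,
    hellinger,
    predictor_correlation,
    richness,
    run_model_battery,
    screen_uninformative,
    shannon,
    tb_rda,
    wilcoxon_rank_sum,
)
from pondnet.synthetic import CommunityConfig, generate_community, generate_site_metrics


def _cm(counts, suborders=None):
    counts = pd.DataFrame(counts)
    counts.columns = [f"sp{i}" for i in range(counts.shape[1])]
    if suborders is None:
        suborders = ["Anisoptera"] * counts.shape[1]
    return CommunityMatrix(counts, pd.Series(suborders, index=counts.columns))


# ------------------------------------------------------------- responses


def test_abundance_richness_shannon_worked_examples():
    cm = _cm([[2, 0, 7], [0, 0, 0], [10, 10, 10], [5, 0, 0], [1, 2, 3]])
    assert abundance(cm, "Anisoptera").tolist() == [9, 0, 30, 5, 6]
    assert richness(cm, "Anisoptera").tolist() == [2, 0, 3, 1, 3]
    h = shannon(cm, "Anisoptera")
    assert h.iloc[2] == pytest.approx(np.log(3))
    assert h.iloc[3] == 0.0
    # direct -sum p ln p for (1,2,3)
    p = np.array([1, 2, 3]) / 6
    assert h.iloc[4] == pytest.approx(float(-(p * np.log(p)).sum()))
    assert h.iloc[4] == pytest.approx(1.0114, abs=1e-4)


def test_responses_match_brute_force(rng):
    counts = rng.integers(0, 20, size=(5, 6))
    sub = ["Anisoptera"] * 4 + ["Zygoptera"] * 2
    cm = _cm(counts, sub)
    for i in range(5):
        assert abundance(cm, "Anisoptera").iloc[i] == sum(counts[i, :4])
        assert richness(cm, "Zygoptera").iloc[i] == sum(1 for v in counts[i, 4:] if v > 0)


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=8))
def test_shannon_bounded_by_log_richness(row):
    cm = _cm([row])
    h = shannon(cm, "Anisoptera").iloc[0]
    s = richness(cm, "Anisoptera").iloc[0]
    assert h <= np.log(s) + 1e-12 if s > 0 else h == 0.0
    if s > 0 and len(set(v for v in row if v > 0)) == 1:
        assert h == pytest.approx(np.log(s))


# ------------------------------------------------------------------ GLM


def test_fit_glm_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_glm(2 * x, x)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_glm_matches_normal_equations():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 5.0])
    slope, intercept, r2 = ols_normal_equations(x, y)
    fit = fit_glm(y, x)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)
    assert fit.slope == pytest.approx(1.1)  # hand-computed


def test_fit_glm_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="zero variance"):
        fit_glm([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        fit_glm([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="non-finite"):
        fit_glm([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


def test_null_slope_coverage_calibration():
    """Slope CI covers 0 in about 95% of null replicates (n=200)."""
    rng = np.random.default_rng(42)
    covered = 0
    for _ in range(100):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        covered += fit_glm(y, x).p_value >= 0.05
    assert covered >= 88


# ------------------------------------------------------------ screening


def test_screening_drops_zero_gain():
    assert screen_uninformative(-100.0, -100.0)["decision"] == "drop"
    assert screen_uninformative(-97.0, -100.0)["decision"] == "keep"


def test_screening_simulation_drops_noise_keeps_signal():
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    dropped_noise = kept_signal = 0
    n = 200
    for _ in range(100):
        x = rng.normal(size=n)
        noise_cov = x + rng.normal(scale=1.0, size=n)  # collinear noise, true beta 0
        y = 2.0 * x + rng.normal(size=n)
        ll_red = sm.OLS(y, sm.add_constant(x)).fit().llf
        ll_noise = sm.OLS(y, sm.add_constant(np.column_stack([x, noise_cov]))).fit().llf
        ll_signal = sm.OLS(np.column_stack([y]), sm.add_constant(np.column_stack([noise_cov]))).fit().llf
        dropped_noise += screen_uninformative(ll_noise, ll_red)["decision"] == "drop"
        # adding the true covariate to a noise-only model is a huge gain
        kept_signal += screen_uninformative(ll_red, ll_signal)["decision"] == "keep"
    assert dropped_noise >= 90
    assert kept_signal == 100


# ------------------------------------------------------------- Hellinger


def test_hellinger_worked_examples():
    out = hellinger(np.array([[1.0, 0.0, 3.0]]))
    np.testing.assert_allclose(out, [[0.5, 0.0, np.sqrt(0.75)]])
    np.testing.assert_allclose(hellinger(np.array([[7.0]])), [[1.0]])


def test_hellinger_rows_have_unit_sum_of_squares(rng):
    counts = rng.integers(0, 30, size=(10, 6)).astype(float)
    counts[3] = 0  # zero-sum row stays zero
    out = hellinger(counts)
    ss = (out**2).sum(axis=1)
    np.testing.assert_allclose(np.delete(ss, 3), 1.0, atol=1e-12)
    assert ss[3] == 0.0


# ------------------------------------------------------------------ RDA


def test_rda_perfect_constraint():
    """A community that is an exact linear function of the predictor."""
    # a two-group predictor with group-constant communities is exactly
    # captured by the constraint even after the Hellinger transform
    xg = np.repeat([0.0, 1.0], 10)
    counts = np.vstack([np.tile([5, 1, 0], (10, 1)), np.tile([0, 2, 8], (10, 1))])
    res = tb_rda(counts, xg, seed=0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.adj_r_squared <= res.r_squared


def test_rda_minimal_p_when_signal_is_strong():
    rng = np.random.default_rng(1)
    x = np.linspace(-2, 2, 40)
    mu = np.exp(np.outer(x, [1.5, -1.5, 0.5]) + 2)
    counts = rng.poisson(mu)
    res = tb_rda(counts, x, seed=3)
    assert res.p_value == pytest.approx(1.0 / 1000.0)


def test_ezekiel_adjustment_closed_form():
    # with R2=0.5, n=11, m=1: 1 - 0.5 * 10/9 = 0.4444...
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 20, size=(11, 5))
    x = rng.normal(size=11)
    res = tb_rda(counts, x, seed=0)
    expected = 1.0 - (1.0 - res.r_squared) * 10.0 / 9.0
    assert res.adj_r_squared == pytest.approx(expected, abs=1e-12)


def test_rda_r2_invariant_under_affine_predictor_rescaling(rng):
    counts = rng.integers(0, 25, size=(15, 6))
    x = rng.normal(size=15)
    a = tb_rda(counts, x, seed=5)
    b = tb_rda(counts, 3.7 * x - 11.0, seed=5)
    assert a.r_squared == pytest.approx(b.r_squared, abs=1e-12)
    assert a.pseudo_f == pytest.approx(b.pseudo_f, abs=1e-9)


def test_rda_null_p_values_uniform():
    """Permutation p-values under a true null pass a KS uniformity check."""
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(200):
        counts = rng.integers(0, 20, size=(25, 5))
        x = rng.normal(size=25)
        ps.append(tb_rda(counts, x, n_permutations=199, seed=int(rng.integers(2**31 - 1))).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_rda_rejects_constant_predictor(rng):
    with pytest.raises(ValueError, match="constant"):
        tb_rda(rng.integers(0, 5, size=(6, 3)), np.ones(6), seed=0)


def test_rda_matches_vegan_oracle(tmp_path):
    """Independent cross-check of R2, adjusted R2 and pseudo-F against vegan."""
    rng = np.random.default_rng(31)
    counts = rng.integers(0, 30, size=(12, 6)).astype(float)
    counts[counts < 3] = 0
    x = rng.normal(size=12)
    res = tb_rda(counts, x, seed=0)

    np.savetxt(tmp_path / "y.csv", counts, delimiter=",")
    np.savetxt(tmp_path / "x.csv", x, delimiter=",")
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        y <- as.matrix(read.csv("y.csv", header=FALSE))
        x <- scan("x.csv", quiet=TRUE)
        m <- rda(decostand(y, "hellinger") ~ x)
        r2 <- m$CCA$tot.chi / m$tot.chi
        adj <- RsquareAdj(m)$adj.r.squared
        f <- (r2/1) / ((1-r2)/(nrow(y)-2))
        cat(r2, adj, f, sep="\\n")
        """
    )
    (tmp_path / "rda.R").write_text(script)
    out = subprocess.run(
        ["Rscript", "rda.R"], cwd=tmp_path, capture_output=True, text=True, check=True
    )
    r2_v, adj_v, f_v = (float(v) for v in out.stdout.split())
    assert res.r_squared == pytest.approx(r2_v, abs=1e-8)
    assert res.adj_r_squared == pytest.approx(adj_v, abs=1e-8)
    assert res.pseudo_f == pytest.approx(f_v, abs=1e-6)


# --------------------------------------------------------------- Wilcoxon


def test_wilcoxon_exact_enumeration():
    res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
    assert res["method"] == "exact"
    assert res["p_value"] == pytest.approx(1.0 / 3.0)
    assert res["W"] == 3.0  # ranks 1 + 2


def test_wilcoxon_identical_groups_midranks():
    res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res["method"] == "asymptotic"  # ties force the approximation
    assert res["p_value"] == pytest.approx(1.0)


def test_wilcoxon_exact_agrees_with_approximation(rng):
    for _ in range(10):
        a = rng.normal(size=6)
        b = rng.normal(loc=0.5, size=6)
        exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        approx = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(exact - approx) <= 0.05
        assert wilcoxon_rank_sum(a, b)["p_value"] == pytest.approx(exact)


def test_wilcoxon_type_one_error_calibration():
    rng = np.random.default_rng(77)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        rejections += wilcoxon_rank_sum(a, b)["p_value"] < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


# ------------------------------------------------------------ correlation


def test_predictor_correlation_examples():
    a = np.array([1.0, 2.0, 3.0])
    assert predictor_correlation(a, a) == pytest.approx(1.0)
    assert predictor_correlation(a, -a) == pytest.approx(-1.0)
    # covariance formula oracle: r = 3 / sqrt(2 * 42/9)
    expected = 3.0 / np.sqrt(2.0 * 42.0 / 9.0)
    assert predictor_correlation(a, [1.0, 2.0, 4.0]) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- battery


def test_battery_produces_twelve_glms_and_four_rdas():
    sites, metrics = generate_site_metrics(30, seed=3)
    m9 = metrics[metrics["scale_m"] == 900.0].reset_index(drop=True)
    cm = generate_community(m9, CommunityConfig(n_sites=30, seed=4))
    glm_df, rda_df = run_model_battery(metrics, cm, seed=5)
    assert len(glm_df) == 12
    assert len(rda_df) == 4
    assert set(glm_df["suborder"]) == {"Anisoptera", "Zygoptera"}
    assert (glm_df[glm_df["suborder"] == "Anisoptera"]["scale_m"] == 900.0).all()
    assert (glm_df[glm_df["suborder"] == "Zygoptera"]["scale_m"] == 300.0).all()
    assert np.isfinite(glm_df["resid_skewness"]).all()


def test_battery_missing_suborder_names_it():
    sites, metrics = generate_site_metrics(10, seed=1)
    m9 = metrics[metrics["scale_m"] == 900.0].reset_index(drop=True)
    cm = generate_community(m9, CommunityConfig(n_sites=10, seed=2))
    counts = cm.counts[[c for c in cm.counts.columns if cm.suborder[c] == "Anisoptera"]]
    drag_only = CommunityMatrix(counts, cm.suborder[counts.columns])
    with pytest.raises(ValueError, match="Zygoptera"):
        run_model_battery(metrics, drag_only, seed=3)
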