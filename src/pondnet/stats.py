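"""Community response variables and the pond-connectivity statistical battery.

Responses per pond are estimated abundance (summed counts), species
richness and Shannon diversity (nats), computed separately for
dragonflies (Anisoptera) and damselflies (Zygoptera). Each response is
regressed on mean current density and on the number of nearest
neighbours in separate Gaussian linear models (the two predictors are
too collinear to share a model), giving 12 models in total. Community
composition is analysed with transformation-based redundancy analysis
(Hellinger transform, single constraint, 999-permutation F test), and
pond types are compared with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "CommunityMatrix",
    "GlmFit",
    "RdaResult",
    "abundance",
    "richness",
    "shannon",
    "fit_glm",
    "screen_uninformative",
    "hellinger",
    "tb_rda",
    "wilcoxon_rank_sum",
    "predictor_correlation",
    "run_model_battery",
]

SUBORDERS = ("Anisoptera", "Zygoptera")


@dataclass
class CommunityMatrix:
    """Site x species count matrix with a suborder label per species."""

    counts: pd.DataFrame  # index: site ids, columns: species
    suborder: pd.Series  # index: species -> {"Anisoptera", "Zygoptera"}

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("site and species labels must be unique")
        missing = set(self.counts.columns) - set(self.suborder.index)
        if missing:
            raise ValueError(f"species without suborder label: {sorted(missing)}")

    def subset(self, suborder: str) -> pd.DataFrame:
        cols = [c for c in self.counts.columns if self.suborder[c] == suborder]
        if not cols:
            raise ValueError(f"no species in suborder {suborder!r}")
        return self.counts[cols]


@dataclass
class GlmFit:
    response: str
    predictor: str
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    log_likelihood: float
    n: int
    resid_skewness: float = float("nan")
    resid_variance_trend: float = float("nan")


@dataclass
class RdaResult:
    r_squared: float
    adj_r_squared: float
    pseudo_f: float
    p_value: float
    species_scores: pd.Series
    n_permutations: int
    n: int


# --------------------------------------------------------------- responses


def abundance(cm: CommunityMatrix, suborder: str) -> pd.Series:
    """Total count per site over the suborder's species."""
    return cm.subset(suborder).sum(axis=1)


def richness(cm: CommunityMatrix, suborder: str) -> pd.Series:
    """Number of species with count > 0 per site."""
    return (cm.subset(suborder) > 0).sum(axis=1)


def shannon(cm: CommunityMatrix, suborder: str) -> pd.Series:
    """Shannon diversity H = -sum p ln p per site, in nats; 0 for empty sites."""
    sub = cm.subset(suborder).to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, sub / np.where(totals[:, None] > 0, totals[:, None], 1.0), 0.0)
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return pd.Series(terms.sum(axis=1), index=cm.counts.index)


# ------------------------------------------------------------------- GLMs


def fit_glm(
    response, predictor, response_name: str = "y", predictor_name: str = "x"
) -> GlmFit:
    """Ordinary least squares fit of response ~ predictor (Gaussian errors).

    Reports the slope's two-sided t-test p-value, R-squared, and the
    Gaussian log-likelihood, plus residual diagnostics: skewness and the
    slope of squared residuals on fitted values (a variance-trend check
    in the spirit of Breusch-Pagan).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values in response or predictor")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    fitted = fit.fittedvalues
    if np.ptp(fitted) > 0:
        vt = float(np.polyfit(fitted, resid**2, 1)[0])
    else:
        vt = 0.0
    return GlmFit(
        response=response_name,
        predictor=predictor_name,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        log_likelihood=float(fit.llf),
        n=len(y),
        resid_skewness=float(sps.skew(resid, bias=False)) if len(y) > 2 else float("nan"),
        resid_variance_trend=vt,
    )


def screen_uninformative(
    loglik_full: float, loglik_reduced: float, threshold: float = 1.92
) -> dict:
    """Decide whether an extra parameter is uninformative.

    The parameter is dropped when the log-likelihood gain of the fuller
    model is below ``threshold`` (default 1.92 = chi-square(1) 95%
    point / 2, the gain at which AIC would start to favour the fuller
    model-equivalently no meaningful improvement).
    """
    gain = float(loglik_full) - float(loglik_reduced)
    return {
        "decision": "drop" if gain < threshold else "keep",
        "loglik_full": float(loglik_full),
        "loglik_reduced": float(loglik_reduced),
        "gain": gain,
        "threshold": threshold,
    }


# -------------------------------------------------------------------- RDA


def hellinger(counts) -> np.ndarray:
    """Hellinger transform: sqrt of within-site relative abundance.

    Rows with zero total are left as all-zero (they carry no
    compositional information); each nonzero row has unit sum of
    squares afterwards.
    """
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    totals = y.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return np.sqrt(y / safe)


def tb_rda(counts, predictor, n_permutations: int = 999, seed: int | None = None) -> RdaResult:
    """Transformation-based RDA with one constraining variable.

    The count matrix is Hellinger-transformed and column-centred; the
    constrained variance fraction R2 is the share of total variance
    captured by regressing each species column on the centred
    predictor. Significance comes from a permutation F test (site rows
    of the predictor permuted; p = (#{F_perm >= F_obs} + 1)/(B + 1)).
    The adjusted R2 is Ezekiel's: 1 - (1 - R2)(n - 1)/(n - m - 1).
    Species scores are the covariances of the (transformed, centred)
    species columns with the constrained site axis.
    """
    x = np.asarray(predictor, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    if isinstance(counts, pd.DataFrame):
        species = counts.columns
        ymat = counts.to_numpy(dtype=float)
    else:
        ymat = np.asarray(counts, dtype=float)
        species = pd.RangeIndex(ymat.shape[1])
    n, _ = ymat.shape
    if n < 3:
        raise ValueError("need >= 3 sites")
    m = 1  # single constraint

    yh = hellinger(ymat)
    yc = yh - yh.mean(axis=0)
    xc = x - x.mean()
    denom = float(xc @ xc)
    ss_total = float((yc**2).sum())
    if ss_total == 0:
        raise ValueError("community matrix has no variance")

    b = yc.T @ xc / denom
    ss_fit = float((b**2).sum() * denom)
    r2 = ss_fit / ss_total
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    with np.errstate(divide="ignore"):
        f_obs = (r2 / m) / ((1.0 - r2) / (n - m - 1))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(xc) for _ in range(n_permutations)])
    ss_fit_perm = ((perms @ yc) ** 2).sum(axis=1) / denom
    r2_perm = ss_fit_perm / ss_total
    with np.errstate(divide="ignore"):  # R2 of 1 gives F = inf, handled by >=
        f_perm = (r2_perm / m) / ((1.0 - r2_perm) / (n - m - 1))
    p = (float(np.count_nonzero(f_perm >= f_obs)) + 1.0) / (n_permutations + 1.0)

    axis = xc / np.linalg.norm(xc)  # constrained site axis, oriented with the predictor
    scores = pd.Series(yc.T @ axis / (n - 1), index=species, name="species_score")
    return RdaResult(
        r_squared=r2,
        adj_r_squared=adj_r2,
        pseudo_f=f_obs,
        p_value=p,
        species_scores=scores,
        n_permutations=n_permutations,
        n=n,
    )


# ------------------------------------------------------- univariate tests


def wilcoxon_rank_sum(group_a, group_b) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Exact enumeration when the combined sample is <= 12 with no ties,
    otherwise the normal approximation with tie and continuity
    corrections. Returns the rank-sum statistic W of the first group,
    the p-value, and which method was used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank-sum of group a
    return {"W": w, "U": float(res.statistic), "p_value": float(min(res.pvalue, 1.0)), "method": method}


def predictor_correlation(a, b) -> float:
    """Sample Pearson correlation between two predictors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    return float(sps.pearsonr(a, b)[0])


# ----------------------------------------------------------------- battery


def run_model_battery(
    metrics: pd.DataFrame,
    cm: CommunityMatrix,
    scales: dict[str, float] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full statistical battery at taxon-specific scales.

    For each suborder at its scale, fits {abundance, shannon, richness}
    x {mean_current, n_neighbours} Gaussian models (12 rows) and runs a
    tb-RDA of the suborder's composition against each predictor (4
    rows). ``metrics`` is the tidy (pond_id, scale_m) table from
    :func:`pondnet.metrics.site_metrics_table`.
    """
    if scales is None:
        scales = {"Anisoptera": 900.0, "Zygoptera": 300.0}
    responses = {"abundance": abundance, "shannon": shannon, "richness": richness}
    predictors = ("mean_current", "n_neighbours")
    rng = np.random.default_rng(seed)

    glm_rows = []
    rda_rows = []
    for suborder, scale in scales.items():
        sub = cm.subset(suborder)  # raises if the suborder has no species
        msub = metrics[metrics["scale_m"] == scale].set_index("pond_id")
        missing = set(cm.counts.index) - set(msub.index)
        if missing:
            raise ValueError(f"metrics at scale {scale} missing ponds: {sorted(missing)[:5]}")
        msub = msub.loc[cm.counts.index]
        for rname, rfun in responses.items():
            y = rfun(cm, suborder)
            for pred in predictors:
                fit = fit_glm(y, msub[pred], response_name=f"{suborder}_{rname}", predictor_name=pred)
                row = fit.__dict__.copy()
                row.update({"suborder": suborder, "scale_m": scale})
                glm_rows.append(row)
        for pred in predictors:
            res = tb_rda(
                sub,
                msub[pred].to_numpy(),
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            top = res.species_scores.idxmax()
            rda_rows.append(
                {
                    "suborder": suborder,
                    "scale_m": scale,
                    "predictor": pred,
                    "r_squared": res.r_squared,
                    "adj_r_squared": res.adj_r_squared,
                    "pseudo_f": res.pseudo_f,
                    "p_value": res.p_value,
                    "top_species": top,
                    "top_species_score": float(res.species_scores[top]),
                    "n_permutations": res.n_permutations,
                }
            )
    return pd.DataFrame(glm_rows), pd.DataFrame(rda_rows)
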