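"""Genus-level RMPG distribution statistics and genome-size regressions.

Works on isolate-level tables (one row per genome assembly) or genus-level
tables (one row per genus with mean RMPG, mean genome size and isolate
count).  Aggregating at the genus level avoids over-weighting heavily
sequenced taxa when summarizing the prokaryote-wide distribution.  The
regressions quantify how weak a predictor genome size is for RM count: an
ordinary least-squares fit of genus-mean RMPG on genus-mean genome size
(Mbp), and a negative-binomial log-link fit with maximum-likelihood
dispersion, summarized by McFadden's pseudo-R-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import mannwhitneyu, permutation_test, rankdata

__all__ = [
    "RegressionFit",
    "DistributionSummary",
    "aggregate_genus",
    "summarize",
    "fit_linear",
    "fit_negbin",
    "delta_size_for_one_rm",
    "rank_sum_test",
]

BP_PER_MBP = 1e6


@dataclass(frozen=True)
class RegressionFit:
    """A fitted RMPG-vs-genome-size regression.

    ``slope`` is per Mbp of genome size.  ``fit_quality`` is R-squared for
    the linear model and McFadden's pseudo-R-squared (1 - ll_fit/ll_null)
    for the negative-binomial model.  ``dispersion`` is the NB alpha
    (variance = mu + alpha mu^2); None for the linear model.
    """

    model: str  # "linear" | "negative-binomial"
    slope: float
    intercept: float
    fit_quality: float
    p_value: float
    dispersion: float | None = None
    n: int = 0
    converged: bool = True


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    median: float
    q05: float
    q95: float
    n_genera: int


def aggregate_genus(isolates: pd.DataFrame, response: str = "rm_total") -> pd.DataFrame:
    """Aggregate an isolate table to genus level.

    Input columns: ``genus``, ``genome_size`` (bp) and the RM-count column
    named by ``response`` (plus optionally ``rm_total_no_iig``, ``phylum``).
    Returns one row per genus with ``n_isolates``, ``mean_rmpg``,
    ``std_rmpg`` (ddof=1; 0 for single-isolate genera), ``mean_bp``.
    """
    if len(isolates) == 0:
        raise ValueError("empty isolate table")
    required = {"genus", "genome_size", response}
    missing = required - set(isolates.columns)
    if missing:
        raise ValueError(f"isolate table missing columns: {sorted(missing)}")
    grouped = isolates.groupby("genus", sort=True)
    out = pd.DataFrame(
        {
            "n_isolates": grouped.size(),
            "mean_rmpg": grouped[response].mean(),
            "std_rmpg": grouped[response].std(ddof=1).fillna(0.0),
            "mean_bp": grouped["genome_size"].mean(),
        }
    )
    if "rm_total_no_iig" in isolates.columns and response != "rm_total_no_iig":
        out["mean_rmpg_no_iig"] = grouped["rm_total_no_iig"].mean()
    if "phylum" in isolates.columns:
        out["phylum"] = grouped["phylum"].first()
    return out.reset_index()


def summarize(genus_table: pd.DataFrame, min_isolates: int = 1) -> DistributionSummary:
    """Distribution summary of genus-mean RMPG.

    Keeps genera with at least ``min_isolates`` sequenced genomes, then
    reports mean, median and 5th/95th quantiles (linear interpolation of
    order statistics, the numpy default).
    """
    if min_isolates < 1:
        raise ValueError("min_isolates must be >= 1")
    kept = genus_table.loc[genus_table["n_isolates"] >= min_isolates, "mean_rmpg"]
    if len(kept) == 0:
        raise ValueError(f"no genera with >= {min_isolates} isolates")
    vals = kept.to_numpy(dtype=float)
    return DistributionSummary(
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        q05=float(np.quantile(vals, 0.05)),
        q95=float(np.quantile(vals, 0.95)),
        n_genera=int(vals.size),
    )


def _prepare_xy(genus_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = genus_table["mean_bp"].to_numpy(dtype=float) / BP_PER_MBP
    y = genus_table["mean_rmpg"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genera to fit a regression")
    if np.ptp(x) == 0:
        raise ValueError("genome size is constant; slope is unidentifiable")
    return x, y


def fit_linear(genus_table: pd.DataFrame) -> RegressionFit:
    """OLS of genus-mean RMPG on genus-mean genome size in Mbp."""
    x, y = _prepare_xy(genus_table)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        model="linear",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        fit_quality=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=x.size,
    )


def _nb_loglike(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Continuous-response NB log-likelihood (gamma-function form).

    Valid for non-integer y >= 0 (genus means), reducing to the ordinary
    NB2 likelihood at integer y.
    """
    size = 1.0 / alpha
    prob = size / (size + mu)
    ll = (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1.0)
        + size * np.log(prob)
        + y * np.log1p(-prob)
    )
    return float(ll.sum())


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, round_response: bool) -> tuple:
    """Profile the NB dispersion alpha by ML, refitting the GLM each time."""
    yy = np.round(y) if round_response else y
    yy = np.maximum(yy, 1e-8)  # log-link likelihood needs y >= 0; guard zeros

    def negll(log_alpha: float) -> float:
        alpha = math.exp(log_alpha)
        model = sm.GLM(yy, X, family=sm.families.NegativeBinomial(alpha=alpha))
        try:
            res = model.fit()
        except Exception:
            return np.inf
        return -_nb_loglike(yy, res.mu, alpha)

    opt = minimize_scalar(negll, bounds=(-10.0, 5.0), method="bounded")
    alpha = math.exp(opt.x)
    res = sm.GLM(yy, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    return res, alpha, yy


def fit_negbin(genus_table: pd.DataFrame, round_response: bool = False) -> RegressionFit:
    """Negative-binomial (log link) regression of genus-mean RMPG on Mbp.

    Genus means are not integers; by default they enter the NB likelihood
    through its gamma-function (continuous) form.  ``round_response=True``
    rounds them to counts first, for comparison.  Dispersion alpha is
    profiled by maximum likelihood; fit quality is McFadden's
    pseudo-R-squared against the intercept-only NB fit.
    """
    x, y = _prepare_xy(genus_table)
    X = sm.add_constant(x)
    try:
        res, alpha, yy = _fit_nb_glm(y, X, round_response)
        res0, alpha0, _ = _fit_nb_glm(y, np.ones((x.size, 1)), round_response)
    except Exception as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"negative-binomial fit failed to converge: {err}") from err
    ll_fit = _nb_loglike(yy, res.mu, alpha)
    ll_null = _nb_loglike(yy, res0.mu, alpha0)
    pseudo_r2 = 1.0 - ll_fit / ll_null if ll_null != 0 else np.nan
    return RegressionFit(
        model="negative-binomial",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        fit_quality=float(pseudo_r2),
        p_value=float(res.pvalues[1]),
        dispersion=float(alpha),
        n=x.size,
        converged=bool(res.converged),
    )


def delta_size_for_one_rm(fit: RegressionFit, baseline_size_mbp: float = 2.0) -> float:
    """Genome expansion (Mbp) needed to gain one RM system.

    Linear model: the reciprocal slope, independent of the baseline.
    NB log-link model: the Delta solving
    exp(b0 + b1 (x + Delta)) = exp(b0 + b1 x) + 1 at the given baseline.
    """
    if fit.slope <= 0:
        raise ValueError("slope must be positive to gain RMs with size")
    if baseline_size_mbp <= 0:
        raise ValueError("baseline genome size must be positive")
    if fit.model == "linear":
        return 1.0 / fit.slope
    eta = fit.intercept + fit.slope * baseline_size_mbp
    return (np.log(np.exp(eta) + 1.0) - eta) / fit.slope


def rank_sum_test(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    For small samples (combined n <= ``exact_max_n``) the null distribution
    is enumerated exactly by permutation of the midrank statistic, which
    remains valid under ties; larger samples use the tie-corrected normal
    approximation with continuity correction.  Returns (U statistic of
    group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_stat = float(mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if a.size + b.size <= exact_max_n:

        def statistic(x, y):
            ranks = rankdata(np.concatenate([x, y]))
            return ranks[: len(x)].sum()

        res = permutation_test(
            (a, b),
            statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return u_stat, float(res.pvalue)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return u_stat, float(res.pvalue)
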