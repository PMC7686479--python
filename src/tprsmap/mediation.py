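"""Brainscore-symptom association, covariate-adjusted regression, and
sex-moderated bootstrap mediation.

The mediation model is the classic two-regression indirect effect: within
each stratum, a is the OLS slope of the mediator on the score (plus
covariates), b the slope of the outcome on the mediator adjusting for the
score (plus covariates), and ab = a * b the indirect effect. Uncertainty
comes from a stratified nonparametric bootstrap over subjects, reported as
the bootstrap SD and the asymmetric 2.5/97.5 percentile interval. Moderation
by stratum (sex) is summarized by the bootstrap distribution of the
difference in ab between strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import batch_ols, rng_for, zscore_vector


@dataclass
class MediationResult:
    a: float
    b: float
    ab: float
    se_ab: float
    ci_ab: tuple
    n: int
    n_boot: int
    seed: object = None
    ab_samples: np.ndarray | None = None

    def __post_init__(self):
        if abs(self.ab - self.a * self.b) > 1e-10:
            raise ValueError("ab must equal a * b")
        if self.ci_ab[0] > self.ci_ab[1]:
            raise ValueError("CI bounds out of order")


def brainscore_symptom_corr(brainscore, symptom) -> tuple[float, float, float]:
    """Pearson r, R^2 and two-sided p between a brainscore and a symptom."""
    x = np.asarray(brainscore, dtype=float)
    y = np.asarray(symptom, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def adjusted_regression(outcome, predictor, covariates=None) -> tuple[float, float]:
    """Standardized OLS coefficient of the predictor with covariate adjustment.

    All continuous columns are z-scored; returns (beta, two-sided p). Rank
    deficiency raises with the offending columns named.
    """
    y = zscore_vector(np.asarray(outcome, float))
    x = zscore_vector(np.asarray(predictor, float))
    cols = [x]
    names = ["predictor"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            col = cov[name].to_numpy(float)
            cols.append(zscore_vector(col) if col.std() > 0 else col * 0.0)
            names.append(str(name))
    X = sm.add_constant(np.column_stack(cols))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate a minimal set of collinear columns for the error message
        bad = []
        kept = [0]
        for j in range(1, X.shape[1]):
            r_new = np.linalg.matrix_rank(X[:, kept + [j]])
            if r_new == len(kept):
                bad.append((["const"] + names)[j])
            else:
                kept.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def multiple_comparison_gate(perm_p, m: int = 9, alpha: float = 0.05):
    """Bonferroni gate: an analysis passes iff its permutation p < alpha/m.

    Returns (pass_array, threshold).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    p = np.asarray(perm_p, dtype=float)
    return p < threshold, threshold


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def _paths(score, mediator, outcome, cov) -> tuple[float, float]:
    n = len(score)
    ones = np.ones((n, 1))
    C = cov if cov is not None else np.empty((n, 0))
    X1 = np.hstack([ones, score[:, None], C])
    a = np.linalg.lstsq(X1, mediator, rcond=None)[0][1]
    X2 = np.hstack([ones, mediator[:, None], score[:, None], C])
    b = np.linalg.lstsq(X2, outcome, rcond=None)[0][1]
    return float(a), float(b)


def _boot_ab(score, mediator, outcome, cov, n_boot, rng) -> np.ndarray:
    n = len(score)
    idx = rng.integers(0, n, size=(n_boot, n))
    C = cov if cov is not None else np.empty((n, 0))
    ones = np.ones((n_boot, n, 1))
    sc = score[idx][..., None]
    md = mediator[idx][..., None]
    Cb = C[idx]
    X1 = np.concatenate([ones, sc, Cb], axis=2)
    a_b = batch_ols(X1, mediator[idx])[:, 1]
    X2 = np.concatenate([ones, md, sc, Cb], axis=2)
    b_b = batch_ols(X2, outcome[idx])[:, 1]
    return a_b * b_b


def _maybe_z(x: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return x
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


class BootstrapMediation(BaseEstimator):
    """Stratified bootstrap mediation (score -> mediator -> outcome).

    Parameters
    ----------
    n_boot : bootstrap draws per stratum (default 5000).
    standardize : z-score all continuous variables within each stratum so
        coefficients are standardized betas. Planted raw-scale effects
        should be checked with standardize=False.
    ci : percentile interval coverage (default 0.95); percentile bootstrap,
        no bias correction.
    random_state : seed.

    After fit: ``results_`` maps stratum label (or "all") to a
    :class:`MediationResult`; with exactly two strata,
    ``moderation_index_`` holds the ab difference with its bootstrap CI.
    """

    def __init__(self, n_boot: int = 5000, standardize: bool = True,
                 ci: float = 0.95, min_stratum: int = 20, random_state=None):
        self.n_boot = n_boot
        self.standardize = standardize
        self.ci = ci
        self.min_stratum = min_stratum
        self.random_state = random_state

    def fit(self, score, mediator, outcome, covariates=None, strata=None):
        score = pd.Series(score)
        mediator = pd.Series(mediator)
        outcome = pd.Series(outcome)
        if not (score.index.equals(mediator.index) and score.index.equals(outcome.index)):
            raise ValueError("score, mediator and outcome must share an index")
        cov_df = pd.DataFrame(covariates) if covariates is not None else None
        if strata is None:
            labels = pd.Series("all", index=score.index)
        else:
            labels = pd.Series(strata)
            labels.index = score.index
        alpha = (1.0 - self.ci) / 2.0 * 100.0
        results: dict = {}
        for li, lab in enumerate(pd.unique(labels)):
            ix = labels[labels == lab].index
            if len(ix) < self.min_stratum:
                raise ValueError(
                    f"stratum {lab!r} has {len(ix)} subjects (< {self.min_stratum})"
                )
            s = _maybe_z(score.loc[ix].to_numpy(float), self.standardize)
            m = _maybe_z(mediator.loc[ix].to_numpy(float), self.standardize)
            y = _maybe_z(outcome.loc[ix].to_numpy(float), self.standardize)
            C = None
            if cov_df is not None and cov_df.shape[1]:
                C = np.column_stack(
                    [
                        _maybe_z(cov_df.loc[ix, c].to_numpy(float), self.standardize)
                        for c in cov_df.columns
                    ]
                )
            a, b = _paths(s, m, y, C)
            rng = rng_for(self.random_state, 303, li)
            ab_samples = _boot_ab(s, m, y, C, self.n_boot, rng)
            results[lab] = MediationResult(
                a=a, b=b, ab=a * b,
                se_ab=float(ab_samples.std(ddof=1)),
                ci_ab=(
                    float(np.percentile(ab_samples, alpha)),
                    float(np.percentile(ab_samples, 100.0 - alpha)),
                ),
                n=len(ix), n_boot=self.n_boot, seed=self.random_state,
                ab_samples=ab_samples,
            )
        self.results_ = results
        self.moderation_index_ = None
        labs = list(results)
        if len(labs) == 2:
            diff = results[labs[0]].ab_samples - results[labs[1]].ab_samples
            self.moderation_index_ = {
                "strata": (labs[0], labs[1]),
                "ab_diff": results[labs[0]].ab - results[labs[1]].ab,
                "ci": (
                    float(np.percentile(diff, alpha)),
                    float(np.percentile(diff, 100.0 - alpha)),
                ),
            }
        return self


def mediate(
    score, mediator, outcome, covariates=None, strata=None,
    n_boot: int = 5000, seed=None, standardize: bool = True,
) -> dict:
    """Per-stratum bootstrap mediation; returns {stratum: MediationResult}
    (plus key "_moderation" when two strata are present)."""
    est = BootstrapMediation(
        n_boot=n_boot, standardize=standardize, random_state=seed
    ).fit(score, mediator, outcome, covariates=covariates, strata=strata)
    out = dict(est.results_)
    if est.moderation_index_ is not None:
        out["_moderation"] = est.moderation_index_
    return out
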