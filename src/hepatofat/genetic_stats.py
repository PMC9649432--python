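"""Statistical genetics: trait standardization, additive association, the
three-group genotype-genotype interaction LRT, fixed-effects IVW
meta-analysis, tiered significance thresholds, genetic risk scores and
Mendelian randomization.

The interaction test follows a two-stage construction: the secondary
variant's effect is estimated separately within each genotype group of the
primary variant, the per-group effects are modelled as
``beta_g = b + gamma * g_p`` by inverse-variance weighted least squares,
and a 1-df likelihood-ratio statistic (Gaussian likelihood with the
per-group standard errors treated as known) compares the free-``gamma``
model against ``gamma = 0``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import AssocResult, GRSWeights, InteractionResult, MetaResult, MRResult

__all__ = [
    "inverse_normal_transform",
    "additive_assoc",
    "interaction_lrt",
    "covariate_interaction",
    "ivw_meta",
    "gws_threshold",
    "grs",
    "mr_ivw_egger",
    "GWS_THRESHOLDS",
]

# Weighted-Bonferroni genome-wide significance tiers by predicted impact.
GWS_THRESHOLDS: Mapping[str, float] = {
    "high": 1.8e-7,
    "moderate": 3.5e-8,
    "low": 3.2e-9,
    "dhs": 1.6e-9,
    "other": 5.3e-10,
}


def gws_threshold(impact_class: str) -> float:
    """Significance threshold for a variant impact class.

    Classes: ``high`` (stop gained/lost, frameshift, splice donor/acceptor),
    ``moderate`` (missense, splice region, in-frame indels), ``low``
    (synonymous, UTR, up/downstream), ``dhs`` (other variants in DNase I
    hypersensitivity sites) and ``other``.
    """
    try:
        return GWS_THRESHOLDS[impact_class]
    except KeyError:
        raise ValueError(
            f"unknown impact class {impact_class!r}; expected one of "
            f"{sorted(GWS_THRESHOLDS)}"
        ) from None


def _residualize(values: np.ndarray, covariates: Optional[pd.DataFrame]) -> np.ndarray:
    if covariates is None:
        return values - values.mean()
    X = np.column_stack([np.ones(len(values)), np.asarray(covariates, dtype=float)])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


def inverse_normal_transform(
    values: Sequence[float], covariates: Optional[pd.DataFrame] = None
) -> np.ndarray:
    """Covariate-adjusted rank-based inverse normal transform.

    Residualizes on the covariates by least squares, then maps ranks to
    normal quantiles with the Blom offset: ``Phi^{-1}((k - 3/8)/(n + 1/4))``,
    with ties receiving average ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 10:
        raise ValueError("need a 1-D sample of at least 10 values")
    if np.ptp(values) == 0:
        raise ValueError("constant input cannot be rank-standardized")
    if covariates is not None and len(covariates) != values.size:
        raise ValueError("covariates not aligned with values")
    resid = _residualize(values, covariates)
    ranks = stats.rankdata(resid, method="average")
    return stats.norm.ppf((ranks - 0.375) / (values.size + 0.25))


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple:
    """Slope, s.e. and Wald p for y ~ 1 + x (closed form)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    tstat = beta / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return beta, se, p


def additive_assoc(
    genotypes: Sequence[int],
    trait: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    binary: Optional[bool] = None,
) -> AssocResult:
    """Additive per-allele association of a variant with a trait.

    Quantitative traits use linear regression (slope in trait units per
    allele); binary traits (auto-detected or forced with ``binary=True``)
    use logistic regression (log-OR per allele). Covariates enter as main
    effects. Monomorphic variants raise; logistic separation is flagged on
    the result and warned about, never silently returned.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.size != y.size:
        raise ValueError("genotypes and trait differ in length")
    if np.ptp(g) == 0:
        raise ValueError("monomorphic variant: genotype has no variance")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    if not binary and covariates is None:
        beta, se, p = _simple_ols(g, y)
        return AssocResult(beta=beta, se=se, p_value=p, n=g.size)

    X = np.column_stack([np.ones(g.size), g])
    if covariates is not None:
        if len(covariates) != g.size:
            raise ValueError("covariates not aligned")
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    if binary:
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        separation = False
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                pass
        if fit is None:
            warnings.warn("perfect separation in logistic association fit")
            return AssocResult(
                beta=float("nan"), se=float("nan"), p_value=float("nan"),
                n=g.size, separation=True,
            )
        if not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 15 or fit.bse[1] > 50:
            separation = True
            warnings.warn("possible separation in logistic association fit")
        return AssocResult(
            beta=float(fit.params[1]),
            se=float(fit.bse[1]),
            p_value=float(fit.pvalues[1]),
            n=g.size,
            separation=separation,
        )
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[1]), se=float(fit.bse[1]), p_value=float(fit.pvalues[1]), n=g.size
    )


def interaction_lrt(
    primary_genotypes: Sequence[int],
    secondary_genotypes: Sequence[int],
    trait: Sequence[float],
    min_group: int = 30,
) -> InteractionResult:
    """Genotype-genotype interaction via per-group effects and a 1-df LRT.

    The population is split into the three genotype groups of the primary
    variant; within each, the secondary variant's additive effect ``beta_g``
    and its standard error are estimated by least squares on the
    (standardized) trait. The linear trend ``beta_g = b + gamma * g_p`` is
    fit by weighted least squares (weights ``1/se^2``) and compared against
    the constant-effect null by the weighted residual-sum-of-squares
    difference, which is chi-square with 1 df when the ``se`` are treated
    as known.
    """
    gp = np.asarray(primary_genotypes)
    gs = np.asarray(secondary_genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    if not (gp.size == gs.size == y.size):
        raise ValueError("inputs differ in length")

    betas, ses, ns = [], [], []
    for level in (0, 1, 2):
        sel = gp == level
        n_g = int(sel.sum())
        if n_g < min_group:
            raise ValueError(
                f"primary genotype group {level} has {n_g} individuals (<{min_group})"
            )
        if np.ptp(gs[sel]) == 0:
            raise ValueError(f"secondary variant monomorphic within primary group {level}")
        beta, se, _ = _simple_ols(gs[sel], y[sel])
        betas.append(beta)
        ses.append(se)
        ns.append(n_g)

    betas_arr = np.array(betas)
    w = 1.0 / np.array(ses) ** 2
    g_levels = np.array([0.0, 1.0, 2.0])

    # weighted least squares for beta_g = b + gamma * g
    sw = w.sum()
    gw = float(w @ g_levels) / sw
    bw = float(w @ betas_arr) / sw
    sgg = float(w @ (g_levels - gw) ** 2)
    gamma = float(w @ ((g_levels - gw) * (betas_arr - bw))) / sgg
    b = bw - gamma * gw
    gamma_se = 1.0 / np.sqrt(sgg)

    rss_free = float(w @ (betas_arr - b - gamma * g_levels) ** 2)
    rss_null = float(w @ (betas_arr - bw) ** 2)
    lrt = max(rss_null - rss_free, 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return InteractionResult(
        group_betas=tuple(betas),
        group_ses=tuple(ses),
        group_ns=tuple(ns),
        b=b,
        gamma=gamma,
        gamma_se=gamma_se,
        lrt_stat=lrt,
        p_value=p,
    )


def covariate_interaction(
    genotypes: Sequence[int],
    covariate: Sequence[float],
    trait: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
) -> AssocResult:
    """Genotype x covariate product-term test with main effects included."""
    g = np.asarray(genotypes, dtype=float)
    c = np.asarray(covariate, dtype=float)
    y = np.asarray(trait, dtype=float)
    if not (g.size == c.size == y.size):
        raise ValueError("inputs differ in length")
    if np.ptp(g) == 0:
        raise ValueError("monomorphic variant")
    if np.ptp(c) == 0:
        raise ValueError("constant covariate")
    X = np.column_stack([np.ones(g.size), g, c, g * c])
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    fit = sm.OLS(y, X).fit()
    return AssocResult(
        beta=float(fit.params[3]), se=float(fit.bse[3]), p_value=float(fit.pvalues[3]), n=g.size
    )


def ivw_meta(effects: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effects inverse-variance meta-analysis with Cochran's Q.

    Combined effect ``sum(w b)/sum(w)`` with ``w = 1/se^2``, combined s.e.
    ``1/sqrt(sum w)``; heterogeneity by Cochran's Q on k-1 df (``p_het`` is
    NaN for a single study).
    """
    b = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size != s.size:
        raise ValueError("effects and ses differ in length")
    if b.size < 1:
        raise ValueError("need at least one study")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    effect = float(w @ b / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = 2.0 * float(stats.norm.sf(abs(effect / se)))
    q = float(w @ (b - effect) ** 2)
    k = b.size
    p_het = float(stats.chi2.sf(q, df=k - 1)) if k > 1 else float("nan")
    return MetaResult(effect=effect, se=se, p_value=p, q_stat=q, p_het=p_het, k=k)


def grs(
    genotypes: pd.DataFrame,
    weights: GRSWeights,
    counted_alleles: Optional[Mapping[str, str]] = None,
    flip_mismatched: bool = False,
) -> pd.Series:
    """Per-individual weighted sum of effect-allele counts.

    ``genotypes`` columns are variant ids with minor-allele counts;
    ``counted_alleles`` maps variant id to the allele the counts refer to.
    A variant in the weights but not in the table is an error, as is a
    counted/effect allele mismatch unless ``flip_mismatched`` is set, in
    which case counts are reflected (``g -> 2 - g``). No variant is ever
    dropped or flipped silently.
    """
    missing = [v for v in weights.variants if v not in genotypes.columns]
    if missing:
        raise ValueError(f"variants missing from genotype table: {missing}")
    G = genotypes[weights.variants].to_numpy(dtype=float)
    w = weights.weights.copy()
    if counted_alleles is not None:
        flips = []
        for j, (variant, effect_allele) in enumerate(zip(weights.variants, weights.effect_alleles)):
            counted = counted_alleles.get(variant)
            if counted is None:
                raise ValueError(f"no counted allele recorded for {variant}")
            if counted != effect_allele:
                flips.append(j)
        if flips and not flip_mismatched:
            raise ValueError(
                f"effect-allele mismatch for {[weights.variants[j] for j in flips]}; "
                "pass flip_mismatched=True to reflect genotype counts"
            )
        for j in flips:
            G[:, j] = 2.0 - G[:, j]
    return pd.Series(G @ w, index=genotypes.index, name="grs")


def mr_ivw_egger(
    exposure_effects: Sequence[float],
    exposure_ses: Sequence[float],
    outcome_effects: Sequence[float],
    outcome_ses: Sequence[float],
) -> MRResult:
    """Mendelian randomization: IVW (through the origin) and Egger regression.

    Both regress the outcome effects on the exposure effects with weights
    ``1/outcome_se^2``. IVW uses fixed-effect standard errors; Egger frees
    the intercept (directional pleiotropy) and inflates its standard errors
    by the residual scale floored at 1. Egger requires at least three
    instruments and is omitted (``None`` fields) with exactly two.
    """
    bx = np.asarray(exposure_effects, dtype=float)
    sx = np.asarray(exposure_ses, dtype=float)
    by = np.asarray(outcome_effects, dtype=float)
    sy = np.asarray(outcome_ses, dtype=float)
    if not (bx.size == sx.size == by.size == sy.size):
        raise ValueError("instrument vectors differ in length")
    if bx.size < 2:
        raise ValueError("IVW requires at least 2 instruments")
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")

    w = 1.0 / sy**2
    sxx = float(w @ bx**2)
    est = float(w @ (bx * by)) / sxx
    se = 1.0 / np.sqrt(sxx)
    p = 2.0 * float(stats.norm.sf(abs(est / se)))

    egger: dict = {}
    if bx.size >= 3:
        X = np.column_stack([np.ones(bx.size), bx])
        WX = X * w[:, None]
        M = np.linalg.inv(X.T @ WX)
        coef = M @ (WX.T @ by)
        resid = by - X @ coef
        df = bx.size - 2
        scale = max(float(w @ resid**2) / df, 1.0)  # floored residual scale
        cov = M * scale
        se_i, se_s = np.sqrt(np.diag(cov))
        egger = {
            "egger_intercept": float(coef[0]),
            "egger_intercept_se": float(se_i),
            "egger_intercept_p": 2.0 * float(stats.t.sf(abs(coef[0] / se_i), df)),
            "egger_slope": float(coef[1]),
            "egger_slope_se": float(se_s),
            "egger_slope_p": 2.0 * float(stats.t.sf(abs(coef[1] / se_s), df)),
        }
    return MRResult(ivw_estimate=est, ivw_se=se, ivw_p=p, **egger)
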