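"""Serum metabolite associations with obesity status.

Each metabolic measure is log-transformed (natural log), z-scored on the
pooled complete cases, and entered into a logistic regression of case status
(patient = 1) with age as covariate.  The exponentiated slope is the odds
ratio of severe obesity per 1 SD increment of the log-measure, with a Wald
95% confidence interval; Benjamini–Hochberg adjustment runs across measures
and the direction label (up/down/ns) is assigned at FDR < 0.05.  Group
comparisons of individual variables use the two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import ValidationError
from .differential import bh_adjust
from .io_formats import MetaboliteTable, SampleMetadata, metadata_frame

logger = logging.getLogger(__name__)

__all__ = ["MetaboliteORResult", "metabolite_logistic", "compare_groups", "metabolite_table"]


@dataclass
class MetaboliteORResult:
    """Odds ratio of severe obesity per 1 SD of one log-transformed measure."""

    measure: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    pval: float
    fdr: float
    direction: str  # up / down / ns
    n: int
    separation: bool = False


def _ridge_logistic(X: np.ndarray, y: np.ndarray, alpha: float = 1.0, max_iter: int = 200):
    """L2-penalized Newton–Raphson logistic fit (intercept unpenalized).

    Fallback for complete separation, where the unpenalized MLE diverges;
    standard errors come from the penalized Hessian, so they are finite but
    conservative in interpretation.
    """
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def metabolite_logistic(
    tbl: MetaboliteTable,
    meta: list[SampleMetadata],
    adjust_for: tuple[str, ...] = ("age",),
    fdr_threshold: float = 0.05,
    zero_policy: str = "error",
) -> list[MetaboliteORResult]:
    """Per-measure age-adjusted logistic association with obesity status.

    ``zero_policy="error"`` (default) raises on non-positive values, because
    silent offsets corrupt odds ratios; ``"half_min"`` replaces them by half
    the smallest positive value of that measure before the log transform.
    Complete separation is flagged and handled with a penalized-likelihood
    fallback instead of crashing.
    """
    mdf = metadata_frame(meta)
    common = [s for s in tbl.samples if s in mdf.index]
    if not common:
        raise ValidationError("no overlap between metabolite table and metadata")
    V = tbl.values.loc[common]
    status = (mdf.loc[common, "group"] == "patient").astype(float)
    covars = mdf.loc[common, list(adjust_for)].astype(float)

    fitted: list[MetaboliteORResult] = []
    for measure in V.columns:
        x = V[measure].to_numpy(dtype=float)
        keep = ~np.isnan(x) & ~covars.isna().any(axis=1).to_numpy()
        x, y = x[keep], status.to_numpy()[keep]
        C = covars.to_numpy(dtype=float)[keep]
        if len(np.unique(y)) < 2:
            raise ValidationError(
                f"measure {measure!r}: only one group among complete cases"
            )
        if (x <= 0).any():
            if zero_policy == "half_min":
                pos = x[x > 0]
                if pos.size == 0:
                    raise ValidationError(f"measure {measure!r} has no positive values")
                x = np.where(x <= 0, pos.min() / 2.0, x)
            else:
                raise ValidationError(
                    f"measure {measure!r} has non-positive values; log transform undefined "
                    "(set zero_policy='half_min' to offset them)"
                )
        lx = np.log(x)
        sd = lx.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"measure {measure!r} is constant after log transform")
        z = (lx - lx.mean()) / sd
        X = np.column_stack([np.ones_like(z), z, C])

        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = fit.params, fit.bse
            if (not fit.mle_retvals.get("converged", False)) or np.abs(beta).max() > 15:
                raise PerfectSeparationError("diverging estimates")
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            separation = True
            beta, se = _ridge_logistic(X, y)
        b, s = float(beta[1]), float(se[1])
        pval = float(2.0 * stats.norm.sf(abs(b / s))) if s > 0 else 1.0
        fitted.append(
            MetaboliteORResult(
                measure=measure,
                or_per_sd=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * s)),
                ci_high=float(np.exp(b + 1.959963984540054 * s)),
                beta=b, se=s, pval=pval, fdr=np.nan, direction="ns",
                n=int(keep.sum()), separation=separation,
            )
        )
    adj = bh_adjust([r.pval for r in fitted])
    for r, q in zip(fitted, adj):
        r.fdr = float(q)
        if q < fdr_threshold:
            r.direction = "up" if r.or_per_sd > 1.0 else "down"
    return fitted


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test between two groups of one variable.

    Exact p-value for small samples without ties (both n <= 8), otherwise the
    tie-corrected normal approximation (no continuity correction, keeping the
    null p-value distribution close to uniform).  Returns ``(U, p)`` for the
    first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("compare_groups needs at least one value per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def metabolite_table(results: list[MetaboliteORResult],
                     category_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Forest-plot-ready results table, optionally ordered by panel category
    (lipoproteins, fatty acids, amino acids, glycolysis-related, other)."""
    df = pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "OR": [r.or_per_sd for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "pval": [r.pval for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
            "n": [r.n for r in results],
            "separation": [r.separation for r in results],
        }
    )
    if category_map:
        df["category"] = df["measure"].map(category_map).fillna("other")
        df = df.sort_values(["category", "measure"], kind="stable").reset_index(drop=True)
    return df
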