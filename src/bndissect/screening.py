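"""Gene pre-selection by per-replicate marginal regressions.

Each gene is tested one at a time in a two-regressor model
``response ~ intercept + gene_score + smoking`` (OLS for quantitative traits,
logistic for the binary disease status).  A gene is *retained* for a response
when its p-value beats the cutoff (default 0.1) in strictly more than half of
the replicates (the ">100 of 200" stability rule); when no replicates exist a
bootstrap over the pooled sample plays their part.  The final network node set
is the union of the retained sets over all responses.

No multiple-testing correction is applied inside the screen: the raw cutoff
plus cross-replicate stability is the error control (a null gene passes the
>100-of-200 rule with Binomial(200, 0.1) tail probability < 1e-10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .gene_scores import GeneScoreMatrix
from .synthetic_data import ReplicateSet

__all__ = [
    "MarginalResult",
    "ScreenResult",
    "marginal_regression",
    "batch_marginal_pvalues",
    "screen_replicates",
    "screen_bootstrap",
    "union_over_responses",
    "overlap_statistic",
]


@dataclass(frozen=True)
class MarginalResult:
    p_value: float
    coefficient: float
    degenerate: bool = False      # constant gene score
    fallback_linear: bool = False  # logistic fit failed, linear-probability used


@dataclass
class ScreenResult:
    """Per-gene replicate p-values and the retention decision for one response."""

    response: str
    p_values: pd.DataFrame  # genes x replicates
    p_cutoff: float
    retention_threshold: int
    mode: str = "replicates"
    flags: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return self.p_values.shape[1]

    @property
    def retention_counts(self) -> pd.Series:
        return (self.p_values < self.p_cutoff).sum(axis=1)

    @property
    def retained(self) -> frozenset[str]:
        counts = self.retention_counts
        return frozenset(counts.index[counts > self.retention_threshold])


def _ols_pvalue(x: np.ndarray, smoking: np.ndarray, y: np.ndarray) -> MarginalResult:
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([x, smoking]), has_constant="add")
    res = sm.OLS(y, X).fit()
    return MarginalResult(p_value=float(res.pvalues[1]), coefficient=float(res.params[1]))


def marginal_regression(
    gene_score,
    smoking,
    response,
    response_kind: str = "continuous",
) -> MarginalResult:
    """Two-sided p-value of the gene term in ``response ~ score + smoking``.

    A constant gene score cannot be tested: p = 1 with the degenerate flag.
    Logistic fits that fail (perfect separation, no convergence) fall back to
    a linear-probability OLS fit, flagged.
    """
    x = np.asarray(gene_score, dtype=float)
    s = np.asarray(smoking, dtype=float)
    y = np.asarray(response, dtype=float)
    if not (x.shape == s.shape == y.shape):
        raise DataError("gene score, smoking and response must have equal length")
    if np.ptp(x) == 0.0:
        return MarginalResult(p_value=1.0, coefficient=0.0, degenerate=True)
    if response_kind == "continuous":
        return _ols_pvalue(x, s, y)
    if response_kind != "binary":
        raise ValueError(f"unknown response_kind: {response_kind!r}")
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([x, s]), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", True) or not np.all(
            np.isfinite(res.bse)
        ):
            raise np.linalg.LinAlgError("logistic fit did not converge")
        return MarginalResult(
            p_value=float(res.pvalues[1]), coefficient=float(res.params[1])
        )
    except Exception:
        out = _ols_pvalue(x, s, y)
        return MarginalResult(
            p_value=out.p_value, coefficient=out.coefficient, fallback_linear=True
        )


def batch_marginal_pvalues(
    scores: np.ndarray,
    smoking: np.ndarray,
    response: np.ndarray,
    response_kind: str = "continuous",
) -> np.ndarray:
    """Gene-term p-values for many genes at once (columns of ``scores``).

    Continuous responses use the Frisch-Waugh closed form (residualize the
    response and every score on [1, smoking], then a simple regression with
    n - 3 residual df), which matches the per-gene OLS fit exactly.  Binary
    responses loop over :func:`marginal_regression`.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n = S.shape[0]
    s = np.asarray(smoking, dtype=float)
    y = np.asarray(response, dtype=float)
    if response_kind == "binary":
        return np.array(
            [marginal_regression(S[:, j], s, y, "binary").p_value for j in range(S.shape[1])]
        )
    Z = np.column_stack([np.ones(n), s])
    # residualize on [1, smoking]
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    ry = y - Z @ coef_y
    coef_S, *_ = np.linalg.lstsq(Z, S, rcond=None)
    RS = S - Z @ coef_S
    ss = np.einsum("ij,ij->j", RS, RS)
    num = RS.T @ ry
    dof = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / ss
        rss = ry @ ry - beta * num
        sigma2 = np.maximum(rss, 0.0) / dof
        tstat = beta / np.sqrt(sigma2 / ss)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p[~np.isfinite(tstat) | (ss <= 1e-12 * n)] = 1.0  # constant scores
    return p


def _resolve_threshold(n_replicates: int, retention_threshold: int | None) -> int:
    # ">100 of 200" scaled: strictly more than half of the replicates.
    return n_replicates // 2 if retention_threshold is None else int(retention_threshold)


def screen_replicates(
    replicates: ReplicateSet,
    scores: GeneScoreMatrix,
    response: str,
    p_cutoff: float = 0.1,
    retention_threshold: int | None = None,
) -> ScreenResult:
    """Apply the marginal screen to every phenotype replicate.

    Genotypes (hence gene scores) are shared across replicates; only the
    responses differ.  Retained iff the per-replicate pass count strictly
    exceeds ``retention_threshold`` (default: half the replicates).
    """
    threshold = _resolve_threshold(replicates.n_replicates, retention_threshold)
    if threshold >= replicates.n_replicates:
        raise DataError("retention_threshold must be below the number of replicates")
    kind = "binary" if response == "affected" else "continuous"
    S = scores.data.to_numpy()
    cols = {}
    for r, ph in enumerate(replicates.phenotypes):
        cols[r] = batch_marginal_pvalues(
            S, ph["smoking"].to_numpy(), ph[response].to_numpy(), kind
        )
    pv = pd.DataFrame(cols, index=scores.genes)
    return ScreenResult(
        response=response,
        p_values=pv,
        p_cutoff=p_cutoff,
        retention_threshold=threshold,
        mode="replicates",
    )


def screen_bootstrap(
    pooled_scores: pd.DataFrame,
    pooled_phenotypes: pd.DataFrame,
    response: str,
    n_bootstrap: int = 200,
    p_cutoff: float = 0.1,
    retention_threshold: int | None = None,
    seed: int = 0,
) -> ScreenResult:
    """Replicate-free variant: bootstrap resamples of the pooled sample.

    ``pooled_scores`` rows must align with ``pooled_phenotypes`` rows (e.g. the
    per-replicate score rows stacked in replicate order).  Each bootstrap draws
    individuals (rows) with replacement at full pooled size and is then treated
    exactly like a replicate.
    """
    if pooled_scores.shape[0] != pooled_phenotypes.shape[0]:
        raise DataError("pooled scores and phenotypes must have equal row counts")
    threshold = _resolve_threshold(n_bootstrap, retention_threshold)
    kind = "binary" if response == "affected" else "continuous"
    rng = np.random.default_rng(seed)
    S = pooled_scores.to_numpy()
    smoking = pooled_phenotypes["smoking"].to_numpy()
    y = pooled_phenotypes[response].to_numpy()
    n = S.shape[0]
    cols = {}
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        cols[b] = batch_marginal_pvalues(S[idx], smoking[idx], y[idx], kind)
    pv = pd.DataFrame(cols, index=list(pooled_scores.columns))
    return ScreenResult(
        response=response,
        p_values=pv,
        p_cutoff=p_cutoff,
        retention_threshold=threshold,
        mode="bootstrap",
    )


def union_over_responses(results: Sequence[ScreenResult]) -> frozenset[str]:
    """Union of the retained gene sets over the response variables."""
    if not results:
        raise DataError("need at least one screen result")
    out: set[str] = set()
    for r in results:
        out |= r.retained
    return frozenset(out)


def overlap_statistic(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard overlap |A n B| / |A u B| between two retained sets (1.0 if both empty)."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)
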