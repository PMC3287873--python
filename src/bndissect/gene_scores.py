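"""Annotation-stratified weighted-sum gene scores and the annotation weight w.

For each gene the burden score of an individual is the weighted sum of minor
allele counts over the gene's variants, with the Madsen-Browning weight
``1 / sqrt(n * q * (1 - q))`` putting more emphasis on rare variants.  Scores
are computed separately from synonymous (``S``) and nonsynonymous (``NS``)
variants and blended into a combined score ``w * NS + (1 - w) * S``, where the
annotation weight ``w`` is estimated from data: per-annotation gene-level
association p-values are converted into proportions of true-positive genes
(``P_s``, ``P_ns``) with a local-FDR style two-group fit, and ``w`` is a ratio
of those proportions.

Two details are deliberately configurable because the source method leaves
them open: the weight function (``madsen_browning`` default; ``inverse_maf``
and ``inverse_sd`` alternatives) and the ``w`` formula.  ``nonsyn_share``
(``P_ns / (P_s + P_ns)``) is the default since ``w`` is the weight *of the
nonsynonymous* scores; the literal ``as_printed`` form ``P_s / (P_s + P_ns)``
is kept available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericalError, UndefinedWeightError

__all__ = [
    "GeneScoreMatrix",
    "WeightEstimate",
    "WEIGHT_FUNCTIONS",
    "weighted_sum_score",
    "score_all_genes",
    "estimate_true_positive_proportion",
    "estimate_weight",
    "combine_scores",
]

AnnotationFilter = Literal["synonymous", "nonsynonymous", "all"]

#: MAF -> per-variant weight; ``n`` is the sample size.
WEIGHT_FUNCTIONS: Mapping[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "madsen_browning": lambda q, n: 1.0 / np.sqrt(n * q * (1.0 - q)),
    "inverse_maf": lambda q, n: 1.0 / q,
    "inverse_sd": lambda q, n: 1.0 / np.sqrt(q * (1.0 - q)),
}


@dataclass
class GeneScoreMatrix:
    """Individuals x genes score matrix plus provenance metadata."""

    data: pd.DataFrame
    score_kind: str
    variant_counts: pd.Series
    degenerate_genes: frozenset[str]
    weight_fn: str = "madsen_browning"
    weight: float | None = None  # w, for combined scores

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise DataError("gene score matrix contains non-finite entries")


@dataclass(frozen=True)
class WeightEstimate:
    """Estimated annotation weight and its ingredients."""

    w: float
    p_s: float
    p_ns: float
    formula: str
    pi1_method: str = ""

    def __post_init__(self) -> None:
        for name, v in (("w", self.w), ("p_s", self.p_s), ("p_ns", self.p_ns)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _variant_mafs(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    maf_source: str,
) -> np.ndarray:
    """Per-variant MAF, either from the table or estimated from the sample.

    The sample estimate uses the pseudo-count form ``(m + 1) / (2n + 2)`` so
    monomorphic variants never yield q = 0.
    """
    if maf_source == "table":
        return variants["maf"].to_numpy(dtype=float)
    if maf_source == "sample":
        n = genotypes.shape[0]
        counts = genotypes.to_numpy().sum(axis=0)
        return (counts + 1.0) / (2.0 * n + 2.0)
    raise ValueError(f"unknown maf_source: {maf_source!r}")


def weighted_sum_score(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    gene: str,
    annotation_filter: AnnotationFilter = "all",
    *,
    maf_source: str = "sample",
    weight_fn: str = "madsen_browning",
) -> pd.Series:
    """Weighted-sum burden score of one gene for every individual.

    A gene with no variants passing the annotation filter yields an all-zero
    score flagged via ``series.attrs["degenerate"]``.
    """
    gene_mask = (variants["gene_id"] == gene).to_numpy()
    if not gene_mask.any():
        raise DataError(f"unknown gene: {gene!r}")
    if annotation_filter != "all":
        gene_mask &= (variants["annotation"] == annotation_filter).to_numpy()
    name = f"{gene}:{annotation_filter}"
    if not gene_mask.any():
        out = pd.Series(0.0, index=genotypes.index, name=name)
        out.attrs["degenerate"] = True
        return out
    q = _variant_mafs(genotypes, variants, maf_source)[gene_mask]
    weights = WEIGHT_FUNCTIONS[weight_fn](q, genotypes.shape[0])
    cols = variants.loc[gene_mask, "variant_id"].tolist()
    scores = genotypes[cols].to_numpy(dtype=float) @ weights
    out = pd.Series(scores, index=genotypes.index, name=name)
    out.attrs["degenerate"] = False
    return out


def score_all_genes(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    annotation_filter: AnnotationFilter = "all",
    *,
    maf_source: str = "sample",
    weight_fn: str = "madsen_browning",
) -> GeneScoreMatrix:
    """Score every gene in the variant table; columns in sorted gene-id order."""
    genes = sorted(variants["gene_id"].unique())
    q_all = _variant_mafs(genotypes, variants, maf_source)
    weights = WEIGHT_FUNCTIONS[weight_fn](q_all, genotypes.shape[0])
    keep = np.ones(len(variants), dtype=bool)
    if annotation_filter != "all":
        keep = (variants["annotation"] == annotation_filter).to_numpy()
    G = genotypes.to_numpy(dtype=float)
    wv = np.where(keep, weights, 0.0)
    gene_of = variants["gene_id"].to_numpy()
    cols = np.empty((genotypes.shape[0], len(genes)))
    counts = {}
    degenerate = set()
    for k, gene in enumerate(genes):
        mask = (gene_of == gene) & keep
        counts[gene] = int(mask.sum())
        if counts[gene] == 0:
            cols[:, k] = 0.0
            degenerate.add(gene)
        else:
            idx = np.flatnonzero(gene_of == gene)
            cols[:, k] = G[:, idx] @ wv[idx]
    kind = annotation_filter if annotation_filter != "all" else "all"
    return GeneScoreMatrix(
        data=pd.DataFrame(cols, index=genotypes.index, columns=genes),
        score_kind=kind,
        variant_counts=pd.Series(counts),
        degenerate_genes=frozenset(degenerate),
        weight_fn=weight_fn,
    )


def informative_genes(matrix: GeneScoreMatrix) -> list[str]:
    """Genes whose score column actually varies in the sample.

    Rare variants are often monomorphic in a finite sample, leaving a gene's
    annotation-restricted score constant; such genes carry no association
    information (their p-value is pinned at 1) and must be excluded before
    estimating the true-positive proportion.
    """
    sd = matrix.data.to_numpy().std(axis=0)
    return [g for g, s in zip(matrix.data.columns, sd) if s > 0]


def estimate_true_positive_proportion(
    p_values,
    method: str = "central",
    *,
    central_z: float = 1.0,
    storey_lambda: float = 0.5,
) -> float:
    """Estimate pi1, the proportion of non-null genes, from association p-values.

    ``central`` (default) converts p to z = Phi^-1(1 - p) and matches the count
    of z in the central interval [-central_z, central_z] against the standard
    normal null (a local-FDR style null-proportion fit with a theoretical
    null); ``storey`` uses the classical tail estimator with the given lambda.
    The return value is clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 50:
        raise DataError("pi1 estimation needs a 1-d vector of >= 50 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    if np.allclose(p, p[0]):
        raise NumericalError("degenerate all-equal p-values; mixture fit impossible")
    if method == "central":
        z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
        central_mass = stats.norm.cdf(central_z) - stats.norm.cdf(-central_z)
        pi0 = np.mean(np.abs(z) <= central_z) / central_mass
    elif method == "storey":
        pi0 = np.mean(p > storey_lambda) / (1.0 - storey_lambda)
    else:
        raise ValueError(f"unknown pi1 method: {method!r}")
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def estimate_weight(
    pi1_synonymous: float,
    pi1_nonsynonymous: float,
    formula: str = "nonsyn_share",
    *,
    pi1_method: str = "central",
) -> WeightEstimate:
    """Annotation weight w from the two true-positive proportions."""
    p_s, p_ns = float(pi1_synonymous), float(pi1_nonsynonymous)
    if not (0.0 <= p_s <= 1.0 and 0.0 <= p_ns <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    total = p_s + p_ns
    if total == 0.0:
        raise UndefinedWeightError(
            "P_s = P_ns = 0: annotation weight undefined (caller may fall back to 0.5)"
        )
    if formula == "as_printed":
        w = p_s / total
    elif formula == "nonsyn_share":
        w = p_ns / total
    else:
        raise ValueError(f"unknown weight formula: {formula!r}")
    return WeightEstimate(w=w, p_s=p_s, p_ns=p_ns, formula=formula, pi1_method=pi1_method)


def combine_scores(
    synonymous: GeneScoreMatrix,
    nonsynonymous: GeneScoreMatrix,
    w: float,
) -> GeneScoreMatrix:
    """Convex combination ``w * NS + (1 - w) * S`` per individual and gene."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if synonymous.data.shape != nonsynonymous.data.shape or list(
        synonymous.data.columns
    ) != list(nonsynonymous.data.columns):
        raise DataError("synonymous/nonsynonymous matrices are not conformable")
    data = w * nonsynonymous.data + (1.0 - w) * synonymous.data
    return GeneScoreMatrix(
        data=data,
        score_kind="combined",
        variant_counts=synonymous.variant_counts + nonsynonymous.variant_counts,
        degenerate_genes=synonymous.degenerate_genes & nonsynonymous.degenerate_genes,
        weight_fn=synonymous.weight_fn,
        weight=float(w),
    )
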