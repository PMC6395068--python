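"""Per-gene multivariable additive linear models, significance calling and
the post-hoc exposure x duration interaction test.

Each gene's log2 intensity is fit by ordinary least squares on a 0/1-coded
design (intercept, exposure, genotype, sex); coefficients get two-sided t
tests, Benjamini-Hochberg q values per factor across all genes, and a
significance flag requiring both q below threshold and |beta| above the
log2 fold-change threshold. Durations are fitted separately; the only
cross-duration fit is the interaction model (intercept, exposure, duration,
exposure x duration) over the listed response genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from factorde.stats import bh_adjust
from factorde.types import (
    FACTOR_LEVELS,
    FACTORS,
    ExpressionMatrix,
    SampleDesign,
    ValidationError,
    align_design,
)

logger = logging.getLogger(__name__)

#: |beta| below this (with zero residual) is treated as exactly zero in the
#: degenerate-fit p-value convention.
_ZERO_BETA_TOL = 1e-8
_ZERO_RSS_TOL = 1e-18


def fold_change_to_beta(fc: float) -> float:
    """log2 of a fold-change ratio (1.3 -> 0.3785...)."""
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    return math.log2(fc)


@dataclass(frozen=True)
class SignificanceCriteria:
    q_threshold: float = 0.05
    fold_change_threshold: float = 1.3

    @property
    def beta_threshold(self) -> float:
        return fold_change_to_beta(self.fold_change_threshold)

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 1.0:
            raise ValidationError("fold_change_threshold must exceed 1")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must lie in (0, 1)")


def encode_design(design: SampleDesign) -> tuple[np.ndarray, list[str]]:
    """0/1 design matrix [intercept, exposure, genotype, sex].

    Second level of each factor (smoke / bENaC / male) codes 1. Requires a
    single duration and both levels of every factor present.
    """
    if len(set(design.duration_days)) > 1:
        raise ValidationError(
            "encode_design expects a single-duration design; "
            f"got durations {sorted(set(design.duration_days))}"
        )
    cols = [np.ones(design.n_samples)]
    names = ["intercept"]
    for factor, levels in FACTOR_LEVELS.items():
        values = getattr(design, factor)
        present = set(values)
        if len(present) < 2:
            raise ValidationError(
                f"factor {factor!r} has a single level {present} in this "
                "design; its effect is not estimable"
            )
        cols.append(np.array([1.0 if v == levels[1] else 0.0 for v in values]))
        names.append(factor)
    return np.column_stack(cols), names


def _ols_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of every column of Y (samples x genes) on X (samples x p).

    Returns (betas, p_values), each genes x p. Two-sided p from the t
    statistic on n-p residual df. Zero-residual fits use the degenerate
    convention: p=1 for (numerically) zero coefficients, p=0 otherwise.

    This single code path serves both the observed fit and the permutation
    null, so any change to the model propagates to both.
    """
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValidationError(f"no residual degrees of freedom (n={n}, p={p})")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y)  # p x genes
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # p x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    degenerate = sigma2 <= _ZERO_RSS_TOL
    if np.any(degenerate):
        logger.warning(
            "%d gene(s) with zero residual variance: degenerate p convention "
            "applied (p=1 for zero coefficients, p=0 otherwise)",
            int(degenerate.sum()),
        )
        zero_beta = np.abs(B) <= _ZERO_BETA_TOL
        deg = np.broadcast_to(degenerate, B.shape)
        pvals = np.where(deg & zero_beta, 1.0, pvals)
        pvals = np.where(deg & ~zero_beta, 0.0, pvals)
    return B.T, pvals.T


def fit_gene_models(
    expr: ExpressionMatrix,
    design: SampleDesign,
    criteria: SignificanceCriteria | None = None,
) -> pd.DataFrame:
    """Fit the additive exposure+genotype+sex model to every gene.

    Returns an effect table indexed by gene with, per factor f, columns
    ``beta_f``, ``p_f``, ``q_f``, ``significant_f``. q values are BH-adjusted
    per factor across all genes; the significance flag requires
    q < q_threshold and |beta| > log2(fold_change_threshold).
    """
    criteria = criteria or SignificanceCriteria()
    design = align_design(expr, design)
    X, names = encode_design(design)
    if design.n_samples <= X.shape[1]:
        raise ValidationError(
            f"need more samples ({design.n_samples}) than parameters "
            f"({X.shape[1]}) for residual-based inference"
        )
    betas, pvals = _ols_stats(X, expr.values.T)
    out = pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene_id"))
    for j, factor in enumerate(names):
        if factor == "intercept":
            out["intercept"] = betas[:, j]
            continue
        q = bh_adjust(pvals[:, j])
        out[f"beta_{factor}"] = betas[:, j]
        out[f"p_{factor}"] = pvals[:, j]
        out[f"q_{factor}"] = q
        out[f"significant_{factor}"] = (q < criteria.q_threshold) & (
            np.abs(betas[:, j]) > criteria.beta_threshold
        )
    return out


def call_response_genes(effects: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Significant genes for a factor, tagged up/down by the beta sign,
    ordered by |beta| descending then identifier."""
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}; known: {FACTORS}")
    cols = (f"beta_{factor}", f"significant_{factor}")
    for c in cols:
        if c not in effects.columns:
            raise KeyError(f"effect table lacks column {c!r}")
    sig = effects[effects[f"significant_{factor}"]]
    beta = sig[f"beta_{factor}"]
    out = pd.DataFrame(
        {
            "beta": beta,
            "direction": np.where(beta > 0, "up", "down"),
        },
        index=sig.index,
    )
    out = out.iloc[
        np.lexsort((out.index.to_numpy(), -np.abs(out["beta"].to_numpy())))
    ]
    return out


def fit_interaction_models(
    expr_both: ExpressionMatrix,
    design_both: SampleDesign,
    exposure_genes: list[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Post-hoc exposure x duration model for the listed response genes.

    Columns: intercept, exposure (smoke=1), duration (day5=1) and their
    product. q_interaction is BH-adjusted over the listed genes only;
    `duration_dependent` flags q_interaction < q_threshold.
    """
    design_both = align_design(expr_both, design_both)
    durations = sorted(set(design_both.duration_days))
    if len(durations) != 2:
        raise ValidationError(
            f"interaction model needs both durations; got {durations}"
        )
    missing = [g for g in exposure_genes if g not in set(expr_both.gene_ids)]
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {missing[:5]}")
    sub = expr_both.subset_genes(exposure_genes)
    exposure = np.array(
        [1.0 if v == "smoke" else 0.0 for v in design_both.exposure]
    )
    day_hi = np.array(
        [1.0 if d == durations[1] else 0.0 for d in design_both.duration_days]
    )
    X = np.column_stack(
        [np.ones(design_both.n_samples), exposure, day_hi, exposure * day_hi]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("interaction design matrix is rank deficient")
    betas, pvals = _ols_stats(X, sub.values.T)
    q = bh_adjust(pvals[:, 3])
    return pd.DataFrame(
        {
            "beta_exposure": betas[:, 1],
            "beta_duration": betas[:, 2],
            "beta_interaction": betas[:, 3],
            "p_interaction": pvals[:, 3],
            "q_interaction": q,
            "duration_dependent": q < q_threshold,
        },
        index=pd.Index(exposure_genes, name="gene_id"),
    )
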