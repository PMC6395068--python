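"""Gene-set association scores with a sample-permutation null.

Per-gene statistics are sign(beta) * (-log p) for the chosen factor; a
set's composite score is the sum of its members' statistics divided by
sqrt(set size). Significance thresholds come from refitting the full
per-gene linear model under random permutations of the sample labels
(whole design rows shuffled against expression columns) and applying a
per-tail plug-in FDR estimate: mean null exceedances over observed
exceedances.

The permutation loop calls the same `_ols_stats` kernel as the observed
fit, so any change to the model propagates to the null by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from factorde import linmod
from factorde.types import (
    FACTORS,
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    SampleDesign,
    align_design,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def match_symbols(
    expr_genes: list[str],
    collection: GeneSetCollection,
    min_set_size: int = 5,
) -> dict[str, list[str]]:
    """Case-insensitive exact matching of set members to expression gene
    identifiers. Sets matching fewer than `min_set_size` genes are dropped
    (with a logged count); matched lists use the expression casing."""
    folded = {}
    for g in expr_genes:
        folded.setdefault(g.casefold(), g)
    matched: dict[str, list[str]] = {}
    dropped = 0
    for name, members in collection.sets.items():
        hits = [folded[m.casefold()] for m in members if m.casefold() in folded]
        if len(hits) >= max(min_set_size, 1):
            matched[name] = hits
        else:
            dropped += 1
    if dropped:
        logger.info(
            "dropped %d set(s) with fewer than %d matched genes", dropped, min_set_size
        )
    return matched


def _signed_neg_log(
    betas: np.ndarray, pvals: np.ndarray, log_base: str, p_floor: float = P_FLOOR
) -> np.ndarray:
    p = np.maximum(pvals, p_floor)
    logs = -np.log10(p) if log_base == "10" else -np.log(p)
    return np.sign(betas) * logs


def gene_stats(
    effects: pd.DataFrame,
    factor: str,
    log_base: str = "natural",
    p_floor: float = P_FLOOR,
) -> pd.Series:
    """Signed -log(p) statistic per gene for one factor; every gene is
    included regardless of significance. p is floored at `p_floor`."""
    if factor not in FACTORS:
        raise KeyError(f"unknown factor {factor!r}; known: {FACTORS}")
    if log_base not in ("natural", "10"):
        raise ValueError('log_base must be "natural" or "10"')
    if p_floor <= 0:
        raise ValueError("p_floor must be positive")
    beta = effects[f"beta_{factor}"].to_numpy(float)
    p = effects[f"p_{factor}"].to_numpy(float)
    return pd.Series(
        _signed_neg_log(beta, p, log_base, p_floor), index=effects.index, name="stat"
    )


def gsa_score(stats: pd.Series, matched: list[str]) -> float:
    """Composite set score: sum of member statistics over sqrt(m)."""
    if len(matched) == 0:
        raise ValueError("matched gene list is empty")
    missing = [g for g in matched if g not in stats.index]
    if missing:
        raise KeyError(f"gene(s) absent from stat vector: {missing[:5]}")
    return float(stats.loc[matched].sum() / math.sqrt(len(matched)))


def _membership_matrix(
    matched: dict[str, list[str]], gene_ids: list[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Indicator matrix (sets x genes) and per-set sqrt(m) normalizers."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    names = list(matched)
    M = np.zeros((len(names), len(gene_ids)))
    for r, name in enumerate(names):
        for g in matched[name]:
            M[r, idx[g]] = 1.0
    m = M.sum(axis=1)
    return names, M, np.sqrt(m)


@dataclass
class PermutationNull:
    set_names: list[str]
    null_scores: np.ndarray  # sets x n_permutations
    n_permutations: int
    seed: int
    factor: str
    log_base: str


def permutation_null(
    expr: ExpressionMatrix,
    design: SampleDesign,
    collection: GeneSetCollection,
    factor: str,
    n_perm: int = 1000,
    seed: int = 0,
    log_base: str = "natural",
    min_set_size: int = 5,
    p_floor: float = P_FLOOR,
) -> PermutationNull:
    """Null distribution of every set score under random permutations of
    sample labels (all factor columns shuffled together)."""
    design = align_design(expr, design)
    X, names = linmod.encode_design(design)
    j = names.index(factor)
    matched = match_symbols(expr.gene_ids, collection, min_set_size)
    set_names, M, sqrt_m = _membership_matrix(matched, expr.gene_ids)
    Y = expr.values.T  # samples x genes
    rng = np.random.default_rng(seed)
    null = np.empty((len(set_names), n_perm))
    for b in range(n_perm):
        perm = rng.permutation(design.n_samples)
        # shuffling design rows against expression columns == permuting X rows
        betas, pvals = linmod._ols_stats(X[perm], Y)
        stats = _signed_neg_log(betas[:, j], pvals[:, j], log_base, p_floor)
        null[:, b] = (M @ stats) / sqrt_m
    return PermutationNull(
        set_names=set_names,
        null_scores=null,
        n_permutations=n_perm,
        seed=seed,
        factor=factor,
        log_base=log_base,
    )


@dataclass
class GSAThresholds:
    positive: float  # +inf when no positive score reaches the FDR level
    negative: float
    fdr: float


def _tail_threshold(
    observed: np.ndarray, null: np.ndarray, fdr: float, tail: int
) -> float:
    """Smallest |t| with plug-in FDR <= fdr for one tail (tail=+1 or -1)."""
    cand = np.sort(observed[np.sign(observed) == tail] * tail)  # ascending magnitudes
    signed_null = null * tail
    signed_obs = observed * tail
    for t in cand:
        n_null = np.mean(np.sum(signed_null >= t, axis=0))  # mean over perms
        n_obs = np.sum(signed_obs >= t)
        if n_obs > 0 and n_null / n_obs <= fdr:
            return float(t * tail)
    return float(tail * np.inf)


def call_significant_sets(
    observed: pd.Series,
    matched: dict[str, list[str]],
    null: PermutationNull,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, GSAThresholds]:
    """Flag sets whose scores lie beyond the per-tail permutation FDR
    thresholds; also reports per-set empirical p values
    (1 + #{|null| >= |obs|}) / (1 + B) against the set's own null row."""
    if list(observed.index) != null.set_names:
        observed = observed.loc[null.set_names]
    obs = observed.to_numpy(float)
    t_pos = _tail_threshold(obs, null.null_scores, fdr, +1)
    t_neg = _tail_threshold(obs, null.null_scores, fdr, -1)
    exceed = np.sum(
        np.abs(null.null_scores) >= np.abs(obs)[:, None], axis=1
    )
    emp_p = (1.0 + exceed) / (1.0 + null.n_permutations)
    significant = (obs >= t_pos) | (obs <= t_neg)
    result = pd.DataFrame(
        {
            "m": [len(matched[s]) for s in null.set_names],
            "score": obs,
            "empirical_p": emp_p,
            "significant": significant,
            "direction": np.where(obs >= 0, "up", "down"),
        },
        index=pd.Index(null.set_names, name="gene_set"),
    )
    return result, GSAThresholds(positive=t_pos, negative=t_neg, fdr=fdr)


def run_gsa(
    expr: ExpressionMatrix,
    design: SampleDesign,
    collection: GeneSetCollection,
    factors: tuple[str, ...] = FACTORS,
    config: RunConfig | None = None,
) -> dict[str, tuple[pd.DataFrame, GSAThresholds]]:
    """Full gene-set analysis, one result table + thresholds per factor."""
    config = config or RunConfig()
    design = align_design(expr, design)
    criteria = linmod.SignificanceCriteria(
        config.q_threshold, config.fold_change_threshold
    )
    effects = linmod.fit_gene_models(expr, design, criteria)
    matched = match_symbols(expr.gene_ids, collection, config.min_set_size)
    results: dict[str, tuple[pd.DataFrame, GSAThresholds]] = {}
    for factor in factors:
        stats = gene_stats(effects, factor, config.log_base_for_gsa)
        observed = pd.Series(
            {name: gsa_score(stats, genes) for name, genes in matched.items()}
        )
        null = permutation_null(
            expr,
            design,
            collection,
            factor,
            n_perm=config.n_permutations,
            seed=config.rng_seed,
            log_base=config.log_base_for_gsa,
            min_set_size=config.min_set_size,
        )
        results[factor] = call_significant_sets(
            observed, matched, null, fdr=config.q_threshold
        )
    return results
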