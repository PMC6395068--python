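"""Synthetic factorial expression datasets with known ground truth.

Generates full-factorial exposure x genotype x sex designs at one or two
durations, additive per-gene log2 effects with optional exposure x duration
interactions and Gaussian noise, and gene-set collections whose members
carry concordant signed exposure effects (enriched) or none (null).

One seed governs everything; each stage draws from its own deterministic
substream so enlarging one stage does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from factorde.types import (
    FACTOR_LEVELS,
    FACTORS,
    ExpressionMatrix,
    GeneSetCollection,
    SampleDesign,
)

#: cosmetic normalized-microarray baseline range, log2 units
BASELINE_RANGE = (4.0, 12.0)
#: default effect magnitudes straddle the 0.379 calling threshold
DEFAULT_EFFECT_RANGE = (0.4, 2.0)
DEFAULT_INTERACTION_FRACTION = 0.3

_STAGES = ("baseline", "effects", "interaction", "noise", "gene_sets")


@dataclass
class TruthTable:
    """Per-gene generating parameters plus per-set enrichment labels."""

    genes: pd.DataFrame  # baseline, beta_exposure/_genotype/_sex/_interaction, noise_sd
    set_labels: dict[str, str] = field(default_factory=dict)  # enriched_up/enriched_down/null

    def null_genes(self) -> list[str]:
        b = self.genes[
            ["beta_exposure", "beta_genotype", "beta_sex", "beta_interaction"]
        ]
        return list(self.genes.index[(b == 0).all(axis=1)])

    def affected_genes(self, factor: str) -> list[str]:
        col = "beta_interaction" if factor == "interaction" else f"beta_{factor}"
        return list(self.genes.index[self.genes[col] != 0])


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(c) for name, c in zip(_STAGES, children)}


def generate_design(
    n_per_cell: int, durations: Sequence[int] = (1, 5)
) -> SampleDesign:
    """Full factorial exposure x genotype x sex design, `n_per_cell`
    samples per cell per duration, deterministically named."""
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2 (model unfittable below that)")
    durations = sorted(set(int(d) for d in durations))
    sample_ids, exposure, genotype, sex, dur = [], [], [], [], []
    for d in durations:
        for e in FACTOR_LEVELS["exposure"]:
            for g in FACTOR_LEVELS["genotype"]:
                for s in FACTOR_LEVELS["sex"]:
                    for r in range(1, n_per_cell + 1):
                        sample_ids.append(f"d{d}_{e}_{g}_{s}_{r:02d}")
                        exposure.append(e)
                        genotype.append(g)
                        sex.append(s)
                        dur.append(d)
    return SampleDesign(sample_ids, exposure, genotype, sex, dur, tuple(durations))


def _pick_affected(
    rng: np.random.Generator, n_genes: int, fraction: float
) -> np.ndarray:
    """Deterministic count: round(fraction * n_genes) genes, chosen uniformly."""
    n_aff = int(round(fraction * n_genes))
    return rng.choice(n_genes, size=n_aff, replace=False)


def generate_expression(
    design: SampleDesign,
    n_genes: int,
    affected_fraction: float | Mapping[str, float] = 0.05,
    effect_size_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    interaction_fraction: float = DEFAULT_INTERACTION_FRACTION,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate log2 intensities over a factorial design.

    value(g, s) = baseline(g) + sum_f beta_f(g) x_f(s)
                  + beta_int(g) x_exposure(s) x_day_high(s) + Normal(0, noise_sd^2)

    Effect signs are +/- with equal probability, magnitudes uniform on
    `effect_size_range`. `affected_fraction` may be a single probability or
    a per-factor mapping; exactly round(fraction * n_genes) genes per factor
    carry a nonzero effect. Interactions apply to `interaction_fraction` of
    the exposure-affected genes (only when the design has two durations).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = effect_size_range
    if not (0 < lo <= hi <= 8):
        raise ValueError("effect_size_range must lie within (0, 8]")
    if isinstance(affected_fraction, Mapping):
        fractions = {f: float(affected_fraction.get(f, 0.0)) for f in FACTORS}
    else:
        fractions = {f: float(affected_fraction) for f in FACTORS}
    for f, fr in fractions.items():
        if not 0.0 <= fr <= 1.0:
            raise ValueError(f"affected fraction for {f!r} outside [0, 1]")
    if not 0.0 <= interaction_fraction <= 1.0:
        raise ValueError("interaction_fraction outside [0, 1]")

    rngs = _stage_rngs(seed)
    gene_ids = [f"gene{g:05d}" for g in range(1, n_genes + 1)]
    baseline = rngs["baseline"].uniform(*BASELINE_RANGE, size=n_genes)

    betas = {f: np.zeros(n_genes) for f in FACTORS}
    eff_rng = rngs["effects"]
    for f in FACTORS:
        idx = _pick_affected(eff_rng, n_genes, fractions[f])
        mags = eff_rng.uniform(lo, hi, size=idx.size)
        signs = eff_rng.choice([-1.0, 1.0], size=idx.size)
        betas[f][idx] = signs * mags

    durations = sorted(set(design.duration_days))
    beta_int = np.zeros(n_genes)
    if len(durations) == 2 and interaction_fraction > 0:
        int_rng = rngs["interaction"]
        exposed_idx = np.flatnonzero(betas["exposure"])
        n_int = int(round(interaction_fraction * exposed_idx.size))
        chosen = int_rng.choice(exposed_idx, size=n_int, replace=False)
        mags = int_rng.uniform(lo, hi, size=n_int)
        signs = int_rng.choice([-1.0, 1.0], size=n_int)
        beta_int[chosen] = signs * mags

    x = {
        f: np.array(
            [1.0 if v == FACTOR_LEVELS[f][1] else 0.0 for v in getattr(design, f)]
        )
        for f in FACTORS
    }
    day_high = np.array(
        [1.0 if d == durations[-1] else 0.0 for d in design.duration_days]
    )
    if len(durations) < 2:
        day_high = np.zeros(design.n_samples)

    values = baseline[:, None] + sum(
        np.outer(betas[f], x[f]) for f in FACTORS
    )
    values = values + np.outer(beta_int, x["exposure"] * day_high)
    if noise_sd > 0:
        values = values + rngs["noise"].normal(
            0.0, noise_sd, size=(n_genes, design.n_samples)
        )

    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "baseline": baseline,
                "beta_exposure": betas["exposure"],
                "beta_genotype": betas["genotype"],
                "beta_sex": betas["sex"],
                "beta_interaction": beta_int,
                "noise_sd": noise_sd,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    expr = ExpressionMatrix(gene_ids, list(design.sample_ids), values)
    return expr, truth


def generate_gene_sets(
    truth: TruthTable,
    n_sets: int,
    size_range: tuple[int, int] = (10, 50),
    enriched_fraction: float = 0.3,
    seed: int = 0,
    concordant_fraction: float = 0.8,
) -> GeneSetCollection:
    """Gene sets with known enrichment labels recorded on `truth`.

    Enriched sets draw >= `concordant_fraction` of members from exposure
    genes whose beta sign matches the set label (up/down alternating) and
    the remainder from null genes; null sets draw uniformly from null
    genes. Universe = all generated genes.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    lo, hi = size_range
    n_genes = len(truth.genes)
    if not (5 <= lo <= hi <= n_genes):
        raise ValueError(f"size_range must lie within [5, {n_genes}]")
    rng = _stage_rngs(seed)["gene_sets"]
    beta_exp = truth.genes["beta_exposure"]
    up_genes = np.array(truth.genes.index[beta_exp > 0])
    down_genes = np.array(truth.genes.index[beta_exp < 0])
    null_genes = np.array(truth.null_genes())

    n_enriched = int(round(enriched_fraction * n_sets))
    sets: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            direction = "up" if i % 2 == 0 else "down"
            pool = up_genes if direction == "up" else down_genes
            n_signal = int(np.ceil(concordant_fraction * size))
            n_bg = size - n_signal
            if pool.size < n_signal or null_genes.size < n_bg:
                raise ValueError(
                    f"not enough {direction}-regulated ({pool.size}) or null "
                    f"({null_genes.size}) genes for an enriched set of size {size}"
                )
            members = list(rng.choice(pool, size=n_signal, replace=False)) + list(
                rng.choice(null_genes, size=n_bg, replace=False)
            )
            label = f"enriched_{direction}"
        else:
            if null_genes.size < size:
                raise ValueError(
                    f"not enough null genes ({null_genes.size}) for a null "
                    f"set of size {size}"
                )
            members = list(rng.choice(null_genes, size=size, replace=False))
            label = "null"
        name = f"set{i + 1:03d}_{label}"
        sets[name] = members
        labels[name] = label
    truth.set_labels.update(labels)
    return GeneSetCollection(
        sets,
        {n: f"synthetic {labels[n]} set" for n in sets},
        universe=list(truth.genes.index),
    )
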