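"""Set algebra and summaries over response-gene lists: duration
partitioning, cross-factor breakdowns and cross-duration beta comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from factorde.stats import (
    RegressionLine,
    ols_line_with_intervals,
    pearson_correlation_test,
    round_half_up,
)


@dataclass(frozen=True)
class DurationPartition:
    """Inclusion-exclusion partition of two duration-specific gene lists."""

    n_day1: int
    n_day5: int
    shared: list[str]
    unique_day1: list[str]
    unique_day5: list[str]
    pooled: list[str]

    @property
    def percent_duration_specific(self) -> int:
        """Whole-percent share of pooled genes significant at only one
        duration."""
        frac = (len(self.unique_day1) + len(self.unique_day5)) / len(self.pooled)
        return int(round_half_up(100.0 * frac))


def partition_by_duration(
    genes_day1: list[str], genes_day5: list[str]
) -> DurationPartition:
    """Exact union/intersection/difference partition of the two lists."""
    for name, lst in (("genes_day1", genes_day1), ("genes_day5", genes_day5)):
        if len(set(lst)) != len(lst):
            dupes = sorted({g for g in lst if lst.count(g) > 1})
            raise ValueError(f"{name} contains duplicates: {dupes[:5]}")
    s1, s5 = set(genes_day1), set(genes_day5)
    shared = sorted(s1 & s5)
    unique1 = sorted(s1 - s5)
    unique5 = sorted(s5 - s1)
    pooled = sorted(s1 | s5)
    assert len(pooled) == len(s1) + len(s5) - len(shared)
    return DurationPartition(
        n_day1=len(s1),
        n_day5=len(s5),
        shared=shared,
        unique_day1=unique1,
        unique_day5=unique5,
        pooled=pooled,
    )


@dataclass(frozen=True)
class FactorBreakdown:
    """Mutually exclusive split of exposure-response genes by additional
    genotype/sex significance. The two '..._only' categories exclude the
    triple-significant genes."""

    exposure_only: int
    exposure_and_genotype_only: int
    exposure_and_sex_only: int
    exposure_genotype_sex: int

    @property
    def total(self) -> int:
        return (
            self.exposure_only
            + self.exposure_and_genotype_only
            + self.exposure_and_sex_only
            + self.exposure_genotype_sex
        )

    @property
    def percent_multifactor(self) -> int:
        multi = self.total - self.exposure_only
        return int(round_half_up(100.0 * multi / self.total))


def cross_factor_breakdown(effects: pd.DataFrame) -> FactorBreakdown:
    """Categorize exposure-significant genes by additional genotype and/or
    sex significance (disjoint, exhaustive categories)."""
    needed = [f"significant_{f}" for f in ("exposure", "genotype", "sex")]
    missing = [c for c in needed if c not in effects.columns]
    if missing:
        raise KeyError(f"effect table lacks significance column(s): {missing}")
    exp = effects["significant_exposure"].to_numpy(bool)
    gen = effects["significant_genotype"].to_numpy(bool)
    sex = effects["significant_sex"].to_numpy(bool)
    sub_g, sub_s = gen[exp], sex[exp]
    triple = int(np.sum(sub_g & sub_s))
    g_only = int(np.sum(sub_g & ~sub_s))
    s_only = int(np.sum(~sub_g & sub_s))
    e_only = int(np.sum(~sub_g & ~sub_s))
    return FactorBreakdown(
        exposure_only=e_only,
        exposure_and_genotype_only=g_only,
        exposure_and_sex_only=s_only,
        exposure_genotype_sex=triple,
    )


@dataclass(frozen=True)
class DurationComparison:
    r: float
    p: float
    line: RegressionLine
    table: pd.DataFrame  # gene_id index; beta_day1, beta_day5, flagged


def compare_duration_betas(
    effects_day1: pd.DataFrame,
    effects_day5: pd.DataFrame,
    factor: str,
    gene_scope: list[str],
    interaction: pd.DataFrame | None = None,
    level: float = 0.95,
) -> DurationComparison:
    """Pearson correlation and least-squares line relating the per-gene
    betas at the two durations over `gene_scope`; genes flagged as
    duration-dependent in `interaction` are marked in the output table."""
    col = f"beta_{factor}"
    for name, tbl in (("day-1", effects_day1), ("day-5", effects_day5)):
        if col not in tbl.columns:
            raise KeyError(f"{name} table lacks column {col!r}")
        absent = [g for g in gene_scope if g not in tbl.index]
        if absent:
            raise KeyError(f"scope gene(s) missing from {name} table: {absent[:5]}")
    b1 = effects_day1.loc[gene_scope, col].to_numpy(float)
    b5 = effects_day5.loc[gene_scope, col].to_numpy(float)
    r, p = pearson_correlation_test(b1, b5)
    line = ols_line_with_intervals(b1, b5, level=level)
    flagged = np.zeros(len(gene_scope), dtype=bool)
    if interaction is not None and "duration_dependent" in interaction.columns:
        dd = set(interaction.index[interaction["duration_dependent"]])
        flagged = np.array([g in dd for g in gene_scope])
    table = pd.DataFrame(
        {"beta_day1": b1, "beta_day5": b5, "flagged": flagged},
        index=pd.Index(gene_scope, name="gene_id"),
    )
    return DurationComparison(r=r, p=p, line=line, table=table)
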