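"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class FormatError(ValueError):
    """Malformed external input (bad layout, non-numeric cell, short line)."""


class ValidationError(ValueError):
    """Structurally well-formed input that violates a domain invariant."""


EXPOSURE_LEVELS = ("sham", "smoke")
GENOTYPE_LEVELS = ("WT", "bENaC")
SEX_LEVELS = ("female", "male")
DEFAULT_DURATIONS = (1, 5)

#: Reference (0-coded) level per factor; the other level is coded 1, so a
#: positive coefficient means higher in smoke / bENaC / male.
FACTOR_LEVELS: dict[str, tuple[str, str]] = {
    "exposure": EXPOSURE_LEVELS,
    "genotype": GENOTYPE_LEVELS,
    "sex": SEX_LEVELS,
}
FACTORS = tuple(FACTOR_LEVELS)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 intensities with identifier vectors.

    Invariants: all values finite, identifiers unique, shape consistent.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset in the order of `genes`; unknown genes raise."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class SampleDesign:
    """Per-sample factor levels for the 2x2x2 (x duration) design."""

    sample_ids: list[str]
    exposure: list[str]
    genotype: list[str]
    sex: list[str]
    duration_days: list[int]
    allowed_durations: tuple[int, ...] = DEFAULT_DURATIONS

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name in ("exposure", "genotype", "sex", "duration_days"):
            col = getattr(self, name)
            if len(col) != n:
                raise ValidationError(
                    f"column {name!r} has {len(col)} entries for {n} samples"
                )
        for name, levels in FACTOR_LEVELS.items():
            for v in getattr(self, name):
                if v not in levels:
                    raise ValidationError(
                        f"invalid {name} level {v!r}; allowed: {levels}"
                    )
        self.duration_days = [int(d) for d in self.duration_days]
        for d in self.duration_days:
            if d not in self.allowed_durations:
                raise ValidationError(
                    f"invalid duration_days value {d}; allowed: "
                    f"{self.allowed_durations}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def factor_values(self, factor: str) -> list:
        if factor == "duration":
            return list(self.duration_days)
        if factor not in FACTOR_LEVELS:
            raise KeyError(f"unknown factor {factor!r}; known: {FACTORS}")
        return list(getattr(self, factor))

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples absent from design: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return SampleDesign(
            [self.sample_ids[i] for i in rows],
            [self.exposure[i] for i in rows],
            [self.genotype[i] for i in rows],
            [self.sex[i] for i in rows],
            [self.duration_days[i] for i in rows],
            self.allowed_durations,
        )

    def for_duration(self, duration: int) -> "SampleDesign":
        keep = [s for s, d in zip(self.sample_ids, self.duration_days) if d == duration]
        return self.subset(keep)


def align_design(expr: ExpressionMatrix, design: SampleDesign) -> SampleDesign:
    """Reconcile a design with a matrix by sample identifier.

    Returns the design reordered to the matrix's sample order; the two must
    cover the same sample set.
    """
    if set(expr.sample_ids) != set(design.sample_ids):
        only_e = set(expr.sample_ids) - set(design.sample_ids)
        only_d = set(design.sample_ids) - set(expr.sample_ids)
        raise ValidationError(
            "expression and design sample sets differ "
            f"(matrix-only: {sorted(only_e)[:5]}, design-only: {sorted(only_d)[:5]})"
        )
    return design.subset(expr.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with case-insensitive member identity.

    Members are deduplicated case-insensitively, keeping the casing of the
    first occurrence for display. An optional universe restricts which
    symbols take part in enrichment computations.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: set[str] = set()
            kept: list[str] = []
            for m in members:
                key = m.casefold()
                if key not in seen:
                    seen.add(key)
                    kept.append(m)
            cleaned[name] = kept
        self.sets = cleaned
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def members_folded(self, name: str) -> set[str]:
        return {m.casefold() for m in self.sets[name]}


@dataclass
class RunConfig:
    """Thresholds and knobs for a pipeline run."""

    q_threshold: float = 0.05
    fold_change_threshold: float = 1.3
    n_permutations: int = 1000
    kmeans_k: int = 5
    kmeans_restarts: int = 50
    rng_seed: int = 0
    log_base_for_gsa: str = "natural"  # {"natural", "10"}
    min_set_size: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValidationError("q_threshold must lie in (0, 1)")
        if self.fold_change_threshold <= 1.0:
            raise ValidationError("fold_change_threshold must exceed 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.log_base_for_gsa not in ("natural", "10"):
            raise ValidationError('log_base_for_gsa must be "natural" or "10"')

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})  # type: ignore[arg-type]
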