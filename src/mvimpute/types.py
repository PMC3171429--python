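"""Shared domain types.

Conventions used throughout the package:

* expression matrices are genes-in-rows, samples-in-columns, log2-ratio scale;
* missingness never lives inside a matrix as a sentinel value — it is carried
  by a boolean :class:`MissingMask` aligned with the matrix;
* class labels are 0/1, one per sample (column).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "MissingMask",
    "ClassLabels",
    "SimulationParameters",
    "SimulatedDataset",
    "ResultRecord",
    "check_aligned",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples grid of finite log2-ratio expression values."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, d = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != d:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {d} columns")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != d:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite; use a MissingMask "
                             "to mark missing entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_values(cls, values: np.ndarray) -> "ExpressionMatrix":
        """Wrap a bare array with generated g<i>/s<j> identifiers."""
        values = np.asarray(values, dtype=float)
        n, d = values.shape
        return cls(values, [f"g{i}" for i in range(n)], [f"s{j}" for j in range(d)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids),
                                list(self.sample_ids))


@dataclass
class MissingMask:
    """Boolean genes x samples grid; ``True`` marks a missing entry."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("mask flags must be a 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape

    @property
    def rate(self) -> float:
        return float(self.flags.mean())

    @property
    def n_missing(self) -> int:
        return int(self.flags.sum())

    def validate_no_empty_gene(self) -> None:
        """Raise if any gene row is entirely missing."""
        fully = np.flatnonzero(self.flags.all(axis=1))
        if fully.size:
            raise ValueError(
                f"gene rows {fully[:5].tolist()} are entirely missing; lower the "
                "missing-value rate or the noise level")

    def copy(self) -> "MissingMask":
        return MissingMask(self.flags.copy())

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "MissingMask":
        return cls(np.zeros(shape, dtype=bool))


@dataclass
class ClassLabels:
    """Per-sample 0/1 class labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.labels)

    def require_two_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


def check_aligned(matrix: ExpressionMatrix, mask: MissingMask) -> None:
    """Fail fast when a matrix and its mask disagree on shape."""
    if matrix.shape != mask.shape:
        raise ValueError(f"matrix shape {matrix.shape} != mask shape {mask.shape}")


@dataclass(frozen=True)
class SimulationParameters:
    """Tunable constants of the generative model.

    Attributes
    ----------
    n_genes, n_markers
        Total genes and the number carrying a class fold-change (markers are
        the first ``n_markers`` rows).
    n_train, n_test
        Balanced sample counts for the training and testing partitions.
    mu_fold, sd_fold
        Mean and SD (log2 units) of the Gaussian fold-change magnitudes;
        0.58 corresponds to a 1.5-fold change on the linear scale.
    block_sd, block_corr, block_size
        Gene-effect covariance: genes in blocks of ``block_size`` share
        pairwise correlation ``block_corr`` with per-gene SD ``block_sd``;
        genes in different blocks are uncorrelated.
    noise_mean
        Mean of the exponential distribution the per-gene noise SDs are drawn
        from (heteroscedastic additive noise).
    mv_rate, mask_mode
        Fraction of entries marked missing, and whether they are chosen by
        quality (largest |noise|) or uniformly at random.
    """

    n_genes: int = 500
    n_markers: int = 30
    n_train: int = 60
    n_test: int = 200
    mu_fold: float = 0.58
    sd_fold: float = 0.1
    block_sd: float = 0.8
    block_corr: float = 0.5
    block_size: int = 25
    noise_mean: float = 0.4
    mv_rate: float = 0.10
    mask_mode: str = "quality"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers > self.n_genes:
            raise ValueError("n_markers must not exceed n_genes")
        if self.n_genes < 1 or self.block_size < 1:
            raise ValueError("counts must be positive")
        if self.n_train < 2 or self.n_test < 1:
            raise ValueError("sample sizes too small")
        if self.sd_fold < 0:
            raise ValueError("sd_fold must be >= 0")
        for name in ("block_sd", "noise_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")
        if not 0 <= self.mv_rate < 1:
            raise ValueError("mv_rate must be in [0, 1)")
        if self.mask_mode not in ("quality", "random"):
            raise ValueError("mask_mode must be 'quality' or 'random'")

    def replace(self, **kwargs) -> "SimulationParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimulatedDataset:
    """Bundle of everything the generator produces for one partition."""

    signal: ExpressionMatrix
    noise: np.ndarray
    measured: ExpressionMatrix
    mask: MissingMask
    labels: ClassLabels
    threshold: float
    params: SimulationParameters


# fixed column order of the long-format results table
RESULT_FIELDS = (
    "repetition", "dataset_kind", "fs_method", "rule", "n_features",
    "mv_rate", "noise_mean", "block_sd", "block_corr", "mask_mode", "seed",
    "error", "nrmse",
)


@dataclass
class ResultRecord:
    """One (repetition, dataset kind, selection, rule, size) evaluation."""

    repetition: int
    dataset_kind: str   # "signal", "orgn", or "imputed:<method>"
    fs_method: str      # "ttest" or "sffs"
    rule: str           # "lda", "3nn", "svm"
    n_features: int
    error: float
    nrmse: float | None
    params: SimulationParameters

    def __post_init__(self) -> None:
        if not 0 <= self.error <= 1:
            raise ValueError("error must be in [0, 1]")
        if self.nrmse is not None and not self.dataset_kind.startswith("imputed:"):
            raise ValueError("nrmse only applies to imputed dataset kinds")

    def to_row(self) -> list:
        p = self.params
        return [self.repetition, self.dataset_kind, self.fs_method, self.rule,
                self.n_features, p.mv_rate, p.noise_mean, p.block_sd,
                p.block_corr, p.mask_mode, p.seed, self.error,
                "" if self.nrmse is None else self.nrmse]
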