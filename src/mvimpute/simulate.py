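"""Generative model for two-class log-ratio expression data.

A measured value decomposes as ``measured = signal + noise``.  The signal of
gene *i* in sample *j* is a class-dependent fold-change offset (nonzero only
for marker genes) plus a zero-mean gene effect drawn, per sample, from a
block-diagonal multivariate Gaussian that correlates genes within a block
(e.g. a pathway) and leaves genes in different blocks independent.  The
additive noise is Gaussian with per-gene SDs drawn from an exponential
distribution, producing the heterogeneous quality observed across probes.

Missing values are marked either by *quality* — the entries with the largest
|noise| magnitudes, i.e. the low-quality spots a scanner would flag — or
uniformly at *random* (the mechanism most prior imputation studies assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    ClassLabels,
    ExpressionMatrix,
    MissingMask,
    SimulatedDataset,
    SimulationParameters,
)

__all__ = [
    "FoldChangeSpec",
    "BlockCovariance",
    "build_block_covariance",
    "sample_fold_changes",
    "sample_signal",
    "sample_noise",
    "quality_threshold",
    "generate_mask",
    "generate_dataset",
    "child_rng",
]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream for (repetition, partition, purpose) keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass
class FoldChangeSpec:
    """Per-gene class offsets; (0, 0) everywhere except marker genes."""

    offsets: np.ndarray          # (n_genes, 2): class-0 and class-1 offsets
    marker_indices: np.ndarray   # indices of marker genes

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.marker_indices = np.asarray(self.marker_indices, dtype=int)
        non_marker = np.setdiff1d(np.arange(self.offsets.shape[0]),
                                  self.marker_indices)
        if self.offsets[non_marker].any():
            raise ValueError("non-marker genes must have zero offsets")


@dataclass
class BlockCovariance:
    """Block-diagonal gene-effect covariance."""

    matrix: np.ndarray
    block_size: int
    block_sd: float
    block_corr: float

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]


def build_block_covariance(n_genes: int, block_size: int, block_sd: float,
                           block_corr: float) -> BlockCovariance:
    """Covariance with diagonal ``block_sd**2`` and within-block off-diagonal
    ``block_sd**2 * block_corr``; zero between blocks.

    If ``block_size`` does not divide ``n_genes`` the final block is smaller.
    Eigenvalues of an m-gene block are ``sd^2 (1 - corr)`` (multiplicity m-1)
    and ``sd^2 (1 + (m-1) corr)``, so the matrix is PSD for corr in [0, 1).
    """
    if n_genes < 1 or block_size < 1:
        raise ValueError("n_genes and block_size must be >= 1")
    if block_sd <= 0:
        raise ValueError("block_sd must be > 0")
    if not 0 <= block_corr < 1:
        raise ValueError("block_corr must be in [0, 1)")
    var = block_sd ** 2
    cov = np.zeros((n_genes, n_genes))
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        cov[start:stop, start:stop] = var * block_corr
    np.fill_diagonal(cov, var)
    return BlockCovariance(cov, block_size, block_sd, block_corr)


def sample_fold_changes(params: SimulationParameters,
                        rng: np.random.Generator) -> FoldChangeSpec:
    """Draw the class fold-change offsets for the marker genes.

    Markers occupy the first ``n_markers`` gene indices.  Each marker gets two
    magnitudes drawn from Normal(mu_fold, sd_fold) — one per class — and a
    random sign s applied with opposite orientation to the two classes:
    class-0 offset ``+s*mag0``, class-1 offset ``-s*mag1``, so the expected
    between-class separation is ``2*mu_fold``.
    """
    n, m = params.n_genes, params.n_markers
    offsets = np.zeros((n, 2))
    markers = np.arange(m)
    if m:
        mags = rng.normal(params.mu_fold, params.sd_fold, size=(m, 2))
        signs = rng.choice((-1.0, 1.0), size=m)
        offsets[markers, 0] = signs * mags[:, 0]
        offsets[markers, 1] = -signs * mags[:, 1]
    return FoldChangeSpec(offsets, markers)


def sample_signal(params: SimulationParameters, fc: FoldChangeSpec,
                  cov: BlockCovariance, labels: ClassLabels,
                  rng: np.random.Generator) -> ExpressionMatrix:
    """Signal matrix: class offset + per-sample draw of the gene effect.

    The gene effect is sampled block by block (the covariance is
    block-diagonal, so this is exact and avoids an n_genes-sized Cholesky).
    """
    if cov.n_genes != params.n_genes:
        raise ValueError("covariance dimension mismatch")
    n, d = params.n_genes, len(labels)
    values = np.empty((n, d))
    var, corr = cov.block_sd ** 2, cov.block_corr
    # within an m-block: x = sd*sqrt(corr)*z_shared + sd*sqrt(1-corr)*z_own
    for start in range(0, n, cov.block_size):
        stop = min(start + cov.block_size, n)
        m = stop - start
        shared = rng.standard_normal(d)
        own = rng.standard_normal((m, d))
        values[start:stop] = (np.sqrt(var * corr) * shared
                              + np.sqrt(var * (1 - corr)) * own)
    values += fc.offsets[:, labels.labels]
    return ExpressionMatrix.from_values(values)


def sample_noise(params: SimulationParameters, n_samples: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Heteroscedastic noise matrix and the per-gene SDs that produced it."""
    if params.noise_mean <= 0:
        raise ValueError("noise_mean must be > 0")
    sds = rng.exponential(params.noise_mean, size=params.n_genes)
    noise = rng.standard_normal((params.n_genes, n_samples)) * sds[:, None]
    return noise, sds


def quality_threshold(noise: np.ndarray, mv_rate: float) -> float:
    """The (1 - mv_rate) quantile of pooled |noise|.

    Entries with |noise| above this cutoff are the low-quality fraction of
    the matrix; flagging them yields approximately ``round(mv_rate * size)``
    missing entries (exact counts come from rank thresholding in
    :func:`generate_mask`).
    """
    if not 0 <= mv_rate < 1:
        raise ValueError("mv_rate must be in [0, 1)")
    return float(np.quantile(np.abs(noise), 1.0 - mv_rate))


def _rank_exact_flags(noise: np.ndarray, k: int) -> np.ndarray:
    """Flag the k largest-|noise| entries; ties broken by lower (gene, sample)
    coordinates in row-major order."""
    flat = np.abs(noise).ravel()
    # stable sort on -|noise| keeps row-major order within ties
    order = np.argsort(-flat, kind="stable")
    flags = np.zeros(flat.size, dtype=bool)
    flags[order[:k]] = True
    return flags.reshape(noise.shape)


def generate_mask(noise: np.ndarray | None = None, t: float | None = None,
                  mode: str = "quality", mv_rate: float | None = None,
                  rng: np.random.Generator | None = None,
                  exact: bool = True) -> MissingMask:
    """Build a missing mask.

    quality mode
        Flags entries by |noise| against threshold ``t``.  With
        ``exact=True`` (and ``mv_rate`` given) rank thresholding hits
        ``round(mv_rate * size)`` entries exactly; with ``exact=False`` the
        rule is plainly ``|noise| > t`` (used for test partitions scored
        against a training-derived threshold).
    random mode
        Flags a uniform random subset of ``round(mv_rate * size)`` entries.
    """
    if mode == "quality":
        if noise is None:
            raise ValueError("quality mode requires the noise matrix")
        if exact:
            if mv_rate is None:
                raise ValueError("exact quality mode requires mv_rate")
            k = int(round(mv_rate * noise.size))
            flags = _rank_exact_flags(noise, k)
        else:
            if t is None:
                raise ValueError("threshold t required when exact=False")
            flags = np.abs(noise) > t
    elif mode == "random":
        if mv_rate is None or noise is None:
            raise ValueError("random mode requires mv_rate and noise (for shape)")
        if rng is None:
            raise ValueError("random mode requires an rng")
        k = int(round(mv_rate * noise.size))
        flat = np.zeros(noise.size, dtype=bool)
        flat[rng.choice(noise.size, size=k, replace=False)] = True
        flags = flat.reshape(noise.shape)
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    mask = MissingMask(flags)
    mask.validate_no_empty_gene()
    return mask


def generate_dataset(params: SimulationParameters, partition: str = "train",
                     shared: tuple[FoldChangeSpec, BlockCovariance, float] | None = None,
                     rng: np.random.Generator | None = None,
                     repetition: int = 0) -> SimulatedDataset:
    """Generate one partition of a simulated study.

    The training partition draws its own fold changes and covariance and sets
    the quality threshold from its own noise.  A test partition must reuse
    the training partition's fold changes, covariance and threshold
    (``shared``); its mask is then its own noise scored against that shared
    threshold, so the realised test MV rate fluctuates around the nominal
    one.  Labels are balanced in both partitions.
    """
    if partition not in ("train", "test"):
        raise ValueError("partition must be 'train' or 'test'")
    purpose = 0 if partition == "train" else 1
    if rng is None:
        rng = child_rng(params.seed, repetition, purpose)

    n_samples = params.n_train if partition == "train" else params.n_test
    half = n_samples // 2
    labels = ClassLabels(np.r_[np.zeros(half, int),
                               np.ones(n_samples - half, int)])

    if partition == "train":
        fc = sample_fold_changes(params, rng)
        cov = build_block_covariance(params.n_genes, params.block_size,
                                     params.block_sd, params.block_corr)
        threshold = None
    else:
        if shared is None:
            raise ValueError("test partition requires the train partition's "
                             "fold changes, covariance and threshold")
        fc, cov, threshold = shared

    signal = sample_signal(params, fc, cov, labels, rng)
    noise, _ = sample_noise(params, n_samples, rng)
    measured = ExpressionMatrix.from_values(signal.values + noise)

    if partition == "train":
        threshold = quality_threshold(noise, params.mv_rate)
        if params.mask_mode == "quality":
            mask = generate_mask(noise=noise, t=threshold, mode="quality",
                                 mv_rate=params.mv_rate, exact=True)
        else:
            mask = generate_mask(noise=noise, mode="random",
                                 mv_rate=params.mv_rate, rng=rng)
    else:
        if params.mask_mode == "quality":
            mask = generate_mask(noise=noise, t=threshold, mode="quality",
                                 exact=False)
        else:
            mask = generate_mask(noise=noise, mode="random",
                                 mv_rate=params.mv_rate, rng=rng)

    ds = SimulatedDataset(signal=signal, noise=noise, measured=measured,
                          mask=mask, labels=labels, threshold=float(threshold),
                          params=params)
    # stash the shared structures so a test partition can reuse them
    ds.fold_changes = fc
    ds.covariance = cov
    return ds


def generate_pair(params: SimulationParameters,
                  repetition: int = 0) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Train and test partitions sharing fold changes, covariance and
    quality threshold."""
    train = generate_dataset(params, "train", repetition=repetition)
    test = generate_dataset(params, "test",
                            shared=(train.fold_changes, train.covariance,
                                    train.threshold),
                            repetition=repetition)
    return train, test
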