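"""Evaluation protocol: train-only imputation, hold-out error, NRMSE.

The central methodological rule: imputation of a test point may use the
training data but never the other test points.  Each test sample is
adjoined, alone, to the measured training matrix; the configured imputation
runs on that augmented matrix; the completed column is extracted and the
training columns' fills are discarded (the classifier was already built).
Imputation of future examples is thereby part of the classification rule.

A condition run generates, per repetition, a training partition and an
independent test partition sharing the same fold changes, covariance and
quality threshold; builds the eight training views (true signal, measured
"orgn", six imputed); trains every (feature selection x rule x size) on
each view; and scores hold-out error like-on-like (signal classifiers on
signal test data, measured on measured, imputed kinds on measured test
data completed one point at a time).  Imputation accuracy is tracked as
signal-referenced NRMSE over the masked training entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .impute import ImputationConfig, impute
from .io import read_results, write_results
from .learn import (
    FeatureSet,
    TrainedClassifier,
    predict,
    select_top_t,
    train,
    two_stage_select,
)
from .simulate import child_rng, generate_dataset
from .types import (
    ClassLabels,
    ExpressionMatrix,
    MissingMask,
    ResultRecord,
    SimulatedDataset,
    SimulationParameters,
    check_aligned,
)

logger = logging.getLogger("mvimpute")

__all__ = [
    "ExperimentPlan",
    "ConditionResult",
    "impute_test_point",
    "complete_test_matrix",
    "holdout_error",
    "nrmse",
    "run_condition",
    "run_plan",
    "summarize",
]

# number of warm-started refinement iterations allowed when completing a
# single adjoined test point with BPCA
BPCA_TEST_POINT_MAX_ITER = 50


def impute_test_point(train_measured: ExpressionMatrix, train_mask: MissingMask,
                      x_measured: np.ndarray, x_mask: np.ndarray,
                      config: ImputationConfig,
                      bpca_warm=None, train_filled: np.ndarray | None = None,
                      bpca_scores: np.ndarray | None = None) -> np.ndarray:
    """Complete one test sample using the training data only.

    The sample is adjoined as an extra column to the measured training
    matrix and its mask; the configured imputation runs on the augmented
    matrix; the completed final column is returned.  For BPCA the
    augmented fit is warm-started from the training fit's parameters
    (extended with a loading row for the new column) when provided, capped
    at a small number of refinement iterations; ``train_filled`` optionally
    supplies the completed training matrix to initialise the fills.
    """
    check_aligned(train_measured, train_mask)
    x_measured = np.asarray(x_measured, dtype=float)
    x_mask = np.asarray(x_mask, dtype=bool)
    if x_measured.shape != (train_measured.shape[0],):
        raise ValueError("test vector length must equal the gene count")
    if not x_mask.any():
        return x_measured.copy()

    aug_vals = np.column_stack([train_measured.values,
                                np.where(x_mask, 0.0, x_measured)])
    aug = ExpressionMatrix(aug_vals, list(train_measured.gene_ids),
                           list(train_measured.sample_ids) + ["__test__"])
    aug_mask = MissingMask(np.column_stack([train_mask.flags, x_mask]))

    if config.method == "BPCA":
        from .bpca import bpca_fit, extend_model, factor_scores
        warm = None
        init = None
        if bpca_warm is not None and bpca_warm.W.shape[0] == train_measured.shape[1]:
            if train_filled is None:
                from .impute import ravg_fill
                train_filled = ravg_fill(train_measured.values, train_mask.flags)
            if bpca_scores is None:
                bpca_scores = factor_scores(bpca_warm, train_filled)
            warm = extend_model(bpca_warm, train_filled, x_measured, x_mask,
                                scores=bpca_scores)
            # start the fills from the training completion; the new
            # column's missing entries start from the extended model's
            # prediction for this sample
            pred = bpca_scores @ warm.W[-1] + warm.mu[-1]
            init = np.column_stack([train_filled,
                                    np.where(x_mask, pred, x_measured)])
        watch = np.zeros_like(aug_mask.flags)
        watch[:, -1] = True
        completed, _ = bpca_fit(aug, aug_mask, config, warm_start=warm,
                                max_iter=BPCA_TEST_POINT_MAX_ITER,
                                init_values=init, watch=watch)
    else:
        # only the final column is consumed, so the local methods need only
        # fill the gene rows missing in it
        completed = impute(aug, aug_mask, config,
                           target_rows=np.flatnonzero(x_mask))
    return completed.values[:, -1].copy()


def complete_test_matrix(train_measured: ExpressionMatrix,
                         train_mask: MissingMask,
                         test_measured: ExpressionMatrix,
                         test_mask: MissingMask,
                         config: ImputationConfig,
                         bpca_warm=None,
                         train_filled: np.ndarray | None = None) -> ExpressionMatrix:
    """Complete every test sample independently (one point at a time)."""
    check_aligned(test_measured, test_mask)
    scores = None
    if config.method == "BPCA" and bpca_warm is not None:
        from .bpca import factor_scores
        from .impute import ravg_fill
        if train_filled is None:
            train_filled = ravg_fill(train_measured.values, train_mask.flags)
        scores = factor_scores(bpca_warm, train_filled)
    out = test_measured.values.copy()
    for j in range(test_measured.shape[1]):
        out[:, j] = impute_test_point(train_measured, train_mask,
                                      test_measured.values[:, j],
                                      test_mask.flags[:, j], config,
                                      bpca_warm=bpca_warm,
                                      train_filled=train_filled,
                                      bpca_scores=scores)
    return ExpressionMatrix(out, list(test_measured.gene_ids),
                            list(test_measured.sample_ids))


def holdout_error(classifier: TrainedClassifier,
                  test_matrix: ExpressionMatrix,
                  test_labels: ClassLabels,
                  test_mask: MissingMask | None = None,
                  config: ImputationConfig | None = None) -> float:
    """Misclassification fraction on a test set.

    When ``config`` is given the test matrix still contains masked entries
    and each point is completed via :func:`impute_test_point` using the
    classifier's stored training reference; otherwise the matrix is taken
    as already complete (signal / measured baselines).
    """
    if len(test_labels) != test_matrix.shape[1]:
        raise ValueError("label count must equal test sample count")
    if len(test_labels) == 0:
        raise ValueError("test set is empty")
    if config is not None:
        if classifier.training_reference is None:
            raise ValueError("classifier lacks a training reference for "
                             "test-point imputation")
        train_measured, train_mask, _ = classifier.training_reference
        test_matrix = complete_test_matrix(
            train_measured, train_mask, test_matrix, test_mask, config,
            bpca_warm=classifier.extra.get("bpca_model"))
    X = test_matrix.values[classifier.features.indices].T
    preds = predict(classifier, X)
    return float((preds != test_labels.labels).mean())


def nrmse(signal: ExpressionMatrix, imputed: ExpressionMatrix,
          mask: MissingMask) -> float:
    """Signal-referenced normalised RMS imputation error.

    Root-mean-square of (imputed - signal) over the masked entries, divided
    by the population SD of the true signal over those same entries.  By
    construction, imputing every masked entry with the mean of the signal's
    masked values gives exactly 1.
    """
    check_aligned(signal, mask)
    check_aligned(imputed, mask)
    flags = mask.flags
    if not flags.any():
        raise ValueError("NRMSE needs at least one masked entry")
    diff = imputed.values[flags] - signal.values[flags]
    sd = float(signal.values[flags].std())  # population SD (divide by count)
    if sd == 0:
        raise ValueError("signal SD over masked entries is zero; "
                         "NRMSE undefined")
    return float(np.sqrt(np.mean(diff ** 2)) / sd)


@dataclass
class ExperimentPlan:
    """Factorial grid for :func:`run_plan`."""

    noise_means: list[float] = dc_field(default_factory=lambda: [0.4])
    block_sds: list[float] = dc_field(default_factory=lambda: [0.8])
    block_corrs: list[float] = dc_field(default_factory=lambda: [0.5])
    mv_rates: list[float] = dc_field(default_factory=lambda: [0.10])
    mask_modes: list[str] = dc_field(default_factory=lambda: ["quality"])
    methods: list[ImputationConfig] = dc_field(
        default_factory=lambda: [ImputationConfig(method=m) for m in
                                 ("RAVG", "KNN", "LLS_L2", "LLS_PC", "LS", "BPCA")])
    fs_methods: list[str] = dc_field(default_factory=lambda: ["ttest"])
    rules: list[str] = dc_field(default_factory=lambda: ["lda", "3nn", "svm"])
    feature_sizes: list[int] = dc_field(default_factory=lambda: [5, 10, 15, 20, 25, 30])
    repetitions: int = 20
    root_seed: int = 0
    base_params: SimulationParameters = dc_field(default_factory=SimulationParameters)
    stage1_size: int = 100
    sffs_mc_points: int = 200

    def __post_init__(self) -> None:
        for name in ("noise_means", "block_sds", "block_corrs", "mv_rates",
                     "mask_modes", "fs_methods", "rules", "feature_sizes"):
            if not getattr(self, name):
                raise ValueError(f"plan list {name} must be non-empty")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    def conditions(self):
        for combo in product(self.noise_means, self.block_sds,
                             self.block_corrs, self.mv_rates, self.mask_modes):
            noise_mean, block_sd, block_corr, mv_rate, mask_mode = combo
            yield self.base_params.replace(
                noise_mean=noise_mean, block_sd=block_sd,
                block_corr=block_corr, mv_rate=mv_rate, mask_mode=mask_mode,
                seed=self.root_seed)


@dataclass
class ConditionResult:
    """Records plus per-method NRMSE summaries for one condition."""

    records: list[ResultRecord]
    nrmse_values: dict[str, list[float]]

    @property
    def nrmse_summary(self) -> dict[str, tuple[float, float]]:
        return {m: (float(np.mean(v)), float(np.std(v)))
                for m, v in self.nrmse_values.items() if v}

    def mean_error(self, dataset_kind: str) -> float:
        errs = [r.error for r in self.records if r.dataset_kind == dataset_kind]
        if not errs:
            raise ValueError(f"no records for kind {dataset_kind!r}")
        return float(np.mean(errs))


def _select(view: ExpressionMatrix, labels: ClassLabels, fs: str,
            n_features: int, rule: str, stage1_size: int,
            mc_points: int, seed: int) -> FeatureSet:
    if fs == "ttest":
        return select_top_t(view, labels, n_features)
    if fs == "sffs":
        stage1 = min(stage1_size, view.shape[0])
        return two_stage_select(view, labels, stage1, n_features, rule,
                                mc_points=mc_points, seed=seed)
    raise ValueError(f"unknown feature selection method {fs!r}")


def run_condition(params: SimulationParameters,
                  methods: list[ImputationConfig] | None = None,
                  fs_methods: list[str] = ("ttest",),
                  rules: list[str] = ("lda",),
                  feature_sizes: list[int] = (30,),
                  repetitions: int = 20,
                  stage1_size: int = 100,
                  sffs_mc_points: int = 200,
                  record_sink=None,
                  skip_repetitions: set[int] | None = None,
                  include_baselines: bool = True) -> ConditionResult:
    """Run one parameter condition for ``repetitions`` repetitions.

    Per repetition: generate train and test partitions; impute the training
    matrix once per method; record NRMSE; then evaluate every dataset kind
    x feature selection x rule x feature size.  A failing repetition is
    logged and skipped; completed repetitions are retained.
    """
    if methods is None:
        methods = [ImputationConfig(method=m) for m in
                   ("RAVG", "KNN", "LLS_L2", "LLS_PC", "LS", "BPCA")]
    records: list[ResultRecord] = []
    nrmse_values: dict[str, list[float]] = {c.method: [] for c in methods}
    skip = skip_repetitions or set()

    for rep in range(repetitions):
        if rep in skip:
            continue
        try:
            rep_records, rep_nrmse = _run_repetition(
                params, rep, methods, fs_methods, rules, feature_sizes,
                stage1_size, sffs_mc_points, include_baselines)
        except Exception:
            logger.exception("repetition %d failed; skipping", rep)
            continue
        for m, v in rep_nrmse.items():
            nrmse_values[m].append(v)
        records.extend(rep_records)
        if record_sink is not None:
            record_sink(rep_records)
    return ConditionResult(records, nrmse_values)


def _run_repetition(params, rep, methods, fs_methods, rules, feature_sizes,
                    stage1_size, sffs_mc_points, include_baselines):
    train_ds = generate_dataset(params, "train", repetition=rep)
    shared = (train_ds.fold_changes, train_ds.covariance, train_ds.threshold)
    test_ds = generate_dataset(params, "test", shared=shared, repetition=rep)

    # training views and matching test evaluation setups
    views: list[tuple[str, ExpressionMatrix, ImputationConfig | None, object]] = []
    if include_baselines:
        views.append(("signal", train_ds.signal, None, None))
        views.append(("orgn", train_ds.measured, None, None))
    from .bpca import bpca_fit
    rep_nrmse: dict[str, float] = {}
    for cfg in methods:
        if cfg.method == "BPCA":
            imputed, model = bpca_fit(train_ds.measured, train_ds.mask, cfg)
        else:
            imputed = impute(train_ds.measured, train_ds.mask, cfg)
            model = None
        rep_nrmse[cfg.method] = nrmse(train_ds.signal, imputed, train_ds.mask)
        views.append((f"imputed:{cfg.method}", imputed, cfg, model))

    # the completed test matrix is classifier-independent, so compute it
    # once per imputation method and share across fs x rule x size
    completed_tests: dict[str, ExpressionMatrix] = {}
    for kind, view, cfg, model in views:
        if cfg is None:
            continue
        completed_tests[kind] = complete_test_matrix(
            train_ds.measured, train_ds.mask, test_ds.measured, test_ds.mask,
            cfg, bpca_warm=model,
            train_filled=view.values if model is not None else None)

    out: list[ResultRecord] = []
    for kind, view, cfg, model in views:
        if cfg is None:
            test_view = test_ds.signal if kind == "signal" else test_ds.measured
        else:
            test_view = completed_tests[kind]
        for fs, rule, n_feat in product(fs_methods, rules, feature_sizes):
            feats = _select(view, train_ds.labels, fs, n_feat, rule,
                            stage1_size, sffs_mc_points,
                            seed=params.seed + 7919 * rep)
            clf = train(rule, view, train_ds.labels, feats)
            err = holdout_error(clf, test_view, test_ds.labels)
            last = rep_nrmse[cfg.method] if cfg is not None else None
            out.append(ResultRecord(
                repetition=rep, dataset_kind=kind, fs_method=fs, rule=rule,
                n_features=n_feat, error=err, nrmse=last, params=params))
    return out, rep_nrmse


def run_plan(plan: ExperimentPlan, out_path: str | Path,
             resume: bool = False) -> Path:
    """Iterate the factorial grid, streaming records to a results TSV.

    With ``resume=True``, (condition, repetition) pairs already present in
    the output are skipped; determinism of the per-repetition seeds makes
    the resumed file identical to an uninterrupted run.
    """
    out_path = Path(out_path)
    done: set[tuple] = set()
    append = False
    if resume and out_path.exists() and out_path.stat().st_size > 0:
        existing = read_results(out_path)
        for _, row in existing.iterrows():
            done.add((row["noise_mean"], row["block_sd"], row["block_corr"],
                      row["mv_rate"], row["mask_mode"], int(row["repetition"])))
        append = True

    first_write = not append
    for params in plan.conditions():
        key_base = (params.noise_mean, params.block_sd, params.block_corr,
                    params.mv_rate, params.mask_mode)
        skip = {rep for rep in range(plan.repetitions)
                if key_base + (rep,) in done}
        if len(skip) == plan.repetitions:
            continue
        logger.info("condition %s: running %d repetitions",
                    key_base, plan.repetitions - len(skip))

        state = {"first": first_write}

        def sink(recs, _state=state):
            write_results(recs, out_path, append=not _state["first"])
            _state["first"] = False

        run_condition(params, methods=plan.methods,
                      fs_methods=plan.fs_methods, rules=plan.rules,
                      feature_sizes=plan.feature_sizes,
                      repetitions=plan.repetitions,
                      stage1_size=plan.stage1_size,
                      sffs_mc_points=plan.sffs_mc_points,
                      record_sink=sink, skip_repetitions=skip)
        first_write = state["first"]
    return out_path


def summarize(results: str | Path | pd.DataFrame,
              plots_dir: str | Path | None = None) -> pd.DataFrame:
    """Mean +/- SD error by condition, dataset kind and feature count,
    plus mean NRMSE; optionally writes simple matplotlib panels."""
    df = results if isinstance(results, pd.DataFrame) else read_results(results)
    if df.empty:
        raise ValueError("no records to summarise")
    group_cols = ["noise_mean", "block_sd", "block_corr", "mv_rate",
                  "mask_mode", "dataset_kind", "fs_method", "rule",
                  "n_features"]
    summary = (df.groupby(group_cols, dropna=False)
                 .agg(error_mean=("error", "mean"), error_sd=("error", "std"),
                      nrmse_mean=("nrmse", "mean"), n=("error", "size"))
                 .reset_index())
    if plots_dir is not None:
        _write_plots(df, summary, Path(plots_dir))
    return summary


def _write_plots(df: pd.DataFrame, summary: pd.DataFrame, plots_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir.mkdir(parents=True, exist_ok=True)
    for (fs, rule), sub in summary.groupby(["fs_method", "rule"]):
        fig, ax = plt.subplots(figsize=(6, 4))
        for kind, ks in sub.groupby("dataset_kind"):
            ks = ks.sort_values("n_features")
            ax.plot(ks["n_features"], ks["error_mean"], marker="o", label=kind)
        ax.set_xlabel("number of selected genes")
        ax.set_ylabel("classification error")
        ax.set_title(f"{fs} + {rule}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plots_dir / f"error_{fs}_{rule}.png", dpi=120)
        plt.close(fig)

    nr = df[df["nrmse"].notna()]
    if not nr.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        curve = (nr.groupby(["dataset_kind", "mv_rate"])["nrmse"]
                   .mean().reset_index())
        for kind, ks in curve.groupby("dataset_kind"):
            ks = ks.sort_values("mv_rate")
            ax.plot(ks["mv_rate"], ks["nrmse"], marker="o", label=kind)
        ax.set_xlabel("MV rate")
        ax.set_ylabel("NRMSE")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plots_dir / "nrmse_vs_mv_rate.png", dpi=120)
        plt.close(fig)
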