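"""Two-stage leave-one-fold-out protocol with rotational validation.

Subjects are split into 4 folds (per sex). For a fixed test fold, the
three remaining folds rotate through the validation role — three models
are trained, each on the two folds that are neither test nor validation —
and the model with the highest validation accuracy is evaluated once on
the untouched test fold. So every trained model sees 50% of the data for
training, 25% for validation and 25% for testing.

Stage 1 (hyperparameter stage) runs this procedure on the fold-4 setting,
optionally over a configuration grid; the selected configuration is then
frozen. Stage 2 (evaluation stage) repeats the procedure with folds 1-3 as
test folds and pools their out-of-fold predictions; fold-4 subjects are
excluded from pooled downstream statistics. An out-of-bag test evaluates
one trained model on a freshly generated cohort never seen at any stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn_models import ModelConfig, NNModel, build_model, predict, train

__all__ = [
    "FeatureSet",
    "FoldPlan",
    "make_folds",
    "run_split_setting",
    "run_evaluation_stage",
    "out_of_bag_test",
]

K_FOLDS = 4


@dataclass
class FeatureSet:
    """Aligned per-subject arrays: ids, STFT tensors, band powers."""

    ids: np.ndarray  # (N,) subject ids
    x: np.ndarray  # (N, T, F, C)
    bp: np.ndarray  # (N, 36)
    signals: np.ndarray | None = None  # (N, 12, L) raw traces, when retained

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        sig = self.signals[mask] if self.signals is not None else None
        return FeatureSet(self.ids[mask], self.x[mask], self.bp[mask], sig)


@dataclass
class FoldPlan:
    """Assignment of subjects to the 4 folds."""

    assignment: dict  # subject_id -> fold in {1..4}
    seed: int
    k: int = K_FOLDS

    def fold_ids(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]

    def mask(self, ids: np.ndarray, folds) -> np.ndarray:
        folds = {folds} if np.isscalar(folds) else set(folds)
        return np.array([self.assignment[s] in folds for s in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": list(self.assignment), "fold": list(self.assignment.values())}
        )


def make_folds(subject_ids, seed: int) -> FoldPlan:
    """Uniform random permutation then round-robin into 4 folds.

    Fold sizes differ by at most 1. Deterministic given `seed`.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in fold assignment")
    if len(ids) < 2 * K_FOLDS:
        raise ValueError(f"need at least {2 * K_FOLDS} subjects for {K_FOLDS} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: (pos % K_FOLDS) + 1 for pos, j in enumerate(order)}
    return FoldPlan(assignment=assignment, seed=seed)


def _ids_checksum(ids) -> str:
    return hashlib.sha256(",".join(sorted(map(str, ids))).encode()).hexdigest()[:16]


def _is_classification(config: ModelConfig) -> bool:
    return not config.task.startswith("regression")


def select_best(scored) -> int:
    """Index of the best (score, validation_fold, config_index) triple.

    Highest score wins; ties break to the lowest validation-fold index,
    then to the earliest grid entry.
    """
    return max(range(len(scored)), key=lambda i: (scored[i][0], -scored[i][1], -scored[i][2]))


def run_split_setting(
    plan: FoldPlan,
    test_fold: int,
    features: FeatureSet,
    labels: np.ndarray,
    config,
) -> tuple[NNModel, pd.DataFrame, dict]:
    """Train the 3 rotation models (x configurations) and test the best.

    `config` is a single ModelConfig or a list of them (a hyperparameter
    grid); with a grid, 3 models are trained per configuration and the
    selection is over all of them. Selection is by highest validation
    accuracy (classification) or lowest validation RMSE (regression), ties
    broken by lowest validation-fold index then grid order. The selected
    model alone is evaluated on the untouched test fold; its normalizer and
    class weights come from its own training folds only.

    Returns (selected model, test prediction table, report).
    """
    configs = [config] if isinstance(config, ModelConfig) else list(config)
    val_folds = [f for f in range(1, K_FOLDS + 1) if f != test_fold]
    labels = np.asarray(labels)
    candidates = []
    rotations = []
    for val_fold in val_folds:
        train_folds = [f for f in val_folds if f != val_fold]
        tr = plan.mask(features.ids, train_folds)
        va = plan.mask(features.ids, val_fold)
        for ci, cfg in enumerate(configs):
            model = build_model(cfg)
            try:
                train(
                    model,
                    features.x[tr],
                    features.bp[tr],
                    labels[tr],
                    validation=(features.x[va], features.bp[va], labels[va]),
                )
            except Exception as exc:  # noqa: BLE001 - rotation failure aborts the setting
                raise RuntimeError(
                    f"rotation (val fold {val_fold}, config {ci}) failed to train: {exc}"
                ) from exc
            score = (
                model.validation_accuracy
                if _is_classification(cfg)
                else -model.validation_rmse
            )
            candidates.append((score, val_fold, ci, model, sorted(train_folds)))
            rotations.append(
                {
                    "validation_fold": val_fold,
                    "train_folds": sorted(train_folds),
                    "config_index": ci,
                    "validation_accuracy": model.validation_accuracy,
                    "validation_rmse": model.validation_rmse,
                    "train_ids_checksum": _ids_checksum(features.ids[tr]),
                }
            )
    best_i = select_best([(c[0], c[1], c[2]) for c in candidates])
    _, sel_val_fold, sel_ci, sel_model, sel_train_folds = candidates[best_i]

    te = plan.mask(features.ids, test_fold)
    assert not np.any(te & plan.mask(features.ids, sel_train_folds)), "test/train overlap"
    table = predict(sel_model, features.x[te], features.bp[te], subject_ids=features.ids[te])
    report = {
        "test_fold": test_fold,
        "rotations": rotations,
        "selected_validation_fold": sel_val_fold,
        "selected_config_index": sel_ci,
        "selected_train_folds": sel_train_folds,
    }
    if _is_classification(sel_model.config):
        report["test_accuracy"] = float(np.mean(table["pred_class"].to_numpy() == labels[te]))
    else:
        err = table["estimate"].to_numpy() - labels[te]
        report["test_rmse"] = float(np.sqrt(np.mean(err**2)))
    return sel_model, table, report


def run_evaluation_stage(
    plan: FoldPlan,
    features: FeatureSet,
    labels: np.ndarray,
    config: ModelConfig,
) -> tuple[pd.DataFrame, list, list[NNModel]]:
    """Pooled out-of-fold predictions for folds 1-3 at fixed hyperparameters.

    Runs one split setting per test fold in {1, 2, 3}; fold-4 subjects are
    excluded, mirroring the exclusion of the hyperparameter-stage test fold
    from downstream statistics. Every fold 1-3 subject appears exactly once,
    predicted by a model whose training folds did not contain it.
    """
    if len(set(features.ids)) != len(features.ids):
        raise ValueError("overlapping subject ids across folds")
    tables, reports, models = [], [], []
    for test_fold in (1, 2, 3):
        model, table, report = run_split_setting(plan, test_fold, features, labels, config)
        tables.append(table)
        reports.append(report)
        models.append(model)
    pooled = pd.concat(tables, ignore_index=True)
    assert pooled["subject_id"].is_unique, "a subject was predicted more than once"
    return pooled, reports, models


def out_of_bag_test(
    model: NNModel,
    features: FeatureSet,
    labels: np.ndarray,
    training_ids=None,
) -> float:
    """Accuracy (or RMSE for regression) on a never-seen fresh cohort."""
    if training_ids is not None:
        overlap = set(features.ids) & set(training_ids)
        if overlap:
            raise ValueError(f"fresh cohort overlaps training ids: {sorted(overlap)[:5]}")
    table = predict(model, features.x, features.bp, subject_ids=features.ids)
    labels = np.asarray(labels)
    if _is_classification(model.config):
        return float(np.mean(table["pred_class"].to_numpy() == labels))
    return float(np.sqrt(np.mean((table["estimate"].to_numpy() - labels) ** 2)))
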