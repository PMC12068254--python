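"""Leave-one-patient-out evaluation, ablation variants, classification
metrics, Taylor-diagram statistics and failed-patient stratification.

The five method variants:

* ``proposed``     — CNN-LSTM-attention model, full composite loss;
* ``baseline``     — plain LSTM + two dense layers, error term only;
* ``only-mae``     — CNN-LSTM-attention model, error term only;
* ``no-patient``   — proposed without the patient-invariance term;
* ``no-unlabeled`` — proposed without the unlabeled-separation term.

Metrics are accuracy, precision, recall and F1 on the 0–100 scale, with
precision/recall/F1 support-weighted across the two classes; cohort-level
numbers are unweighted means over patients (each patient counts once).
A score above 0.5 is called HR (1); exactly 0.5 is called TW (0).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .exceptions import ConfigError, DataError
from .io import UNLABELED, Trajectory
from .kinematics import feature_matrix
from .model import ModelConfig, attention_map
from .training import LossConfig, OptimizerParams, train_model

VARIANTS = ("proposed", "baseline", "only-mae", "no-patient", "no-unlabeled")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class FoldResult:
    patient_id: str
    scores: np.ndarray
    y_pred: np.ndarray
    y_true: np.ndarray
    attention: np.ndarray | None
    metrics: dict
    train_fingerprint: str = ""   # hash of the training patient ids (leakage audit)


@dataclass
class TaylorStats:
    """Taylor-diagram triple relating the score series to the label series.

    Satisfies the law of cosines:
    crmse^2 = sd_model^2 + sd_reference^2 - 2 sd_model sd_reference r.
    """

    sd_model: float
    sd_reference: float
    pearson_r: float
    centered_rmse: float


def predict_labels(scores, threshold: float = 0.5) -> np.ndarray:
    """Binary call: 1 (HR) iff score strictly exceeds the threshold."""
    scores = np.asarray(scores, dtype=float)
    return (scores > threshold).astype(int)


def classification_metrics(y_true, y_pred) -> dict:
    """Accuracy plus support-weighted precision/recall/F1, in percent.

    A class never predicted contributes precision 0 to the weighted average
    — this is what pins a constant predictor on balanced labels to
    50 / 25 / 50 / 33.33.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise DataError("empty input")
    if y_true.shape != y_pred.shape:
        raise DataError("length mismatch")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="weighted", zero_division=0
    )
    return {
        "accuracy": round(100.0 * accuracy_score(y_true, y_pred), 2),
        "precision": round(100.0 * prec, 2),
        "recall": round(100.0 * rec, 2),
        "f1": round(100.0 * f1, 2),
    }


def variant_configs(
    variant: str, model_config: ModelConfig, loss_config: LossConfig
) -> tuple[ModelConfig, LossConfig]:
    """Adjust the model/loss configuration for one ablation variant."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    m, l = model_config, loss_config
    if variant == "baseline":
        m = replace(m, architecture="lstm_baseline")
        l = replace(l, weight_patient=0.0, weight_unlabeled=0.0)
    elif variant == "only-mae":
        l = replace(l, weight_patient=0.0, weight_unlabeled=0.0)
    elif variant == "no-patient":
        l = replace(l, weight_patient=0.0)
    elif variant == "no-unlabeled":
        l = replace(l, weight_unlabeled=0.0)
    return m, l


def _predict_chunked(model, X, chunk: int = 256):
    """Score a fold in fixed-size chunks to bound peak memory."""
    from .model import forward

    scores, attn = [], []
    for lo in range(0, len(X), chunk):
        s, _, attns = forward(model, X[lo : lo + chunk])
        scores.append(s)
        if attns:
            attn.append(np.mean(attns, axis=0))
    return np.concatenate(scores), (np.concatenate(attn) if attn else None)


def _fingerprint(patient_ids) -> str:
    joined = ",".join(sorted(set(map(str, patient_ids))))
    return hashlib.sha256(joined.encode()).hexdigest()[:16]


def lopo_cross_validate(
    trajectories: list[Trajectory],
    variant: str = "proposed",
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    optimizer_params: OptimizerParams | None = None,
    epochs: int = 10,
    seed: int = 0,
    interpolation_factor: int = 1,
) -> tuple[list[FoldResult], dict]:
    """Leave-one-patient-out cross-validation.

    One fold per patient; the fold's model is trained on every *other*
    patient's points (labeled and unlabeled) with normalization statistics
    from those training patients only, then scores the held-out patient's
    labeled points.  Returns the folds and the unweighted per-patient mean
    of each metric.
    """
    mcfg = model_config or ModelConfig()
    lcfg = loss_config or LossConfig()
    mcfg, lcfg = variant_configs(variant, mcfg, lcfg)

    X, y, patients = feature_matrix(trajectories, interpolation_factor)
    unique_patients = list(dict.fromkeys(patients))
    if len(unique_patients) < 2:
        raise DataError("LOPO needs at least 2 patients")

    folds: list[FoldResult] = []
    for k, held_out in enumerate(unique_patients):
        test_mask = (patients == held_out) & (y != UNLABELED)
        if not test_mask.any():
            warnings.warn(f"patient {held_out} has no labeled points; fold skipped",
                          stacklevel=2)
            continue
        train_mask = patients != held_out
        fold_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0]
            % (2**31)
        )
        model, _ = train_model(
            dataset=(X[train_mask], y[train_mask], patients[train_mask]),
            model_config=replace(mcfg, seed=fold_seed),
            loss_config=replace(lcfg, seed=fold_seed),
            optimizer_params=optimizer_params,
            epochs=epochs,
            seed=fold_seed,
        )
        scores, attn = _predict_chunked(model, X[test_mask])
        y_true = y[test_mask]
        y_pred = predict_labels(scores)
        folds.append(
            FoldResult(
                patient_id=str(held_out),
                scores=scores,
                y_pred=y_pred,
                y_true=y_true,
                attention=attn,
                metrics=classification_metrics(y_true, y_pred),
                train_fingerprint=_fingerprint(patients[train_mask]),
            )
        )
    if not folds:
        raise DataError("no fold had labeled points")
    summary = {
        m: float(np.mean([f.metrics[m] for f in folds])) for m in METRIC_NAMES
    }
    summary["n_folds"] = len(folds)
    return folds, summary


def run_ablation(
    trajectories: list[Trajectory],
    variants=VARIANTS,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    optimizer_params: OptimizerParams | None = None,
    epochs: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run LOPO for several variants with identical folds and seeds.

    Returns (metrics table with one row per variant, dict of per-variant
    fold lists)."""
    for v in variants:
        if v not in VARIANTS:
            raise ConfigError(f"unknown variant {v!r}")
    rows, all_folds = [], {}
    for v in variants:
        folds, summary = lopo_cross_validate(
            trajectories, variant=v, model_config=model_config,
            loss_config=loss_config, optimizer_params=optimizer_params,
            epochs=epochs, seed=seed,
        )
        rows.append({"variant": v, **{m: summary[m] for m in METRIC_NAMES}})
        all_folds[v] = folds
    return pd.DataFrame(rows).set_index("variant"), all_folds


def taylor_statistics(scores, labels) -> TaylorStats:
    """Population SDs, Pearson r and centered RMSE of scores vs labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size < 2 or scores.shape != labels.shape:
        raise DataError("need two equal-length series of length >= 2")
    if np.std(labels) == 0:
        raise DataError("constant reference: correlation undefined")
    sd_m = float(np.std(scores))
    sd_r = float(np.std(labels))
    if sd_m == 0:
        raise DataError("constant scores: correlation undefined")
    r = float(np.corrcoef(scores, labels)[0, 1])
    cs = scores - scores.mean()
    cl = labels - labels.mean()
    crmse = float(np.sqrt(np.mean((cs - cl) ** 2)))
    return TaylorStats(sd_model=sd_m, sd_reference=sd_r, pearson_r=r, centered_rmse=crmse)


def stratify_patients(fold_results: list[FoldResult], cutoff: float = 80.0) -> dict:
    """Split patients into failed (accuracy < cutoff) and succeeded sets
    under a reference variant's fold results, with stratified metric means."""
    failed = [f for f in fold_results if f.metrics["accuracy"] < cutoff]
    succeeded = [f for f in fold_results if f.metrics["accuracy"] >= cutoff]

    def _mean(group):
        if not group:
            return {m: float("nan") for m in METRIC_NAMES}
        return {m: float(np.mean([f.metrics[m] for f in group])) for m in METRIC_NAMES}

    return {
        "failed": [f.patient_id for f in failed],
        "succeeded": [f.patient_id for f in succeeded],
        "failed_metrics": _mean(failed),
        "succeeded_metrics": _mean(succeeded),
        "cutoff": cutoff,
    }
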