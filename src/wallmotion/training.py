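"""Composite training loss and the optimization loop.

The loss combines three terms:

* an error term between the scalar score and the 0/1 label — mean absolute
  error by default, squared error selectable;
* a patient-invariance term L_p: the mean Euclidean distance in embedding
  (dense_1) space between same-class points from *different* patients;
  minimizing it pulls same-class points together across patients, yielding
  patient-independent movement features;
* an unlabeled-separation term L_m: the mean embedding distance between
  labeled and unlabeled points, *subtracted* from the loss so that ambiguous
  unlabeled points are pushed away from the labeled classes.

total = w_err * err + w_patient * L_p - w_unlabeled * L_m

Because maximizing an unbounded mean distance diverges (the optimizer can
simply inflate embedding norms), L_m is capped at a margin m per pair:
min(d, m).  m = inf recovers the literal unbounded form.

Zeroing w_patient reproduces the "w/o patient-invariance" ablation, zeroing
w_unlabeled the "w/o unlabeled" ablation, zeroing both the plain
error-only ("only MAE") training; these identities are exact, not
approximate, because zero-weight terms are skipped entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, concat
from .exceptions import ConfigError, DataError
from .io import UNLABELED, Trajectory
from .kinematics import feature_matrix, normalization_stats
from .model import ModelConfig, TrainedModel, forward_graph, init_model

_EPS = 1e-12  # inside sqrt of pairwise distances; keeps the gradient finite


@dataclass
class LossConfig:
    error_term: str = "mae"            # "mae" (text form) or "mse" (printed form)
    weight_error: float = 1.0
    # auxiliary weights default to 0.1: L_p is pure attraction (no repulsion),
    # so when it rivals the error term, collapsing every embedding to one
    # point becomes a strong local minimum and training degenerates to a
    # constant predictor; small weights keep both terms regularizers
    weight_patient: float = 0.1
    weight_unlabeled: float = 0.1
    margin: float = 10.0               # cap on L_m pair distances; inf = uncapped
    normalize_embeddings: bool = True  # L2-normalize embeddings for L_p / L_m
    batch_size: int = 32
    unlabeled_fraction: float = 0.25   # unlabeled points added per batch
    seed: int = 0

    def __post_init__(self):
        if self.error_term not in ("mae", "mse"):
            raise ConfigError("error_term must be 'mae' or 'mse'")
        if min(self.weight_error, self.weight_patient, self.weight_unlabeled) < 0:
            raise ConfigError("loss weights must be >= 0")
        if self.margin < 0:
            raise ConfigError("margin must be >= 0")
        if self.batch_size < 2 and self.weight_patient > 0:
            raise ConfigError("batch_size must be >= 2 when the patient term is on")


@dataclass
class OptimizerParams:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    steps_per_epoch: int = 25
    early_stopping: bool = True
    patience: int = 10
    validation_fraction: float = 0.1
    validation_max: int = 128   # cap so per-epoch validation stays cheap
    aux_warmup_epochs: float = 1.0  # ramp L_p / L_m weights in from zero


# ---------------------------------------------------------------------------
# Loss terms (Tensor graph versions + numpy-facing wrappers)
# ---------------------------------------------------------------------------

def l2_normalize(emb: Tensor) -> Tensor:
    """Row-wise L2 normalization (eps-guarded).

    The auxiliary loss terms act on the unit sphere by default: a subtracted
    distance term on raw embeddings can be maximized by simply inflating
    embedding norms, which saturates the sigmoid output and stalls the error
    term; on normalized embeddings every pair distance is bounded by 2.
    """
    norm = ((emb * emb).sum(axis=1, keepdims=True) + _EPS).sqrt()
    return emb / norm


def _pairwise_distances(a: Tensor, b: Tensor) -> Tensor:
    n, d = a.data.shape
    m = b.data.shape[0]
    diff = a.reshape(n, 1, d) - b.reshape(1, m, d)
    return ((diff * diff).sum(axis=2) + _EPS).sqrt()


def error_term_graph(preds: Tensor, labels: np.ndarray, kind: str) -> Tensor:
    labels_t = Tensor(np.asarray(labels, dtype=float))
    if preds.data.shape != labels_t.data.shape:
        raise DataError("prediction/label length mismatch")
    diff = preds - labels_t
    return diff.abs().mean() if kind == "mae" else (diff * diff).mean()


def patient_invariance_term_graph(
    embeddings: Tensor, labels: np.ndarray, patient_ids: np.ndarray
) -> Tensor:
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    n = embeddings.data.shape[0]
    same_label = labels[:, None] == labels[None, :]
    diff_patient = patient_ids[:, None] != patient_ids[None, :]
    mask = np.triu(same_label & diff_patient, k=1)
    if not mask.any():
        return Tensor(0.0)
    dist = _pairwise_distances(embeddings, embeddings)
    return (dist * Tensor(mask.astype(float))).sum() * (1.0 / mask.sum())


def unlabeled_separation_term_graph(
    labeled_emb: Tensor, unlabeled_emb: Tensor, margin: float
) -> Tensor:
    if margin < 0:
        raise ConfigError("margin must be >= 0")
    if labeled_emb.data.shape[0] == 0 or unlabeled_emb.data.shape[0] == 0:
        return Tensor(0.0)
    dist = _pairwise_distances(labeled_emb, unlabeled_emb)
    if np.isfinite(margin):
        dist = dist.minimum(margin)
    return dist.mean()


def error_term(preds, labels, kind: str = "mae") -> float:
    """Mean |y - yhat| ("mae") or mean (y - yhat)^2 ("mse")."""
    if kind not in ("mae", "mse"):
        raise ConfigError("kind must be 'mae' or 'mse'")
    preds = np.asarray(preds, dtype=float)
    if len(preds) < 1:
        raise DataError("need at least one prediction")
    return float(error_term_graph(Tensor(preds), labels, kind).data)


def patient_invariance_term(embeddings, labels, patient_ids) -> float:
    """Mean embedding distance over cross-patient same-label pairs (0 if none)."""
    return float(
        patient_invariance_term_graph(
            Tensor(np.asarray(embeddings, dtype=float)), labels, patient_ids
        ).data
    )


def unlabeled_separation_term(labeled_embeddings, unlabeled_embeddings, margin: float = 10.0) -> float:
    """Mean margin-capped embedding distance over labeled x unlabeled pairs."""
    return float(
        unlabeled_separation_term_graph(
            Tensor(np.atleast_2d(np.asarray(labeled_embeddings, dtype=float))),
            Tensor(np.atleast_2d(np.asarray(unlabeled_embeddings, dtype=float))),
            margin,
        ).data
    )


def composite_loss_graph(
    preds: Tensor,
    labels: np.ndarray,
    labeled_emb: Tensor,
    patient_ids: np.ndarray,
    unlabeled_emb: Tensor | None,
    cfg: LossConfig,
) -> tuple[Tensor, dict]:
    """Weighted total loss; zero-weight terms are skipped so ablation
    identities hold bitwise.  Returns (total Tensor, per-term float breakdown)."""
    err = error_term_graph(preds, labels, cfg.error_term)
    total = cfg.weight_error * err if cfg.weight_error != 0 else Tensor(0.0)
    breakdown = {"error": float(err.data), "patient": 0.0, "unlabeled": 0.0}
    if cfg.weight_error == 0:
        total = err * 0.0
    aux_lab = aux_unl = None
    if cfg.weight_patient != 0 or (cfg.weight_unlabeled != 0 and unlabeled_emb is not None):
        aux_lab = l2_normalize(labeled_emb) if cfg.normalize_embeddings else labeled_emb
        if unlabeled_emb is not None:
            aux_unl = (
                l2_normalize(unlabeled_emb) if cfg.normalize_embeddings else unlabeled_emb
            )
    if cfg.weight_patient != 0:
        lp = patient_invariance_term_graph(aux_lab, labels, patient_ids)
        breakdown["patient"] = float(lp.data)
        total = total + cfg.weight_patient * lp
    if cfg.weight_unlabeled != 0 and unlabeled_emb is not None:
        lm = unlabeled_separation_term_graph(aux_lab, aux_unl, cfg.margin)
        breakdown["unlabeled"] = float(lm.data)
        total = total - cfg.weight_unlabeled * lm
    breakdown["total"] = float(total.data)
    return total, breakdown


def composite_loss(
    preds, labels, embeddings, patient_ids, unlabeled_embeddings=None,
    loss_config: LossConfig | None = None,
) -> tuple[float, dict]:
    """Numpy-facing composite loss; see :func:`composite_loss_graph`."""
    cfg = loss_config or LossConfig()
    unl = (
        None
        if unlabeled_embeddings is None or len(unlabeled_embeddings) == 0
        else Tensor(np.asarray(unlabeled_embeddings, dtype=float))
    )
    total, breakdown = composite_loss_graph(
        Tensor(np.asarray(preds, dtype=float)),
        labels,
        Tensor(np.asarray(embeddings, dtype=float)),
        np.asarray(patient_ids),
        unl,
        cfg,
    )
    return float(total.data), breakdown


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _sample_batch(rng, labeled_by_patient: dict, n_labeled: int, unlab_idx, n_unlab: int):
    """Sample labeled indices spanning >= 2 patients (when available) plus
    unlabeled indices."""
    patients = [p for p, idx in labeled_by_patient.items() if len(idx)]
    chosen: list = []
    if len(patients) >= 2:
        for p in rng.choice(patients, size=2, replace=False):
            chosen.append(rng.choice(labeled_by_patient[p]))
    pool = np.concatenate([labeled_by_patient[p] for p in patients])
    remaining = max(n_labeled - len(chosen), 0)
    chosen.extend(rng.choice(pool, size=remaining, replace=len(pool) < remaining))
    lab = np.array(chosen, dtype=int)
    unl = (
        rng.choice(unlab_idx, size=min(n_unlab, len(unlab_idx)), replace=False)
        if n_unlab > 0 and len(unlab_idx)
        else np.empty(0, dtype=int)
    )
    return lab, unl


def train_model(
    trajectories: list[Trajectory] | None = None,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    optimizer_params: OptimizerParams | None = None,
    epochs: int = 10,
    seed: int = 0,
    interpolation_factor: int = 1,
    dataset: tuple | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Train on a cohort of trajectories (or a precomputed ``dataset``
    triple (X, y, patients) from :func:`~wallmotion.kinematics.feature_matrix`).

    Adam with the configured learning rate; each step draws a batch holding
    labeled points from at least two patients (when the cohort has them) and
    a configurable fraction of unlabeled points.  Normalization statistics
    are computed from this training data only and stored with the model.
    Returns the model and a per-epoch loss-history DataFrame.
    """
    mcfg = model_config or ModelConfig()
    lcfg = loss_config or LossConfig()
    opt_p = optimizer_params or OptimizerParams()
    if dataset is not None:
        X, y, patients = dataset
    else:
        if not trajectories:
            raise DataError("no trajectories given")
        X, y, patients = feature_matrix(trajectories, interpolation_factor)
    labeled_mask = y != UNLABELED
    if not labeled_mask.any():
        raise DataError("training requires at least one labeled point")
    if lcfg.weight_patient > 0 and len(np.unique(patients[labeled_mask])) < 2:
        warnings.warn(
            "patient-invariance term is on but the cohort has a single patient; "
            "the term will be zero", stacklevel=2,
        )

    model = init_model(replace(mcfg, seed=mcfg.seed))
    model.norm_stats = normalization_stats(X)
    history: list[dict] = []
    if epochs == 0:
        return model, pd.DataFrame(history)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    lab_idx = np.flatnonzero(labeled_mask)
    unlab_idx = np.flatnonzero(~labeled_mask)

    # held-out labeled validation split for early stopping
    val_idx = np.empty(0, dtype=int)
    if opt_p.early_stopping and len(lab_idx) >= 20:
        n_val = min(
            max(1, int(round(opt_p.validation_fraction * len(lab_idx)))),
            opt_p.validation_max,
        )
        perm = rng.permutation(lab_idx)
        val_idx, lab_idx = perm[:n_val], perm[n_val:]

    labeled_by_patient = {
        p: lab_idx[patients[lab_idx] == p] for p in np.unique(patients[lab_idx])
    }
    n_unlab_per_batch = (
        int(round(lcfg.unlabeled_fraction * lcfg.batch_size))
        if lcfg.weight_unlabeled != 0
        else 0  # the term is off; don't spend forward passes on unlabeled points
    )
    optimizer = Adam(model.parameters(), lr=opt_p.lr, beta1=opt_p.beta1, beta2=opt_p.beta2)

    best_val, best_params, wait = np.inf, None, 0
    for epoch in range(epochs):
        sums = {"total": 0.0, "error": 0.0, "patient": 0.0, "unlabeled": 0.0}
        for step in range(opt_p.steps_per_epoch):
            # ramp the auxiliary terms in so they regularize an embedding the
            # error signal has already begun to shape, rather than distorting
            # a random one
            if opt_p.aux_warmup_epochs > 0:
                ramp = min(
                    1.0,
                    (epoch + step / opt_p.steps_per_epoch) / opt_p.aux_warmup_epochs,
                )
            else:
                ramp = 1.0
            step_cfg = (
                lcfg
                if ramp == 1.0
                else replace(
                    lcfg,
                    weight_patient=ramp * lcfg.weight_patient,
                    weight_unlabeled=ramp * lcfg.weight_unlabeled,
                )
            )
            bl, bu = _sample_batch(
                rng, labeled_by_patient, lcfg.batch_size, unlab_idx, n_unlab_per_batch
            )
            idx = np.concatenate([bl, bu])
            scores, emb, _ = forward_graph(model, X[idx])
            n_l = len(bl)
            lab_scores = scores[:n_l] if len(bu) else scores
            lab_emb = emb[:n_l] if len(bu) else emb
            unl_emb = emb[n_l:] if len(bu) else None
            total, breakdown = composite_loss_graph(
                lab_scores, y[bl], lab_emb, patients[bl], unl_emb, step_cfg
            )
            total.backward()
            optimizer.step()
            for k in sums:
                sums[k] += breakdown[k]
        rec = {"epoch": epoch, **{k: v / opt_p.steps_per_epoch for k, v in sums.items()}}

        if len(val_idx):
            vs, _, _ = forward_graph(model, X[val_idx])
            rec["val_error"] = error_term(vs.data, y[val_idx], lcfg.error_term)
            if rec["val_error"] < best_val - 1e-6:
                best_val = rec["val_error"]
                best_params = {k: v.data.copy() for k, v in model.params.items()}
                wait = 0
            else:
                wait += 1
        history.append(rec)
        if len(val_idx) and wait >= opt_p.patience:
            break

    if best_params is not None:
        for k, v in model.params.items():
            v.data = best_params[k]
    return model, pd.DataFrame(history)


def sweep_loss_weights(
    trajectories,
    weight_grid,
    model_config: ModelConfig | None = None,
    loss_config: LossConfig | None = None,
    optimizer_params: OptimizerParams | None = None,
    epochs: int = 6,
    seeds=(0,),
    interpolation_factor: int = 1,
) -> pd.DataFrame:
    """Sensitivity sweep over loss-term weightings.

    ``weight_grid`` is an iterable of dicts overriding LossConfig fields
    (typically weight_patient / weight_unlabeled / margin).  Each setting is
    evaluated by leave-one-patient-out cross-validation for every seed;
    returns a tidy DataFrame of cohort metrics per (setting, seed).
    """
    from .evaluation import lopo_cross_validate  # deferred: avoids cycle

    base = loss_config or LossConfig()
    rows = []
    for overrides in weight_grid:
        lcfg = replace(base, **overrides)
        for seed in seeds:
            _, summary = lopo_cross_validate(
                trajectories,
                variant="proposed",
                model_config=model_config,
                loss_config=lcfg,
                optimizer_params=optimizer_params,
                epochs=epochs,
                seed=seed,
                interpolation_factor=interpolation_factor,
            )
            rows.append({**overrides, "seed": seed, **summary})
    return pd.DataFrame(rows)
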