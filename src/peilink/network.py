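"""Pruned feed-forward network for the pollution exposure index (PEI).

The PEI of chemical k at location i is a sum over emission sources j of a
learned per-source contribution::

    PEI_{i,k} = sum_j g(T_i, H_i, EM_{j,k}, D_{i,j}, ED_{i,j}, W_{i,j})

where ``g`` is a small multilayer perceptron (two tanh hidden layers, softplus
output so contributions are non-negative) applied to standardized source-
receptor features.  Monitoring records are the training ground truth: the
loss is the mean squared error between the *summed* contributions at a
monitor site and the measured value, so gradients flow through the shared
network applied to every source row of the site.

Training is full-batch Adam with uphill-step rejection (a step that increases
the training loss is reverted and the learning rate halved), which makes the
recorded loss trajectory non-increasing, plus early stopping on a site-level
validation split.  Pruning is iterative global magnitude pruning with
retraining of the surviving weights; masked weights are exactly zero and stay
zero.  Cross-validation is site-level k-fold: all records of a monitoring
site share a fold, so a site never appears in both train and test.

Calibration onto monitor units is a least-squares rescale through the origin,
folded into ``g`` itself — multiplicative, so the exact additivity of PEI
over source subsets is preserved.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureScaler, SourceSet, pair_feature_block, raw_to_network_inputs, feature_matrix

__all__ = [
    "TrainConfig",
    "PruneSchedule",
    "PrunedFNN",
    "CVReport",
    "train",
    "prune",
    "cross_validate",
]


def _softplus(z):
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class TrainConfig:
    """Hyperparameters for full-batch training.

    ``val_fraction`` is the share of monitoring *sites* (not records) held
    out for early stopping; ``log_target`` switches the loss to log1p scale
    for heavy-tailed concentrations.
    """

    hidden: tuple[int, ...] = (16, 8)
    lr: float = 0.03
    epochs: int = 400
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 50
    checkpoint_every: int = 20
    log_target: bool = True
    calibrate: bool = True


@dataclass
class PruneSchedule:
    """Iterative global magnitude-pruning schedule.

    ``fractions`` are cumulative shares of all weights to mask (increasing);
    after each step the survivors are retrained for ``retrain_epochs``;
    pruning stops before the validation loss exceeds
    ``(1 + tolerance) * pre-pruning loss``.
    """

    fractions: tuple[float, ...] = (0.3, 0.5, 0.7)
    retrain_epochs: int = 150
    tolerance: float = 0.10


class PrunedFNN:
    """The learned per-source contribution function g, with pruning mask."""

    def __init__(self, weights, biases, masks, scaler: FeatureScaler,
                 calibration_scale: float = 1.0, meta: dict | None = None):
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.masks = [np.asarray(m, dtype=bool) for m in masks]
        self.scaler = scaler
        self.calibration_scale = float(calibration_scale)
        self.meta = meta or {}
        self._apply_masks()

    # -- construction -------------------------------------------------------
    @classmethod
    def initialize(cls, n_inputs: int, hidden: tuple[int, ...], scaler: FeatureScaler,
                   rng: np.random.Generator) -> "PrunedFNN":
        sizes = (n_inputs, *hidden, 1)
        weights, biases, masks = [], [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
            masks.append(np.ones((fan_in, fan_out), dtype=bool))
        return cls(weights, biases, masks, scaler)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    def _apply_masks(self) -> None:
        for w, m in zip(self.weights, self.masks):
            w[~m] = 0.0

    def copy(self) -> "PrunedFNN":
        return PrunedFNN([w.copy() for w in self.weights],
                         [b.copy() for b in self.biases],
                         [m.copy() for m in self.masks],
                         self.scaler, self.calibration_scale,
                         copy.deepcopy(self.meta))

    def pruned_fraction(self) -> float:
        total = sum(m.size for m in self.masks)
        masked = sum((~m).sum() for m in self.masks)
        return masked / total

    # -- forward pass -------------------------------------------------------
    def _forward(self, Z: np.ndarray, need_cache: bool = False):
        acts = [Z]
        a = Z
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
            acts.append(a)
        z_out = (a @ self.weights[-1] + self.biases[-1]).ravel()
        g = self.calibration_scale * _softplus(z_out)
        return (g, acts, z_out) if need_cache else g

    def contributions(self, Z: np.ndarray) -> np.ndarray:
        """g >= 0 for each standardized feature row."""
        return self._forward(np.atleast_2d(np.asarray(Z, dtype=float)))

    def predict_contribution(self, table: pd.DataFrame) -> np.ndarray:
        """Per-source contributions for rows of a raw feature table."""
        if len(table) == 0:
            return np.empty(0)
        return self.contributions(feature_matrix(table, self.scaler))

    def predict_pei(self, table: pd.DataFrame) -> float:
        """PEI for a feature table filtered to one (receptor, chemical, year).

        The sum of per-source contributions; 0 for an empty table.
        """
        if len(table) == 0:
            return 0.0
        return float(self.predict_contribution(table).sum())

    def pei_by_receptor(self, table: pd.DataFrame) -> pd.Series:
        """PEI per receptor_id for a multi-receptor feature table."""
        if len(table) == 0:
            return pd.Series(dtype=float)
        g = self.predict_contribution(table)
        return pd.Series(g).groupby(table["receptor_id"].to_numpy()).sum()

    def pei_at_points(self, x, y, inventory, climate, terrain,
                      chemical: str, year: int, src: SourceSet | None = None) -> np.ndarray:
        """PEI at arbitrary points, bypassing the long-table representation."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if src is None:
            src = SourceSet.from_inventory(inventory, climate, terrain, chemical, int(year))
        if len(src) == 0:
            return np.zeros(len(x))
        blk = pair_feature_block(x, y, src, climate, terrain)
        R, S = len(x), len(src)
        X = raw_to_network_inputs(
            np.repeat(blk["T"], S), np.repeat(blk["H"], S),
            np.tile(src.emission, R), blk["D"].ravel(),
            blk["ED"].ravel(), blk["W"].ravel())
        g = self.contributions(self.scaler.transform(X))
        return g.reshape(R, S).sum(axis=1)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "peilink-pruned-fnn/1",
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "masks": [m.astype(int).tolist() for m in self.masks],
            "scaler": self.scaler.to_dict(),
            "calibration_scale": self.calibration_scale,
            "activation": "tanh",
            "output_transform": "softplus",
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PrunedFNN":
        return cls([np.asarray(w) for w in d["weights"]],
                   [np.asarray(b) for b in d["biases"]],
                   [np.asarray(m, dtype=bool) for m in d["masks"]],
                   FeatureScaler.from_dict(d["scaler"]),
                   d.get("calibration_scale", 1.0), d.get("meta", {}))

    @classmethod
    def load(cls, path) -> "PrunedFNN":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class _TrainingData:
    """Row-level features with record-level targets (sum inside the loss)."""

    X: np.ndarray            # (n_rows, 6) standardized inputs
    row_record: np.ndarray   # (n_rows,) record ordinal per row
    y: np.ndarray            # (n_records,) measured values
    record_site: np.ndarray  # (n_records,) site label per record
    sites: np.ndarray        # unique site labels


def _prepare(table: pd.DataFrame, records: pd.DataFrame,
             scaler: FeatureScaler | None = None) -> tuple[_TrainingData, FeatureScaler]:
    if len(records) == 0:
        raise ValueError("no monitor records to train on")
    chems = set(records["chemical"].unique()) | set(table["chemical"].unique())
    if len(chems) > 1:
        raise ValueError(f"train one network per chemical; got {sorted(chems)}")
    rec = records.reset_index(drop=True)
    key_to_ord = {(s, int(yr)): i for i, (s, yr)
                  in enumerate(zip(rec["site_id"], rec["year"]))}
    if len(key_to_ord) != len(rec):
        raise ValueError("duplicate (site, year) monitor records")
    row_keys = list(zip(table["receptor_id"], table["year"].astype(int)))
    row_record = np.array([key_to_ord.get(k, -1) for k in row_keys])
    covered = np.unique(row_record[row_record >= 0])
    missing = set(range(len(rec))) - set(covered.tolist())
    if missing:
        bad = [f"{rec['site_id'][i]}/{rec['year'][i]}" for i in sorted(missing)[:5]]
        raise ValueError(f"monitor records without matching feature rows: {bad}")
    keep = row_record >= 0
    sub = table.loc[keep]
    X_raw = raw_to_network_inputs(sub["T"], sub["H"], sub["EM"],
                                  sub["D"], sub["ED"], sub["W"])
    if scaler is None:
        scaler = FeatureScaler.fit(X_raw)
    data = _TrainingData(X=scaler.transform(X_raw),
                         row_record=row_record[keep],
                         y=rec["measured_value"].to_numpy(dtype=float),
                         record_site=rec["site_id"].to_numpy(),
                         sites=np.unique(rec["site_id"].to_numpy()))
    return data, scaler


def _loss_and_grad(net: PrunedFNN, X, row_record, y, rec_mask, log_target, want_grad=True):
    """MSE over the records selected by ``rec_mask``; returns (loss, grads)."""
    g, acts, z_out = net._forward(X, need_cache=True)
    pred = np.bincount(row_record, weights=g, minlength=len(y))
    if log_target:
        resid = np.log1p(pred) - np.log1p(y)
    else:
        resid = pred - y
    m = rec_mask.sum()
    loss = float((resid[rec_mask] ** 2).sum() / m)
    if not want_grad:
        return loss, None
    dpred = np.where(rec_mask, 2.0 * resid / m, 0.0)
    if log_target:
        dpred = dpred / (1.0 + pred)
    dg = dpred[row_record]
    dz = (dg * net.calibration_scale * _sigmoid(z_out))[:, None]
    gW, gB = [], []
    for layer in range(len(net.weights) - 1, -1, -1):
        a_prev = acts[layer]
        gW.append((a_prev.T @ dz) * net.masks[layer])
        gB.append(dz.sum(axis=0))
        if layer > 0:
            da = dz @ net.weights[layer].T
            dz = da * (1.0 - acts[layer] ** 2)
    return loss, (gW[::-1], gB[::-1])


def _adam_fit(net: PrunedFNN, data: _TrainingData, train_rec: np.ndarray,
              val_rec: np.ndarray, lr: float, epochs: int, patience: int,
              checkpoint_every: int, log_target: bool) -> dict:
    """Full-batch Adam with uphill rejection and site-split early stopping."""
    params = net.weights + net.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr0 = lr
    t = 0
    use_val = val_rec.any()
    val_every = 5
    checkpoints: list[tuple[int, float]] = []
    accepted_loss = np.inf
    saved = None
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(epochs):
        # single forward+backward per epoch; an uphill step is detected at the
        # next evaluation, reverted, and retried with half the learning rate
        loss, grads_wb = _loss_and_grad(net, data.X, data.row_record, data.y,
                                        train_rec, log_target)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss became non-finite at epoch {epoch} (lr={lr:g}); "
                "inputs may be degenerate")
        if loss > accepted_loss and saved is not None:
            for p, s in zip(params, saved):
                p[...] = s
            lr *= 0.5
            continue
        accepted_loss = loss
        lr = min(lr * 1.05, lr0)
        if epoch % checkpoint_every == 0 or epoch == epochs - 1:
            checkpoints.append((epoch, accepted_loss))
        if use_val and epoch % val_every == 0:
            vloss, _ = _loss_and_grad(net, data.X, data.row_record, data.y,
                                      val_rec, log_target, want_grad=False)
            if vloss < best_val - 1e-15:
                best_val = vloss
                best_state = [p.copy() for p in params]
                stale = 0
            else:
                stale += val_every
                if stale > patience:
                    break
        saved = [p.copy() for p in params]
        grads = grads_wb[0] + grads_wb[1]
        t += 1
        for p, g_, m_, v_ in zip(params, grads, m_t, v_t):
            m_ *= b1
            m_ += (1 - b1) * g_
            v_ *= b2
            v_ += (1 - b2) * g_**2
            mhat = m_ / (1 - b1**t)
            vhat = v_ / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        net._apply_masks()
    if use_val and best_state is not None:
        for p, s in zip(params, best_state):
            p[...] = s
        net._apply_masks()
    final_train, _ = _loss_and_grad(net, data.X, data.row_record, data.y,
                                    train_rec, log_target, want_grad=False)
    out = {"checkpoints": checkpoints, "final_train_loss": final_train}
    if use_val:
        vloss, _ = _loss_and_grad(net, data.X, data.row_record, data.y,
                                  val_rec, log_target, want_grad=False)
        out["val_loss"] = vloss
    return out


def _site_split(data: _TrainingData, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    sites = data.sites.copy()
    rng.shuffle(sites)
    n_val = int(round(val_fraction * len(sites)))
    val_sites = set(sites[:n_val].tolist())
    val_rec = np.array([s in val_sites for s in data.record_site])
    return ~val_rec, val_rec


def train(feature_table: pd.DataFrame, monitor_records: pd.DataFrame,
          config: TrainConfig | None = None) -> PrunedFNN:
    """Train the contribution network for one chemical.

    ``feature_table`` must cover every (site, year) present in
    ``monitor_records`` (one chemical only).  Deterministic for a fixed
    config seed.
    """
    config = config or TrainConfig()
    data, scaler = _prepare(feature_table, monitor_records)
    if len(data.y) < 20:
        raise ValueError(f"need at least 20 monitor records, got {len(data.y)}")
    rng = np.random.default_rng(config.seed)
    net = PrunedFNN.initialize(data.X.shape[1], tuple(config.hidden), scaler, rng)
    # start with per-source contributions whose sum matches the target scale,
    # otherwise softplus outputs (~0.69 each) over hundreds of sources swamp
    # the measured values and early training only fights the output bias
    rows_per_record = len(data.X) / len(data.y)
    target_g = max(float(np.mean(data.y)) / rows_per_record, 1e-6)
    net.biases[-1][:] = np.log(np.expm1(min(target_g, 30.0)))
    train_rec, val_rec = _site_split(data, config.val_fraction, rng)
    if not train_rec.any():
        train_rec, val_rec = np.ones_like(train_rec), np.zeros_like(val_rec)
    info = _adam_fit(net, data, train_rec, val_rec, config.lr, config.epochs,
                     config.patience, config.checkpoint_every, config.log_target)
    if config.calibrate:
        g = net._forward(data.X)
        pred = np.bincount(data.row_record, weights=g, minlength=len(data.y))
        denom = float((pred[train_rec] ** 2).sum())
        if denom > 0:
            net.calibration_scale = float((pred[train_rec] * data.y[train_rec]).sum() / denom)
    net.meta.update({
        "seed": config.seed,
        "epochs": config.epochs,
        "n_records": int(len(data.y)),
        "train_loss": info["final_train_loss"],
        "val_loss": info.get("val_loss"),
        "loss_checkpoints": [[int(e), float(l)] for e, l in info["checkpoints"]],
        "chemical": str(monitor_records["chemical"].iloc[0]),
    })
    return net


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _mask_global_fraction(net: PrunedFNN, fraction: float) -> None:
    """Mask the smallest-magnitude weights so ``fraction`` of all are zero."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("pruning fraction must be in [0, 1]")
    mags = np.concatenate([np.abs(w).ravel() for w in net.weights])
    alive = np.concatenate([m.ravel() for m in net.masks])
    n_total = mags.size
    n_target = int(round(fraction * n_total))
    n_masked = int((~alive).sum())
    extra = n_target - n_masked
    if extra <= 0:
        return
    order = np.argsort(np.where(alive, mags, np.inf), kind="stable")
    to_kill = order[:extra]
    flat = np.concatenate([m.ravel() for m in net.masks])
    flat[to_kill] = False
    pos = 0
    for i, m in enumerate(net.masks):
        net.masks[i] = flat[pos:pos + m.size].reshape(m.shape)
        pos += m.size
    net._apply_masks()


def prune(net: PrunedFNN, feature_table: pd.DataFrame, monitor_records: pd.DataFrame,
          schedule: PruneSchedule | None = None,
          config: TrainConfig | None = None) -> PrunedFNN:
    """Iterative global magnitude pruning with retraining.

    Each step masks the smallest surviving weights up to the next cumulative
    fraction, retrains the survivors, and keeps the result only while the
    site-split validation loss stays within ``(1 + tolerance)`` of the
    pre-pruning loss.  Returns a new network; the input is untouched.
    """
    schedule = schedule or PruneSchedule()
    config = config or TrainConfig()
    data, _ = _prepare(feature_table, monitor_records, scaler=net.scaler)
    rng = np.random.default_rng(config.seed)
    train_rec, val_rec = _site_split(data, config.val_fraction, rng)
    if not val_rec.any():
        val_rec = train_rec  # degenerate split: validate on the training records
    base_loss, _ = _loss_and_grad(net, data.X, data.row_record, data.y,
                                  val_rec, config.log_target, want_grad=False)
    best = net.copy()
    for frac in sorted(schedule.fractions):
        cand = best.copy()
        _mask_global_fraction(cand, frac)
        if schedule.retrain_epochs > 0 and frac < 1.0:
            _adam_fit(cand, data, train_rec, val_rec, config.lr,
                      schedule.retrain_epochs, config.patience,
                      config.checkpoint_every, config.log_target)
        loss, _ = _loss_and_grad(cand, data.X, data.row_record, data.y,
                                 val_rec, config.log_target, want_grad=False)
        if loss > (1.0 + schedule.tolerance) * base_loss:
            break
        best = cand
        best.meta["pruned_fraction"] = best.pruned_fraction()
        best.meta["prune_val_loss"] = loss
    return best


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold correlations between predicted PEI and held-out monitors."""

    folds: pd.DataFrame  # fold, n_sites, n_records, pearson, spearman

    @property
    def mean_pearson(self) -> float:
        return float(self.folds["pearson"].mean())

    @property
    def sd_pearson(self) -> float:
        return float(self.folds["pearson"].std(ddof=1))

    @property
    def mean_spearman(self) -> float:
        return float(self.folds["spearman"].mean())

    def to_csv(self, path) -> None:
        self.folds.to_csv(path, index=False)


def cross_validate(feature_table: pd.DataFrame, monitor_records: pd.DataFrame,
                   k: int = 10, seed: int = 0,
                   config: TrainConfig | None = None) -> CVReport:
    """Site-level k-fold cross-validation.

    Folds partition monitoring *sites* (k equal to the number of sites gives
    leave-one-site-out); each fold's model is trained, with its own scaler,
    on the remaining sites only.
    """
    config = config or TrainConfig()
    sites = np.unique(monitor_records["site_id"].to_numpy())
    if k < 2 or k > len(sites):
        raise ValueError(f"k must be in [2, n_sites={len(sites)}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    fold_of = np.empty(len(sites), dtype=int)
    fold_of[order] = np.arange(len(sites)) % k
    site_fold = dict(zip(sites, fold_of))

    rows = []
    rec_sites = monitor_records["site_id"].to_numpy()
    tab_sites = feature_table["receptor_id"].to_numpy()
    for fold in range(k):
        held = np.array([site_fold[s] == fold for s in rec_sites])
        held_tab = np.array([site_fold[s] == fold for s in tab_sites])
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + 1000 + fold})
        net = train(feature_table.loc[~held_tab], monitor_records.loc[~held], fold_cfg)
        held_rec = monitor_records.loc[held]
        sub = feature_table.loc[held_tab]
        g = net.predict_contribution(sub)
        sums = pd.Series(g).groupby(
            [sub["receptor_id"].to_numpy(), sub["year"].to_numpy().astype(int)]).sum()
        pei = np.asarray([float(sums.get((sid, int(yr)), 0.0))
                          for sid, yr in zip(held_rec["site_id"], held_rec["year"])])
        y = held_rec["measured_value"].to_numpy(dtype=float)
        if len(y) >= 2 and np.std(y) > 0 and np.std(pei) > 0:
            pearson = float(stats.pearsonr(pei, y).statistic)
            spearman = float(stats.spearmanr(pei, y).statistic)
        else:
            pearson = spearman = np.nan
        rows.append({"fold": fold, "n_sites": int((fold_of == fold).sum()),
                     "n_records": int(held.sum()), "pearson": pearson,
                     "spearman": spearman})
    return CVReport(folds=pd.DataFrame(rows))
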