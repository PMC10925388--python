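"""Training: losses, metrics, EMA smoothing, optimizer, loop, checkpoints.

The loss is a weighted sum of mean-squared errors on energies and forces,
each averaged over all of its elements.  Training on forces differentiates
the force error with respect to the weights, i.e. a second derivative
through the energy gradient; the autodiff engine supports that directly.

Validation reports L1 and MSE for energies and forces separately; test
reporting uses the L1 pair alone.  Logged losses are smoothed with an
exponential moving average (new = alpha * x + (1 - alpha) * old); the EMA
touches only the logged metrics, never the weights.

The optimizer is Adam with plateau-based learning-rate decay — the loop
needs *an* optimizer and the framework does not prescribe one; all of its
hyperparameters live in :class:`TrainingConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import ConformerDataset, ConformerRecord
from .featurization import RadialConfig
from .geometry import ParticleSystem
from .model import AssembledModel, Prediction
from .outputs import OutputConfig
from .priors import build_prior
from .representations import RepresentationConfig

__all__ = [
    "LossWeights",
    "TrainingConfig",
    "EMAState",
    "ema_update",
    "loss_tensors",
    "validation_metrics",
    "collate",
    "Adam",
    "train_loop",
    "save_checkpoint",
    "load_model",
]


@dataclass(frozen=True)
class LossWeights:
    energy: float = 1.0
    force: float = 0.0

    def __post_init__(self):
        if self.energy < 0 or self.force < 0:
            raise ValueError("loss weights must be non-negative")
        if self.energy == 0 and self.force == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class EMAState:
    """Exponentially smoothed metric; first update initializes to the value."""

    alpha: float = 0.05
    value: float | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("EMA decay alpha must be in (0, 1]")


def ema_update(state: EMAState, value: float) -> EMAState:
    new = value if state.value is None else (
        state.alpha * value + (1.0 - state.alpha) * state.value
    )
    return EMAState(alpha=state.alpha, value=new)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-2
    weights: LossWeights = field(default_factory=LossWeights)
    ema_alpha: float = 0.05
    seed: int = 0
    lr_factor: float = 0.5
    lr_patience: int = 20
    lr_min: float = 1e-5
    precision: int = 64


def collate(records: list[ConformerRecord]) -> tuple[ParticleSystem, np.ndarray, np.ndarray | None]:
    """Concatenate heterogeneous records into one batched system."""
    z = np.concatenate([r.z for r in records])
    pos = np.vstack([r.pos for r in records])
    batch = np.concatenate(
        [np.full(len(r.z), i, dtype=np.int64) for i, r in enumerate(records)]
    )
    q = None
    if all(r.q is not None for r in records):
        q = np.concatenate([r.q for r in records])
    system = ParticleSystem(pos, z, batch=batch, charges=q)
    y = np.array([r.y for r in records])
    neg_dy = None
    if all(r.neg_dy is not None for r in records):
        neg_dy = np.vstack([r.neg_dy for r in records])
    return system, y, neg_dy


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - ad.constant(target)
    return ad.tmean(ad.mul(diff, diff))


def loss_tensors(
    y: Tensor,
    neg_dy: Tensor | None,
    y_target: np.ndarray,
    neg_dy_target: np.ndarray | None,
    weights: LossWeights,
) -> Tensor:
    """lambda_E * MSE(y) + lambda_F * MSE(neg_dy), element-averaged."""
    if weights.force > 0 and (neg_dy is None or neg_dy_target is None):
        raise ValueError(
            "force loss weight > 0 but predictions or targets lack forces"
        )
    total = None
    if weights.energy > 0:
        total = ad.mul(_mse(y, y_target), weights.energy)
    if weights.force > 0:
        f = ad.mul(_mse(neg_dy, neg_dy_target), weights.force)
        total = f if total is None else total + f
    return total


def validation_metrics(
    pred: Prediction, y_target: np.ndarray, neg_dy_target: np.ndarray | None = None
) -> dict[str, float]:
    """L1 and MSE for energies and, when available, forces."""
    out = {
        "l1_energy": float(np.mean(np.abs(pred.y - y_target))),
        "mse_energy": float(np.mean((pred.y - y_target) ** 2)),
    }
    if pred.neg_dy is not None and neg_dy_target is not None:
        diff = pred.neg_dy - neg_dy_target
        out["l1_force"] = float(np.mean(np.abs(diff)))
        out["mse_force"] = float(np.mean(diff**2))
    return out


class Adam:
    """Adaptive-moment estimation over the model's trainable parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "lr": self.lr,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]


def _train_step(
    model: AssembledModel,
    system: ParticleSystem,
    y_target: np.ndarray,
    neg_dy_target: np.ndarray | None,
    weights: LossWeights,
    optimizer: Adam,
) -> float:
    y, positions = model.forward_tensors(system)
    neg_dy = None
    if weights.force > 0:
        (gpos,) = ad.grad(ad.tsum(y), positions, create_graph=True)
        neg_dy = ad.mul(gpos, -1.0)
    loss = loss_tensors(y, neg_dy, y_target, neg_dy_target, weights)
    value = loss.item()
    if not np.isfinite(value):
        raise FloatingPointError("non-finite training loss")
    params = [p for p in model.parameters() if p.requires_grad]
    grads = ad.grad(loss, params)
    optimizer.step(grads)
    return value


def _evaluate(
    model: AssembledModel,
    dataset: ConformerDataset,
    indices: np.ndarray,
    batch_size: int,
    weights: LossWeights,
) -> dict[str, float]:
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for lo in range(0, len(indices), batch_size):
        chunk = [dataset[int(i)] for i in indices[lo : lo + batch_size]]
        system, y_t, f_t = collate(chunk)
        pred = model.predict(system)
        m = validation_metrics(pred, y_t, f_t)
        n_e = len(chunk)
        n_f = system.n_atoms * 3
        for key, val in m.items():
            w = n_f if "force" in key else n_e
            sums[key] = sums.get(key, 0.0) + val * w
            counts[key] = counts.get(key, 0) + w
    metrics = {k: sums[k] / counts[k] for k in sums}
    val_loss = weights.energy * metrics.get("mse_energy", 0.0)
    if weights.force > 0:
        val_loss += weights.force * metrics.get("mse_force", 0.0)
    metrics["val_loss"] = val_loss
    return metrics


def train_loop(
    model: AssembledModel,
    dataset: ConformerDataset,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainingConfig,
    checkpoint_path: str | None = None,
    resume_from: str | None = None,
    log_callback=None,
) -> dict:
    """Mini-batch training with per-epoch validation and best tracking.

    Deterministic under a fixed seed: the shuffle of epoch ``e`` is drawn
    from ``default_rng([seed, e])``, so resuming from a checkpoint at any
    epoch reproduces the uninterrupted run exactly.

    Returns a history dict with per-epoch raw and EMA-smoothed metrics.
    """
    train_idx, val_idx, _ = splits
    if config.weights.force > 0 and not dataset.has_forces:
        raise ValueError("force loss requested but the dataset has no forces")
    optimizer = Adam(
        [p for p in model.parameters() if p.requires_grad], lr=config.learning_rate
    )
    history: list[dict] = []
    ema: dict[str, EMAState] = {}
    best = {"val_loss": np.inf, "epoch": -1}
    start_epoch = 0
    plateau = {"bad": 0, "best": np.inf}

    if resume_from is not None:
        model2, extra = _load_checkpoint(resume_from)
        model.load_state_dict(model2.state_dict())
        optimizer.load_state_dict(extra["optimizer"])
        history = extra["history"]
        start_epoch = extra["epoch"] + 1
        plateau = extra["plateau"]
        best = extra["best"]
        ema = {
            k: EMAState(alpha=config.ema_alpha, value=v)
            for k, v in extra["ema"].items()
        }

    for epoch in range(start_epoch, config.epochs):
        order = np.random.default_rng([config.seed, epoch]).permutation(
            len(train_idx)
        )
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            rows = train_idx[order[lo : lo + config.batch_size]]
            chunk = [dataset[int(i)] for i in rows]
            system, y_t, f_t = collate(chunk)
            try:
                epoch_losses.append(
                    _train_step(model, system, y_t, f_t, config.weights, optimizer)
                )
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"{err} at epoch {epoch}, batch {lo // config.batch_size}"
                ) from err
        metrics = _evaluate(
            model, dataset, val_idx, config.batch_size, config.weights
        )
        metrics["train_loss"] = float(np.mean(epoch_losses))
        metrics["lr"] = optimizer.lr
        smoothed = {}
        for key in ("train_loss", "val_loss"):
            ema[key] = ema_update(
                ema.get(key, EMAState(alpha=config.ema_alpha)), metrics[key]
            )
            smoothed[f"ema_{key}"] = ema[key].value
        row = {"epoch": epoch, **metrics, **smoothed}
        history.append(row)
        if log_callback:
            log_callback(row)

        # plateau LR decay on the smoothed validation loss
        if smoothed["ema_val_loss"] < plateau["best"] * (1 - 1e-4):
            plateau["best"] = smoothed["ema_val_loss"]
            plateau["bad"] = 0
        else:
            plateau["bad"] += 1
            if plateau["bad"] > config.lr_patience:
                optimizer.lr = max(optimizer.lr * config.lr_factor, config.lr_min)
                plateau["bad"] = 0

        if metrics["val_loss"] < best["val_loss"]:
            best = {"val_loss": metrics["val_loss"], "epoch": epoch}
            if checkpoint_path is not None:
                save_checkpoint(
                    str(checkpoint_path).replace(".npz", "") + "_best.npz",
                    model, optimizer, epoch, history, plateau, best, ema,
                )
        if checkpoint_path is not None:
            save_checkpoint(
                checkpoint_path, model, optimizer, epoch, history, plateau,
                best, ema,
            )
    return {"history": history, "best": best}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str,
    model: AssembledModel,
    optimizer: Adam | None = None,
    epoch: int = -1,
    history: list | None = None,
    plateau: dict | None = None,
    best: dict | None = None,
    ema: dict | None = None,
) -> None:
    """Serialize config + weights (+ optimizer state) to an NPZ container."""
    payload: dict[str, np.ndarray] = {
        "config_json": np.frombuffer(
            json.dumps(model.config_dict()).encode(), dtype=np.uint8
        )
    }
    for name, arr in model.state_dict().items():
        payload[f"param::{name}"] = arr
    meta = {
        "epoch": epoch,
        "history": history or [],
        "plateau": plateau or {},
        "best": _jsonable(best or {}),
        "ema": {k: v.value for k, v in (ema or {}).items()},
    }
    payload["meta_json"] = np.frombuffer(
        json.dumps(_jsonable(meta)).encode(), dtype=np.uint8
    )
    if optimizer is not None:
        payload["opt_t"] = np.array(optimizer.t)
        payload["opt_lr"] = np.array(optimizer.lr)
        for i, (m, v) in enumerate(zip(optimizer.m, optimizer.v)):
            payload[f"opt_m::{i}"] = m
            payload[f"opt_v::{i}"] = v
    np.savez(path, **payload)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _model_from_config(cfg: dict) -> AssembledModel:
    m = cfg["model"]
    rep = RepresentationConfig(
        model=m["model"],
        embedding_dimension=m["embedding_dimension"],
        num_layers=m["num_layers"],
        radial=RadialConfig(
            cutoff=m["cutoff"], num_rbf=m["num_rbf"],
            trainable_rbf=m.get("trainable_rbf", False),
        ),
        max_z=m["max_z"],
        vector_cutoff=m.get("vector_cutoff", True),
    )
    out = OutputConfig(
        hidden_channels=m["hidden_channels"], reduce_op=m["reduce_op"]
    )
    priors = [build_prior(s, cutoff=m["cutoff"]) for s in cfg.get("priors", [])]
    return AssembledModel(
        rep, out, priors,
        derivative=m.get("derivative", True),
        max_num_neighbors=m.get("max_num_neighbors", 32),
        seed=m.get("seed", 0),
        precision=m.get("precision", 64),
    )


def _load_checkpoint(path: str) -> tuple[AssembledModel, dict]:
    try:
        with np.load(path, allow_pickle=False) as f:
            cfg = json.loads(bytes(f["config_json"].tobytes()).decode())
            model = _model_from_config(cfg)
            state = {
                k.split("::", 1)[1]: f[k] for k in f.files if k.startswith("param::")
            }
            model.load_state_dict(state)
            meta = json.loads(bytes(f["meta_json"].tobytes()).decode())
            extra = dict(meta)
            if "opt_t" in f.files:
                n = len([k for k in f.files if k.startswith("opt_m::")])
                extra["optimizer"] = {
                    "t": f["opt_t"][()],
                    "lr": f["opt_lr"][()],
                    "m": [f[f"opt_m::{i}"] for i in range(n)],
                    "v": [f[f"opt_v::{i}"] for i in range(n)],
                }
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as err:
        raise ValueError(f"cannot load checkpoint {path!r}: {err}") from err
    return model, extra


def load_model(path: str, derivative: bool | None = None) -> AssembledModel:
    """One-call load-for-inference; the derivative flag may be overridden."""
    model, _ = _load_checkpoint(path)
    if derivative is not None:
        model.derivative = derivative
    return model
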