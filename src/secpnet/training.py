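"""Training recipe: multi-class cross-entropy (base-2 logarithm), polynomial
learning-rate decay, SGD with momentum, and the staged schedule for the
cascaded network.

The cascade is trained in up to four ordered stages:

1. ``backbone``  — train a plain U-Net to convergence;
2. ``secp``      — build the pyramid network, initialise its shared
                   encoder/decoder weights from stage 1, train it;
3. ``secondary`` — freeze the primary network and train the secondary U-Net
                   on auto-context inputs (image + primary probabilities);
4. ``finetune``  — unfreeze everything and fine-tune end-to-end at a reduced
                   initial learning rate (lr0 / 10 by default).

Stages may be skipped but never reordered; each stage restarts the
polynomial decay from its own initial learning rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from ._runtime import configure_runtime
from .autodiff import Tensor, concat_channels, cross_entropy_from_probs, softmax_channels
from .layers import Module, parameter_hash
from .nets import CascadeNet, NetworkConfig, UNetBackbone, save_checkpoint

__all__ = [
    "TrainPlan",
    "cross_entropy_loss",
    "poly_lr",
    "SGD",
    "make_optimizer",
    "run_staged_training",
    "StagedTrainingResult",
    "batched_probabilities",
]

STAGE_ORDER = ("backbone", "secp", "secondary", "finetune")
_PREREQUISITE = {"secp": "backbone", "secondary": "secp", "finetune": "secondary"}


@dataclass
class TrainPlan:
    """Hyperparameters of the training recipe.

    Defaults follow the standard recipe for this model family: SGD with
    momentum 0.9 and weight decay 1e-4, initial learning rate 0.01 decayed
    polynomially (power 0.9) over ``epochs_total`` epochs per stage, batch
    size 16.
    """

    epochs_total: int = 100
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 16
    stages: tuple = STAGE_ORDER
    loss_base: float = 2.0
    finetune_lr_scale: float = 0.1
    plateau_patience: int = 10
    plateau_rel_tol: float = 1e-4
    stage_epochs: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if self.epochs_total < 1:
            raise ValueError("epochs_total must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        positions = [STAGE_ORDER.index(s) for s in self.stages]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError(
                f"stages must be a subsequence of {STAGE_ORDER}, got {self.stages}"
            )

    def epochs_for(self, stage: str) -> int:
        return int(self.stage_epochs.get(stage, self.epochs_total))


def cross_entropy_loss(probs, target, eps: float = 1e-12, base: float = 2.0):
    """Mean per-pixel cross-entropy -log_base(q_true + eps) against integer
    labels.

    With the default base 2 the loss is measured in bits; a uniform C-class
    prediction therefore costs exactly log2(C) per pixel.  Switching to the
    natural logarithm rescales the loss (and its gradient) by exactly ln 2
    without changing the optimisation direction.

    Accepts a :class:`Tensor` (returns a scalar Tensor with gradients) or a
    plain array (returns a float).  ``target`` may be (B, H, W) or (H, W).
    """
    is_tensor = isinstance(probs, Tensor)
    if is_tensor:
        p = probs
        if p.ndim != 4:
            raise ValueError(f"expected (B,C,H,W) probabilities, got {p.shape}")
    else:
        arr = np.asarray(probs, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        p = Tensor(arr)
    t = np.asarray(target)
    if t.ndim == 2:
        t = t[None]
    out = cross_entropy_from_probs(p, t, eps=eps, base=base)
    return out if is_tensor else float(out.data)


def poly_lr(n: int, total: int, lr0: float, power: float = 0.9) -> float:
    """Polynomial decay ``lr0 * (1 - n/total)**power``, applied before each
    epoch's updates; exactly lr0 at epoch 0 and exactly 0 at the final
    epoch index."""
    if not 0 <= n <= total:
        raise ValueError(f"epoch index {n} outside [0, {total}]")
    return float(lr0 * (1.0 - n / total) ** power)


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled-in-
    the-usual-sense L2 weight decay added to the raw gradient."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=1e-4):
        self.params = [p for p in params]
        if not self.params:
            raise ValueError("optimizer needs a nonempty parameter set")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def make_optimizer(params, plan: TrainPlan, epoch: int = 0, total=None, lr0=None) -> SGD:
    """SGD configured from the plan with the polynomially decayed learning
    rate for ``epoch``."""
    total = plan.epochs_total if total is None else total
    lr0 = plan.lr0 if lr0 is None else lr0
    return SGD(
        params,
        lr=poly_lr(epoch, total, lr0),
        momentum=plan.momentum,
        weight_decay=plan.weight_decay,
    )


# ---------------------------------------------------------------------------
# staged training
# ---------------------------------------------------------------------------


@dataclass
class StagedTrainingResult:
    backbone: UNetBackbone | None
    cascade: CascadeNet
    log: list  # dicts: stage, epoch, lr, loss
    checkpoints: dict  # stage -> Path

    def log_to_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["stage", "epoch", "lr", "loss"])
            writer.writeheader()
            writer.writerows(self.log)
        return path


def batched_probabilities(model: Module, images: np.ndarray, batch_size: int = 16):
    """Run ``model`` in eval mode over ``images`` (N, C, H, W); returns the
    (N, num_classes, H, W) probability array."""
    was_training = model.training
    model.eval()
    chunks = []
    for start in range(0, len(images), batch_size):
        out = model(images[start : start + batch_size])
        if isinstance(out, tuple):  # SECPNet returns (logits, probs)
            probs = out[1]
        else:
            probs = softmax_channels(out)
        chunks.append(probs.data)
    if was_training:
        model.train()
    return np.concatenate(chunks, axis=0)


def _load_matching(module: Module, state: dict) -> None:
    """Copy entries of ``state`` into ``module`` by name where shapes match."""
    params = dict(module.named_parameters())
    bufs = dict(module._named_buffers())
    compatible = {}
    for name, arr in state.items():
        tgt = params[name].data if name in params else bufs.get(name)
        if tgt is not None and tgt.shape == np.shape(arr):
            compatible[name] = arr
    module.load_state_dict(compatible, strict=False)


def _train_stage(forward_loss, params, plan, epochs, lr0, n_samples, rng, stage, log):
    """Generic per-stage epoch loop with polynomial decay and plateau stop."""
    opt = SGD(params, lr=lr0, momentum=plan.momentum, weight_decay=plan.weight_decay)
    history = []
    for epoch in range(epochs):
        opt.lr = poly_lr(epoch, epochs, lr0)
        perm = rng.permutation(n_samples)
        total, weight = 0.0, 0
        for start in range(0, n_samples, plan.batch_size):
            idx = perm[start : start + plan.batch_size]
            loss = forward_loss(idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            weight += len(idx)
        mean_loss = total / weight
        history.append(mean_loss)
        log.append({"stage": stage, "epoch": epoch, "lr": opt.lr, "loss": mean_loss})
        p = plan.plateau_patience
        if p and len(history) > p:
            ref = history[-1 - p]
            if abs(ref - mean_loss) / max(abs(ref), 1e-12) < plan.plateau_rel_tol:
                break


def run_staged_training(
    cascade: CascadeNet,
    images: np.ndarray,
    masks: np.ndarray,
    plan: TrainPlan,
    seed: int,
    out_dir=None,
) -> StagedTrainingResult:
    """Execute the staged schedule on an in-memory dataset.

    ``images`` is (N, in_channels, H, W) float, ``masks`` is (N, H, W) int.
    Per-stage checkpoints (parameter archive + config sidecar) and a CSV
    epoch log are written under ``out_dir`` when given.  The whole run is a
    deterministic function of ``seed``.
    """
    configure_runtime()
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks)
    if images.ndim != 4 or masks.ndim != 3 or len(images) != len(masks):
        raise ValueError("expected images (N,C,H,W) and masks (N,H,W) of equal length")
    n = len(images)
    cfg: NetworkConfig = cascade.primary.cfg
    rng = np.random.default_rng(seed)
    log: list = []
    checkpoints: dict = {}
    out_dir = Path(out_dir) if out_dir is not None else None

    def ce(probs, idx):
        return cross_entropy_from_probs(probs, masks[idx], base=plan.loss_base)

    backbone = None
    completed: set = set()
    for stage in plan.stages:
        prereq = _PREREQUISITE.get(stage)
        if prereq is not None and prereq not in completed:
            raise RuntimeError(
                f"stage '{stage}' requires stage '{prereq}' to have run first"
            )
        stage_rng = np.random.default_rng(rng.integers(2**31))
        epochs = plan.epochs_for(stage)

        if stage == "backbone":
            backbone = UNetBackbone(cfg, np.random.default_rng(rng.integers(2**31)))
            backbone.train()

            def loss_fn(idx, _m=backbone):
                return ce(softmax_channels(_m(images[idx])), idx)

            _train_stage(
                loss_fn, backbone.parameters(), plan, epochs, plan.lr0, n,
                stage_rng, stage, log,
            )
            trained = backbone

        elif stage == "secp":
            cascade.primary.load_state_dict(backbone.state_dict(), strict=False)
            cascade.primary.train()

            def loss_fn(idx, _m=cascade.primary):
                return ce(_m(images[idx])[1], idx)

            _train_stage(
                loss_fn, cascade.primary.parameters(), plan, epochs, plan.lr0, n,
                stage_rng, stage, log,
            )
            trained = cascade.primary

        elif stage == "secondary":
            # warm-start from the stage-1 backbone wherever shapes allow;
            # only the first convolution differs (its input now carries the
            # probability channels) and starts fresh
            _load_matching(cascade.secondary, backbone.state_dict())
            # primary is frozen: run it once in eval mode and train the
            # secondary on the cached auto-context stacks
            cascade.primary.requires_grad_(False)
            primary_probs = batched_probabilities(
                cascade.primary, images, plan.batch_size
            )
            stacked = np.concatenate([images, primary_probs], axis=1)
            cascade.secondary.train()

            def loss_fn(idx, _m=cascade.secondary, _s=stacked):
                return ce(softmax_channels(_m(_s[idx])), idx)

            _train_stage(
                loss_fn, cascade.secondary.parameters(), plan, epochs, plan.lr0, n,
                stage_rng, stage, log,
            )
            cascade.primary.requires_grad_(True)
            trained = cascade

        elif stage == "finetune":
            cascade.train()

            def loss_fn(idx, _m=cascade):
                x = Tensor(images[idx])
                _, primary_probs = _m.primary(x)
                final_logits = _m.secondary(concat_channels(x, primary_probs))
                return ce(softmax_channels(final_logits), idx)

            _train_stage(
                loss_fn, cascade.parameters(), plan, epochs,
                plan.lr0 * plan.finetune_lr_scale, n, stage_rng, stage, log,
            )
            trained = cascade

        completed.add(stage)
        if out_dir is not None:
            checkpoints[stage] = save_checkpoint(trained, out_dir / stage)

    result = StagedTrainingResult(backbone, cascade, log, checkpoints)
    if out_dir is not None:
        result.log_to_csv(out_dir / "training_log.csv")
    return result
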