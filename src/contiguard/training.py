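"""Training protocol: epoch construction, window selection, optimization.

Misassembled contigs are rare, so every epoch uses all positives and an
independently re-drawn 10% subsample of the negatives; the realized positive
fraction is ``P / (P + round(f * N))``.  Long contigs enter as one window of
at most 20 kb per epoch — for a misassembled contig the window is drawn
uniformly among windows containing a (uniformly chosen) breakpoint, so the
junction signal is always in view; for a correct contig the window is
uniform.  Optimization is binary cross-entropy under Adam with gradient
clipping (element-wise to 0.5, then global norm to 1), learning-rate decay
of 0.8 on validation plateau, and model selection by validation AUPRC
evaluated every other epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .nn import AdamOptimizer, ModelConfig, ResidualNet, bce_with_logits

__all__ = ["TrainConfig", "make_epoch_sample", "select_window",
           "pad_batch", "train_network", "TrainingHistory"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the published protocol)."""

    epochs: int = 50
    batch_size: int = 200
    lr: float = 1e-4
    lr_decay: float = 0.8
    patience: int = 2              # evaluations without improvement -> decay
    grad_clip_norm: float = 1.0
    grad_clip_value: float = 0.5
    neg_subsample_frac: float = 0.10
    validation_frac: float = 0.10
    eval_every: int = 2            # epochs between validation evaluations
    window_len: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.neg_subsample_frac <= 1.0:
            raise ValueError("neg_subsample_frac must be in (0, 1]")
        if not 0.0 < self.validation_frac < 1.0:
            raise ValueError("validation_frac must be in (0, 1)")
        if self.window_len <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("window_len, epochs, batch_size must be positive")


def make_epoch_sample(
    labels: np.ndarray,
    neg_frac: float,
    rng: int | np.random.Generator | None,
) -> np.ndarray:
    """Indices for one epoch: all positives plus a fresh random
    ``neg_frac`` of the negatives (without replacement), shuffled."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0:
        import warnings
        warnings.warn("no positive examples; epoch is negatives only")
    k = int(round(neg_frac * len(neg)))
    chosen_neg = rng.choice(neg, size=k, replace=False) if k else neg[:0]
    idx = np.concatenate([pos, chosen_neg])
    rng.shuffle(idx)
    return idx


def select_window(
    length: int,
    label: int,
    breakpoints: Sequence[int],
    window_len: int,
    rng: int | np.random.Generator | None,
) -> tuple[int, int]:
    """Pick the (start, end) interval fed to the network for one contig.

    Contigs shorter than the window enter whole (zero-padded downstream).
    Misassembled long contigs get a uniformly random window constrained to
    contain a uniformly chosen breakpoint; correct long contigs get a
    uniformly random window.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    if length <= window_len:
        return 0, length
    rng = np.random.default_rng(rng)
    if label == 1:
        if not breakpoints:
            raise ValueError("misassembled contig without breakpoints")
        bp = int(breakpoints[int(rng.integers(len(breakpoints)))])
        lo = max(0, bp - window_len + 1)
        hi = min(length - window_len, bp - 1)
        if hi < lo:    # breakpoint too close to a contig end
            start = min(max(0, bp - window_len // 2), length - window_len)
        else:
            start = int(rng.integers(lo, hi + 1))
    else:
        start = int(rng.integers(0, length - window_len + 1))
    return start, start + window_len


def pad_batch(arrays: Sequence[np.ndarray], min_len: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad (L_i, C) arrays to a common (B, M, C) batch.

    Valid lengths are reported as max(L_i, min_len) so that contigs shorter
    than the network's receptive minimum count their padding as input.
    """
    lengths = np.array([max(a.shape[0], min_len) for a in arrays])
    M = int(lengths.max())
    C = arrays[0].shape[1]
    x = np.zeros((len(arrays), M, C), dtype=np.float32)
    for i, a in enumerate(arrays):
        x[i, :a.shape[0]] = a
    return x, lengths


@dataclass
class TrainingHistory:
    """Per-epoch training record and the selected best checkpoint."""

    table: pd.DataFrame
    best_state: dict
    best_val_auprc: float
    best_epoch: int
    n_checkpoints: int
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None


def _predict_batched(net, items, batch_size, min_len):
    """items: list of (L, C) arrays; returns probabilities."""
    order = np.argsort([-a.shape[0] for a in items], kind="stable")
    probs = np.empty(len(items))
    for i in range(0, len(items), batch_size):
        sel = order[i:i + batch_size]
        x, lens = pad_batch([items[j] for j in sel], min_len)
        probs[sel] = net.predict_proba(x, lens)
    return probs


def train_network(
    net: ResidualNet,
    windows_of: Callable[[int, np.random.Generator], np.ndarray],
    labels: np.ndarray,
    config: TrainConfig,
    verbose: bool = False,
) -> TrainingHistory:
    """Run the training protocol on a prepared dataset.

    Parameters
    ----------
    net : ResidualNet
    windows_of : callable(index, rng) -> (L, C) float32 array
        Returns the (window-selected, normalized) model input for contig
        ``index``; called fresh each epoch so window randomness is per-epoch.
    labels : array of 0/1, one per contig
    config : TrainConfig
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    master = np.random.default_rng(config.seed)
    split_rng = np.random.default_rng(master.integers(2 ** 31))
    perm = split_rng.permutation(n)
    n_val = max(1, int(round(config.validation_frac * n)))
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    if len(val_idx) == 0 or len(train_idx) == 0:
        raise ValueError("dataset too small for a train/validation split")

    # validation windows fixed once so AUPRC is comparable across epochs
    val_rng = np.random.default_rng(master.integers(2 ** 31))
    val_items = [windows_of(i, val_rng) for i in val_idx]
    val_labels = labels[val_idx]

    min_len = net.config.min_input_length()
    opt = AdamOptimizer(net, lr=config.lr)
    rows = []
    best_state, best_auprc, best_epoch = None, -np.inf, -1
    n_ckpt = 0
    evals_since_improve = 0
    epoch_seed_rng = np.random.default_rng(master.integers(2 ** 31))

    for epoch in range(1, config.epochs + 1):
        erng = np.random.default_rng(epoch_seed_rng.integers(2 ** 31))
        idx = make_epoch_sample(labels[train_idx],
                                config.neg_subsample_frac, erng)
        idx = train_idx[idx]
        items = [windows_of(i, erng) for i in idx]
        # batch by length to limit padding waste, then shuffle batch order
        order = np.argsort([-a.shape[0] for a in items], kind="stable")
        batches = [order[i:i + config.batch_size]
                   for i in range(0, len(order), config.batch_size)]
        erng.shuffle(batches)
        total_loss, total_n = 0.0, 0
        for sel in batches:
            x, lens = pad_batch([items[j] for j in sel], min_len)
            yb = labels[idx[sel]].astype(np.float64)
            net.zero_grad()
            z = net.forward_logits(x, lens, training=True)
            loss, dz = bce_with_logits(z, yb)
            net.backward(dz)
            opt.step(config.grad_clip_value, config.grad_clip_norm)
            total_loss += loss * len(sel)
            total_n += len(sel)
        epoch_loss = total_loss / max(total_n, 1)

        val_auprc = np.nan
        if epoch % config.eval_every == 0 or epoch == config.epochs:
            probs = _predict_batched(net, val_items, config.batch_size,
                                     min_len)
            if val_labels.sum() > 0:
                val_auprc = float(average_precision_score(val_labels, probs))
            else:
                val_auprc = np.nan
            if np.isfinite(val_auprc) and val_auprc > best_auprc:
                best_auprc = val_auprc
                best_state = net.state_dict()
                best_epoch = epoch
                n_ckpt += 1
                evals_since_improve = 0
            else:
                evals_since_improve += 1
                if evals_since_improve >= config.patience:
                    opt.lr *= config.lr_decay
                    evals_since_improve = 0
        rows.append({"epoch": epoch, "loss": epoch_loss,
                     "val_auprc": val_auprc, "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}  "
                  f"val AUPRC {val_auprc if np.isfinite(val_auprc) else float('nan'):.4f}  "
                  f"lr {opt.lr:.2e}")

    if best_state is None:      # no finite validation score ever
        best_state = net.state_dict()
        best_auprc = float("nan")
        best_epoch = config.epochs
    return TrainingHistory(
        table=pd.DataFrame(rows), best_state=best_state,
        best_val_auprc=best_auprc, best_epoch=best_epoch,
        n_checkpoints=n_ckpt, train_idx=train_idx, val_idx=val_idx)
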