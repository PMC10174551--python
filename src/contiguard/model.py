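"""Model and results objects tying the pipeline together.

`MisassemblyDetector` is built from raw per-contig feature matrices plus
truth labels/breakpoints; `fit()` runs the training protocol and returns a
`MisassemblyResults` carrying the selected network, the fitted
normalization statistics, the training history and the evaluation /
filtering / reporting methods.  The flow mirrors the familiar
model-object / results-object split of statistical modelling packages:

>>> detector = MisassemblyDetector(matrices, labels, breakpoints)   # doctest: +SKIP
>>> res = detector.fit(seed=0)                                      # doctest: +SKIP
>>> print(res.summary())                                            # doctest: +SKIP
>>> preds = res.predict(matrices)                                   # doctest: +SKIP
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import (InferenceConfig, PredictionResult, chunk_contig,
                         evaluate_scores)
from .features import (FeatureCatalog, FeatureMatrix, FeatureStats,
                       apply_normalization, fit_normalization)
from .nn import ModelConfig, ResidualNet
from .store import FeatureStore
from .training import (TrainConfig, TrainingHistory, pad_batch, select_window,
                       train_network)

__all__ = ["MisassemblyDetector", "MisassemblyResults"]


def _as_matrices(data) -> dict[str, FeatureMatrix]:
    if isinstance(data, FeatureStore):
        return data.matrices()
    if isinstance(data, Mapping):
        return dict(data)
    return {m.contig_id: m for m in data}


class MisassemblyDetector:
    """Misassembly detection model over raw pileup feature matrices.

    Parameters
    ----------
    matrices : mapping contig_id -> FeatureMatrix (raw), or FeatureStore
    labels : mapping contig_id -> 0/1
        May be omitted when ``matrices`` is a store carrying labels.
    breakpoints : mapping contig_id -> breakpoint positions
    model_config, train_config : architecture and protocol settings
    """

    def __init__(
        self,
        matrices,
        labels: Mapping[str, int] | None = None,
        breakpoints: Mapping[str, Sequence[int]] | None = None,
        model_config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
    ):
        if isinstance(matrices, FeatureStore) and labels is None:
            labels = matrices.labels
            breakpoints = {cid: matrices.breakpoints(cid)
                           for cid in matrices.contig_ids}
        self.matrices = _as_matrices(matrices)
        if labels is None:
            raise ValueError("labels are required")
        self.contig_ids = list(self.matrices)
        self.labels = np.array([int(labels[c]) for c in self.contig_ids])
        self.breakpoints = {c: tuple((breakpoints or {}).get(c, ()))
                            for c in self.contig_ids}
        self.model_config = model_config
        self.train_config = train_config
        cat = next(iter(self.matrices.values())).catalog
        if len(cat.selected) != model_config.in_channels:
            raise ValueError(
                f"catalog selects {len(cat.selected)} channels but the "
                f"model expects {model_config.in_channels}")
        self.catalog = cat

    @classmethod
    def from_store(cls, store: FeatureStore, **kwargs) -> "MisassemblyDetector":
        return cls(store, **kwargs)

    def fit(self, seed: int | None = None,
            verbose: bool = False) -> "MisassemblyResults":
        """Train the network and return the best-validation-AUPRC results.

        Normalization statistics are fitted on the training contigs only
        (the validation split is carved out first) and stored with the
        results so later predictions use the same transform.
        """
        cfg = self.train_config
        if seed is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
        # Carve out the validation split deterministically (the same split
        # train_network will derive from the seed) to fit stats train-only.
        master = np.random.default_rng(cfg.seed)
        split_rng = np.random.default_rng(master.integers(2 ** 31))
        perm = split_rng.permutation(len(self.contig_ids))
        n_val = max(1, int(round(cfg.validation_frac * len(perm))))
        train_ids = [self.contig_ids[i] for i in perm[n_val:]]
        stats = fit_normalization((self.matrices[c] for c in train_ids),
                                  self.catalog)
        normalized = {
            c: apply_normalization(self.matrices[c], stats).select()
            for c in self.contig_ids}

        def windows_of(i: int, rng: np.random.Generator) -> np.ndarray:
            cid = self.contig_ids[i]
            arr = normalized[cid]
            s, e = select_window(arr.shape[0], int(self.labels[i]),
                                 self.breakpoints[cid], cfg.window_len, rng)
            return arr[s:e]

        net = ResidualNet(self.model_config,
                          seed=np.random.default_rng(cfg.seed + 1))
        history = train_network(net, windows_of, self.labels, cfg,
                                verbose=verbose)
        net.load_state_dict(history.best_state)
        return MisassemblyResults(self, net, stats, history, cfg)


class MisassemblyResults:
    """Fitted detector: selected network, stats, history, and evaluation."""

    def __init__(self, model: MisassemblyDetector | None, net: ResidualNet,
                 stats: FeatureStats, history: TrainingHistory | None,
                 train_config: TrainConfig | None,
                 catalog: FeatureCatalog | None = None):
        self.model = model
        self.net = net
        self.stats = stats
        self.history = history
        self.train_config = train_config
        self.catalog = catalog or (model.catalog if model else None)

    # -- reporting ----------------------------------------------------------

    @property
    def best_val_auprc(self) -> float:
        return self.history.best_val_auprc if self.history else float("nan")

    def summary(self) -> str:
        """Human-readable fit summary."""
        total, trainable = self.net.count_parameters()
        lines = [
            "Misassembly detector — fit summary",
            "=" * 44,
            f"{'Input channels':<28}{self.net.config.in_channels}",
            f"{'Residual blocks per group':<28}"
            f"{list(self.net.config.group_blocks)}",
            f"{'Filters per group':<28}{list(self.net.config.group_filters)}",
            f"{'Parameters (total)':<28}{total:,}",
            f"{'Parameters (trainable)':<28}{trainable:,}",
        ]
        if self.history is not None:
            n_pos = int(self.model.labels.sum()) if self.model else -1
            lines += [
                f"{'Contigs (train+val)':<28}"
                f"{len(self.model.labels) if self.model else 'n/a'}",
                f"{'Positives':<28}{n_pos}",
                f"{'Epochs run':<28}{len(self.history.table)}",
                f"{'Best epoch':<28}{self.history.best_epoch}",
                f"{'Best validation AUPRC':<28}"
                f"{self.history.best_val_auprc:.4f}",
                f"{'Checkpoints saved':<28}{self.history.n_checkpoints}",
            ]
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------------

    def _prepare(self, m: FeatureMatrix) -> np.ndarray:
        if not m.normalized:
            m = apply_normalization(m, self.stats)
        return m.select()

    def predict(
        self,
        data,
        config: InferenceConfig = InferenceConfig(),
    ) -> pd.DataFrame:
        """Score contigs (chunked, max-aggregated).

        ``data`` is a mapping of raw or normalized FeatureMatrix objects, a
        FeatureStore, or an iterable of matrices.  Returns a DataFrame with
        contig_id, length, n_chunks and score.
        """
        results = self.predict_detailed(data, config)
        return pd.DataFrame(
            [{"contig_id": r.contig_id,
              "length": r.chunks[-1][1],
              "n_chunks": len(r.chunks),
              "score": r.score} for r in results])

    def predict_detailed(
        self,
        data,
        config: InferenceConfig = InferenceConfig(),
    ) -> list[PredictionResult]:
        matrices = _as_matrices(data)
        min_len = self.net.config.min_input_length()
        jobs: list[tuple[str, tuple[int, int]]] = []
        arrays: list[np.ndarray] = []
        prepared = {cid: self._prepare(m) for cid, m in matrices.items()}
        chunk_lists = {}
        for cid, arr in prepared.items():
            chunks = chunk_contig(len(arr), config.window_len,
                                  config.chunk_overlap)
            chunk_lists[cid] = chunks
            for (s, e) in chunks:
                jobs.append((cid, (s, e)))
                arrays.append(arr[s:e])
        order = np.argsort([-a.shape[0] for a in arrays], kind="stable")
        scores = np.empty(len(arrays))
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            x, lens = pad_batch([arrays[j] for j in sel], min_len)
            scores[sel] = self.net.predict_proba(x, lens)
        per_contig: dict[str, list[float]] = {cid: [] for cid in prepared}
        for (cid, _), sc in zip(jobs, scores):
            per_contig[cid].append(sc)
        return [PredictionResult(cid, chunk_lists[cid],
                                 np.asarray(per_contig[cid]))
                for cid in prepared]

    def evaluate(self, data, labels: Mapping[str, int],
                 config: InferenceConfig = InferenceConfig()) -> dict:
        """Predict then compute AUPRC/AUROC against truth labels."""
        preds = self.predict(data, config)
        y = np.array([labels[c] for c in preds["contig_id"]])
        out = evaluate_scores(preds["score"].to_numpy(), y)
        out["predictions"] = preds
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights, config, catalog and stats."""
        extra = {
            "catalog": self.catalog.to_dict() if self.catalog else None,
            "stats": json.loads(self.stats.to_json()),
            "best_val_auprc": (None if self.history is None or
                               not np.isfinite(self.best_val_auprc)
                               else float(self.best_val_auprc)),
        }
        self.net.save(path, extra=extra)

    @classmethod
    def load(cls, path) -> "MisassemblyResults":
        net, meta = ResidualNet.load(path)
        stats = FeatureStats.from_json(json.dumps(meta["stats"]))
        catalog = (FeatureCatalog.from_dict(meta["catalog"])
                   if meta.get("catalog") else None)
        return cls(model=None, net=net, stats=stats, history=None,
                   train_config=None, catalog=catalog)
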