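"""Shared fixtures: small genomes/contigs and the desk-scale experiment."""

from __future__ import annotations

import numpy as np
import pytest

from contiguard import (MisassemblyDetector, compute_pileup, generate_genome,
                        simulate_dataset, subsample_to_coverage)
from contiguard.training import TrainConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def genome_pool():
    return [generate_genome(30_000, 0.5, seed=100 + i, id=f"g{i}",
                            taxon_tag=f"sp{i}") for i in range(8)]


def _pileup_dataset(ds, max_cov=20.0, seed=0):
    rng = np.random.default_rng(seed)
    mats, labels, bps = {}, {}, {}
    for sc in ds.contigs:
        sub = subsample_to_coverage(sc.alignments, len(sc.contig),
                                    max_cov, rng)
        mats[sc.contig.id] = compute_pileup(sc.contig, sub)
        labels[sc.contig.id] = sc.contig.label
        bps[sc.contig.id] = sc.contig.breakpoints
    return mats, labels, bps


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-contig dataset with features, for fast integration tests."""
    ds = simulate_dataset(n_contigs=120, seed=7)
    mats, labels, bps = _pileup_dataset(ds, seed=7)
    return {"ds": ds, "matrices": mats, "labels": labels,
            "breakpoints": bps}


@pytest.fixture(scope="session")
def desk_experiment():
    """The desk-scale end-to-end experiment: 2,000 contigs, 25%
    misassembled, mean coverage 10, ~0.5% sequencing error; training for a
    handful of epochs per seed, stopping once two seeds have beaten twice
    the baseline (random-score AUPRC equals prevalence).
    """
    runs = []
    successes = 0
    for seed in (11, 22, 33):
        ds = simulate_dataset(n_contigs=2000, misassembly_frac=0.25,
                              coverage=10.0, error_profile="HiSeq2500",
                              seed=seed)
        mats, labels, bps = _pileup_dataset(ds, seed=seed)
        cfg = TrainConfig(epochs=3, batch_size=64, lr=1e-3, eval_every=2,
                          validation_frac=0.10, seed=seed)
        det = MisassemblyDetector(mats, labels, bps, train_config=cfg)
        res = det.fit()
        ids = det.contig_ids
        val_idx = res.history.val_idx
        val_ids = [ids[i] for i in val_idx]
        val_prev = float(det.labels[val_idx].mean())
        success = (np.isfinite(res.best_val_auprc)
                   and res.best_val_auprc >= 2.0 * val_prev)
        runs.append({
            "seed": seed,
            "results": res,
            "matrices": mats,
            "labels": {c: labels[c] for c in ids},
            "val_ids": val_ids,
            "val_prevalence": val_prev,
            "val_auprc": res.best_val_auprc,
            "success": success,
        })
        # free the bulky read-level objects
        for sc in ds.contigs:
            sc.alignments = []
        successes += int(success)
        if successes >= 2:
            break
    return runs
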