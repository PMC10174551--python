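"""Per-position alignment features (pileup) and their preprocessing.

Given a contig and the reads aligned over it, this module computes the
per-position feature channels a misassembly detector consumes: coverage,
aligned-base composition, SNV counts, pairing counts (proper / orphan /
discordant), summary statistics of mapping quality, alignment score and
insert size over covering reads, and two sequence-context channels
(windowed entropy and GC).

Preprocessing follows the detector's contract: count channels are divided
by coverage (into [0, 1]); numeric channels are standardized with mean/sd
fitted on training data; positions with zero coverage are masked and set to
zero (the post-standardization mean) before entering the network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import AlignedRead, ContigRecord

__all__ = [
    "FeatureCatalog", "DEFAULT_CATALOG", "FeatureMatrix", "FeatureStats",
    "compute_pileup", "subsample_to_coverage", "fit_normalization",
    "apply_normalization", "insert_size_profile", "InsertSizeProfile",
    "TRAIN_INSERT_BOUNDS",
]

#: Closed interval of acceptable insert-size quantiles, as fitted on the
#: reference training corpus.
TRAIN_INSERT_BOUNDS = (117.0, 493.0)

COUNT = "count"
NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered channel names with kinds, plus the selected model subset."""

    channels: tuple[tuple[str, str], ...]
    selected: tuple[str, ...]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        missing = set(self.selected) - set(names)
        if missing:
            raise ValueError(f"selected channels not in catalog: {missing}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.channels)

    @property
    def kinds(self) -> dict[str, str]:
        return dict(self.channels)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def by_kind(self, kind: str) -> tuple[str, ...]:
        return tuple(n for n, k in self.channels if k == kind)

    def to_dict(self) -> dict:
        return {"channels": [list(c) for c in self.channels],
                "selected": list(self.selected)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureCatalog":
        return cls(tuple((n, k) for n, k in d["channels"]),
                   tuple(d["selected"]))


#: The full 23-channel catalog and the default 14-channel model input.
DEFAULT_CATALOG = FeatureCatalog(
    channels=(
        ("ref_base", CATEGORICAL),
        ("coverage", NUMERIC),
        ("num_query_A", COUNT),
        ("num_query_C", COUNT),
        ("num_query_G", COUNT),
        ("num_query_T", COUNT),
        ("num_SNPs", COUNT),
        ("num_discordant", COUNT),
        ("num_proper", COUNT),
        ("num_orphan", COUNT),
        ("num_proper_SNP", COUNT),
        ("min_mapq", NUMERIC),
        ("mean_mapq", NUMERIC),
        ("stdev_mapq", NUMERIC),
        ("min_al_score", NUMERIC),
        ("mean_al_score", NUMERIC),
        ("stdev_al_score", NUMERIC),
        ("min_insert_size", NUMERIC),
        ("mean_insert_size", NUMERIC),
        ("stdev_insert_size", NUMERIC),
        ("max_insert_size", NUMERIC),
        ("seq_window_entropy", NUMERIC),
        ("seq_window_gc", NUMERIC),
    ),
    selected=(
        "num_query_A", "num_query_C", "num_query_G", "num_query_T",
        "num_SNPs", "num_proper", "num_orphan", "num_proper_SNP",
        "mean_al_score", "min_al_score", "stdev_al_score",
        "mean_mapq", "coverage", "min_insert_size",
    ),
)


@dataclass
class FeatureMatrix:
    """positions x channels feature values for one contig.

    ``values`` is float32 of shape (length, n_channels) in catalog order.
    Numeric summary channels are NaN at positions with zero coverage (the
    missingness mask); normalization replaces them with zero.
    """

    contig_id: str
    values: np.ndarray
    catalog: FeatureCatalog
    normalized: bool = False
    missing_mask: np.ndarray | None = None   # True at covered positions

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or \
                self.values.shape[1] != len(self.catalog.channels):
            raise ValueError("values shape inconsistent with catalog")

    def __len__(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.catalog.index(name)]

    @property
    def coverage(self) -> np.ndarray:
        return self.channel("coverage")

    @property
    def mask(self) -> np.ndarray:
        """True at covered (non-missing) positions.

        On a normalized matrix the coverage column is standardized, so the
        mask recorded at normalization time is used instead.
        """
        if self.missing_mask is not None:
            return self.missing_mask
        if self.normalized:
            raise ValueError(
                "normalized matrix without a recorded missingness mask")
        return self.coverage > 0

    def select(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Extract the (length, len(names)) model-input block."""
        names = self.catalog.selected if names is None else names
        idx = [self.catalog.index(n) for n in names]
        return self.values[:, idx]


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def _window_stats(codes: np.ndarray, window: int = 50):
    """Sliding-window Shannon entropy (nats) and GC fraction, centered,
    truncated at the contig ends."""
    L = len(codes)
    onehot = np.zeros((L + 1, 4), dtype=np.float64)
    onehot[1:][np.arange(L), codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    half = window // 2
    lo = np.clip(np.arange(L) - half, 0, L)
    hi = np.clip(np.arange(L) + window - half, 0, L)
    counts = cum[hi] - cum[lo]
    tot = counts.sum(axis=1, keepdims=True)
    p = counts / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    gc = (counts[:, 1] + counts[:, 2]) / tot[:, 0]
    return ent, gc


def compute_pileup(
    contig: ContigRecord,
    alignments: Sequence[AlignedRead],
    catalog: FeatureCatalog = DEFAULT_CATALOG,
) -> FeatureMatrix:
    """Compute the raw per-position feature matrix for one contig.

    Interval-constant counts (coverage, pairing counts, running sums for the
    mean/stdev statistics) are accumulated with difference arrays and a
    cumulative sum, so cost is linear in reads plus contig length; the
    min/max statistics use per-read slice updates.
    """
    L = len(contig)
    n_reads = len(alignments)
    cov_d = np.zeros(L + 1)
    prop_d = np.zeros(L + 1)
    orph_d = np.zeros(L + 1)
    disc_d = np.zeros(L + 1)
    sum_d = {k: np.zeros(L + 1) for k in ("mapq", "al", "ins")}
    sumsq_d = {k: np.zeros(L + 1) for k in ("mapq", "al", "ins")}
    ins_cov_d = np.zeros(L + 1)
    min_mapq = np.full(L, np.inf)
    min_al = np.full(L, np.inf)
    min_ins = np.full(L, np.inf)
    max_ins = np.full(L, -np.inf)
    base_counts = np.zeros((4, L))
    snp = np.zeros(L)
    proper_snp = np.zeros(L)

    from ._seq import encode as _encode
    for a in alignments:
        s, e = a.pos, a.end
        if s < 0 or e > L:
            raise ValueError(
                f"alignment {a.qname!r}/{a.mate} out of contig bounds "
                f"[{s}, {e}) vs length {L}")
        cov_d[s] += 1
        cov_d[e] -= 1
        if a.is_proper:
            prop_d[s] += 1
            prop_d[e] -= 1
        if a.is_orphan:
            orph_d[s] += 1
            orph_d[e] -= 1
        if a.is_discordant:
            disc_d[s] += 1
            disc_d[e] -= 1
        for key, v in (("mapq", float(a.mapq)), ("al", float(a.al_score))):
            sum_d[key][s] += v
            sum_d[key][e] -= v
            sumsq_d[key][s] += v * v
            sumsq_d[key][e] -= v * v
        min_mapq[s:e] = np.minimum(min_mapq[s:e], a.mapq)
        min_al[s:e] = np.minimum(min_al[s:e], a.al_score)
        if a.is_proper:
            v = float(a.insert_size)
            sum_d["ins"][s] += v
            sum_d["ins"][e] -= v
            sumsq_d["ins"][s] += v * v
            sumsq_d["ins"][e] -= v * v
            ins_cov_d[s] += 1
            ins_cov_d[e] -= 1
            min_ins[s:e] = np.minimum(min_ins[s:e], v)
            max_ins[s:e] = np.maximum(max_ins[s:e], v)
        codes = _encode(a.seq)
        np.add.at(base_counts, (codes, np.arange(s, e)), 1)
        if a.mismatch_positions:
            mp = np.asarray(a.mismatch_positions, dtype=np.int64)
            np.add.at(snp, mp, 1)
            if a.is_proper:
                np.add.at(proper_snp, mp, 1)

    cov = np.cumsum(cov_d[:-1])
    n_prop = np.cumsum(prop_d[:-1])
    n_orph = np.cumsum(orph_d[:-1])
    n_disc = np.cumsum(disc_d[:-1])
    ins_cov = np.cumsum(ins_cov_d[:-1])

    def stats(key, denom):
        s = np.cumsum(sum_d[key][:-1])
        ss = np.cumsum(sumsq_d[key][:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(denom > 0, s / denom, np.nan)
            var = np.where(denom > 0, ss / denom - mean ** 2, np.nan)
        sd = np.sqrt(np.clip(var, 0.0, None))
        return mean, sd

    mean_mapq, sd_mapq = stats("mapq", cov)
    mean_al, sd_al = stats("al", cov)
    mean_ins, sd_ins = stats("ins", ins_cov)
    min_mapq[cov == 0] = np.nan
    min_al[cov == 0] = np.nan
    min_ins[ins_cov == 0] = np.nan
    max_ins[ins_cov == 0] = np.nan
    min_ins[np.isinf(min_ins)] = np.nan
    max_ins[np.isinf(max_ins)] = np.nan

    ent, gc = _window_stats(contig.codes)
    data = {
        "ref_base": contig.codes.astype(np.float64),
        "coverage": cov,
        "num_query_A": base_counts[0],
        "num_query_C": base_counts[1],
        "num_query_G": base_counts[2],
        "num_query_T": base_counts[3],
        "num_SNPs": snp,
        "num_discordant": n_disc,
        "num_proper": n_prop,
        "num_orphan": n_orph,
        "num_proper_SNP": proper_snp,
        "min_mapq": min_mapq,
        "mean_mapq": mean_mapq,
        "stdev_mapq": sd_mapq,
        "min_al_score": min_al,
        "mean_al_score": mean_al,
        "stdev_al_score": sd_al,
        "min_insert_size": min_ins,
        "mean_insert_size": mean_ins,
        "stdev_insert_size": sd_ins,
        "max_insert_size": max_ins,
        "seq_window_entropy": ent,
        "seq_window_gc": gc,
    }
    values = np.stack([data[n] for n in catalog.names], axis=1)
    return FeatureMatrix(contig_id=contig.id,
                         values=values.astype(np.float32), catalog=catalog)


# ---------------------------------------------------------------------------
# Coverage subsampling
# ---------------------------------------------------------------------------

def subsample_to_coverage(
    alignments: Sequence[AlignedRead],
    contig_length: int,
    max_mean_cov: float = 20.0,
    seed: int | np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Randomly drop whole read pairs until mean coverage <= ``max_mean_cov``.

    Mean coverage is total aligned bases divided by contig length.  Mates are
    kept or dropped together.  If the input is already at or below the
    target, it is returned unchanged.
    """
    total = sum(a.read_len for a in alignments)
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if total / contig_length <= max_mean_cov:
        return list(alignments)
    rng = np.random.default_rng(seed)
    pair_ids = sorted({a.pair_id for a in alignments})
    order = rng.permutation(len(pair_ids))
    bases = {pid: 0 for pid in pair_ids}
    for a in alignments:
        bases[a.pair_id] += a.read_len
    budget = max_mean_cov * contig_length
    keep: set[str] = set()
    used = 0.0
    for i in order:
        pid = pair_ids[i]
        if used + bases[pid] <= budget:
            keep.add(pid)
            used += bases[pid]
    return [a for a in alignments if a.pair_id in keep]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class FeatureStats:
    """Per-channel mean and standard deviation fitted on training data."""

    mean: dict[str, float]
    sd: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd}, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "FeatureStats":
        d = json.loads(s)
        return cls(mean=d["mean"], sd=d["sd"])


def fit_normalization(
    matrices: Iterable[FeatureMatrix],
    catalog: FeatureCatalog = DEFAULT_CATALOG,
) -> FeatureStats:
    """Fit standardization statistics over all covered positions.

    Only numeric channels are standardized; count channels are
    coverage-normalized instead and are not included here.  A channel with
    zero variance stores sd = 1 (with a warning) so that standardizing
    maps it to identically zero.
    """
    numeric = catalog.by_kind(NUMERIC)
    acc = {n: [] for n in numeric}
    for m in matrices:
        mask = m.mask
        if not mask.any():
            continue
        for n in numeric:
            v = m.channel(n)[mask]
            acc[n].append(v[np.isfinite(v)])
    mean, sd = {}, {}
    for n in numeric:
        if not acc[n] or sum(len(v) for v in acc[n]) == 0:
            raise ValueError(f"no covered positions to fit channel {n!r}")
        v = np.concatenate(acc[n]).astype(np.float64)
        mean[n] = float(v.mean())
        s = float(v.std())
        if s == 0.0:
            warnings.warn(f"channel {n!r} has zero variance; storing sd=1")
            s = 1.0
        sd[n] = s
    return FeatureStats(mean=mean, sd=sd)


def apply_normalization(
    matrix: FeatureMatrix,
    stats: FeatureStats,
    catalog: FeatureCatalog | None = None,
) -> FeatureMatrix:
    """Normalize a raw feature matrix for model input.

    Count channels are divided by coverage (values in [0, 1]); numeric
    channels are standardized with the fitted statistics; missing values and
    entire zero-coverage rows become 0 (the post-standardization mean).
    Categorical channels pass through unchanged.
    """
    catalog = catalog or matrix.catalog
    values = matrix.values.astype(np.float64).copy()
    cov = matrix.coverage.astype(np.float64)
    covered = cov > 0
    for j, (name, kind) in enumerate(catalog.channels):
        col = values[:, j]
        if kind == COUNT:
            with np.errstate(divide="ignore", invalid="ignore"):
                col = np.where(covered, col / cov, 0.0)
        elif kind == NUMERIC:
            if name not in stats.mean:
                raise KeyError(f"no fitted stats for numeric channel {name!r}")
            col = (col - stats.mean[name]) / stats.sd[name]
            col = np.where(np.isfinite(col), col, 0.0)
        values[:, j] = col
    values[~covered, :] = 0.0
    return FeatureMatrix(contig_id=matrix.contig_id,
                         values=values.astype(np.float32),
                         catalog=catalog, normalized=True,
                         missing_mask=covered.copy())


# ---------------------------------------------------------------------------
# Insert-size applicability profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertSizeProfile:
    """Quantiles of observed proper-pair insert sizes for one dataset."""

    q05: float
    q50: float
    q95: float
    n_pairs: int

    def passes(self, bounds: tuple[float, float] = TRAIN_INSERT_BOUNDS) -> bool:
        """Closed-interval check against the training insert-size bounds."""
        lo, hi = bounds
        return self.q05 >= lo and self.q95 <= hi


def insert_size_profile(
    alignments: Iterable[AlignedRead],
) -> InsertSizeProfile:
    """Summarize proper-pair insert sizes (each pair counted once)."""
    seen: dict[str, int] = {}
    for a in alignments:
        if a.is_proper and a.pair_id not in seen:
            seen[a.pair_id] = a.insert_size
    if not seen:
        raise ValueError("no proper pairs: insert-size profile undefined")
    ins = np.array(list(seen.values()), dtype=float)
    q05, q50, q95 = np.quantile(ins, [0.05, 0.5, 0.95])
    return InsertSizeProfile(q05=float(q05), q50=float(q50), q95=float(q95),
                             n_pairs=len(ins))
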