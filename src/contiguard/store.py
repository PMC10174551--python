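"""On-disk feature store.

One compressed ``.npz`` file holds the per-contig feature matrices together
with a JSON header describing the channel catalog, truth labels, breakpoint
positions and (optionally) fitted normalization statistics, so a store is
self-describing and supports random access by contig id and position window.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureCatalog, FeatureMatrix, FeatureStats

__all__ = ["FeatureStore"]


class FeatureStore:
    """Random-access container of per-contig feature matrices."""

    def __init__(self, npz, header: dict):
        self._npz = npz
        self._header = header
        self._index: dict[str, dict] = header["contigs"]
        self.catalog = FeatureCatalog.from_dict(header["catalog"])
        self.stats = (FeatureStats.from_json(json.dumps(header["stats"]))
                      if header.get("stats") else None)
        self.insert_profile: dict | None = header.get("insert_profile")

    # -- writing ------------------------------------------------------------

    @staticmethod
    def write(
        path,
        matrices: Mapping[str, FeatureMatrix] | Iterable[FeatureMatrix],
        labels: Mapping[str, int],
        breakpoints: Mapping[str, Sequence[int]] | None = None,
        stats: FeatureStats | None = None,
        insert_profile: dict | None = None,
    ) -> None:
        """Write matrices (all sharing one catalog) plus truth metadata."""
        if not isinstance(matrices, Mapping):
            matrices = {m.contig_id: m for m in matrices}
        if not matrices:
            raise ValueError("no matrices to write")
        catalog = next(iter(matrices.values())).catalog
        index = {}
        arrays = {}
        for i, (cid, m) in enumerate(matrices.items()):
            if m.catalog != catalog:
                raise ValueError("matrices use inconsistent catalogs")
            key = f"m{i}"
            arrays[key] = m.values
            index[cid] = {
                "key": key,
                "length": len(m),
                "label": int(labels[cid]),
                "breakpoints": list(map(int, (breakpoints or {}).get(cid, ()))),
                "normalized": bool(m.normalized),
            }
        header = {
            "format_version": 1,
            "catalog": catalog.to_dict(),
            "contigs": index,
            "stats": json.loads(stats.to_json()) if stats else None,
            "insert_profile": insert_profile,
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            **arrays)

    # -- reading ------------------------------------------------------------

    @classmethod
    def open(cls, path) -> "FeatureStore":
        npz = np.load(path)
        header = json.loads(bytes(npz["header"]).decode())
        return cls(npz, header)

    def close(self) -> None:
        self._npz.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @property
    def contig_ids(self) -> list[str]:
        return list(self._index)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._index

    def _entry(self, contig_id: str) -> dict:
        try:
            return self._index[contig_id]
        except KeyError:
            raise KeyError(f"contig {contig_id!r} not in store") from None

    def length(self, contig_id: str) -> int:
        return self._entry(contig_id)["length"]

    def label(self, contig_id: str) -> int:
        return self._entry(contig_id)["label"]

    def breakpoints(self, contig_id: str) -> tuple[int, ...]:
        return tuple(self._entry(contig_id)["breakpoints"])

    @property
    def labels(self) -> dict[str, int]:
        return {cid: e["label"] for cid, e in self._index.items()}

    def get(self, contig_id: str,
            window: tuple[int, int] | None = None) -> FeatureMatrix:
        """Load one contig's matrix, optionally restricted to a half-open
        position window."""
        e = self._entry(contig_id)
        values = self._npz[e["key"]]
        if window is not None:
            s, t = window
            if not 0 <= s < t <= e["length"]:
                raise ValueError(f"window [{s}, {t}) out of range "
                                 f"for length {e['length']}")
            values = values[s:t]
        return FeatureMatrix(contig_id=contig_id, values=values.copy(),
                             catalog=self.catalog,
                             normalized=e["normalized"])

    def matrices(self) -> dict[str, FeatureMatrix]:
        return {cid: self.get(cid) for cid in self._index}
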