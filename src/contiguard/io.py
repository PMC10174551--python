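"""Readers for the standard interchange formats (FASTA, SAM, labels TSV).

Parsing is delegated to pysam / Biopython; this module only adapts records
into the package's in-memory types.  Mismatch positions are reconstructed by
comparing each aligned read with the contig sequence (alignments written by
this package are substitution-only, all-match CIGARs).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pysam
from Bio import SeqIO

from ._seq import encode
from .simulate import AlignedRead

__all__ = ["read_fasta", "read_sam", "read_labels_tsv"]


def read_fasta(path) -> dict[str, str]:
    """Sequences by id, upper-cased."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_labels_tsv(path) -> tuple[dict[str, int], dict[str, tuple[int, ...]]]:
    """Read a truth-label table (contig_id, label, type, breakpoints)."""
    labels: dict[str, int] = {}
    breakpoints: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cid = parts[col["contig_id"]]
            labels[cid] = int(parts[col["label"]])
            bp_field = parts[col["breakpoints"]] if "breakpoints" in col else ""
            breakpoints[cid] = tuple(
                int(b) for b in bp_field.split(",") if b.strip())
    return labels, breakpoints


def read_sam(path, contigs: Mapping[str, str]
             ) -> dict[str, list[AlignedRead]]:
    """Load a SAM/BAM file into per-contig alignment lists.

    Pairing flags are taken from the SAM flags; the alignment score comes
    from the ``AS`` tag when present, else from ``-6 * NM``, else from the
    recomputed mismatch count.
    """
    codes = {cid: encode(seq) for cid, seq in contigs.items()}
    out: dict[str, list[AlignedRead]] = {cid: [] for cid in contigs}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name not in codes:
                continue
            cid = rec.reference_name
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"record {rec.query_name!r} lacks a sequence")
            pos = rec.reference_start
            ref = codes[cid][pos:pos + len(seq)]
            if len(ref) != len(seq):
                raise ValueError(
                    f"record {rec.query_name!r} extends past contig {cid!r}")
            mism = tuple(int(i) + pos
                         for i in np.flatnonzero(encode(seq) != ref))
            if rec.has_tag("AS"):
                al = int(rec.get_tag("AS"))
            elif rec.has_tag("NM"):
                al = -6 * int(rec.get_tag("NM"))
            else:
                al = -6 * len(mism)
            both = rec.is_paired and not rec.mate_is_unmapped
            out[cid].append(AlignedRead(
                qname=rec.query_name,
                pair_id=rec.query_name,
                mate=2 if rec.is_read2 else 1,
                pos=pos,
                strand="-" if rec.is_reverse else "+",
                seq=seq,
                mapq=rec.mapping_quality,
                al_score=al,
                mismatch_positions=mism,
                is_proper=rec.is_proper_pair,
                is_orphan=rec.is_paired and rec.mate_is_unmapped,
                is_discordant=both and not rec.is_proper_pair,
                tlen=rec.template_length,
                mate_pos=rec.next_reference_start if both else -1,
            ))
    return out
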