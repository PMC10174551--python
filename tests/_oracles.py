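"""Independent reference implementations used as test oracles.

These deliberately use naive nested loops and direct definitions so they
share no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_pileup(contig_seq: str, alignments) -> dict[str, np.ndarray]:
    """Per-position features by looping over positions and reads."""
    L = len(contig_seq)
    out = {k: np.zeros(L) for k in (
        "coverage", "num_query_A", "num_query_C", "num_query_G",
        "num_query_T", "num_SNPs", "num_discordant", "num_proper",
        "num_orphan", "num_proper_SNP")}
    stats = {k: np.full(L, np.nan) for k in (
        "min_mapq", "mean_mapq", "stdev_mapq", "min_al_score",
        "mean_al_score", "stdev_al_score", "min_insert_size",
        "mean_insert_size", "stdev_insert_size", "max_insert_size")}
    for p in range(L):
        mapqs, als, inss = [], [], []
        for a in alignments:
            if not (a.pos <= p < a.pos + len(a.seq)):
                continue
            out["coverage"][p] += 1
            base = a.seq[p - a.pos]
            out[f"num_query_{base}"][p] += 1
            if p in a.mismatch_positions:
                out["num_SNPs"][p] += 1
                if a.is_proper:
                    out["num_proper_SNP"][p] += 1
            if a.is_proper:
                out["num_proper"][p] += 1
                inss.append(abs(a.tlen))
            if a.is_orphan:
                out["num_orphan"][p] += 1
            if a.is_discordant:
                out["num_discordant"][p] += 1
            mapqs.append(a.mapq)
            als.append(a.al_score)
        if mapqs:
            stats["min_mapq"][p] = min(mapqs)
            stats["mean_mapq"][p] = np.mean(mapqs)
            stats["stdev_mapq"][p] = np.std(mapqs)
            stats["min_al_score"][p] = min(als)
            stats["mean_al_score"][p] = np.mean(als)
            stats["stdev_al_score"][p] = np.std(als)
        if inss:
            stats["min_insert_size"][p] = min(inss)
            stats["mean_insert_size"][p] = np.mean(inss)
            stats["stdev_insert_size"][p] = np.std(inss)
            stats["max_insert_size"][p] = max(inss)
    out.update(stats)
    return out


def average_precision_by_enumeration(labels, scores) -> float:
    """AP = sum over ranked thresholds of (recall step) * precision."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        flagged = scores >= t
        tp = int((labels[flagged] == 1).sum())
        precision = tp / flagged.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def n50_bruteforce(lengths) -> int:
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= total / 2:
            return l
    raise AssertionError("unreachable")


def random_alignments(contig_seq: str, n_reads: int, rng,
                      read_len_range=(20, 120)):
    """Random but internally consistent AlignedRead records for a contig.

    Reads are substrings of the contig with injected substitutions;
    mismatch positions are recomputed by direct comparison, so the records
    are honest inputs for any pileup implementation.
    """
    from contiguard.simulate import AlignedRead

    L = len(contig_seq)
    bases = "ACGT"
    out = []
    for i in range(n_reads):
        rl = int(rng.integers(read_len_range[0],
                              min(read_len_range[1], L) + 1))
        pos = int(rng.integers(0, L - rl + 1))
        seq = list(contig_seq[pos:pos + rl])
        for j in range(rl):
            if rng.random() < 0.05:
                seq[j] = bases[int(rng.integers(4))]
        seq = "".join(seq)
        mism = tuple(pos + j for j in range(rl)
                     if seq[j] != contig_seq[pos + j])
        kind = rng.random()
        proper = kind < 0.6
        orphan = 0.6 <= kind < 0.8
        discordant = kind >= 0.8
        tlen = int(rng.integers(100, 600)) if proper else 0
        out.append(AlignedRead(
            qname=f"r{i}", pair_id=f"r{i}", mate=1, pos=pos,
            strand="+" if rng.random() < 0.5 else "-", seq=seq,
            mapq=int(rng.integers(0, 43)),
            al_score=-6 * len(mism),
            mismatch_positions=mism,
            is_proper=proper, is_orphan=orphan, is_discordant=discordant,
            tlen=tlen, mate_pos=-1))
    return out
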