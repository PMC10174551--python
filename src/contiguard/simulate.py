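"""Desk-scale synthetic metagenome data with known misassemblies.

This module emulates, in-process, the statistical structure of the external
simulation chain used to train misassembly detectors (community sampling,
Illumina-style paired-end read simulation, chimeric-contig construction and
truth-based read alignment).  Every contig carries its ground-truth label and
breakpoint positions, so downstream feature extraction, model training and
evaluation are testable end to end without external tools or downloads.

Conventions
-----------
* Coordinates are 0-based, half-open everywhere; the SAM writer converts to
  1-based at the boundary.
* All randomness flows through ``numpy.random.Generator`` objects; a fixed
  seed reproduces every dataset bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import decode, encode, revcomp_codes

__all__ = [
    "SimGrid", "SimParams", "GridRestriction", "TABLE1_GRID",
    "TABLE1_RESTRICTIONS", "NOVEL_GRID", "enumerate_grid",
    "grid_to_yaml", "grid_from_yaml",
    "CommunityProfile", "sample_community",
    "ReferenceGenome", "generate_genome", "mutate_strain",
    "ContigRecord", "inject_misassembly", "derive_breakpoints",
    "ErrorProfile", "ERROR_PROFILES", "get_error_profile",
    "ReadPairTruth", "simulate_read_pairs", "simulate_contig_reads",
    "PairingRules", "AlignedRead", "truth_align",
    "SimulatedContig", "SimulatedDataset", "simulate_dataset",
    "write_fasta", "write_fastq_pairs", "write_sam", "write_labels_tsv",
]

MISASSEMBLY_TYPES = (
    "none", "relocation", "inversion", "translocation",
    "interspecies_translocation",
)


# ---------------------------------------------------------------------------
# Simulation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """One cell of the simulation parameter grid."""

    richness: int
    sigma: float
    replicate: int
    read_len: int
    insert_mean: float
    insert_sd: float
    error_profile: str
    depth: int
    assembler: str


@dataclass(frozen=True)
class SimGrid:
    """Axes of the full simulation grid.

    ``insert_specs`` holds (mean, sd) pairs in bp.  ``replicate_count``
    replicates differ only by the genome-subsampling seed.
    """

    richness_values: tuple[int, ...]
    sigma_values: tuple[float, ...]
    replicate_count: int
    read_lengths: tuple[int, ...]
    insert_specs: tuple[tuple[float, float], ...]
    error_profiles: tuple[str, ...]
    depths: tuple[int, ...]
    assemblers: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("richness_values", "sigma_values", "read_lengths",
                     "insert_specs", "error_profiles", "depths", "assemblers"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid axis {name!r} is empty")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if any(d <= 0 for d in self.depths):
            raise ValueError("sequencing depths must be positive")
        if any(m <= 0 or s <= 0 for m, s in self.insert_specs):
            raise ValueError("insert mean and sd must be positive")


@dataclass(frozen=True)
class GridRestriction:
    """Restrict one insert-size distribution to a subset of the grid.

    For the given ``insert_spec``, only the listed error profiles are
    enumerated, each with its own number of replicates (``None`` means all
    replicates of the grid).
    """

    insert_spec: tuple[float, float]
    profile_replicates: Mapping[str, int | None]


#: The published simulation grid: 4 richness x 3 sigma x 3 replicates x
#: 2 read lengths x 4 insert-size distributions x 2 error profiles x
#: 5 sequencing depths x 2 assemblers, with per-insert restrictions.
TABLE1_GRID = SimGrid(
    richness_values=(50, 1000, 3000, 5000),
    sigma_values=(0.5, 1.0, 2.0),
    replicate_count=3,
    read_lengths=(100, 150),
    insert_specs=((190.0, 75.0), (270.0, 50.0), (350.0, 75.0), (450.0, 120.0)),
    error_profiles=("HiSeq2500", "HiSeq2500-L150"),
    depths=(500_000, 2_000_000, 8_000_000, 12_000_000, 20_000_000),
    assemblers=("megahit", "metaspades"),
)

#: Restrictions attached to the published grid: the 350&75 insert keeps 3
#: replicates for the L150 profile and 1 for the default profile; the 450&120
#: insert keeps only the L150 profile (all replicates).
TABLE1_RESTRICTIONS = (
    GridRestriction((350.0, 75.0),
                    {"HiSeq2500-L150": None, "HiSeq2500": 1}),
    GridRestriction((450.0, 120.0), {"HiSeq2500-L150": None}),
)

#: The held-out test grid: one replicate, one profile, one insert size.
NOVEL_GRID = SimGrid(
    richness_values=(50, 1000, 3000, 5000),
    sigma_values=(0.5, 1.0, 2.0),
    replicate_count=1,
    read_lengths=(100, 150),
    insert_specs=((270.0, 50.0),),
    error_profiles=("HiSeq2500",),
    depths=(500_000, 2_000_000, 8_000_000, 12_000_000, 20_000_000),
    assemblers=("megahit", "metaspades"),
)


def grid_to_yaml(grid: SimGrid, path, seed: int | None = None) -> None:
    """Serialize a grid (plus an optional top-level seed) as YAML."""
    import yaml
    doc = {
        "richness_values": list(grid.richness_values),
        "sigma_values": list(grid.sigma_values),
        "replicate_count": grid.replicate_count,
        "read_lengths": list(grid.read_lengths),
        "insert_specs": [list(s) for s in grid.insert_specs],
        "error_profiles": list(grid.error_profiles),
        "depths": list(grid.depths),
        "assemblers": list(grid.assemblers),
    }
    if seed is not None:
        doc["seed"] = seed
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def grid_from_yaml(path) -> tuple[SimGrid, int | None]:
    """Load a grid and its optional seed from a YAML document."""
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    seed = doc.pop("seed", None)
    grid = SimGrid(
        richness_values=tuple(doc["richness_values"]),
        sigma_values=tuple(doc["sigma_values"]),
        replicate_count=int(doc["replicate_count"]),
        read_lengths=tuple(doc["read_lengths"]),
        insert_specs=tuple(tuple(s) for s in doc["insert_specs"]),
        error_profiles=tuple(doc["error_profiles"]),
        depths=tuple(doc["depths"]),
        assemblers=tuple(doc["assemblers"]),
    )
    return grid, seed


def enumerate_grid(
    grid: SimGrid,
    restrictions: Sequence[GridRestriction] | None = None,
) -> list[SimParams]:
    """Enumerate all parameter combinations of a grid, in deterministic order.

    The Cartesian product of all axes is taken; for insert sizes named in
    ``restrictions`` only the allowed (profile, replicate) combinations are
    kept.  Replicate indices are 0-based.
    """
    restr = {r.insert_spec: r.profile_replicates for r in (restrictions or ())}
    out: list[SimParams] = []
    for rich, sig, ins, prof, rep, rl, dep, asm in itertools.product(
            grid.richness_values, grid.sigma_values, grid.insert_specs,
            grid.error_profiles, range(grid.replicate_count),
            grid.read_lengths, grid.depths, grid.assemblers):
        if ins in restr:
            allowed = restr[ins]
            if prof not in allowed:
                continue
            n_rep = allowed[prof]
            if n_rep is not None and rep >= n_rep:
                continue
        out.append(SimParams(rich, sig, rep, rl, ins[0], ins[1],
                             prof, dep, asm))
    return out


# ---------------------------------------------------------------------------
# Community abundances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityProfile:
    """Relative genome abundances of one simulated community.

    Abundances are proportional to draws from ``Lognormal(mu, sigma)`` and
    normalized to sum to one; ``sigma`` tunes community evenness (larger
    sigma, less even).  Only relative abundances matter downstream, so ``mu``
    (default 10) shifts nothing after normalization.
    """

    genome_ids: tuple[str, ...]
    rel_abundances: tuple[float, ...]
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if len(self.genome_ids) != len(self.rel_abundances):
            raise ValueError("genome_ids and rel_abundances length mismatch")
        if abs(sum(self.rel_abundances) - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1")
        if any(a <= 0 for a in self.rel_abundances):
            raise ValueError("relative abundances must be positive")


def sample_community(
    pool: Sequence["ReferenceGenome"],
    richness: int,
    sigma: float,
    mu: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> CommunityProfile:
    """Draw a community of ``richness`` genomes with lognormal abundances."""
    if richness > len(pool):
        raise ValueError(
            f"richness {richness} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=richness, replace=False)
    draws = rng.lognormal(mean=mu, sigma=sigma, size=richness)
    abund = draws / draws.sum()
    return CommunityProfile(
        genome_ids=tuple(pool[i].id for i in idx),
        rel_abundances=tuple(float(a) for a in abund),
        mu=mu, sigma=sigma,
    )


# ---------------------------------------------------------------------------
# Reference genomes
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """A single-replicon reference genome.

    Parameters
    ----------
    id : str
    sequence : str
        A/C/G/T only.
    taxon_tag : str
        Species/family label used for novelty splits and to distinguish
        intra- from inter-species translocations.
    repeat_intervals : sequence of (start, end)
        Regions the simulator treats as repeated; reads drawn from them get
        the low mapping-quality surrogate.
    """

    def __init__(self, id: str, sequence: str, taxon_tag: str = "",
                 repeat_intervals: Sequence[tuple[int, int]] = ()):
        self.id = id
        self.sequence = sequence
        self.taxon_tag = taxon_tag
        self.repeat_intervals = tuple(repeat_intervals)
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.sequence)
        return self._codes

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ReferenceGenome(id={self.id!r}, len={len(self)}, "
                f"taxon_tag={self.taxon_tag!r})")


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int | np.random.Generator | None = None,
    id: str = "genome",
    taxon_tag: str = "",
) -> ReferenceGenome:
    """Generate an i.i.d. random genome at the requested GC fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at]).astype(np.uint8)
    return ReferenceGenome(id=id, sequence=decode(codes), taxon_tag=taxon_tag)


def mutate_strain(
    genome: ReferenceGenome,
    substitution_rate: float,
    seed: int | np.random.Generator | None = None,
    id: str | None = None,
) -> ReferenceGenome:
    """Derive a strain by i.i.d. substitutions (no indels).

    Each position mutates with probability ``substitution_rate``, uniformly
    to one of the three other bases.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    codes = genome.codes.copy()
    if substitution_rate > 0.0:
        hit = rng.random(len(codes)) < substitution_rate
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return ReferenceGenome(
        id=id or f"{genome.id}_strain",
        sequence=decode(codes),
        taxon_tag=genome.taxon_tag,
        repeat_intervals=genome.repeat_intervals,
    )


# ---------------------------------------------------------------------------
# Contigs and misassemblies
# ---------------------------------------------------------------------------

def derive_breakpoints(sources: Sequence[tuple[str, int, int, str]]) -> tuple[int, ...]:
    """Breakpoints are the internal junctions between source segments."""
    bps = []
    off = 0
    for gid, s, e, strand in sources[:-1]:
        off += e - s
        bps.append(off)
    return tuple(bps)


@dataclass(frozen=True)
class ContigRecord:
    """A contig with ground-truth assembly provenance.

    ``sources`` lists (genome_id, start, end, strand) segments that tile the
    contig exactly, in contig order; ``strand == '-'`` means the contig holds
    the reverse complement of that genome slice.  ``label`` is 1 iff the
    contig is misassembled, equivalently iff it has at least one breakpoint.
    """

    id: str
    sequence: str
    label: int
    misassembly_type: str
    breakpoints: tuple[int, ...]
    sources: tuple[tuple[str, int, int, str], ...]

    def __post_init__(self) -> None:
        if self.misassembly_type not in MISASSEMBLY_TYPES:
            raise ValueError(f"unknown misassembly type {self.misassembly_type!r}")
        seg_len = sum(e - s for _, s, e, _ in self.sources)
        if seg_len != len(self.sequence):
            raise ValueError("source segments do not tile the contig")
        if self.breakpoints != derive_breakpoints(self.sources):
            raise ValueError("breakpoints inconsistent with source junctions")
        if self.label != (1 if self.breakpoints else 0):
            raise ValueError("label must be 1 iff breakpoints are present")
        if any(not 0 < b < len(self.sequence) for b in self.breakpoints):
            raise ValueError("breakpoints must lie strictly inside the contig")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)


def _segment(genome: ReferenceGenome, start: int, end: int,
             strand: str = "+") -> np.ndarray:
    if not (0 <= start < end <= len(genome)):
        raise ValueError(
            f"segment [{start}, {end}) out of range for genome "
            f"{genome.id!r} of length {len(genome)}")
    codes = genome.codes[start:end]
    return revcomp_codes(codes) if strand == "-" else codes


def inject_misassembly(
    genomes: Sequence[ReferenceGenome],
    mis_type: str,
    geometry,
    contig_id: str = "contig",
) -> ContigRecord:
    """Build a contig of a given misassembly class with known breakpoints.

    Geometry by type (all coordinates 0-based half-open, on the genome):

    ``none``
        ``(start, end)`` — a contiguous substring of ``genomes[0]``; label 0.
    ``inversion``
        ``(start, inv_start, inv_end, end)`` — the contig covers
        ``[start, end)`` of ``genomes[0]`` with ``[inv_start, inv_end)``
        reverse-complemented; breakpoints at the two junctions.
    ``relocation``
        ``((s1, e1), (s2, e2))`` — two non-adjacent segments of
        ``genomes[0]`` joined; one breakpoint.
    ``translocation`` / ``interspecies_translocation``
        ``((s1, e1), (s2, e2))`` — segment 1 of ``genomes[0]`` joined to
        segment 2 of ``genomes[1]``; the interspecies variant requires the
        two genomes to carry different taxon tags.
    """
    if mis_type == "none":
        g = genomes[0]
        s, e = geometry
        seq = _segment(g, s, e)
        sources = ((g.id, s, e, "+"),)
    elif mis_type == "inversion":
        g = genomes[0]
        s, i0, i1, e = geometry
        if not s <= i0 < i1 <= e:
            raise ValueError("inversion geometry must satisfy s <= i0 < i1 <= e")
        parts, sources = [], []
        if i0 > s:
            parts.append(_segment(g, s, i0))
            sources.append((g.id, s, i0, "+"))
        parts.append(_segment(g, i0, i1, "-"))
        sources.append((g.id, i0, i1, "-"))
        if e > i1:
            parts.append(_segment(g, i1, e))
            sources.append((g.id, i1, e, "+"))
        seq = np.concatenate(parts)
        sources = tuple(sources)
    elif mis_type == "relocation":
        g = genomes[0]
        (s1, e1), (s2, e2) = geometry
        if e1 == s2:
            raise ValueError("relocation segments must be non-adjacent")
        seq = np.concatenate([_segment(g, s1, e1), _segment(g, s2, e2)])
        sources = ((g.id, s1, e1, "+"), (g.id, s2, e2, "+"))
    elif mis_type in ("translocation", "interspecies_translocation"):
        if len(genomes) < 2:
            raise ValueError(f"{mis_type} requires two genomes")
        g1, g2 = genomes[0], genomes[1]
        if mis_type == "interspecies_translocation" and \
                g1.taxon_tag == g2.taxon_tag:
            raise ValueError(
                "interspecies translocation requires genomes with "
                "different taxon tags")
        (s1, e1), (s2, e2) = geometry
        seq = np.concatenate([_segment(g1, s1, e1), _segment(g2, s2, e2)])
        sources = ((g1.id, s1, e1, "+"), (g2.id, s2, e2, "+"))
    else:
        raise ValueError(f"unknown misassembly type {mis_type!r}")

    bps = derive_breakpoints(sources)
    return ContigRecord(
        id=contig_id, sequence=decode(seq), label=1 if bps else 0,
        misassembly_type=mis_type, breakpoints=bps, sources=sources,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorProfile:
    """Substitution-only sequencing error model.

    The per-base substitution rate rises linearly from ``rate_start`` at the
    first cycle to ``rate_end`` at the last, mimicking the quality decay of
    Illumina chemistry.  Mean rate = (rate_start + rate_end) / 2.
    """

    name: str
    rate_start: float
    rate_end: float

    def rates(self, read_len: int) -> np.ndarray:
        if read_len == 1:
            return np.array([self.rate_start])
        t = np.arange(read_len) / (read_len - 1)
        return self.rate_start + (self.rate_end - self.rate_start) * t


ERROR_PROFILES = {
    # Mean rate 0.5%: typical Illumina short-read substitution load.
    "HiSeq2500": ErrorProfile("HiSeq2500", 0.002, 0.008),
    # The longer-read profile is slightly cleaner early and noisier late.
    "HiSeq2500-L150": ErrorProfile("HiSeq2500-L150", 0.001, 0.009),
    "zero": ErrorProfile("zero", 0.0, 0.0),
}


def get_error_profile(profile: str | ErrorProfile) -> ErrorProfile:
    if isinstance(profile, ErrorProfile):
        return profile
    try:
        return ERROR_PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown error profile {profile!r}; known: "
            f"{sorted(ERROR_PROFILES)}") from None


@dataclass
class ReadPairTruth:
    """A simulated read pair with its true placement.

    ``frag_start``/``frag_end`` delimit the sequenced fragment on the source
    genome (0-based, half-open).  Mate 1 reads the fragment start on the
    forward strand; mate 2 reads the fragment end reverse-complemented.
    ``seq1``/``seq2`` are the sequences as the sequencer reports them (mate 2
    already reverse-complemented), errors included; ``err_pos1``/``err_pos2``
    give the injected error positions in read coordinates.
    """

    pair_id: str
    genome_id: str
    frag_start: int
    frag_end: int
    read_len: int
    seq1: str
    seq2: str
    err_pos1: tuple[int, ...]
    err_pos2: tuple[int, ...]

    @property
    def mate1_interval(self) -> tuple[int, int]:
        return self.frag_start, self.frag_start + self.read_len

    @property
    def mate2_interval(self) -> tuple[int, int]:
        return self.frag_end - self.read_len, self.frag_end


def _draw_fragments(rng, n, glen, read_len, insert_mean, insert_sd):
    """Fragment lengths ~ Normal(mean, sd), resampled until within
    [read_len, glen]; starts uniform on the feasible range."""
    frag = np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(np.int64)
    bad = (frag < read_len) | (frag > glen)
    while bad.any():
        frag[bad] = np.rint(
            rng.normal(insert_mean, insert_sd, size=int(bad.sum()))
        ).astype(np.int64)
        bad = (frag < read_len) | (frag > glen)
    starts = rng.integers(0, glen - frag + 1)
    return starts, starts + frag


def _reads_from_genome(rng, genome, n_pairs, read_len, insert_mean, insert_sd,
                       profile, pair_prefix, lo=0, hi=None):
    """Vectorized pair simulation from genome window [lo, hi)."""
    hi = len(genome) if hi is None else hi
    window = hi - lo
    if read_len > window:
        raise ValueError(
            f"read length {read_len} exceeds genome window {window}")
    starts, ends = _draw_fragments(rng, n_pairs, window, read_len,
                                   insert_mean, insert_sd)
    starts = starts + lo
    ends = ends + lo
    codes = genome.codes
    k = np.arange(read_len)
    m1 = codes[starts[:, None] + k]
    m2 = 3 - codes[ends[:, None] - 1 - k]          # reverse complement
    rates = profile.rates(read_len)
    pairs = []
    for mates in (m1, m2):
        hit = rng.random(mates.shape) < rates
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        mates[hit] = (mates[hit] + shift) % 4
        pairs.append(hit)
    hit1, hit2 = pairs
    out = []
    for i in range(n_pairs):
        out.append(ReadPairTruth(
            pair_id=f"{pair_prefix}{i}",
            genome_id=genome.id,
            frag_start=int(starts[i]),
            frag_end=int(ends[i]),
            read_len=read_len,
            seq1=decode(m1[i].astype(np.uint8)),
            seq2=decode(m2[i].astype(np.uint8)),
            err_pos1=tuple(np.flatnonzero(hit1[i]).tolist()),
            err_pos2=tuple(np.flatnonzero(hit2[i]).tolist()),
        ))
    return out


def simulate_read_pairs(
    community: CommunityProfile,
    genomes: Mapping[str, ReferenceGenome],
    depth: int,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_profile: str | ErrorProfile = "HiSeq2500",
    seed: int | np.random.Generator | None = None,
) -> list[ReadPairTruth]:
    """Simulate ``depth`` read pairs from a community.

    Pairs are allocated to genomes by a multinomial weighted by relative
    abundance times genome length (longer genomes emit more fragments at the
    same molar abundance), then drawn with uniformly placed fragments of
    Normal(insert_mean, insert_sd) length truncated to [read_len, genome
    length].
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    profile = get_error_profile(error_profile)
    gids = list(community.genome_ids)
    w = np.array([a * len(genomes[g]) for g, a in
                  zip(gids, community.rel_abundances)], dtype=float)
    counts = rng.multinomial(depth, w / w.sum())
    out: list[ReadPairTruth] = []
    for gid, n in zip(gids, counts):
        if n == 0:
            continue
        out.extend(_reads_from_genome(
            rng, genomes[gid], int(n), read_len, insert_mean, insert_sd,
            profile, pair_prefix=f"{gid}:"))
    return out


def simulate_contig_reads(
    contig: ContigRecord,
    genomes: Mapping[str, ReferenceGenome],
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_profile: str | ErrorProfile = "HiSeq2500",
    seed: int | np.random.Generator | None = None,
) -> list[ReadPairTruth]:
    """Simulate reads covering one contig at a target mean coverage.

    Fragments are drawn from each source-genome region underlying the contig,
    extended by one insert length on both sides, so that reads and pairs
    naturally straddle segment boundaries — exactly the signal (mismatch
    tails, orphans, discordant pairs) that real misassembly junctions leave
    in alignments.
    """
    rng = np.random.default_rng(seed)
    profile = get_error_profile(error_profile)
    pad = int(insert_mean + 3 * insert_sd)
    out: list[ReadPairTruth] = []
    for si, (gid, s, e, strand) in enumerate(contig.sources):
        g = genomes[gid]
        lo, hi = max(0, s - pad), min(len(g), e + pad)
        # Pairs so that reads whose fragments fall in [lo, hi) give the
        # requested mean coverage over [s, e).
        n = int(round(coverage * (hi - lo) / (2 * read_len)))
        if n == 0:
            continue
        out.extend(_reads_from_genome(
            rng, g, n, read_len, insert_mean, insert_sd, profile,
            pair_prefix=f"{contig.id}:s{si}:", lo=lo, hi=hi))
    return out


# ---------------------------------------------------------------------------
# Truth-based alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingRules:
    """Pairing semantics of the alignment surrogate.

    A pair is *proper* iff both mates map to the contig in FR orientation
    with an observed insert inside ``insert_mean ± 3 insert_sd`` (an
    approximation of a real aligner's -I/-X window).  ``mapq_unique`` /
    ``mapq_repeat`` are the mapping-quality surrogates; the alignment score
    is 0 minus ``mismatch_penalty`` per mismatch.
    """

    insert_mean: float
    insert_sd: float
    mapq_unique: int = 42
    mapq_repeat: int = 1
    mismatch_penalty: int = 6

    @property
    def insert_window(self) -> tuple[float, float]:
        return (self.insert_mean - 3 * self.insert_sd,
                self.insert_mean + 3 * self.insert_sd)


@dataclass
class AlignedRead:
    """One mapped mate in SAM-like terms (0-based positions internally)."""

    qname: str
    pair_id: str
    mate: int                   # 1 or 2
    pos: int                    # leftmost contig position
    strand: str                 # '+' or '-' on the contig
    seq: str                    # contig-forward orientation
    mapq: int
    al_score: int
    mismatch_positions: tuple[int, ...]   # contig coordinates
    is_proper: bool
    is_orphan: bool
    is_discordant: bool
    tlen: int                   # signed template length; 0 if not proper-ish
    mate_pos: int               # mate leftmost position, -1 if unmapped

    @property
    def read_len(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)

    @property
    def insert_size(self) -> int:
        return abs(self.tlen)

    @property
    def cigar(self) -> str:
        return f"{len(self.seq)}M"

    @property
    def flag(self) -> int:
        f = 0x1  # paired in sequencing
        if self.is_proper:
            f |= 0x2
        if self.is_orphan:
            f |= 0x8          # mate unmapped
        if self.strand == "-":
            f |= 0x10
        f |= 0x40 if self.mate == 1 else 0x80
        return f


def _project_mate(contig, seg_table, interval, genome_strand):
    """Project a mate's true genome interval onto the contig.

    Returns (contig_start, contig_strand) or None.  The mate anchors to the
    source segment holding the largest share of its bases, provided the
    projected interval lies fully inside the contig.
    """
    p0, p1 = interval
    best = None
    best_ov = 0
    off = 0
    for gid_seg, s, e, seg_strand in seg_table:
        ov = min(p1, e) - max(p0, s)
        if gid_seg is not None and ov > best_ov:
            best_ov = ov
            best = (s, e, seg_strand, off)
        off += e - s
    if best is None or best_ov * 2 < (p1 - p0):
        return None
    s, e, seg_strand, off = best
    if seg_strand == "+":
        cstart = off + (p0 - s)
        cstrand = genome_strand
    else:
        cstart = off + (e - p1)
        cstrand = "-" if genome_strand == "+" else "+"
    if cstart < 0 or cstart + (p1 - p0) > len(contig.sequence):
        return None
    return cstart, cstrand


def truth_align(
    pairs: Iterable[ReadPairTruth],
    contig: ContigRecord,
    rules: PairingRules,
    genomes: Mapping[str, ReferenceGenome] | None = None,
) -> list[AlignedRead]:
    """Align simulated reads to a contig from their known true placements.

    Each mate whose majority segment lies on the contig is emitted as one
    all-match record; its mismatch set is the base-by-base difference between
    the (possibly reverse-complemented) read and the contig, so sequencing
    errors, strain substitutions and bases read across a misassembly junction
    all surface as SNVs.  Pairing flags follow :class:`PairingRules`.
    Reads not touching the contig produce no record.  When ``genomes`` is
    given, mates drawn from a genome's marked repeat intervals receive the
    low mapping-quality surrogate.
    """
    ccodes = contig.codes
    lo_ins, hi_ins = rules.insert_window
    out: list[AlignedRead] = []
    for pair in pairs:
        placements = []
        for mate, (interval, gstrand, seq) in enumerate(
                ((pair.mate1_interval, "+", pair.seq1),
                 (pair.mate2_interval, "-", pair.seq2)), start=1):
            seg_table = [(gid if gid == pair.genome_id else None, s, e, st)
                         for gid, s, e, st in contig.sources]
            proj = _project_mate(contig, seg_table, interval, gstrand)
            placements.append((mate, interval, gstrand, seq, proj))
        mapped = [p for p in placements if p[4] is not None]
        if not mapped:
            continue
        both = len(mapped) == 2
        proper = False
        tlen_abs = 0
        if both:
            (_, _, _, _, (c1, st1)), (_, _, _, _, (c2, st2)) = mapped
            rl = pair.read_len
            left, right = (c1, c2) if c1 <= c2 else (c2, c1)
            st_left = st1 if c1 <= c2 else st2
            st_right = st2 if c1 <= c2 else st1
            tlen_abs = right + rl - left
            fr = st_left == "+" and st_right == "-"
            proper = fr and lo_ins <= tlen_abs <= hi_ins
        for mate, interval, gstrand, seq, proj in placements:
            if proj is None:
                continue
            cstart, cstrand = proj
            mate_codes = encode(seq)
            if gstrand == "-":
                mate_codes = revcomp_codes(mate_codes)  # genome forward
            # orient to contig forward: mate_codes is genome-forward; a '-'
            # source segment flips it
            contig_codes = mate_codes
            if (cstrand == "-") != (gstrand == "-"):
                contig_codes = revcomp_codes(mate_codes)
            window = ccodes[cstart:cstart + pair.read_len]
            mism = np.flatnonzero(contig_codes != window) + cstart
            mapq = rules.mapq_unique
            if genomes is not None:
                reps = genomes[pair.genome_id].repeat_intervals
                if any(max(interval[0], rs) < min(interval[1], re)
                       for rs, re in reps):
                    mapq = rules.mapq_repeat
            is_orphan = not both
            other = [p for p in placements if p[0] != mate][0]
            mate_pos = other[4][0] if other[4] is not None else -1
            tlen = 0
            if both:
                mpos = mate_pos
                if cstart < mpos or (cstart == mpos and mate == 1):
                    tlen = tlen_abs
                else:
                    tlen = -tlen_abs
            out.append(AlignedRead(
                qname=pair.pair_id,
                pair_id=pair.pair_id,
                mate=mate,
                pos=int(cstart),
                strand=cstrand,
                seq=decode(contig_codes),
                mapq=mapq,
                al_score=-rules.mismatch_penalty * len(mism),
                mismatch_positions=tuple(int(m) for m in mism),
                is_proper=proper,
                is_orphan=is_orphan,
                is_discordant=both and not proper,
                tlen=int(tlen),
                mate_pos=int(mate_pos),
            ))
    return out


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedContig:
    """A contig together with its simulated alignments."""

    contig: ContigRecord
    alignments: list[AlignedRead]


@dataclass
class SimulatedDataset:
    """A labeled desk-scale dataset: contigs, alignments and provenance."""

    contigs: list[SimulatedContig]
    genomes: dict[str, ReferenceGenome]
    read_len: int
    insert_mean: float
    insert_sd: float

    @property
    def labels(self) -> np.ndarray:
        return np.array([sc.contig.label for sc in self.contigs], dtype=int)

    def contig_records(self) -> list[ContigRecord]:
        return [sc.contig for sc in self.contigs]


def _lognormal_lengths(rng, n, median, sigma, lo, hi):
    lengths = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return np.clip(np.rint(lengths).astype(int), lo, hi)


def simulate_dataset(
    n_contigs: int = 2000,
    misassembly_frac: float = 0.25,
    coverage: float = 10.0,
    read_len: int = 100,
    insert_mean: float = 270.0,
    insert_sd: float = 50.0,
    error_profile: str | ErrorProfile = "HiSeq2500",
    n_genomes: int = 12,
    genome_length: int = 60_000,
    length_median: int = 1500,
    length_sigma: float = 0.45,
    min_length: int = 600,
    max_length: int = 6000,
    strain_rate: float = 0.005,
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate a full labeled dataset of contigs with aligned reads.

    A pool of random genomes (plus one mutated strain per genome, providing
    intra-species diversity that surfaces as low-level SNV background) is
    built; each contig is either a clean substring of one genome or carries
    one injected misassembly of a random class; reads are simulated around
    each contig's source regions at the target coverage and truth-aligned.

    Defaults mirror the desk-scale study conditions: 2,000 contigs, 25%
    misassembled, mean coverage 10, ~0.5% sequencing error, read length 100,
    insert 270 +- 50, contig lengths lognormal with median ~1.5 kb.
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, ReferenceGenome] = {}
    for i in range(n_genomes):
        g = generate_genome(genome_length, 0.35 + 0.3 * rng.random(),
                            seed=rng, id=f"g{i}", taxon_tag=f"sp{i}")
        genomes[g.id] = g
        strain = mutate_strain(g, strain_rate, seed=rng, id=f"g{i}_s1")
        genomes[strain.id] = strain
    base_ids = [f"g{i}" for i in range(n_genomes)]

    lengths = _lognormal_lengths(rng, n_contigs, length_median, length_sigma,
                                 min_length, max_length)
    n_mis = int(round(misassembly_frac * n_contigs))
    is_mis = np.zeros(n_contigs, dtype=bool)
    is_mis[rng.choice(n_contigs, size=n_mis, replace=False)] = True
    mis_classes = ("relocation", "inversion", "translocation",
                   "interspecies_translocation")

    rules = PairingRules(insert_mean, insert_sd)
    out: list[SimulatedContig] = []
    for ci in range(n_contigs):
        L = int(lengths[ci])
        cid = f"contig_{ci:05d}"
        gid = base_ids[int(rng.integers(len(base_ids)))]
        g = genomes[gid]
        if not is_mis[ci]:
            s = int(rng.integers(0, len(g) - L + 1))
            contig = inject_misassembly([g], "none", (s, s + L), cid)
        else:
            mt = mis_classes[int(rng.integers(len(mis_classes)))]
            # breakpoint placed away from the ends so reads can span it
            cut = int(rng.integers(int(0.25 * L), int(0.75 * L) + 1))
            if mt == "inversion":
                s = int(rng.integers(0, len(g) - L + 1))
                i0 = s + cut
                i1 = min(s + L, i0 + int(rng.integers(max(2, L // 4), L)))
                i1 = max(i1, i0 + 1)
                contig = inject_misassembly(
                    [g], "inversion", (s, i0, i1, s + L), cid)
            elif mt == "relocation":
                l1, l2 = cut, L - cut
                s1 = int(rng.integers(0, len(g) - L + 1))
                # second segment from a distant region of the same genome
                s2 = int(rng.integers(0, len(g) - l2 + 1))
                while abs(s2 - (s1 + l1)) < insert_mean:
                    s2 = int(rng.integers(0, len(g) - l2 + 1))
                contig = inject_misassembly(
                    [g], "relocation", ((s1, s1 + l1), (s2, s2 + l2)), cid)
            else:
                l1, l2 = cut, L - cut
                if mt == "translocation":
                    g2 = genomes[f"{gid}_s1"]     # same species, other strain
                else:
                    other = [b for b in base_ids if b != gid]
                    g2 = genomes[other[int(rng.integers(len(other)))]]
                s1 = int(rng.integers(0, len(g) - l1 + 1))
                s2 = int(rng.integers(0, len(g2) - l2 + 1))
                contig = inject_misassembly(
                    [g, g2], mt, ((s1, s1 + l1), (s2, s2 + l2)), cid)
        reads = simulate_contig_reads(
            contig, genomes, coverage, read_len, insert_mean, insert_sd,
            error_profile, seed=rng)
        alns = truth_align(reads, contig, rules)
        out.append(SimulatedContig(contig=contig, alignments=alns))
    return SimulatedDataset(contigs=out, genomes=genomes, read_len=read_len,
                            insert_mean=insert_mean, insert_sd=insert_sd)


# ---------------------------------------------------------------------------
# Writers (FASTA / FASTQ / SAM / labels TSV)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) records as 60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq_pairs(pairs: Iterable[ReadPairTruth], path1, path2,
                      quality_char: str = "I") -> None:
    """Write mates as a pair of Phred+33 FASTQ files with constant quality."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q = quality_char * p.read_len
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q}\n")


def write_sam(alignments_by_contig: Mapping[str, Sequence[AlignedRead]],
              contig_lengths: Mapping[str, int], path,
              quality_char: str = "I") -> None:
    """Write alignments as a headered SAM file (1-based at this boundary)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, clen in contig_lengths.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{clen}\n")
        for cid, alns in alignments_by_contig.items():
            for a in alns:
                rnext = "=" if a.mate_pos >= 0 else "*"
                pnext = a.mate_pos + 1 if a.mate_pos >= 0 else 0
                fh.write("\t".join([
                    a.qname, str(a.flag), cid, str(a.pos + 1), str(a.mapq),
                    a.cigar, rnext, str(pnext), str(a.tlen), a.seq,
                    quality_char * a.read_len,
                    f"AS:i:{a.al_score}", f"NM:i:{len(a.mismatch_positions)}",
                ]) + "\n")


def write_labels_tsv(contigs: Iterable[ContigRecord], path) -> None:
    """Truth labels: contig_id, label, type, comma-separated breakpoints."""
    with open(path, "w") as fh:
        fh.write("contig_id\tlabel\tmisassembly_type\tbreakpoints\n")
        for c in contigs:
            bps = ",".join(str(b) for b in c.breakpoints)
            fh.write(f"{c.id}\t{c.label}\t{c.misassembly_type}\t{bps}\n")
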