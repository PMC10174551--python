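"""Synthetic-data generator: grids, communities, misassemblies, reads."""

import numpy as np
import pysam
import pytest
from Bio import SeqIO

from contiguard._seq import encode, revcomp
from contiguard.io import read_labels_tsv, read_sam
from contiguard.simulate import (ERROR_PROFILES, NOVEL_GRID, TABLE1_GRID,
                                 TABLE1_RESTRICTIONS, GridRestriction,
                                 PairingRules, ReferenceGenome, SimGrid,
                                 derive_breakpoints, enumerate_grid,
                                 generate_genome, inject_misassembly,
                                 mutate_strain, sample_community,
                                 simulate_contig_reads, simulate_dataset,
                                 simulate_read_pairs, truth_align,
                                 write_fasta, write_fastq_pairs,
                                 write_labels_tsv, write_sam)


def _single_insert_grid(insert, profiles=("HiSeq2500", "HiSeq2500-L150")):
    return SimGrid(
        richness_values=TABLE1_GRID.richness_values,
        sigma_values=TABLE1_GRID.sigma_values,
        replicate_count=3,
        read_lengths=TABLE1_GRID.read_lengths,
        insert_specs=(insert,),
        error_profiles=profiles,
        depths=TABLE1_GRID.depths,
        assemblers=TABLE1_GRID.assemblers,
    )


class TestGridEnumeration:
    def test_full_published_grid(self):
        assert len(enumerate_grid(TABLE1_GRID, TABLE1_RESTRICTIONS)) == 4560

    def test_one_unrestricted_insert_size(self):
        assert len(enumerate_grid(_single_insert_grid((270.0, 50.0)))) == 1440

    def test_restricted_insert_350(self):
        grid = _single_insert_grid((350.0, 75.0))
        restr = [GridRestriction((350.0, 75.0),
                                 {"HiSeq2500-L150": None, "HiSeq2500": 1})]
        assert len(enumerate_grid(grid, restr)) == 960

    def test_restricted_insert_450(self):
        grid = _single_insert_grid((450.0, 120.0))
        restr = [GridRestriction((450.0, 120.0), {"HiSeq2500-L150": None})]
        assert len(enumerate_grid(grid, restr)) == 720

    def test_heldout_grid(self):
        assert len(enumerate_grid(NOVEL_GRID)) == 240

    def test_singleton_grid(self):
        grid = SimGrid((50,), (1.0,), 1, (100,), ((270.0, 50.0),),
                       ("HiSeq2500",), (1000,), ("megahit",))
        assert len(enumerate_grid(grid)) == 1

    def test_yaml_config_roundtrip(self, tmp_path):
        from contiguard.simulate import grid_from_yaml, grid_to_yaml
        path = tmp_path / "grid.yaml"
        grid_to_yaml(TABLE1_GRID, path, seed=99)
        grid, seed = grid_from_yaml(path)
        assert seed == 99
        assert grid == TABLE1_GRID
        assert len(enumerate_grid(grid, TABLE1_RESTRICTIONS)) == 4560

    def test_deterministic_order(self):
        a = enumerate_grid(TABLE1_GRID, TABLE1_RESTRICTIONS)
        b = enumerate_grid(TABLE1_GRID, TABLE1_RESTRICTIONS)
        assert a == b

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            SimGrid((), (1.0,), 1, (100,), ((270.0, 50.0),),
                    ("HiSeq2500",), (1000,), ("megahit",))


class TestCommunity:
    def test_degenerate_sigma_gives_uniform(self, genome_pool):
        prof = sample_community(genome_pool, 5, sigma=1e-12, seed=0)
        assert np.allclose(prof.rel_abundances, 1 / 5, atol=1e-6)

    def test_richness_and_normalization(self, genome_pool):
        prof = sample_community(genome_pool, 5, sigma=1.0, seed=1)
        assert len(set(prof.genome_ids)) == 5
        assert abs(sum(prof.rel_abundances) - 1.0) < 1e-9

    def test_richness_exceeding_pool(self, genome_pool):
        with pytest.raises(ValueError):
            sample_community(genome_pool, 99, sigma=1.0, seed=0)

    def test_evenness_decreases_with_sigma(self):
        # Pielou evenness of sigma=0.5 draws should usually beat sigma=2
        pool = [ReferenceGenome(f"g{i}", "ACGT") for i in range(1000)]

        def pielou(ab):
            p = np.asarray(ab)
            return -(p * np.log(p)).sum() / np.log(len(p))

        wins = 0
        for seed in range(100):
            lo = sample_community(pool, 1000, 0.5, seed=seed)
            hi = sample_community(pool, 1000, 2.0, seed=seed)
            wins += pielou(lo.rel_abundances) > pielou(hi.rel_abundances)
        assert wins > 50


class TestGenomes:
    def test_generate_length_and_alphabet(self):
        g = generate_genome(10_000, 0.5, seed=0)
        assert len(g) == 10_000
        assert set(g.sequence) <= set("ACGT")

    def test_gc_fraction_respected(self):
        g = generate_genome(100_000, 0.7, seed=0)
        gc = sum(b in "GC" for b in g.sequence) / len(g)
        assert abs(gc - 0.7) < 0.01

    def test_zero_rate_strain_identical(self):
        g = generate_genome(5_000, 0.5, seed=0)
        assert mutate_strain(g, 0.0, seed=1).sequence == g.sequence

    def test_strain_divergence_near_rate(self):
        g = generate_genome(100_000, 0.5, seed=0)
        s = mutate_strain(g, 0.02, seed=1)
        ham = np.mean(encode(g.sequence) != encode(s.sequence))
        assert 0.015 <= ham <= 0.025

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            generate_genome(0, 0.5, seed=0)
        g = generate_genome(100, 0.5, seed=0)
        with pytest.raises(ValueError):
            mutate_strain(g, 1.0, seed=0)


class TestMisassemblies:
    def test_inversion_construction(self, genome_pool):
        g = genome_pool[0]
        s, i0, i1, e = 1000, 1400, 1900, 2500
        c = inject_misassembly([g], "inversion", (s, i0, i1, e))
        assert c.sequence[:i0 - s] == g.sequence[s:i0]
        assert c.sequence[i0 - s:i1 - s] == revcomp(g.sequence[i0:i1])
        assert c.sequence[i1 - s:] == g.sequence[i1:e]
        assert c.breakpoints == (i0 - s, i1 - s)
        assert c.label == 1

    def test_interspecies_chimera(self, genome_pool):
        g1, g2 = genome_pool[0], genome_pool[1]
        c = inject_misassembly([g1, g2], "interspecies_translocation",
                               ((0, 5000), (0, 5000)))
        assert len(c) == 10_000
        assert c.breakpoints == (5000,)
        assert c.sequence == g1.sequence[:5000] + g2.sequence[:5000]

    def test_clean_window(self, genome_pool):
        g = genome_pool[0]
        c = inject_misassembly([g], "none", (100, 4100))
        assert c.label == 0 and c.breakpoints == ()
        assert c.sequence == g.sequence[100:4100]

    def test_relocation_breakpoint(self, genome_pool):
        g = genome_pool[0]
        c = inject_misassembly([g], "relocation", ((0, 1500), (9000, 10500)))
        assert c.breakpoints == (1500,)
        assert c.sequence == g.sequence[:1500] + g.sequence[9000:10500]

    def test_adjacent_relocation_rejected(self, genome_pool):
        with pytest.raises(ValueError):
            inject_misassembly([genome_pool[0]], "relocation",
                               ((0, 1500), (1500, 3000)))

    def test_out_of_range_segment(self, genome_pool):
        with pytest.raises(ValueError):
            inject_misassembly([genome_pool[0]], "none", (0, 10 ** 7))

    def test_interspecies_needs_distinct_taxa(self, genome_pool):
        g = genome_pool[0]
        with pytest.raises(ValueError):
            inject_misassembly([g, g], "interspecies_translocation",
                               ((0, 100), (200, 300)))

    def test_breakpoints_rederivable_from_sources(self):
        ds = simulate_dataset(n_contigs=60, seed=3)
        for sc in ds.contigs:
            c = sc.contig
            assert c.breakpoints == derive_breakpoints(c.sources)
            assert c.label == (1 if c.breakpoints else 0)
            assert sum(e - s for _, s, e, _ in c.sources) == len(c)


class TestReadSimulation:
    def test_zero_error_reads_are_exact_substrings(self, genome_pool):
        g = genome_pool[0]
        from contiguard.simulate import CommunityProfile
        prof = CommunityProfile((g.id,), (1.0,), 10.0, 1.0)
        pairs = simulate_read_pairs(prof, {g.id: g}, 200, 100, 270, 50,
                                    "zero", seed=0)
        for p in pairs:
            assert p.seq1 == g.sequence[p.frag_start:p.frag_start + 100]
            assert p.seq2 == revcomp(
                g.sequence[p.frag_end - 100:p.frag_end])

    def test_fragment_length_distribution(self, genome_pool):
        g = generate_genome(200_000, 0.5, seed=5, id="big")
        from contiguard.simulate import CommunityProfile
        prof = CommunityProfile((g.id,), (1.0,), 10.0, 1.0)
        pairs = simulate_read_pairs(prof, {g.id: g}, 10_000, 100, 270, 50,
                                    "zero", seed=0)
        frags = np.array([p.frag_end - p.frag_start for p in pairs])
        assert abs(frags.mean() - 270) < 1.5   # ~3 standard errors

    def test_mean_coverage_matches_lander_waterman(self):
        g = generate_genome(100_000, 0.5, seed=6, id="cov")
        from contiguard.simulate import CommunityProfile
        prof = CommunityProfile((g.id,), (1.0,), 10.0, 1.0)
        pairs = simulate_read_pairs(prof, {g.id: g}, 10_000, 150, 400, 50,
                                    "zero", seed=0)
        depth = np.zeros(len(g) + 1)
        for p in pairs:
            for s, e in (p.mate1_interval, p.mate2_interval):
                depth[s] += 1
                depth[e] -= 1
        mean_cov = np.cumsum(depth[:-1]).mean()
        expected = 10_000 * 300 / 100_000
        assert abs(mean_cov - expected) / expected < 0.05

    def test_read_longer_than_genome_window(self, genome_pool):
        g = ReferenceGenome("tiny", "ACGT" * 10)
        from contiguard.simulate import CommunityProfile
        prof = CommunityProfile(("tiny",), (1.0,), 10.0, 1.0)
        with pytest.raises(ValueError):
            simulate_read_pairs(prof, {"tiny": g}, 10, 100, 270, 50,
                                "zero", seed=0)

    def test_error_profile_rates(self):
        prof = ERROR_PROFILES["HiSeq2500"]
        rates = prof.rates(100)
        assert rates[0] == prof.rate_start
        assert rates[-1] == prof.rate_end
        assert abs(rates.mean() - 0.005) < 1e-12


class TestTruthAlignment:
    def _clean_setup(self, genome, length=4000, coverage=8):
        contig = inject_misassembly([genome], "none", (2000, 2000 + length))
        pairs = simulate_contig_reads(
            contig, {genome.id: genome}, coverage, 100, 270, 50, "zero",
            seed=0)
        rules = PairingRules(270, 50)
        return contig, pairs, truth_align(pairs, contig, rules)

    def test_clean_contig_all_proper_no_mismatch(self, genome_pool):
        contig, pairs, alns = self._clean_setup(genome_pool[0])
        assert len(alns) > 0
        for a in alns:
            assert not a.is_orphan or a.pos < 300 or a.pos > len(contig) - 400
        # pairs fully inside the contig must be proper with zero mismatches
        inner = [a for a in alns if not a.is_orphan]
        assert inner and all(a.is_proper for a in inner)
        assert all(len(a.mismatch_positions) == 0 for a in alns)

    def test_orphans_at_contig_boundary(self, genome_pool):
        # mate 2 falls beyond the contig end -> mate 1 is an orphan
        g = genome_pool[0]
        contig = inject_misassembly([g], "none", (1000, 3000))
        from contiguard.simulate import ReadPairTruth
        pair = ReadPairTruth("p", g.id, 2900, 3170, 100,
                             g.sequence[2900:3000],
                             revcomp(g.sequence[3070:3170]), (), ())
        alns = truth_align([pair], contig, PairingRules(270, 50))
        assert len(alns) == 1
        assert alns[0].mate == 1 and alns[0].is_orphan

    def test_breakpoint_spanning_read_mismatches(self, genome_pool):
        g = genome_pool[0]
        s, i0, i1, e = 0, 1000, 2200, 3000
        contig = inject_misassembly([g], "inversion", (s, i0, i1, e))
        # read of length 150 starting 90 bp before the junction: its true
        # source is the genome, so the 60 bases past the junction are
        # compared against reverse-complemented sequence
        from contiguard.simulate import ReadPairTruth
        start = i0 - 90
        pair = ReadPairTruth("p", g.id, start, start + 400, 150,
                             g.sequence[start:start + 150],
                             revcomp(g.sequence[start + 250:start + 400]),
                             (), ())
        alns = truth_align([pair], contig, PairingRules(270, 50))
        mate1 = [a for a in alns if a.mate == 1][0]
        expected = [start + j for j in range(150)
                    if g.sequence[start + j] != contig.sequence[start + j]]
        assert list(mate1.mismatch_positions) == expected
        assert len(expected) > 0
        assert mate1.al_score == -6 * len(expected)

    def test_repeat_region_lowers_mapq(self):
        g = generate_genome(6000, 0.5, seed=9, id="rep")
        g.repeat_intervals = ((0, 6000),)
        contig = inject_misassembly([g], "none", (1000, 3000))
        pairs = simulate_contig_reads(contig, {"rep": g}, 5, 100, 270, 50,
                                      "zero", seed=0)
        alns = truth_align(pairs, contig, PairingRules(270, 50),
                           genomes={"rep": g})
        assert alns and all(a.mapq == 1 for a in alns)

    def test_bit_reproducibility(self):
        a = simulate_dataset(n_contigs=15, seed=42)
        b = simulate_dataset(n_contigs=15, seed=42)
        for sa, sb in zip(a.contigs, b.contigs):
            assert sa.contig.sequence == sb.contig.sequence
            assert len(sa.alignments) == len(sb.alignments)
            for x, y in zip(sa.alignments, sb.alignments):
                assert (x.pos, x.seq, x.flag, x.tlen) == \
                       (y.pos, y.seq, y.flag, y.tlen)


class TestWriters:
    def test_fasta_roundtrip(self, tmp_path):
        recs = [("a", "ACGT" * 40), ("b", "TTTT")]
        path = tmp_path / "x.fasta"
        write_fasta(recs, path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines) <= 60
        back = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert back == dict(recs)

    def test_fastq_pairs(self, tmp_path):
        ds = simulate_dataset(n_contigs=4, seed=0)
        g = next(iter(ds.genomes.values()))
        from contiguard.simulate import CommunityProfile
        prof = CommunityProfile((g.id,), (1.0,), 10.0, 1.0)
        pairs = simulate_read_pairs(prof, {g.id: g}, 25, 100, 270, 50,
                                    "zero", seed=0)
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq_pairs(pairs, p1, p2)
        r1 = list(SeqIO.parse(str(p1), "fastq"))
        r2 = list(SeqIO.parse(str(p2), "fastq"))
        assert len(r1) == len(r2) == 25
        assert str(r1[0].seq) == pairs[0].seq1
        assert str(r2[0].seq) == pairs[0].seq2

    def test_sam_roundtrip_via_pysam(self, tmp_path):
        ds = simulate_dataset(n_contigs=10, seed=5)
        sc = next(s for s in ds.contigs if len(s.alignments) > 4)
        path = tmp_path / "aln.sam"
        write_sam({sc.contig.id: sc.alignments},
                  {sc.contig.id: len(sc.contig)}, path)
        with pysam.AlignmentFile(str(path), "r") as fh:
            recs = list(fh)
        assert len(recs) == len(sc.alignments)
        for rec, a in zip(recs, sc.alignments):
            assert rec.reference_start == a.pos
            assert rec.is_proper_pair == a.is_proper
            assert rec.is_reverse == (a.strand == "-")
            assert rec.get_tag("NM") == len(a.mismatch_positions)
        # and through the package reader, features are reconstructible
        loaded = read_sam(path, {sc.contig.id: sc.contig.sequence})
        got = loaded[sc.contig.id]
        assert len(got) == len(sc.alignments)
        for x, a in zip(got, sc.alignments):
            assert x.mismatch_positions == a.mismatch_positions
            assert x.is_proper == a.is_proper
            assert abs(x.tlen) == abs(a.tlen)

    def test_labels_tsv_roundtrip(self, tmp_path):
        ds = simulate_dataset(n_contigs=20, seed=6)
        path = tmp_path / "labels.tsv"
        write_labels_tsv((sc.contig for sc in ds.contigs), path)
        labels, bps = read_labels_tsv(path)
        for sc in ds.contigs:
            assert labels[sc.contig.id] == sc.contig.label
            assert bps[sc.contig.id] == sc.contig.breakpoints
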