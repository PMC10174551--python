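"""Pileup feature extraction and preprocessing."""

import numpy as np
import pytest

from _oracles import brute_force_pileup, random_alignments
from contiguard.features import (DEFAULT_CATALOG, FeatureStats,
                                 apply_normalization, compute_pileup,
                                 fit_normalization, insert_size_profile,
                                 subsample_to_coverage)
from contiguard.simulate import (AlignedRead, ContigRecord, generate_genome,
                                 inject_misassembly, simulate_dataset)
from contiguard.store import FeatureStore


def _contig(seq: str, cid="c") -> ContigRecord:
    return ContigRecord(id=cid, sequence=seq, label=0,
                        misassembly_type="none", breakpoints=(),
                        sources=(("src", 0, len(seq), "+"),))


def _read(pos, seq, **kw):
    defaults = dict(qname="r", pair_id="r", mate=1, pos=pos, strand="+",
                    seq=seq, mapq=42, al_score=0, mismatch_positions=(),
                    is_proper=True, is_orphan=False, is_discordant=False,
                    tlen=300, mate_pos=-1)
    defaults.update(kw)
    return AlignedRead(**defaults)


class TestPileup:
    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(40):
            L = int(rng.integers(60, 2000))
            g = generate_genome(L, 0.5, seed=rng, id=f"t{trial}")
            contig = _contig(g.sequence, f"t{trial}")
            alns = random_alignments(g.sequence,
                                     int(rng.integers(1, 51)), rng)
            m = compute_pileup(contig, alns)
            ref = brute_force_pileup(g.sequence, alns)
            for name in ref:
                got = m.channel(name)
                np.testing.assert_allclose(
                    got, ref[name], atol=1e-3, rtol=1e-4, equal_nan=True,
                    err_msg=f"channel {name} trial {trial}")

    def test_two_overlapping_reads_coverage(self):
        contig = _contig("A" * 15)
        alns = [_read(0, "A" * 10, qname="a", pair_id="a"),
                _read(5, "A" * 10, qname="b", pair_id="b")]
        cov = compute_pileup(contig, alns).coverage
        assert list(cov) == [1] * 5 + [2] * 5 + [1] * 5

    def test_uncovered_positions_masked(self):
        contig = _contig("ACGT" * 10)
        m = compute_pileup(contig, [_read(0, "ACGT")])
        assert m.mask[:4].all() and not m.mask[4:].any()
        assert np.isnan(m.channel("mean_mapq")[4:]).all()
        assert (m.channel("num_SNPs")[4:] == 0).all()

    def test_base_counts_partition_coverage(self, rng):
        g = generate_genome(500, 0.5, seed=0, id="p")
        contig = _contig(g.sequence)
        alns = random_alignments(g.sequence, 30, rng)
        m = compute_pileup(contig, alns)
        total = sum(m.channel(f"num_query_{b}") for b in "ACGT")
        np.testing.assert_array_equal(total, m.coverage)
        assert (m.channel("num_proper_SNP") <= m.channel("num_SNPs")).all()
        assert (m.channel("num_SNPs") <= m.coverage).all()

    def test_single_read_stdev_zero(self):
        contig = _contig("ACGTACGT")
        m = compute_pileup(contig, [_read(0, "ACGT")])
        assert (m.channel("stdev_mapq")[:4] == 0).all()

    def test_out_of_bounds_alignment_raises(self):
        contig = _contig("ACGT")
        with pytest.raises(ValueError, match="out of contig bounds"):
            compute_pileup(contig, [_read(2, "ACGTA")])


class TestSubsampling:
    def _aligned_dataset(self, coverage, seed=0):
        ds = simulate_dataset(n_contigs=1, coverage=coverage,
                              min_length=2500, max_length=2600, seed=seed)
        sc = ds.contigs[0]
        return sc.contig, sc.alignments

    def test_low_coverage_untouched(self):
        contig, alns = self._aligned_dataset(12)
        out = subsample_to_coverage(alns, len(contig), 20, seed=0)
        assert out == list(alns)

    def test_high_coverage_reduced_to_window(self):
        contig, alns = self._aligned_dataset(40)
        out = subsample_to_coverage(alns, len(contig), 20, seed=0)
        mean_cov = sum(a.read_len for a in out) / len(contig)
        assert 18 < mean_cov <= 20

    def test_deterministic(self):
        contig, alns = self._aligned_dataset(40)
        a = subsample_to_coverage(alns, len(contig), 20, seed=5)
        b = subsample_to_coverage(alns, len(contig), 20, seed=5)
        assert [x.qname for x in a] == [x.qname for x in b]

    def test_mates_kept_together(self):
        contig, alns = self._aligned_dataset(40)
        out = subsample_to_coverage(alns, len(contig), 20, seed=0)
        full = {}
        for a in alns:
            full.setdefault(a.pair_id, 0)
            full[a.pair_id] += 1
        kept = {}
        for a in out:
            kept.setdefault(a.pair_id, 0)
            kept[a.pair_id] += 1
        for pid, n in kept.items():
            assert n == full[pid]

    def test_never_increases_positionwise_coverage(self):
        contig, alns = self._aligned_dataset(40)
        out = subsample_to_coverage(alns, len(contig), 20, seed=0)
        before = compute_pileup(contig, alns).coverage
        after = compute_pileup(contig, out).coverage
        assert (after <= before).all()


@pytest.fixture(scope="module")
def fitted():
    ds = simulate_dataset(n_contigs=25, seed=9)
    mats = [compute_pileup(sc.contig, sc.alignments) for sc in ds.contigs]
    with pytest.warns(UserWarning):   # constant mapq in clean data
        stats = fit_normalization(mats)
    return mats, stats


class TestNormalization:
    def test_fit_then_apply_standardizes(self, fitted):
        mats, stats = fitted
        # re-standardizing pooled covered values gives mean ~0, sd ~1
        for name in ("mean_al_score", "coverage", "seq_window_gc"):
            vals = []
            for m in mats:
                nm = apply_normalization(m, stats)
                vals.append(nm.channel(name)[m.mask])
            v = np.concatenate(vals)
            assert abs(v.mean()) < 1e-5
            assert abs(v.std() - 1.0) < 1e-5

    def test_count_channels_bounded(self, fitted):
        mats, stats = fitted
        for m in mats[:5]:
            nm = apply_normalization(m, stats)
            for name in nm.catalog.by_kind("count"):
                col = nm.channel(name)
                assert (col >= 0).all() and (col <= 1).all()

    def test_zero_coverage_rows_all_zero(self, fitted):
        mats, stats = fitted
        contig = _contig("ACGT" * 200)
        m = compute_pileup(contig, [_read(0, "ACGT" * 10)])
        nm = apply_normalization(m, stats)
        assert (nm.values[40:] == 0).all()

    def test_proper_fraction_example(self, fitted):
        _, stats = fitted
        contig = _contig("A" * 20)
        alns = [_read(0, "A" * 10, qname=f"p{i}", pair_id=f"p{i}")
                for i in range(7)]
        alns += [_read(0, "A" * 10, qname=f"o{i}", pair_id=f"o{i}",
                       is_proper=False, is_orphan=True, tlen=0)
                 for i in range(3)]
        m = compute_pileup(contig, alns)
        nm = apply_normalization(m, stats)
        assert nm.channel("num_proper")[0] == pytest.approx(0.7)

    def test_constant_channel_standardizes_to_zero(self):
        contig = _contig("ACGT" * 50)
        m = compute_pileup(contig, [_read(0, "ACGT" * 10)])
        with pytest.warns(UserWarning):
            stats = fit_normalization([m])
        nm = apply_normalization(m, stats)
        assert (nm.channel("mean_mapq")[m.mask] == 0).all()

    def test_stats_json_roundtrip_bitwise(self, fitted):
        mats, stats = fitted
        stats2 = FeatureStats.from_json(stats.to_json())
        a = apply_normalization(mats[0], stats).values
        b = apply_normalization(mats[0], stats2).values
        np.testing.assert_array_equal(a, b)

    def test_duplicating_reads_leaves_count_channels_unchanged(self, rng):
        g = generate_genome(400, 0.5, seed=3, id="d")
        contig = _contig(g.sequence)
        alns = random_alignments(g.sequence, 20, rng)
        doubled = alns + [
            AlignedRead(**{**a.__dict__, "qname": a.qname + "x",
                           "pair_id": a.pair_id + "x"}) for a in alns]
        stats = FeatureStats(
            mean={n: 0.0 for n in DEFAULT_CATALOG.by_kind("numeric")},
            sd={n: 1.0 for n in DEFAULT_CATALOG.by_kind("numeric")})
        m1 = apply_normalization(compute_pileup(contig, alns), stats)
        m2 = apply_normalization(compute_pileup(contig, doubled), stats)
        for name in DEFAULT_CATALOG.by_kind("count"):
            np.testing.assert_allclose(m1.channel(name), m2.channel(name),
                                       atol=1e-6)


class TestInsertProfile:
    def _alns_with_inserts(self, inserts):
        return [_read(0, "ACGT", qname=f"r{i}", pair_id=f"r{i}",
                      tlen=int(t)) for i, t in enumerate(inserts)]

    def test_normal_inserts_pass(self, rng):
        ins = rng.normal(270, 50, size=2000)
        prof = insert_size_profile(self._alns_with_inserts(ins))
        assert 117 < prof.q05 and prof.q95 < 493
        assert prof.passes()

    def test_constant_600_fails(self):
        prof = insert_size_profile(self._alns_with_inserts([600] * 50))
        assert prof.q05 == prof.q95 == 600
        assert not prof.passes()

    def test_constant_300_passes(self):
        prof = insert_size_profile(self._alns_with_inserts([300] * 50))
        assert prof.passes()

    def test_boundary_closed(self):
        prof = insert_size_profile(self._alns_with_inserts([117] * 50))
        assert prof.passes()

    def test_no_proper_pairs_raises(self):
        alns = [_read(0, "ACGT", is_proper=False, is_orphan=True, tlen=0)]
        with pytest.raises(ValueError):
            insert_size_profile(alns)


class TestFeatureStore:
    @pytest.fixture()
    def store(self, tmp_path, small_dataset):
        path = tmp_path / "store.npz"
        mats = dict(list(small_dataset["matrices"].items())[:10])
        FeatureStore.write(path, mats, small_dataset["labels"],
                           small_dataset["breakpoints"],
                           insert_profile={"q05": 180.0, "q50": 270.0,
                                           "q95": 360.0, "n_pairs": 100})
        return path, mats

    def test_roundtrip_exact(self, store):
        path, mats = store
        with FeatureStore.open(path) as s:
            for cid, m in mats.items():
                np.testing.assert_array_equal(s.get(cid).values, m.values)
            assert s.catalog == m.catalog

    def test_window_read(self, store):
        path, mats = store
        cid, m = next(iter(mats.items()))
        with FeatureStore.open(path) as s:
            w = s.get(cid, window=(100, 200))
            np.testing.assert_array_equal(w.values, m.values[100:200])

    def test_unknown_contig_raises(self, store):
        path, _ = store
        with FeatureStore.open(path) as s:
            with pytest.raises(KeyError):
                s.get("nope")

    def test_labels_and_profile_preserved(self, store, small_dataset):
        path, mats = store
        with FeatureStore.open(path) as s:
            for cid in mats:
                assert s.label(cid) == small_dataset["labels"][cid]
                assert s.breakpoints(cid) == tuple(
                    small_dataset["breakpoints"][cid])
            assert s.insert_profile["q95"] == 360.0
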