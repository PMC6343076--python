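"""Quality filter, dereplication, OTU/ZOTU formation, mapping, decontamination."""

import numpy as np
import pytest

from riboratio.seqio import Read
from riboratio.units import (
    CountTable,
    UniqueSequence,
    dereplicate,
    greedy_cluster_otus,
    map_reads_to_units,
    map_zotus_to_otus,
    quality_filter,
    remove_contaminants,
    unoise_denoise,
)
from .conftest import make_count_table


def read_of(seq: str, q: int = 30, rid: str = "r") -> Read:
    return Read(rid, seq, chr(33 + q) * len(seq))


def uniq(seq: str, size: int, sample: str = "S1", pool: str = "rDNA") -> UniqueSequence:
    return UniqueSequence(seq, size, {(sample, pool): size})


def mutate(seq: str, positions: list[int], base: str = "T") -> str:
    out = list(seq)
    for p in positions:
        out[p] = base if out[p] != base else "G"
    return "".join(out)


class TestQualityFilter:
    def test_expected_error_discards_q20_250mer(self):
        # 250 bases at Q20: EE = 250 * 0.01 = 2.5 > 1
        kept, stats = quality_filter([read_of("A" * 250, q=20)])
        assert kept == [] and stats.n_failed_ee == 1

    def test_length_discards_short_high_quality_read(self):
        kept, stats = quality_filter([read_of("A" * 229, q=40)])
        assert kept == [] and stats.n_failed_length == 1

    def test_q30_230mer_retained(self):
        # EE = 230 * 0.001 = 0.23 <= 1
        kept, stats = quality_filter([read_of("A" * 230, q=30)])
        assert len(kept) == 1 and stats.retained_fraction == 1.0

    def test_order_preserved_and_malformed_rejected(self):
        reads = [read_of("A" * 240, rid="a"), read_of("C" * 240, rid="b")]
        kept, _ = quality_filter(reads)
        assert [r.id for r in kept] == ["a", "b"]
        with pytest.raises(ValueError, match="index 0"):
            quality_filter([Read("bad", "ACGT" * 60, "III")])


class TestDereplicate:
    def test_sizes_and_order(self):
        s1, s2 = "A" * 240, "C" * 240
        corpus = {("S1", "rDNA"): [read_of(s1)] * 3 + [read_of(s2)]}
        uniques = dereplicate(corpus)
        assert [(u.sequence, u.size) for u in uniques] == [(s1, 3), (s2, 1)]

    def test_ties_break_lexicographically(self):
        corpus = {("S1", "rDNA"): [read_of("C" * 240), read_of("A" * 240)]}
        uniques = dereplicate(corpus)
        assert [u.sequence for u in uniques] == ["A" * 240, "C" * 240]

    def test_sizes_sum_to_read_count_with_provenance(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(20)]
        corpus = {
            ("S1", "rDNA"): [read_of(seqs[rng.integers(20)]) for _ in range(150)],
            ("S1", "rRNA"): [read_of(seqs[rng.integers(20)]) for _ in range(100)],
        }
        uniques = dereplicate(corpus)
        assert sum(u.size for u in uniques) == 250
        for u in uniques:
            assert u.size == sum(u.provenance.values())


class TestGreedyClustering:
    def test_single_unique_single_otu(self):
        units = greedy_cluster_otus([uniq("A" * 100, 10)])
        assert len(units) == 1 and units[0].founder_size == 10

    def test_098_identity_pair_merges_into_larger(self):
        base = "ACGT" * 25
        variant = mutate(base, [10, 50])  # identity 0.98
        units = greedy_cluster_otus([uniq(base, 50), uniq(variant, 20)])
        assert len(units) == 1
        assert units[0].representative == base
        assert units[0].total_size == 70

    def test_095_identity_pair_stays_separate(self):
        base = "ACGT" * 25
        far = mutate(base, [5, 25, 45, 65, 85])  # identity 0.95
        units = greedy_cluster_otus([uniq(base, 50), uniq(far, 20)])
        assert len(units) == 2

    def test_small_unique_cannot_found_centroid(self):
        base = "ACGT" * 25
        far = mutate(base, [5, 25, 45, 65, 85])
        units = greedy_cluster_otus([uniq(base, 50), uniq(far, 7)], minsize=8)
        assert len(units) == 1  # the size-7 unique is dropped from formation

    def test_centroids_pairwise_below_threshold_members_above(self):
        from riboratio.align import pairwise_identity
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=150))
        uniques = [uniq(base, 100)]
        for k in range(1, 12):
            positions = list(rng.choice(150, size=rng.integers(1, 12), replace=False))
            uniques.append(uniq(mutate(base, positions), 100 - 8 * k + 7))
        uniques.sort(key=lambda u: -u.size)
        units = greedy_cluster_otus(uniques)
        reps = [u.representative for u in units]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert pairwise_identity(reps[i], reps[j]) < 0.97
        for unit in units:
            for member in unit.members:
                assert pairwise_identity(member.sequence, unit.representative) >= 0.97

    def test_empty_input(self):
        assert greedy_cluster_otus([]) == []


class TestUnoise:
    def test_d1_variant_below_skew_merges(self):
        base = "ACGT" * 60
        variant = mutate(base, [100])
        units = unoise_denoise([uniq(base, 1000), uniq(variant, 100)])
        # beta(1) = 1/8; skew 0.1 <= 0.125 -> merged
        assert len(units) == 1 and units[0].total_size == 1100

    def test_d1_variant_above_skew_becomes_centroid(self):
        base = "ACGT" * 60
        variant = mutate(base, [100])
        units = unoise_denoise([uniq(base, 1000), uniq(variant, 200)])
        # skew 0.2 > 1/8 -> new centroid
        assert len(units) == 2
        assert {u.representative for u in units} == {base, variant}

    def test_minsize_removes_small_uniques(self):
        base = "ACGT" * 60
        units = unoise_denoise([uniq(base, 1000), uniq(mutate(base, [3]), 7)])
        assert len(units) == 1 and units[0].total_size == 1000

    def test_beta_scales_with_distance(self):
        base = "ACGT" * 60
        d3 = mutate(base, [10, 60, 110])
        # beta(3) = 2^-7 = 1/128: size 8 vs 1000 has skew 0.008 > 0.0078 -> kept
        units = unoise_denoise([uniq(base, 1000), uniq(d3, 8)])
        assert len(units) == 2
        # size 7 would be below minsize anyway; use 1280 centroid: skew 0.00625 <= beta
        units = unoise_denoise([uniq(base, 1280), uniq(d3, 8)])
        assert len(units) == 1

    def test_input_permutation_invariance_via_derep_ordering(self):
        """Shuffling reads does not change the ZOTU set (canonical ordering)."""
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=200))
        reads = [read_of(base)] * 500 + [read_of(mutate(base, [7]))] * 30 \
            + [read_of(mutate(base, [9, 90]))] * 30
        shuffled = list(reads)
        rng.shuffle(shuffled)
        u1 = unoise_denoise(dereplicate({("S1", "rDNA"): reads}))
        u2 = unoise_denoise(dereplicate({("S1", "rDNA"): shuffled}))
        assert [u.representative for u in u1] == [u.representative for u in u2]

    def test_empty_input(self):
        assert unoise_denoise([]) == []


class TestMapping:
    def test_exact_and_near_reads(self):
        rng = np.random.default_rng(5)
        rep = "".join(rng.choice(list("ACGT"), size=250))
        zotu = unoise_denoise([uniq(rep, 100)])
        one_off = mutate(rep, [13])
        corpus = {("S1", "rDNA"): [read_of(rep), read_of(one_off)]}
        table = map_reads_to_units(corpus, zotu, min_identity=1.0)
        assert table.counts.iloc[0, 0] == 1
        assert table.unassigned.iloc[0] == 1  # 1 mismatch fails 100% identity
        otu = greedy_cluster_otus([uniq(rep, 100)])
        table97 = map_reads_to_units(corpus, otu, min_identity=0.97)
        assert table97.counts.iloc[0, 0] == 2  # identity 0.996 >= 0.97
        assert table97.unassigned.iloc[0] == 0

    def test_empty_units_rejected(self):
        with pytest.raises(ValueError):
            map_reads_to_units({("S1", "rDNA"): []}, [], 1.0)

    def test_mapped_reads_meet_threshold_by_realignment(self):
        """Spot-check: reads only count toward units they truly match at 97%."""
        from riboratio.align import pairwise_identity
        rng = np.random.default_rng(6)
        reps = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(3)]
        units = greedy_cluster_otus([uniq(r, 50) for r in reps])
        reads = []
        for rep in reps:
            for _ in range(5):
                pos = list(rng.choice(200, size=int(rng.integers(0, 5)),
                                      replace=False))
                reads.append(read_of(mutate(rep, pos)))
        table = map_reads_to_units({("S1", "rDNA"): reads}, units, 0.97)
        assert table.counts.sum().sum() + table.unassigned.sum() == len(reads)
        assert table.unassigned.sum() == 0  # <= 4 edits over 200 bp stays >= 0.97
        rep_by_id = {u.unit_id: u.representative for u in units}
        seq_counts = {r.sequence for r in reads}
        for seq in seq_counts:
            best = max(table.counts.index,
                       key=lambda uid: pairwise_identity(seq, rep_by_id[uid]))
            assert pairwise_identity(seq, rep_by_id[best]) >= 0.97


class TestContaminantRemoval:
    def test_rule_boundaries(self):
        table = make_count_table({
            ("S1", "rDNA"): {"U1": 100, "U2": 50, "U3": 40},
            ("NC1", "rDNA"): {"U1": 6, "U2": 5, "U3": 0},
            ("NC2", "rDNA"): {"U1": 6, "U2": 5, "U3": 0},
        })
        # control totals are 11: U1 at 6/11=54% removed; U2 at 45% removed...
        cleaned, dropped = remove_contaminants(
            table, [("NC1", "rDNA"), ("NC2", "rDNA")], threshold=0.5)
        assert dropped == ["U1"]
        assert "U1" not in cleaned.counts.index

    def test_exact_threshold_retained(self):
        table = make_count_table({
            ("S1", "rDNA"): {"U1": 10, "U2": 90},
            ("NC1", "rDNA"): {"U1": 5, "U2": 95},
        })
        cleaned, dropped = remove_contaminants(table, [("NC1", "rDNA")], 0.05)
        assert "U1" not in dropped  # exactly 5% is not "> 5%"
        assert "U1" in cleaned.counts.index

    def test_absent_from_controls_retained_and_zero_control_counts_as_zero(self):
        table = make_count_table({
            ("S1", "rDNA"): {"U1": 10, "U2": 90},
            ("NC1", "rDNA"): {"U1": 0, "U2": 0},
            ("NC2", "rDNA"): {"U1": 1, "U2": 0},
        })
        cleaned, dropped = remove_contaminants(
            table, [("NC1", "rDNA"), ("NC2", "rDNA")], 0.4)
        # U1: (0 + 1.0)/2 = 0.5 > 0.4 -> dropped; zero-read control contributes 0
        assert dropped == ["U1"]

    def test_column_totals_never_increase(self):
        rng = np.random.default_rng(7)
        table = make_count_table({
            ("S1", "rDNA"): {f"U{i}": int(rng.integers(0, 50)) for i in range(10)},
            ("NC1", "rDNA"): {f"U{i}": int(rng.integers(0, 10)) for i in range(10)},
        })
        before = table.counts.sum()
        cleaned, _ = remove_contaminants(table, [("NC1", "rDNA")], 0.05)
        after = cleaned.counts.sum()
        assert (after <= before).all()

    def test_blacklist_hook(self):
        table = make_count_table({
            ("S1", "rDNA"): {"U1": 10, "U2": 90},
            ("NC1", "rDNA"): {"U1": 0, "U2": 0},
        })
        _, dropped = remove_contaminants(table, [("NC1", "rDNA")],
                                         blacklist=["U2"])
        assert dropped == ["U2"]


class TestZotuToOtuMapping:
    def test_identical_and_distant_representatives(self):
        rng = np.random.default_rng(8)
        rep = "".join(rng.choice(list("ACGT"), size=200))
        far = "".join(rng.choice(list("ACGT"), size=200))
        otus = greedy_cluster_otus([uniq(rep, 100)])
        zotus = unoise_denoise([uniq(rep, 60), uniq(far, 50)])
        import pandas as pd
        mapping = map_zotus_to_otus(zotus, otus)
        assert mapping.loc["ZOTU1", "otu_id"] == "OTU1"
        assert pd.isna(mapping.loc["ZOTU2", "otu_id"])

    def test_clustered_members_map_back_to_their_otu(self, clean_run):
        """Every ZOTU whose sequence joined an OTU cluster maps to that OTU."""
        from riboratio.pipeline import run_corpus
        import riboratio.simulate as sim
        scenario, community, result = clean_run
        corpus = {}
        for pool in ("rDNA", "rRNA"):
            corpus[("S1", pool)] = sim.sample_amplicon_reads(
                community, pool, scenario, "S1")
        otu_result = run_corpus(corpus, method="OTU")
        membership = {}
        for otu in otu_result.units:
            for member in otu.members:
                membership[member.sequence] = otu.unit_id
        mapping = map_zotus_to_otus(result.units, otu_result.units)
        for zotu in result.units:
            if zotu.representative in membership:
                assert mapping.loc[zotu.unit_id, "otu_id"] == \
                    membership[zotu.representative]


def test_zero_error_recovery_no_spurious_zotus(clean_run):
    """With no errors, ZOTUs are exactly the true references with >= 8 reads."""
    import riboratio.simulate as sim
    scenario, community, result = clean_run
    pooled: dict[str, int] = {}
    for pool in ("rDNA", "rRNA"):
        for read in sim.sample_amplicon_reads(community, pool, scenario, "S1"):
            pooled[read.sequence] = pooled.get(read.sequence, 0) + 1
    expected = {s for s in community.references if pooled.get(s, 0) >= 8}
    assert {u.representative for u in result.units} == expected


def test_count_table_tsv_round_trip(tmp_path, toy_table):
    path = tmp_path / "table.tsv"
    toy_table.to_tsv(path)
    back = CountTable.from_tsv(path, method="ZOTU")
    assert back.counts.equals(toy_table.counts)
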