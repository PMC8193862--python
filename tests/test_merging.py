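import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umidedup.consensus import consensus_read
from umidedup.grouping import RunConfig, UmiGroup
from umidedup.merging import (
    CorrectedGroup,
    correct_groups,
    hamming,
    merge_umi_groups,
)

from conftest import make_read
from oracles import brute_merge

SEED_UMI = "GAGCTTCAACTC"
PARTNER_UMIS = ["GCGCTTCAACTC", "GATCTTCAACTC", "GAGCTTCCACTC"]


def make_group(umi, n_reads, r1_seq, r2_seq=None, r1_quals=35, r2_quals=35):
    members = [make_read(r1_seq, r1_quals, read_id=f"{umi}_{i}") for i in range(n_reads)]
    mates = (
        [make_read(r2_seq, r2_quals, read_id=f"{umi}_{i}") for i in range(n_reads)]
        if r2_seq is not None
        else None
    )
    return UmiGroup(umi, members, mates)


def cfg(umi_distance=1, seq_distance=3, **kw):
    return RunConfig(
        UMIlength=4, sequenceLength=5, UMIdistance=umi_distance,
        sequenceDistance=seq_distance, **kw,
    )


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (SEED_UMI, "GCGCTTCAACTC", 1),
            (SEED_UMI, SEED_UMI, 0),
            ("GCGCTTCAACTC", "GATCTTCAACTC", 2),
            ("AAAA", "TTTT", 4),
        ],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming("AA", "AAA")

    @given(
        st.integers(1, 12).flatmap(
            lambda n: st.tuples(
                st.text("ACGT", min_size=n, max_size=n),
                st.text("ACGT", min_size=n, max_size=n),
                st.text("ACGT", min_size=n, max_size=n),
            )
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_metric_axioms(self, strings):
        a, b, c = strings
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, a) == 0
        assert (hamming(a, b) == 0) == (a == b)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)
        assert 0 <= hamming(a, b) <= len(a)


class TestWorkedExampleCluster:
    """A molecule split over four barcodes by sequencing error: the dominant
    barcode (1,001 reads) absorbs its three 1-mismatch neighbours (23, 13
    and 12 reads) when their consensus inserts are close enough."""

    def build(self):
        r2_variants = ["ACGTGACGTG", "ACGTGACGTT", "ACGTGACGAT", "ACGTGACGTG"]
        groups = [make_group(SEED_UMI, 1001, "AACCGGTTAA", r2_variants[0])]
        for umi, n, r2 in zip(PARTNER_UMIS, [23, 13, 12], r2_variants[1:]):
            groups.append(make_group(umi, n, "AACCGGTTAA", r2))
        return correct_groups(groups)

    def test_single_cluster_with_three_partners(self):
        config = RunConfig(
            pairedData=True, UMIlength=12, sequenceLength=10,
            countsCutoff=6, UMIdistance=1, sequenceDistance=3,
        )
        clusters = merge_umi_groups(self.build(), config)
        assert len(clusters) == 1
        (cluster,) = clusters
        assert cluster.representative_umi == SEED_UMI
        assert sorted(cluster.absorbed_umis) == sorted(PARTNER_UMIS)
        assert len(cluster.absorbed_umis) == 3
        assert cluster.pooled_count == 1001 + 23 + 13 + 12
        assert cluster.final_r1.sequence == "AACCGGTTAA"
        # the dominant group's mate sequence wins the pooled consensus
        assert cluster.final_r2.sequence == "ACGTGACGTG"


class TestGreedyMerging:
    def test_all_distant_umis_stay_singletons(self):
        groups = correct_groups(
            [make_group(u, 3, "ACGTA") for u in ["AAAA", "CCCC", "GGGG"]]
        )
        clusters = merge_umi_groups(groups, cfg())
        assert len(clusters) == 3
        assert all(not c.absorbed_umis for c in clusters)

    def test_greedy_rounds_no_chaining(self):
        # AAAT is 1 from seed AAAA (absorbed); AATT is 2 from AAAA but 1
        # from AAAT -- it must NOT chain in, and seeds round 2 alone.
        groups = correct_groups(
            [
                make_group("AAAA", 10, "ACGTA"),
                make_group("AAAT", 5, "ACGTA"),
                make_group("AATT", 3, "ACGTA"),
            ]
        )
        clusters = merge_umi_groups(groups, cfg())
        assert [(c.representative_umi, c.absorbed_umis) for c in clusters] == [
            ("AAAA", ["AAAT"]),
            ("AATT", []),
        ]
        assert clusters[0].pooled_count == 15

    def test_sequence_distance_vetoes_umi_match(self):
        groups = correct_groups(
            [
                make_group("AAAA", 10, "AAAAA"),
                make_group("AAAT", 5, "TTTTT"),  # UMI close, insert far
            ]
        )
        clusters = merge_umi_groups(groups, cfg(seq_distance=3))
        assert len(clusters) == 2

    def test_paired_requires_both_mates_close(self):
        groups = correct_groups(
            [
                make_group("AAAA", 10, "AAAAA", "CCCCC"),
                make_group("AAAT", 5, "AAAAA", "GGGGG"),  # R2 too far
            ]
        )
        clusters = merge_umi_groups(groups, cfg(pairedData=True))
        assert len(clusters) == 2

    def test_zero_umi_distance_gives_singletons_equal_to_first_pass(self):
        groups = correct_groups(
            [make_group("AAAA", 4, "ACGTA"), make_group("AAAT", 2, "ACGTA")]
        )
        clusters = merge_umi_groups(groups, cfg(umi_distance=0))
        assert len(clusters) == 2
        for cluster, cg in zip(clusters, groups):
            assert cluster.final_r1 == cg.consensus_r1

    def test_partition_conserves_reads(self, rng):
        umis = ["AAAA", "AAAT", "AATT", "CCCC", "CCCT", "GGGG"]
        groups = correct_groups(
            [make_group(u, rng.randint(1, 20), "ACGTA") for u in umis]
        )
        clusters = merge_umi_groups(groups, cfg())
        assert sum(c.pooled_count for c in clusters) == sum(g.count for g in groups)
        seen = [c.representative_umi for c in clusters] + [
            u for c in clusters for u in c.absorbed_umis
        ]
        assert sorted(seen) == sorted(umis)

    def test_input_order_does_not_matter(self, rng):
        umis = ["AAAA", "AAAT", "AATT", "CCCC"]
        base = [make_group(u, n, "ACGTA") for u, n in zip(umis, [7, 7, 3, 2])]
        reference = None
        for _ in range(5):
            shuffled = base[:]
            rng.shuffle(shuffled)
            clusters = merge_umi_groups(correct_groups(shuffled), cfg())
            key = [(c.representative_umi, sorted(c.absorbed_umis)) for c in clusters]
            if reference is None:
                reference = key
            assert key == reference

    def test_matches_direct_transcription_oracle(self, rng):
        """The greedy max-count procedure agrees with an independent
        line-by-line transcription on randomized instances."""
        for _ in range(200):
            n_groups = rng.randint(1, 10)
            umi_len, seq_len = 4, 6
            seen = set()
            groups = []
            for _ in range(n_groups):
                umi = "".join(rng.choice("ACGT") for _ in range(umi_len))
                if umi in seen:
                    continue
                seen.add(umi)
                groups.append(
                    make_group(
                        umi,
                        rng.randint(1, 12),
                        "".join(rng.choice("ACGT") for _ in range(seq_len)),
                    )
                )
            corrected = correct_groups(groups)
            config = cfg(umi_distance=rng.randint(0, 2), seq_distance=rng.randint(0, 3))
            clusters = merge_umi_groups(corrected, config)
            expected = brute_merge(
                [(cg.umi, cg.count, cg.consensus_r1.sequence, None) for cg in corrected],
                config.UMIdistance,
                config.sequenceDistance,
            )
            got = [(c.representative_umi, sorted(c.absorbed_umis)) for c in clusters]
            assert got == expected
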