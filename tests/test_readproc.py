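"""Read matching, UMI collapse and FASTQ counting against oracles."""

import numpy as np
import pandas as pd
import pytest

from rtmis import simdata
from rtmis.readproc import (CHIMERA, NO_MATCH, FastqFormatError, ProbeMatcher,
                            ReadLayout, collapse_umis, count_fastq)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_match(read: str, panel, layout):
    """Brute-force per-half Hamming scan over every probe, pure Python."""
    best_left = best_right = None
    off = layout.insert_offset
    for p in panel.probes:
        dl = hamming(read[off:off + len(p.left_seq)], p.left_seq)
        dr = hamming(read[off + len(p.left_seq):
                          off + len(p.left_seq) + len(p.right_seq)],
                     p.right_seq)
        if best_left is None or dl < best_left[1]:
            best_left = (p.marker_id, dl, False)
        elif dl == best_left[1]:
            best_left = (best_left[0], dl, True)
        if best_right is None or dr < best_right[1]:
            best_right = (p.marker_id, dr, False)
        elif dr == best_right[1]:
            best_right = (best_right[0], dr, True)
    if (best_left[1] > layout.max_mismatches
            or best_right[1] > layout.max_mismatches
            or best_left[2] or best_right[2]):
        return NO_MATCH
    if best_left[0] != best_right[0]:
        return CHIMERA
    return best_left[0]


class TestMatchRead:
    def test_exact_product_assigned_with_umi(self, panel, layout):
        matcher = ProbeMatcher(panel, layout)
        probe = panel.probe("MME_1")
        read = "ACGTACG" + probe.product
        assert matcher.match(read) == ("MME_1", "ACGTACG")

    def test_two_mismatches_tolerated_three_rejected(self, panel, layout):
        matcher = ProbeMatcher(panel, layout)
        probe = panel.probe("MME_1")
        left = list(probe.left_seq)
        for i in range(2):
            left[i] = "A" if left[i] != "A" else "C"
        read2 = "ACGTACG" + "".join(left) + probe.right_seq
        assert matcher.match(read2)[0] == "MME_1"
        for i in range(3):
            left[i] = "A" if probe.left_seq[i] != "A" else "C"
        read3 = "ACGTACG" + "".join(left) + probe.right_seq
        assert matcher.match(read3)[0] == NO_MATCH

    def test_halves_from_different_probes_is_chimera(self, panel, layout):
        matcher = ProbeMatcher(panel, layout)
        read = ("TTTTTTT" + panel.probe("MME_1").left_seq
                + panel.probe("CD5_1").right_seq)
        assert matcher.match(read)[0] == CHIMERA

    def test_matches_brute_force_oracle_under_errors(self, panel, layout):
        """1000 noisy reads: vectorised matcher equals the Hamming scan."""
        rng = np.random.default_rng(42)
        matcher = ProbeMatcher(panel, layout)
        probes = panel.probes
        for _ in range(1000):
            p = probes[rng.integers(len(probes))]
            read = "ACGTACG" + p.product
            arr = list(read)
            for i in range(len(arr)):
                if rng.random() < 0.01:
                    arr[i] = "ACGT"[rng.integers(4)]
            read = "".join(arr)
            assert matcher.match(read)[0] == oracle_match(read, panel, layout)


class TestCollapseUmis:
    def test_pcr_duplicates_collapse_to_one(self):
        events = [("S1", "MYC_1", "AAAAAAA")] * 5
        cm = collapse_umis(events)
        assert cm.counts.loc["S1", "MYC_1"] == 1

    def test_interpretability_boundary(self):
        def build(n):
            # n distinct UMIs via base-4 expansion of the index
            umis = []
            for i in range(n):
                s, x = "", i
                for _ in range(7):
                    s += "ACGT"[x % 4]
                    x //= 4
                umis.append(s)
            return [("S1", "MYC_1", u) for u in umis]

        assert not collapse_umis(build(4999)).interpretable.loc["S1"]
        assert collapse_umis(build(5000)).interpretable.loc["S1"]

    def test_non_acgt_umi_dropped_as_below_quality(self):
        cm = collapse_umis([("S1", "MYC_1", "AAANAAA"),
                            ("S1", "MYC_1", "CCCCCCC")])
        assert cm.counts.loc["S1", "MYC_1"] == 1
        assert cm.discard_stats.loc["S1", "below_quality"] == 1

    def test_distinct_umi_counts_match_set_oracle(self):
        rng = np.random.default_rng(3)
        markers = [f"G{i}_1" for i in range(10)]
        events = []
        for _ in range(10_000):
            m = markers[rng.integers(10)]
            umi = "".join("ACGT"[b] for b in rng.integers(0, 4, 7))
            events.append(("S1", m, umi))
        cm = collapse_umis(events)
        oracle = {}
        for s, m, u in events:
            oracle.setdefault(m, set()).add(u)
        for m in markers:
            assert cm.counts.loc["S1", m] == len(oracle[m])

    def test_directional_hamming1_merges_errors_into_parent(self):
        events = ([("S1", "A_1", "AAAAAAA")] * 10
                  + [("S1", "A_1", "AAAAAAT")] * 3     # child of the above
                  + [("S1", "A_1", "TTTTTTT")] * 4)    # independent molecule
        exact = collapse_umis(events, umi_collapse="exact")
        merged = collapse_umis(events, umi_collapse="hamming1")
        assert exact.counts.loc["S1", "A_1"] == 3
        assert merged.counts.loc["S1", "A_1"] == 2

    def test_total_umis_is_row_sum(self):
        events = [("S1", "A_1", "AAAAAAA"), ("S1", "B_1", "CCCCCCC"),
                  ("S2", "A_1", "GGGGGGG")]
        cm = collapse_umis(events)
        assert (cm.total_umis == cm.counts.sum(axis=1)).all()


class TestCountFastq:
    def write_fastq(self, path, reads):
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    def test_generator_round_trip_zero_error(self, panel, layout, tmp_path):
        sim = simdata.simulate_cohort(
            simdata.SimConfig(n_per_class=1, depth_median=1500, seed=11))
        row = sim.counts.counts.iloc[0]
        cfg = simdata.SimConfig(seq_error_rate=0.0, chimera_rate=0.0,
                                pcr_duplicate_mean=3.0, seed=11)
        path = tmp_path / "s.fastq"
        simdata.simulate_fastq(row, panel, layout, cfg, str(path), seed=13)
        cm = count_fastq({"S1": path}, panel, layout)
        assert cm.counts.loc["S1"].equals(row.astype(int))

    def test_empty_fastq_zero_row_not_interpretable(self, panel, layout,
                                                    tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        cm = count_fastq({"S1": path}, panel, layout)
        assert cm.counts.loc["S1"].sum() == 0
        assert not cm.interpretable.loc["S1"]

    def test_malformed_fastq_raises(self, panel, layout, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("this is not fastq\nat all\n")
        with pytest.raises(FastqFormatError, match="bad.fastq"):
            count_fastq({"S1": path}, panel, layout)

    def test_read_conservation_and_order_invariance(self, panel, layout,
                                                    tmp_path):
        sim = simdata.simulate_cohort(
            simdata.SimConfig(n_per_class=1, depth_median=800, seed=21))
        row = sim.counts.counts.iloc[0]
        cfg = simdata.SimConfig(seq_error_rate=0.01, chimera_rate=0.03,
                                seed=21)
        path = tmp_path / "s.fastq"
        n_reads = simdata.simulate_fastq(row, panel, layout, cfg, str(path),
                                         seed=23)
        cm = count_fastq({"S1": path}, panel, layout)
        stats = cm.discard_stats.loc["S1"]
        assert stats.sum() == n_reads  # assigned + discards == reads in
        # reversing read order changes nothing
        reads = [line for i, line in
                 enumerate(path.read_text().splitlines()) if i % 4 == 1]
        rev = tmp_path / "rev.fastq"
        self.write_fastq(rev, reads[::-1])
        cm2 = count_fastq({"S1": rev}, panel, layout)
        assert cm2.counts.equals(cm.counts)

    def test_duplication_invariance_and_monotonicity(self, panel, layout,
                                                     tmp_path):
        probe = panel.probe("MME_1")
        base = ["AAAACCC" + probe.product, "GGGTTTA" + probe.product]
        p1 = tmp_path / "a.fastq"
        self.write_fastq(p1, base)
        c1 = count_fastq({"S1": p1}, panel, layout).counts
        p2 = tmp_path / "b.fastq"
        self.write_fastq(p2, base * 3)  # duplicate every read (same UMIs)
        c2 = count_fastq({"S1": p2}, panel, layout).counts
        assert c1.equals(c2)
        p3 = tmp_path / "c.fastq"
        self.write_fastq(p3, base + ["CCCCGGG" + probe.product])
        c3 = count_fastq({"S1": p3}, panel, layout).counts
        assert (c3 >= c1).all().all()

    def test_short_read_counted_below_quality(self, panel, layout, tmp_path):
        path = tmp_path / "short.fastq"
        self.write_fastq(path, ["ACGTACGTT"])
        cm = count_fastq({"S1": path}, panel, layout)
        assert cm.discard_stats.loc["S1", "below_quality"] == 1
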