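"""Guide/UCB extraction, filter cascade and one-to-one assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mosaicscreen.amplicon import (
    GuideLibrary,
    apply_read_filters,
    assign_screen,
    call_cell_assignments,
    clone_stats,
    extract_insert,
    length_filter,
    match_whitelist,
    matches_iupac,
    resolve_ucb,
)

FLANK5 = "TGGAAAGGACGAAACACCG"
FLANK3 = "GTTTTAGAGCTAGAAATAGC"


@pytest.fixture()
def library():
    return GuideLibrary(
        spacers={
            "geneA": ("ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT"),
            "geneB": ("GGGGACGTACGTACGTACGT", "CCCCTTTTAAAAGGGGCCCC"),
            "control": ("GATCGATCGATCGATCGATC", "CTAGCTAGCTAGCTAGCTAG"),
        },
        control_labels=frozenset({"control"}),
    )


class TestExtractInsert:
    INSERT = "ACGTACGTACGTACGTACG"

    def test_exact_flanks(self):
        seq = FLANK5 + self.INSERT + FLANK3
        assert extract_insert(seq, FLANK5, FLANK3) == self.INSERT

    def test_tolerates_ten_percent_errors(self):
        # one substitution per 10 nt in the 5' flank
        mutated = list(FLANK5)
        mutated[2] = "A" if FLANK5[2] != "A" else "C"
        seq = "".join(mutated) + self.INSERT + FLANK3
        assert extract_insert(seq, FLANK5, FLANK3, max_error_rate=0.10) \
            == self.INSERT

    def test_no_flanks_gives_none(self):
        assert extract_insert("ACGT" * 20, FLANK5, FLANK3) is None

    def test_partial_overlap_at_read_ends(self):
        # only the last 5 nt of the 5' flank and first 5 of the 3' flank
        seq = FLANK5[-5:] + self.INSERT + FLANK3[:5]
        assert extract_insert(seq, FLANK5, FLANK3, min_overlap=3) \
            == self.INSERT

    def test_min_overlap_respected(self):
        seq = FLANK5[-2:] + self.INSERT + FLANK3
        assert extract_insert(seq, FLANK5, FLANK3, min_overlap=3) is None

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            extract_insert("ACGT", "", FLANK3)
        with pytest.raises(ValueError):
            extract_insert("ACGT", FLANK5, FLANK3, max_error_rate=0.6)


class TestLengthFilter:
    @pytest.mark.parametrize("n,expected", [(14, False), (15, True),
                                            (21, True), (22, False)])
    def test_guide_length_bounds(self, n, expected):
        assert length_filter("A" * n, "grna") is expected

    def test_ucb_pattern_by_per_position_oracle(self, rng):
        pattern = "NVDNHBNVDNHB"
        table = {"N": "ACGT", "V": "ACG", "D": "AGT", "H": "ACT", "B": "CGT"}
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), 12))
            expected = all(s in table[p] for s, p in zip(seq, pattern))
            assert length_filter(seq, "ucb", ucb_pattern=pattern) is expected
        assert not length_filter("ACG", "ucb", ucb_pattern=pattern)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            length_filter("ACGT", "protein")

    def test_empty_seq(self):
        with pytest.raises(ValueError):
            length_filter("", "grna")


class TestMatchWhitelist:
    def test_exact_match(self, library):
        assert match_whitelist("ACGTACGTACGTACGTACGT", library) == "geneA"

    def test_two_substitutions_match(self, library):
        seq = "TCGTACGTACGTACGTACGA"  # 2 subs of geneA spacer1
        assert match_whitelist(seq, library) == "geneA"

    def test_three_substitutions_fail(self, library):
        seq = "TCGAACGTACGTACGTACGA"
        assert match_whitelist(seq, library) is None

    def test_equidistant_ambiguity_counted(self):
        lib = GuideLibrary(spacers={
            "g1": ("AAAAAAAAAA", "CCCCCCCCCC"),
            "g2": ("AAAAAAAAGG", "TTTTTTTTTT"),
        })
        # distance 1 to both g1 and g2 spacers
        counters = {}
        assert match_whitelist("AAAAAAAAAG", lib, counters=counters) is None
        assert counters["ambiguous"] == 1

    def test_partial_overlap_of_short_insert(self, library):
        # 17-nt insert: suffix of the geneA spacer
        assert match_whitelist("GTACGTACGTACGTACG", library) == "geneA"

    def test_best_distance_from_full_enumeration(self, library, rng):
        """Winning label agrees with brute-force distances to all spacers."""
        def brute_best(seq):
            best = {}
            for label, pair in library.spacers.items():
                dmin = np.inf
                for sp in pair:
                    L, S = len(seq), len(sp)
                    mo = max(min(L, S) - 2, 1)
                    for t in range(-(L - mo), S - mo + 1):
                        lo, hi = max(0, -t), min(L, S - t)
                        if hi - lo < mo:
                            continue
                        d = sum(a != b for a, b in
                                zip(seq[lo:hi], sp[lo + t:hi + t]))
                        dmin = min(dmin, d)
                best[label] = dmin
            return best

        for _ in range(100):
            base = library.spacers["geneA" if rng.random() < 0.5 else "geneB"][
                int(rng.integers(0, 2))]
            seq = list(base)
            for i in rng.choice(len(seq), int(rng.integers(0, 4)),
                                replace=False):
                seq[i] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(seq)
            got = match_whitelist(seq, library)
            best = brute_best(seq)
            dmin = min(best.values())
            winners = [k for k, v in best.items() if v == dmin]
            expected = winners[0] if dmin <= 2 and len(winners) == 1 else None
            assert got == expected


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["cbc", "umi", "label", "reads"])


class TestReadFilters:
    def test_cutoff_is_fraction_of_median_of_cell_maxima(self):
        counts = counts_frame([
            ("c1", "u1", "A", 100),
            ("c2", "u1", "A", 50),
            ("c3", "u1", "A", 10),
            ("c3", "u2", "A", 1),  # cutoff = 0.01 * 50 = 0.5 -> survives
        ])
        out = apply_read_filters(counts)
        assert len(out) == 4

    def test_entries_at_or_below_cutoff_dropped(self):
        counts = counts_frame([
            ("c1", "u1", "A", 300),
            ("c2", "u1", "A", 300),
            ("c3", "u1", "A", 300),
            ("c3", "u2", "A", 3),  # cutoff = 3 -> dropped (strict >)
            ("c3", "u3", "A", 4),  # survives
        ])
        out = apply_read_filters(counts)
        assert set(zip(out.cbc, out.umi)) == {("c1", "u1"), ("c2", "u1"),
                                              ("c3", "u1"), ("c3", "u3")}

    def test_within_umi_twenty_percent_rule(self):
        counts = counts_frame([
            ("c1", "u1", "A", 10),
            ("c1", "u1", "B", 1),   # 1 <= 0.2*10 -> dropped
            ("c1", "u2", "A", 10),
            ("c1", "u2", "B", 3),   # 3 > 2 -> kept
        ])
        out = apply_read_filters(counts)
        kept = set(zip(out.umi, out.label))
        assert ("u1", "B") not in kept
        assert {("u1", "A"), ("u2", "A"), ("u2", "B")} <= kept

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            out = apply_read_filters(counts_frame([]))
        assert out.empty

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["c1", "c2", "c3"]),
                  st.sampled_from(["u1", "u2"]),
                  st.sampled_from(["A", "B"]),
                  st.integers(1, 200)),
        min_size=1, max_size=20, unique_by=lambda r: r[:3]))
    def test_raising_cutoff_shrinks_survivors(self, rows):
        counts = counts_frame(rows)
        low = apply_read_filters(counts, cutoff_fraction=0.01)
        high = apply_read_filters(counts, cutoff_fraction=0.2)
        key = lambda df: set(zip(df.cbc, df.umi, df.label))
        assert key(high) <= key(low)

    def test_permutation_invariance(self, rng):
        rows = [("c%d" % rng.integers(3), "u%d" % rng.integers(3),
                 "AB"[rng.integers(2)], int(rng.integers(1, 100)))
                for _ in range(15)]
        counts = counts_frame(rows).drop_duplicates(["cbc", "umi", "label"])
        a = apply_read_filters(counts)
        b = apply_read_filters(counts.sample(frac=1, random_state=0))
        key = lambda df: sorted(zip(df.cbc, df.umi, df.label, df.reads))
        assert key(a) == key(b)


class TestCallAssignments:
    def test_clear_majority_assigned(self):
        rows = [("c1", f"u{i}", "A", 10) for i in range(5)]
        rows += [("c1", f"v{i}", "B", 10) for i in range(3)]
        out = call_cell_assignments(counts_frame(rows))
        r = out.iloc[0]
        assert (r.label, r.status, r.umi_count) == ("A", "assigned", 5)

    def test_umi_tie_is_ambiguous(self):
        rows = [("c1", f"u{i}", "A", 10) for i in range(5)]
        rows += [("c1", f"v{i}", "B", 10) for i in range(5)]
        out = call_cell_assignments(counts_frame(rows))
        assert out.iloc[0].status == "ambiguous"

    def test_single_read_support_unassigned(self):
        out = call_cell_assignments(counts_frame([("c1", "u1", "A", 1)]))
        assert out.iloc[0].status == "unassigned"

    def test_multiple_single_read_umis_still_unassigned(self):
        rows = [("c1", f"u{i}", "A", 1) for i in range(4)]
        out = call_cell_assignments(counts_frame(rows))
        assert out.iloc[0].status == "unassigned"


class TestUcbResolution:
    def make_reads(self, library, entries):
        rows = []
        for cbc, umi, ucb, reads in entries:
            seq = "AC" + library.ucb_flank5 + ucb + library.ucb_flank3 + "GT"
            rows.append((cbc, umi, seq, reads))
        return pd.DataFrame(rows, columns=["cbc", "umi", "seq", "reads"])

    def test_single_clean_barcode(self, library):
        ucb = "ACAGCTCGATAC"
        assert matches_iupac(ucb, library.ucb_pattern)
        reads = self.make_reads(library, [("c1", f"u{i}", ucb, 5)
                                          for i in range(3)])
        out = resolve_ucb(reads, library)
        r = out.iloc[0]
        assert (r.label, r.status, r.umi_count) == (ucb, "assigned", 3)

    def test_equal_umi_barcodes_ambiguous(self, library):
        reads = self.make_reads(library, [
            ("c1", "u1", "ACAGCTCGATAC", 5), ("c1", "u2", "ACAGCTCGATAC", 5),
            ("c1", "u3", "GCTGAGACTGAT", 5), ("c1", "u4", "GCTGAGACTGAT", 5),
        ])
        out = resolve_ucb(reads, library)
        assert out.iloc[0].status == "ambiguous"

    def test_pattern_violation_excluded(self, library):
        # 'T' at a V position (position 2 of NVD...) violates the pattern
        bad = "ATAGCTCGATAC"
        assert not matches_iupac(bad, library.ucb_pattern)
        good = "ACAGCTCGATAC"
        reads = self.make_reads(library, [
            ("c1", "u1", bad, 50), ("c1", "u2", bad, 50),
            ("c1", "u3", good, 5), ("c1", "u4", good, 5),
        ])
        out = resolve_ucb(reads, library)
        r = out.iloc[0]
        assert (r.label, r.status) == (good, "assigned")


class TestCloneStats:
    def make_assignments(self, sizes):
        rows = []
        i = 0
        for label, ucb, size in sizes:
            for _ in range(size):
                rows.append((f"c{i}", label, ucb, 3, 30, "assigned"))
                i += 1
        return pd.DataFrame(rows, columns=[
            "cbc", "grna_label", "ucb", "umi_count", "read_count", "status"])

    def test_sizes_and_mean(self):
        a = self.make_assignments([("g1", "U1", 3), ("g1", "U2", 2),
                                   ("g2", "U3", 1)])
        st_ = clone_stats(a)
        assert len(st_.clones) == 3
        assert st_.mean_cells_per_clone == pytest.approx(2.0)
        g1 = st_.per_label.set_index("grna_label").loc["g1"]
        assert g1.n_clones == 2 and g1.mean_cells_per_clone == 2.5

    def test_all_unique_ucbs(self):
        a = self.make_assignments([("g1", f"U{i}", 1) for i in range(6)])
        st_ = clone_stats(a)
        assert len(st_.clones) == 6
        assert st_.mean_cells_per_clone == 1.0

    def test_recovers_planted_clones(self, mini_screen):
        truth = mini_screen["truth"]
        meta = mini_screen["meta"]
        assignments = assign_screen(mini_screen["reads"],
                                    mini_screen["library"])
        st_ = clone_stats(assignments, meta)
        truth_clones = (
            pd.DataFrame({"grna": truth.cell_grna, "ucb": truth.cell_ucb})
            .loc[[c for c in truth.cell_grna.index
                  if c not in truth.doublet_cells]]
            .groupby(["grna", "ucb"]).size()
        )
        recovered = st_.clones.set_index(["grna_label", "ucb"])["n_cells"]
        shared = truth_clones.index.intersection(recovered.index)
        # nearly all planted clones recovered at their exact size
        assert len(shared) / len(truth_clones) > 0.95
        assert (recovered.loc[shared] == truth_clones.loc[shared]).mean() > 0.95


class TestEndToEnd:
    def test_cascade_is_order_independent(self, mini_screen):
        reads = mini_screen["reads"]
        lib = mini_screen["library"]
        a = assign_screen(reads, lib)
        b = assign_screen(reads.sample(frac=1, random_state=1), lib)
        a = a.sort_values("cbc").reset_index(drop=True)
        b = b.sort_values("cbc").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_error_free_reads_assign_exactly(self):
        from mosaicscreen.simulate import (
            ScreenConfig, make_guide_library, simulate_cells, simulate_reads,
        )
        cfg = ScreenConfig(seed=5, n_libraries=1, cells_per_library=150,
                           n_grnas=4, control_fraction=0.05,
                           substitution_rate=0.0, doublet_fraction=0.0)
        meta, truth = simulate_cells(cfg)
        lib = make_guide_library(cfg, np.random.default_rng(4))
        reads = simulate_reads(meta, truth, cfg, lib)
        out = assign_screen(reads, lib)
        assigned = out[out.status == "assigned"].set_index("cbc")
        assert (assigned["grna_label"] ==
                truth.cell_grna.loc[assigned.index]).all()
        assert len(assigned) == len(meta)
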