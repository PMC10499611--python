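"""Synthetic screen generator: determinism, planted truth, file contracts."""

import numpy as np
import pandas as pd
import pytest

from mosaicscreen import io as msio
from mosaicscreen.amplicon import GuideLibrary, assign_screen, matches_iupac
from mosaicscreen.fate import circular_coords, validate_fate_matrix
from mosaicscreen.simulate import (
    ScreenConfig,
    default_composition,
    make_guide_library,
    simulate_cells,
    simulate_expression,
    simulate_fates,
    simulate_reads,
    simulate_representation,
    simulate_screen,
)


class TestConfig:
    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="composition"):
            ScreenConfig(seed=1, composition={"RGC": 0.5})

    def test_planted_effect_on_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown cell type"):
            ScreenConfig(seed=1, planted_effects=(("g01", "nope", 1.0),))

    def test_default_composition_is_a_distribution(self):
        comp = default_composition()
        assert sum(comp.values()) == pytest.approx(1.0)


class TestSimulateCells:
    def test_same_seed_identical_output(self):
        cfg = ScreenConfig(seed=42, n_libraries=2, cells_per_library=300)
        m1, t1 = simulate_cells(cfg)
        m2, t2 = simulate_cells(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(t1.cell_ucb, t2.cell_ucb)

    def test_null_composition_matches_baseline(self):
        cfg = ScreenConfig(seed=43, n_libraries=4, cells_per_library=2500)
        meta, _ = simulate_cells(cfg)
        frac = meta["cell_type"].value_counts(normalize=True)
        for ctype, p in cfg.composition.items():
            se = np.sqrt(p * (1 - p) / len(meta))
            assert abs(frac.get(ctype, 0.0) - p) < 5 * se

    def test_planted_log_odds_realized(self):
        cfg = ScreenConfig(
            seed=44, n_libraries=5, cells_per_library=2000, n_grnas=4,
            control_fraction=0.2, planted_effects=(("g01", "IPC", 1.5),),
        )
        meta, _ = simulate_cells(cfg)
        g = meta[meta.grna_label == "g01"]
        c = meta[meta.grna_label == "control"]
        def odds(df):
            p = (df.cell_type == "IPC").mean()
            return p / (1 - p)
        assert abs(np.log(odds(g) / odds(c)) - 1.5) < 0.2

    def test_clone_barcodes_follow_pattern(self):
        cfg = ScreenConfig(seed=45, n_libraries=1, cells_per_library=200)
        _, truth = simulate_cells(cfg)
        assert all(matches_iupac(u, cfg.ucb_pattern)
                   for u in truth.cell_ucb.unique())

    def test_clone_sizes_variable(self):
        cfg = ScreenConfig(seed=46, n_libraries=2, cells_per_library=1000)
        _, truth = simulate_cells(cfg)
        sizes = truth.cell_ucb.value_counts()
        assert sizes.max() > 1
        assert (sizes == 1).any()


class TestSimulateReads:
    def test_error_free_inserts_match_truth(self):
        cfg = ScreenConfig(seed=47, n_libraries=1, cells_per_library=50,
                           n_grnas=3, substitution_rate=0.0,
                           doublet_fraction=0.0)
        meta, truth = simulate_cells(cfg)
        lib = make_guide_library(cfg, np.random.default_rng(0))
        reads = simulate_reads(meta, truth, cfg, lib)
        spacers = {sp for pair in lib.spacers.values() for sp in pair}
        grna_reads = reads[reads.seq.str.contains(lib.flank5)]
        assert len(grna_reads) > 0
        for seq in grna_reads.seq:
            assert any(sp in seq for sp in spacers)

    def test_doublet_fraction_realized(self):
        cfg = ScreenConfig(seed=48, n_libraries=2, cells_per_library=500,
                           n_grnas=5, doublet_fraction=0.05)
        meta, truth = simulate_cells(cfg)
        lib = make_guide_library(cfg, np.random.default_rng(1))
        simulate_reads(meta, truth, cfg, lib)
        frac = len(truth.doublet_cells) / len(meta)
        assert 0.03 < frac < 0.07

    def test_same_seed_identical_reads(self):
        cfg = ScreenConfig(seed=49, n_libraries=1, cells_per_library=100,
                           n_grnas=3)
        meta, truth = simulate_cells(cfg)
        lib = make_guide_library(cfg, np.random.default_rng(2))
        r1 = simulate_reads(meta, truth, cfg, lib)
        meta2, truth2 = simulate_cells(cfg)
        r2 = simulate_reads(meta2, truth2, cfg, lib)
        pd.testing.assert_frame_equal(r1, r2)


class TestSimulateExpression:
    def test_same_seed_identical_matrix(self):
        cfg = ScreenConfig(seed=50, n_libraries=1, cells_per_library=100)
        meta, _ = simulate_cells(cfg)
        e1 = simulate_expression(meta, n_genes=50, seed=9)
        e2 = simulate_expression(meta, n_genes=50, seed=9)
        assert np.array_equal(e1.X, e2.X)
        assert np.array_equal(e1.n_umi, e2.n_umi)

    def test_planted_fold_change_direction(self):
        cfg = ScreenConfig(seed=51, n_libraries=1, cells_per_library=800,
                           n_grnas=2, control_fraction=0.4)
        meta, _ = simulate_cells(cfg)
        expr = simulate_expression(
            meta, n_genes=60, seed=10,
            planted_effects=(("g01", "G0020", 1.5),))
        g = (meta.grna_label == "g01").to_numpy()
        j = expr.genes.index("G0020")
        assert expr.X[g, j].mean() > expr.X[~g, j].mean()

    def test_numi_positive_and_consistent(self):
        cfg = ScreenConfig(seed=52, n_libraries=1, cells_per_library=60)
        meta, _ = simulate_cells(cfg)
        expr = simulate_expression(meta, n_genes=30, seed=11)
        assert (expr.n_umi > 0).all()
        assert expr.X.shape == (60, 30)


class TestSimulateFates:
    def test_rows_sum_to_one(self):
        cfg = ScreenConfig(seed=53, n_libraries=1, cells_per_library=200)
        meta, _ = simulate_cells(cfg)
        fates, emb = simulate_fates(meta, seed=12)
        validate_fate_matrix(fates)
        assert emb.shape == fates.shape

    def test_shifted_grna_has_higher_state_probability(self):
        cfg = ScreenConfig(seed=54, n_libraries=1, cells_per_library=2000,
                           n_grnas=3, control_fraction=0.3)
        meta, _ = simulate_cells(cfg)
        fates, _ = simulate_fates(meta, shifted_grna="g02",
                                  shifted_state="OPC", shift=3.0, seed=13)
        g = (meta.grna_label == "g02").to_numpy()
        assert fates["OPC"].to_numpy()[g].mean() > \
            fates["OPC"].to_numpy()[~g].mean() + 0.2

    def test_symmetric_dirichlet_centroid_near_origin(self):
        cfg = ScreenConfig(seed=55, n_libraries=1, cells_per_library=3000)
        meta, _ = simulate_cells(cfg)
        fates, _ = simulate_fates(meta, seed=14)
        coords = circular_coords(fates)
        assert np.linalg.norm(coords.mean(axis=0)) < 0.05


class TestRepresentationSimulator:
    def test_planted_depletion_shifts_induced_fractions(self):
        rep = simulate_representation(
            n_induced=6, n_uninduced=6, labels=("g01", "g02", "g03"),
            fold_changes={"g02": 0.25}, seed=15)
        ind = rep[rep.induced & (rep.grna == "g02")].fraction.mean()
        unind = rep[~rep.induced & (rep.grna == "g02")].fraction.mean()
        assert ind < unind * 0.5

    def test_fractions_sum_to_one_per_sample(self):
        rep = simulate_representation(seed=16)
        sums = rep.groupby("sample_id").fraction.sum()
        assert np.allclose(sums, 1.0)


class TestScreenEmission:
    def test_emitted_files_validate_and_roundtrip(self, tmp_path):
        cfg = ScreenConfig(seed=56, n_libraries=2, cells_per_library=60,
                           n_grnas=3, control_fraction=0.1)
        paths = simulate_screen(cfg, tmp_path / "run")
        meta = msio.read_cell_meta(paths["meta"])
        assert len(meta) == 120
        wl = msio.read_whitelist(paths["whitelist"])
        lib = GuideLibrary.from_whitelist(wl)
        assert len(lib.spacers) == 4  # 3 guides + control
        expr = msio.read_expression_mtx(paths["mtx"], paths["genes"],
                                        paths["cells"], paths["n_umi"])
        assert expr.n_cells == 120
        fates = msio.read_fate_matrix(paths["fates"])
        validate_fate_matrix(fates)
        reads_tsv = msio.read_read_table(paths["reads"])
        reads_fq = msio.read_fastq_reads(paths["fastq"])
        assert reads_tsv.reads.sum() == reads_fq.reads.sum()

    def test_end_to_end_assignment_recovers_truth(self, mini_screen):
        """The acceptance-suite workhorse at small scale: simulate ->
        assign -> compare with planted truth."""
        truth = mini_screen["truth"]
        out = assign_screen(mini_screen["reads"], mini_screen["library"])
        merged = out.merge(
            pd.DataFrame({"cbc": truth.cell_grna.index,
                          "true": truth.cell_grna.to_numpy()}), on="cbc")
        assigned = merged[merged.status == "assigned"]
        assert (assigned.grna_label == assigned.true).mean() >= 0.99
        doublets = merged[merged.cbc.isin(truth.doublet_cells)]
        assert (doublets.status == "ambiguous").all()
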