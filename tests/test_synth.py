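"""Synthetic-data generator: truth lineages, intensity rendering, study bundles."""

import numpy as np
import pandas as pd
import pytest

from mitohet.quantify import CELL_RECORD_COLUMNS, compute_cv, h_table
from mitohet.simulate import SimConfig
from mitohet.synth import (
    GeneratorConfig,
    copies_to_intensity,
    generate_heteroplasmy_study,
    generate_truth_lineage,
)


@pytest.fixture(scope="module")
def truth_3h():
    cfg = GeneratorConfig(sim=SimConfig(ndau=14, nspl=4), seed=21)
    return cfg, generate_truth_lineage(cfg, duration_h=3.0)


class TestTruthLineage:
    def test_mother_dips_and_recovers(self, truth_3h):
        cfg, truth = truth_3h
        founder = truth[(truth.cell_id == "c0") & (truth.time_h <= 1.5)]
        total = founder.copies0 + founder.copies1
        assert total.iloc[0] == pytest.approx(32)
        assert total.min() < 32 - 0.25 * cfg.sim.ndau
        assert total.iloc[-1] == pytest.approx(32)

    def test_daughter_rises_within_exchange_window(self, truth_3h):
        cfg, truth = truth_3h
        dau = truth[(truth.cell_id == "c1") & (truth.time_h <= 1.5)]
        total = (dau.copies0 + dau.copies1).to_numpy()
        assert total[0] < cfg.sim.ndau  # still filling up
        assert all(b >= a for a, b in zip(total, total[1:]))
        in_window = dau[dau.time_h * 60 <= cfg.exchange_duration_min]
        assert (in_window.copies0 + in_window.copies1).max() <= cfg.sim.ndau + 1e-9

    def test_mother_plus_daughter_reach_double_capacity(self, truth_3h):
        cfg, truth = truth_3h
        end = truth[truth.time_h == 1.5]
        total = (end.copies0 + end.copies1).sum()
        assert total == pytest.approx(2 * cfg.sim.n_copies)

    def test_no_dropout_means_no_empty_cells(self, truth_3h):
        _, truth = truth_3h
        assert ((truth.copies0 + truth.copies1) > 0).all()

    def test_bud_ratio_crosses_matching_stage(self, truth_3h):
        _, truth = truth_3h
        founder = truth[truth.cell_id == "c0"]
        assert founder.bud_ratio.max() >= 0.2


class TestIntensityRendering:
    def test_steady_state_fixed_point(self):
        """Constant copies with no noise or bleaching settle the intensity at
        gain * copies / (k * volume) above the recorded background."""
        cfg = GeneratorConfig(noise_cv=0.0, photobleach_factor=1.0, autofluor=0.0, seed=3)
        frames = np.arange(13)
        truth = pd.DataFrame({
            "cell_id": "x", "parent_id": None, "birth_generation": 0,
            "frame": frames, "time_h": frames * 0.25,
            "copies0": 10.0, "copies1": 6.0, "volume": 40.0, "bud_ratio": np.nan,
        })
        rec = copies_to_intensity(truth, cfg)
        expected_ng = cfg.synthesis_gain * 10.0 / (cfg.protein_decay_k * 40.0)
        assert (rec.i_ng - rec.bg_ng).to_numpy() == pytest.approx(np.full(13, expected_ng), rel=1e-9)

    def test_h_matches_true_fraction_at_steady_state(self):
        cfg = GeneratorConfig(noise_cv=0.0, photobleach_factor=1.0, autofluor=0.0, seed=3)
        frames = np.arange(6)
        truth = pd.concat([
            pd.DataFrame({
                "cell_id": f"x{i}", "parent_id": None, "birth_generation": 0,
                "frame": frames, "time_h": frames * 0.25,
                "copies0": 32.0 * (1 - f), "copies1": 32.0 * f,
                "volume": 40.0, "bud_ratio": np.nan,
            })
            for i, f in enumerate([0.25, 0.5, 0.75])
        ])
        ht = h_table(copies_to_intensity(truth, cfg))
        for i, f in enumerate([0.25, 0.5, 0.75]):
            got = ht[ht.cell_id == f"x{i}"].h
            assert got.to_numpy() == pytest.approx(np.full(6, f), abs=1e-9)

    def test_cap_window_yields_exact_exponential(self):
        cfg = GeneratorConfig(noise_cv=0.0, photobleach_factor=1.0, seed=3,
                              cap_start_h=0.0, cap_end_h=10.0)
        frames = np.arange(25)
        truth = pd.DataFrame({
            "cell_id": "x", "parent_id": None, "birth_generation": 0,
            "frame": frames, "time_h": frames * 0.25,
            "copies0": 16.0, "copies1": 16.0, "volume": 40.0, "bud_ratio": np.nan,
        })
        rec = copies_to_intensity(truth, cfg)
        # protein starts at zero inside the window, so only autofluorescence remains
        assert (rec.i_ng - rec.bg_ng).to_numpy() == pytest.approx(
            np.full(25, cfg.autofluor), rel=1e-9
        )

    def test_record_schema_is_complete(self, truth_3h):
        cfg, truth = truth_3h
        rec = copies_to_intensity(truth, cfg)
        assert set(CELL_RECORD_COLUMNS) <= set(rec.columns)


class TestStudyBundle:
    def test_seeded_bundle_is_byte_identical(self):
        cfg = GeneratorConfig(seed=7)
        a, ta = generate_heteroplasmy_study(cfg, n_populations=2, duration_h=3.0)
        b, tb = generate_heteroplasmy_study(cfg, n_populations=2, duration_h=3.0)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        assert ta.to_csv(index=False) == tb.to_csv(index=False)

    def test_truth_accompanies_observables(self):
        records, truth = generate_heteroplasmy_study(GeneratorConfig(seed=7), 2, 3.0)
        assert set(records.cell_id) == set(truth.cell_id)
        assert "true_fraction" in truth.columns

    def test_pure_founder_classifies_entirely_mkate(self):
        """Every cell of a pure variant-1 lineage scores homo_mKate on the
        volume-corrected h (per-frame median normalization presumes a mixed
        population, so it is bypassed for a homogeneous one)."""
        from mitohet.quantify import compute_h

        cfg = GeneratorConfig(sim=SimConfig(founder_fraction1=1.0), seed=9)
        records, _ = generate_heteroplasmy_study(cfg, n_populations=1, duration_h=3.0)
        ng = (records.i_ng - records.bg_ng).clip(lower=0) / records.volume
        mk = (records.i_mkate - records.bg_mkate).clip(lower=0) / records.volume
        h = compute_h(ng, mk)
        assert (h[~np.isnan(h)] > 0.71).all()

    def test_end_to_end_trimodal_distribution(self):
        """A full study run through quantification shows the trimodal h
        geometry: homoplasmic modes near the edges, heteroplasmic middle."""
        from mitohet.classify import fit_three_gaussians

        cfg = GeneratorConfig(sim=SimConfig(ndau=14, nspl=4), seed=5)
        records, _ = generate_heteroplasmy_study(cfg, n_populations=9, duration_h=8.0)
        parts = [h_table(sub) for _, sub in records.groupby("population")]
        ht = pd.concat(parts, ignore_index=True)
        final = ht[ht.frame == ht.frame.max()].dropna(subset=["h"])
        comps = fit_three_gaussians(final.h.to_numpy())
        assert comps[0].mean < 0.3
        assert 0.35 < comps[1].mean < 0.65
        assert comps[2].mean > 0.7

    def test_dropout_raises_intensity_cv(self):
        """Sporadic total mtDNA loss (the ∆abf2-like condition) inflates the
        cell-to-cell variability of single-variant fluorescence."""
        cvs = {}
        for rate in (0.0, 0.15):
            cfg = GeneratorConfig(
                sim=SimConfig(founder_fraction1=1.0), dropout_rate=rate,
                autofluor=0.0, seed=13,
            )
            records, _ = generate_heteroplasmy_study(cfg, n_populations=3, duration_h=6.0)
            final = records[records.frame == records.frame.max()]
            cvs[rate] = compute_cv((final.i_mkate - final.bg_mkate).clip(lower=0) / final.volume)
        assert cvs[0.15] > cvs[0.0]
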