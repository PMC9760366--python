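"""Synthetic plate and field generators: determinism, noiseless
exactness, Monte-Carlo consistency with the generative model, and
ground-truth bookkeeping."""

import math

import numpy as np
import pytest

import exomod
from exomod.errors import ConfigError, SimulationError
from exomod.simgen import (
    CONTROL_COMPOUNDS,
    MCF7_CONTEXT,
    MDA_CONTEXT,
    TEST_COMPOUNDS,
    ImageSimConfig,
    ScreenSimConfig,
    generate_field_image,
    generate_reference_screen,
    generate_screen_plate,
)


class TestScreenPlate:
    def test_same_seed_gives_identical_tables(self):
        t1, _ = generate_screen_plate(ScreenSimConfig(seed=42))
        t2, _ = generate_screen_plate(ScreenSimConfig(seed=42))
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_different_seed_differs(self):
        t1, _ = generate_screen_plate(ScreenSimConfig(seed=1))
        t2, _ = generate_screen_plate(ScreenSimConfig(seed=2))
        assert not t1["alpha_counts"].equals(t2["alpha_counts"])

    def test_noiseless_multiplier_recovered_exactly(self):
        cfg = ScreenSimConfig(n_compounds=1, effect_multiplier=0.5, noise_cv=0.0)
        table, _ = generate_screen_plate(cfg)
        per_nuc = table["alpha_counts"] / table["nuclei"]
        ctrl = per_nuc[table["condition"] == "vehicle"].mean()
        treated = per_nuc[table["condition"] == "C01"].to_numpy()
        assert np.allclose(treated, 0.5 * ctrl, rtol=0, atol=1e-12)

    def test_percent_of_control_mean_within_3_sem_of_truth(self):
        cfg = ScreenSimConfig(n_compounds=1, effect_multiplier=0.5,
                              noise_cv=0.05, wells_per_condition=6, seed=11)
        table, _ = generate_screen_plate(cfg)
        st = exomod.percent_of_control(table)
        row = st.summary.loc[st.summary["condition"] == "C01"].iloc[0]
        assert abs(row["percent_mean"] - 50.0) <= 3 * row["percent_sem"]

    def test_control_well_cv_matches_noise_cv(self):
        # 200 replicate plates: pooled vehicle-well CV within 20% relative
        cv = 0.05
        values = []
        for seed in range(200):
            cfg = ScreenSimConfig(n_compounds=0, noise_cv=cv, seed=seed)
            table, _ = generate_screen_plate(cfg)
            values.append(table.loc[table["condition"] == "vehicle",
                                    "alpha_counts"].to_numpy())
        values = np.concatenate(values)
        empirical = values.std(ddof=1) / values.mean()
        assert abs(empirical - cv) / cv < 0.20

    def test_plate_contains_assay_control_wells(self):
        table, _ = generate_screen_plate(ScreenSimConfig(n_compounds=2))
        counts = table["condition"].value_counts()
        for label in ("vehicle", "pos_ctrl", "neg_ctrl"):
            assert counts[label] == 6

    @pytest.mark.parametrize("bad", [
        dict(noise_cv=-0.1),
        dict(noise_cv=float("nan")),
        dict(baseline_alpha=float("inf")),
        dict(viability_factor=0.0),
        dict(viability_factor=1.5),
        dict(wells_per_condition=1),
        dict(effect_multiplier=[1.0]),  # wrong length for 14 compounds
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            generate_screen_plate(ScreenSimConfig(**bad))


class TestFieldImage:
    def test_empty_field_has_no_objects(self):
        cfg = ImageSimConfig(n_cells=0, n_artifact_spots=0, seed=0)
        field, truth = generate_field_image(cfg)
        assert truth.cells == [] and truth.granules == []
        # background only: everything close to background level
        assert abs(float(field.pixels.mean()) - cfg.background_level) < 5

    def test_artifacts_only_fall_outside_all_cells(self):
        cfg = ImageSimConfig(granules_per_cell=0.0, n_artifact_spots=5, seed=1)
        field, truth = generate_field_image(cfg)
        assert len(truth.artifacts) == 5 and len(truth.granules) == 0
        for art in truth.artifacts:
            ay, ax = art["centroid"]
            for cell in truth.cells:
                cy, cx = cell["center"]
                d = math.hypot(ay - cy, ax - cx)
                assert d > cfg.cell_radius_px

    def test_truth_bookkeeping_is_self_consistent(self, default_field):
        _, truth = default_field
        per_cell = truth.granules_per_cell()
        assert sum(per_cell.values()) == len(truth.granules)
        assert set(per_cell) == {c["label"] for c in truth.cells}

    def test_same_seed_gives_identical_pixels(self):
        f1, _ = generate_field_image(ImageSimConfig(seed=5))
        f2, _ = generate_field_image(ImageSimConfig(seed=5))
        assert np.array_equal(f1.pixels, f2.pixels)

    def test_overcrowded_field_reports_achieved_count(self):
        cfg = ImageSimConfig(field_shape=(128, 128), n_cells=50, seed=0)
        with pytest.raises(SimulationError) as exc:
            generate_field_image(cfg)
        assert exc.value.achieved is not None and exc.value.achieved < 50

    def test_nucleus_must_be_smaller_than_cell(self):
        with pytest.raises(ConfigError):
            generate_field_image(ImageSimConfig(nucleus_radius_px=40,
                                                cell_radius_px=34))

    def test_tiff_round_trip(self, tmp_path, default_field):
        field, _ = default_field
        path = tmp_path / "field.tiff"
        field.save_tiff(path)
        loaded = exomod.FieldImage.load_tiff(path)
        assert np.array_equal(loaded.pixels, field.pixels)


class TestReferenceScreen:
    def test_regeneration_is_deterministic(self, reference_screen):
        again = generate_reference_screen()
        assert reference_screen.exoscreen.to_csv(index=False) == \
            again.exoscreen.to_csv(index=False)
        assert reference_screen.lbpa.to_csv(index=False) == \
            again.lbpa.to_csv(index=False)

    @pytest.mark.parametrize("context", [MDA_CONTEXT, MCF7_CONTEXT])
    def test_contains_fourteen_test_compounds_plus_controls(self, reference_screen, context):
        sub = reference_screen.exoscreen
        compounds = set(sub.loc[sub["context"] == context, "compound"])
        assert set(TEST_COMPOUNDS) <= compounds
        assert len(TEST_COMPOUNDS) == 14
        assert set(CONTROL_COMPOUNDS) <= compounds

    @pytest.mark.parametrize("context", [MDA_CONTEXT, MCF7_CONTEXT])
    def test_docetaxel_signal_below_cutoff_in_both_contexts(self, reference_screen, context):
        st = exomod.percent_of_control(reference_screen.exoscreen)
        row = st.summary.loc[(st.summary["context"] == context)
                             & (st.summary["condition"] == "docetaxel")]
        assert float(row["percent_mean"].iloc[0]) < 80.0
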