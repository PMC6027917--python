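"""Phantom generator: OPD physics, phenotype structure, determinism."""

import dataclasses

import numpy as np
import pytest

from phasedrop import synth


class TestMakePhantomField:
    def test_empty_field(self, small_geometry):
        ph = synth.make_phantom_field(0, {"undifferentiated": 1.0}, small_geometry, 0)
        assert ph.truth_cells == []
        assert not ph.thickness_map.any()
        assert not ph.truth_label_map.any()

    def test_all_adipocytic_labels_and_droplets(self, small_geometry):
        ph = synth.make_phantom_field(50, {"adipocytic": 1.0}, small_geometry, 7)
        assert len(ph.truth_cells) == 50
        assert all(c.phenotype == "adipocytic" for c in ph.truth_cells)
        assert all(c.droplet_volume_fraction > 0 for c in ph.truth_cells)

    def test_seed_determinism_bitwise(self, small_geometry):
        a = synth.make_phantom_field(
            30, {"adipocytic": 0.4, "undifferentiated": 0.6}, small_geometry, 11
        )
        b = synth.make_phantom_field(
            30, {"adipocytic": 0.4, "undifferentiated": 0.6}, small_geometry, 11
        )
        np.testing.assert_array_equal(a.thickness_map, b.thickness_map)
        np.testing.assert_array_equal(a.refindex_map, b.refindex_map)
        assert a.truth_cells == b.truth_cells

    def test_invalid_inputs(self, small_geometry):
        with pytest.raises(ValueError):
            synth.make_phantom_field(-1, {"undifferentiated": 1.0}, small_geometry, 0)
        with pytest.raises(ValueError):
            synth.make_phantom_field(5, {"undifferentiated": 0.7}, small_geometry, 0)

    def test_phantom_invariants(self, mixed_phantom):
        ph = mixed_phantom
        assert (ph.thickness_map >= 0).all()
        body = ph.thickness_map > 0
        assert (ph.refindex_map[body] >= ph.medium_index).all()
        assert all(0 <= c.droplet_volume_fraction <= 1 for c in ph.truth_cells)


class TestRenderPhaseImage:
    def test_eq1_direct_substitution(self):
        """A 5 um slab of cytoplasm at n=1.380 over medium 1.337 gives 215 nm."""
        geom = synth.PhantomGeometry(field_shape=(8, 8))
        ph = synth.make_phantom_field(0, {"undifferentiated": 1.0}, geom, 0)
        ph.thickness_map[:] = 5000.0
        ph.refindex_map[:] = 1.380
        optics = synth.OpticsConfig(
            field_shape=(8, 8), opd_noise_sd_nm=0, background_drift_amplitude_nm=0
        )
        img = synth.render_phase_image(ph, optics)
        np.testing.assert_allclose(img.opd_map, 215.0, rtol=1e-12)

    def test_zero_contrast(self):
        geom = synth.PhantomGeometry(field_shape=(8, 8))
        ph = synth.make_phantom_field(0, {"undifferentiated": 1.0}, geom, 0)
        ph.thickness_map[:] = 4000.0
        ph.refindex_map[:] = ph.medium_index
        optics = synth.OpticsConfig(
            field_shape=(8, 8), opd_noise_sd_nm=0, background_drift_amplitude_nm=0
        )
        assert not synth.render_phase_image(ph, optics).opd_map.any()

    def test_droplet_index_brighter_than_cytoplasm(self):
        """Same thickness, droplet index vs cytoplasm index: droplet wins."""
        geom = synth.PhantomGeometry()
        d = 3000.0
        assert d * (geom.droplet_index - geom.medium_index) > d * (
            geom.cytoplasm_index - geom.medium_index
        )

    def test_shape_mismatch_raises(self, mixed_phantom):
        with pytest.raises(ValueError):
            synth.render_phase_image(
                mixed_phantom, synth.OpticsConfig(field_shape=(64, 64))
            )

    def test_phenotype_opd_contrast_many_seeds(self, small_geometry):
        """Adipocytic truth cells out-shine undifferentiated ones, 20 fields."""
        for seed in range(20):
            ph = synth.make_phantom_field(
                16,
                {"adipocytic": 0.5, "undifferentiated": 0.5},
                dataclasses.replace(small_geometry, min_separation_frac=1.1),
                seed,
            )
            opd = ph.noiseless_opd
            means = {"adipocytic": [], "undifferentiated": []}
            for cell in ph.truth_cells:
                pix = opd[ph.truth_label_map == cell.cell_id]
                if pix.size:
                    means[cell.phenotype].append(pix.mean())
            assert np.mean(means["adipocytic"]) > np.mean(means["undifferentiated"])


class TestFluorChannels:
    def test_no_dead_cells_death_channel_dark(self, small_geometry):
        ph = synth.make_phantom_field(
            12, {"adipocytic": 0.5, "undifferentiated": 0.5}, small_geometry, 3
        )
        ff = synth.render_fluor_channels(ph, seed=3)
        cfg = synth.StainConfig()
        assert ff.death_channel.max() < 0.5 * cfg.death_amplitude

    def test_lipid_intensity_monotone_in_droplet_fraction(self, sparse_geometry):
        ph = synth.make_phantom_field(6, {"adipocytic": 1.0}, sparse_geometry, 5)
        cfg = synth.StainConfig(illumination_amplitude=0.0, noise_sd=0.0)
        ff = synth.render_fluor_channels(ph, cfg, seed=5)
        integrated = {
            c.cell_id: ff.lipid_channel[ph.truth_label_map == c.cell_id].sum()
            for c in ph.truth_cells
        }
        cells = sorted(ph.truth_cells, key=lambda c: c.droplet_volume_fraction)
        lo, hi = cells[0], cells[-1]
        assert lo.droplet_volume_fraction < hi.droplet_volume_fraction
        assert integrated[lo.cell_id] < integrated[hi.cell_id]

    def test_stain_failure_scales_lipid_only(self, small_geometry):
        ph = synth.make_phantom_field(10, {"adipocytic": 1.0}, small_geometry, 9)
        base = synth.StainConfig(noise_sd=0.0, background_level=0.0)
        ok = synth.render_fluor_channels(ph, base, seed=9)
        bad = synth.render_fluor_channels(
            ph, dataclasses.replace(base, stain_failure=True), seed=9
        )
        np.testing.assert_array_equal(ok.nuclear_channel, bad.nuclear_channel)
        np.testing.assert_allclose(
            bad.lipid_channel,
            ok.lipid_channel * base.stain_failure_scale,
            atol=1e-9,
        )


class TestTimecourse:
    def test_uninduced_stays_at_baseline(self, small_geometry, small_optics):
        cfg = synth.TimecourseConfig(
            geometry=small_geometry,
            optics=small_optics,
            cells_per_field=25,
            fields_per_well=2,
            n_wells_per_arm=8,
            render_fluor=False,
        )
        _, truth = synth.simulate_timecourse(6, induced=False, config=cfg, seed=2)
        day6 = truth[truth.day == 6]
        # binomial sampling error around the 5% spontaneous baseline
        assert abs(day6.realized_adipocytic.mean() - 0.05) < 0.03

    def test_induced_truth_nondecreasing(self):
        cfg = synth.TimecourseConfig()
        fracs = [synth.induced_fraction_curve(d, cfg) for d in range(1, 7)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == pytest.approx(cfg.baseline_fraction)

    def test_day1_arms_equal(self, small_geometry, small_optics):
        cfg = synth.TimecourseConfig(
            geometry=small_geometry,
            optics=small_optics,
            cells_per_field=25,
            fields_per_well=2,
            n_wells_per_arm=3,
            render_fluor=False,
        )
        _, t_ind = synth.simulate_timecourse(1, True, cfg, seed=8)
        _, t_ctl = synth.simulate_timecourse(1, False, cfg, seed=8)
        assert (
            t_ind.expected_adipocytic.to_numpy()
            == t_ctl.expected_adipocytic.to_numpy()
        ).all()

    def test_days_must_be_positive(self):
        with pytest.raises(ValueError):
            synth.simulate_timecourse(0, True)


class TestDoseResponse:
    def test_hill_midpoint(self):
        m = synth.CompoundResponse(direction="antagonist", true_ec50=1e-6)
        mid = synth.expected_adipocytic_fraction(m, 1e-6)
        assert mid == pytest.approx(0.5 * (m.baseline_fraction + m.max_fraction))

    def test_agonist_low_dose_asymptote(self):
        m = synth.CompoundResponse(direction="agonist", true_ec50=1e-6)
        assert synth.expected_adipocytic_fraction(m, 1e-15) == pytest.approx(
            m.baseline_fraction, abs=1e-6
        )

    def test_truth_monotone_in_concentration(self):
        conc = synth.dose_series()
        for direction in ("agonist", "antagonist"):
            m = synth.CompoundResponse(direction=direction, true_ec50=1e-6)
            f = [synth.expected_adipocytic_fraction(m, c) for c in conc]
            diffs = np.diff(f)  # conc descending
            assert (diffs <= 0).all() if direction == "agonist" else (diffs >= 0).all()

    def test_toxic_concentration_raises_dead_fraction(self):
        m = synth.CompoundResponse(
            direction="antagonist", true_ec50=1e-6, toxicity_threshold=10e-6
        )
        base = 0.02
        assert synth.expected_dead_fraction(m, 30e-6, base) > base
        assert synth.expected_dead_fraction(m, 1e-6, base) == pytest.approx(base)

    def test_unknown_compound_rejected(self, small_geometry, small_optics):
        layout = synth.PlateLayout(
            wells=(
                synth.WellSpec("w1", compound="mystery", concentration=1e-6),
            )
        )
        with pytest.raises(KeyError):
            synth.simulate_dose_response_plate(layout, {}, seed=0)

    def test_plate_truth_and_determinism(self, small_geometry, small_optics):
        cfg = synth.SimulationConfig(
            geometry=small_geometry,
            optics=small_optics,
            cells_per_field=20,
            fields_per_well=1,
            render_fluor=False,
        )
        model = {
            "cmp": synth.CompoundResponse(direction="antagonist", true_ec50=1e-6)
        }
        layout = synth.PlateLayout(
            wells=tuple(
                synth.WellSpec(f"w{i}", "cmp", float(c), induced=True, n_fields=1)
                for i, c in enumerate(synth.dose_series(n=5))
            )
        )
        _, t1 = synth.simulate_dose_response_plate(layout, model, cfg, seed=4)
        _, t2 = synth.simulate_dose_response_plate(layout, model, cfg, seed=4)
        assert t1.equals(t2)
        assert (t1.realized_adipocytic >= 0).all()
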