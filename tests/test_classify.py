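"""Cell feature extraction and phenotype classification."""

import dataclasses
import math

import numpy as np
import pytest

from phasedrop import classify, evaluate, phase, synth


def make_record(**kwargs) -> classify.CellRecord:
    defaults = dict(
        cell_id=1,
        centroid=(10.0, 10.0),
        area_um2=900.0,
        perimeter_um=110.0,
        form_factor=0.9,
        eccentricity=0.3,
        mean_opd_nm=80.0,
        integrated_opd=72000.0,
        opd_sd_nm=10.0,
        opd_p90_nm=95.0,
    )
    defaults.update(kwargs)
    return classify.CellRecord(**defaults)


def shape_image(binary: np.ndarray, value: float = 100.0) -> np.ndarray:
    return binary.astype(float) * value


def segment(img: np.ndarray) -> phase.LabeledMask:
    return phase.fixed_threshold_segment(img, min_area_um2=4.0, pixel_size_um=1.0)


class TestExtractCellFeatures:
    def test_circle_geometry(self):
        rr = np.arange(128)[:, None]
        cc = np.arange(128)[None, :]
        r = 20
        img = shape_image((rr - 64) ** 2 + (cc - 64) ** 2 < r**2)
        recs = classify.extract_cell_features(img, segment(img), pixel_size_um=1.0)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.area_um2 == pytest.approx(math.pi * r**2, rel=0.05)
        assert rec.form_factor >= 0.95
        assert rec.phenotype == "error"  # not yet classified

    def test_elongated_ellipse(self):
        rr = np.arange(128)[:, None]
        cc = np.arange(128)[None, :]
        circle = shape_image((rr - 64) ** 2 + (cc - 64) ** 2 < 15**2)
        ellipse = shape_image(((rr - 64) / 10) ** 2 + ((cc - 64) / 30) ** 2 < 1)
        rec_c = classify.extract_cell_features(circle, segment(circle), 1.0)[0]
        rec_e = classify.extract_cell_features(ellipse, segment(ellipse), 1.0)[0]
        assert rec_e.eccentricity > 0.9
        assert rec_e.form_factor < rec_c.form_factor

    def test_constant_opd_integrates(self):
        rr = np.arange(64)[:, None]
        cc = np.arange(64)[None, :]
        img = shape_image((rr - 32) ** 2 + (cc - 32) ** 2 < 10**2, value=215.0)
        rec = classify.extract_cell_features(img, segment(img), 1.0)[0]
        assert rec.mean_opd_nm == pytest.approx(215.0)
        assert rec.integrated_opd == pytest.approx(215.0 * rec.area_um2)

    def test_border_objects_get_no_record(self):
        rr = np.arange(64)[:, None]
        cc = np.arange(64)[None, :]
        img = shape_image((rr - 0) ** 2 + (cc - 32) ** 2 < 10**2)
        assert classify.extract_cell_features(img, segment(img), 1.0) == []


class TestRuleClassification:
    def test_large_low_opd_is_undifferentiated(self):
        recs = classify.classify_cells_rules([make_record(mean_opd_nm=80.0)])
        assert recs[0].phenotype == "undifferentiated"

    def test_large_high_opd_is_adipocytic(self):
        recs = classify.classify_cells_rules([make_record(mean_opd_nm=180.0)])
        assert recs[0].phenotype == "adipocytic"

    def test_small_round_high_opd_is_dead(self):
        recs = classify.classify_cells_rules(
            [make_record(area_um2=60.0, form_factor=0.95, mean_opd_nm=180.0)]
        )
        assert recs[0].phenotype == "dead"

    def test_small_low_opd_debris_is_error(self):
        recs = classify.classify_cells_rules(
            [make_record(area_um2=60.0, form_factor=0.95, mean_opd_nm=30.0)]
        )
        assert recs[0].phenotype == "error"

    def test_rules_match_truth_on_separated_regimes(self, quiet_optics):
        """Noise-free phantoms with well-separated phenotype parameters:
        rule calls agree with simulator truth for >= 99% of cells."""
        geom = dataclasses.replace(
            synth.PhantomGeometry(field_shape=(384, 384)),
            min_separation_frac=1.15,
            placement_margin_frac=0.15,
            spread_thickness_nm=(3000.0, 4200.0),
            droplet_area_fraction=(0.25, 0.45),
            dead_radius_um=(4.0, 7.0),
            dead_thickness_nm=(7000.0, 10000.0),
        )
        optics = dataclasses.replace(quiet_optics, field_shape=(384, 384))
        agree = total = 0
        for seed in range(16):
            ph = synth.make_phantom_field(
                6,
                {"undifferentiated": 0.45, "adipocytic": 0.4, "dead": 0.15},
                geom,
                seed,
            )
            img = synth.render_phase_image(ph, optics)
            mask = phase.fixed_threshold_segment(img)
            recs = classify.extract_cell_features(img, mask)
            truth = evaluate.truth_phenotypes_for_records(recs, mask, ph)
            recs = classify.classify_cells_rules(recs)
            for rec, t in zip(recs, truth):
                if t is not None:
                    total += 1
                    agree += rec.phenotype == t
        assert total > 80
        assert agree / total >= 0.99


class TestTrainedClassifier:
    @pytest.fixture(scope="class")
    def labelled_records(self):
        rng = np.random.default_rng(5)
        records, labels = [], []
        for phenotype, n in (("undifferentiated", 80), ("adipocytic", 80), ("dead", 40)):
            for _ in range(n):
                if phenotype == "dead":
                    rec = make_record(
                        area_um2=rng.uniform(40, 180),
                        form_factor=rng.uniform(0.86, 1.0),
                        mean_opd_nm=rng.uniform(130, 220),
                        opd_p90_nm=rng.uniform(150, 260),
                    )
                elif phenotype == "adipocytic":
                    rec = make_record(
                        area_um2=rng.uniform(400, 2500),
                        mean_opd_nm=rng.uniform(100, 260),
                        opd_p90_nm=rng.uniform(200, 500),
                    )
                else:
                    rec = make_record(
                        area_um2=rng.uniform(400, 2500),
                        mean_opd_nm=rng.uniform(50, 115),
                        opd_p90_nm=rng.uniform(60, 150),
                    )
                records.append(rec)
                labels.append(phenotype)
        return records, labels

    def test_deterministic_given_seed(self, labelled_records):
        records, labels = labelled_records
        m1 = classify.train_cell_classifier(records, labels, seed=3)
        m2 = classify.train_cell_classifier(records, labels, seed=3)
        p1, _ = classify.apply_cell_classifier(m1, records)
        p2, _ = classify.apply_cell_classifier(m2, records)
        assert [r.phenotype for r in p1] == [r.phenotype for r in p2]

    def test_resubstitution_beats_rules(self, labelled_records):
        records, labels = labelled_records
        model = classify.train_cell_classifier(records, labels, seed=0)
        predicted, _ = classify.apply_cell_classifier(model, records)
        acc_model = np.mean([r.phenotype == t for r, t in zip(predicted, labels)])
        ruled = classify.classify_cells_rules(records)
        acc_rules = np.mean([r.phenotype == t for r, t in zip(ruled, labels)])
        assert acc_model >= acc_rules

    def test_one_nearest_neighbour_resubstitution_is_perfect(self, labelled_records):
        records, labels = labelled_records
        model = classify.train_cell_classifier(
            records, labels, algorithm="k_neighbors", n_neighbors=1
        )
        predicted, _ = classify.apply_cell_classifier(model, records)
        assert all(r.phenotype == t for r, t in zip(predicted, labels))

    def test_counts_partition_records(self, labelled_records):
        records, labels = labelled_records
        model = classify.train_cell_classifier(records, labels, seed=0)
        predicted, counts = classify.apply_cell_classifier(model, records)
        assert sum(counts.values()) == len(predicted) == len(records)

    def test_single_class_rejected(self):
        recs = [make_record(), make_record(cell_id=2)]
        with pytest.raises(ValueError):
            classify.train_cell_classifier(recs, ["dead", "dead"])

    def test_save_load_round_trip(self, labelled_records, tmp_path):
        records, labels = labelled_records
        model = classify.train_cell_classifier(records, labels, seed=0)
        path = tmp_path / "model.joblib"
        classify.save_classifier(model, path)
        loaded = classify.load_classifier(path)
        p1, _ = classify.apply_cell_classifier(model, records)
        p2, _ = classify.apply_cell_classifier(loaded, records)
        assert [r.phenotype for r in p1] == [r.phenotype for r in p2]


class TestDeadFraction:
    @pytest.mark.parametrize(
        "phenotypes,expected",
        [
            (["dead"] * 2 + ["adipocytic"] * 8, 0.2),
            (["adipocytic"] * 5, 0.0),
            (["dead"] * 3, 1.0),
        ],
    )
    def test_fractions(self, phenotypes, expected):
        recs = [
            dataclasses.replace(make_record(cell_id=i), phenotype=p)
            for i, p in enumerate(phenotypes)
        ]
        assert classify.dead_fraction(recs) == pytest.approx(expected)

    def test_no_records_flagged(self):
        assert math.isnan(classify.dead_fraction([]))

    def test_errors_excluded_from_denominator(self):
        recs = [
            dataclasses.replace(make_record(cell_id=i), phenotype=p)
            for i, p in enumerate(["dead", "error", "adipocytic", "error"])
        ]
        assert classify.dead_fraction(recs) == pytest.approx(0.5)
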