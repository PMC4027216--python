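"""Synthetic-data generator: determinism, construction fidelity, and the
statistical contracts the downstream analysis relies on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skimage.draw import ellipse as draw_ellipse

from hdrscreen import (FourPL, NoiseModel, PlateSpec, WellSpec, derive_seed,
                       generate_dose_response, generate_field, generate_plate,
                       simulate_well_counts)
from hdrscreen.segmentation import make_rings, segment_nuclei
from scipy import ndimage as ndi


def well(**kw):
    base = dict(well_id="A1", n_cells=50, translocation_fraction=1.0,
                apoptotic_fraction=0.0, dead_fraction=0.0)
    base.update(kw)
    return WellSpec(**base)


class TestGenerateField:
    def test_empty_field_is_background_only(self):
        image, truth = generate_field(well(n_cells=0), seed=3)
        assert len(truth) == 0
        assert image.dapi.shape == (512, 512)
        # background plus noise only: nowhere near a nucleus intensity
        assert image.dapi.max() < 1000

    def test_counts_by_construction(self):
        image, truth = generate_field(
            well(translocation_fraction=1.0, true_hdr_fraction=0.0), seed=5)
        assert truth["translocated"].all()
        assert not truth["gfp_positive"].any()

    def test_same_seed_bit_identical(self):
        a, ta = generate_field(well(), seed=42)
        b, tb = generate_field(well(), seed=42)
        for ch in ("dapi", "mcherry", "gfp"):
            np.testing.assert_array_equal(getattr(a, ch), getattr(b, ch))
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_differs(self):
        a, _ = generate_field(well(), seed=1)
        b, _ = generate_field(well(), seed=2)
        assert not np.array_equal(a.dapi, b.dapi)

    def test_gfp_only_in_positive_nuclei(self):
        image, truth = generate_field(
            well(true_hdr_fraction=0.5), seed=9,
            plate_noise=NoiseModel(read_noise_sd=0.0, shot_scale=0.0))
        pos = truth[truth["gfp_positive"]]
        neg = truth[~truth["gfp_positive"]]
        assert len(pos) and len(neg)
        for t in pos.itertuples():
            rr, cc = draw_ellipse(t.center_r, t.center_c,
                                  0.7 * t.radius_major, 0.7 * t.radius_minor,
                                  shape=image.gfp.shape, rotation=t.orientation)
            assert image.gfp[rr, cc].mean() > 500
        for t in neg.itertuples():
            rr, cc = draw_ellipse(t.center_r, t.center_c,
                                  0.7 * t.radius_major, 0.7 * t.radius_minor,
                                  shape=image.gfp.shape, rotation=t.orientation)
            assert image.gfp[rr, cc].mean() < 300

    def test_uint16_export_round(self):
        image, _ = generate_field(well(n_cells=5), seed=0)
        u16 = image.to_uint16()
        assert all(v.dtype == np.uint16 for v in u16.values())


class TestConstructionFidelity:
    """Rendered mCherry partition matches the drawn translocation state."""

    @staticmethod
    def _nc_pairs(image, truth):
        label_map = segment_nuclei(image.dapi)
        rings = make_rings(label_map.labels)
        pairs = []
        for t in truth.itertuples():
            if t.phenotype != "healthy":
                continue
            lab = label_map.labels[int(round(t.center_r)), int(round(t.center_c))]
            if lab == 0 or lab in rings.ring_failed:
                continue
            nuc = ndi.mean(image.mcherry, label_map.labels, lab)
            ring = ndi.mean(image.mcherry, rings.rings, lab)
            pairs.append((t.translocated, nuc, ring))
        return pairs

    def test_translocated_nuclear_exceeds_ring_before_noise(self):
        spec = well(n_cells=80)
        image, truth = generate_field(spec, seed=21, apply_noise=False)
        pairs = self._nc_pairs(image, truth)
        assert len(pairs) > 50
        assert all(nuc > ring for tr, nuc, ring in pairs if tr)

    def test_translocated_nuclear_exceeds_ring_after_noise(self):
        spec = well(n_cells=80)
        image, truth = generate_field(spec, seed=21)
        pairs = self._nc_pairs(image, truth)
        frac = np.mean([nuc > ring for tr, nuc, ring in pairs if tr])
        assert frac >= 0.95

    def test_apoptotic_cv_exceeds_healthy_before_noise(self):
        spec = well(n_cells=60, apoptotic_fraction=0.5)
        image, truth = generate_field(spec, seed=13, apply_noise=False)
        cvs = {"healthy": [], "apoptotic": []}
        for t in truth.itertuples():
            if t.phenotype == "dead":
                continue
            rr, cc = draw_ellipse(t.center_r, t.center_c,
                                  0.85 * t.radius_major, 0.85 * t.radius_minor,
                                  shape=image.dapi.shape, rotation=t.orientation)
            px = image.dapi[rr, cc]
            cvs[t.phenotype].append(px.std() / px.mean())
        assert len(cvs["apoptotic"]) and len(cvs["healthy"])
        assert min(cvs["apoptotic"]) > max(cvs["healthy"])


class TestGeneratePlate:
    def test_manifest_has_one_record_per_field(self):
        wells = tuple(well(well_id=w, n_cells=0)
                      for w in [f"{r}{c}" for r in "ABCDEFGH"
                                for c in range(1, 13)])
        spec = PlateSpec(plate_id="P1", wells=wells, fields_per_well=12,
                         image_shape=(64, 64), rng_seed=1)
        plate = generate_plate(spec)
        fields = plate.manifest[["well", "field"]].drop_duplicates()
        assert len(fields) == 96 * 12
        assert len(plate.manifest) == 96 * 12 * 3  # one row per channel

    def test_duplicate_well_rejected_with_name(self):
        with pytest.raises(ValueError, match="B2"):
            PlateSpec(plate_id="P1",
                      wells=(well(well_id="B2"), well(well_id="B2")))

    def test_same_seed_identical_images(self):
        wells = tuple(well(well_id=w, n_cells=10) for w in ("A1", "A2"))
        spec = PlateSpec(plate_id="P1", wells=wells, fields_per_well=2,
                         image_shape=(128, 128), rng_seed=7)
        a = generate_plate(spec)
        b = generate_plate(spec)
        for key in a.images:
            np.testing.assert_array_equal(a.images[key].dapi, b.images[key].dapi)
            np.testing.assert_array_equal(a.images[key].gfp, b.images[key].gfp)
        pd.testing.assert_frame_equal(a.cell_truth, b.cell_truth)

    def test_pooled_gfp_fraction_matches_hdr_rate(self):
        p = 0.05
        wells = tuple(well(well_id=f"A{c}", n_cells=40, true_hdr_fraction=p)
                      for c in range(1, 13))
        spec = PlateSpec(plate_id="P1", wells=wells, fields_per_well=1,
                         image_shape=(350, 350), rng_seed=3)
        plate = generate_plate(spec)
        trans = plate.cell_truth[plate.cell_truth["translocated"]]
        k, n = int(trans["gfp_positive"].sum()), len(trans)
        assert n > 300
        # exact binomial oracle: the draw must be consistent with rate p
        assert stats.binomtest(k, n, p).pvalue > 0.01

    def test_well_truth_accounting(self):
        wells = (well(well_id="A1", n_cells=20, true_hdr_fraction=1.0),)
        plate = generate_plate(PlateSpec(
            plate_id="P", wells=wells, fields_per_well=2,
            image_shape=(256, 256), rng_seed=0))
        row = plate.well_truth.iloc[0]
        assert row["n_cells"] == len(plate.cell_truth)
        assert row["n_gfp_positive"] == row["n_translocated"]


class TestWellCounts:
    def test_gfp_counts_binomial_over_96_wells(self):
        """Chi-square goodness of fit of per-well GFP-positive counts against
        Binomial(n_selected, true_hdr_fraction), alpha = 0.01."""
        p = 0.03
        wells = [well(well_id=w, n_cells=2500, translocation_fraction=0.8,
                      true_hdr_fraction=p)
                 for w in [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]]
        counts = simulate_well_counts(wells, seed=2024)
        n = counts["n_selected"].to_numpy(dtype=float)
        x = counts["n_gfp_positive"].to_numpy(dtype=float)
        chi2 = np.sum((x - n * p) ** 2 / (n * p * (1 - p)))
        assert stats.chi2.sf(chi2, df=96) > 0.01

    def test_counts_are_nested(self):
        counts = simulate_well_counts([well(well_id="A1", n_cells=100,
                                            translocation_fraction=0.5,
                                            true_hdr_fraction=0.2)], seed=1)
        row = counts.iloc[0]
        assert 0 <= row["n_gfp_positive"] <= row["n_selected"] <= row["n_detected"]


class TestDeriveSeed:
    def test_stable_and_distinct(self):
        assert derive_seed(1, "A1", 0) == derive_seed(1, "A1", 0)
        assert derive_seed(1, "A1", 0) != derive_seed(1, "A1", 1)
        assert 0 <= derive_seed(99, "H12", 11) < 2**31


class TestDoseResponseTable:
    def test_zero_noise_on_curve(self):
        p = FourPL(bottom=0, top=100, hill=1, ec50=10)
        df = generate_dose_response(p, [1, 10, 100], noise_sd=0, n_replicates=2)
        np.testing.assert_allclose(
            df["response"], p.predict(df["concentration_uM"]))

    def test_midpoint_identity(self):
        p = FourPL(bottom=20, top=80, hill=2, ec50=7.5)
        df = generate_dose_response(p, [7.5], noise_sd=0)
        assert df["response"].iloc[0] == pytest.approx((80 + 20) / 2)

    def test_row_count(self):
        p = FourPL(bottom=0, top=100, hill=1, ec50=10)
        df = generate_dose_response(p, np.geomspace(0.1, 100, 8),
                                    noise_sd=1.0, n_replicates=3, seed=0)
        assert len(df) == 24

    def test_nonpositive_concentration_rejected(self):
        p = FourPL(bottom=0, top=100, hill=1, ec50=10)
        with pytest.raises(ValueError, match="positive"):
            generate_dose_response(p, [0.0, 1.0], noise_sd=0)


class TestSpecValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="true_hdr_fraction"):
            WellSpec(well_id="A1", true_hdr_fraction=1.5)

    def test_gfp_requires_translocation(self):
        from hdrscreen import CellSpec
        with pytest.raises(ValueError, match="translocated"):
            CellSpec(center=(5, 5), radii=(5, 4), orientation=0.0,
                     phenotype="healthy", translocated=False,
                     gfp_positive=True, dapi_level=1, mcherry_nuc_level=1,
                     mcherry_cyto_level=1, gfp_nuc_level=1)
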