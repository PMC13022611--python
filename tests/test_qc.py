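"""Patch QC: Otsu thresholding, tissue fractions, two-stage filtering."""

import numpy as np
import pytest

from conftest import make_texture_patches
from wsimil import qc
from wsimil.tiling import PatchRecord, PatchSpec


def make_patch(gray_values: np.ndarray, pad_mask=None) -> PatchRecord:
    """Gray image -> RGB PatchRecord with given padding mask."""
    g = np.asarray(gray_values, dtype=np.uint8)
    pixels = np.repeat(g[..., None], 3, axis=2)
    if pad_mask is None:
        pad_mask = np.zeros(g.shape, dtype=bool)
    return PatchRecord("s", PatchSpec(0, 0, 0, 0), pixels, pad_mask)


class TestOtsu:
    def test_bimodal_histogram_threshold_separates_modes(self):
        img = np.concatenate([np.full(500, 50.0), np.full(500, 200.0)])
        t = qc.compute_scan_otsu(img)
        assert 50 < t <= 200

    def test_exhaustive_between_class_variance_agrees(self):
        rng = np.random.default_rng(0)
        img = np.concatenate(
            [rng.normal(60, 10, 4000), rng.normal(210, 12, 6000)]
        ).clip(0, 255)
        t = qc.compute_scan_otsu(img)
        # brute-force maximization of between-class variance over 256 levels
        best_t, best_v = None, -1.0
        for cand in np.linspace(img.min(), img.max(), 256):
            lo, hi = img[img < cand], img[img >= cand]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / img.size, hi.size / img.size
            v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, cand
        assert abs(t - best_t) < 5.0

    def test_constant_image_returns_constant(self):
        assert qc.compute_scan_otsu(np.full((10, 10), 77.0)) == 77.0

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            qc.compute_scan_otsu(np.zeros((0,)))

    def test_valid_mask_excludes_padding(self):
        img = np.full((10, 10), 200.0)
        img[:, :5] = 0.0  # fake padding
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, 5:] = True
        assert qc.compute_scan_otsu(img, valid_mask=mask) == 200.0


class TestTissueFraction:
    def test_all_white_patch_is_zero(self):
        assert qc.tissue_fraction(make_patch(np.full((8, 8), 255)), 128.0) == 0.0

    def test_half_dark_half_bright_is_half(self):
        g = np.full((10, 10), 250)
        g[:5] = 10
        assert qc.tissue_fraction(make_patch(g), 128.0) == 0.5

    def test_fully_padded_patch_is_zero(self):
        patch = make_patch(np.zeros((8, 8)), pad_mask=np.ones((8, 8), dtype=bool))
        assert qc.tissue_fraction(patch, 128.0) == 0.0

    def test_padding_excluded_from_both_counts(self):
        g = np.zeros((10, 10))
        g[:, 5:] = 255
        pad = np.zeros((10, 10), dtype=bool)
        pad[:, :5] = True  # the dark half is padding
        assert qc.tissue_fraction(make_patch(g, pad), 128.0) == 0.0

    def test_invariant_to_pixel_permutation(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 256, size=(12, 12))
        f1 = qc.tissue_fraction(make_patch(g), 100.0)
        f2 = qc.tissue_fraction(make_patch(rng.permuted(g.ravel()).reshape(12, 12)), 100.0)
        assert f1 == f2


class TestTissueFilter:
    def boundary_patch(self, n_dark: int) -> PatchRecord:
        g = np.full(100, 255)
        g[:n_dark] = 10
        return make_patch(g.reshape(10, 10))

    def test_strict_inequality_at_20_percent(self):
        """19% tissue is rejected; 21% is retained; exactly 20% is retained."""
        for n_dark, expected in [(19, "low_tissue_rejected"), (20, "retained"), (21, "retained")]:
            patch = self.boundary_patch(n_dark)
            qc.apply_tissue_filter([patch], 128.0)
            assert patch.qc_status == expected, n_dark

    def test_zero_minimum_rejects_nothing(self):
        patch = self.boundary_patch(0)
        qc.apply_tissue_filter([patch], 128.0, qc.QCConfig(min_tissue_fraction=0.0))
        assert patch.qc_status == "retained"

    def test_counts_partition_total(self):
        patches = [self.boundary_patch(k) for k in (0, 10, 30, 90)]
        _, report = qc.apply_tissue_filter(patches, 128.0)
        assert sum(report.counts.values()) == len(patches)
        assert report.counts["low_tissue_rejected"] == 2

    def test_all_rejected_scan_still_reports(self):
        patches = [self.boundary_patch(0) for _ in range(4)]
        filtered, report = qc.apply_tissue_filter(patches, 128.0)
        assert report.counts["retained"] == 0
        assert len(filtered) == 4


@pytest.fixture(scope="module")
def pen_model():
    rng = np.random.default_rng(21)
    x = np.concatenate(
        [make_texture_patches(rng, 60, "plain"), make_texture_patches(rng, 60, "pen")]
    )
    y = np.repeat([0, 1], 60)
    return qc.train_artifact_filter(x, y)


class TestArtifactFilter:
    def test_known_artifact_patches_rejected_exactly(self, pen_model):
        rng = np.random.default_rng(22)
        tissue = make_texture_patches(rng, 20, "plain")
        pen = make_texture_patches(rng, 10, "pen")
        records = [
            PatchRecord("s", PatchSpec(0, 0, 0, 0), p, np.zeros((32, 32), bool))
            for p in np.concatenate([tissue, pen])
        ]
        qc.apply_artifact_filter(records, pen_model)
        statuses = [r.qc_status for r in records]
        assert statuses[:20] == ["retained"] * 20
        assert statuses[20:] == ["artifact_rejected"] * 10

    def test_threshold_extremes(self, pen_model):
        rng = np.random.default_rng(23)
        pens = make_texture_patches(rng, 5, "pen")
        recs = [PatchRecord("s", PatchSpec(0, 0, 0, 0), p, np.zeros((32, 32), bool)) for p in pens]
        qc.apply_artifact_filter(recs, pen_model, qc.QCConfig(artifact_threshold=1.0))
        assert all(r.qc_status == "retained" for r in recs)
        qc.apply_artifact_filter(recs, pen_model, qc.QCConfig(artifact_threshold=0.0))
        assert all(r.qc_status == "artifact_rejected" for r in recs)  # sigmoid p > 0 always

    def test_training_rejects_degenerate_inputs(self):
        rng = np.random.default_rng(24)
        x = make_texture_patches(rng, 10, "plain")
        with pytest.raises(ValueError):
            qc.train_artifact_filter(x, np.zeros(10))
        with pytest.raises(ValueError):
            qc.train_artifact_filter(x[:0], np.zeros(0))

    def test_untrained_model_raises(self):
        import wsimil.classifier as clf

        cfg = clf.CNNConfig(input_size=32, filters=(4, 8, 16, 32))
        tm = clf.TrainedModel("artifact_filter", clf.build_model(cfg), cfg, history={})
        with pytest.raises(RuntimeError):
            qc.apply_artifact_filter([], tm)


class TestEndToEndQC:
    def test_mask_oracle_agreement(self, tiny_dataset):
        """QC decisions match the ground-truth-mask oracle on >=95% of patches."""
        patches, _, _ = tiny_dataset
        agree = total = 0
        for rec in patches:
            oracle_reject = (
                rec.extras["tissue_cover"] < 0.2 or rec.extras["artifact_cover"] > 0.25
            )
            agree += int(oracle_reject == (rec.qc_status != "retained"))
            total += 1
        assert total > 100
        assert agree / total >= 0.95

    def test_retained_patches_have_true_tissue(self, tiny_dataset):
        """>=95% of retained patches really carry >=20% tissue per the masks."""
        patches, _, _ = tiny_dataset
        retained = [r for r in patches if r.qc_status == "retained"]
        ok = np.mean([r.extras["tissue_cover"] >= 0.2 for r in retained])
        assert ok >= 0.95

    def test_statuses_partition(self, tiny_dataset):
        patches, _, reports = tiny_dataset
        assert all(
            r.qc_status in ("retained", "artifact_rejected", "low_tissue_rejected")
            for r in patches
        )
        assert sum(sum(rep.counts.values()) for rep in reports) == len(patches)
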