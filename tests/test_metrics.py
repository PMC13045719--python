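"""Metric correctness: gCNR, SSIM (vs an independent windowed-formula
oracle), Jaccard, overlay rendering and the evaluation grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from us2ct.metrics import (
    MetricRecord,
    aggregate_records,
    gcnr,
    jaccard,
    records_to_frame,
    render_overlay,
    ssim,
)


def _ssim_oracle(a, b, data_range=1.0, win=7):
    """Independent sliding-window SSIM: direct evaluation of the windowed
    formula with unbiased covariance, uniform window."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = a.shape
    vals = []
    np_ = win * win
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            pa = a[i : i + win, j : j + win].ravel()
            pb = b[i : i + win, j : j + win].ravel()
            ma, mb = pa.mean(), pb.mean()
            va = ((pa - ma) ** 2).sum() / (np_ - 1)
            vb = ((pb - mb) ** 2).sum() / (np_ - 1)
            cov = ((pa - ma) * (pb - mb)).sum() / (np_ - 1)
            vals.append(
                ((2 * ma * mb + c1) * (2 * cov + c2))
                / ((ma**2 + mb**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


class TestGcnr:
    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 200)
        img = np.concatenate([vals, vals]).reshape(20, 20)
        roi = np.zeros((20, 20), bool)
        roi[:10] = True
        assert gcnr(img, roi, ~roi) == 0.0

    def test_disjoint_supports_give_one(self):
        img = np.concatenate([np.linspace(0, 0.4, 50), np.linspace(0.6, 1, 50)])
        img = img.reshape(10, 10)
        roi = np.zeros((10, 10), bool)
        roi.ravel()[:50] = True
        assert gcnr(img, roi, ~roi) == 1.0

    def test_hand_computed_three_bin_case(self):
        """p_ROI = (.5,.5,0), p_BG = (0,.5,.5) over 3 shared bins → 0.5."""
        roi_vals = np.array([0.1, 0.5])
        bg_vals = np.array([0.5, 0.9])
        img = np.concatenate([roi_vals, bg_vals]).reshape(2, 2)
        roi = np.array([[True, True], [False, False]])
        assert gcnr(img, roi, ~roi, n_bins=3) == pytest.approx(0.5)

    def test_degenerate_constant_image_is_zero(self):
        img = np.full((8, 8), 0.3)
        roi = np.zeros((8, 8), bool)
        roi[:4] = True
        assert gcnr(img, roi, ~roi) == 0.0

    def test_errors(self):
        img = np.zeros((4, 4))
        empty = np.zeros((4, 4), bool)
        full = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            gcnr(img, empty, full)
        with pytest.raises(ValueError):
            gcnr(img, full, full)  # overlapping masks

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        offset=st.floats(min_value=-10.0, max_value=10.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_affine_invariance_property(self, scale, offset, seed):
        """Property: any positive affine intensity remap leaves gCNR
        unchanged (bins recomputed on the remapped pooled range)."""
        rng = np.random.default_rng(seed)
        img = rng.normal(0.5, 0.2, (16, 16))
        roi = np.zeros((16, 16), bool)
        roi[4:8, 4:8] = True
        bg = ~roi
        assert gcnr(scale * img + offset, roi, bg) == pytest.approx(
            gcnr(img, roi, bg), abs=1e-9
        )

    @pytest.mark.parametrize("scale,offset", [(1.0, 0.0), (2.5, -0.7), (0.1, 3.0)])
    def test_affine_intensity_invariance(self, scale, offset):
        """gCNR is exactly invariant under positive affine remapping when
        bins are recomputed on the remapped pooled range."""
        rng = np.random.default_rng(1)
        img = rng.normal(0.5, 0.2, (32, 32))
        roi = np.zeros((32, 32), bool)
        roi[8:16, 8:16] = True
        bg = ~roi
        bg[0] = False
        base = gcnr(img, roi, bg)
        assert gcnr(scale * img + offset, roi, bg) == pytest.approx(base, abs=1e-12)


class TestSsim:
    def test_self_similarity_is_one(self):
        img = np.random.default_rng(2).uniform(0, 1, (32, 32))
        assert ssim(img, img) == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (64, 64))
        b = np.clip(a + rng.normal(0, 0.1, (64, 64)), 0, 1)
        assert ssim(a, b) == pytest.approx(_ssim_oracle(a, b), abs=1e-8)

    def test_checkerboard_inversion_scores_low(self):
        yy, xx = np.mgrid[:32, :32]
        board = ((yy + xx) % 2).astype(float)
        value = ssim(board, 1.0 - board)
        assert value < 0.5
        assert value == pytest.approx(_ssim_oracle(board, 1.0 - board), abs=1e-8)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 9)))


class TestJaccard:
    def test_identity_disjoint_and_hand_case(self):
        a = np.zeros((6, 6), bool)
        a[2:4, 2:4] = True
        assert jaccard(a, a) == 1.0
        b = np.zeros((6, 6), bool)
        b[0, 0] = True
        assert jaccard(a, b) == 0.0
        shifted = np.zeros((6, 6), bool)
        shifted[2:4, 3:5] = True  # overlap 2, union 6
        assert jaccard(a, shifted) == pytest.approx(1.0 / 3.0)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestOverlay:
    def test_identical_stack_red_channel(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1, (16, 16))
        bmode = rng.uniform(0, 1, (16, 16))
        out = render_overlay(bmode, [img] * 6)
        norm = (img - img.min()) / (img.max() - img.min())
        assert np.allclose(out[..., 0], norm)
        assert out.shape == (16, 16, 3)

    def test_degenerate_stacks(self):
        bmode = np.random.default_rng(5).uniform(0, 1, (8, 8))
        zero = render_overlay(bmode, [np.zeros((8, 8))] * 6)
        assert np.all(zero[..., 0] == 0.0)
        const = render_overlay(bmode, [np.full((8, 8), 0.4)] * 6)
        assert np.all(const[..., 0] == 0.5)

    def test_wrong_stack_size(self):
        with pytest.raises(ValueError):
            render_overlay(np.zeros((8, 8)), [np.zeros((8, 8))] * 5)


class TestEvaluationGrid:
    def _setup(self):
        from us2ct.pairs import TrainingPair
        from us2ct.pix2pix import TrainConfig, init_model

        rng = np.random.default_rng(6)
        model = init_model(TrainConfig(steps=0, seed=0, scale_preset="desk_64"))
        size = 64

        def masks(has_anech, has_hyper):
            m = {
                "anechoic": np.zeros((size, size), bool),
                "hyperechoic": np.zeros((size, size), bool),
            }
            if has_anech:
                m["anechoic"][10:18, 10:18] = True
            if has_hyper:
                m["hyperechoic"][30:40, 30:40] = True
            m["background"] = ~(m["anechoic"] | m["hyperechoic"])
            return m

        pairs = [
            TrainingPair(rng.uniform(-1, 1, (size, size)),
                         rng.uniform(-1, 1, (size, size)), pid, "upsampling")
            for pid in ("lesioned", "empty")
        ]
        phantom_masks = {"lesioned": masks(True, True), "empty": masks(False, False)}
        return model, pairs, phantom_masks

    def test_record_grid(self):
        from us2ct.metrics import evaluate_testset

        model, pairs, phantom_masks = self._setup()
        records = evaluate_testset(
            {"upsampling": model}, {"upsampling": pairs}, phantom_masks, "ct_visible"
        )
        df = records_to_frame(records)
        empty = df[df.phantom_id == "empty"]
        assert set(empty.metric) == {"ssim"}           # no gCNR without inclusions
        lesioned = df[df.phantom_id == "lesioned"]
        gc = lesioned[lesioned.metric == "gcnr"]
        # one generated + one B-mode record per present ROI class
        assert len(gc) == 4
        assert set(gc.stage) == {"upsampling", "bmode"}
        assert set(gc.roi_class) == {"anechoic", "hyperechoic"}
        assert df.value.between(0, 1).all()

    def test_aggregation_hand_check(self):
        records = [
            MetricRecord("a", "upsampling", "ct_visible", "ssim", "none", 0.8),
            MetricRecord("b", "upsampling", "ct_visible", "ssim", "none", 0.6),
        ]
        agg = aggregate_records(records)
        row = agg.iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["std"] == pytest.approx(np.std([0.8, 0.6], ddof=1))
        assert row["count"] == 2
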