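"""Volume inference contracts and the bulk-HU baseline."""

import numpy as np
import pytest

import mr2sct as m
from mr2sct.gan import GeneratorSpec
from mr2sct.phantoms import CLASS_LABELS
from mr2sct.preprocess import DEFAULT_CT_WINDOW, DEFAULT_MR_WINDOW
from mr2sct.train import TranslationModel
from mr2sct.volume import Volume


class _CentreChannelStub:
    """Stands in for a generator: returns the centre input channel."""

    def __call__(self, x):
        return x[..., 1:2]


def _stub_model():
    scale = m.StandardScale((1, 50, 99), (0.0, 50.0, 100.0))
    model = TranslationModel.__new__(TranslationModel)
    model.generator = _CentreChannelStub()
    model.gen_spec = GeneratorSpec()
    model.scale = scale
    model.window_mr = DEFAULT_MR_WINDOW
    model.window_ct = DEFAULT_CT_WINDOW
    return model


class TestPredictVolume:
    def test_identity_stub_maps_mr_through_ct_window(self, phantom):
        """With a pass-through generator the output is exactly the MR values
        re-expressed through the CT window: unscale(scale(mr))."""
        model = _stub_model()
        pred = m.predict_volume(model, phantom.mr)
        mr_unit = m.scale_to_unit(phantom.mr, model.window_mr)
        expected = m.unscale_from_unit(mr_unit, model.window_ct)
        assert np.array_equal(pred.data, expected.data)

    def test_output_grid_matches_input(self, phantom):
        pred = m.predict_volume(_stub_model(), phantom.mr)
        assert pred.shape == phantom.mr.shape
        assert pred.spacing == phantom.mr.spacing
        assert pred.origin == phantom.mr.origin
        assert pred.modality == "CT"

    def test_incompatible_extent_rejected(self):
        mr = Volume(np.zeros((16, 60, 60), dtype=np.float32), (3, 2, 2),
                    modality="MR")
        model = _stub_model()
        model.generator = m.build_generator(seed=0)
        with pytest.raises(ValueError, match="extent"):
            m.predict_volume(model, mr)

    def test_prediction_deterministic(self, study_runs):
        run = study_runs[1]
        case = run["test_cases"][0]
        from mr2sct.preprocess import nyul_transform
        mr_n = nyul_transform(case.mr, run["model"].scale, case.body_mask)
        a = m.predict_volume(run["model"], mr_n)
        b = m.predict_volume(run["model"], mr_n)
        assert np.array_equal(a.data, b.data)

    def test_bone_prediction_beats_affine_baseline(self, study_runs):
        """Median predicted HU inside bone is closer to the true bone HU than
        the affine baseline's median, for every seed: the network resolves
        the dark-MR ambiguity that a global map cannot."""
        for seed, run in study_runs.items():
            for rec in run["per_case"]:
                err_gan = abs(rec["bone_median_gan"] - rec["bone_median_true"])
                err_aff = abs(rec["bone_median_affine"] - rec["bone_median_true"])
                assert err_gan < err_aff, (
                    f"seed {seed}: bone median error {err_gan:.0f} HU (GAN) "
                    f"vs {err_aff:.0f} HU (affine)")


class TestBulkBaseline:
    def test_uniform_soft_tissue_phantom(self):
        data = np.full((16, 16, 16), 45.0, dtype=np.float32)
        mr = Volume(data, (1, 1, 1), modality="MR")
        body = np.zeros((16, 16, 16), dtype=np.uint8)
        body[4:12, 4:12, 4:12] = 1
        mask = Volume(body, (1, 1, 1), modality="MASK")
        out = m.bulk_sct_baseline(mr, mask, thresholds=(20.0, 80.0))
        assert np.all(out.data[body > 0] == 40.0)
        assert np.all(out.data[body == 0] == -1000.0)

    def test_class_counts_match_histogram_oracle(self, phantom):
        """Voxel count per assigned bulk class equals direct thresholded
        histogram counts."""
        lo, hi = 20.0, 80.0
        out = m.bulk_sct_baseline(phantom.mr, phantom.body_mask, (lo, hi))
        x = phantom.mr.data
        body = phantom.body_mask.data.astype(bool)
        expected = {
            -1000.0: int((~body).sum()),
            700.0: int((body & (x < lo)).sum()),
            40.0: int((body & (x >= lo) & (x <= hi)).sum()),
            10.0: int((body & (x > hi)).sum()),
        }
        values, counts = np.unique(out.data, return_counts=True)
        got = dict(zip(values.tolist(), counts.tolist()))
        for hu, n in expected.items():
            assert got.get(hu, 0) == n

    def test_marrow_guarantees_positive_error(self, phantom):
        """Marrow HU is not in the bulk set, so the baseline cannot reach
        zero MAE on any phantom containing marrow."""
        assert (phantom.class_map == CLASS_LABELS["marrow"]).any()
        out = m.bulk_sct_baseline(phantom.mr, phantom.body_mask, (20.0, 80.0))
        assert m.mae(out, phantom.ct, phantom.body_mask) > 0.0

    def test_thresholds_must_increase(self, phantom):
        with pytest.raises(ValueError, match="increasing"):
            m.bulk_sct_baseline(phantom.mr, phantom.body_mask, (80.0, 20.0))

    def test_estimator_requires_fit(self, phantom):
        with pytest.raises(RuntimeError, match="fit"):
            m.BulkHUBaseline().predict(phantom.mr, phantom.body_mask)


def test_gan_beats_bulk_baseline_in_mae(study_runs):
    """The study-level ordering: learned translation outperforms bulk
    assignment in mean MAE on every seed's test set."""
    for seed, run in study_runs.items():
        mae_gan = np.mean([r["mae_gan"] for r in run["per_case"]])
        mae_bulk = np.mean([r["mae_bulk"] for r in run["per_case"]])
        assert mae_gan < mae_bulk, (
            f"seed {seed}: GAN MAE {mae_gan:.1f} HU not below bulk "
            f"baseline {mae_bulk:.1f} HU")
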