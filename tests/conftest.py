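"""Shared fixtures.

The expensive fixture is ``study_runs``: the full scaled-down study
(16 training / 4 test phantoms on 64x64x16 grids, 50 epochs) repeated
for three fixed seeds, with GAN, least-squares-affine and bulk-HU
synthetic CTs evaluated in both image and dose similarity.  It is
session-scoped and shared by the training, inference and acceptance
tests so the translation GAN is trained exactly once per seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import mr2sct as m
from mr2sct.phantoms import CLASS_LABELS
from mr2sct.preprocess import nyul_transform

STUDY_SEEDS = (1, 2, 3)
STUDY_SHAPE = (16, 64, 64)
STUDY_SPACING = (3.0, 2.0, 2.0)
N_TRAIN, N_TEST = 16, 4
EPOCHS = 50


@pytest.fixture(scope="session")
def phantom():
    return m.generate_phantom(7, shape=STUDY_SHAPE, spacing=STUDY_SPACING)


@pytest.fixture(scope="session")
def cohort20():
    """20 phantoms with injected scan variation, for Nyul checks."""
    train, test = m.generate_cohort(16, 4, seed=11)
    return train + test


def _affine_fit(train_cases, scale):
    """Least-squares HU ~ a*MR + b on standardized training MR."""
    xs, ys = [], []
    for c in train_cases:
        mr_n = nyul_transform(c.mr, scale, c.body_mask)
        body = c.body_mask.data.astype(bool)
        xs.append(mr_n.data[body].astype(np.float64))
        ys.append(c.ct.data[body].astype(np.float64))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    design = np.stack([x, np.ones_like(x)], axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef  # (slope, intercept)


def _run_study(seed: int) -> dict:
    train_cases, test_cases = m.generate_cohort(
        N_TRAIN, N_TEST, seed=seed, shape=STUDY_SHAPE, spacing=STUDY_SPACING)
    model, history = m.train(train_cases, m.TrainConfig(epochs=EPOCHS, seed=seed))
    coef = _affine_fit(train_cases, model.scale)
    baseline = m.BulkHUBaseline().fit(
        [nyul_transform(c.mr, model.scale, c.body_mask) for c in train_cases],
        [c.body_mask for c in train_cases])

    per_case = []
    for case in test_cases:
        mr_n = nyul_transform(case.mr, model.scale, case.body_mask)
        pred = m.predict_volume(model, mr_n)
        affine = case.ct.with_data(
            (coef[0] * mr_n.data + coef[1]).astype(np.float32))
        bulk = baseline.predict(mr_n, case.body_mask)

        beams = m.BeamConfig(target_mask=case.target_mask)
        ref_dose = m.compute_dose(case.ct, beams)
        rec = {
            "case": case,
            "mae_gan": m.mae(pred, case.ct, case.body_mask),
            "mae_affine": m.mae(affine, case.ct, case.body_mask),
            "mae_bulk": m.mae(bulk, case.ct, case.body_mask),
        }
        bone = case.class_map == CLASS_LABELS["bone"]
        rec["bone_median_true"] = float(np.median(case.ct.data[bone]))
        rec["bone_median_gan"] = float(np.median(pred.data[bone]))
        rec["bone_median_affine"] = float(np.median(affine.data[bone]))
        mr_contour = m.extract_body_mask(mr_n)
        rec["dsc_mr_gan"] = m.dice(mr_contour, m.extract_body_mask(pred))
        rec["dsc_mr_bulk"] = m.dice(mr_contour, m.extract_body_mask(bulk))
        for name, sct in (("gan", pred), ("bulk", bulk)):
            gmap = m.gamma_index(ref_dose, m.compute_dose(sct, beams),
                                 m.GammaParams(cutoff_fraction=0.10))
            rec[f"gpr10_{name}"] = m.gamma_passing_rate(gmap)
            rec[f"gpr60_{name}"] = m.gamma_passing_rate(gmap, cutoff_fraction=0.60)
        per_case.append(rec)

    return {"seed": seed, "model": model, "history": history,
            "train_cases": train_cases, "test_cases": test_cases,
            "per_case": per_case}


@pytest.fixture(scope="session")
def study_runs():
    return {seed: _run_study(seed) for seed in STUDY_SEEDS}
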