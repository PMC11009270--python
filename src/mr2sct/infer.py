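"""Whole-volume synthetic-CT prediction and the bulk-HU baseline.

``predict_volume`` runs the trained generator slice by slice using the
same 2.5D stacking rule as training (one prediction per slice, no
overlap averaging) and maps the [-1, 1] network output back to HU.

``bulk_sct_baseline`` is a deliberately simple stand-in for commercial
segmentation-based synthetic CT (MRCAT-like): the body is partitioned by
two MR intensity thresholds and each partition receives a single bulk HU
value (dark -> bone, mid -> soft tissue, bright -> fluid), air outside
the body.  It mimics only the bulk-assignment character of such systems
— the real product uses multi-echo mDixon decomposition, which is out of
scope here.
"""

from __future__ import annotations

import numpy as np

from .train import TranslationModel, make_training_triplets
from .preprocess import scale_to_unit, unscale_from_unit
from .volume import Volume

#: default bulk HU assignments for the segmentation baseline
DEFAULT_BULK_HU = {"air": -1000.0, "bone": 700.0, "soft": 40.0, "fluid": 10.0}


def predict_volume(model: TranslationModel, mr: Volume,
                   batch_slices: int = 8) -> Volume:
    """Synthesize a CT volume from a Nyul-standardized MR volume.

    The MR volume must already be on the model's standard intensity scale
    (see :class:`~mr2sct.preprocess.NyulStandardizer`); windowing to
    [-1, 1] and back to HU is handled here.  Output grid equals the input
    grid; the prediction is deterministic.
    """
    mr_s = scale_to_unit(mr, model.window_mr)
    stacks, _ = make_training_triplets(mr_s)
    div = 2 ** model.gen_spec.depth
    h, w = stacks.shape[1], stacks.shape[2]
    if h % div or w % div:
        raise ValueError(
            f"in-plane extent {h}x{w} is incompatible with the model "
            f"(depth {model.gen_spec.depth} requires multiples of {div})"
        )
    out = np.empty((len(stacks), h, w), dtype=np.float32)
    for b0 in range(0, len(stacks), batch_slices):
        out[b0:b0 + batch_slices] = model.generator(
            stacks[b0:b0 + batch_slices])[..., 0]
    pred = Volume(out, mr.spacing, mr.origin, "CT")
    return unscale_from_unit(pred, model.window_ct)


def bulk_sct_baseline(mr: Volume, body_mask: Volume,
                      thresholds: tuple[float, float],
                      bulk_hu: dict | None = None) -> Volume:
    """Piecewise-constant synthetic CT from MR intensity thresholds.

    Inside the body: MR below ``thresholds[0]`` maps to bone bulk HU
    (cortical bone is dark on T2), between the thresholds to soft-tissue
    bulk HU, above ``thresholds[1]`` to fluid bulk HU (bright bladder).
    Outside the body everything is air.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be increasing, got ({lo}, {hi})")
    hu = dict(DEFAULT_BULK_HU, **(bulk_hu or {}))
    mr.check_same_grid(body_mask, "mr and body_mask")
    x = np.asarray(mr.data, dtype=np.float64)
    body = np.asarray(body_mask.data) > 0
    out = np.full(mr.shape, hu["air"], dtype=np.float32)
    out[body & (x < lo)] = hu["bone"]
    out[body & (x >= lo) & (x <= hi)] = hu["soft"]
    out[body & (x > hi)] = hu["fluid"]
    return Volume(out, mr.spacing, mr.origin, "CT")


class BulkHUBaseline:
    """Sklearn-style wrapper for the bulk-HU baseline.

    ``fit`` places the two MR thresholds at fixed percentiles of the
    within-body standardized MR intensities of the training cases (bone
    and fluid occupy the histogram tails); ``predict`` applies
    :func:`bulk_sct_baseline`.
    """

    def __init__(self, lower_percentile: float = 6.0,
                 upper_percentile: float = 94.0, bulk_hu: dict | None = None):
        self.lower_percentile = lower_percentile
        self.upper_percentile = upper_percentile
        self.bulk_hu = bulk_hu

    def get_params(self, deep: bool = True) -> dict:
        return {"lower_percentile": self.lower_percentile,
                "upper_percentile": self.upper_percentile,
                "bulk_hu": self.bulk_hu}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, mr_volumes: list[Volume], masks: list[Volume]):
        vals = np.concatenate([
            np.asarray(v.data, dtype=np.float64)[np.asarray(m.data) > 0]
            for v, m in zip(mr_volumes, masks)
        ])
        self.thresholds_ = (float(np.percentile(vals, self.lower_percentile)),
                            float(np.percentile(vals, self.upper_percentile)))
        return self

    def predict(self, mr: Volume, body_mask: Volume) -> Volume:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("BulkHUBaseline is not fitted; call fit first")
        return bulk_sct_baseline(mr, body_mask, self.thresholds_, self.bulk_hu)
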