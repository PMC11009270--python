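"""2.5D sample construction and the adversarial training loop.

Each axial slice becomes one training sample: the MR stack holds the
slice itself plus its neighbours above and below (edge slices replicate
themselves), so a volume with S slices yields exactly S samples and the
whole CT volume is predicted once per pass.  Per batch the discriminator
is updated first, then the generator, on the same generator forward
pass.

Training hyperparameters default to Adam with learning rate 2e-4,
mini-batch 3 and 100 epochs, L1 and adversarial loss weights both 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nnet
from .gan import (DiscriminatorSpec, GeneratorSpec, LossWeights,
                  UNetGenerator, build_discriminator, build_generator,
                  discriminator_loss, generator_loss)
from .preprocess import (DEFAULT_CT_WINDOW, DEFAULT_MR_WINDOW, NyulStandardizer,
                         ScaleWindow, StandardScale, scale_to_unit)
from .volume import PairedCase, Volume

_PCLIP = 1e-6  # keep sigmoid outputs strictly inside (0, 1)


@dataclass
class TrainConfig:
    """Optimization settings for the translation GAN."""

    learning_rate: float = 2e-4
    batch_size: int = 3
    epochs: int = 100
    adam_betas: tuple = (0.5, 0.999)
    seed: int = 0
    val_fraction: float = 0.1
    window_ct: ScaleWindow = field(default_factory=lambda: DEFAULT_CT_WINDOW)
    window_mr: ScaleWindow = field(default_factory=lambda: DEFAULT_MR_WINDOW)
    checkpoint_interval: int = 0  # epochs between checkpoints; 0 = none
    augment_flip: bool = False  # random left-right flips (off by default)
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1 = constant)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["window_ct"] = [self.window_ct.lo, self.window_ct.hi]
        d["window_mr"] = [self.window_mr.lo, self.window_mr.hi]
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("window_ct", "window_mr"):
            if key in d and not isinstance(d[key], ScaleWindow):
                d[key] = ScaleWindow(*d[key])
        if "adam_betas" in d:
            d["adam_betas"] = tuple(d["adam_betas"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch loss and validation-metric records."""

    g_loss: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    val_mae: list = field(default_factory=list)
    val_ssim: list = field(default_factory=list)
    train_case_ids: list = field(default_factory=list)
    val_case_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.g_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "g_loss": self.g_loss,
            "d_loss": self.d_loss,
            "val_mae": self.val_mae,
            "val_ssim": self.val_ssim,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class TranslationModel:
    """Everything inference needs: the generator plus the preprocessing
    state (Nyul scale and intensity windows) it was trained with."""

    generator: UNetGenerator
    gen_spec: GeneratorSpec
    scale: StandardScale
    window_mr: ScaleWindow
    window_ct: ScaleWindow

    def save(self, path: str | Path) -> None:
        meta = {
            "gen_spec": asdict(self.gen_spec),
            "scale": {"percentiles": list(self.scale.percentiles),
                      "standard_landmarks": list(self.scale.standard_landmarks),
                      "s_range": list(self.scale.s_range)},
            "window_mr": [self.window_mr.lo, self.window_mr.hi],
            "window_ct": [self.window_ct.lo, self.window_ct.hi],
            "format_version": 1,
        }
        nnet.save_params(path, self.generator.params(), meta)

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        import numpy as _np

        with _np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
        spec = GeneratorSpec(**meta["gen_spec"])
        gen = build_generator(spec, seed=0)
        nnet.load_params(path, gen.params())
        sc = meta["scale"]
        scale = StandardScale(tuple(sc["percentiles"]),
                              tuple(sc["standard_landmarks"]),
                              tuple(sc["s_range"]))
        return cls(gen, spec, scale,
                   ScaleWindow(*meta["window_mr"]), ScaleWindow(*meta["window_ct"]))


def make_training_triplets(mr: Volume, ct: Volume | None = None):
    """Per-slice 2.5D samples: stacks ``(k-1, k, k+1)`` with edge replication.

    Returns ``(stacks, targets)`` where ``stacks`` is ``(S, H, W, 3)`` and
    ``targets`` is ``(S, H, W, 1)`` (or None when ``ct`` is not given).  A
    volume with S axial slices yields exactly S samples; concatenating the
    targets reconstructs the CT volume bit-exactly.
    """
    if ct is not None:
        mr.check_same_grid(ct, "mr and ct")
    s = mr.shape[0]
    if s < 1:
        raise ValueError("need at least one axial slice")
    lo = np.clip(np.arange(s) - 1, 0, s - 1)
    hi = np.clip(np.arange(s) + 1, 0, s - 1)
    stacks = np.stack([mr.data[lo], mr.data[np.arange(s)], mr.data[hi]],
                      axis=-1).astype(nnet.F32)
    targets = None
    if ct is not None:
        targets = np.asarray(ct.data, dtype=nnet.F32)[..., None]
    return stacks, targets


def _prepare_case(case: PairedCase, standardizer: NyulStandardizer,
                  cfg: TrainConfig):
    mr_n = standardizer.transform(case.mr, case.body_mask)
    mr_s = scale_to_unit(mr_n, cfg.window_mr)
    ct_s = scale_to_unit(case.ct, cfg.window_ct)
    return make_training_triplets(mr_s, ct_s)


def train(train_cases: list[PairedCase], config: TrainConfig | None = None,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None,
          weights: LossWeights | None = None,
          run_dir: str | Path | None = None,
          verbose: bool = False):
    """Fit the conditional GAN on paired phantom cases.

    Nyul standardization is fitted on the training MR volumes and applied
    internally; MR and CT are windowed to [-1, 1].  Per batch the
    discriminator takes one update (real vs generated pairs), then the
    generator one (L1 + adversarial).  Returns ``(TranslationModel,
    TrainHistory)``.
    """
    cfg = config or TrainConfig()
    gen_spec = gen_spec or GeneratorSpec()
    weights = weights or LossWeights()
    if len(train_cases) < 2:
        raise ValueError("training requires at least 2 paired cases")
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(in_channels=gen_spec.in_slices + 1)
    if not disc_spec.conditional:
        disc_spec = DiscriminatorSpec(**{**asdict(disc_spec), "in_channels": 1})

    rng = np.random.default_rng(cfg.seed)

    # train/validation split by case (validation cases never produce gradients)
    order = rng.permutation(len(train_cases))
    n_val = int(round(cfg.val_fraction * len(train_cases))) if cfg.val_fraction > 0 else 0
    n_val = min(n_val, len(train_cases) - 2)
    val_idx = list(order[len(train_cases) - n_val:])
    fit_idx = list(order[: len(train_cases) - n_val])
    fit_cases = [train_cases[i] for i in fit_idx]
    val_cases = [train_cases[i] for i in val_idx]

    standardizer = NyulStandardizer().fit(
        [c.mr for c in fit_cases], masks=[c.body_mask for c in fit_cases])

    xs, ys = [], []
    for case in fit_cases:
        stacks, targets = _prepare_case(case, standardizer, cfg)
        xs.append(stacks)
        ys.append(targets)
    x_all = np.concatenate(xs, axis=0)
    y_all = np.concatenate(ys, axis=0)
    n_samples = len(x_all)

    gen = build_generator(gen_spec, seed=cfg.seed)
    disc = build_discriminator(disc_spec, seed=cfg.seed + 1)
    g_opt = nnet.Adam(gen.params(), lr=cfg.learning_rate, betas=cfg.adam_betas)
    d_opt = nnet.Adam(disc.params(), lr=cfg.learning_rate, betas=cfg.adam_betas)

    model = TranslationModel(gen, gen_spec, standardizer.scale_,
                             cfg.window_mr, cfg.window_ct)
    history = TrainHistory(
        train_case_ids=[train_cases[i].case_id for i in fit_idx],
        val_case_ids=[train_cases[i].case_id for i in val_idx],
    )
    from .infer import predict_volume  # local import; infer depends on this module
    from .metrics import mae, ssim

    lsgan = weights.adv_mode == "lsgan"

    def d_pair(x, y):
        if disc_spec.conditional:
            return np.concatenate([x, y], axis=3)
        return y

    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n_samples)
        g_losses, d_losses = [], []
        for b0 in range(0, n_samples, cfg.batch_size):
            sel = perm[b0:b0 + cfg.batch_size]
            xb, yb = x_all[sel], y_all[sel]
            if cfg.augment_flip and rng.random() < 0.5:
                xb, yb = xb[:, :, ::-1], yb[:, :, ::-1]
            nb = len(sel)

            fake = gen.forward(xb, train=True)

            # --- discriminator update (generator output detached) ---
            pr = np.clip(disc.forward(d_pair(xb, yb), train=True), _PCLIP, 1 - _PCLIP)
            disc.backward((2 * (pr - 1) / nb) if lsgan else (-1.0 / pr / nb))
            pf = np.clip(disc.forward(d_pair(xb, fake), train=True), _PCLIP, 1 - _PCLIP)
            disc.backward((2 * pf / nb) if lsgan else (1.0 / (1.0 - pf) / nb))
            d_opt.step()
            d_opt.zero_grad()

            # --- generator update (re-score the same fake with updated D) ---
            pf2 = np.clip(disc.forward(d_pair(xb, fake), train=True), _PCLIP, 1 - _PCLIP)
            dadv_in = disc.backward((2 * (pf2 - 1) / nb) if lsgan else (-1.0 / pf2 / nb))
            d_opt.zero_grad()  # discriminator grads from this pass are discarded
            dadv = dadv_in[..., gen_spec.in_slices:] if disc_spec.conditional else dadv_in
            dl1 = np.sign(fake - yb) / fake.size
            gen.backward((weights.lambda_l1 * dl1
                          + weights.lambda_adv * dadv).astype(nnet.F32))
            g_opt.step()
            g_opt.zero_grad()

            gl = generator_loss(fake, yb, pf2, weights)
            dl = discriminator_loss(pr, pf, weights.adv_mode)
            if not (np.isfinite(gl) and np.isfinite(dl)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}: "
                    f"g_loss={gl}, d_loss={dl}"
                )
            g_losses.append(gl)
            d_losses.append(dl)

        g_opt.lr *= cfg.lr_decay
        d_opt.lr *= cfg.lr_decay

        # validation on held-out cases (training cases if no split requested)
        vcases = val_cases if val_cases else fit_cases[:2]
        vmae, vssim = [], []
        for case in vcases:
            from .preprocess import nyul_transform
            mr_n = nyul_transform(case.mr, standardizer.scale_, case.body_mask)
            pred = predict_volume(model, mr_n)
            vmae.append(mae(pred, case.ct, case.body_mask))
            vssim.append(ssim(pred, case.ct, case.body_mask))
        history.g_loss.append(float(np.mean(g_losses)))
        history.d_loss.append(float(np.mean(d_losses)))
        history.val_mae.append(float(np.mean(vmae)))
        history.val_ssim.append(float(np.mean(vssim)))
        if verbose:
            print(f"epoch {epoch:3d}/{cfg.epochs}  g={history.g_loss[-1]:.4f} "
                  f"d={history.d_loss[-1]:.4f}  val_mae={history.val_mae[-1]:.2f} HU "
                  f"val_ssim={history.val_ssim[-1]:.4f}")
        if run_dir and cfg.checkpoint_interval and epoch % cfg.checkpoint_interval == 0:
            run_dir = Path(run_dir)
            run_dir.mkdir(parents=True, exist_ok=True)
            model.save(run_dir / f"checkpoint_epoch{epoch:04d}.npz")

    if run_dir:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        model.save(run_dir / "model_final.npz")
        history.to_csv(run_dir / "history.csv")
        cfg.to_yaml(run_dir / "train_config.yaml")
    return model, history


class GanTranslator:
    """Sklearn-style estimator: fit on paired cases, predict CT from MR.

    Thin object wrapper over :func:`train` and
    :func:`mr2sct.infer.predict_volume`; hyperparameters mirror
    :class:`TrainConfig`, :class:`~mr2sct.gan.GeneratorSpec` and
    :class:`~mr2sct.gan.LossWeights`.
    """

    def __init__(self, epochs: int = 100, learning_rate: float = 2e-4,
                 batch_size: int = 3, seed: int = 0, val_fraction: float = 0.1,
                 base_channels: int = 8, depth: int = 4,
                 n_residual_blocks: int = 2, skip_connections: bool = True,
                 lambda_l1: float = 1.0, lambda_adv: float = 1.0,
                 adv_mode: str = "bce"):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed
        self.val_fraction = val_fraction
        self.base_channels = base_channels
        self.depth = depth
        self.n_residual_blocks = n_residual_blocks
        self.skip_connections = skip_connections
        self.lambda_l1 = lambda_l1
        self.lambda_adv = lambda_adv
        self.adv_mode = adv_mode

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "epochs", "learning_rate", "batch_size", "seed", "val_fraction",
            "base_channels", "depth", "n_residual_blocks", "skip_connections",
            "lambda_l1", "lambda_adv", "adv_mode")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: list[PairedCase], y=None, run_dir=None, verbose=False):
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size, epochs=self.epochs,
                          seed=self.seed, val_fraction=self.val_fraction)
        spec = GeneratorSpec(base_channels=self.base_channels, depth=self.depth,
                             n_residual_blocks=self.n_residual_blocks,
                             skip_connections=self.skip_connections)
        w = LossWeights(self.lambda_l1, self.lambda_adv, self.adv_mode)
        self.model_, self.history_ = train(X, cfg, gen_spec=spec, weights=w,
                                           run_dir=run_dir, verbose=verbose)
        return self

    def predict(self, mr: Volume, body_mask: Volume | None = None) -> Volume:
        from .infer import predict_volume
        from .preprocess import extract_body_mask, nyul_transform

        if not hasattr(self, "model_"):
            raise RuntimeError("GanTranslator is not fitted; call fit first")
        mask = body_mask if body_mask is not None else extract_body_mask(mr)
        mr_n = nyul_transform(mr, self.model_.scale, mask)
        return predict_volume(self.model_, mr_n)
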