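"""Training / evaluation / prediction pipeline.

Protocol: images resized to the network input size, random-rotation and
horizontal-flip augmentation, Adam with initial learning rate 1e-4, at most
30 epochs with early stopping on the validation loss, 80/10/10
train/validation/test split.  Each training step computes the main
prediction Pm and the auxiliary prediction Pa from the shared encoder and
backpropagates L = Ls + alpha*Lc through both decoders and the encoder
(no stop-gradient: the consistency pressure is meant to reach the encoder).
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .encoder import ConfigurationError
from .losses import MetricReport, consistency_loss, dice_loss, evaluate, total_loss
from .model import PlutoNet
from .nn import Adam, Tensor

log = logging.getLogger("plutonet")
if not log.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 30
    patience: int = 5
    batch_size: int = 8
    input_size: int = 224
    alpha: float = 1.0
    epsilon: float = 1e-6
    augment: bool = True
    rotation_deg: float = 30.0
    split_ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigurationError("split ratios must sum to 1")


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    seed: int = 0

    def parts(self):
        return {"train": self.train, "val": self.val, "test": self.test}


@dataclass
class TrainResult:
    weights_path: str | None
    history: list = field(default_factory=list)   # per-epoch dicts
    stopping_epoch: int = 0
    model: PlutoNet | None = None


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def read_manifest(path) -> list[tuple[str, str]]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((row["image"], row["mask"]))
    return rows


def load_pair(image_path, mask_path, input_size: int):
    """Decode a PNG/JPEG pair, resize bilinearly to the network input size,
    scale to [0,1], and re-binarise the mask."""
    img = Image.open(image_path).convert("RGB").resize(
        (input_size, input_size), Image.BILINEAR)
    msk = Image.open(mask_path).convert("L").resize(
        (input_size, input_size), Image.BILINEAR)
    image = np.asarray(img, dtype=np.float32) / 255.0
    mask = (np.asarray(msk, dtype=np.float32) / 255.0 >= 0.5).astype(np.float32)
    return image, mask


# ---------------------------------------------------------------------------
# split and augmentation
# ---------------------------------------------------------------------------


def split_dataset(manifest: list, ratios=(0.8, 0.1, 0.1), seed: int = 0
                  ) -> DatasetSplit:
    """Seeded shuffle, then partition at the ratio boundaries.

    Sizes are the floors of n*ratio; leftover items go one each to the
    splits in priority order (train, then validation, then test).
    """
    if not manifest:
        raise ValueError("manifest is empty")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(manifest))
    items = [manifest[i] for i in order]
    n = len(items)
    sizes = [int(np.floor(n * r)) for r in ratios]
    leftover = n - sum(sizes)
    for i in range(leftover):
        sizes[i % 3] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(train=items[:a], val=items[a:b], test=items[b:], seed=seed)


def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            rotation_deg: float = 30.0):
    """Jointly rotate (uniform in +-rotation_deg, reflect borders) and
    possibly horizontally flip an image/mask pair; mask is re-binarised."""
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-rotation_deg, rotation_deg))
    flip = bool(rng.random() < 0.5)
    img = ndimage.rotate(image, angle, axes=(0, 1), reshape=False,
                         order=1, mode="reflect")
    msk = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                         order=1, mode="reflect")
    if flip:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    return (np.ascontiguousarray(np.clip(img, 0, 1), dtype=np.float32),
            np.ascontiguousarray(msk >= 0.5, dtype=np.float32))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batch_arrays(pairs, input_size, augment_seed=None, rotation_deg=30.0):
    imgs, msks = [], []
    for j, (ip, mp) in enumerate(pairs):
        im, mk = load_pair(ip, mp, input_size)
        if augment_seed is not None:
            im, mk = augment(im, mk, augment_seed + j, rotation_deg)
        imgs.append(im)
        msks.append(mk)
    return np.stack(imgs), np.stack(msks)[..., None]


def _epoch_losses(model, pairs, cfg, training=False):
    """Mean (Ls, Lc, L) over `pairs` without augmentation (validation)."""
    ls_s = lc_s = 0.0
    nb = 0
    for i in range(0, len(pairs), cfg.batch_size):
        x, t = _batch_arrays(pairs[i:i + cfg.batch_size], cfg.input_size)
        pm, pa = model.forward(x, training=training,
                               with_aux=cfg.alpha > 0)
        ls_s += dice_loss(pm, t, cfg.epsilon).item()
        lc_s += (consistency_loss(pm, pa, cfg.epsilon).item()
                 if pa is not None else 0.0)
        nb += 1
    ls, lc = ls_s / nb, lc_s / nb
    return ls, lc, ls + cfg.alpha * lc


def train(config: TrainConfig, split: DatasetSplit,
          model: PlutoNet | None = None,
          weights_path: str | None = None) -> TrainResult:
    """Optimise L = Ls + alpha*Lc; checkpoint the best validation loss."""
    config.validate()
    if not split.train or not split.val:
        raise ValueError("train and validation splits must be non-empty")
    if model is None:
        model = PlutoNet(seed=config.seed, with_aux=config.alpha > 0)
        if model.encoder_config.input_size != config.input_size:
            from .encoder import EncoderConfig
            model = PlutoNet(EncoderConfig(input_size=config.input_size),
                             with_aux=config.alpha > 0, seed=config.seed)
    params = model.trainable_parameters(include_aux=config.alpha > 0)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_state = None
    patience_left = config.patience
    history = []
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.time()
        order = rng.permutation(len(split.train))
        ls_s = lc_s = 0.0
        nb = 0
        for i in range(0, len(order), config.batch_size):
            pairs = [split.train[j] for j in order[i:i + config.batch_size]]
            aug_seed = int(rng.integers(2 ** 31)) if config.augment else None
            x, t = _batch_arrays(pairs, config.input_size,
                                 augment_seed=aug_seed,
                                 rotation_deg=config.rotation_deg)
            pm, pa = model.forward(x, training=True, with_aux=config.alpha > 0)
            ls = dice_loss(pm, t, config.epsilon)
            if pa is not None:
                lc = consistency_loss(pm, pa, config.epsilon)
                loss = total_loss(ls, lc, config.alpha)
                lc_val = lc.item()
            else:
                loss = ls
                lc_val = 0.0
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {nb}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ls_s += ls.item()
            lc_s += lc_val
            nb += 1
        ls_m, lc_m = ls_s / nb, lc_s / nb
        val_ls, val_lc, val_l = _epoch_losses(model, split.val, config)
        history.append({"epoch": epoch, "Ls": ls_m, "Lc": lc_m,
                        "L": ls_m + config.alpha * lc_m,
                        "val_loss": val_l, "seconds": time.time() - t0})
        log.info("epoch %d  Ls=%.4f Lc=%.4f L=%.4f val=%.4f (%.1fs)",
                 epoch, ls_m, lc_m, history[-1]["L"], val_l,
                 history[-1]["seconds"])
        if val_l < best_val - 1e-6:
            best_val = val_l
            best_state = [p.data.copy() for p in params]
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                log.info("early stop at epoch %d (best val %.4f)", epoch, best_val)
                break
    if best_state is not None:
        for p, d in zip(params, best_state):
            p.data = d
    if weights_path:
        model.save_weights(weights_path, include_aux=False)
    return TrainResult(weights_path=weights_path, history=history,
                       stopping_epoch=epoch, model=model)


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------


def predict(model: PlutoNet, image_paths, out_dir=None, threshold: float = 0.5):
    """Main-branch inference; probabilities are resized back to each image's
    native resolution and thresholded masks written as {0,255} PNGs."""
    size = model.encoder_config.input_size
    results = []
    for ip in image_paths:
        raw = Image.open(ip).convert("RGB")
        w, h = raw.size
        x = np.asarray(raw.resize((size, size), Image.BILINEAR),
                       dtype=np.float32)[None] / 255.0
        prob = model.predict(x)[0, :, :, 0]
        prob_native = np.asarray(
            Image.fromarray(prob).resize((w, h), Image.BILINEAR))
        mask = (prob_native >= threshold).astype(np.uint8) * 255
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out / (Path(ip).stem + "_mask.png"), mask)
        results.append((prob_native, mask))
    return results


def evaluate_dataset(model: PlutoNet, pairs, out_csv=None,
                     threshold: float = 0.5) -> pd.DataFrame:
    """Per-image metrics at native ground-truth resolution plus a mean row."""
    size = model.encoder_config.input_size
    rows = []
    for ip, mp in pairs:
        try:
            truth = (np.asarray(Image.open(mp).convert("L"),
                                dtype=np.float32) / 255.0 >= 0.5)
        except OSError:
            log.warning("missing mask %s; skipping", mp)
            continue
        raw = Image.open(ip).convert("RGB")
        x = np.asarray(raw.resize((size, size), Image.BILINEAR),
                       dtype=np.float32)[None] / 255.0
        prob = model.predict(x)[0, :, :, 0]
        prob_native = np.asarray(Image.fromarray(prob).resize(
            (truth.shape[1], truth.shape[0]), Image.BILINEAR))
        rep = evaluate(prob_native, truth.astype(np.float64), threshold)
        rows.append({"image": str(ip), **rep.as_row()})
    df = pd.DataFrame(rows)
    if len(df):
        mean = df.drop(columns="image").mean().to_dict()
        df = pd.concat([df, pd.DataFrame([{"image": "MEAN", **mean}])],
                       ignore_index=True)
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df
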