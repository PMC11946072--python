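"""Training loop, dataset split, and the three reconstruction metrics.

Quality of a restored image against its ground-truth glyph is scored by the
Pearson correlation coefficient (PCC) over pixels, the structural similarity
index (SSIM, Gaussian 11x11 window, sigma 1.5, K1=0.01, K2=0.03), and the
peak signal-to-noise ratio PSNR = 10 log10(MAX^2 / MSE) in dB.  Zero-MSE
PSNR is reported as a 100 dB cap so table aggregation stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from skimage.metrics import structural_similarity

from ._rng import rng_for
from .dataset import SpeckleDataset
from .model import RestorationModel
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "MetricReport",
    "split_dataset",
    "pcc",
    "ssim",
    "psnr",
    "train",
    "evaluate",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 100.0


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over flattened pixels; 0 (with a warning) if degenerate."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("constant image in pcc(): correlation undefined, returning 0", stacklevel=2)
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean windowed SSIM (Gaussian window 11, sigma 1.5, K1=0.01, K2=0.03).

    Images smaller than the window fall back to global (single-window)
    statistics, with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    if min(a.shape) < 11:
        warnings.warn("image smaller than the 11x11 window: using global SSIM", stacklevel=2)
        c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = np.mean((a - mu_a) * (b - mu_b))
        return float(
            ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
            / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
        )
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, win_size=11,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; zero MSE reported as the cap."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return PSNR_CAP_DB
    return float(min(10 * np.log10(max_value**2 / mse), PSNR_CAP_DB))


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_dataset(
    dataset: SpeckleDataset, ratio: tuple[int, int] = (8, 2), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test split, shuffled by seed.

    Stratified across drift epochs: each epoch contributes its own
    ``ratio``-proportioned share of test samples, so a model trained on the
    split sees (and is tested on) every acquisition session.
    """
    r_train, r_test = ratio
    if r_train <= 0 or r_test <= 0:
        raise ValueError("both split parts must be positive")
    n = len(dataset)
    frac_test = r_test / (r_train + r_test)
    rng = rng_for(seed, "split")
    train_idx, test_idx = [], []
    for e in np.unique(dataset.epoch):
        members = np.flatnonzero(dataset.epoch == e)
        members = members[rng.permutation(len(members))]
        n_test = int(round(frac_test * len(members)))
        if len(members) >= 2:
            n_test = min(max(n_test, 1), len(members) - 1)
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    if len(train) == 0 or len(test) == 0:
        raise ValueError("dataset too small for a nonempty train/test split")
    return train, test


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    split_ratio: tuple[int, int] = (8, 2)
    loss: str = "l2"  # pixelwise l2 | l1
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    eval_subset: Optional[int] = 128  # test images scored per epoch log (None = all)


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    test_pcc: float
    test_ssim: float
    test_psnr: float


def _loss_tensor(pred: Tensor, target: np.ndarray, kind: str) -> Tensor:
    diff = pred - Tensor(target)
    if kind == "l2":
        return (diff * diff).mean()
    if kind == "l1":
        # |x| = x * sign(x), sign treated as constant
        return (diff * Tensor(np.sign(diff.data))).mean()
    raise ValueError(f"unknown loss {kind!r}")


def train(
    model: RestorationModel,
    dataset: SpeckleDataset,
    config: TrainConfig,
    train_idx: Optional[np.ndarray] = None,
    test_idx: Optional[np.ndarray] = None,
    verbose: bool = False,
) -> list[EpochLog]:
    """Minimize the configured pixelwise loss; returns the per-epoch log.

    The split is derived from the config seed before training if indices are
    not supplied.  Fully reproducible: shuffling, batching and initialization
    all derive from explicit seeds.
    """
    if train_idx is None or test_idx is None:
        train_idx, test_idx = split_dataset(dataset, config.split_ratio, seed=config.seed)
    if dataset.n_label_channels != model.config.output_channels:
        raise ValueError(
            f"dataset has {dataset.n_label_channels} label channel(s) but the model "
            f"emits {model.config.output_channels}"
        )
    x = dataset.speckle.astype(np.float32)[:, None]
    y = dataset.label.astype(np.float32)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    logs: list[EpochLog] = []
    for epoch in range(config.epochs):
        order = rng_for(config.seed, "shuffle", epoch).permutation(train_idx)
        total, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            pred = model(Tensor(x[batch]))
            loss = _loss_tensor(pred, y[batch], config.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            seen += len(batch)
        sub = test_idx
        if config.eval_subset is not None and len(sub) > config.eval_subset:
            sub = sub[: config.eval_subset]
        rep = evaluate(model, dataset, sub)
        logs.append(
            EpochLog(epoch, total / max(seen, 1), rep.mean_pcc, rep.mean_ssim, rep.mean_psnr)
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {logs[-1].train_loss:.5f}  "
                f"test PCC {rep.mean_pcc:.4f}  SSIM {rep.mean_ssim:.4f}  "
                f"PSNR {rep.mean_psnr:.2f} dB"
            )
    return logs


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image, per-channel metrics plus aggregate means.

    ``per_image_*`` arrays have shape (n_images, n_channels); the scalar
    means average over both axes.  ``groups`` optionally maps a group key
    (drift epoch, thickness label, ...) to a nested MetricReport.
    """

    indices: np.ndarray
    per_image_pcc: np.ndarray
    per_image_ssim: np.ndarray
    per_image_psnr: np.ndarray
    groups: dict = field(default_factory=dict)

    @property
    def mean_pcc(self) -> float:
        return float(self.per_image_pcc.mean())

    @property
    def mean_ssim(self) -> float:
        return float(self.per_image_ssim.mean())

    @property
    def mean_psnr(self) -> float:
        return float(self.per_image_psnr.mean())

    def channel_means(self) -> dict[str, np.ndarray]:
        return {
            "pcc": self.per_image_pcc.mean(axis=0),
            "ssim": self.per_image_ssim.mean(axis=0),
            "psnr": self.per_image_psnr.mean(axis=0),
        }

    def summary(self) -> dict[str, float]:
        return {
            "pcc": self.mean_pcc,
            "ssim": self.mean_ssim,
            "psnr": self.mean_psnr,
            "pcc_std": float(self.per_image_pcc.mean(axis=1).std()),
            "ssim_std": float(self.per_image_ssim.mean(axis=1).std()),
            "psnr_std": float(self.per_image_psnr.mean(axis=1).std()),
            "n": int(len(self.indices)),
        }


def evaluate(
    model: RestorationModel,
    dataset: SpeckleDataset,
    indices: Iterable[int],
    group_by: Optional[str] = None,
    batch_size: int = 32,
) -> MetricReport:
    """Score restorations of the indexed samples against their labels.

    ``group_by`` may name a per-sample provenance field (``"epoch"``) to get
    nested per-group reports alongside the overall one.
    """
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("empty index set")
    n_ch = dataset.n_label_channels
    p = np.empty((len(idx), n_ch))
    s = np.empty((len(idx), n_ch))
    r = np.empty((len(idx), n_ch))
    for start in range(0, len(idx), batch_size):
        sel = idx[start : start + batch_size]
        pred = model.predict(dataset.speckle[sel])
        for j, i in enumerate(sel):
            for c in range(n_ch):
                truth = dataset.label[i, c].astype(np.float64)
                est = pred[j, c].astype(np.float64)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p[start + j, c] = pcc(est, truth)
                s[start + j, c] = ssim(est, truth)
                r[start + j, c] = psnr(est, truth)
    report = MetricReport(idx, p, s, r)
    if group_by is not None:
        key = getattr(dataset, group_by)
        for val in np.unique(key[idx]):
            mask = key[idx] == val
            report.groups[int(val)] = MetricReport(idx[mask], p[mask], s[mask], r[mask])
    return report
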