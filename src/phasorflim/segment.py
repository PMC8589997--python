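"""Single-fibroblast segmentation and ROI/single-cell statistics.

Fibroblasts in the dermis are segmented from a four-plane multimodal input
(NAD(P)H and FAD intensities plus their phase-lifetime maps) either with a
compact encoder-decoder pixel classifier or with a classical
intensity-threshold fallback; both share the same postprocessing contract:
threshold -> 8-connected labeling -> removal of labels below an area
threshold.  Basal keratinocytes are deliberately not single-cell segmented:
the basal unit of analysis is the whole-ROI average.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import _unet
from .io import DOSE_BY_CONDITION, AcquisitionMeta
from .phasor import MetabolicMaps

__all__ = [
    "MultimodalInput", "LabelMask", "preprocess", "postprocess_binary",
    "UNetSegmenter", "ClassicalSegmenter", "train_classifier", "predict_mask",
    "classical_mask", "roi_statistics",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class MultimodalInput:
    """Aligned, preprocessed 4-plane input: (4, H, W) float64 in [0, 1].

    Plane order: NAD(P)H intensity, FAD intensity, NAD(P)H tau_phi,
    FAD tau_phi.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != 4:
            raise ValueError("MultimodalInput needs shape (4, H, W)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class LabelMask:
    """Integer-labelled instance mask; 0 is background."""

    labels: np.ndarray

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def areas(self) -> np.ndarray:
        """Pixel area of each label, index 0 = label 1."""
        if self.n_labels == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.labels.ravel())[1:]

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _normalize_plane(plane: np.ndarray, quantile: float) -> np.ndarray:
    p = np.nan_to_num(np.asarray(plane, dtype=float), nan=0.0, posinf=0.0,
                      neginf=0.0)
    if p.size == 0:
        return p
    hi = np.quantile(p, quantile)
    p = np.minimum(p, hi)
    mx = p.max()
    return p / mx if mx > 0 else p


def preprocess(
    intensity_nadph: np.ndarray,
    intensity_fad: np.ndarray,
    tau_phi_nadph: np.ndarray,
    tau_phi_fad: np.ndarray,
    quantile: float = 0.99,
) -> MultimodalInput:
    """Clip each plane at its 0.99 quantile (outlier removal) and scale to
    [0, 1] by its maximum.  NaNs (invalid lifetime pixels) become 0."""
    planes = [intensity_nadph, intensity_fad, tau_phi_nadph, tau_phi_fad]
    shapes = {np.shape(p) for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"planes must be aligned, got shapes {shapes}")
    return MultimodalInput(
        data=np.stack([_normalize_plane(p, quantile) for p in planes]))


def postprocess_binary(binary: np.ndarray, area_threshold: float) -> LabelMask:
    """Shared postprocessing: 8-connected labeling then removal of labels
    smaller than ``area_threshold`` px^2, with sequential relabeling.
    Idempotent: applying it to its own foreground is a no-op."""
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n:
        areas = np.bincount(labels.ravel())
        keep = np.flatnonzero(areas >= area_threshold)
        keep = keep[keep > 0]
        remap = np.zeros(n + 1, dtype=np.int32)
        remap[keep] = np.arange(1, len(keep) + 1)
        labels = remap[labels]
    return LabelMask(labels=labels.astype(np.int32))


def _augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gamma or log contrast perturbation of the (already [0, 1]) planes."""
    x = x.copy()
    if rng.random() < 0.5:
        gamma = rng.uniform(0.5, 2.0)
        x = np.clip(x, 0.0, 1.0) ** gamma
    else:
        c = rng.uniform(0.5, 2.0)
        x = np.log1p(c * np.clip(x, 0.0, 1.0)) / np.log1p(c)
    return x


def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
        x = np.pad(x, pad, mode="reflect")
    return x, (h, w)


class UNetSegmenter(BaseEstimator):
    """Compact encoder-decoder fibroblast segmenter (scikit-learn style).

    Parameters
    ----------
    base_channels, depth : network width and number of pooling stages
        (defaults 8 and 2: ~3e4 parameters, trainable on a CPU in seconds
        to minutes on synthetic scenes).
    epochs, lr, batch_size, fg_weight : training schedule; the foreground
        class is up-weighted to counter the sparse-cell class imbalance.
    augment : apply gamma / log contrast augmentation during training,
        emulating the acquisition-to-acquisition contrast variability of
        real tissue data.
    prob_threshold : probability cut on the softmax foreground map (0.5).
    area_threshold : minimum label area in px^2.
    random_state : seed; training is deterministic given the seed and
        thread count.

    Attributes
    ----------
    net_ : trained network
    loss_history_ : per-epoch mean training loss
    """

    def __init__(self, base_channels: int = 8, depth: int = 2,
                 epochs: int = 30, lr: float = 2e-3, batch_size: int = 4,
                 augment: bool = True, fg_weight: float = 3.0,
                 prob_threshold: float = 0.5, area_threshold: float = 150.0,
                 random_state: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.augment = augment
        self.fg_weight = fg_weight
        self.prob_threshold = prob_threshold
        self.area_threshold = area_threshold
        self.random_state = random_state

    def fit(self, X: list[MultimodalInput], y: list[np.ndarray]
            ) -> "UNetSegmenter":
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        if len(X) < self.batch_size:
            raise ValueError(
                f"dataset of {len(X)} pairs is smaller than batch_size="
                f"{self.batch_size}"
            )
        rng = np.random.default_rng(self.random_state)
        net = _unet.UNet(in_channels=4, base_channels=self.base_channels,
                         depth=self.depth, seed=self.random_state)
        opt = _unet.Adam(net, lr=self.lr)
        xs = [np.asarray(xi.data, dtype=np.float64) for xi in X]
        ys = [np.asarray(yi > 0, dtype=np.int64) for yi in y]
        m = 2 ** self.depth
        self.loss_history_ = []
        n = len(xs)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n - self.batch_size + 1, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = np.stack([xs[i] for i in idx])
                yb = np.stack([ys[i] for i in idx])
                if self.augment:
                    xb = np.stack([_augment(b, rng) for b in xb])
                xb, (h, w) = _pad_to_multiple(xb, m)
                yb_p, _ = _pad_to_multiple(yb, m)
                logits = net.forward(xb, train=True)
                loss, dlogits = _unet.softmax_xent(logits, yb_p,
                                                   fg_weight=self.fg_weight)
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        self.net_ = net
        return self

    def predict_proba(self, X: MultimodalInput) -> np.ndarray:
        """Foreground probability map (H, W)."""
        xb, (h, w) = _pad_to_multiple(
            np.asarray(X.data, dtype=np.float64)[None], 2 ** self.depth)
        prob = _unet.softmax_prob(self.net_.forward(xb))
        return prob[0, 1, :h, :w]

    def predict(self, X: MultimodalInput) -> LabelMask:
        binary = self.predict_proba(X) >= self.prob_threshold
        return postprocess_binary(binary, self.area_threshold)

    def weights_hash(self) -> str:
        return self.net_.weights_hash()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        config = {k: v for k, v in self.get_params().items()}
        config["weights_hash"] = self.weights_hash()
        (path / "config.json").write_text(json.dumps(config, indent=1))
        np.savez(path / "weights.npz", **self.net_.state_dict())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        path = Path(path)
        config = json.loads((path / "config.json").read_text())
        expected_hash = config.pop("weights_hash", None)
        est = cls(**config)
        est.net_ = _unet.UNet(in_channels=4, base_channels=est.base_channels,
                              depth=est.depth, seed=est.random_state)
        with np.load(path / "weights.npz") as state:
            est.net_.load_state_dict(dict(state))
        if expected_hash is not None and est.weights_hash() != expected_hash:
            raise ValueError("weight hash mismatch: corrupted model artifact")
        est.loss_history_ = []
        return est


class ClassicalSegmenter(BaseEstimator):
    """Threshold-based fallback segmenter (no training required).

    Gaussian-smoothed NAD(P)H intensity is thresholded at the Otsu level
    (with an absolute floor so blank fields stay empty), morphologically
    opened, then run through the shared labeling / area-filter
    postprocessing.
    """

    def __init__(self, smooth_sigma: float = 1.0, min_intensity: float = 0.15,
                 opening_radius: int = 2, area_threshold: float = 150.0):
        self.smooth_sigma = smooth_sigma
        self.min_intensity = min_intensity
        self.opening_radius = opening_radius
        self.area_threshold = area_threshold

    def fit(self, X=None, y=None) -> "ClassicalSegmenter":
        return self

    def predict(self, X: MultimodalInput) -> LabelMask:
        from skimage.filters import threshold_otsu
        from skimage.morphology import disk, opening

        img = ndimage.gaussian_filter(X.data[0], self.smooth_sigma)
        thresh = self.min_intensity
        if img.max() > img.min():
            thresh = max(float(threshold_otsu(img)), self.min_intensity)
        binary = img > thresh
        if self.opening_radius > 0:
            binary = opening(binary, disk(self.opening_radius))
        return postprocess_binary(binary, self.area_threshold)


def train_classifier(dataset: list[tuple[MultimodalInput, np.ndarray]],
                     augment: bool = True, epochs: int = 30,
                     seed: int = 0, **kwargs) -> UNetSegmenter:
    """Train the encoder-decoder classifier on (input, truth mask) pairs."""
    X = [d[0] for d in dataset]
    y = [d[1] for d in dataset]
    return UNetSegmenter(augment=augment, epochs=epochs, random_state=seed,
                         **kwargs).fit(X, y)


def predict_mask(model: UNetSegmenter, input: MultimodalInput,
                 prob_threshold: float = 0.5,
                 area_threshold: float | None = None) -> LabelMask:
    """Probability map -> binary at threshold -> 8-connected labels ->
    area filter."""
    binary = model.predict_proba(input) >= prob_threshold
    at = model.area_threshold if area_threshold is None else area_threshold
    return postprocess_binary(binary, at)


def classical_mask(input: MultimodalInput,
                   params: dict | None = None) -> LabelMask:
    """Classical fallback with the same postprocessing contract."""
    return ClassicalSegmenter(**(params or {})).predict(input)


def _unit_row(maps: MetabolicMaps, sel: np.ndarray, weighted: bool) -> dict:
    ph = maps.phasor
    w = ph.intensity[sel].astype(float)
    if not weighted:
        w = np.ones_like(w)
    if w.sum() <= 0:
        return {}
    z = complex((ph.g[sel] * w).sum() / w.sum(), (ph.s[sel] * w).sum() / w.sum())
    omega = ph.omega
    a, b = maps.free_anchor, maps.bound_anchor
    f = ((z - a) * np.conj(b - a)).real / abs(b - a) ** 2
    tau_phi = z.imag / (z.real * omega) if z.real > 0 else np.nan
    m2 = abs(z) ** 2
    tau_mod = np.sqrt(1.0 / m2 - 1.0) / omega if 0 < m2 <= 1 else np.nan
    return dict(f_bound=float(np.clip(f, 0.0, 1.0)), tau_phi=float(tau_phi),
                tau_mod=float(tau_mod), n_pixels=int(sel.sum()))


def roi_statistics(
    maps: dict[str, MetabolicMaps] | MetabolicMaps,
    mask_or_roi: LabelMask | np.ndarray | None = None,
    unit: str = "roi",
    meta: dict[str, AcquisitionMeta] | None = None,
    intensity_weighted: bool = True,
) -> pd.DataFrame:
    """Per-ROI or per-cell study-table rows from metabolic maps.

    ``unit="roi"`` (basal layer): one row per channel, from the
    intensity-weighted mean phasor over valid pixels (optionally restricted
    to a boolean/label ROI mask); fraction-of-bound and lifetimes are derived
    from the mean phasor.  ``unit="cell"`` (dermis): one row per label of the
    instance mask — cells are never pooled.
    """
    if isinstance(maps, MetabolicMaps):
        maps = {maps.channel: maps}
    if unit not in ("roi", "cell"):
        raise ValueError("unit must be 'roi' or 'cell'")
    labels = None
    if mask_or_roi is not None:
        labels = (mask_or_roi.labels if isinstance(mask_or_roi, LabelMask)
                  else np.asarray(mask_or_roi))
    if unit == "cell" and labels is None:
        raise ValueError("per-cell statistics need an instance mask")
    rows = []
    for chan, mm in maps.items():
        m = (meta or {}).get(chan)
        base = dict(
            sample_id=m.sample_id if m else "",
            condition=m.condition.value if m and m.condition else "",
            dose=DOSE_BY_CONDITION[m.condition] if m and m.condition else np.nan,
            timepoint=m.timepoint.value if m and m.timepoint else "",
            layer=m.layer.value if m and m.layer else "",
            roi_id=m.roi_id if m else "",
            biomarker=chan,
        )
        valid = mm.valid
        if unit == "roi":
            sel = valid if labels is None else (valid & (labels > 0))
            vals = _unit_row(mm, sel, intensity_weighted)
            if vals:
                rows.append(base | dict(unit_type="ROI",
                                        unit_id=base["roi_id"]) | vals)
        else:
            for k in range(1, int(labels.max()) + 1):
                sel = valid & (labels == k)
                vals = _unit_row(mm, sel, intensity_weighted)
                if vals:
                    rows.append(base | dict(
                        unit_type="cell",
                        unit_id=f"{base['roi_id']}-C{k}") | vals)
    return pd.DataFrame(rows)
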