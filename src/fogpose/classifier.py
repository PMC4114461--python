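"""Vision-based heading classification from plan-view height templates.

A person standing upright leaves a characteristic top-down height
footprint (shoulder ellipse plus a head blob displaced toward the ventral
side). A small feed-forward network maps a 21x21 normalized height window
(441 values) plus the normalization constant and the non-zero cell count
-- 443 features in all -- to one of eight headings spaced 45 degrees
apart. The winning output unit's activation doubles as a classification
quality score; tracked over consecutive frames it yields the *static
heading* proposition used by the vision-inertial fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .planview import PlanViewMaps

__all__ = [
    "HeightTemplate",
    "HeadingClassifierModel",
    "extract_height_template",
    "train_classifier",
    "classify",
    "confirm_static_heading",
    "StaticHeadingTracker",
    "TEMPLATE_SIZE",
    "N_CLASSES",
]

TEMPLATE_SIZE = 21
N_CLASSES = 8
N_FEATURES = TEMPLATE_SIZE * TEMPLATE_SIZE + 2  # 443


@dataclass(frozen=True)
class HeightTemplate:
    """21x21 window of heights normalized by the window maximum, plus the
    normalization constant (m) and the count of non-zero cells."""

    values: np.ndarray
    norm_constant: float
    nonzero_count: int

    def feature_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.values.ravel(),
                [self.norm_constant, float(self.nonzero_count)],
            ]
        )


def extract_height_template(
    maps: PlanViewMaps, center, size: int = TEMPLATE_SIZE
) -> HeightTemplate:
    """Cut a ``size x size`` height window centered on the person.

    Cells outside the connected component nearest the center are zeroed so
    neighboring objects do not leak into the template; heights are divided
    by the window maximum (stored as ``norm_constant``). An empty window
    is returned as the valid degenerate all-zero template.
    """
    cx, cy = maps.cell_index(center[0], center[1])
    if not maps.in_bounds(np.array(cx), np.array(cy)):
        raise ValueError("template center outside the map bounds")
    half = size // 2
    nx, ny = maps.shape
    window = np.zeros((size, size))
    x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, nx)
    y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, ny)
    window[
        x_lo - (cx - half) : x_hi - (cx - half),
        y_lo - (cy - half) : y_hi - (cy - half),
    ] = maps.height[x_lo:x_hi, y_lo:y_hi]

    occupied = window > 0
    if not occupied.any():
        return HeightTemplate(values=window, norm_constant=0.0, nonzero_count=0)

    labels, _ = ndimage.label(occupied, structure=np.ones((3, 3)))
    center_label = labels[half, half]
    if center_label == 0:
        # pick the component closest to the window center
        ii, jj = np.nonzero(occupied)
        d2 = (ii - half) ** 2 + (jj - half) ** 2
        center_label = labels[ii[np.argmin(d2)], jj[np.argmin(d2)]]
    window = np.where(labels == center_label, window, 0.0)

    norm = float(window.max())
    values = window / norm
    return HeightTemplate(
        values=values,
        norm_constant=norm,
        nonzero_count=int(np.count_nonzero(values)),
    )


# ---------------------------------------------------------------------------
# The 443-25-8 network


@dataclass
class HeadingClassifierModel:
    """Feed-forward net 443 -> 25 -> 8 with symmetric-sigmoid (tanh) units.

    Inputs are standardized with the training-set mean/std; targets are
    one-hot in {-1, +1}; class k encodes heading k * 45 degrees.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    input_mean: np.ndarray
    input_std: np.ndarray
    epochs: int = 0
    learning_rate: float = 0.0
    seed: int = 0

    def forward(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(features)
        x = (x - self.input_mean) / self.input_std
        h = np.tanh(x @ self.w1 + self.b1)
        return np.tanh(h @ self.w2 + self.b2)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(features), axis=1)

    def to_json(self, path):
        payload = {
            "topology": [N_FEATURES, self.w1.shape[1], N_CLASSES],
            "activation": "symmetric_sigmoid",
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "input_mean": self.input_mean.tolist(),
            "input_std": self.input_std.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HeadingClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            w1=np.array(d["w1"]),
            b1=np.array(d["b1"]),
            w2=np.array(d["w2"]),
            b2=np.array(d["b2"]),
            input_mean=np.array(d["input_mean"]),
            input_std=np.array(d["input_std"]),
            epochs=d["epochs"],
            learning_rate=d["learning_rate"],
            seed=d["seed"],
        )


def train_classifier(
    templates,
    labels,
    epochs: int = 200,
    lr: float = 0.01,
    seed: int = 0,
    hidden: int = 25,
    batch_size: int = 32,
) -> HeadingClassifierModel:
    """Classic back-propagation (mini-batch SGD on mean squared error)
    with symmetric sigmoid activations; deterministic given the seed.

    ``templates`` may be :class:`HeightTemplate` objects or ready feature
    vectors of length 443; ``labels`` are classes 0..7.
    """
    feats = np.array(
        [
            t.feature_vector() if isinstance(t, HeightTemplate) else np.asarray(t)
            for t in templates
        ],
        dtype=float,
    )
    y = np.asarray(labels, dtype=int)
    if feats.size == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= N_CLASSES:
        raise ValueError("labels must be in 0..7")
    present = np.unique(y)
    if len(present) < N_CLASSES:
        import warnings

        missing = sorted(set(range(N_CLASSES)) - set(present.tolist()))
        warnings.warn(f"classes missing from training data: {missing}")

    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std < 1e-9] = 1.0
    x = (feats - mean) / std
    targets = -np.ones((len(y), N_CLASSES))
    targets[np.arange(len(y)), y] = 1.0

    rng = np.random.default_rng(seed)
    n_in = x.shape[1]
    w1 = rng.uniform(-1, 1, (n_in, hidden)) * np.sqrt(6.0 / (n_in + hidden))
    b1 = np.zeros(hidden)
    w2 = rng.uniform(-1, 1, (hidden, N_CLASSES)) * np.sqrt(6.0 / (hidden + N_CLASSES))
    b2 = np.zeros(N_CLASSES)

    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, tb = x[idx], targets[idx]
            h = np.tanh(xb @ w1 + b1)
            o = np.tanh(h @ w2 + b2)
            # MSE gradient through tanh output units
            d_o = (o - tb) * (1.0 - o**2)
            d_h = (d_o @ w2.T) * (1.0 - h**2)
            m = len(idx)
            w2 -= lr * (h.T @ d_o) / m
            b2 -= lr * d_o.mean(axis=0)
            w1 -= lr * (xb.T @ d_h) / m
            b1 -= lr * d_h.mean(axis=0)

    return HeadingClassifierModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        input_mean=mean,
        input_std=std,
        epochs=epochs,
        learning_rate=lr,
        seed=seed,
    )


def classify(model: HeadingClassifierModel, template):
    """Classify one template.

    Returns ``(class, heading_deg, quality)`` where heading = class * 45
    and quality is the winning unit's activation rescaled from [-1, 1] to
    [0, 1]. Ties go to the lowest class index; an all-zero template gets
    quality 0.
    """
    if isinstance(template, HeightTemplate):
        feats = template.feature_vector()
        empty = template.nonzero_count == 0
    else:
        feats = np.asarray(template, dtype=float)
        empty = not np.any(feats[: TEMPLATE_SIZE * TEMPLATE_SIZE])
    out = model.forward(feats)[0]
    cls = int(np.argmax(out))  # argmax takes the lowest index on ties
    quality = 0.0 if empty else float(np.clip((out[cls] + 1.0) / 2.0, 0.0, 1.0))
    return cls, cls * 45.0, quality


class StaticHeadingTracker:
    """Temporal consistency gate for the classifier output.

    Emits the class heading once the same class with quality above the
    threshold has persisted for ``k_frames`` consecutive frames; any
    class change or quality dip resets the run.
    """

    def __init__(self, q_threshold: float = 0.8, k_frames: int = 3):
        self.q_threshold = q_threshold
        self.k_frames = k_frames
        self._run_class: int | None = None
        self._run_len = 0

    def update(self, cls: int | None, quality: float | None) -> float | None:
        if cls is None or quality is None or quality <= self.q_threshold:
            self._run_class, self._run_len = None, 0
            return None
        if cls != self._run_class:
            self._run_class, self._run_len = cls, 1
        else:
            self._run_len += 1
        if self._run_len >= self.k_frames:
            return cls * 45.0
        return None

    def reset(self):
        self._run_class, self._run_len = None, 0


def confirm_static_heading(stream, q_threshold: float = 0.8, k_frames: int = 3):
    """Run the consistency gate over a ``(class, quality)`` stream.

    Returns the first confirmed static heading, or None.
    """
    tracker = StaticHeadingTracker(q_threshold, k_frames)
    for cls, quality in stream:
        heading = tracker.update(cls, quality)
        if heading is not None:
            return heading
    return None
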