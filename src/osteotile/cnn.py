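"""Patch-level deep-learning path.

A small convolutional network classifies 128x128 RGB patches into NT/NEC/VT:
three valid-padding convolution + 2x2 max-pool pairs (5x5/4, 5x5/8, 3x3/16
filters), then two fully connected layers (256 hidden units, 3 outputs).
Hidden activations are logistic sigmoids; the output layer is multinomial
logistic regression (softmax).  Training is minibatch stochastic gradient
descent with Nesterov momentum (gamma 0.9), learning rate 1e-3, batch 100,
20 epochs, weights initialized N(0, 0.01) (variance; std 0.1).

Preprocessing mirrors the slide-scanning realities the network must ignore:

* **Euler-value significance filter** — mostly-background patches are
  detected by the Euler number (objects minus holes) of the Otsu-binarized
  dark-tissue image; the default keeps patches with e >= -3.
* **Lightness normalization** — the L channel of CIELAB is rescaled to a
  fixed mean/spread, leaving a*/b* untouched, to cancel illumination and
  contrast differences between scans.
* **Augmentation** — the 8 dihedral transforms of the square patch, and a
  PCA color shift: each image gains q . (lambda o alpha) per pixel, with
  (q_i, lambda_i) the eigenpairs of the pooled 3x3 RGB covariance and
  alpha_i ~ N(1, 0.1) drawn once per image.

The network is implemented directly in numpy (im2col convolutions); no GPU
or deep-learning framework is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi
from scipy.special import expit
from skimage import color as skcolor
from skimage.filters import threshold_otsu

from .synth import CLASS_LABELS, PatchRecord

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


# ---------------------------------------------------------------------------
# Preprocessing

def euler_value(patch: np.ndarray) -> int:
    """Euler number of the patch: dark-tissue objects minus their holes.

    The patch is binarized by global Otsu with the darker (stain-dense) side
    as foreground; objects are 8-connected foreground components, holes are
    4-connected background components that do not touch the image border.
    A constant (pure background) patch has no objects and no holes: e = 0.
    """
    arr = np.asarray(patch)
    gray = skcolor.rgb2gray(arr) if arr.ndim == 3 else arr.astype(float)
    if np.all(gray == gray.flat[0]):
        return 0
    fore = gray < threshold_otsu(gray)
    _, n_obj = ndi.label(fore, structure=_STRUCT8)
    bg_labels, n_bg = ndi.label(~fore, structure=_STRUCT4)
    border = np.unique(np.concatenate([
        bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]]))
    n_border = np.count_nonzero(border)
    n_holes = n_bg - n_border
    return int(n_obj - n_holes)


def significance_filter(patches: list[PatchRecord], threshold: int = -3,
                        keep_greater_equal: bool = True) -> list[PatchRecord]:
    """Flag and return the significant patches (default: keep e >= -3).

    Computes the Euler value for patches that lack one, sets ``keep`` on all
    records, and returns the kept subset.  Raising the keep-threshold never
    adds patches.
    """
    kept = []
    for p in patches:
        if p.euler is None:
            p.euler = euler_value(p.image)
        p.keep = (p.euler >= threshold) if keep_greater_equal else (p.euler <= threshold)
        if p.keep:
            kept.append(p)
    return kept


def lightness_normalize(patch: np.ndarray, target_mean: float = 70.0,
                        target_std: float = 12.0) -> np.ndarray:
    """Rescale the CIELAB L channel to a fixed mean/spread; a*, b* untouched.

    Returns float RGB in [0, 255].  A constant-L patch is shifted to the
    target mean.  Near-idempotent: normalizing twice equals normalizing once
    up to float round-trip error.
    """
    arr = np.asarray(patch, dtype=float) / 255.0
    lab = skcolor.rgb2lab(arr)
    L = lab[..., 0]
    mu, sd = L.mean(), L.std()
    if sd > 1e-9:
        lab[..., 0] = np.clip((L - mu) / sd * target_std + target_mean, 0, 100)
    else:
        lab[..., 0] = target_mean
    out = skcolor.lab2rgb(lab)
    return np.clip(out, 0, 1) * 255.0


def dihedral_augment(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral-group images of a square patch.

    Order: identity, rot90, rot180, rot270, horizontal flip, vertical flip,
    and the two flipped rotations (transpose / anti-transpose).
    """
    arr = np.asarray(patch)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("dihedral_augment requires a square patch")
    f = np.flip(arr, axis=1)  # mirror along the vertical axis
    return [arr.copy(),
            np.rot90(arr, 1).copy(), np.rot90(arr, 2).copy(), np.rot90(arr, 3).copy(),
            f.copy(), np.flip(arr, axis=0).copy(),
            np.rot90(f, 1).copy(), np.rot90(f, 3).copy()]


def pca_color_augment(patches: np.ndarray, seed: int = 0,
                      alpha_mean: float = 1.0, alpha_sd: float = 0.1
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-image principal-color perturbation of a patch stack.

    The 3x3 covariance of all RGB pixels (unit scale, pooled over the stack)
    is eigen-decomposed; each image receives the additive per-pixel shift
    ``Q @ (lambda * alpha)`` with alpha_i ~ N(alpha_mean, alpha_sd) drawn
    once per image.  ``alpha_mean=1`` follows the published scheme; set 0
    for the canonical zero-centered variant.  Returns
    ``(augmented uint8 stack, eigenvalues desc, eigenvectors as columns)``.
    """
    X = np.asarray(patches)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("expected a stack of shape (n, h, w, 3)")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 patches for a nondegenerate covariance")
    flat = X.reshape(-1, 3).astype(float) / 255.0
    cov = np.cov(flat, rowvar=False)
    lam, Q = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, Q = lam[order], Q[:, order]
    if np.any(lam < 1e-12):
        warnings.warn("rank-deficient RGB covariance: zero shift along "
                      "null color directions")
        lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    alphas = rng.normal(alpha_mean, alpha_sd, size=(X.shape[0], 3))
    shifts = (Q @ (lam[:, None] * alphas.T)).T * 255.0  # (n, 3)
    out = X.astype(float) + shifts[:, None, None, :]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), lam, Q


@dataclass(frozen=True)
class AugmentationSpec:
    """Training-fold augmentation: the 8-member dihedral set plus PCA color
    perturbation (alpha ~ N(alpha_mean, alpha_sd) per image).

    Applied to training data only — augmenting before a split would leak
    transformed copies of test patches into training.
    """

    dihedral: bool = True
    pca: bool = True
    alpha_mean: float = 1.0
    alpha_sd: float = 0.1
    seed: int = 0

    @property
    def geometric_count(self) -> int:
        return 8 if self.dihedral else 1


def augment_training_set(X: np.ndarray, y: np.ndarray,
                         spec: AugmentationSpec = AugmentationSpec()
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Expand a training patch stack by the configured augmentations.

    Dihedral transforms multiply the set by 8 (each transform keeps the
    label); the PCA color shift then perturbs every image once.
    """
    if spec.dihedral:
        X = np.concatenate([np.stack(dihedral_augment(img)) for img in X])
        y = np.repeat(y, 8)
    if spec.pca:
        X, _, _ = pca_color_augment(X, seed=spec.seed,
                                    alpha_mean=spec.alpha_mean,
                                    alpha_sd=spec.alpha_sd)
    return X, y


# ---------------------------------------------------------------------------
# Network configuration

@dataclass(frozen=True)
class CnnConfig:
    """Architecture and optimization hyperparameters.

    Only the first conv layer's filter count (4) is pinned by the reference
    feature-map size 62x62x4; later widths default to 8 and 16.  ``init_sd``
    is the std of the N(0, 0.01)-variance weight initialization.
    """

    input_size: int = 128
    kernels: tuple[int, int, int] = (5, 5, 3)
    filters: tuple[int, int, int] = (4, 8, 16)
    pool: int = 2
    hidden: int = 256
    n_classes: int = 3
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 100
    momentum: float = 0.9
    init_sd: float = 0.1
    seed: int = 0


def layer_shapes(config: CnnConfig) -> list[tuple[int, int, int]]:
    """Spatial edge after each conv-pool pair: (in, after conv, after pool).

    Valid-padding convolution (edge - k + 1) then floor-halving pooling;
    128 -> 124 -> 62 for the first pair.
    """
    edge = config.input_size
    shapes = []
    for k in config.kernels:
        conv_edge = edge - k + 1
        pool_edge = conv_edge // config.pool
        if pool_edge <= 0:
            raise ValueError(f"non-positive feature map edge after kernel {k}")
        shapes.append((edge, conv_edge, pool_edge))
        edge = pool_edge
    return shapes


@dataclass
class PatchPrediction:
    parent_tin: str
    probabilities: np.ndarray  # (3,) NT/NEC/VT order, sums to 1
    label: str


# ---------------------------------------------------------------------------
# The network

def _sigmoid(z):
    return expit(z)


def _conv_forward(x, W, b):
    # x (N,H,W,C); W (k,k,C,F).  im2col once, contiguous, reused in backward.
    k, _, C, F = W.shape
    n, H, Wd, _ = x.shape
    Ho, Wo = H - k + 1, Wd - k + 1
    cols = sliding_window_view(x, (k, k), axis=(1, 2))      # (n,Ho,Wo,C,k,k)
    cols_mat = cols.reshape(n * Ho * Wo, C * k * k)          # copy, [c,u,v]
    W_mat = W.transpose(2, 0, 1, 3).reshape(C * k * k, F)
    pre = (cols_mat @ W_mat).reshape(n, Ho, Wo, F) + b
    return pre, cols_mat


def _conv_backward_weights(cols_mat, dpre, kernel, channels):
    k, C, F = kernel, channels, dpre.shape[-1]
    dW_mat = cols_mat.T @ dpre.reshape(-1, F)
    return dW_mat.reshape(C, k, k, F).transpose(1, 2, 0, 3)


def _conv_backward_input(dpre, W, chunk: int = 32):
    # full correlation of dpre with the 180-degree rotated kernels
    k, _, C, F = W.shape
    Wr_mat = W[::-1, ::-1, :, :].transpose(3, 0, 1, 2).reshape(F * k * k, C)
    n = dpre.shape[0]
    outs = []
    pad = ((0, 0), (k - 1, k - 1), (k - 1, k - 1), (0, 0))
    for s in range(0, n, chunk):
        dp = np.pad(dpre[s:s + chunk], pad)
        m, H, Wd = dp.shape[0], dp.shape[1] - k + 1, dp.shape[2] - k + 1
        win = sliding_window_view(dp, (k, k), axis=(1, 2))   # (m,H,W,F,k,k)
        win_mat = win.reshape(m * H * Wd, F * k * k)
        outs.append((win_mat @ Wr_mat).reshape(m, H, Wd, C))
    return np.concatenate(outs, axis=0)


def _pool_forward(a, p=2):
    n, h, w, f = a.shape
    h2, w2 = h // p, w // p
    r = a[:, :h2 * p, :w2 * p, :].reshape(n, h2, p, w2, p, f)
    r = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, f, p * p)
    am = r.argmax(axis=-1)
    pooled = np.take_along_axis(r, am[..., None], axis=-1)[..., 0]
    return pooled, am, (h, w)


def _pool_backward(dpool, am, in_shape, p=2):
    n, h2, w2, f = dpool.shape
    h, w = in_shape
    scat = np.zeros((n, h2, w2, f, p * p), dtype=dpool.dtype)
    np.put_along_axis(scat, am[..., None], dpool[..., None], axis=-1)
    scat = scat.reshape(n, h2, w2, f, p, p).transpose(0, 1, 4, 2, 5, 3)
    out = np.zeros((n, h, w, f), dtype=dpool.dtype)
    out[:, :h2 * p, :w2 * p, :] = scat.reshape(n, h2 * p, w2 * p, f)
    return out


class PatchCNN:
    """Minimal numpy implementation of the 3-conv / 3-pool / 2-MLP network.

    Deterministic given the config seed and a fixed iteration order; training
    state (Nesterov velocity buffers) lives on the instance.
    """

    def __init__(self, config: CnnConfig = CnnConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k1, k2, k3 = config.kernels
        f1, f2, f3 = config.filters
        sd = config.init_sd
        shapes = layer_shapes(config)
        flat = shapes[-1][2] ** 2 * f3
        def init(*shape):
            return rng.normal(0.0, sd, size=shape).astype(np.float32)
        self.params = {
            "W1": init(k1, k1, 3, f1), "b1": np.zeros(f1, dtype=np.float32),
            "W2": init(k2, k2, f1, f2), "b2": np.zeros(f2, dtype=np.float32),
            "W3": init(k3, k3, f2, f3), "b3": np.zeros(f3, dtype=np.float32),
            "W4": init(flat, config.hidden), "b4": np.zeros(config.hidden, dtype=np.float32),
            "W5": init(config.hidden, config.n_classes),
            "b5": np.zeros(config.n_classes, dtype=np.float32),
        }
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.input_stats: tuple[np.ndarray, np.ndarray] | None = None
        self.history: list[dict[str, float]] = []

    # -- data plumbing ------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        mean, std = self.input_stats
        return ((X.astype(np.float32) / 255.0) - mean) / std

    def fit_input_stats(self, X: np.ndarray) -> None:
        x = X.astype(np.float32) / 255.0
        mean = x.mean(axis=(0, 1, 2))
        std = np.maximum(x.std(axis=(0, 1, 2)), 1e-6)
        self.input_stats = (mean, std)

    # -- forward / backward -------------------------------------------------

    def _forward(self, xb, train=False):
        P = self.params
        cache = {}
        a = xb
        for layer in (1, 2, 3):
            pre, cols_mat = _conv_forward(a, P[f"W{layer}"], P[f"b{layer}"])
            act = _sigmoid(pre)
            pooled, am, in_shape = _pool_forward(act, self.config.pool)
            if train:
                cache[layer] = (cols_mat, act, am, in_shape)
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        z4 = flat @ P["W4"] + P["b4"]
        a4 = _sigmoid(z4)
        z5 = a4 @ P["W5"] + P["b5"]
        z5 = z5 - z5.max(axis=1, keepdims=True)
        e = np.exp(z5)
        probs = e / e.sum(axis=1, keepdims=True)
        if train:
            cache["flat"] = flat
            cache["a4"] = a4
            cache["pool3_shape"] = a.shape
        return probs, cache

    def _backward(self, probs, yb, cache):
        P = self.params
        # gradients are accumulated per sample (summed over the minibatch):
        # the stated learning rate is a per-sample rate, as in classical
        # LeNet-style SGD; batch-mean averaging would shrink the effective
        # step by the batch size
        grads = {}
        dz5 = probs - yb
        grads["W5"] = cache["a4"].T @ dz5
        grads["b5"] = dz5.sum(axis=0)
        da4 = dz5 @ P["W5"].T
        dz4 = da4 * cache["a4"] * (1 - cache["a4"])
        grads["W4"] = cache["flat"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        dflat = dz4 @ P["W4"].T
        da = dflat.reshape(cache["pool3_shape"])
        for layer in (3, 2, 1):
            cols_mat, act, am, in_shape = cache[layer]
            dact = _pool_backward(da, am, in_shape, self.config.pool)
            dpre = dact * act * (1 - act)
            W = P[f"W{layer}"]
            grads[f"W{layer}"] = _conv_backward_weights(
                cols_mat, dpre, W.shape[0], W.shape[2])
            grads[f"b{layer}"] = dpre.sum(axis=(0, 1, 2))
            if layer > 1:
                da = _conv_backward_input(dpre, W)
        return grads

    def _sgd_step(self, grads):
        lr = self.config.learning_rate
        gamma = self.config.momentum
        for k, g in grads.items():
            buf = self.velocity[k]
            buf *= gamma
            buf += g
            self.params[k] -= lr * (g + gamma * buf)

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int | None = None,
            shuffle_seed: int | None = None) -> "PatchCNN":
        """Train on a uint8 patch stack (n, 128, 128, 3) and integer class
        indices (or string labels) by minibatch SGD with Nesterov momentum."""
        y_idx = self._as_indices(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.input_stats is None:
            self.fit_input_stats(X)
        epochs = self.config.epochs if epochs is None else epochs
        rng = np.random.default_rng(
            self.config.seed + 1 if shuffle_seed is None else shuffle_seed)
        Y = np.eye(self.config.n_classes, dtype=np.float32)[y_idx]
        bs = self.config.batch_size
        for _ in range(epochs):
            order = rng.permutation(X.shape[0])
            losses, hits, total = [], 0, 0
            for s in range(0, X.shape[0], bs):
                sel = order[s:s + bs]
                xb = self._standardize(X[sel])
                probs, cache = self._forward(xb, train=True)
                eps = 1e-12
                losses.append(float(
                    -(Y[sel] * np.log(probs + eps)).sum(axis=1).mean()))
                hits += int((probs.argmax(1) == y_idx[sel]).sum())
                total += len(sel)
                grads = self._backward(probs, Y[sel], cache)
                self._sgd_step(grads)
            self.history.append({"loss": float(np.mean(losses)),
                                 "accuracy": hits / total})
        return self

    def predict_proba(self, X: np.ndarray, batch: int = 100) -> np.ndarray:
        out = []
        for s in range(0, X.shape[0], batch):
            xb = self._standardize(X[s:s + batch])
            probs, _ = self._forward(xb, train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        return np.asarray(CLASS_LABELS)[idx]

    @staticmethod
    def _as_indices(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "iu":
            return y.astype(np.int64)
        index = {c: i for i, c in enumerate(CLASS_LABELS)}
        return np.array([index[v] for v in y], dtype=np.int64)


def patches_to_array(patches: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack PatchRecords into (uint8 images (n,h,w,3), labels array)."""
    X = np.stack([p.image for p in patches]).astype(np.uint8)
    y = np.array([p.label for p in patches])
    return X, y


def train_cnn(patches, labels=None, config: CnnConfig = CnnConfig()) -> PatchCNN:
    """Train the patch network on PatchRecords (or an image stack + labels).

    Patches are expected to be significance-filtered and normalized upstream;
    augmentation, when used, must be applied to training folds only.
    """
    if labels is None:
        X, y = patches_to_array(patches)
    else:
        X, y = np.asarray(patches), np.asarray(labels)
    model = PatchCNN(config)
    return model.fit(X, y)


def predict_patches(model: PatchCNN, patches: list[PatchRecord]
                    ) -> list[PatchPrediction]:
    X, _ = patches_to_array(patches)
    probs = model.predict_proba(X)
    preds = []
    for p, pr in zip(patches, probs):
        preds.append(PatchPrediction(parent_tin=p.parent_tin,
                                     probabilities=pr,
                                     label=CLASS_LABELS[int(pr.argmax())]))
    return preds


def tile_vote(predictions: list[PatchPrediction]) -> str:
    """Aggregate one tile's kept-patch predictions to a tile label.

    Majority vote; ties broken by the highest mean probability among the tied
    classes; a tile with zero kept patches defaults to NT with a warning.
    """
    if not predictions:
        warnings.warn("tile with zero kept patches: defaulting to NT")
        return "NT"
    votes = np.zeros(3)
    mean_probs = np.zeros(3)
    for p in predictions:
        votes[CLASS_LABELS.index(p.label)] += 1
        mean_probs += p.probabilities
    mean_probs /= len(predictions)
    best = np.flatnonzero(votes == votes.max())
    if len(best) == 1:
        return CLASS_LABELS[best[0]]
    return CLASS_LABELS[best[np.argmax(mean_probs[best])]]
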