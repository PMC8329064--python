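"""Patch-based semantic segmentation of H&E histology into 8 tumour regions.

The model is a fully convolutional DenseNet ("tiramisu"-style encoder/decoder
with dense blocks and skip connections) implemented on a small reverse-mode
tape over numpy arrays, trained with sparse categorical cross-entropy, an L2
weight penalty and RMSprop.  A desk-scale preset (2 down blocks, 2 layers per
block, growth 8) trains in minutes on one CPU; the 103-layer layout of the
original design is expressible through the same config.

Conventions: images are ``uint8`` RGB ``(H, W, 3)``; masks are ``uint8``
``(H, W)`` with labels 0..7; batches are ``(N, H, W, C)`` float32.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .util import get_logger

log = get_logger("segmentation")

# ---------------------------------------------------------------------------
# Region classes
# ---------------------------------------------------------------------------

#: The eight semantic classes, label index = position.  BG is label 0.
REGION_LABELS: tuple[str, ...] = (
    "BG", "LE", "IT", "CT", "CTmvp", "CTpan", "CTpnz", "CTne",
)

#: Non-background tumour regions, in label order.
TUMOUR_REGIONS: tuple[str, ...] = REGION_LABELS[1:]

#: Display palette.  CT green, IT purple, CTmvp orange, CTne black follow the
#: conventional mask colouring for these regions; the rest are distinct.
REGION_COLORS: dict[str, tuple[int, int, int]] = {
    "BG": (255, 255, 255),
    "LE": (64, 128, 255),
    "IT": (128, 0, 192),
    "CT": (0, 160, 0),
    "CTmvp": (255, 128, 0),
    "CTpan": (0, 128, 128),
    "CTpnz": (192, 192, 64),
    "CTne": (0, 0, 0),
}


@dataclass(frozen=True)
class RegionClassMap:
    """Ordered mapping label index <-> region name <-> display colour."""

    labels: tuple[str, ...] = REGION_LABELS
    colors: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(REGION_COLORS))

    def __post_init__(self):
        if len(self.labels) != 8:
            raise ValueError("exactly 8 region classes are required")
        if self.labels[0] != "BG":
            raise ValueError("label 0 must be BG")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index(self, name: str) -> int:
        return self.labels.index(name)

    def name(self, idx: int) -> str:
        return self.labels[idx]

    def palette(self) -> list[int]:
        """Flat RGB palette for indexed-PNG writing (256 * 3 ints)."""
        pal = []
        for lab in self.labels:
            pal.extend(self.colors[lab])
        pal.extend([0] * (768 - len(pal)))
        return pal


CLASS_MAP = RegionClassMap()


@dataclass
class LabeledSlide:
    """An RGB histology image paired with its 8-class region label mask.

    ``nuclei`` optionally records planted nuclei centroids per region
    (synthetic slides only; real slides carry ``None``).
    """

    image: np.ndarray
    mask: np.ndarray
    nuclei: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match image")


# ---------------------------------------------------------------------------
# Pre-processing: resize, patches, normalisation, augmentation
# ---------------------------------------------------------------------------

def resize_pair(slide: LabeledSlide, target_size: int) -> LabeledSlide:
    """Resize image and mask to a square ``target_size``.

    The image is resampled bilinearly; the mask strictly nearest-neighbour so
    labels are never blended.  Identity sizes return byte-identical copies.
    """
    from skimage.transform import resize as _sk_resize

    if not np.isscalar(target_size):
        raise ValueError("target size must be a single integer (square output)")
    target_size = int(target_size)
    if target_size < 32:
        raise ValueError("target_size must be >= 32")
    h, w = slide.mask.shape
    if (h, w) == (target_size, target_size):
        return LabeledSlide(slide.image.copy(), slide.mask.copy())
    img = _sk_resize(slide.image, (target_size, target_size), order=1,
                     preserve_range=True, anti_aliasing=True)
    msk = _sk_resize(slide.mask, (target_size, target_size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return LabeledSlide(np.clip(np.rint(img), 0, 255).astype(np.uint8),
                        msk.astype(np.uint8))


@dataclass
class PatchSet:
    """Systematic grid tiling of one slide (row-major patch order)."""

    patches: list[tuple[np.ndarray, np.ndarray | None, int, int]]
    patch_size: int
    stride: int
    source_size: tuple[int, int]
    padded_size: tuple[int, int]
    padding_mode: str

    def __len__(self) -> int:
        return len(self.patches)


def _grid_steps(size: int, patch: int, stride: int) -> int:
    if size <= patch:
        return 1
    return int(np.ceil((size - patch) / stride)) + 1


def extract_patches(slide: LabeledSlide | np.ndarray, patch_size: int,
                    stride: int | None = None) -> PatchSet:
    """Systematically tile an image (and mask) on a regular grid.

    If the image does not divide evenly, it is reflection-padded on the
    bottom/right up to the next grid-covering size; :func:`stitch_patches`
    strips the padding, so the round trip is pixel-exact.
    """
    if isinstance(slide, LabeledSlide):
        image, mask = slide.image, slide.mask
    else:
        image, mask = np.asarray(slide), None
    patch_size = int(patch_size)
    stride = patch_size if stride is None else int(stride)
    if patch_size < 16:
        raise ValueError("patch_size must be >= 16")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    if patch_size > max(2 * h - 2, 1) or patch_size > max(2 * w - 2, 1):
        raise ValueError(
            f"patch_size {patch_size} too large for source {h}x{w}")
    nr, nc = _grid_steps(h, patch_size, stride), _grid_steps(w, patch_size, stride)
    ph = (nr - 1) * stride + patch_size
    pw = (nc - 1) * stride + patch_size
    mode = "reflect" if (ph, pw) != (h, w) else "none"
    pads = ((0, ph - h), (0, pw - w))
    img_p = np.pad(image, pads + ((0, 0),), mode="reflect") if mode != "none" else image
    msk_p = None
    if mask is not None:
        msk_p = np.pad(mask, pads, mode="reflect") if mode != "none" else mask
    patches = []
    for r in range(nr):
        for c in range(nc):
            y, x = r * stride, c * stride
            it = img_p[y:y + patch_size, x:x + patch_size]
            mt = msk_p[y:y + patch_size, x:x + patch_size] if msk_p is not None else None
            patches.append((it.copy(), None if mt is None else mt.copy(), r, c))
    return PatchSet(patches, patch_size, stride, (h, w), (ph, pw), mode)


def stitch_patches(patchset: PatchSet) -> tuple[np.ndarray, np.ndarray | None]:
    """Reassemble a :class:`PatchSet`; exact inverse of :func:`extract_patches`."""
    ph, pw = patchset.padded_size
    h, w = patchset.source_size
    first_img = patchset.patches[0][0]
    img = np.zeros((ph, pw) + first_img.shape[2:], dtype=first_img.dtype)
    msk = None
    if patchset.patches[0][1] is not None:
        msk = np.zeros((ph, pw), dtype=patchset.patches[0][1].dtype)
    s, p = patchset.stride, patchset.patch_size
    for it, mt, r, c in patchset.patches:
        img[r * s:r * s + p, c * s:c * s + p] = it
        if msk is not None:
            msk[r * s:r * s + p, c * s:c * s + p] = mt
    return img[:h, :w], None if msk is None else msk[:h, :w]


def normalize_patches(patchset: PatchSet) -> PatchSet:
    """Scale 8-bit image tiles into [0, 1] by dividing by 255."""
    out = []
    for it, mt, r, c in patchset.patches:
        if it.dtype != np.uint8:
            raise ValueError("normalize_patches expects 8-bit input tiles")
        out.append((it.astype(np.float32) / np.float32(255.0), mt, r, c))
    return dataclasses.replace(patchset, patches=out)


def augment(image_tile: np.ndarray, mask_tile: np.ndarray, seed: int,
            crop_size: int | None = None, flip_prob: float = 0.5,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Random crop + vertical flip, identically applied to image and mask."""
    h, w = mask_tile.shape
    crop = h if crop_size is None else int(crop_size)
    if crop > h or crop > w:
        raise ValueError("crop size must not exceed the tile size")
    rng = np.random.default_rng(seed)
    y = int(rng.integers(0, h - crop + 1))
    x = int(rng.integers(0, w - crop + 1))
    it = image_tile[y:y + crop, x:x + crop]
    mt = mask_tile[y:y + crop, x:x + crop]
    if flip_prob > 0 and rng.random() < flip_prob:
        it, mt = it[::-1], mt[::-1]
    return np.ascontiguousarray(it), np.ascontiguousarray(mt)


# ---------------------------------------------------------------------------
# Reverse-mode tape over numpy (only the ops this network needs)
# ---------------------------------------------------------------------------

class _T:
    """Tape node: array + grad + closure producing parent grads."""

    __slots__ = ("data", "grad", "parents", "grad_fn")

    def __init__(self, data, parents=(), grad_fn=None):
        self.data = data
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn


def _backward(root: _T, seed_grad=None) -> None:
    order, seen = [], set()

    def visit(node):
        stack = [(node, False)]
        while stack:
            n, done = stack.pop()
            if done:
                order.append(n)
                continue
            if id(n) in seen:
                continue
            seen.add(id(n))
            stack.append((n, True))
            for p in n.parents:
                stack.append((p, False))

    visit(root)
    root.grad = np.float32(1.0) if seed_grad is None else seed_grad
    for node in reversed(order):
        if node.grad_fn is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.grad_fn(node.grad)):
            if g is None:
                continue
            parent.grad = g if parent.grad is None else parent.grad + g


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # n,h,w,c,kh,kw
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, kh * kw * c)


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int) -> np.ndarray:
    n, h, w, c = xshape
    ph, pw = kh // 2, kw // 2
    d = dcols.reshape(n, h, w, kh, kw, c)
    dxp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + h, j:j + w, :] += d[:, :, :, i, j, :]
    return dxp[:, ph:ph + h, pw:pw + w, :]


def _conv2d(x: _T, w: _T, b: _T) -> _T:
    kh, kw, cin, cout = w.data.shape
    n, h, wd, _ = x.data.shape
    cols = _im2col(x.data, kh, kw)
    wmat = w.data.reshape(kh * kw * cin, cout)
    y = (cols @ wmat + b.data).reshape(n, h, wd, cout)

    def gf(dy):
        dymat = dy.reshape(n * h * wd, cout)
        cols_b = _im2col(x.data, kh, kw)  # recomputed: trades FLOPs for memory
        dw = (cols_b.T @ dymat).reshape(w.data.shape)
        db = dymat.sum(axis=0)
        dcols = dymat @ wmat.T
        dx = _col2im(dcols, x.data.shape, kh, kw)
        return dx, dw, db

    return _T(y, (x, w, b), gf)


def _relu(x: _T) -> _T:
    mask = x.data > 0
    return _T(x.data * mask, (x,), lambda dy: (dy * mask,))


def _maxpool2(x: _T) -> _T:
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial size {h}x{w} not divisible by 2 at a pooling step")
    if h < 2 or w < 2:
        raise ValueError("spatial collapse below 1x1 at the bottleneck")
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(
        0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(-1)
    y = np.take_along_axis(xr, idx[..., None], -1)[..., 0]

    def gf(dy):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], -1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        return (dx,)

    return _T(y, (x,), gf)


def _upsample2(x: _T) -> _T:
    y = x.data.repeat(2, axis=1).repeat(2, axis=2)
    n, h, w, c = x.data.shape

    def gf(dy):
        return (dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4)),)

    return _T(y, (x,), gf)


def _concat(ts: Sequence[_T]) -> _T:
    y = np.concatenate([t.data for t in ts], axis=3)
    splits = np.cumsum([t.data.shape[3] for t in ts])[:-1]

    def gf(dy):
        return tuple(np.split(dy, splits, axis=3))

    return _T(y, tuple(ts), gf)


def _dropout(x: _T, rate: float, rng: np.random.Generator) -> _T:
    keep = (rng.random(x.data.shape) >= rate).astype(np.float32) / np.float32(1 - rate)
    return _T(x.data * keep, (x,), lambda dy: (dy * keep,))


def _softmax(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=-1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_ce(logits: _T, labels: np.ndarray) -> _T:
    p = _softmax(logits.data)
    npx = labels.size
    flat = p.reshape(npx, -1)
    ll = np.log(np.maximum(flat[np.arange(npx), labels.ravel()], 1e-30))
    loss = -(ll.mean())

    def gf(dy):
        g = flat.copy()
        g[np.arange(npx), labels.ravel()] -= 1.0
        return ((dy / npx) * g.reshape(logits.data.shape),)

    return _T(loss, (logits,), gf)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegModelConfig:
    """Configuration of the dense segmentation network.

    ``layers_per_block`` may be a single int (same depth everywhere) or a
    tuple with one entry per down block; ``bottleneck_layers`` defaults to the
    last down-block depth.  Parameter count is a pure function of this config.
    """

    dense_blocks_down: int = 2
    layers_per_block: int | tuple[int, ...] = 2
    growth_rate: int = 8
    dropout_rate: float = 0.0
    l2_strength: float = 1e-5
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    bottleneck_layers: int | None = None
    n_classes: int = 8
    in_channels: int = 3
    lr_decay: float = 1.0      # per-epoch multiplicative decay

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def down_layers(self) -> tuple[int, ...]:
        if isinstance(self.layers_per_block, int):
            return (self.layers_per_block,) * self.dense_blocks_down
        lp = tuple(self.layers_per_block)
        if len(lp) != self.dense_blocks_down:
            raise ValueError("layers_per_block tuple must match dense_blocks_down")
        return lp

    @property
    def bneck_layers(self) -> int:
        if self.bottleneck_layers is not None:
            return self.bottleneck_layers
        return self.down_layers[-1]


#: Desk-scale preset: trains in minutes on one CPU at 64x64 tiles.
DESK_PRESET = SegModelConfig(dense_blocks_down=2, layers_per_block=2,
                             growth_rate=8, epochs=15, learning_rate=1.5e-3,
                             lr_decay=0.92)

#: The 103-layer layout of the original fully convolutional DenseNet design
#: (5 down blocks of 4/5/7/10/12 layers, bottleneck 15, growth 16).
PAPER_PRESET = SegModelConfig(dense_blocks_down=5,
                              layers_per_block=(4, 5, 7, 10, 12),
                              bottleneck_layers=15, growth_rate=16,
                              dropout_rate=0.2, epochs=100,
                              learning_rate=1e-3)


class SegModel:
    """Fully convolutional dense segmentation network (build via :func:`build_model`)."""

    FIRST_CONV_MULT = 2   # first conv emits FIRST_CONV_MULT * growth channels
    COMPRESS_MULT = 4     # up-path compression conv emits COMPRESS_MULT * growth

    def __init__(self, config: SegModelConfig):
        self.config = config
        self.params: dict[str, _T] = {}
        self._weight_names: list[str] = []
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        c = self.FIRST_CONV_MULT * g
        self._add_conv(rng, "conv_in", 3, config.in_channels, c)
        self.skip_channels = []
        for i, nl in enumerate(config.down_layers):
            for j in range(nl):
                self._add_conv(rng, f"down{i}_l{j}", 3, c + j * g, g)
            c += nl * g
            self.skip_channels.append(c)
            self._add_conv(rng, f"td{i}", 1, c, c)
        for j in range(config.bneck_layers):
            self._add_conv(rng, f"bneck_l{j}", 3, c + j * g, g)
        c += config.bneck_layers * g
        comp = self.COMPRESS_MULT * g
        for k, i in enumerate(reversed(range(config.dense_blocks_down))):
            cin = c + self.skip_channels[i]
            self._add_conv(rng, f"up{k}_comp", 3, cin, comp)
            nl = config.down_layers[i]
            for j in range(nl):
                self._add_conv(rng, f"up{k}_l{j}", 3, comp + j * g, g)
            c = comp + nl * g
        self._add_conv(rng, "conv_out", 1, c, config.n_classes)

    def _add_conv(self, rng, name, k, cin, cout):
        std = np.sqrt(2.0 / (k * k * cin))
        w = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(np.float32)
        b = np.zeros(cout, dtype=np.float32)
        self.params[name + ".w"] = _T(w)
        self.params[name + ".b"] = _T(b)
        self._weight_names.append(name + ".w")

    # -- architecture ------------------------------------------------------

    @property
    def min_input(self) -> int:
        return 2 ** self.config.dense_blocks_down

    @property
    def param_count(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def _conv(self, x, name):
        return _conv2d(x, self.params[name + ".w"], self.params[name + ".b"])

    def _dense_block(self, x, prefix, n_layers, train, rng):
        for j in range(n_layers):
            h = _relu(self._conv(x, f"{prefix}_l{j}"))
            if train and self.config.dropout_rate > 0:
                h = _dropout(h, self.config.dropout_rate, rng)
            x = _concat([x, h])
        return x

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> _T:
        n, h, w, _ = x.shape
        depth = self.config.dense_blocks_down
        if h % self.min_input or w % self.min_input:
            raise ValueError(
                f"input {h}x{w} must be divisible by 2**{depth}")
        if h // self.min_input < 1 or w // self.min_input < 1:
            raise ValueError("spatial collapse below 1x1 at the bottleneck")
        t = _relu(self._conv(_T(x.astype(np.float32)), "conv_in"))
        skips = []
        for i, nl in enumerate(self.config.down_layers):
            t = self._dense_block(t, f"down{i}", nl, train, rng)
            skips.append(t)
            t = _relu(self._conv(t, f"td{i}"))
            t = _maxpool2(t)
        t = self._dense_block(t, "bneck", self.config.bneck_layers, train, rng)
        for k, i in enumerate(reversed(range(depth))):
            t = _upsample2(t)
            t = _concat([t, skips[i]])
            t = _relu(self._conv(t, f"up{k}_comp"))
            t = self._dense_block(t, f"up{k}", self.config.down_layers[i],
                                  train, rng)
        return self._conv(t, "conv_out")

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (sum to 1 along the last axis)."""
        return _softmax(self.forward(np.asarray(x, dtype=np.float32)).data)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file archive: weights (npz) + config (json)."""
        arrays = {k: t.data for k, t in self.params.items()}
        buf = _io.BytesIO()
        np.savez(buf, **arrays)
        cfg = dataclasses.asdict(self.config)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(cfg))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "SegModel":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            if isinstance(cfg.get("layers_per_block"), list):
                cfg["layers_per_block"] = tuple(cfg["layers_per_block"])
            model = cls(SegModelConfig(**cfg))
            with np.load(_io.BytesIO(zf.read("weights.npz"))) as npz:
                for k in model.params:
                    model.params[k].data = npz[k]
        return model


def build_model(config: SegModelConfig) -> SegModel:
    """Instantiate the dense segmentation network for ``config``."""
    return SegModel(config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _as_tiles(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Accept a PatchSet or a sequence of (image_tile, mask_tile) pairs."""
    if isinstance(dataset, PatchSet):
        return [(it, mt) for it, mt, _, _ in dataset.patches]
    return [(it, mt) for it, mt in dataset]


def train(model: SegModel, train_set, val_set, config: SegModelConfig | None = None,
          batch_size: int = 1, use_augment: bool = False,
          ) -> tuple[SegModel, dict[str, list[float]]]:
    """Train with cross-entropy + L2 penalty under RMSprop.

    ``train_set``/``val_set`` are sequences of ``(image_tile, mask_tile)``
    with images already normalised to [0, 1].  Returns the model and a
    history of per-epoch train loss and validation pixel accuracy; runs are
    deterministic given ``config.seed``.
    """
    config = config or model.config
    tiles = _as_tiles(train_set)
    val_tiles = _as_tiles(val_set)
    if not tiles:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    weights = [model.params[n] for n in model._weight_names]
    cache = {k: np.zeros_like(t.data) for k, t in model.params.items()}
    rho, eps = 0.9, 1e-7
    history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": []}
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** epoch
        order = rng.permutation(len(tiles))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = [tiles[i] for i in order[start:start + batch_size]]
            if use_augment:
                batch = [augment(it, mt, int(rng.integers(2 ** 31)))
                         for it, mt in batch]
            xb = np.stack([it for it, _ in batch]).astype(np.float32)
            yb = np.stack([mt for _, mt in batch]).astype(np.int64)
            for t in model.params.values():
                t.grad = None
            logits = model.forward(xb, train=True, rng=rng)
            loss = _softmax_ce(logits, yb)
            l2 = 0.5 * config.l2_strength * sum(
                float((t.data.astype(np.float64) ** 2).sum()) for t in weights)
            _backward(loss)
            for t in weights:
                t.grad = t.grad + config.l2_strength * t.data
            for k, t in model.params.items():
                if t.grad is None:
                    continue
                cache[k] = rho * cache[k] + (1 - rho) * t.grad ** 2
                t.data = t.data - lr * t.grad / (np.sqrt(cache[k]) + eps)
            losses.append(float(loss.data) + l2)
        acc = _validation_accuracy(model, val_tiles)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(acc)
        log.info("epoch %d/%d loss=%.4f val_acc=%.4f",
                 epoch + 1, config.epochs, history["train_loss"][-1], acc)
    return model, history


def _validation_accuracy(model: SegModel, val_tiles) -> float:
    if not val_tiles:
        return float("nan")
    correct = total = 0
    for it, mt in val_tiles:
        pred = model.predict_proba(it[None]).argmax(-1)[0]
        correct += int((pred == mt).sum())
        total += mt.size
    return correct / total


def hyperparameter_search(space: Mapping[str, Sequence], n_trials: int, seed: int,
                          train_set=None, val_set=None,
                          base_config: SegModelConfig | None = None):
    """Random search: draw ``n_trials`` configs uniformly from ``space``,
    train each, and rank descending by validation pixel accuracy."""
    import pandas as pd

    if not space:
        raise ValueError("empty search space")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = base_config or DESK_PRESET
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        draw = {k: v[int(rng.integers(len(v)))] for k, v in space.items()}
        cfg = dataclasses.replace(base, **draw, seed=int(rng.integers(2 ** 31)))
        model = build_model(cfg)
        _, hist = train(model, train_set, val_set, cfg)
        rows.append({"trial": trial, **draw,
                     "val_accuracy": hist["val_accuracy"][-1],
                     "final_loss": hist["train_loss"][-1]})
    table = pd.DataFrame(rows).sort_values(
        ["val_accuracy", "trial"], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Prediction, evaluation, review
# ---------------------------------------------------------------------------

def predict_mask(model: SegModel, slide: LabeledSlide | np.ndarray,
                 patch_size: int = 64) -> np.ndarray:
    """Patch the image, predict per tile, stitch; argmax per pixel
    (ties broken toward the lowest label index)."""
    image = slide.image if isinstance(slide, LabeledSlide) else np.asarray(slide)
    pset = extract_patches(image, patch_size)
    out = []
    for it, _, r, c in pset.patches:
        proba = model.predict_proba(it[None].astype(np.float32) / 255.0)[0]
        out.append((proba.argmax(-1).astype(np.uint8), None, r, c))
    stitched, _ = stitch_patches(dataclasses.replace(pset, patches=out))
    return stitched


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts per class plus micro-pooled totals."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def pooled(self) -> tuple[int, int, int, int]:
        return (int(self.tp.sum()), int(self.tn.sum()),
                int(self.fp.sum()), int(self.fn.sum()))


def pixel_accuracy(pred_mask: np.ndarray, gt_mask: np.ndarray,
                   n_classes: int = 8) -> tuple[float, ConfusionCounts]:
    """Global pixel accuracy (TP+TN)/(TP+TN+FP+FN) under one-vs-rest
    micro-pooling, which equals the fraction of correctly classified pixels."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes differ")
    npx = gt_mask.size
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    tn = np.zeros(n_classes, dtype=np.int64)
    for k in range(n_classes):
        p = pred_mask == k
        g = gt_mask == k
        tp[k] = np.sum(p & g)
        fp[k] = np.sum(p & ~g)
        fn[k] = np.sum(~p & g)
        tn[k] = npx - tp[k] - fp[k] - fn[k]
    counts = ConfusionCounts(tp, tn, fp, fn)
    acc = float(np.mean(pred_mask == gt_mask))
    return acc, counts


def review_report(pred_masks: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                  area_priors: Mapping[str, tuple[float, float]],
                  z_threshold: float = 3.0):
    """Machine side of the expert review loop: flag masks whose region-fraction
    vector deviates from cohort priors beyond ``z_threshold`` standard
    deviations.  Masks are never modified."""
    import pandas as pd

    if isinstance(pred_masks, Mapping):
        items = list(pred_masks.items())
    else:
        items = [(str(i), m) for i, m in enumerate(pred_masks)]
    if not items:
        raise ValueError("at least one mask is required")
    rows = []
    for name, mask in items:
        counts = np.bincount(np.asarray(mask).ravel(), minlength=8)
        frac = counts / counts.sum()
        worst_z, worst_region = 0.0, ""
        for region, (mu, sd) in area_priors.items():
            idx = CLASS_MAP.index(region)
            z = abs(frac[idx] - mu) / sd if sd > 0 else (
                0.0 if frac[idx] == mu else np.inf)
            if z > worst_z:
                worst_z, worst_region = z, region
        rows.append({"mask": name, "max_abs_z": worst_z,
                     "worst_region": worst_region,
                     "flagged": worst_z > z_threshold})
    table = pd.DataFrame(rows)
    flagged = table[table.flagged]
    lines = [f"Review list ({len(flagged)} of {len(table)} masks flagged, "
             f"z-threshold {z_threshold:g}):"]
    for _, r in flagged.iterrows():
        lines.append(f"  - {r['mask']}: {r.worst_region} fraction deviates "
                     f"{r.max_abs_z:.1f} sigma from prior")
    if flagged.empty:
        lines.append("  (none)")
    return table, "\n".join(lines)
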