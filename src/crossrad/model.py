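"""Dual-branch vision-transformer classifier for radiograph pairs.

One transformer encoder per input stream (the full radiograph and its
ROI crop), fused by plain concatenation of the two classification-token
features and finished by a small fully connected head with a single
fracture logit.  No cross-attention or other dedicated fusion blocks
exist: the fusion IS the concatenation.  A ``single`` mode uses only the
original-image branch and serves as the baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EncoderConfig",
    "ViTEncoder",
    "FusionClassifier",
    "patchify",
    "fuse_features",
    "classify",
    "DESK_ENCODER",
    "PAPER_ENCODER",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of one transformer encoder branch.

    image_size must be divisible by patch_size and embed_dim by n_heads.
    """

    image_size: int = 64
    patch_size: int = 8
    embed_dim: int = 96
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0 or self.patch_size <= 0:
            raise ValueError("image_size and patch_size must be positive")
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2


DESK_ENCODER = EncoderConfig(image_size=64, patch_size=8, embed_dim=96, depth=4, n_heads=4)
PAPER_ENCODER = EncoderConfig(image_size=224, patch_size=16, embed_dim=192, depth=12, n_heads=3)


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Split a 2-D image into non-overlapping row-major patches.

    Returns an array of shape (n_patches, patch_size**2); each row is one
    flattened patch.  Dimensions not divisible by patch_size are an error
    (resizing happens upstream; silent padding would shift patch content).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("patchify expects a 2-D image")
    h, w = image.shape
    if h % patch_size != 0 or w % patch_size != 0:
        raise ValueError(
            f"image shape {image.shape} not divisible by patch_size {patch_size}"
        )
    gh, gw = h // patch_size, w // patch_size
    patches = (
        image.reshape(gh, patch_size, gw, patch_size)
        .transpose(0, 2, 1, 3)
        .reshape(gh * gw, patch_size * patch_size)
    )
    return patches


def _patchify_batch(images: np.ndarray, patch_size: int) -> np.ndarray:
    b, h, w = images.shape
    gh, gw = h // patch_size, w // patch_size
    return (
        images.reshape(b, gh, patch_size, gw, patch_size)
        .transpose(0, 1, 3, 2, 4)
        .reshape(b, gh * gw, patch_size * patch_size)
    )


class ViTEncoder:
    """Standard transformer encoder: patch embedding, CLS token, learned
    positional embeddings, pre-norm attention/MLP blocks, final layer norm.

    Parameters are plain autodiff tensors initialized from ``config.seed``
    (truncated-normal-like, std 0.02); there is no pretraining.
    """

    def __init__(self, config: EncoderConfig, prefix: str = "enc"):
        self.config = config
        self.prefix = prefix
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        ps2 = config.patch_size ** 2
        p: dict[str, Tensor] = {}

        def param(name, shape, std=0.02):
            p[f"{prefix}.{name}"] = Tensor(rng.normal(0.0, std, shape), requires_grad=True)

        def zeros(name, shape):
            p[f"{prefix}.{name}"] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name, shape):
            p[f"{prefix}.{name}"] = Tensor(np.ones(shape), requires_grad=True)

        param("embed.W", (ps2, d))
        zeros("embed.b", (d,))
        zeros("cls", (1, 1, d))
        param("pos", (1, config.n_patches + 1, d))
        hidden = int(round(config.mlp_ratio * d))
        for i in range(config.depth):
            ones(f"blk{i}.ln1.g", (d,))
            zeros(f"blk{i}.ln1.b", (d,))
            param(f"blk{i}.qkv.W", (d, 3 * d))
            zeros(f"blk{i}.qkv.b", (3 * d,))
            param(f"blk{i}.proj.W", (d, d))
            zeros(f"blk{i}.proj.b", (d,))
            ones(f"blk{i}.ln2.g", (d,))
            zeros(f"blk{i}.ln2.b", (d,))
            param(f"blk{i}.mlp1.W", (d, hidden))
            zeros(f"blk{i}.mlp1.b", (hidden,))
            param(f"blk{i}.mlp2.W", (hidden, d))
            zeros(f"blk{i}.mlp2.b", (d,))
        ones("ln_f.g", (d,))
        zeros("ln_f.b", (d,))
        self.params = p

    def _p(self, name: str) -> Tensor:
        return self.params[f"{self.prefix}.{name}"]

    def forward(
        self,
        images: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_tokens: bool = False,
    ) -> Tensor | tuple[Tensor, Tensor]:
        """Encode a batch of images (B, H, W) in [0,1] to CLS features (B, D).

        With ``capture_tokens`` the patch-token activations entering the
        final layer norm are also returned (used for activation mapping).
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        cfg = self.config
        if images.shape[1:] != (cfg.image_size, cfg.image_size):
            raise ValueError(
                f"expected images of size {cfg.image_size}, got {images.shape[1:]}"
            )
        b = images.shape[0]
        d, heads = cfg.embed_dim, cfg.n_heads
        dh = d // heads
        # center intensities to [-1, 1] for better-conditioned patch embeddings
        patches = _patchify_batch(2.0 * images - 1.0, cfg.patch_size)  # (B, N, ps^2)
        x = nn.add(nn.matmul(Tensor(patches), self._p("embed.W")), self._p("embed.b"))
        cls = nn.add(Tensor(np.zeros((b, 1, d))), self._p("cls"))
        x = nn.concat([cls, x], axis=1)
        x = nn.add(x, self._p("pos"))
        t = cfg.n_patches + 1
        drop = cfg.dropout if training else 0.0
        for i in range(cfg.depth):
            h = nn.layer_norm(x, self._p(f"blk{i}.ln1.g"), self._p(f"blk{i}.ln1.b"))
            qkv = nn.add(nn.matmul(h, self._p(f"blk{i}.qkv.W")), self._p(f"blk{i}.qkv.b"))
            q = nn.narrow(qkv, 2, 0, d)
            k = nn.narrow(qkv, 2, d, d)
            v = nn.narrow(qkv, 2, 2 * d, d)

            def heads_first(z):
                return nn.transpose(nn.reshape(z, (b, t, heads, dh)), (0, 2, 1, 3))

            q, k, v = heads_first(q), heads_first(k), heads_first(v)
            att = nn.scale(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
            att = nn.softmax(att, axis=-1)
            if drop > 0.0:
                att = nn.dropout(att, drop, rng, training)
            out = nn.matmul(att, v)  # (B, heads, T, dh)
            out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (b, t, d))
            out = nn.add(nn.matmul(out, self._p(f"blk{i}.proj.W")), self._p(f"blk{i}.proj.b"))
            x = nn.add(x, out)
            h = nn.layer_norm(x, self._p(f"blk{i}.ln2.g"), self._p(f"blk{i}.ln2.b"))
            h = nn.gelu(nn.add(nn.matmul(h, self._p(f"blk{i}.mlp1.W")), self._p(f"blk{i}.mlp1.b")))
            if drop > 0.0:
                h = nn.dropout(h, drop, rng, training)
            h = nn.add(nn.matmul(h, self._p(f"blk{i}.mlp2.W")), self._p(f"blk{i}.mlp2.b"))
            x = nn.add(x, h)
        pre_ln = x  # token stream entering the final layer norm; on the
        # gradient path, so its .grad is available after backward
        x = nn.layer_norm(x, self._p("ln_f.g"), self._p("ln_f.b"))
        feat = nn.reshape(nn.narrow(x, 1, 0, 1), (b, d))
        if capture_tokens:
            return feat, pre_ln
        return feat

    def encode(self, image: np.ndarray) -> np.ndarray:
        """Deterministic single-image feature vector of length embed_dim."""
        return self.forward(np.asarray(image)[None]).data[0]


def fuse_features(a, b) -> Tensor:
    """Concatenate two feature batches along the feature axis (a first)."""
    a = a if isinstance(a, Tensor) else Tensor(np.atleast_2d(a))
    b = b if isinstance(b, Tensor) else Tensor(np.atleast_2d(b))
    if a.data.size == 0 or b.data.size == 0:
        raise ValueError("cannot fuse an empty feature vector")
    if not (np.all(np.isfinite(a.data)) and np.all(np.isfinite(b.data))):
        raise ValueError("feature vectors must be finite")
    return nn.concat([a, b], axis=-1)


def classify(fused, head_params: dict[str, Tensor]) -> Tensor:
    """Fully connected head then logistic transform -> fracture probability."""
    logits = head_logits(fused, head_params)
    return nn.sigmoid(logits)


def head_logits(fused, head_params: dict[str, Tensor]) -> Tensor:
    fused = fused if isinstance(fused, Tensor) else Tensor(np.atleast_2d(fused))
    w1 = head_params["head.fc1.W"]
    if fused.data.shape[-1] != w1.data.shape[0]:
        raise ValueError(
            f"fused width {fused.data.shape[-1]} != head input width {w1.data.shape[0]}"
        )
    h = nn.gelu(nn.add(nn.matmul(fused, w1), head_params["head.fc1.b"]))
    z = nn.add(nn.matmul(h, head_params["head.fc2.W"]), head_params["head.fc2.b"])
    return nn.reshape(z, (z.data.shape[0],))


class FusionClassifier:
    """Single- or dual-branch transformer classifier.

    mode "multi": two parallel encoders (original + ROI crop), concatenated
    CLS features, fully connected head.  mode "single": original branch only;
    the crop input is ignored entirely.
    """

    HEAD_HIDDEN = 64

    def __init__(self, config: EncoderConfig, mode: str = "multi",
                 crop_config: EncoderConfig | None = None):
        if mode not in ("single", "multi"):
            raise ValueError("mode must be 'single' or 'multi'")
        self.mode = mode
        self.config = config
        self.encoder_original = ViTEncoder(config, prefix="orig")
        self.encoder_crop = None
        in_width = config.embed_dim
        if mode == "multi":
            crop_cfg = crop_config or EncoderConfig(**{**asdict(config), "seed": config.seed + 1})
            self.crop_config = crop_cfg
            self.encoder_crop = ViTEncoder(crop_cfg, prefix="crop")
            in_width += crop_cfg.embed_dim
        else:
            self.crop_config = None
        rng = np.random.default_rng(config.seed + 2)
        self.head_params = {
            "head.fc1.W": Tensor(rng.normal(0, 0.02, (in_width, self.HEAD_HIDDEN)), requires_grad=True),
            "head.fc1.b": Tensor(np.zeros(self.HEAD_HIDDEN), requires_grad=True),
            # zero-initialized final layer: training starts at probability 0.5
            "head.fc2.W": Tensor(np.zeros((self.HEAD_HIDDEN, 1)), requires_grad=True),
            "head.fc2.b": Tensor(np.zeros(1), requires_grad=True),
        }
        # filled by forward(capture_tokens=True); used for saliency maps
        self._captured_tokens: Tensor | None = None

    @property
    def params(self) -> dict[str, Tensor]:
        p = dict(self.encoder_original.params)
        if self.encoder_crop is not None:
            p.update(self.encoder_crop.params)
        p.update(self.head_params)
        return p

    def forward_logits(
        self,
        originals: np.ndarray,
        crops: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        capture_tokens: bool = False,
    ) -> Tensor:
        if capture_tokens:
            feat_o, tokens = self.encoder_original.forward(
                originals, training, rng, capture_tokens=True
            )
            self._captured_tokens = tokens
        else:
            feat_o = self.encoder_original.forward(originals, training, rng)
            self._captured_tokens = None
        if self.mode == "multi":
            if crops is None:
                raise ValueError("multi mode requires crop inputs")
            feat_c = self.encoder_crop.forward(crops, training, rng)
            fused = fuse_features(feat_o, feat_c)
        else:
            fused = feat_o
        return head_logits(fused, self.head_params)

    def predict_proba(self, originals: np.ndarray, crops: np.ndarray | None = None) -> np.ndarray:
        """Fracture probabilities in [0,1], deterministic (dropout off)."""
        z = self.forward_logits(originals, crops, training=False)
        return nn.sigmoid(z).data

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        for k, v in state.items():
            if params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for parameter {k}")
            params[k].data = np.array(v, dtype=np.float64)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def save(self, path) -> None:
        """Checkpoint: config JSON + parameter blob in one .npz file."""
        meta = {
            "mode": self.mode,
            "config": asdict(self.config),
            "crop_config": asdict(self.crop_config) if self.crop_config else None,
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "FusionClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {
                k.replace("__", "."): z[k] for k in z.files if k != "__meta__"
            }
        cfg = EncoderConfig(**meta["config"])
        crop_cfg = EncoderConfig(**meta["crop_config"]) if meta["crop_config"] else None
        model = cls(cfg, mode=meta["mode"], crop_config=crop_cfg)
        model.load_state_dict(state)
        return model
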