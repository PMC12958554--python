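"""Masked-image-modeling architecture for nucleus crops.

A single-channel crop of side ``H`` (= ``W``) is divided into ``N = H*W/P^2``
non-overlapping ``P x P`` patches. Each flattened patch is linearly projected
to a ``d``-dimensional token (``z_i = W_p x_i + b_p``); a learnable
representation token is prepended and positional encodings are added. During
pretraining a random subset of patches is masked; only the representation
token and visible-patch tokens enter the transformer encoder. The decoder
re-inserts a learnable mask token at every masked position (after a linear
projection to the decoder width), adds its own positional encodings, and
reconstructs all patches; the loss is the mean squared reconstruction error
over the masked patches only. After pretraining, the encoder output at
position 0 (the representation token) is the global morphological embedding
of the image.

Default geometry: 112x112 images, 8-px patches, hidden size 768, encoder of
12 blocks x 12 heads, decoder of 8 blocks x 16 heads, mask ratio 75%. A
"tiny" profile (56x56, d=64, 2 blocks) supports fast CPU experimentation.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn as _nn
from .nn import Linear, Module, Param, Transformer, gelu, gelu_grad, softmax

__all__ = [
    "ModelConfig",
    "TINY",
    "DEFAULT",
    "MaskSpec",
    "sample_mask",
    "patchify",
    "unpatchify",
    "MaskedAutoencoder",
    "Head",
    "HeadSpec",
    "FineTunedModel",
    "attention_rollout",
    "extract_representation",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Geometry and capacity of the masked autoencoder."""

    image_size: int = 112
    patch_size: int = 8
    d: int = 768
    enc_depth: int = 12
    enc_heads: int = 12
    dec_d: int = 512
    dec_depth: int = 8
    dec_heads: int = 16
    mask_ratio: float = 0.75

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if not 0 <= self.mask_ratio < 1:
            raise ValueError("mask_ratio must be in [0, 1)")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid * self.grid


DEFAULT = ModelConfig()
TINY = ModelConfig(
    image_size=56, patch_size=8, d=64, enc_depth=2, enc_heads=4,
    dec_d=64, dec_depth=2, dec_heads=4, mask_ratio=0.75,
)


# ---------------------------------------------------------------------------
# Patches and masks
# ---------------------------------------------------------------------------

def patchify(images: np.ndarray, P: int) -> np.ndarray:
    """Split images into flattened non-overlapping P x P patches.

    Accepts (H, W) or (B, H, W); returns (N, P*P) or (B, N, P*P) with patches
    in row-major grid order and pixels within a patch in row-major order.
    """
    single = images.ndim == 2
    x = images[None] if single else images
    B, H, W = x.shape
    if H % P != 0 or W % P != 0:
        raise ValueError(f"image dims {H}x{W} not divisible by patch size {P}")
    gh, gw = H // P, W // P
    patches = (
        x.reshape(B, gh, P, gw, P).transpose(0, 1, 3, 2, 4).reshape(B, gh * gw, P * P)
    )
    return patches[0] if single else patches


def unpatchify(patches: np.ndarray, P: int, H: int, W: int) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    single = patches.ndim == 2
    x = patches[None] if single else patches
    B, N, PP = x.shape
    gh, gw = H // P, W // P
    if N != gh * gw or PP != P * P:
        raise ValueError("patch sequence inconsistent with target geometry")
    imgs = x.reshape(B, gh, gw, P, P).transpose(0, 1, 3, 2, 4).reshape(B, H, W)
    return imgs[0] if single else imgs


@dataclass
class MaskSpec:
    """A binary patch mask: M[i] = 1 if patch i is masked, 0 if visible."""

    M: np.ndarray
    visible_idx: np.ndarray
    masked_idx: np.ndarray

    @property
    def n(self) -> int:
        return len(self.M)

    @property
    def m(self) -> int:
        """Number of visible patches."""
        return len(self.visible_idx)


def sample_mask(N: int, ratio: float, seed: int | np.random.Generator) -> MaskSpec:
    """Mask exactly ``round(ratio * N)`` patches chosen uniformly at random.

    At least one patch is always left visible (the encoder needs input).
    Deterministic for a fixed seed.
    """
    if not 0 <= ratio < 1:
        raise ValueError(f"mask ratio must be in [0, 1), got {ratio}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_masked = min(int(round(ratio * N)), N - 1)
    perm = rng.permutation(N)
    masked = np.sort(perm[:n_masked])
    visible = np.sort(perm[n_masked:])
    M = np.zeros(N, dtype=np.int8)
    M[masked] = 1
    return MaskSpec(M=M, visible_idx=visible, masked_idx=masked)


def masked_mse_loss(X: np.ndarray, X_hat: np.ndarray, M: np.ndarray) -> float:
    """Mean over masked patches of the per-patch squared reconstruction error.

    ``X`` and ``X_hat`` are (N, P*P) patch sequences (or batched (B, N, P*P)
    with a (B, N) mask); the squared error is summed over the P*P pixels of
    each patch and averaged over patches with M_i = 1 only.
    """
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    M = np.asarray(M)
    if X.shape != X_hat.shape:
        raise ValueError("X and X_hat must have identical shapes")
    if M.shape != X.shape[:-1]:
        raise ValueError("mask must have one entry per patch")
    total_masked = M.sum()
    if total_masked == 0:
        raise ValueError("loss undefined with zero masked patches")
    per_patch = ((X - X_hat) ** 2).sum(axis=-1)
    return float((per_patch * M).sum() / total_masked)


# ---------------------------------------------------------------------------
# Positional encodings (fixed 2-D sinusoidal over the patch grid)
# ---------------------------------------------------------------------------

def sincos_pos_2d(d: int, grid: int) -> np.ndarray:
    """Fixed 2-D sin-cos positional table, one row per patch (grid*grid, d)."""
    if d % 4 != 0:
        raise ValueError("positional dimension must be divisible by 4")
    half = d // 2

    def axis_embed(pos: np.ndarray) -> np.ndarray:
        omega = 1.0 / (10000 ** (np.arange(half // 2) / (half / 2.0)))
        out = pos[:, None] * omega[None, :]
        return np.concatenate([np.sin(out), np.cos(out)], axis=1)

    coords = np.arange(grid, dtype=np.float64)
    rows = np.repeat(coords, grid)
    cols = np.tile(coords, grid)
    return np.concatenate([axis_embed(rows), axis_embed(cols)], axis=1)


# ---------------------------------------------------------------------------
# The masked autoencoder
# ---------------------------------------------------------------------------

class MaskedAutoencoder(Module):
    """Encoder-decoder masked autoencoder over nucleus-crop patches."""

    def __init__(self, cfg: ModelConfig = TINY, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        PP = cfg.patch_size * cfg.patch_size
        self.patch_embed = Linear(PP, cfg.d, rng, "patch_embed")
        self.rep_token = Param(rng.normal(0, 0.02, size=cfg.d), "rep_token")
        self.rep_pos = Param(np.zeros(cfg.d), "rep_pos")  # learnable row for the rep token
        self.enc_pos = sincos_pos_2d(cfg.d, cfg.grid).astype(_nn.DTYPE)  # fixed, (N, d)
        self.encoder = Transformer(cfg.d, cfg.enc_depth, cfg.enc_heads, rng, "enc")
        self.dec_embed = Linear(cfg.d, cfg.dec_d, rng, "dec_embed")
        self.mask_token = Param(rng.normal(0, 0.02, size=cfg.dec_d), "mask_token")
        self.dec_pos = sincos_pos_2d(cfg.dec_d, cfg.grid).astype(_nn.DTYPE)  # fixed, (N, d_dec)
        self.decoder = Transformer(cfg.dec_d, cfg.dec_depth, cfg.dec_heads, rng, "dec")
        self.dec_head = Linear(cfg.dec_d, PP, rng, "dec_head")
        self._enc_cache = None

    # -- encoder ------------------------------------------------------------

    def encode(self, images: np.ndarray, visible_idx: np.ndarray | None = None) -> np.ndarray:
        """Run patchify -> embed -> encoder.

        ``visible_idx`` is (B, m) (or None for all patches visible, the
        fine-tuning mode). Returns encoder output (B, m+1, d); position 0 is
        the representation token. Caches everything needed by
        :meth:`encode_backward`.
        """
        cfg = self.cfg
        if images.ndim == 2:
            images = images[None]
        B = images.shape[0]
        if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
            raise ValueError(
                f"expected {cfg.image_size}x{cfg.image_size} images, got {images.shape[1:]}"
            )
        patches = patchify(images, cfg.patch_size).astype(_nn.DTYPE)  # (B, N, PP)
        if visible_idx is None:
            visible_idx = np.broadcast_to(np.arange(cfg.n_patches), (B, cfg.n_patches))
        visible_idx = np.asarray(visible_idx)
        if visible_idx.shape[1] == 0:
            raise ValueError("encoder requires at least one visible patch")
        bidx = np.arange(B)[:, None]
        vis_patches = patches[bidx, visible_idx]  # (B, m, PP)
        z = self.patch_embed.forward(vis_patches) + self.enc_pos[visible_idx]
        rep = (self.rep_token.value + self.rep_pos.value)[None, None, :]
        tokens = np.concatenate([np.broadcast_to(rep, (B, 1, cfg.d)), z], axis=1)
        H_out = self.encoder.forward(tokens)
        self._enc_cache = (B, visible_idx)
        return H_out

    def encode_backward(self, dH_out: np.ndarray) -> None:
        """Backprop through encoder + embedding, accumulating grads."""
        B, visible_idx = self._enc_cache
        dtokens = self.encoder.backward(dH_out)
        drep = dtokens[:, 0, :].sum(axis=0)
        self.rep_token.grad += drep
        self.rep_pos.grad += drep
        self.patch_embed.backward(dtokens[:, 1:, :])

    @property
    def encoder_attention(self) -> list[np.ndarray]:
        """Per-layer (B, heads, T, T) attention from the last encode call."""
        return self.encoder.attention_stack

    # -- decoder ------------------------------------------------------------

    def decode(
        self, H_out: np.ndarray, visible_idx: np.ndarray, masked_idx: np.ndarray
    ) -> np.ndarray:
        """Reconstruct all N patches from encoder output.

        Drops the representation token, projects visible tokens to the
        decoder width, inserts the learnable mask token at every masked
        position (visible token for patch k ends up at sequence position k),
        adds decoder positional encodings, runs the decoder stack and the
        linear reconstruction head. Returns X_hat (B, N, P*P).
        """
        cfg = self.cfg
        B, m1, _ = H_out.shape
        visible_idx = np.asarray(visible_idx)
        masked_idx = np.asarray(masked_idx)
        if visible_idx.shape != (B, m1 - 1):
            raise ValueError("visible index set inconsistent with encoder state")
        vis = self.dec_embed.forward(H_out[:, 1:, :])  # (B, m, d_dec)
        H_all = np.broadcast_to(
            self.mask_token.value[None, None, :], (B, cfg.n_patches, cfg.dec_d)
        ).copy()
        bidx = np.arange(B)[:, None]
        H_all[bidx, visible_idx] = vis
        self.last_H_all = H_all  # pre-positional sequence, kept for inspection
        H_dec = H_all + self.dec_pos
        dec_out = self.decoder.forward(H_dec)
        X_hat = self.dec_head.forward(dec_out)
        self._dec_cache = (B, visible_idx, masked_idx)
        return X_hat

    def decode_backward(self, dX_hat: np.ndarray) -> np.ndarray:
        """Backprop through the decoder; returns gradient w.r.t. encoder
        output H_out (rep-token position receives zero gradient)."""
        B, visible_idx, masked_idx = self._dec_cache
        ddec_out = self.dec_head.backward(dX_hat)
        dH_all = self.decoder.backward(ddec_out)
        bidx = np.arange(B)[:, None]
        if masked_idx.shape[1] > 0:
            self.mask_token.grad += dH_all[bidx, masked_idx].sum(axis=(0, 1))
        dvis = dH_all[bidx, visible_idx]  # (B, m, d_dec)
        dH_enc = self.dec_embed.backward(dvis)  # (B, m, d)
        dH_out = np.zeros((B, visible_idx.shape[1] + 1, self.cfg.d), dtype=_nn.DTYPE)
        dH_out[:, 1:, :] = dH_enc
        return dH_out

    # -- pretraining objective ----------------------------------------------

    def reconstruction_loss(
        self,
        images: np.ndarray,
        visible_idx: np.ndarray,
        masked_idx: np.ndarray,
        with_grad: bool = False,
    ) -> float:
        """Masked-MSE loss of a batch; optionally accumulate gradients.

        All images in the batch share the same mask *count* (not the same
        mask), so indices stack into rectangular (B, m) / (B, N-m) arrays.
        """
        cfg = self.cfg
        if images.ndim == 2:
            images = images[None]
        B = images.shape[0]
        patches = patchify(images, cfg.patch_size).astype(_nn.DTYPE)
        H_out = self.encode(images, visible_idx)
        X_hat = self.decode(H_out, visible_idx, masked_idx)
        bidx = np.arange(B)[:, None]
        diff = X_hat[bidx, masked_idx] - patches[bidx, masked_idx]  # (B, n_masked, PP)
        n_masked_total = B * masked_idx.shape[1]
        loss = float((diff**2).sum() / n_masked_total)
        if with_grad:
            dX_hat = np.zeros_like(X_hat)
            dX_hat[bidx, masked_idx] = 2.0 * diff / n_masked_total
            dH_out = self.decode_backward(dX_hat)
            self.encode_backward(dH_out)
        return loss

    # -- representations -----------------------------------------------------

    def represent(self, images: np.ndarray) -> np.ndarray:
        """Global representation h_rep for each image (no masking)."""
        single = images.ndim == 2
        H_out = self.encode(images[None] if single else images, None)
        reps = H_out[:, 0, :]
        return reps[0] if single else reps


def extract_representation(image: np.ndarray, model: MaskedAutoencoder) -> np.ndarray:
    """h_rep of one image: patchify -> embed -> encode with empty mask, token 0."""
    return model.represent(np.asarray(image, dtype=np.float64))


# ---------------------------------------------------------------------------
# Prediction heads and fine-tuned models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadSpec:
    """Task head attached to h_rep for fine-tuning.

    task: classification | regression | tls_score | infiltration
    output_dim: classes for classification, outputs for regression, 1 for
        the sigmoid tasks (tls_score, infiltration uses identity output).
    hidden: optional MLP hidden width (None = single linear layer).
    """

    task: str
    output_dim: int
    hidden: int | None = None

    def __post_init__(self):
        if self.task not in {"classification", "regression", "tls_score", "infiltration"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


class Head(Module):
    """Linear or 2-layer-MLP prediction head over h_rep."""

    def __init__(self, spec: HeadSpec, d: int, seed: int = 0, zero_init: bool = False):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.hidden is None:
            self.fc1 = Linear(d, spec.output_dim, rng, "head.fc")
            self.fc2 = None
        else:
            self.fc1 = Linear(d, spec.hidden, rng, "head.fc1")
            self.fc2 = Linear(spec.hidden, spec.output_dim, rng, "head.fc2")
        if zero_init:
            for p in self.parameters():
                p.value[...] = 0.0
        self._pre = None

    def forward(self, h: np.ndarray) -> np.ndarray:
        out = self.fc1.forward(h)
        if self.fc2 is not None:
            self._pre = out
            out = self.fc2.forward(gelu(out))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.fc2 is not None:
            dout = self.fc1_backward_chain(dout)
            return dout
        return self.fc1.backward(dout)

    def fc1_backward_chain(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dout)
        return self.fc1.backward(dh * gelu_grad(self._pre))


class FineTunedModel:
    """An encoder plus a task head; predictions use zero masking."""

    def __init__(self, model: MaskedAutoencoder, head: Head):
        self.model = model
        self.head = head

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Raw head outputs; probabilities for classification/tls_score."""
        if images.ndim == 2:
            images = images[None]
        outs = []
        for i in range(0, len(images), batch_size):
            h = self.model.represent(images[i : i + batch_size])
            logits = self.head.forward(h)
            if self.head.spec.task == "classification":
                outs.append(softmax(logits, axis=-1))
            elif self.head.spec.task == "tls_score":
                outs.append(1.0 / (1.0 + np.exp(-logits)))
            else:
                outs.append(logits)
        return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Attention rollout
# ---------------------------------------------------------------------------

def attention_rollout(attn_stack: list[np.ndarray]) -> np.ndarray:
    """Propagate attention through layers to a per-patch relevance map.

    Each element of ``attn_stack`` is one layer's attention: (T, T) or
    (heads, T, T), rows being probability distributions. Per layer, heads
    are averaged, the residual connection is folded in as A' = (A + I)/2
    and rows re-normalized; the rollout is the ordered product
    R = A'_L @ ... @ A'_1. The representation-token row of R, restricted to
    patch positions and renormalized to sum 1, is returned (length T-1).
    """
    if not attn_stack:
        raise ValueError("empty attention stack")
    mats = []
    T = None
    for A in attn_stack:
        A = np.asarray(A, dtype=np.float64)
        if A.ndim == 3:
            A = A.mean(axis=0)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("attention matrices must be square")
        if T is None:
            T = A.shape[0]
        elif A.shape[0] != T:
            raise ValueError("inconsistent attention sizes across layers")
        Ap = 0.5 * (A + np.eye(T))
        Ap /= Ap.sum(axis=1, keepdims=True)
        mats.append(Ap)
    R = mats[0]
    for Ap in mats[1:]:
        R = Ap @ R
    rel = R[0, 1:]
    s = rel.sum()
    if s <= 0:
        # no attention mass reaches the patches (e.g. identity attention):
        # relevance is uninformative, report it as uniform
        return np.full(T - 1, 1.0 / (T - 1))
    return rel / s


def relevance_map(model: MaskedAutoencoder, image: np.ndarray) -> np.ndarray:
    """Attention-rollout relevance over the patch grid for one image."""
    model.encode(np.asarray(image, dtype=np.float64)[None], None)
    stack = [A[0] for A in model.encoder_attention]  # (heads, T, T) per layer
    rel = attention_rollout(stack)
    g = model.cfg.grid
    return rel.reshape(g, g)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path,
    model: MaskedAutoencoder,
    head: Head | None = None,
    extra: dict | None = None,
) -> None:
    """Save all weights plus a JSON config block in one zip archive."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "model_config": asdict(model.cfg),
        "head_spec": None if head is None else asdict(head.spec),
        "extra": extra or {},
    }
    arrays = {f"model_{i}": p.value for i, p in enumerate(model.parameters())}
    if head is not None:
        arrays.update({f"head_{i}": p.value for i, p in enumerate(head.parameters())})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[MaskedAutoencoder, Head | None, dict]:
    """Rebuild a model (and head, if saved) from a checkpoint archive."""
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("config.json"))
        with zf.open("weights.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    model = MaskedAutoencoder(ModelConfig(**meta["model_config"]))
    for i, p in enumerate(model.parameters()):
        p.value[...] = arrays[f"model_{i}"]
    head = None
    if meta["head_spec"] is not None:
        head = Head(HeadSpec(**meta["head_spec"]), meta["model_config"]["d"])
        for i, p in enumerate(head.parameters()):
            p.value[...] = arrays[f"head_{i}"]
    return model, head, meta.get("extra", {})
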