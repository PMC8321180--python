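"""3D densely-connected backbone with Embedded-Gaussian non-local self-attention.

The default configuration follows the published layer plan: a 3x3x3 stem
producing 32 channels, six dense blocks of [6, 8, 8, 8, 8, 6] separable-conv
layers (growth 16) each preceded by [0, 1, 2, 3, 4, 5] non-local blocks and
followed by a 1x1x1-conv + 2x2x2-maxpool transition, yielding a 736-long
visual embedding.  The embedding is concatenated with a 15-element clinical
vector (751 total) and classified by an FC stack of widths
375/187/93/46/46/46/2 with a terminal softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Module,
    Conv3d,
    DepthwiseConv3d,
    PointwiseConv3d,
    BatchNorm3d,
    ReLU,
    MaxPool3d,
    Linear,
    softmax,
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyper-parameters fully determining the model topology."""

    input_shape: tuple[int, int, int] = (16, 64, 64)
    stem_channels: int = 32
    dense_block_layers: tuple[int, ...] = (6, 8, 8, 8, 8, 6)
    nonlocal_counts: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    growth: int = 16
    fc_widths: tuple[int, ...] = (375, 187, 93, 46, 46, 46, 2)
    clinical_dim: int = 15
    nonlocal_inner: int | None = None  # default: half the block's input channels
    nonlocal_residual: bool = True

    def __post_init__(self):
        if len(self.dense_block_layers) != len(self.nonlocal_counts):
            raise ValueError("dense_block_layers and nonlocal_counts must have equal length")
        if self.fc_widths[-1] != 2:
            raise ValueError("final FC width must be 2 (binary classification)")

    @property
    def n_stages(self) -> int:
        return len(self.dense_block_layers)

    def channel_ledger(self) -> list[int]:
        """Output channels after each dense block: stem + cumulative growth."""
        out, c = [], self.stem_channels
        for n in self.dense_block_layers:
            c += n * self.growth
            out.append(c)
        return out

    def spatial_ledger(self) -> list[tuple[int, int, int]]:
        """Spatial shape after each transition (2x pooling clamped at 1)."""
        out, shape = [], tuple(self.input_shape)
        for _ in self.dense_block_layers:
            shape = tuple(s // min(2, s) for s in shape)
            out.append(shape)
        return out

    @property
    def embedding_dim(self) -> int:
        c = self.channel_ledger()[-1]
        d, h, w = self.spatial_ledger()[-1]
        return c * d * h * w

    @property
    def fused_dim(self) -> int:
        return self.embedding_dim + self.clinical_dim

    def inner_dim(self, channels: int) -> int:
        return self.nonlocal_inner if self.nonlocal_inner is not None else max(1, channels // 2)

    @classmethod
    def small(cls, clinical_dim: int = 15) -> "ArchitectureSpec":
        """Reduced-width configuration for CPU-scale training and tests."""
        return cls(
            input_shape=(8, 16, 16),
            stem_channels=8,
            dense_block_layers=(2, 2),
            nonlocal_counts=(0, 1),
            growth=8,
            fc_widths=(32, 16, 2),
            clinical_dim=clinical_dim,
            nonlocal_inner=8,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("input_shape", "dense_block_layers", "nonlocal_counts", "fc_widths"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        for k in ("input_shape", "dense_block_layers", "nonlocal_counts", "fc_widths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class SeparableConv3d(Module):
    """3x3x3 depth-wise convolution followed by a 1x1x1 point-wise stage."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float64):
        self.depthwise = DepthwiseConv3d(c_in, rng, dtype=dtype)
        self.pointwise = PointwiseConv3d(c_in, c_out, rng, bias=True, dtype=dtype)

    def forward(self, x, train=False):
        return self.pointwise.forward(self.depthwise.forward(x, train), train)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))


class DenseLayer(Module):
    """BN -> ReLU -> separable 3x3x3 conv, emitting ``growth`` channels."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator, dtype=np.float64):
        self.bn = BatchNorm3d(c_in, dtype=dtype)
        self.relu = ReLU()
        self.conv = SeparableConv3d(c_in, growth, rng, dtype=dtype)

    def forward(self, x, train=False):
        return self.conv.forward(self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, grad):
        return self.bn.backward(self.relu.backward(self.conv.backward(grad)))


class DenseBlock(Module):
    """Dense connectivity: layer i consumes the concatenation of the block
    input and all previous layer outputs; the block emits that full
    concatenation (input channels + n_layers * growth)."""

    def __init__(self, c_in: int, n_layers: int, growth: int, rng: np.random.Generator, dtype=np.float64):
        self.c_in = c_in
        self.growth = growth
        self.layers = [DenseLayer(c_in + i * growth, growth, rng, dtype=dtype) for i in range(n_layers)]
        self.c_out = c_in + n_layers * growth

    def forward(self, x, train=False):
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            feats.append(layer.forward(inp, train))
        return feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)

    def backward(self, grad):
        sizes = [self.c_in] + [self.growth] * len(self.layers)
        bounds = np.cumsum(sizes)[:-1]
        gfeats = list(np.split(grad, bounds, axis=1))
        for i in range(len(self.layers) - 1, -1, -1):
            gin = self.layers[i].backward(gfeats[i + 1])
            parts = np.split(gin, np.cumsum(sizes[: i + 1])[:-1], axis=1) if i > 0 else [gin]
            for j, part in enumerate(parts):
                gfeats[j] = gfeats[j] + part
        return gfeats[0]


class TransitionDown(Module):
    """1x1x1 convolution (channel-preserving) followed by clamped 2x2x2 max pool."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float64):
        self.conv = PointwiseConv3d(channels, channels, rng, bias=True, dtype=dtype)
        self.pool = MaxPool3d()

    def forward(self, x, train=False):
        return self.pool.forward(self.conv.forward(x, train), train)

    def backward(self, grad):
        return self.conv.backward(self.pool.backward(grad))


class NonLocalBlock(Module):
    """Embedded-Gaussian self-attention over all spatio-temporal positions.

    Response at position i is a softmax-normalised affinity-weighted sum of
    the value embedding at every position j::

        y_i = sum_j softmax_j( theta(x_i) . phi(x_j) ) * beta(x_j)

    theta and phi project to ``inner_dim`` channels; beta keeps the full
    channel count so the block output is shape-compatible with its input.
    With ``residual`` the block returns ``x + y`` (identity-friendly when
    stacked), otherwise ``y`` alone.
    """

    def __init__(self, channels: int, inner_dim: int, rng: np.random.Generator,
                 residual: bool = True, dtype=np.float64):
        self.channels = channels
        self.inner_dim = inner_dim
        self.residual = residual
        self.theta = PointwiseConv3d(channels, inner_dim, rng, bias=False, dtype=dtype)
        self.phi = PointwiseConv3d(channels, inner_dim, rng, bias=False, dtype=dtype)
        self.beta = PointwiseConv3d(channels, channels, rng, bias=False, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        p = d * h * w
        t = self.theta.forward(x, train).reshape(n, self.inner_dim, p)
        f = self.phi.forward(x, train).reshape(n, self.inner_dim, p)
        b = self.beta.forward(x, train).reshape(n, c, p)
        # affinity[i, j] = theta(x_i) . phi(x_j); softmax over j (max-stabilised)
        aff = np.einsum("nip,niq->npq", t, f)
        aff -= aff.max(axis=2, keepdims=True)
        np.exp(aff, out=aff)
        aff /= aff.sum(axis=2, keepdims=True)
        y = np.einsum("npq,ncq->ncp", aff, b).reshape(n, c, d, h, w)
        self._cache = (t, f, b, aff, x.shape)
        return x + y if self.residual else y

    def backward(self, grad):
        t, f, b, aff, shape = self._cache
        self._cache = None
        n, c, d, h, w = shape
        p = d * h * w
        gy = grad.reshape(n, c, p)
        gb = np.einsum("npq,ncp->ncq", aff, gy)
        gaff = np.einsum("ncp,ncq->npq", gy, b)
        # softmax backward over axis j
        gaff = aff * (gaff - (gaff * aff).sum(axis=2, keepdims=True))
        gt = np.einsum("npq,niq->nip", gaff, f)
        gf = np.einsum("npq,nip->niq", gaff, t)
        gx = self.theta.backward(gt.reshape(n, self.inner_dim, d, h, w))
        gx += self.phi.backward(gf.reshape(n, self.inner_dim, d, h, w))
        gx += self.beta.backward(gb.reshape(n, c, d, h, w))
        if self.residual:
            gx += grad
        return gx


class ResponseNet(Module):
    """Full model: backbone -> flatten -> concat clinical -> FC stack -> softmax.

    ``clinical_dim == 0`` yields the visual-only ablation variant (no
    concatenation stage).
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float64):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ledger = spec.channel_ledger()
        # channel-conservation check: stem + sum(layers * growth) == final width
        assert ledger[-1] == spec.stem_channels + sum(n * spec.growth for n in spec.dense_block_layers)

        self.stages: list[tuple[str, Module]] = []
        self.stages.append(("stem", Conv3d(1, spec.stem_channels, rng, dtype=dtype)))
        c = spec.stem_channels
        for i, (n_layers, n_nl) in enumerate(zip(spec.dense_block_layers, spec.nonlocal_counts), start=1):
            for j in range(n_nl):
                self.stages.append(
                    (f"stage{i}.nonlocal{j + 1}",
                     NonLocalBlock(c, spec.inner_dim(c), rng, residual=spec.nonlocal_residual, dtype=dtype))
                )
            self.stages.append((f"stage{i}.dense", DenseBlock(c, n_layers, spec.growth, rng, dtype=dtype)))
            c += n_layers * spec.growth
            self.stages.append((f"stage{i}.transition", TransitionDown(c, rng, dtype=dtype)))

        self.fc_layers: list[Linear] = []
        self.fc_relus: list[ReLU] = []
        widths = [spec.fused_dim] + list(spec.fc_widths)
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            self.fc_layers.append(Linear(n_in, n_out, rng, dtype=dtype))
            self.fc_relus.append(ReLU())
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.stages:
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")
        for i, fc in enumerate(self.fc_layers):
            yield from fc.named_parameters(prefix=f"{prefix}fc{i + 1}.")

    # -- introspection -------------------------------------------------
    def layer_names(self) -> list[str]:
        return [name for name, _ in self.stages]

    def describe(self) -> list[dict]:
        """Per-stage output shapes of a symbolic forward trace (no compute)."""
        rows = []
        c = 1
        shape = tuple(self.spec.input_shape)
        for name, mod in self.stages:
            if isinstance(mod, Conv3d):
                c = mod.c_out
            elif isinstance(mod, DenseBlock):
                c = mod.c_out
            elif isinstance(mod, TransitionDown):
                shape = tuple(s // min(2, s) for s in shape)
            rows.append({"layer": name, "output_shape": (c, *shape)})
        rows.append({"layer": "flatten", "output_shape": (self.spec.embedding_dim,)})
        if self.spec.clinical_dim:
            rows.append({"layer": "concatenation", "output_shape": (self.spec.fused_dim,)})
        for i, fc in enumerate(self.fc_layers):
            kind = "classification" if i == len(self.fc_layers) - 1 else "fully_connected"
            rows.append({"layer": f"{kind}{i + 1}", "output_shape": (fc.n_out,)})
        return rows

    # -- forward / backward --------------------------------------------
    def forward(self, voi: np.ndarray, clinical: np.ndarray | None = None, train: bool = False):
        """Returns ``(probs, info)`` where info carries the visual embedding,
        fused vector, logits, and every backbone activation by layer name."""
        voi = np.asarray(voi, dtype=self.dtype)
        if voi.ndim == 3:
            voi = voi[None]
        if voi.ndim == 4:
            voi = voi[:, None]
        if voi.shape[2:] != tuple(self.spec.input_shape):
            raise ValueError(f"expected input spatial shape {self.spec.input_shape}, got {voi.shape[2:]}")
        n = voi.shape[0]
        if self.spec.clinical_dim:
            if clinical is None:
                raise ValueError("model fuses clinical features; clinical vector is required")
            clinical = np.asarray(clinical, dtype=self.dtype)
            if clinical.ndim == 1:
                clinical = clinical[None]
            if clinical.shape != (n, self.spec.clinical_dim):
                raise ValueError(
                    f"expected clinical shape ({n},{self.spec.clinical_dim}), got {clinical.shape}")

        acts = {}
        x = voi
        for name, mod in self.stages:
            x = mod.forward(x, train=train)
            acts[name] = x
        embedding = x.reshape(n, -1)
        if embedding.shape[1] != self.spec.embedding_dim:
            raise AssertionError("backbone embedding width drifted from spec")
        fused = np.concatenate([embedding, clinical], axis=1) if self.spec.clinical_dim else embedding

        h = fused
        for i, (fc, relu) in enumerate(zip(self.fc_layers, self.fc_relus)):
            h = fc.forward(h, train=train)
            if i < len(self.fc_layers) - 1:
                h = relu.forward(h, train=train)
        logits = h
        probs = softmax(logits, axis=1)
        self._cache = (n, x.shape)
        info = {
            "embedding": embedding,
            "fused": fused,
            "logits": logits,
            "activations": acts,
            "probs": probs,
        }
        return probs, info

    def backward(self, dlogits: np.ndarray, until: str | None = None):
        """Backpropagate a gradient w.r.t. the logits.

        With ``until`` set to a backbone layer name, stops there and returns
        the gradient w.r.t. that layer's *output*; otherwise propagates to
        the input and returns its gradient.
        """
        n, final_shape = self._cache
        g = dlogits
        for i in range(len(self.fc_layers) - 1, -1, -1):
            if i < len(self.fc_layers) - 1:
                g = self.fc_relus[i].backward(g)
            g = self.fc_layers[i].backward(g)
        if self.spec.clinical_dim:
            g = g[:, : self.spec.embedding_dim]
        g = g.reshape(final_shape)
        for name, mod in reversed(self.stages):
            if until is not None and name == until:
                return g
            g = mod.backward(g)
        if until is not None:
            raise KeyError(f"layer {until!r} not found; valid names: {self.layer_names()}")
        return g

    def backbone_forward(self, voi: np.ndarray) -> np.ndarray:
        """Visual embedding only (inference): (N, embedding_dim)."""
        voi = np.asarray(voi, dtype=self.dtype)
        if voi.ndim == 3:
            voi = voi[None]
        if voi.ndim == 4:
            voi = voi[:, None]
        if voi.shape[2:] != tuple(self.spec.input_shape):
            raise ValueError(f"expected input spatial shape {self.spec.input_shape}, got {voi.shape[2:]}")
        x = voi
        for _, mod in self.stages:
            x = mod.forward(x, train=False)
        return x.reshape(x.shape[0], -1)

    def classifier_forward(self, embedding: np.ndarray, clinical: np.ndarray | None = None):
        """Classification head only (inference): returns (probs, fused)."""
        embedding = np.atleast_2d(np.asarray(embedding, dtype=self.dtype))
        if embedding.shape[1] != self.spec.embedding_dim:
            raise ValueError(
                f"expected embedding width {self.spec.embedding_dim}, got {embedding.shape[1]}")
        if self.spec.clinical_dim:
            if clinical is None:
                raise ValueError("model fuses clinical features; clinical vector is required")
            clinical = np.atleast_2d(np.asarray(clinical, dtype=self.dtype))
            if clinical.shape != (embedding.shape[0], self.spec.clinical_dim):
                raise ValueError(
                    f"expected clinical shape ({embedding.shape[0]},{self.spec.clinical_dim}), "
                    f"got {clinical.shape}")
            fused = np.concatenate([embedding, clinical], axis=1)
        else:
            fused = embedding
        h = fused
        for i, (fc, relu) in enumerate(zip(self.fc_layers, self.fc_relus)):
            h = fc.forward(h, train=False)
            if i < len(self.fc_layers) - 1:
                h = relu.forward(h, train=False)
        return softmax(h, axis=1), fused

    def predict_proba(self, vois, clinicals=None, batch_size: int = 8) -> np.ndarray:
        out = []
        for i in range(0, len(vois), batch_size):
            cl = None if clinicals is None else clinicals[i:i + batch_size]
            probs, _ = self.forward(vois[i:i + batch_size], cl, train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)
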