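"""FCN, U-net and ResUnet segmentation networks with an optional RFF layer.

Each network is a composition M_hat = phi_L o ... o phi_1(I) of convolutional
layers ending in a linear 1x1 "logit" layer G followed by a sigmoid, trained
by minimizing the Dice-based loss with mini-batch Adam. The random-Fourier-
feature layer — a fixed 1x1 mapping x -> sqrt(2/Q) cos(omega x + b) that
approximates a Gaussian-kernel feature space — is inserted where the spatial
grid is smallest: after the last pooling in the FCN, and at the bottleneck
end in U-net and ResUnet, so an 8x8xD grid becomes 8x8xQ for a 128x128 input
with four pooling stages.

Filter counts, kernel sizes and the upsampling scheme are configurable
defaults (base_filters doubling per stage, 3x3 convolutions, 2x2 max
pooling, transposed-convolution upsampling); they are not prescribed by the
method itself.

Networks run on the package's internal numpy autodiff engine, so everything
here is CPU-sized: small images, small filter banks.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from ._autodiff import Tensor
from .metrics import EPS
from .rff import RFFParams, median_heuristic_sigma, sample_rff_params

__all__ = [
    "ModelConfig",
    "SegModel",
    "build_fcn",
    "build_unet",
    "build_resunet",
    "build_model",
    "residual_block",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "RFFSegmenter",
]

Q_FACTOR_GRID = (8, 16, 32, 64, 128)


@dataclass
class ModelConfig:
    architecture: str = "unet"
    input_size: tuple = (128, 128)
    depth: int = 4
    base_filters: int = 16
    use_rff: bool = True
    q_factor: int = 8
    rff_sigma: object = "median"   # "median" or a positive float
    rff_trainable: bool = False
    rff_seed: int = 0
    final_activation: str = "sigmoid"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    optimizer_seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("fcn", "unet", "resunet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        r, c = self.input_size
        if r % 2 ** self.depth or c % 2 ** self.depth:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth")
        if self.use_rff and self.q_factor not in Q_FACTOR_GRID:
            raise ValueError(f"q_factor must be one of {Q_FACTOR_GRID}")
        if self.final_activation != "sigmoid":
            raise ValueError("only bi-class (sigmoid) heads are supported")


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _he_init(rng, k, cin, cout):
    return rng.normal(0.0, np.sqrt(2.0 / (k * k * cin)),
                      size=(k, k, cin, cout)).astype(np.float32)


class Conv:
    kind = "conv"

    def __init__(self, name, k, cin, cout, activation, rng):
        self.name, self.k, self.cin, self.cout = name, k, cin, cout
        self.activation = activation
        self.w = Tensor(_he_init(rng, k, cin, cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        out = x.conv2d(self.w, self.b)
        return out.relu() if self.activation == "relu" else out

    def params(self):
        return [self.w, self.b]

    def describe(self):
        return {"name": self.name, "type": "conv", "k": self.k,
                "cin": self.cin, "cout": self.cout,
                "activation": self.activation}


class MaxPool:
    kind = "pool"

    def __init__(self, name):
        self.name = name

    def __call__(self, x):
        return x.maxpool2()

    def params(self):
        return []

    def describe(self):
        return {"name": self.name, "type": "maxpool", "k": 2}


class UpConv:
    """Transposed convolution with kernel == stride (2x per decoder stage)."""

    kind = "upconv"

    def __init__(self, name, k, cin, cout, rng):
        self.name, self.k, self.cin, self.cout = name, k, cin, cout
        self.w = Tensor(_he_init(rng, k, cin, cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return x.conv_transpose_block(self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def describe(self):
        return {"name": self.name, "type": "upconv", "k": self.k,
                "cin": self.cin, "cout": self.cout}


class RFFLayer:
    """Per-position random Fourier map: 1x1 'convolution' with cos activation."""

    kind = "rff"

    def __init__(self, name, rff_params: RFFParams):
        self.name = name
        self.set_params(rff_params)

    def set_params(self, rff_params: RFFParams):
        self.rff_params = rff_params
        train = rff_params.trainable
        self.wt = Tensor(rff_params.omega.T.astype(np.float32),
                         requires_grad=train)
        self.bt = Tensor(rff_params.b.astype(np.float32), requires_grad=train)

    def __call__(self, x):
        q = self.rff_params.Q
        return (x.dot_last(self.wt) + self.bt).cos() * np.float32(
            np.sqrt(2.0 / q))

    def params(self):
        return [self.wt, self.bt] if self.rff_params.trainable else []

    def describe(self):
        return {"name": self.name, "type": "rff", "cin": self.rff_params.P,
                "cout": self.rff_params.Q,
                "sigma": self.rff_params.sigma}


class ResidualBlock:
    """F -> ReLU(conv(ReLU(conv(F))) + proj(F)); identity skip when shapes match."""

    kind = "resblock"

    def __init__(self, name, cin, cout, rng):
        self.name, self.cin, self.cout = name, cin, cout
        self.conv1 = Conv(f"{name}_conv1", 3, cin, cout, "relu", rng)
        self.conv2 = Conv(f"{name}_conv2", 3, cout, cout, "linear", rng)
        self.proj = (Conv(f"{name}_proj", 1, cin, cout, "linear", rng)
                     if cin != cout else None)

    def __call__(self, x):
        inner = self.conv2(self.conv1(x))
        skip = self.proj(x) if self.proj is not None else x
        return (inner + skip).relu()

    def params(self):
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def describe(self):
        return {"name": self.name, "type": "resblock", "cin": self.cin,
                "cout": self.cout, "projected": self.proj is not None}


def residual_block(F: np.ndarray, transform, proj=None) -> np.ndarray:
    """Functional residual rewrite F -> transform(F) + F (optionally projected).

    ``transform`` maps an R x C x D grid to a same-spatial-shape grid;
    ``proj`` adapts channel counts when they differ (identity otherwise).
    """
    F = np.asarray(F, dtype=np.float64)
    inner = np.asarray(transform(F), dtype=np.float64)
    skip = F if proj is None else np.asarray(proj(F), dtype=np.float64)
    if inner.shape != skip.shape:
        raise ValueError("transform changed the grid shape and no projection "
                         "was given")
    return inner + skip


# --------------------------------------------------------------------------
# the network container
# --------------------------------------------------------------------------

class SegModel:
    """A built network: ordered layers plus the wiring of skips and taps.

    ``forward`` returns the sigmoid probability grid; ``forward_full``
    additionally exposes the pre-activation logits G and every intermediate
    feature tensor by name (autodiff tensors, so gradients of a scalar in
    the graph can be read off any of them).
    """

    def __init__(self, config: ModelConfig, encoder, bottleneck, rff,
                 decoder, head, cam_layer_name):
        self.config = config
        self.encoder = encoder          # list of (block_layers, pool)
        self.bottleneck = bottleneck    # list of layers
        self.rff = rff                  # RFFLayer or None
        self.decoder = decoder          # list of (upconv, block_layers)
        self.head = head                # list of layers, last one linear
        self.cam_layer_name = cam_layer_name

    # -- structure ---------------------------------------------------------
    def layers(self):
        out = []
        for block, pool in self.encoder:
            out.extend(block)
            out.append(pool)
        out.extend(self.bottleneck)
        if self.rff is not None:
            out.append(self.rff)
        for up, block in self.decoder:
            out.append(up)
            out.extend(block)
        out.extend(self.head)
        return out

    def layer_summary(self):
        return [layer.describe() for layer in self.layers()]

    def parameters(self):
        ps = []
        for layer in self.layers():
            ps.extend(layer.params())
        return ps

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward -----------------------------------------------------------
    @staticmethod
    def _as_batch(images):
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[..., None]
        return x

    def forward_full(self, images, input_requires_grad=False):
        x = Tensor(self._as_batch(images),
                   requires_grad=bool(input_requires_grad))
        feats = {"input": x}
        skips = []
        for block, pool in self.encoder:
            for layer in block:
                x = layer(x)
                feats[layer.name] = x
            skips.append(x)
            x = pool(x)
            feats[pool.name] = x
        for layer in self.bottleneck:
            x = layer(x)
            feats[layer.name] = x
        if self.rff is not None:
            x = self.rff(x)
            feats[self.rff.name] = x
        for (up, block), skip in zip(self.decoder, reversed(skips)):
            x = up(x)
            x = Tensor.concat([x, skip], axis=-1)
            feats[up.name] = x
            for layer in block:
                x = layer(x)
                feats[layer.name] = x
        for layer in self.head:
            x = layer(x)
            feats[layer.name] = x
        logits = x
        prob = logits.sigmoid()
        return prob, logits, feats

    def forward(self, images) -> np.ndarray:
        prob, _, _ = self.forward_full(images)
        return prob.data[..., 0]

    def predict_proba(self, images) -> np.ndarray:
        return self.forward(images)

    def predict(self, images, threshold: float = 0.5) -> np.ndarray:
        return (self.forward(images) >= threshold).astype(np.uint8)

    # -- RFF bandwidth resolution -------------------------------------------
    def pre_rff_features(self, images) -> np.ndarray:
        """Feature vectors entering the RFF layer (flattened over positions)."""
        _, _, feats = self.forward_full(images)
        name = self.cam_layer_name if self.rff is None else self._pre_rff_name
        f = feats[name].data
        return f.reshape(-1, f.shape[-1])

    def resolve_rff_sigma(self, warmup_images, seed=None):
        """Set the RFF bandwidth by the median heuristic on a warm-up batch."""
        if self.rff is None:
            return None
        feats = self.pre_rff_features(warmup_images)
        sigma = median_heuristic_sigma(feats)
        cfg = self.config
        seed = cfg.rff_seed if seed is None else seed
        params = sample_rff_params(self.rff.rff_params.P,
                                   self.rff.rff_params.Q, sigma, seed)
        self.rff.set_params(replace(params, trainable=cfg.rff_trainable))
        return sigma


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _initial_rff(cfg: ModelConfig, P: int) -> RFFParams:
    sigma = 1.0 if isinstance(cfg.rff_sigma, str) else float(cfg.rff_sigma)
    params = sample_rff_params(P, cfg.q_factor, sigma, cfg.rff_seed)
    return replace(params, trainable=cfg.rff_trainable)


def _conv_pair(name, cin, cout, rng):
    return [Conv(f"{name}_conv1", 3, cin, cout, "relu", rng),
            Conv(f"{name}_conv2", 3, cout, cout, "relu", rng)]


def build_unet(config: ModelConfig) -> SegModel:
    """Symmetric encoder-decoder with skip connections (plain conv blocks)."""
    return _build_ushaped(config, residual=False)


def build_resunet(config: ModelConfig) -> SegModel:
    """U-net topology with residual blocks in place of plain conv pairs."""
    return _build_ushaped(config, residual=True)


def _build_ushaped(config: ModelConfig, residual: bool) -> SegModel:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.optimizer_seed, 17]))
    f = config.base_filters

    def block(name, cin, cout):
        if residual:
            return [ResidualBlock(name, cin, cout, rng)]
        return _conv_pair(name, cin, cout, rng)

    encoder, cin = [], 1
    for d in range(config.depth):
        cout = f * 2 ** d
        encoder.append((block(f"enc{d + 1}", cin, cout),
                        MaxPool(f"pool{d + 1}")))
        cin = cout
    bneck_c = f * 2 ** config.depth
    bottleneck = block("bottleneck", cin, bneck_c)

    rff = None
    dec_in = bneck_c
    if config.use_rff:
        rff = RFFLayer("rff", _initial_rff(config, bneck_c))
        dec_in = config.q_factor

    decoder = []
    for d in reversed(range(config.depth)):
        cout = f * 2 ** d
        up = UpConv(f"up{d + 1}", 2, dec_in, cout, rng)
        decoder.append((up, block(f"dec{d + 1}", 2 * cout, cout)))
        dec_in = cout
    head = [Conv("logit", 1, dec_in, 1, "linear", rng)]

    model = SegModel(config, encoder, bottleneck, rff, decoder, head,
                     cam_layer_name=bottleneck[-1].name)
    model._pre_rff_name = bottleneck[-1].name
    return model


def build_fcn(config: ModelConfig) -> SegModel:
    """VGG-style encoder with a single 2^depth-upsampling score head.

    The RFF layer (when enabled) consumes the last pooling output and feeds
    the 1x1 score convolution, which a block transposed convolution brings
    back to input resolution.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.optimizer_seed, 17]))
    f = config.base_filters

    encoder, cin = [], 1
    for d in range(config.depth):
        cout = f * 2 ** d
        encoder.append((_conv_pair(f"enc{d + 1}", cin, cout, rng),
                        MaxPool(f"pool{d + 1}")))
        cin = cout

    rff = None
    score_in = cin
    if config.use_rff:
        rff = RFFLayer("rff", _initial_rff(config, cin))
        score_in = config.q_factor

    up_k = 2 ** config.depth
    head = [Conv("score", 1, score_in, 1, "linear", rng),
            UpConv("upsample", up_k, 1, 1, rng)]

    model = SegModel(config, encoder, [], rff, [], head,
                     cam_layer_name=encoder[-1][0][-1].name)
    model._pre_rff_name = encoder[-1][1].name  # last pooling output
    return model


_BUILDERS = {"fcn": build_fcn, "unet": build_unet, "resunet": build_resunet}


def build_model(config: ModelConfig) -> SegModel:
    return _BUILDERS[config.architecture](config)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _batch_dice_loss(prob: Tensor, masks: np.ndarray) -> Tensor:
    """Mean over the batch of (1 - soft Dice), eps = 1 in both terms."""
    n = prob.shape[0]
    dt = prob.data.dtype
    p = prob.reshape(n, -1)
    m = masks.reshape(n, -1).astype(dt)
    one, eps = dt.type(1.0), dt.type(EPS)
    inter = (p * m).sum(axis=1)
    sums = p.sum(axis=1) + Tensor(m.sum(axis=1))
    s = (dt.type(2.0) * inter + eps) / (sums + eps)
    return (one - s).mean()


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - (self.lr * mhat /
                               (np.sqrt(vhat) + eps)).astype(p.data.dtype)


def _split_arrays(pairs, splits):
    out = {}
    for name in ("train", "val", "test"):
        sel = [p for p, s in zip(pairs, splits) if s == name]
        if sel:
            out[name] = (np.stack([p.image for p in sel]).astype(np.float32),
                         np.stack([p.mask for p in sel]).astype(np.float32))
    return out


def train(model: SegModel, pairs, splits, verbose: bool = False):
    """Mini-batch Adam minimization of the Dice loss with best-val checkpointing.

    ``history['val_loss'][0]`` is the pre-training validation loss; entry e
    (e >= 1) follows epoch e. The parameter state achieving the lowest
    validation loss is restored before returning.
    """
    data = _split_arrays(pairs, splits)
    if "train" not in data or "val" not in data:
        raise ValueError("train and validation splits must be non-empty")
    cfg = model.config
    x_tr, y_tr = data["train"]

    if model.rff is not None and isinstance(cfg.rff_sigma, str):
        model.resolve_rff_sigma(x_tr[:min(len(x_tr), cfg.batch_size)])

    params = model.parameters()
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.optimizer_seed, 29]))

    def val_loss():
        x_va, y_va = data["val"]
        prob, _, _ = model.forward_full(x_va)
        return float(_batch_dice_loss(prob, y_va).data)

    history = {"train_loss": [], "val_loss": [val_loss()]}
    best = (history["val_loss"][0],
            [p.data.copy() for p in params])
    steps = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(x_tr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            prob, _, _ = model.forward_full(x_tr[idx])
            loss = _batch_dice_loss(prob, y_tr[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, step {steps}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            steps += 1
        history["train_loss"].append(float(np.mean(losses)))
        vl = val_loss()
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, [p.data.copy() for p in params])
        if verbose:
            print(f"epoch {epoch + 1:3d}  train {history['train_loss'][-1]:.4f}"
                  f"  val {vl:.4f}")
    for p, b in zip(params, best[1]):
        p.data = b
    history["steps"] = steps
    history["best_val_loss"] = best[0]
    return model, history


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(model: SegModel, path: str):
    """Single-file archive: weights (npz) + config (json) + RFF params."""
    cfg = asdict(model.config)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    if model.rff is not None:
        arrays["rff_omega"] = model.rff.rff_params.omega
        arrays["rff_b"] = model.rff.rff_params.b
        cfg["rff_sigma"] = float(model.rff.rff_params.sigma)
    with zipfile.ZipFile(path, "w") as z:
        z.writestr("config.json", json.dumps(cfg))
        import io
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        z.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path: str) -> SegModel:
    with zipfile.ZipFile(path) as z:
        cfg = json.loads(z.read("config.json"))
        import io
        arrays = np.load(io.BytesIO(z.read("arrays.npz")))
        cfg["input_size"] = tuple(cfg["input_size"])
        config = ModelConfig(**cfg)
        model = build_model(config)
        if model.rff is not None:
            model.rff.set_params(RFFParams(
                omega=arrays["rff_omega"], b=arrays["rff_b"],
                sigma=cfg["rff_sigma"], trainable=config.rff_trainable))
        for i, p in enumerate(model.parameters()):
            p.data = arrays[f"param_{i}"].astype(p.data.dtype)
    return model


# --------------------------------------------------------------------------
# scikit-learn estimator facade
# --------------------------------------------------------------------------

class RFFSegmenter:
    """scikit-learn-style segmenter: fit on (images, masks), predict masks.

    Parameters mirror :class:`ModelConfig`; ``fit`` accepts arrays of shape
    (n, R, C) for both images (floats in [0,1]) and masks ({0,1}), holds out
    ``validation_fraction`` of the samples for checkpoint selection unless
    ``validation_data`` is given, and stores the trained network in ``net_``.
    """

    def __init__(self, architecture="unet", depth=3, base_filters=8,
                 use_rff=True, q_factor=8, rff_sigma="median",
                 rff_trainable=False, learning_rate=1e-3, batch_size=32,
                 epochs=30, validation_fraction=0.1, threshold=0.5,
                 random_state=0):
        self.architecture = architecture
        self.depth = depth
        self.base_filters = base_filters
        self.use_rff = use_rff
        self.q_factor = q_factor
        self.rff_sigma = rff_sigma
        self.rff_trainable = rff_trainable
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state

    # sklearn plumbing (kept explicit: no fancy introspection needed)
    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "architecture", "depth", "base_filters", "use_rff", "q_factor",
            "rff_sigma", "rff_trainable", "learning_rate", "batch_size",
            "epochs", "validation_fraction", "threshold", "random_state")}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self, input_size):
        return ModelConfig(
            architecture=self.architecture, input_size=input_size,
            depth=self.depth, base_filters=self.base_filters,
            use_rff=self.use_rff, q_factor=self.q_factor,
            rff_sigma=self.rff_sigma, rff_trainable=self.rff_trainable,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, optimizer_seed=self.random_state)

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must both be (n, R, C) with equal shapes")
        from .synthetic import ImagePair  # local to avoid import cycle
        cfg = self._config(tuple(X.shape[1:]))
        net = build_model(cfg)
        pairs = [ImagePair(image=xi, mask=yi) for xi, yi in zip(X, y)]
        if validation_data is not None:
            xv, yv = validation_data
            pairs += [ImagePair(image=np.asarray(a, dtype=np.float32),
                                mask=np.asarray(b, dtype=np.float32))
                      for a, b in zip(xv, yv)]
            labels = ["train"] * len(X) + ["val"] * len(xv)
        else:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            rng = np.random.default_rng(self.random_state)
            val_idx = set(rng.choice(len(X), n_val, replace=False).tolist())
            labels = ["val" if i in val_idx else "train"
                      for i in range(len(X))]
        _, history = train(net, pairs, labels)
        self.net_ = net
        self.history_ = history
        self.rff_params_ = None if net.rff is None else net.rff.rff_params
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        self._check_fitted()
        return self.net_.forward(np.asarray(X, dtype=np.float32))

    def predict(self, X):
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y):
        """Mean soft-Dice similarity (in [0,1]) over the given pairs."""
        from .metrics import dice_similarity
        probs = self.predict_proba(X)
        return float(np.mean([dice_similarity(m, p)
                              for m, p in zip(np.asarray(y), probs)]))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("this RFFSegmenter instance is not fitted yet")
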