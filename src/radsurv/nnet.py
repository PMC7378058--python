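"""Two-branch risk CNNs trained by negative Cox partial likelihood, with
convolutional auto-encoder pre-training.

Each branch maps a side x side x 3 patch stack to a single unbounded risk
score through conv(3x3, 32, ReLU) -> pool(2x2) -> conv(3x3, 32, ReLU) ->
pool(2x2) -> FC(32, ReLU) -> FC(1, linear). Training is plain SGD over
shuffled mini-batches; the loss of a batch is the negative Breslow partial
log-likelihood with the risk set restricted to the batch, normalized by the
number of batch events (event-free batches are skipped). The engine is a
compact float32 implementation on im2col matrix products, seeded end to end.

The reference optimizer schedule is lr 1e-5 for 2000 epochs; the
``desk_scale`` preset (150 epochs, lr 2e-4) keeps the product of learning
rate and step count in the same regime for test-sized runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as _k
from .survival import cox_partial_loglik, cox_partial_loglik_grad

__all__ = [
    "RiskNetSpec",
    "RiskNet",
    "build_risk_net",
    "parameter_count",
    "batch_cox_loss",
    "batch_cox_loss_grad",
    "train_risk_net",
    "extract_penultimate",
    "ConvAutoEncoder",
    "pretrain_cae",
    "SKIP_BATCH",
]

SKIP_BATCH = None  # sentinel for an event-free batch: no loss, no step


@dataclass(frozen=True)
class RiskNetSpec:
    input_side: int = 80
    channels: int = 3
    conv_filters: int = 3       # filter side
    feature_maps: int = 32
    fc_width: int = 32
    learning_rate: float = 1e-5
    epochs: int = 2000
    batch_size: int = 32
    lr_decay: str = "constant"  # "constant" | "linear" (to 0 over epochs)
    augment: bool = False       # random flips / 90-degree rotations

    def desk_scale(self, epochs=150, learning_rate=1e-3, lr_decay="linear",
                   augment=True):
        """Scaled-down schedule for interactive/test runs: fewer epochs at
        a larger, linearly decayed step size, with flip/rotation
        augmentation to offset the small sample."""
        return replace(self, epochs=epochs, learning_rate=learning_rate,
                       lr_decay=lr_decay, augment=augment)

    def validate(self):
        if self.input_side < 8 or self.input_side % 4 != 0:
            raise ValueError(
                "input side must be >= 8 and divisible by 4 "
                "(two 2x2 pooling stages)")
        for f in ("feature_maps", "fc_width", "epochs", "batch_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# primitive layers (float32, NHWC)
# ---------------------------------------------------------------------------

def _im2col3(x):
    """(B,H,W,C) -> (B*H*W, 9C) 'same'-padded 3x3 patches."""
    return _k.im2col3(x)


def conv3_forward(x, W, b, cols=None, ws=None, key="conv"):
    """'Same'-padded 3x3 convolution as one GEMM over extracted patches.

    ``W`` has shape (9C, F) with rows ordered offset-major; ``cols`` may
    carry precomputed patches; ``ws`` is an optional buffer pool.
    """
    B, H, Wd, C = x.shape
    F = W.shape[1]
    if cols is None:
        cols = _k.im2col3(x, ws, key + "_cols")
    if ws is None:
        out = cols @ W
    else:
        out = ws.get(key + "_out", (B * H * Wd, F), cols.dtype)
        np.matmul(cols, W, out=out)
    out += b
    return out.reshape(B, H, Wd, F), cols


def conv3_backward(dout, cols, W, x_shape, need_dx=True, ws=None, key="conv"):
    F = W.shape[1]
    dflat = np.ascontiguousarray(dout.reshape(-1, F))
    dW = (dflat.T @ cols).T  # transposed orientation is faster in BLAS here
    db = dflat.sum(axis=0)
    dx = None
    if need_dx:
        WT = np.ascontiguousarray(W.T)
        if ws is None:
            dcols = dflat @ WT
        else:
            dcols = ws.get(key + "_dcols", (dflat.shape[0], W.shape[0]),
                           dflat.dtype)
            np.matmul(dflat, WT, out=dcols)
        dx = _k.col2im3(dcols, x_shape, ws, key + "_dpad")
    return dx, dW, db


def relu_forward(x):
    return np.maximum(x, 0.0)


def relu_backward(dout, out):
    return np.where(out > 0, dout, 0.0)


def pool2_forward(x, ws=None, key="pool"):
    """2x2 stride-2 max pool.

    Returns the pooled map and the winning quadrant per pooled cell
    (0..3 in the order 00, 01, 10, 11; earliest wins ties).
    """
    return _k.pool2(np.ascontiguousarray(x), ws, key)


def pool2_backward(dout, x_shape, q, ws=None, key="unpool"):
    """Scatter pooled gradients back to the winning positions."""
    return _k.unpool2(np.ascontiguousarray(dout), q, x_shape, ws, key)


def upsample2_forward(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dout):
    B, H, W, C = dout.shape
    return (dout.reshape(B, H // 2, 2, W // 2, 2, C)
                .sum(axis=(2, 4)))


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# risk network
# ---------------------------------------------------------------------------

def parameter_count(spec: RiskNetSpec) -> int:
    """Closed-form number of trainable parameters for a spec."""
    F, C, W = spec.feature_maps, spec.channels, spec.fc_width
    side = spec.input_side // 4
    conv1 = 9 * C * F + F
    conv2 = 9 * F * F + F
    fc1 = side * side * F * W + W
    fc2 = W * 1 + 1
    return conv1 + conv2 + fc1 + fc2


class RiskNet:
    """One CNN risk branch. Parameters live in ``self.params``."""

    def __init__(self, spec: RiskNetSpec, seed=0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, C, Wd = spec.feature_maps, spec.channels, spec.fc_width
        side = spec.input_side // 4
        flat = side * side * F
        self.params = {
            "conv1_W": _glorot(rng, 9 * C, F, (9 * C, F)),
            "conv1_b": np.zeros(F, dtype=np.float32),
            "conv2_W": _glorot(rng, 9 * F, F, (9 * F, F)),
            "conv2_b": np.zeros(F, dtype=np.float32),
            "fc1_W": _glorot(rng, flat, Wd, (flat, Wd)),
            "fc1_b": np.zeros(Wd, dtype=np.float32),
            "fc2_W": _glorot(rng, Wd, 1, (Wd, 1)),
            "fc2_b": np.zeros(1, dtype=np.float32),
        }

    # -- forward / backward -------------------------------------------------

    def forward(self, x, want_cache=False, cols1=None, ws=None):
        """x: (B, side, side, channels) -> risk scores (B,).

        ``cols1`` may carry precomputed first-layer patches of ``x`` (the
        training loop extracts them once per dataset since they depend on
        the data only, not on the weights); with ``cols1`` given, ``x``
        may be None. ``ws`` is a reusable buffer pool; when supplied, the
        returned cache aliases its buffers, which are valid until the next
        forward call with the same workspace.
        """
        side, C = self.spec.input_side, self.spec.channels
        if x is None:
            if cols1 is None:
                raise ValueError("need x or precomputed cols1")
            x_shape = (cols1.shape[0] // (side * side), side, side, C)
        else:
            x = np.ascontiguousarray(x, dtype=np.float32)
            if x.ndim != 4 or x.shape[1] != side or x.shape[3] != C:
                raise ValueError("input does not match the network spec")
            x_shape = x.shape
        p = self.params
        # pooling is applied to the raw conv maps and ReLU to the pooled
        # quarter-size maps; since ReLU is monotone this equals the
        # conv->ReLU->pool composition while touching 4x less memory
        if cols1 is None:
            cols1 = _k.im2col3(x, ws, "c1_cols")
        if ws is None:
            a1 = (cols1 @ p["conv1_W"] + p["conv1_b"]).reshape(
                x_shape[0], side, side, -1)
        else:
            a1_flat = ws.get("c1_out", (cols1.shape[0],
                                        p["conv1_W"].shape[1]))
            np.matmul(cols1, p["conv1_W"], out=a1_flat)
            a1_flat += p["conv1_b"]
            a1 = a1_flat.reshape(x_shape[0], side, side, -1)
        m1, q1 = pool2_forward(a1, ws, "p1")
        a1_shape = a1.shape
        del a1
        if ws is None:
            r1 = relu_forward(m1)
        else:
            r1 = ws.get("r1", m1.shape)
            np.maximum(m1, np.float32(0), out=r1)
        a2, cols2 = conv3_forward(r1, p["conv2_W"], p["conv2_b"],
                                  ws=ws, key="c2")
        m2, q2 = pool2_forward(a2, ws, "p2")
        flat = relu_forward(m2).reshape(x_shape[0], -1)
        h = relu_forward(flat @ p["fc1_W"] + p["fc1_b"])
        eta = (h @ p["fc2_W"] + p["fc2_b"]).ravel()
        if not want_cache:
            return eta
        cache = dict(x_shape=x_shape, cols1=cols1, a1_shape=a1_shape,
                     q1=q1, r1=r1, cols2=cols2, a2_shape=a2.shape, q2=q2,
                     m2=m2, flat=flat, h=h)
        return eta, cache

    def backward(self, cache, deta, ws=None):
        """Gradient of a scalar loss given d loss / d eta."""
        p = self.params
        g = {}
        deta32 = deta[:, None].astype(np.float32)
        dh = deta32 @ p["fc2_W"].T
        g["fc2_W"] = cache["h"].T @ deta32
        g["fc2_b"] = deta32.sum(axis=0)
        dh = relu_backward(dh, cache["h"])
        g["fc1_W"] = cache["flat"].T @ dh
        g["fc1_b"] = dh.sum(axis=0)
        dflat = dh @ p["fc1_W"].T
        dm2 = np.where(cache["m2"] > 0,
                       dflat.reshape(cache["m2"].shape), np.float32(0))
        da2 = pool2_backward(dm2, cache["a2_shape"], cache["q2"], ws, "u2")
        # conv2 backward with its input gradient fused through the ReLU
        # mask and the first pooling stage in a single kernel pass
        F = p["conv2_W"].shape[1]
        dflat2 = np.ascontiguousarray(da2.reshape(-1, F))
        g["conv2_W"] = (dflat2.T @ cache["cols2"]).T
        g["conv2_b"] = dflat2.sum(axis=0)
        W2T = np.ascontiguousarray(p["conv2_W"].T)
        if ws is None:
            dcols = dflat2 @ W2T
        else:
            # cols2 has served its last reader (the dW GEMM above): reuse
            # its buffer for the patch gradients to halve the footprint
            dcols = ws.get("c2_cols", (dflat2.shape[0], W2T.shape[1]),
                           dflat2.dtype)
            np.matmul(dflat2, W2T, out=dcols)
        da1 = _k.convdx_relu_unpool(dcols, cache["r1"], cache["q1"],
                                    cache["a1_shape"], ws, "u1")
        _, g["conv1_W"], g["conv1_b"] = conv3_backward(
            da1, cache["cols1"], p["conv1_W"], cache["x_shape"],
            need_dx=False, ws=ws, key="c1")
        return g

    def penultimate(self, x):
        """Activations of the 32-wide FC layer before the risk unit."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.params
        a1, _ = conv3_forward(x, p["conv1_W"], p["conv1_b"])
        r1 = relu_forward(pool2_forward(a1)[0])
        a2, _ = conv3_forward(r1, p["conv2_W"], p["conv2_b"])
        flat = relu_forward(pool2_forward(a2)[0]).reshape(len(x), -1)
        return relu_forward(flat @ p["fc1_W"] + p["fc1_b"])

    def sgd_step(self, grads, lr):
        for k, gk in grads.items():
            self.params[k] -= np.float32(lr) * gk

    def load_trunk(self, trunk):
        """Transfer conv trunk weights (e.g. from a pre-trained CAE)."""
        for k in ("conv1_W", "conv1_b", "conv2_W", "conv2_b"):
            if trunk[k].shape != self.params[k].shape:
                raise ValueError(f"shape mismatch transferring {k}")
            self.params[k] = trunk[k].astype(np.float32).copy()


def build_risk_net(spec: RiskNetSpec, seed=0) -> RiskNet:
    return RiskNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# batch Cox loss
# ---------------------------------------------------------------------------

def batch_cox_loss(eta, time, event):
    """Negative batch-restricted Breslow partial log-likelihood per event.

    Returns :data:`SKIP_BATCH` for an event-free batch (no gradient step is
    taken for it).
    """
    event = np.asarray(event)
    d = int(event.sum())
    if d == 0:
        return SKIP_BATCH
    return -cox_partial_loglik(np.asarray(eta, float), time, event) / d


def batch_cox_loss_grad(eta, time, event):
    event = np.asarray(event)
    d = int(event.sum())
    if d == 0:
        return SKIP_BATCH
    return -cox_partial_loglik_grad(np.asarray(eta, float), time, event) / d


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_risk_net(net: RiskNet, stacks, time, event, seed=0,
                   log_every=None):
    """SGD training of one branch on aligned stacks and survival records.

    Returns ``(net, risk_scores, history)`` where history is the per-epoch
    mean batch loss. Risk scores are the final linear-unit outputs in the
    input order (so they are invariant to case order by construction).
    """
    stacks = np.ascontiguousarray(stacks, dtype=np.float32)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(stacks) != len(time):
        raise ValueError("stacks and records must align")
    if event.sum() == 0:
        raise ValueError("cannot train on an all-censored set")
    spec = net.spec
    rng = np.random.default_rng(seed)
    n = len(stacks)
    side = spec.input_side
    hw = side * side
    # without augmentation the first-layer patches depend only on the
    # data and are extracted once for the whole run
    cols_all = None if spec.augment else _im2col3(stacks)
    ws = _k.Workspace()
    history = []
    for epoch in range(spec.epochs):
        if spec.lr_decay == "linear":
            lr = spec.learning_rate * (1.0 - epoch / spec.epochs)
        else:
            lr = spec.learning_rate
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            if len(idx) < 2:
                continue
            tb, eb = time[idx], event[idx]
            if eb.sum() == 0:
                continue  # event-free batch: skip, no step
            if spec.augment:
                xb = stacks[idx]
                # per-sample random dihedral transform; the survival labels
                # are invariant to patch orientation
                flips = rng.integers(0, 2, size=(len(idx), 2))
                rots = rng.integers(0, 4, size=len(idx))
                xb = np.stack([
                    np.rot90(_maybe_flip(xb[j], flips[j]), k=int(rots[j]),
                             axes=(0, 1))
                    for j in range(len(idx))])
                eta, cache = net.forward(np.ascontiguousarray(xb),
                                         want_cache=True, ws=ws)
            else:
                cols_b = ws.get("cols1", (len(idx) * hw, cols_all.shape[1]))
                for j, s in enumerate(idx):  # block memcpy per sample
                    cols_b[j * hw:(j + 1) * hw] = \
                        cols_all[s * hw:(s + 1) * hw]
                eta, cache = net.forward(None, want_cache=True, cols1=cols_b,
                                         ws=ws)
            losses.append(batch_cox_loss(eta, tb, eb))
            deta = batch_cox_loss_grad(eta, tb, eb)
            grads = net.backward(cache, deta, ws=ws)
            net.sgd_step(grads, lr)
        history.append(float(np.mean(losses)) if losses else np.nan)
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{spec.epochs} loss {history[-1]:.4f}")
    risks = score_risks(net, stacks)
    return net, risks, history


def _maybe_flip(x, flips):
    if flips[0]:
        x = x[::-1, :, :]
    if flips[1]:
        x = x[:, ::-1, :]
    return x


def score_risks(net: RiskNet, stacks, batch=64):
    stacks = np.ascontiguousarray(stacks, dtype=np.float32)
    out = [net.forward(stacks[i:i + batch]) for i in range(0, len(stacks), batch)]
    return np.concatenate(out) if out else np.empty(0)


def extract_penultimate(net: RiskNet, stacks, batch=64):
    """Per-case activations of the layer before the risk unit (width 32)."""
    stacks = np.ascontiguousarray(stacks, dtype=np.float32)
    out = [net.penultimate(stacks[i:i + batch])
           for i in range(0, len(stacks), batch)]
    return np.concatenate(out) if out else np.empty((0, net.spec.fc_width))


def save_weights(net: RiskNet, path, seed=None, extra=None):
    """Serialize a branch to a single NPZ archive with a JSON metadata
    header (spec fields, seed, anything in ``extra``)."""
    import dataclasses
    import json

    meta = {"spec": dataclasses.asdict(net.spec), "seed": seed}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **net.params)
    return path


def load_weights(path) -> RiskNet:
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        spec = RiskNetSpec(**meta["spec"])
        net = RiskNet(spec, seed=0)
        for k in net.params:
            net.params[k] = archive[k].copy()
    return net


# ---------------------------------------------------------------------------
# convolutional auto-encoder pre-training
# ---------------------------------------------------------------------------

class ConvAutoEncoder:
    """Encoder = the risk net's conv/pool trunk; decoder mirrors it with
    nearest-neighbor upsampling: up2 -> conv(3x3,32,ReLU) -> up2 ->
    conv(3x3,32,ReLU) -> conv(3x3,channels,linear). Trained on mean squared
    reconstruction error."""

    def __init__(self, spec: RiskNetSpec, seed=0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, C = spec.feature_maps, spec.channels
        self.params = {
            "conv1_W": _glorot(rng, 9 * C, F, (9 * C, F)),
            "conv1_b": np.zeros(F, dtype=np.float32),
            "conv2_W": _glorot(rng, 9 * F, F, (9 * F, F)),
            "conv2_b": np.zeros(F, dtype=np.float32),
            "dec1_W": _glorot(rng, 9 * F, F, (9 * F, F)),
            "dec1_b": np.zeros(F, dtype=np.float32),
            "dec2_W": _glorot(rng, 9 * F, F, (9 * F, F)),
            "dec2_b": np.zeros(F, dtype=np.float32),
            "dec3_W": _glorot(rng, 9 * F, C, (9 * F, C)),
            "dec3_b": np.zeros(C, dtype=np.float32),
        }

    def forward(self, x, want_cache=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.params
        a1, cols1 = conv3_forward(x, p["conv1_W"], p["conv1_b"])
        m1, q1 = pool2_forward(a1)
        r1 = relu_forward(m1)
        a2, cols2 = conv3_forward(r1, p["conv2_W"], p["conv2_b"])
        m2, q2 = pool2_forward(a2)
        r2 = relu_forward(m2)
        u1 = upsample2_forward(r2)
        d1, dcols1 = conv3_forward(u1, p["dec1_W"], p["dec1_b"])
        rd1 = relu_forward(d1)
        u2 = upsample2_forward(rd1)
        d2, dcols2 = conv3_forward(u2, p["dec2_W"], p["dec2_b"])
        rd2 = relu_forward(d2)
        recon, dcols3 = conv3_forward(rd2, p["dec3_W"], p["dec3_b"])
        if not want_cache:
            return recon
        cache = dict(x=x, cols1=cols1, a1_shape=a1.shape, q1=q1, m1=m1,
                     r1=r1, cols2=cols2, a2_shape=a2.shape, q2=q2, m2=m2,
                     u1=u1, dcols1=dcols1, rd1=rd1, u2=u2, dcols2=dcols2,
                     rd2=rd2, dcols3=dcols3, recon=recon)
        return recon, cache

    def loss_and_grads(self, x):
        recon, c = self.forward(x, want_cache=True)
        diff = recon - c["x"]
        loss = float(np.mean(diff ** 2))
        dre = ((2.0 / diff.size) * diff).astype(np.float32)
        p, g = self.params, {}
        drd2, g["dec3_W"], g["dec3_b"] = conv3_backward(
            dre, c["dcols3"], p["dec3_W"], c["rd2"].shape)
        dd2 = relu_backward(drd2, c["rd2"])
        du2, g["dec2_W"], g["dec2_b"] = conv3_backward(
            dd2, c["dcols2"], p["dec2_W"], c["u2"].shape)
        drd1 = upsample2_backward(du2)
        dd1 = relu_backward(drd1, c["rd1"])
        du1, g["dec1_W"], g["dec1_b"] = conv3_backward(
            dd1, c["dcols1"], p["dec1_W"], c["u1"].shape)
        dm2 = relu_backward(upsample2_backward(du1), c["m2"])
        da2 = pool2_backward(dm2, c["a2_shape"], c["q2"])
        dr1, g["conv2_W"], g["conv2_b"] = conv3_backward(
            da2, c["cols2"], p["conv2_W"], c["r1"].shape)
        dm1 = relu_backward(dr1, c["r1"])
        da1 = pool2_backward(dm1, c["a1_shape"], c["q1"])
        _, g["conv1_W"], g["conv1_b"] = conv3_backward(
            da1, c["cols1"], p["conv1_W"], c["x"].shape, need_dx=False)
        return loss, g

    def reconstruction_loss(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        recon = self.forward(x)
        return float(np.mean((recon - x) ** 2))

    def trunk(self):
        return {k: self.params[k].copy()
                for k in ("conv1_W", "conv1_b", "conv2_W", "conv2_b")}


def pretrain_cae(stacks, spec: RiskNetSpec, epochs=100, learning_rate=1e-3,
                 batch_size=32, seed=0):
    """Train a CAE on unlabeled stacks; returns (trunk weights, history).

    The unlabeled set should be disjoint from the survival cohort; the
    returned trunk initializes :meth:`RiskNet.load_trunk`.
    """
    stacks = np.ascontiguousarray(stacks, dtype=np.float32)
    cae = ConvAutoEncoder(spec, seed=seed)
    rng = np.random.default_rng(seed)
    n = len(stacks)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = cae.loss_and_grads(stacks[idx])
            for k, gk in grads.items():
                cae.params[k] -= np.float32(learning_rate) * gk
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return cae.trunk(), history
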