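"""Pair scoring: direct descriptor distance and the trainable same-fold network.

Two ways to decide whether two structures share a fold:

* ``zdzd_score`` — the classic score 1 / (1 + ||a - b||) on raw descriptors,
  thresholded at 0.1;
* ``nn_score`` — a siamese network that encodes each 121-component
  descriptor through shared hidden layers of 250, 200 and 150 rectified
  units, assembles a 1,452-feature comparison vector (both raw descriptors,
  both concatenated encodings, four comparison metrics — Euclidean
  distance, cosine distance, Manhattan distance, dot product — applied to
  the raw and to the encoded representation, and the vertex/face count
  differences of the two surface meshes), and maps it through a hidden
  comparator layer to a sigmoid same-fold probability. Default decision
  thresholds: 0.5 for full-atom descriptors, 0.6 for main-chain.

The network is plain numpy with hand-derived gradients and Adam, trained
on balanced batches (32 positive + 32 negative) with binary cross-entropy;
training is bit-deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .zernike import ZernikeDescriptor

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "PairScore",
    "TrainingLog",
    "zdzd_score",
    "encode",
    "pair_metrics",
    "build_pair_features",
    "pair_feature_length",
    "nn_score",
    "train_network",
    "score_pairs",
]

ZDZD_THRESHOLD = 0.1
NN_THRESHOLDS = {"full_atom": 0.5, "main_chain": 0.6}


@dataclass
class NetworkConfig:
    """Hyperparameters of the same-fold network."""

    descriptor_length: int = 121
    encoder_widths: tuple[int, int, int] = (250, 200, 150)
    comparator_width: int = 128
    learning_rate: float = 0.005
    batch_size: int = 64  # sampled as batch_size/2 positive + batch_size/2 negative
    epochs: int = 40
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (balanced batches)")


@dataclass
class PairScore:
    """A similarity in [0, 1] plus the threshold that binarizes it."""

    value: float
    method: Literal["zdzd", "nn"]
    threshold: float
    asymmetry: float = 0.0  # |score(a,b) - score(b,a)| for the nn method

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"score {self.value} outside [0, 1]")

    @property
    def same_fold(self) -> bool:
        return self.value >= self.threshold


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def zdzd_score(a: ZernikeDescriptor, b: ZernikeDescriptor) -> PairScore:
    """Direct descriptor similarity 1 / (1 + Euclidean distance)."""
    if a.order != b.order:
        raise ValueError(f"descriptor order mismatch: {a.order} vs {b.order}")
    dist = float(np.linalg.norm(a.values - b.values))
    return PairScore(value=1.0 / (1.0 + dist), method="zdzd", threshold=ZDZD_THRESHOLD)


def pair_feature_length(descriptor_length: int, widths: Sequence[int]) -> int:
    """Closed formula: 2*D + 2*sum(widths) + 2*4 + 2 (= 1452 by default)."""
    return 2 * descriptor_length + 2 * sum(widths) + 2 * 4 + 2


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class NetworkParams:
    """Weight arrays plus the feature standardization fitted at training."""

    ENCODER_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3")
    COMPARATOR_KEYS = ("Wc1", "bc1", "Wc2", "bc2")

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        self.config = config
        d = config.descriptor_length
        h1, h2, h3 = config.encoder_widths
        hc = config.comparator_width
        nfeat = pair_feature_length(d, config.encoder_widths)
        if rng is None:
            rng = np.random.default_rng(config.seed)

        def he(n_in: int, n_out: int) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))

        self.weights: dict[str, np.ndarray] = {
            "W1": he(d, h1), "b1": np.zeros(h1),
            "W2": he(h1, h2), "b2": np.zeros(h2),
            "W3": he(h2, h3), "b3": np.zeros(h3),
            "Wc1": he(nfeat, hc), "bc1": np.zeros(hc),
            # near-zero head: the first predictions sit at p ~ 0.5, which
            # keeps early Adam steps at lr 0.005 from overshooting
            "Wc2": 0.01 * he(hc, 1), "bc2": np.zeros(1),
        }
        self.feat_mean = np.zeros(nfeat)
        self.feat_std = np.ones(nfeat)
        self.trained = False

    def copy(self) -> "NetworkParams":
        out = NetworkParams.__new__(NetworkParams)
        out.config = self.config
        out.weights = {k: v.copy() for k, v in self.weights.items()}
        out.feat_mean = self.feat_mean.copy()
        out.feat_std = self.feat_std.copy()
        out.trained = self.trained
        return out

    def save(self, path: str | Path) -> None:
        cfg = {
            "descriptor_length": self.config.descriptor_length,
            "encoder_widths": list(self.config.encoder_widths),
            "comparator_width": self.config.comparator_width,
            "learning_rate": self.config.learning_rate,
            "batch_size": self.config.batch_size,
            "epochs": self.config.epochs,
            "validation_fraction": self.config.validation_fraction,
            "seed": self.config.seed,
            "trained": self.trained,
        }
        np.savez(
            path,
            config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            **self.weights,
        )

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config"]).decode())
            trained = cfg.pop("trained")
            cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
            config = NetworkConfig(**cfg)
            out = cls(config)
            for k in list(out.weights):
                out.weights[k] = data[k]
            out.feat_mean = data["feat_mean"]
            out.feat_std = data["feat_std"]
            out.trained = trained
        return out


def encode(d: ZernikeDescriptor | np.ndarray, params: NetworkParams) -> list[np.ndarray]:
    """Activations of the three shared encoder layers for one descriptor."""
    x = d.values if isinstance(d, ZernikeDescriptor) else np.asarray(d, dtype=float)
    if x.shape[-1] != params.config.descriptor_length:
        raise ValueError(
            f"descriptor length {x.shape[-1]} does not match network input "
            f"{params.config.descriptor_length}"
        )
    w = params.weights
    h1 = _relu(x @ w["W1"] + w["b1"])
    h2 = _relu(h1 @ w["W2"] + w["b2"])
    h3 = _relu(h2 @ w["W3"] + w["b3"])
    return [h1, h2, h3]


def pair_metrics(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """The four comparison metrics, batched: rows of (u, v) -> (B, 4).

    Euclidean distance, cosine distance (1 - cosine similarity), Manhattan
    distance (element-wise absolute difference, summed) and dot product
    (element-wise product, summed).
    """
    u = np.atleast_2d(u)
    v = np.atleast_2d(v)
    diff = u - v
    euclid = np.linalg.norm(diff, axis=1)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = np.where((nu > 0) & (nv > 0), nu * nv, 1.0)
    cos_sim = np.where((nu > 0) & (nv > 0), np.sum(u * v, axis=1) / denom, 0.0)
    manhattan = np.sum(np.abs(diff), axis=1)
    dot = np.sum(u * v, axis=1)
    return np.stack([euclid, 1.0 - cos_sim, manhattan, dot], axis=1)


def build_pair_features(
    a: ZernikeDescriptor,
    b: ZernikeDescriptor,
    enc_a: Sequence[np.ndarray],
    enc_b: Sequence[np.ndarray],
) -> np.ndarray:
    """Assemble the comparator input for one pair (length 1452 by default)."""
    ea = np.concatenate(list(enc_a))
    eb = np.concatenate(list(enc_b))
    if ea.shape != eb.shape:
        raise ValueError("encoder outputs of the two branches differ in shape")
    return np.concatenate(
        [
            a.values,
            b.values,
            ea,
            eb,
            pair_metrics(a.values, b.values)[0],
            pair_metrics(ea, eb)[0],
            [float(a.mesh_vertices - b.mesh_vertices)],
            [float(a.mesh_faces - b.mesh_faces)],
        ]
    )


def _batch_features(
    xa: np.ndarray, xb: np.ndarray, meta: np.ndarray, params: NetworkParams
) -> tuple[np.ndarray, dict]:
    """Features for a batch; caches intermediates for backprop.

    ``meta`` holds (dv, df) per pair: mesh vertex/face count differences.
    """
    w = params.weights
    cache: dict = {}
    acts = {}
    for tag, x in (("a", xa), ("b", xb)):
        h1 = _relu(x @ w["W1"] + w["b1"])
        h2 = _relu(h1 @ w["W2"] + w["b2"])
        h3 = _relu(h2 @ w["W3"] + w["b3"])
        acts[tag] = (h1, h2, h3)
    ea = np.concatenate(acts["a"], axis=1)
    eb = np.concatenate(acts["b"], axis=1)
    feats = np.concatenate(
        [xa, xb, ea, eb, pair_metrics(xa, xb), pair_metrics(ea, eb), meta],
        axis=1,
    )
    cache.update(xa=xa, xb=xb, acts=acts, ea=ea, eb=eb)
    return feats, cache


def _forward_scores(
    xa: np.ndarray, xb: np.ndarray, meta: np.ndarray, params: NetworkParams
) -> tuple[np.ndarray, dict]:
    feats, cache = _batch_features(xa, xb, meta, params)
    phis = (feats - params.feat_mean) / params.feat_std
    w = params.weights
    u = _relu(phis @ w["Wc1"] + w["bc1"])
    z = (u @ w["Wc2"]).ravel() + w["bc2"][0]
    p = expit(z)
    cache.update(phis=phis, u=u, p=p)
    return p, cache


def _metric_grads(
    u: np.ndarray, v: np.ndarray, gm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of the 4 metrics w.r.t. both inputs, weighted by gm (B, 4)."""
    diff = u - v
    d = np.linalg.norm(diff, axis=1, keepdims=True)
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    safe_d = np.where(d > 0, d, 1.0)
    unit = np.where(d > 0, diff / safe_d, 0.0)
    ok = ((nu > 0) & (nv > 0)).astype(float)
    snu = np.where(nu > 0, nu, 1.0)
    snv = np.where(nv > 0, nv, 1.0)
    dots = np.sum(u * v, axis=1, keepdims=True)
    # d(cos_dist)/du = -(v/(|u||v|) - (u.v) u/(|u|^3 |v|))
    dcos_du = -ok * (v / (snu * snv) - dots * u / (snu**3 * snv))
    dcos_dv = -ok * (u / (snu * snv) - dots * v / (snv**3 * snu))
    sgn = np.sign(diff)
    gu = (
        gm[:, 0:1] * unit
        + gm[:, 1:2] * dcos_du
        + gm[:, 2:3] * sgn
        + gm[:, 3:4] * v
    )
    gv = (
        gm[:, 0:1] * (-unit)
        + gm[:, 1:2] * dcos_dv
        + gm[:, 2:3] * (-sgn)
        + gm[:, 3:4] * u
    )
    return gu, gv


def _backward(
    y: np.ndarray, cache: dict, params: NetworkParams
) -> dict[str, np.ndarray]:
    """Hand-derived gradients of mean BCE w.r.t. every weight array."""
    w = params.weights
    cfg = params.config
    d = cfg.descriptor_length
    h_sum = sum(cfg.encoder_widths)
    batch = len(y)
    p, u, phis = cache["p"], cache["u"], cache["phis"]
    xa, xb, ea, eb = cache["xa"], cache["xb"], cache["ea"], cache["eb"]

    dz = (p - y) / batch
    g = {k: np.zeros_like(v) for k, v in w.items()}
    g["Wc2"] = u.T @ dz[:, None]
    g["bc2"] = np.array([dz.sum()])
    du = np.outer(dz, w["Wc2"].ravel())
    dzc1 = du * (u > 0)
    g["Wc1"] = phis.T @ dzc1
    g["bc1"] = dzc1.sum(axis=0)
    dphi = (dzc1 @ w["Wc1"].T) / params.feat_std

    # feature layout: [xa(d), xb(d), ea(h), eb(h), m_raw(4), m_enc(4), dv, df]
    o = 2 * d
    dea = dphi[:, o : o + h_sum].copy()
    deb = dphi[:, o + h_sum : o + 2 * h_sum].copy()
    gm_enc = dphi[:, o + 2 * h_sum + 4 : o + 2 * h_sum + 8]
    gea_m, geb_m = _metric_grads(ea, eb, gm_enc)
    dea += gea_m
    deb += geb_m

    h1w, h2w, _ = cfg.encoder_widths
    for tag, x, de in (("a", xa, dea), ("b", xb, deb)):
        h1, h2, h3 = cache["acts"][tag]
        dh3 = de[:, h1w + h2w :]
        dz3 = dh3 * (h3 > 0)
        g["W3"] += h2.T @ dz3
        g["b3"] += dz3.sum(axis=0)
        dh2 = dz3 @ w["W3"].T + de[:, h1w : h1w + h2w]
        dz2 = dh2 * (h2 > 0)
        g["W2"] += h1.T @ dz2
        g["b2"] += dz2.sum(axis=0)
        dh1 = dz2 @ w["W2"].T + de[:, :h1w]
        dz1 = dh1 * (h1 > 0)
        g["W1"] += x.T @ dz1
        g["b1"] += dz1.sum(axis=0)
    return g


def _descriptor_matrix(
    pairs: Sequence[tuple[ZernikeDescriptor, ZernikeDescriptor, int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    xa = np.array([p[0].values for p in pairs])
    xb = np.array([p[1].values for p in pairs])
    meta = np.array(
        [
            [p[0].mesh_vertices - p[1].mesh_vertices, p[0].mesh_faces - p[1].mesh_faces]
            for p in pairs
        ],
        dtype=float,
    )
    y = np.array([p[2] for p in pairs], dtype=float)
    return xa, xb, meta, y


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train_network(
    pairs: Sequence[tuple[ZernikeDescriptor, ZernikeDescriptor, int]],
    config: NetworkConfig | None = None,
) -> tuple[NetworkParams, TrainingLog]:
    """Train the same-fold network on labeled descriptor pairs.

    Each step draws a balanced batch (half positive, half negative, with
    replacement) from the training split; the checkpoint with the best
    validation loss is returned. Deterministic given ``config.seed``.
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(config.seed)
    labels = np.array([p[2] for p in pairs])
    if labels.min() == labels.max():
        raise ValueError("training needs both positive and negative pairs")

    idx = rng.permutation(len(pairs))
    n_val = int(round(config.validation_fraction * len(pairs)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    # ensure both classes in the training split
    if labels[train_idx].min() == labels[train_idx].max():
        train_idx = idx
        val_idx = idx
    pos_pool = train_idx[labels[train_idx] == 1]
    neg_pool = train_idx[labels[train_idx] == 0]
    if len(pos_pool) == 0 or len(neg_pool) == 0:
        raise ValueError("training split lost one of the classes")

    xa, xb, meta, y = _descriptor_matrix(pairs)
    params = NetworkParams(config, rng)
    feats, _ = _batch_features(xa[train_idx], xb[train_idx], meta[train_idx], params)
    params.feat_mean = feats.mean(axis=0)
    params.feat_std = np.maximum(feats.std(axis=0), 1e-8)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.weights.items()}
    v = {k: np.zeros_like(w) for k, w in params.weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    half = config.batch_size // 2
    steps = max(1, len(train_idx) // config.batch_size)
    log = TrainingLog()
    best = params.copy()
    best_val = np.inf

    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            pick = np.concatenate(
                [rng.choice(pos_pool, half), rng.choice(neg_pool, half)]
            )
            p, cache = _forward_scores(xa[pick], xb[pick], meta[pick], params)
            epoch_loss += _bce(p, y[pick])
            grads = _backward(y[pick], cache, params)
            t += 1
            for k in params.weights:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                params.weights[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        log.train_loss.append(epoch_loss / steps)
        pv, _ = _forward_scores(xa[val_idx], xb[val_idx], meta[val_idx], params)
        vloss = _bce(pv, y[val_idx])
        log.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            best = params.copy()
            log.best_epoch = epoch
    best.trained = True
    return best, log


def nn_score(
    a: ZernikeDescriptor,
    b: ZernikeDescriptor,
    params: NetworkParams,
    threshold: float | None = None,
) -> PairScore:
    """Same-fold probability for a pair, symmetrized over argument order.

    The raw network is not exactly symmetric in (a, b); the reported score
    is the mean of both orderings and the residual |difference| is kept as
    ``asymmetry``. The default threshold follows the descriptors' surface
    mode: 0.6 when both are main-chain, else 0.5.
    """
    if params is None or not params.trained:
        raise ValueError("nn_score requires trained network parameters")
    if threshold is None:
        mode = "main_chain" if a.source_mode == b.source_mode == "main_chain" else "full_atom"
        threshold = NN_THRESHOLDS[mode]
    pairs = [(a, b, 0), (b, a, 0)]
    xa, xb, meta, _ = _descriptor_matrix(pairs)
    p, _ = _forward_scores(xa, xb, meta, params)
    return PairScore(
        value=float(np.clip(p.mean(), 0.0, 1.0)),
        method="nn",
        threshold=threshold,
        asymmetry=float(abs(p[0] - p[1])),
    )


def score_pairs(
    pairs: Sequence[tuple[ZernikeDescriptor, ZernikeDescriptor, int]],
    params: NetworkParams,
) -> np.ndarray:
    """Vectorized symmetrized network scores for many pairs."""
    if params is None or not params.trained:
        raise ValueError("score_pairs requires trained network parameters")
    xa, xb, meta, _ = _descriptor_matrix(pairs)
    p_fwd, _ = _forward_scores(xa, xb, meta, params)
    p_rev, _ = _forward_scores(xb, xa, -meta, params)
    return (p_fwd + p_rev) / 2.0
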