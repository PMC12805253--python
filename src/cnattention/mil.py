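"""Attention-based multiple-instance model over copy-number profiles.

A bag is a set of K patient profiles sharing one cancer-type label. The
model composes three learned maps:

* an instance embedder f_psi: one hidden affine layer with ReLU, then an
  affine map to the embedding width M, applied independently per instance;
* gated attention pooling: per-instance scores
  ``e_k = w^T [ tanh(V h_k) * sigmoid(U h_k) ]`` softmax-normalized into
  weights ``a_k`` that form the bag embedding ``z = sum_k a_k h_k`` — a
  permutation-invariant, convex combination of instance embeddings;
* a bag classifier g_phi: affine map of z to C logits with a softmax head.

Training minimizes the multinomial negative log-likelihood of the bag label,
``-log p[label]``. The network is small and fixed, so the forward pass and
analytic backpropagation are implemented directly on numpy arrays; gradient
correctness is pinned to finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .utils import logger

EPS_LOG = 1e-12

CHECKPOINT_VERSION = 1
PARAM_NAMES = ("W1", "b1", "W2", "b2", "V", "U", "w", "Wc", "bc")


@dataclass
class Bag:
    """K instance profiles sharing one (optional) class label."""

    instances: np.ndarray  # (K, D) float
    sample_ids: list[str]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if self.instances.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match instance count")
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")

    @property
    def K(self) -> int:
        return self.instances.shape[0]


@dataclass
class MILModelParams:
    """All trainable arrays plus dimensions (input D, embedding M, attention L,
    classes C). The hidden layer of the embedder has width M as well."""

    W1: np.ndarray  # (M, D)
    b1: np.ndarray  # (M,)
    W2: np.ndarray  # (M, M)
    b2: np.ndarray  # (M,)
    V: np.ndarray   # (L, M) tanh branch
    U: np.ndarray   # (L, M) sigmoid gate
    w: np.ndarray   # (L,)
    Wc: np.ndarray  # (C, M)
    bc: np.ndarray  # (C,)
    gene_ids: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    @property
    def dims(self) -> tuple[int, int, int, int]:
        M, D = self.W1.shape
        L = self.V.shape[0]
        C = self.Wc.shape[0]
        return D, M, L, C

    @classmethod
    def initialize(cls, D: int, M: int, L: int, C: int, seed: int = 0,
                   gene_ids: Optional[Sequence[str]] = None,
                   class_names: Optional[Sequence[str]] = None) -> "MILModelParams":
        """He-scaled random embedder/attention weights; the classifier starts at
        zero so a fresh model predicts the uniform distribution exactly."""
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return cls(
            W1=he((M, D), D), b1=np.zeros(M),
            W2=he((M, M), M), b2=np.zeros(M),
            V=he((L, M), M), U=he((L, M), M),
            w=he((L,), L),
            Wc=np.zeros((C, M)), bc=np.zeros(C),
            gene_ids=list(gene_ids or []), class_names=list(class_names or []),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def copy(self) -> "MILModelParams":
        return MILModelParams(**{k: v.copy() for k, v in self.arrays().items()},
                              gene_ids=list(self.gene_ids),
                              class_names=list(self.class_names))

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: JSON with parameter arrays as nested lists."""
        payload = {
            "format": "cnattention-checkpoint",
            "version": CHECKPOINT_VERSION,
            "dims": dict(zip(("D", "M", "L", "C"), self.dims)),
            "gene_ids": self.gene_ids,
            "class_names": self.class_names,
            "params": {k: v.tolist() for k, v in self.arrays().items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MILModelParams":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "cnattention-checkpoint":
            raise ValueError(f"{path}: not a model checkpoint")
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
        arrays = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(**arrays, gene_ids=payload["gene_ids"], class_names=payload["class_names"])


@dataclass
class BagOutput:
    bag_probs: np.ndarray   # (C,) on the simplex
    attention: np.ndarray   # (K,) positive, sums to 1
    embeddings: np.ndarray  # (K, M)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - np.max(x)
    e = np.exp(z)
    return e / e.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def embed_instances(params: MILModelParams, X: np.ndarray) -> np.ndarray:
    """Map each instance profile independently to its M-dim embedding."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = params.dims[0]
    if X.shape[1] != D:
        raise ValueError(f"instance width {X.shape[1]} != model input dim {D}")
    A1 = X @ params.W1.T + params.b1
    R = np.maximum(A1, 0.0)
    return R @ params.W2.T + params.b2


def gated_attention(params: MILModelParams, embeddings: np.ndarray) -> np.ndarray:
    """Softmax attention weights from the tanh x sigmoid gating of embeddings."""
    H = np.atleast_2d(embeddings)
    T = np.tanh(H @ params.V.T)
    S = _sigmoid(H @ params.U.T)
    scores = (T * S) @ params.w
    return _softmax(scores)


def pool_bag(embeddings: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Convex combination of embedding rows under the attention weights."""
    a = np.asarray(attention, dtype=float)
    if not np.isclose(a.sum(), 1.0, atol=1e-6):
        raise ValueError(f"attention must sum to 1, got {a.sum()}")
    return a @ np.atleast_2d(embeddings)


def classify_bag(params: MILModelParams, bag: Bag) -> BagOutput:
    """Full forward pass: embed, attend, pool, classify."""
    H = embed_instances(params, bag.instances)
    a = gated_attention(params, H)
    z = pool_bag(H, a)
    probs = _softmax(params.Wc @ z + params.bc)
    return BagOutput(bag_probs=probs, attention=a, embeddings=H)


def bag_nll(bag_probs: np.ndarray, label: int) -> float:
    """Multinomial negative log-likelihood of the bag label."""
    p = float(bag_probs[label])
    if p <= 0.0:
        logger.warning("bag probability at label is 0; clamping log at %g", EPS_LOG)
        p = EPS_LOG
    return -float(np.log(p))


def forward_backward(params: MILModelParams, X: np.ndarray,
                     label: int) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients of the bag NLL for one bag.

    Mirrors :func:`classify_bag` exactly; the backward pass is the manual
    reverse-mode differentiation of that computation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    # forward (caching intermediates)
    A1 = X @ params.W1.T + params.b1          # (K, M)
    R = np.maximum(A1, 0.0)
    H = R @ params.W2.T + params.b2           # (K, M)
    PT = H @ params.V.T                       # (K, L)
    PS = H @ params.U.T
    T = np.tanh(PT)
    S = _sigmoid(PS)
    e = (T * S) @ params.w                    # (K,)
    a = _softmax(e)
    z = a @ H                                 # (M,)
    logits = params.Wc @ z + params.bc
    p = _softmax(logits)
    loss = bag_nll(p, label)

    # backward
    dlogits = p.copy()
    dlogits[label] -= 1.0
    dWc = np.outer(dlogits, z)
    dbc = dlogits
    dz = params.Wc.T @ dlogits                # (M,)
    da = H @ dz                               # (K,)
    dH = np.outer(a, dz)                      # from z = a @ H
    de = a * (da - float(a @ da))             # softmax Jacobian-vector product
    dG = np.outer(de, params.w)               # (K, L), G = T*S
    dw = (T * S).T @ de
    dPT = dG * S * (1.0 - T**2)
    dPS = dG * T * S * (1.0 - S)
    dV = dPT.T @ H
    dU = dPS.T @ H
    dH += dPT @ params.V + dPS @ params.U
    dW2 = dH.T @ R
    db2 = dH.sum(axis=0)
    dR = dH @ params.W2
    dA1 = dR * (A1 > 0)
    dW1 = dA1.T @ X
    db1 = dA1.sum(axis=0)

    grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2,
             "V": dV, "U": dU, "w": dw, "Wc": dWc, "bc": dbc}
    return loss, grads
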