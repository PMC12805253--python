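"""Instance-level prediction and per-cancer-type CNA signature generation.

After training, every instance i of a bag has an attention weight w_i and an
instance-level class-probability vector p_i (obtained by classifying the
singleton bag {x_i} with the full model). The normalized weighted score is

    p_hat[i, k] = (w_i / sum_j w_j) * p_i[k]

so the p_hat entries of a bag sum to one over instances and classes, and the
predicted class of an instance is c_hat[i] = argmax_k p_hat[i, k] (identical
to argmax_k p_i[k], since the attention factor is a positive scalar).

Signatures project those attention-weighted predictions onto gene features:
for class k, the score of gene g is the mean over instances predicted as k of
p_hat[i, k] * x[i, g], where x is the instance's discrete copy-number call —
linear in the instance predictions and sign-preserving, so positive scores
mark duplication-associated genes and negative scores deletion-associated
ones. A gradient-times-input attribution is available behind the same
contract as an alternative projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CNAMatrix, LabeledCohort
from .mil import Bag, MILModelParams, classify_bag, forward_backward
from .utils import logger

Normalization = Literal["per_class_max", "l1"]
ProjectionMethod = Literal["weighted_value", "grad_x_input"]


@dataclass
class InstancePrediction:
    sample_id: str
    bag_index: int
    attention: float            # w_i within its bag
    probs: np.ndarray           # p_i, singleton-bag class probabilities
    weighted_scores: np.ndarray  # p_hat[i, :]
    predicted_class: int        # c_hat[i]


@dataclass
class SignatureSet:
    """Per-class signed gene importance scores and the top-N gene lists."""

    scores: pd.DataFrame        # genes x classes, signed
    top_genes: dict[str, list[tuple[str, float, str]]]  # class -> (gene, score, direction)
    n_per_class: int

    @property
    def gene_union(self) -> set[str]:
        return {g for rows in self.top_genes.values() for g, _, _ in rows}

    def genes_of(self, class_name: str) -> set[str]:
        return {g for g, _, _ in self.top_genes[class_name]}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.scores.columns:
            for rank, (gene, score, direction) in enumerate(self.top_genes[cls], start=1):
                rows.append({"class": cls, "gene": gene, "score": score,
                             "direction": direction, "rank": rank})
        return pd.DataFrame(rows, columns=["class", "gene", "score", "direction", "rank"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "class": str})
    required = {"class", "gene", "score", "direction", "rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature table needs columns {sorted(required)}")
    return df


def instance_predictions(params: MILModelParams, bags: Sequence[Bag]
                         ) -> list[InstancePrediction]:
    """Attention weights, singleton-bag probabilities, and normalized scores."""
    preds: list[InstancePrediction] = []
    for b_idx, bag in enumerate(bags):
        out = classify_bag(params, bag)
        w = out.attention
        w_norm = w / w.sum()
        for i, sid in enumerate(bag.sample_ids):
            p_i = classify_bag(params, Bag(bag.instances[i:i + 1], [sid])).bag_probs
            p_hat = w_norm[i] * p_i
            preds.append(InstancePrediction(
                sample_id=sid, bag_index=b_idx, attention=float(w[i]), probs=p_i,
                weighted_scores=p_hat, predicted_class=int(np.argmax(p_hat))))
    return preds


def instance_accuracy(predictions: Sequence[InstancePrediction],
                      labels: Mapping[str, int]) -> float:
    """Fraction of instances whose predicted class matches the true class."""
    if not predictions:
        raise ValueError("no predictions given")
    hits = sum(int(p.predicted_class == labels[p.sample_id]) for p in predictions)
    return hits / len(predictions)


def project_to_features(predictions: Sequence[InstancePrediction],
                        matrix: CNAMatrix, class_index: int,
                        normalization: Normalization = "per_class_max",
                        method: ProjectionMethod = "weighted_value",
                        params: Optional[MILModelParams] = None) -> np.ndarray:
    """Signed per-gene score vector s[:, k] for one class.

    ``weighted_value``: mean over instances predicted as k of
    p_hat[i, k] * x[i, g]. ``grad_x_input``: mean of the input gradient of
    the class-k singleton log-probability times the input, weighted by
    p_hat[i, k] (requires ``params``).
    """
    row_of = {s: i for i, s in enumerate(matrix.sample_ids)}
    assigned = [p for p in predictions if p.predicted_class == class_index]
    if not assigned:
        logger.warning("no instance predicted class %d; zero signature", class_index)
        return np.zeros(matrix.n_genes)
    X = matrix.values.astype(float)
    s = np.zeros(matrix.n_genes)
    for p in assigned:
        x = X[row_of[p.sample_id]]
        weight = float(p.weighted_scores[class_index])
        if method == "weighted_value":
            s += weight * x
        elif method == "grad_x_input":
            if params is None:
                raise ValueError("grad_x_input projection needs model params")
            s += weight * _input_gradient(params, x, class_index) * x
        else:
            raise ValueError(f"unknown projection method {method!r}")
    s /= len(assigned)
    return _normalize_scores(s, normalization)


def _input_gradient(params: MILModelParams, x: np.ndarray, class_index: int) -> np.ndarray:
    """d log p[class] / d x for a singleton bag, via backprop through f_psi.

    Attention contributes no input gradient for K=1 (the softmax over one
    element is constant), so only the embedder and classifier paths remain.
    """
    x = np.asarray(x, dtype=float)
    A1 = x @ params.W1.T + params.b1
    R = np.maximum(A1, 0.0)
    # d log p[c] / d logits = onehot(c) - p
    H = R @ params.W2.T + params.b2
    from .mil import _softmax  # reuse the numerically-stable softmax
    p = _softmax(params.Wc @ H + params.bc)
    dlogits = -p
    dlogits[class_index] += 1.0
    dH = params.Wc.T @ dlogits
    dR = dH @ params.W2
    dA1 = dR * (A1 > 0)
    return dA1 @ params.W1


def _normalize_scores(s: np.ndarray, normalization: Normalization) -> np.ndarray:
    if normalization == "per_class_max":
        m = np.abs(s).max()
        return s / m if m > 0 else s
    if normalization == "l1":
        t = np.abs(s).sum()
        return s / t if t > 0 else s
    raise ValueError(f"unknown normalization {normalization!r}")


def extract_signature(scores: pd.DataFrame, n_per_class: int) -> SignatureSet:
    """Top-N genes per class by absolute score, ties broken by gene id.

    ``scores`` is a genes x classes frame of signed values. Direction is
    ``dup`` for nonnegative scores and ``del`` for negative ones.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    n = n_per_class
    if n > scores.shape[0]:
        logger.warning("n_per_class=%d exceeds gene count %d; keeping all genes",
                       n, scores.shape[0])
        n = scores.shape[0]
    top: dict[str, list[tuple[str, float, str]]] = {}
    for cls in scores.columns:
        col = scores[cls]
        order = sorted(col.index, key=lambda g: (-abs(col[g]), g))
        top[cls] = [(g, float(col[g]), "dup" if col[g] >= 0 else "del")
                    for g in order[:n]]
    return SignatureSet(scores=scores.copy(), top_genes=top, n_per_class=n)


def compute_signatures(params: MILModelParams, cohort: LabeledCohort,
                       bags: Sequence[Bag], n_per_class: int = 50,
                       normalization: Normalization = "per_class_max",
                       method: ProjectionMethod = "weighted_value") -> SignatureSet:
    """End-to-end signature generation from a trained model and a bagged cohort."""
    preds = instance_predictions(params, bags)
    matrix = cohort.matrix
    if params.gene_ids and list(matrix.gene_ids) != list(params.gene_ids):
        matrix = matrix.subset_genes(params.gene_ids)
    cols = {}
    for k, cls in enumerate(cohort.class_names):
        cols[cls] = project_to_features(preds, matrix, k, normalization,
                                        method=method, params=params)
    scores = pd.DataFrame(cols, index=matrix.gene_ids)
    return extract_signature(scores, n_per_class)
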