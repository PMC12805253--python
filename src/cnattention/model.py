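"""Statsmodels-style front end: a model object built from a labeled cohort
whose ``fit`` returns a results object carrying the trained parameters,
training log, evaluation, signature generation and a text summary.

    >>> cohort, truth = simulate_cohort(SimulationConfig(seed=0))
    >>> model = CNAttention(cohort, embed_dim=32, attention_dim=16)
    >>> res = model.fit(TrainConfig(epochs=30, seed=0))
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .feature_selection import RFECVConfig, RFECVResult, rfecv_select
from .io import LabeledCohort
from .mil import MILModelParams
from .signatures import SignatureSet, compute_signatures, instance_predictions
from .training import EvalReport, TrainConfig, evaluate, make_bags, train
from .utils import derive_seed


class CNAttention:
    """Attention-based multiple-instance classifier of cancer types from
    gene-level copy-number profiles.

    Parameters
    ----------
    cohort : LabeledCohort
        Training samples with one cancer-type label each.
    selected_genes : list of str, optional
        Restrict the model to these genes (e.g. the output of
        :meth:`select_features`). Default: all genes of the cohort.
    embed_dim, attention_dim : int
        Width M of the instance embedding and width L of the gated
        attention's hidden space.
    """

    def __init__(self, cohort: LabeledCohort,
                 selected_genes: Optional[Sequence[str]] = None,
                 embed_dim: int = 128, attention_dim: int = 64):
        self.cohort = cohort
        self.selected_genes = list(selected_genes) if selected_genes is not None else None
        self.embed_dim = embed_dim
        self.attention_dim = attention_dim

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, labels: dict[str, str],
                       **kwargs) -> "CNAttention":
        """Build from a samples x genes DataFrame of discrete calls."""
        from .io import CNAMatrix
        cohort = LabeledCohort(CNAMatrix.from_frame(values), labels)
        return cls(cohort, **kwargs)

    def select_features(self, config: Optional[RFECVConfig] = None) -> RFECVResult:
        """Cross-validated recursive feature elimination on the cohort;
        stores the selection on the model and returns the full result."""
        result = rfecv_select(self.cohort, config or RFECVConfig())
        self.selected_genes = result.selected_genes
        return result

    def fit(self, config: Optional[TrainConfig] = None,
            val_cohort: Optional[LabeledCohort] = None) -> "CNAttentionResults":
        config = config or TrainConfig()
        params, log = train(self.cohort, self.selected_genes,
                            embed_dim=self.embed_dim,
                            attention_dim=self.attention_dim,
                            config=config, val_cohort=val_cohort)
        return CNAttentionResults(self, params, log, config)


@dataclass
class CNAttentionResults:
    """Fit results: trained parameters, training log, and derived analyses."""

    model: CNAttention
    params: MILModelParams
    log: dict
    config: TrainConfig
    _eval_cache: dict = field(default_factory=dict, repr=False)

    def _restrict(self, cohort: LabeledCohort) -> LabeledCohort:
        genes = self.params.gene_ids
        if genes and list(cohort.matrix.gene_ids) != list(genes):
            return LabeledCohort(cohort.matrix.subset_genes(genes),
                                 cohort.labels, cohort.class_names)
        return cohort

    def evaluate(self, cohort: Optional[LabeledCohort] = None,
                 bag_size: Optional[int] = None, seed: int = 0) -> EvalReport:
        cohort = self._restrict(cohort or self.model.cohort)
        return evaluate(self.params, cohort, bag_size or self.config.bag_size, seed)

    def signatures(self, cohort: Optional[LabeledCohort] = None,
                   n_per_class: int = 50, seed: int = 0,
                   normalization: str = "per_class_max",
                   method: str = "weighted_value") -> SignatureSet:
        cohort = self._restrict(cohort or self.model.cohort)
        bags = make_bags(cohort, self.config.bag_size,
                         seed=derive_seed(seed, "signature_bags"),
                         mode="epoch_partition")
        return compute_signatures(self.params, cohort, bags, n_per_class,
                                  normalization=normalization, method=method)

    def instance_predictions(self, cohort: Optional[LabeledCohort] = None,
                             seed: int = 0):
        cohort = self._restrict(cohort or self.model.cohort)
        bags = make_bags(cohort, self.config.bag_size,
                         seed=derive_seed(seed, "pred_bags"), mode="epoch_partition")
        return instance_predictions(self.params, bags)

    def save(self, path) -> None:
        self.params.save(path)

    def summary(self, eval_cohort: Optional[LabeledCohort] = None) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        D, M, L, C = self.params.dims
        rep = self.evaluate(eval_cohort)
        lines = [
            "      Attention-MIL copy-number classifier",
            "=" * 52,
            f"classes:            {C}",
            f"genes (features):   {D}",
            f"embedding width M:  {M}",
            f"attention width L:  {L}",
            f"bag size K:         {self.config.bag_size}",
            f"epochs run:         {len(self.log['epoch_loss'])}"
            + (f" (early stop at {self.log['stopped_epoch']})"
               if self.log.get("stopped_epoch") is not None else ""),
            f"final train loss:   {self.log['epoch_loss'][-1]:.4f}",
        ]
        if self.log.get("val_bag_accuracy"):
            lines.append(f"best val bag acc:   {max(self.log['val_bag_accuracy']):.4f}")
        lines += [
            f"bag accuracy:       {rep.bag_accuracy:.4f}",
            f"instance accuracy:  {rep.instance_accuracy:.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_training(self, ax=None):
        """Loss (and validation NLL) per epoch."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["epoch_loss"], label="train bag NLL")
        if self.log.get("val_nll"):
            ax.plot(self.log["val_nll"], label="validation bag NLL")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean bag NLL")
        ax.legend()
        return ax

    def plot_confusion(self, cohort: Optional[LabeledCohort] = None, ax=None):
        """Row-stochastic instance confusion matrix as a heatmap."""
        import matplotlib.pyplot as plt
        rep = self.evaluate(cohort)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(rep.confusion, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(rep.class_names)), rep.class_names, rotation=90)
        ax.set_yticks(range(len(rep.class_names)), rep.class_names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax, label="fraction of class")
        return ax
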