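"""End-to-end pipeline: split, feature selection, training, evaluation,
signature generation and comparison tables, with one global seed from which
every stage seed is derived deterministically."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from .compare import aggregate_to_arms, frequency_profile
from .feature_selection import RFECVConfig
from .io import (LabeledCohort, read_cohort, read_gene_annotation)
from .model import CNAttention
from .training import TrainConfig
from .utils import derive_seed, logger


@dataclass
class PipelineConfig:
    matrix_path: str = ""
    labels_path: str = ""
    annotation_path: Optional[str] = None
    output_dir: str = "cnattention_out"
    matrix_dialect: str = "samples_as_rows"
    test_fraction: float = 0.2
    rfecv: RFECVConfig = field(default_factory=RFECVConfig)
    embed_dim: int = 128
    attention_dim: int = 64
    train: TrainConfig = field(default_factory=TrainConfig)
    signature_n: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.rfecv, dict):
            self.rfecv = RFECVConfig(**self.rfecv)
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        # all stage seeds derive from the single global seed
        self.rfecv.seed = derive_seed(self.seed, "rfecv")
        self.train.seed = derive_seed(self.seed, "train")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 cohort: Optional[LabeledCohort] = None) -> dict:
    """Execute split -> feature selection -> train -> evaluate -> signatures.

    Writes all artifacts under ``config.output_dir`` and returns their paths
    plus the in-memory results. Any stage failure is re-raised with the stage
    name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "config_hash": config.config_hash(),
            "seed": config.seed}
    artifacts: dict = {"meta": str(out / "run_meta.json")}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("load")
        if cohort is None:
            cohort = read_cohort(config.matrix_path, config.labels_path,
                                 config.matrix_dialect)
        annotation = (read_gene_annotation(config.annotation_path)
                      if config.annotation_path else None)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load' failed: {exc}") from exc

    try:
        stage("split")
        from .io import split_cohort
        train_cohort, test_cohort = split_cohort(
            cohort, config.test_fraction, derive_seed(config.seed, "split"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'split' failed: {exc}") from exc

    try:
        stage("select-features")
        model = CNAttention(train_cohort, embed_dim=config.embed_dim,
                            attention_dim=config.attention_dim)
        sel = model.select_features(config.rfecv)
        genes_path = out / "selected_genes.txt"
        genes_path.write_text("\n".join(sel.selected_genes) + "\n")
        path_tsv = out / "score_path.tsv"
        with open(path_tsv, "w") as fh:
            fh.write("n_features\tmean_cv_score\n")
            for n, s in sel.score_path:
                fh.write(f"{n}\t{s:.10g}\n")
        artifacts["selected_genes"] = str(genes_path)
        artifacts["score_path"] = str(path_tsv)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select-features' failed: {exc}") from exc

    try:
        stage("train")
        results = model.fit(config.train)
        model_path = out / "model.json"
        results.save(model_path)
        artifacts["model"] = str(model_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'train' failed: {exc}") from exc

    try:
        stage("evaluate")
        report = results.evaluate(test_cohort, seed=derive_seed(config.seed, "eval"))
        report_path = out / "eval_report.json"
        payload = report.to_dict()
        payload.update({"config_hash": meta["config_hash"], "seed": config.seed})
        report_path.write_text(json.dumps(payload, indent=2))
        import pandas as pd
        pd.DataFrame(report.confusion, index=report.class_names,
                     columns=report.class_names).to_csv(
            out / "confusion.tsv", sep="\t", float_format="%.10g")
        artifacts["eval_report"] = str(report_path)
        artifacts["confusion"] = str(out / "confusion.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'evaluate' failed: {exc}") from exc

    try:
        stage("signatures")
        sigs = results.signatures(n_per_class=config.signature_n,
                                  seed=derive_seed(config.seed, "signatures"))
        sig_path = out / "signatures.tsv"
        sigs.save(sig_path)
        artifacts["signatures"] = str(sig_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'signatures' failed: {exc}") from exc

    try:
        stage("compare")
        freq = frequency_profile(cohort.matrix)
        freq_path = out / "frequency_profile.tsv"
        freq.save(freq_path)
        artifacts["frequency_profile"] = str(freq_path)
        if annotation is not None:
            arms = aggregate_to_arms(freq, annotation)
            arm_path = out / "arm_profile.tsv"
            arms.save(arm_path)
            artifacts["arm_profile"] = str(arm_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'compare' failed: {exc}") from exc

    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    artifacts["results"] = results
    artifacts["report"] = report
    artifacts["signature_set"] = sigs
    return artifacts
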