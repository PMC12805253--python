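"""Cohort and signature comparison metrics.

Frequency profiles follow the Progenetix convention: per gene, the fraction
of samples carrying any gain (call >= +1) and any loss (call <= -1); a flag
restricts counting to high-level events (|call| = 2). Arm-level profiles
average per-gene values over the genes annotated to each chromosome arm
(unweighted), and arm concordance between two profiles is the Spearman rank
correlation of their net scores (mean gain minus mean loss). Gene-level
signature overlap is the Jaccard index of the two gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .io import CNAMatrix, GeneAnnotation
from .utils import logger


@dataclass
class FrequencyProfile:
    table: pd.DataFrame  # index gene; columns gain_freq, loss_freq
    n_samples: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def save(self, path: str | Path) -> None:
        out = self.table.copy()
        out["n"] = self.n_samples
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


@dataclass
class ArmProfile:
    table: pd.DataFrame  # index arm (e.g. "chr1p"); columns gain_freq, loss_freq, net
    n_genes_skipped: int = 0

    @property
    def arms(self) -> list[str]:
        return list(self.table.index)

    @property
    def net(self) -> pd.Series:
        return self.table["net"]

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="arm", float_format="%.10g")


def frequency_profile(matrix: CNAMatrix,
                      sample_subset: Optional[Sequence[str]] = None,
                      high_level_only: bool = False) -> FrequencyProfile:
    """Per-gene gain and loss frequencies over a sample subset (default: all)."""
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValueError("sample subset is empty")
        matrix = matrix.subset_samples(list(sample_subset))
    if matrix.n_samples == 0:
        raise ValueError("matrix has no samples")
    v = matrix.values
    gain_cut, loss_cut = (2, -2) if high_level_only else (1, -1)
    gain = (v >= gain_cut).mean(axis=0)
    loss = (v <= loss_cut).mean(axis=0)
    table = pd.DataFrame({"gain_freq": gain, "loss_freq": loss}, index=matrix.gene_ids)
    return FrequencyProfile(table, matrix.n_samples)


def aggregate_to_arms(profile_or_scores: FrequencyProfile | pd.Series,
                      annotation: GeneAnnotation) -> ArmProfile:
    """Unweighted per-arm means of per-gene values; unannotated genes skipped."""
    if isinstance(profile_or_scores, FrequencyProfile):
        df = profile_or_scores.table[["gain_freq", "loss_freq"]].copy()
    else:
        s = pd.Series(profile_or_scores, dtype=float)
        df = pd.DataFrame({"gain_freq": s.clip(lower=0),
                           "loss_freq": (-s).clip(lower=0)})
    ann = annotation.table
    annotated = df.index.intersection(ann.index)
    skipped = len(df.index) - len(annotated)
    if skipped:
        logger.info("aggregate_to_arms: %d genes without annotation skipped", skipped)
    if not len(annotated):
        raise ValueError("no input gene is annotated to any arm")
    df = df.loc[annotated]
    arm = ann.loc[annotated, "chrom"].astype(str) + ann.loc[annotated, "arm"].astype(str)
    grouped = df.groupby(arm).mean()
    grouped["net"] = grouped["gain_freq"] - grouped["loss_freq"]
    return ArmProfile(grouped.sort_index(), n_genes_skipped=skipped)


def arm_spearman(a: ArmProfile, b: ArmProfile) -> float:
    """Spearman rank correlation of net scores over the shared arms (>= 3)."""
    shared = a.table.index.intersection(b.table.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared arms, got {len(shared)}")
    rho, _ = stats.spearmanr(a.net.loc[shared], b.net.loc[shared])
    return float(rho)


def signature_jaccard(genes_a: Set[str], genes_b: Set[str]) -> float:
    """|A & B| / |A | B| of two signature gene sets."""
    a, b = set(genes_a), set(genes_b)
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return len(a & b) / len(a | b)
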