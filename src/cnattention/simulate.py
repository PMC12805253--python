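"""Synthetic multi-class cohorts of five-level discrete copy-number profiles.

The generator plants class-specific contiguous aberration blocks (mimicking
segmental gains and losses) on a diploid background with per-gene noise, and
can split a class into subtypes carrying their own distinct block sets — the
kind of intra-type heterogeneity (e.g. co-deletion subtypes) that motivates a
multiple-instance treatment of cancer-type classification.

Composition rule: background noise and planted signal overwrite, planted
value wins — a sample's call at a locus is a single observed state. Subtype
block sets are carried jointly (one penetrance draw per sample per subtype
block set), modelling co-occurring events such as a 1p/19q co-deletion;
class-level blocks are carried independently per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CNAMatrix, GeneAnnotation, LabeledCohort
from .utils import logger


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SubtypeDef:
    """A subtype of one class: a name, its sample fraction, and how many
    extra planted blocks it carries (all with one sign, carried jointly)."""

    name: str
    fraction: float
    n_blocks: int = 1
    sign: int = -1


@dataclass
class SimulationConfig:
    n_classes: int = 3
    samples_per_class: int | Sequence[int] = 40
    n_genes: int = 500
    blocks_per_class: int = 2
    block_size: int = 10
    block_signs: Optional[Sequence[int]] = None  # per block; default alternates +1, -1
    penetrance: float = 0.9
    high_level_fraction: float = 0.3
    background_rate: float = 0.02
    subtype_spec: Optional[dict[int, list[SubtypeDef]]] = None
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "high_level_fraction", "background_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.block_signs is None:
            self.block_signs = [1 if j % 2 == 0 else -1 for j in range(self.blocks_per_class)]
        if len(self.block_signs) != self.blocks_per_class:
            raise ConfigError("block_signs length must equal blocks_per_class")
        if any(s not in (-1, 1) for s in self.block_signs):
            raise ConfigError("block signs must be +1 or -1")
        if self.subtype_spec:
            for cls, defs in self.subtype_spec.items():
                if not 0 <= cls < self.n_classes:
                    raise ConfigError(f"subtype_spec refers to unknown class {cls}")
                total = sum(d.fraction for d in defs)
                if not np.isclose(total, 1.0):
                    raise ConfigError(f"subtype fractions of class {cls} sum to {total}, not 1")

    @property
    def per_class_counts(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        counts = list(self.samples_per_class)
        if len(counts) != self.n_classes:
            raise ConfigError("samples_per_class list length must equal n_classes")
        return counts

    def total_planted_genes(self) -> int:
        n = self.n_classes * self.blocks_per_class * self.block_size
        if self.subtype_spec:
            n += sum(d.n_blocks * self.block_size
                     for defs in self.subtype_spec.values() for d in defs)
        return n


@dataclass
class GroundTruth:
    """What the simulator planted: per class, gene -> sign (+1 gain / -1 loss);
    subtype block maps and per-sample subtype assignment when subtypes exist."""

    blocks: dict[str, dict[str, int]]
    subtype_blocks: dict[str, dict[str, int]] = field(default_factory=dict)
    subtype_assignment: dict[str, str] = field(default_factory=dict)
    annotation: Optional[GeneAnnotation] = None
    typical: dict[str, bool] = field(default_factory=dict)  # sample carries all its blocks


def make_annotation(gene_ids: Sequence[str], n_chromosomes: int) -> GeneAnnotation:
    """Place genes uniformly on simulated chromosomes, p/q split at the midpoint."""
    n = len(gene_ids)
    per_chrom = int(np.ceil(n / n_chromosomes))
    rows = []
    for j, g in enumerate(gene_ids):
        chrom_idx, pos = divmod(j, per_chrom)
        n_on_chrom = min(per_chrom, n - chrom_idx * per_chrom)
        arm = "p" if pos < n_on_chrom / 2 else "q"
        start = pos * 1000
        rows.append({"gene": g, "chrom": f"chr{chrom_idx + 1}", "start": start,
                     "end": start + 500, "arm": arm})
    return GeneAnnotation(pd.DataFrame(rows).set_index("gene"))


def _class_name(i: int) -> str:
    return f"type{i + 1:02d}"


def simulate_cohort(config: SimulationConfig) -> tuple[LabeledCohort, GroundTruth]:
    """Generate a labeled cohort and the planted ground truth.

    Deterministic given ``config.seed``. Planted blocks of different classes
    (and subtypes) occupy disjoint contiguous gene intervals allocated from
    the start of the gene list.
    """
    needed = config.total_planted_genes()
    if config.n_genes < needed:
        raise ConfigError(f"n_genes={config.n_genes} < {needed} genes needed for planted blocks")
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{j:05d}" for j in range(config.n_genes)]
    counts = config.per_class_counts

    # allocate disjoint block intervals: class blocks first, then subtype blocks
    cursor = 0
    class_blocks: dict[int, list[tuple[np.ndarray, int]]] = {}
    for c in range(config.n_classes):
        blocks = []
        for sign in config.block_signs:
            blocks.append((np.arange(cursor, cursor + config.block_size), int(sign)))
            cursor += config.block_size
        class_blocks[c] = blocks
    subtype_blocks: dict[tuple[int, str], list[tuple[np.ndarray, int]]] = {}
    if config.subtype_spec:
        for c, defs in config.subtype_spec.items():
            for d in defs:
                blocks = []
                for _ in range(d.n_blocks):
                    blocks.append((np.arange(cursor, cursor + config.block_size), int(d.sign)))
                    cursor += config.block_size
                subtype_blocks[(c, d.name)] = blocks

    n_total = sum(counts)
    values = np.zeros((n_total, config.n_genes), dtype=np.int8)
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    truth = GroundTruth(blocks={}, annotation=make_annotation(gene_ids, config.n_chromosomes))

    for c in range(config.n_classes):
        cname = _class_name(c)
        gene_signs: dict[str, int] = {}
        for idx, sign in class_blocks[c]:
            for j in idx:
                gene_signs[gene_ids[j]] = sign
        truth.blocks[cname] = gene_signs

    if config.subtype_spec:
        for (c, sname), blocks in subtype_blocks.items():
            key = f"{_class_name(c)}/{sname}"
            truth.subtype_blocks[key] = {
                gene_ids[j]: sign for idx, sign in blocks for j in idx
            }

    row = 0
    for c in range(config.n_classes):
        cname = _class_name(c)
        # assign subtypes by fraction, deterministically sized
        defs = (config.subtype_spec or {}).get(c)
        subtype_of_sample: list[Optional[SubtypeDef]] = [None] * counts[c]
        if defs:
            sizes = [int(np.floor(d.fraction * counts[c])) for d in defs]
            while sum(sizes) < counts[c]:
                sizes[int(np.argmax([d.fraction for d in defs]))] += 1
            order = rng.permutation(counts[c])
            pos = 0
            for d, size in zip(defs, sizes):
                for i in order[pos:pos + size]:
                    subtype_of_sample[i] = d
                pos += size
        for i in range(counts[c]):
            sid = f"{cname}_s{i:04d}"
            sample_ids.append(sid)
            labels[sid] = cname
            profile = values[row]
            # background noise
            noisy = rng.random(config.n_genes) < config.background_rate
            if noisy.any():
                mags = np.where(rng.random(noisy.sum()) < config.high_level_fraction, 2, 1)
                signs = rng.choice([-1, 1], size=noisy.sum())
                profile[noisy] = (mags * signs).astype(np.int8)
            # class blocks, independent penetrance per block; planted value wins
            carried_all = True
            for idx, sign in class_blocks[c]:
                if rng.random() < config.penetrance:
                    mag = np.where(rng.random(idx.size) < config.high_level_fraction, 2, 1)
                    profile[idx] = (sign * mag).astype(np.int8)
                else:
                    carried_all = False
            # subtype block set, carried jointly
            d = subtype_of_sample[i]
            if d is not None:
                truth.subtype_assignment[sid] = f"{cname}/{d.name}"
                if rng.random() < config.penetrance:
                    for idx, sign in subtype_blocks[(c, d.name)]:
                        mag = np.where(rng.random(idx.size) < config.high_level_fraction, 2, 1)
                        profile[idx] = (sign * mag).astype(np.int8)
                else:
                    carried_all = False
            truth.typical[sid] = carried_all
            row += 1

    matrix = CNAMatrix(sample_ids, gene_ids, values)
    cohort = LabeledCohort(matrix, labels, [_class_name(c) for c in range(config.n_classes)])
    return cohort, truth


def subtype_labels(truth: GroundTruth) -> dict[str, str]:
    """Map sample -> subtype that generated it; error when no subtypes exist."""
    if not truth.subtype_assignment:
        raise ValueError("cohort was simulated without subtype_spec")
    return dict(truth.subtype_assignment)
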