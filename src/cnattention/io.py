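"""Containers and readers/writers for gene-level copy-number data.

Copy-number calls are discrete, GISTIC-style five-level codes per gene:
-2 (deep loss), -1 (shallow loss), 0 (diploid), +1 (low-level gain),
+2 (high-level amplification). All tabular formats are TSV with a header
row and the identifier in the first column; matrices are accepted in
either orientation (samples-as-rows or genes-as-rows, the cBioPortal
export convention) via an explicit dialect flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .utils import logger

VALID_CALLS = frozenset({-2, -1, 0, 1, 2})

MatrixDialect = Literal["genes_as_rows", "samples_as_rows"]
AlignPolicy = Literal["intersect", "union_fill_zero"]


class ValidationError(ValueError):
    """A table violated the discrete copy-number data contract."""


@dataclass
class CNAMatrix:
    """Samples x genes matrix of five-level discrete copy-number calls."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_genes), integer, values in {-2..2}

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError(f"matrix must be 2-D, got shape {self.values.shape}")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.issubdtype(self.values.dtype, np.integer):
            float_vals = np.asarray(self.values, dtype=float)
            rounded = np.round(float_vals)
            bad = ~np.isclose(float_vals, rounded) | ~np.isfinite(float_vals)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer value {float_vals[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
                )
            self.values = rounded.astype(np.int8)
        else:
            self.values = self.values.astype(np.int8)
        out = (self.values < -2) | (self.values > 2)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValidationError(
                f"copy-number call {int(self.values[i, j])} out of range {{-2..2}} "
                f"at sample {self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CNAMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CNAMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return CNAMatrix(list(sample_ids), list(self.gene_ids), self.values[rows])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CNAMatrix":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"unknown gene(s): {missing[:5]}")
        cols = [idx[g] for g in gene_ids]
        return CNAMatrix(list(self.sample_ids), list(gene_ids), self.values[:, cols])


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier {x!r}")
        seen.add(x)


@dataclass
class LabeledCohort:
    """A CNA matrix plus one cancer-type label per sample.

    Class indices used throughout the package are 0-based positions in
    ``class_names``.
    """

    matrix: CNAMatrix
    labels: dict[str, str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in self.matrix.sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without a label: {missing[:5]}")
        if not self.class_names:
            self.class_names = sorted({self.labels[s] for s in self.matrix.sample_ids})
        known = set(self.class_names)
        for s in self.matrix.sample_ids:
            if self.labels[s] not in known:
                raise ValidationError(
                    f"label {self.labels[s]!r} of sample {s!r} not in class_names"
                )
        self.labels = {s: self.labels[s] for s in self.matrix.sample_ids}

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def y(self) -> np.ndarray:
        """Integer class index per sample, aligned with matrix rows."""
        pos = {c: i for i, c in enumerate(self.class_names)}
        return np.array([pos[self.labels[s]] for s in self.matrix.sample_ids])

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for s in self.matrix.sample_ids:
            counts[self.labels[s]] += 1
        return counts

    def subset_samples(self, sample_ids: Sequence[str]) -> "LabeledCohort":
        sub = self.matrix.subset_samples(sample_ids)
        return LabeledCohort(sub, {s: self.labels[s] for s in sample_ids}, list(self.class_names))


@dataclass
class GeneAnnotation:
    """Per-gene genomic placement: chromosome, 0-based half-open interval, arm."""

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, arm

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "arm"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"annotation needs columns {sorted(required)}")
        bad_arm = ~self.table["arm"].isin(["p", "q"])
        if bad_arm.any():
            gene = self.table.index[bad_arm][0]
            raise ValidationError(f"gene {gene!r} has arm {self.table.loc[gene, 'arm']!r}")
        if (self.table["start"] >= self.table["end"]).any():
            raise ValidationError("annotation has start >= end")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene in annotation")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def arm_of(self, gene: str) -> str:
        row = self.table.loc[gene]
        return f"{row['chrom']}{row['arm']}"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cna_matrix(path: str | Path, dialect: MatrixDialect = "samples_as_rows") -> CNAMatrix:
    """Read a TSV copy-number matrix, normalizing orientation to samples-as-rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if dialect == "genes_as_rows":
        df = df.T
    elif dialect != "samples_as_rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    return CNAMatrix.from_frame(df)


def write_cna_matrix(matrix: CNAMatrix, path: str | Path,
                     dialect: MatrixDialect = "samples_as_rows") -> None:
    df = matrix.to_frame()
    if dialect == "genes_as_rows":
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("label table needs two columns: sample_id, cancer_type")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.keys()), "cancer_type": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a BED-like annotation: chrom, start, end, gene, arm (no header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene", "arm"], dtype={"gene": str})
    return GeneAnnotation(df.set_index("gene"))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.reset_index()[["chrom", "start", "end", "gene", "arm"]]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_cohort(matrix_path: str | Path, labels_path: str | Path,
                dialect: MatrixDialect = "samples_as_rows") -> LabeledCohort:
    return LabeledCohort(read_cna_matrix(matrix_path, dialect), read_labels(labels_path))


# ---------------------------------------------------------------------------
# cohort operations
# ---------------------------------------------------------------------------

def align_gene_sets(a: CNAMatrix, b: CNAMatrix,
                    policy: AlignPolicy = "intersect") -> tuple[CNAMatrix, CNAMatrix]:
    """Put two matrices on an identical, sorted gene set.

    ``intersect`` keeps shared genes; ``union_fill_zero`` takes the union,
    filling genes absent from a cohort with 0 (diploid, the neutral call).
    """
    genes_a, genes_b = set(a.gene_ids), set(b.gene_ids)
    if policy == "intersect":
        shared = sorted(genes_a & genes_b)
        if not shared:
            raise ValidationError("gene sets have empty intersection")
        return a.subset_genes(shared), b.subset_genes(shared)
    if policy == "union_fill_zero":
        union = sorted(genes_a | genes_b)
        return _reindex_fill(a, union), _reindex_fill(b, union)
    raise ValueError(f"unknown policy {policy!r}")


def _reindex_fill(m: CNAMatrix, genes: list[str]) -> CNAMatrix:
    df = m.to_frame().reindex(columns=genes, fill_value=0)
    return CNAMatrix.from_frame(df)


def split_cohort(cohort: LabeledCohort, test_fraction: float,
                 seed: int) -> tuple[LabeledCohort, LabeledCohort]:
    """Stratified train/test split of a labeled cohort.

    Per class, ``floor(n * test_fraction)`` samples (at least one whenever the
    class has two or more) go to the test part; a singleton class stays whole
    in the training part with a logged warning. Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {c: [] for c in cohort.class_names}
    for s in cohort.matrix.sample_ids:
        by_class[cohort.labels[s]].append(s)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in cohort.class_names:
        members = by_class[c]
        if len(members) < 2:
            if members:
                logger.warning("class %r has a single sample; kept in training", c)
                train_ids.extend(members)
            continue
        n_test = max(1, int(np.floor(len(members) * test_fraction)))
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        test_ids.extend(shuffled[:n_test])
        train_ids.extend(shuffled[n_test:])
    # preserve original sample order inside each part
    original = {s: i for i, s in enumerate(cohort.matrix.sample_ids)}
    train_ids.sort(key=original.__getitem__)
    test_ids.sort(key=original.__getitem__)
    return cohort.subset_samples(train_ids), cohort.subset_samples(test_ids)
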