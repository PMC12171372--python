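"""Labeled classification tables built from a simulation cohort.

Two designs are supported:

* the **pair** dataset — one row per (mother, child) pair; negative class
  (``NormalKinship``) is every normal parent-child pair, positive class
  (``IncestKinship``) draws equal quotas from the incest-paternity and
  incest-sib pair sets, keeping the classes balanced. Features are the
  mother's then the child's two allele columns per marker (4 per marker).
* the **offspring-only** dataset — one row per child profile; normal rows
  come from each parent-child pairing's child plus the second member of each
  sib pair, incest rows from the incest offspring. Features are the child's
  two allele columns per marker.

Allele features are categorical text labels by default (learners with native
categorical handling consume them directly); ``encode_numeric`` converts to
their repeat-number values for learners that need numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .freqdb import format_allele
from .pedsim import KinshipCategory, SimulationCohort

__all__ = [
    "LabeledDataset",
    "NORMAL_LABEL",
    "INCEST_LABEL",
    "assemble_pair_dataset",
    "assemble_offspring_only",
    "split_dataset",
    "subset_markers",
    "encode_numeric",
]

NORMAL_LABEL = "NormalKinship"
INCEST_LABEL = "IncestKinship"

_META_COLUMNS = ("label", "provenance", "partition", "family")


@dataclass
class LabeledDataset:
    """Flat feature table with binary kinship label and optional partition."""

    df: pd.DataFrame
    markers: tuple[str, ...]
    feature_columns: tuple[str, ...]
    design: str  # "pair" | "offspring-only"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_columns if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature columns missing from frame: {missing}")
        if "label" not in self.df.columns:
            raise ValueError("dataset frame needs a 'label' column")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> pd.Series:
        return self.df["label"]

    @property
    def X(self) -> pd.DataFrame:
        return self.df[list(self.feature_columns)]

    @property
    def y(self) -> np.ndarray:
        """Binary target, positive class = IncestKinship."""
        return (self.df["label"] == INCEST_LABEL).to_numpy(dtype=int)

    def partition(self, name: str) -> "LabeledDataset":
        if "partition" not in self.df.columns:
            raise ValueError("dataset has not been split into partitions")
        sub = self.df[self.df["partition"] == name]
        if sub.empty:
            raise ValueError(f"partition {name!r} is empty")
        return LabeledDataset(
            sub.reset_index(drop=True),
            self.markers,
            self.feature_columns,
            self.design,
            self.seed,
        )

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def manifest(self) -> dict:
        out = {
            "design": self.design,
            "markers": list(self.markers),
            "n_rows": len(self),
            "n_features": len(self.feature_columns),
            "class_counts": {str(k): int(v) for k, v in self.class_counts().items()},
            "seed": self.seed,
        }
        if "partition" in self.df.columns:
            out["partition_counts"] = {
                str(k): int(v) for k, v in self.df["partition"].value_counts().items()
            }
        return out

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _allele_frame(values: np.ndarray, loci: Sequence[str], prefix: str) -> pd.DataFrame:
    """Categorical allele-label columns ``<prefix><locus>_1/_2`` from (n, L, 2)."""
    cols = {}
    for j, locus in enumerate(loci):
        for slot in (0, 1):
            raw = values[:, j, slot]
            uniq, codes = np.unique(raw, return_inverse=True)
            labels = [format_allele(v) for v in uniq]
            cols[f"{prefix}{locus}_{slot + 1}"] = pd.Categorical.from_codes(
                codes, categories=labels
            )
    return pd.DataFrame(cols)


def _unify_categories(df: pd.DataFrame, feature_columns: Sequence[str]) -> None:
    """Coerce feature columns to a single categorical dtype per column.

    Concatenating blocks whose categoricals carry different category sets
    degrades to object dtype; learners with native categorical support need a
    consistent category dtype instead.
    """
    for col in feature_columns:
        if not isinstance(df[col].dtype, pd.CategoricalDtype):
            df[col] = df[col].astype("category")


def assemble_pair_dataset(
    cohort: SimulationCohort,
    markers: Sequence[str] | None = None,
    seed: int = 0,
    incest_quota: int | None = None,
) -> LabeledDataset:
    """Build the balanced mother-child pair table.

    ``incest_quota`` pairs are drawn (seeded, without replacement) from each of
    the two incest categories; the default is half the normal-paternity pair
    count, which balances the classes (100,000 each at the reference scale of
    50,000 founders). Requesting more pairs than a category holds is an error.
    """
    markers = tuple(markers) if markers is not None else cohort.panel.loci
    rng = np.random.default_rng(seed)
    np_pairs = cohort.pairs(KinshipCategory.NORMAL_PATERNITY).subset_markers(markers)
    if incest_quota is None:
        incest_quota = len(np_pairs) // 2
    frames = []
    for category, label in (
        (KinshipCategory.NORMAL_PATERNITY, NORMAL_LABEL),
        (KinshipCategory.INCEST_PATERNITY, INCEST_LABEL),
        (KinshipCategory.INCEST_SIBS, INCEST_LABEL),
    ):
        ps = cohort.pairs(category).subset_markers(markers)
        if label == INCEST_LABEL:
            if incest_quota > len(ps):
                raise ValueError(
                    f"incest quota {incest_quota} exceeds the {len(ps)} available "
                    f"{category.value} pairs"
                )
            ps = ps.sample(incest_quota, rng)
        frame = pd.concat(
            [
                _allele_frame(ps.mother_values, markers, "mother_"),
                _allele_frame(ps.child_values, markers, "child_"),
            ],
            axis=1,
        )
        frame["label"] = label
        frame["provenance"] = category.value
        if ps.family is not None:
            frame["family"] = ps.family
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    feature_columns = tuple(c for c in df.columns if c not in _META_COLUMNS)
    _unify_categories(df, feature_columns)
    return LabeledDataset(df, markers, feature_columns, "pair", seed)


def assemble_offspring_only(
    cohort: SimulationCohort,
    markers: Sequence[str] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Build the child-profile-only table (no parental columns).

    Normal rows: the child of every normal parent-child pairing (children are
    duplicated across their two pairings, matching the reference totals) plus
    the second member of each sib pair. Incest rows: every incest-paternity
    and incest-sib offspring. At the reference scale this gives 350,000 rows
    per class, 700,000 in total.
    """
    markers = tuple(markers) if markers is not None else cohort.panel.loci
    blocks = []
    np_pairs = cohort.pairs(KinshipCategory.NORMAL_PATERNITY).subset_markers(markers)
    ns_pairs = cohort.pairs(KinshipCategory.NORMAL_SIBS).subset_markers(markers)
    ip_pairs = cohort.pairs(KinshipCategory.INCEST_PATERNITY).subset_markers(markers)
    is_pairs = cohort.pairs(KinshipCategory.INCEST_SIBS).subset_markers(markers)
    for pairs, label, provenance in (
        (np_pairs, NORMAL_LABEL, KinshipCategory.NORMAL_PATERNITY.value),
        (ns_pairs, NORMAL_LABEL, KinshipCategory.NORMAL_SIBS.value),
        (ip_pairs, INCEST_LABEL, KinshipCategory.INCEST_PATERNITY.value),
        (is_pairs, INCEST_LABEL, KinshipCategory.INCEST_SIBS.value),
    ):
        frame = _allele_frame(pairs.child_values, markers, "child_")
        frame["label"] = label
        frame["provenance"] = provenance
        if pairs.family is not None:
            frame["family"] = pairs.family
        blocks.append(frame)
    df = pd.concat(blocks, ignore_index=True)
    feature_columns = tuple(c for c in df.columns if c not in _META_COLUMNS)
    _unify_categories(df, feature_columns)
    return LabeledDataset(df, markers, feature_columns, "offspring-only", seed)


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
    group: str | None = None,
) -> LabeledDataset:
    """Assign disjoint train/validation/test partitions.

    The default split is row-level and stratified by label: within each class,
    ``round(f_train * n)`` rows go to train and ``round(f_val * n)`` to
    validation; the remainder is the test partition. Because pair and
    offspring tables reuse profiles across rows, the row-level split lets the
    same simulated individual contribute to more than one partition;
    ``group="family"`` instead assigns whole source families to partitions so
    no profile is shared between them (stratification then holds only
    approximately, since every family feeds both classes).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    partition = np.empty(len(ds), dtype=object)
    if group is None:
        for label in ds.labels.unique():
            idx = np.flatnonzero((ds.labels == label).to_numpy())
            idx = rng.permutation(idx)
            n = len(idx)
            n_train = int(round(fractions[0] * n))
            n_val = int(round(fractions[1] * n))
            if n_train + n_val > n:
                n_val = n - n_train
            partition[idx[:n_train]] = "train"
            partition[idx[n_train : n_train + n_val]] = "validation"
            partition[idx[n_train + n_val :]] = "test"
    elif group == "family":
        if "family" not in ds.df.columns:
            raise ValueError("dataset carries no family provenance")
        families = rng.permutation(ds.df["family"].unique())
        n_fam = len(families)
        n_train = int(round(fractions[0] * n_fam))
        n_val = int(round(fractions[1] * n_fam))
        assign = {}
        for f in families[:n_train]:
            assign[f] = "train"
        for f in families[n_train : n_train + n_val]:
            assign[f] = "validation"
        for f in families[n_train + n_val :]:
            assign[f] = "test"
        partition = ds.df["family"].map(assign).to_numpy()
    else:
        raise ValueError(f"unknown grouping {group!r}")
    df = ds.df.copy()
    df["partition"] = partition
    return LabeledDataset(df, ds.markers, ds.feature_columns, ds.design, seed)


def subset_markers(obj, markers: Sequence[str]):
    """Restrict a dataset or cohort to the named markers (idempotent)."""
    markers = list(markers)
    if isinstance(obj, SimulationCohort):
        return obj.subset_markers(markers)
    if isinstance(obj, LabeledDataset):
        unknown = [m for m in markers if m not in obj.markers]
        if unknown:
            raise KeyError(f"unknown markers {unknown!r}")
        prefixes = ("mother_", "child_") if obj.design == "pair" else ("child_",)
        keep = tuple(
            f"{p}{m}_{s}" for m in markers for p in prefixes for s in (1, 2)
        )
        # preserve the mother-block-then-child-block layout of pair datasets
        keep = tuple(c for c in obj.feature_columns if c in set(keep))
        meta = [c for c in _META_COLUMNS if c in obj.df.columns]
        return LabeledDataset(
            obj.df[list(keep) + meta].copy(),
            tuple(markers),
            keep,
            obj.design,
            obj.seed,
        )
    raise TypeError(f"cannot subset markers on {type(obj).__name__}")


def encode_numeric(X: pd.DataFrame) -> pd.DataFrame:
    """Convert categorical allele-label columns to their numeric repeat values."""
    out = {}
    for col in X.columns:
        s = X[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            s = s.astype(str)
        out[col] = pd.to_numeric(s).astype(float)
    return pd.DataFrame(out, index=X.index)
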