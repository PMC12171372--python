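"""Population STR allele-frequency tables.

A frequency table holds, for one population, a categorical distribution over
observed alleles at each STR locus. Alleles are repeat numbers; microvariants
such as TH01 9.3 carry a decimal part, so allele labels are kept as text with a
numeric shadow value used for ordering and step-mutation arithmetic.

The canonical file dialect is comma-separated with header
``locus,allele,frequency``; the writer sorts loci alphabetically and alleles
numerically so serialized tables diff reproducibly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Allele",
    "LocusDistribution",
    "FrequencyTable",
    "read_frequency_table",
    "write_frequency_table",
    "normalize_frequencies",
    "filter_rare_alleles",
    "synth_frequency_table",
]

#: tolerance for "frequencies sum to one"
NORMALIZATION_TOL = 1e-9


def format_allele(value: float) -> str:
    """Render a numeric repeat number as its STR nomenclature label.

    Integral values lose the decimal point (``12.0`` -> ``"12"``); microvariant
    values keep one fractional digit (``9.3`` stays ``"9.3"``).
    """
    if float(value) <= 0:
        raise ValueError(f"allele value must be positive, got {value}")
    rounded = round(float(value), 1)
    if rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.1f}"


@dataclass(frozen=True, order=True)
class Allele:
    """One STR allele: a text label and its decimal repeat-number value."""

    sort_index: float = field(init=False, repr=False)
    label: str = field(compare=False)
    value: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"allele value must be > 0, got {self.value!r}")
        if format_allele(self.value) != self.label:
            raise ValueError(
                f"allele label {self.label!r} does not round-trip through its "
                f"numeric value {self.value!r}"
            )
        object.__setattr__(self, "sort_index", self.value)

    @classmethod
    def from_label(cls, label: str) -> "Allele":
        try:
            value = float(label)
        except ValueError as exc:
            raise ValueError(f"allele label {label!r} is not numeric") from exc
        return cls(label=format_allele(value), value=value)

    @classmethod
    def from_value(cls, value: float) -> "Allele":
        return cls(label=format_allele(value), value=float(value))


class LocusDistribution:
    """Categorical allele distribution at one STR locus."""

    def __init__(
        self,
        locus_name: str,
        alleles: Sequence[Allele],
        frequencies: Sequence[float],
    ) -> None:
        if len(alleles) == 0:
            raise ValueError(f"locus {locus_name!r} has no alleles")
        if len(alleles) != len(frequencies):
            raise ValueError(
                f"locus {locus_name!r}: {len(alleles)} alleles but "
                f"{len(frequencies)} frequencies"
            )
        freqs = np.asarray(frequencies, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError(f"locus {locus_name!r} has non-positive frequencies")
        labels = [a.label for a in alleles]
        if len(set(labels)) != len(labels):
            raise ValueError(f"locus {locus_name!r} has duplicate allele labels")
        order = np.argsort([a.value for a in alleles], kind="stable")
        self.locus_name = str(locus_name)
        self.alleles: tuple[Allele, ...] = tuple(alleles[i] for i in order)
        self.frequencies: np.ndarray = freqs[order]
        self.frequencies.setflags(write=False)

    @property
    def values(self) -> np.ndarray:
        """Numeric allele values, ascending."""
        return np.array([a.value for a in self.alleles])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.alleles)

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.frequencies.sum()) - 1.0) <= NORMALIZATION_TOL

    def normalized(self) -> "LocusDistribution":
        total = float(self.frequencies.sum())
        if total <= 0:
            raise ValueError(f"locus {self.locus_name!r} has zero total frequency")
        return LocusDistribution(
            self.locus_name, self.alleles, self.frequencies / total
        )

    def expected_homozygosity(self) -> float:
        """Hardy-Weinberg homozygosity sum(p_i^2) for this locus."""
        return float(np.sum(self.frequencies**2))

    def __len__(self) -> int:
        return len(self.alleles)

    def __repr__(self) -> str:
        return (
            f"LocusDistribution({self.locus_name!r}, {len(self)} alleles, "
            f"sum={float(self.frequencies.sum()):.6f})"
        )


class FrequencyTable:
    """Per-locus allele distributions for one population."""

    def __init__(self, population_id: str, loci: Iterable[LocusDistribution]) -> None:
        loci = list(loci)
        if not loci:
            raise ValueError("a frequency table needs at least one locus")
        names = [l.locus_name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names in frequency table")
        self.population_id = str(population_id)
        self.loci: tuple[LocusDistribution, ...] = tuple(loci)
        self._by_name = {l.locus_name: l for l in self.loci}

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.locus_name for l in self.loci)

    def locus(self, name: str) -> LocusDistribution:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"locus {name!r} not in table {self.population_id!r}")

    @property
    def n_alleles(self) -> int:
        """Total allele rows across all loci."""
        return sum(len(l) for l in self.loci)

    @property
    def is_normalized(self) -> bool:
        return all(l.is_normalized for l in self.loci)

    def subset(self, markers: Sequence[str]) -> "FrequencyTable":
        """Restrict to the named loci, in the given order."""
        missing = [m for m in markers if m not in self._by_name]
        if missing:
            raise KeyError(f"unknown loci {missing!r} in table {self.population_id!r}")
        return FrequencyTable(self.population_id, [self._by_name[m] for m in markers])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (l.locus_name, a.label, f)
            for l in sorted(self.loci, key=lambda l: l.locus_name)
            for a, f in zip(l.alleles, l.frequencies)
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency"])

    def __len__(self) -> int:
        return len(self.loci)

    def __repr__(self) -> str:
        return (
            f"FrequencyTable({self.population_id!r}, {len(self)} loci, "
            f"{self.n_alleles} alleles)"
        )


def read_frequency_table(path: str | Path | io.TextIOBase, population_id: str) -> FrequencyTable:
    """Read a ``locus,allele,frequency`` CSV into a :class:`FrequencyTable`.

    Alleles come out sorted ascending by numeric value at every locus; the input
    row order is otherwise irrelevant. Duplicate (locus, allele) rows, frequency
    values outside (0, 1], and non-numeric frequencies are hard errors (the
    offending row number is reported, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str)
    required = ["locus", "allele", "frequency"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"expected header {','.join(required)!r}, got {','.join(df.columns)!r}"
        )
    if df.empty:
        raise ValueError("frequency file contains no data rows")

    freqs = pd.to_numeric(df["frequency"], errors="coerce")
    bad = freqs.isna() | (freqs <= 0) | (freqs > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(
            f"row {row}: frequency {df['frequency'].iloc[row - 2]!r} is not a "
            "number in (0, 1]"
        )
    dup = df.duplicated(subset=["locus", "allele"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["locus", "allele"]].iloc[0]
        raise ValueError(
            f"duplicate allele row: locus {pair['locus']!r} allele {pair['allele']!r}"
        )

    loci = []
    for name, grp in df.groupby("locus", sort=False):
        alleles = [Allele.from_label(lbl) for lbl in grp["allele"]]
        loci.append(LocusDistribution(name, alleles, freqs[grp.index].to_numpy()))
    return FrequencyTable(population_id, loci)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Write the canonical CSV dialect (loci alphabetical, alleles ascending)."""
    table.to_dataframe().to_csv(path, index=False)


def normalize_frequencies(table: FrequencyTable) -> FrequencyTable:
    """Divide each locus's frequencies by their sum so each sums to one."""
    return FrequencyTable(table.population_id, [l.normalized() for l in table.loci])


def filter_rare_alleles(table: FrequencyTable, max_excluded: float = 0.002) -> FrequencyTable:
    """Delete alleles with frequency <= ``max_excluded`` and renormalize.

    Mirrors the curation applied to low-diversity population tables where
    alleles at frequency 0.001-0.002 are dropped before profile simulation.
    The table must already be normalized so the threshold is interpretable.
    """
    if not table.is_normalized:
        raise ValueError("filter_rare_alleles requires a normalized table")
    loci = []
    for l in table.loci:
        keep = l.frequencies > max_excluded
        if not keep.any():
            raise ValueError(
                f"locus {l.locus_name!r}: threshold {max_excluded} removes every "
                "allele"
            )
        kept = [a for a, k in zip(l.alleles, keep) if k]
        loci.append(LocusDistribution(l.locus_name, kept, l.frequencies[keep]).normalized())
    return FrequencyTable(table.population_id, loci)


def synth_frequency_table(
    n_loci: int = 21,
    alleles_per_locus: int = 10,
    concentration: float = 1.0,
    seed: int = 0,
    population_id: str = "synthetic",
) -> FrequencyTable:
    """Generate a synthetic population table for download-free runs.

    Each locus gets ``alleles_per_locus`` consecutive integer repeat numbers
    starting at a random offset in [5, 20], with frequencies drawn from a
    symmetric Dirichlet with the given concentration. A concentration of 1
    over ~10 alleles yields expected homozygosity sum(p^2) ~= 2/(k+1) ~ 0.18,
    i.e. locus diversity in the range of real autosomal forensic STR panels.
    Identical arguments give byte-identical tables.
    """
    if n_loci < 1 or alleles_per_locus < 1:
        raise ValueError("n_loci and alleles_per_locus must be >= 1")
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        start = int(rng.integers(5, 21))
        values = np.arange(start, start + alleles_per_locus, dtype=float)
        freqs = rng.dirichlet(np.full(alleles_per_locus, concentration))
        while np.any(freqs <= 0):  # Dirichlet can underflow to exactly 0
            freqs = rng.dirichlet(np.full(alleles_per_locus, concentration))
        alleles = [Allele.from_value(v) for v in values]
        loci.append(LocusDistribution(f"SYN{i + 1:02d}", alleles, freqs))
    return FrequencyTable(population_id, loci)
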