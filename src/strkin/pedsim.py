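"""Mendelian simulation of STR profiles and incest-kinship cohorts.

Founders are drawn from a population frequency table under Hardy-Weinberg
equilibrium (two independent allele draws per locus); children receive one
uniformly chosen allele from each parent; loci segregate independently. From
``n`` founders the cohort builder derives the four kinship categories used for
classification:

* ``NormalPaternity`` — every (parent, child) combination within a family
  (2 parents x 4 children, so ``8 * n/2`` pairs);
* ``NormalSibs`` — all 6 within-family child pairs (``6 * n/2`` pairs);
* ``IncestPaternity`` — for each parent-child pair, an offspring of that
  mating, paired with its within-pair mother (the younger-generation member);
* ``IncestSibs`` — for each sib pair, an offspring of the sib mating, paired
  with the first-listed sibling as mother.

Offspring of parent-child and of full-sib matings both have inbreeding
coefficient F = 1/4, which is what elevates their homozygosity and their
profile similarity to the mother relative to random mating.

Genotypes are held in numpy arrays of numeric repeat values with shape
``(n_profiles, n_loci, 2)``, the two allele slots sorted ascending (the
smaller-allele / larger-allele column convention of forensic STR tables);
:class:`Profile` objects are lightweight per-row views.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .freqdb import FrequencyTable, format_allele

__all__ = [
    "KinshipCategory",
    "MarkerPanel",
    "Profile",
    "ProfileSet",
    "PairSet",
    "MutationSpec",
    "SimulationCohort",
    "sample_founder",
    "sample_founders",
    "cross",
    "simulate_cohort",
    "apply_one_step_mutation",
]


class KinshipCategory(str, enum.Enum):
    """The four simulated kinship categories."""

    NORMAL_PATERNITY = "NormalPaternity"
    NORMAL_SIBS = "NormalSibs"
    INCEST_PATERNITY = "IncestPaternity"
    INCEST_SIBS = "IncestSibs"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered tuple of locus names shared by a set of profiles."""

    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names in marker panel")
        if not self.loci:
            raise ValueError("marker panel is empty")

    def index_of(self, markers: Sequence[str]) -> np.ndarray:
        pos = {name: i for i, name in enumerate(self.loci)}
        missing = [m for m in markers if m not in pos]
        if missing:
            raise KeyError(f"unknown markers {missing!r}")
        return np.array([pos[m] for m in markers], dtype=int)

    def __len__(self) -> int:
        return len(self.loci)


class Profile:
    """One individual's diploid STR genotype across a marker panel."""

    __slots__ = ("profile_id", "panel", "values", "parent_ids", "generation_tag")

    def __init__(
        self,
        profile_id: str,
        panel: MarkerPanel,
        values: np.ndarray,
        parent_ids: tuple[str, ...] = (),
        generation_tag: str = "founder",
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(panel), 2):
            raise ValueError(
                f"genotype shape {values.shape} does not match panel of "
                f"{len(panel)} loci"
            )
        if np.any(values[:, 0] > values[:, 1]):
            raise ValueError("allele pairs must be sorted ascending (a1 <= a2)")
        if parent_ids and len(parent_ids) != 2:
            raise ValueError("parent_ids must be empty or exactly two ids")
        if generation_tag == "founder" and parent_ids:
            raise ValueError("founders have no parents")
        self.profile_id = profile_id
        self.panel = panel
        self.values = values
        self.parent_ids = tuple(parent_ids)
        self.generation_tag = generation_tag

    def genotype(self, locus: str) -> tuple[str, str]:
        i = self.panel.index_of([locus])[0]
        return format_allele(self.values[i, 0]), format_allele(self.values[i, 1])

    def is_homozygous(self, locus: str) -> bool:
        i = self.panel.index_of([locus])[0]
        return bool(self.values[i, 0] == self.values[i, 1])

    def __repr__(self) -> str:
        return (
            f"Profile({self.profile_id!r}, {len(self.panel)} loci, "
            f"{self.generation_tag})"
        )


class ProfileSet:
    """Array-backed collection of profiles sharing one marker panel."""

    def __init__(
        self,
        panel: MarkerPanel,
        values: np.ndarray,
        ids: Sequence[str],
        parents: Sequence[tuple[str, ...]] | None = None,
        generation_tag: str = "founder",
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[1:] != (len(panel), 2):
            raise ValueError(f"values shape {values.shape} invalid for panel")
        if len(ids) != values.shape[0]:
            raise ValueError("ids length mismatch")
        self.panel = panel
        self.values = values
        self.ids = list(ids)
        self.parents = list(parents) if parents is not None else [()] * len(ids)
        self.generation_tag = generation_tag

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Profile:
        return Profile(
            self.ids[i], self.panel, self.values[i], self.parents[i], self.generation_tag
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def subset_markers(self, markers: Sequence[str]) -> "ProfileSet":
        idx = self.panel.index_of(markers)
        return ProfileSet(
            MarkerPanel(tuple(markers)),
            self.values[:, idx, :],
            self.ids,
            self.parents,
            self.generation_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Serialize with the ``<locus>_1``/``<locus>_2`` column convention."""
        data: dict[str, object] = {"profile_id": self.ids}
        for j, locus in enumerate(self.panel.loci):
            data[f"{locus}_1"] = [format_allele(v) for v in self.values[:, j, 0]]
            data[f"{locus}_2"] = [format_allele(v) for v in self.values[:, j, 1]]
        data["parent1"] = [p[0] if p else "" for p in self.parents]
        data["parent2"] = [p[1] if p else "" for p in self.parents]
        data["category"] = self.generation_tag
        return pd.DataFrame(data)


@dataclass
class PairSet:
    """Category-labelled (mother, child) profile pairs, array-backed."""

    category: KinshipCategory
    panel: MarkerPanel
    mother_values: np.ndarray  # (n, L, 2)
    child_values: np.ndarray  # (n, L, 2)
    mother_ids: list[str] = field(default_factory=list)
    child_ids: list[str] = field(default_factory=list)
    family: np.ndarray | None = None  # (n,) source family index

    def __post_init__(self) -> None:
        if self.mother_values.shape != self.child_values.shape:
            raise ValueError("mother/child genotype arrays differ in shape")

    def __len__(self) -> int:
        return self.mother_values.shape[0]

    def subset_markers(self, markers: Sequence[str]) -> "PairSet":
        idx = self.panel.index_of(markers)
        return PairSet(
            self.category,
            MarkerPanel(tuple(markers)),
            self.mother_values[:, idx, :],
            self.child_values[:, idx, :],
            self.mother_ids,
            self.child_ids,
            self.family,
        )

    def sample(self, n: int, rng: np.random.Generator) -> "PairSet":
        if n > len(self):
            raise ValueError(f"cannot sample {n} pairs from {len(self)}")
        take = rng.choice(len(self), size=n, replace=False)
        return PairSet(
            self.category,
            self.panel,
            self.mother_values[take],
            self.child_values[take],
            [self.mother_ids[i] for i in take] if self.mother_ids else [],
            [self.child_ids[i] for i in take] if self.child_ids else [],
            self.family[take] if self.family is not None else None,
        )


# ---------------------------------------------------------------------------
# sampling and crossing


def _locus_matrix(table: FrequencyTable) -> tuple[MarkerPanel, list[np.ndarray], list[np.ndarray]]:
    panel = MarkerPanel(table.locus_names)
    values = [l.values for l in table.loci]
    freqs = [np.asarray(l.frequencies, dtype=float) for l in table.loci]
    return panel, values, freqs


def sample_founders(
    table: FrequencyTable, n: int, rng: np.random.Generator, id_prefix: str = "F"
) -> ProfileSet:
    """Draw ``n`` unrelated founder profiles under Hardy-Weinberg equilibrium."""
    if not table.is_normalized:
        raise ValueError("frequency table must be normalized before sampling")
    if n < 1:
        raise ValueError("need n >= 1 founders")
    panel, values, freqs = _locus_matrix(table)
    out = np.empty((n, len(panel), 2), dtype=float)
    for j in range(len(panel)):
        out[:, j, :] = rng.choice(values[j], size=(n, 2), p=freqs[j])
    out.sort(axis=2)
    ids = [f"{id_prefix}{i}" for i in range(n)]
    return ProfileSet(panel, out, ids, generation_tag="founder")


def sample_founder(table: FrequencyTable, rng: np.random.Generator) -> Profile:
    """Draw a single founder profile (see :func:`sample_founders`)."""
    return sample_founders(table, 1, rng)[0]


def _cross_values(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Mendelian cross of genotype arrays shaped (n, L, 2)."""
    n, L, _ = a.shape
    pick_a = rng.integers(0, 2, size=(n, L))
    pick_b = rng.integers(0, 2, size=(n, L))
    child = np.empty((n, L, 2), dtype=float)
    child[:, :, 0] = np.take_along_axis(a, pick_a[:, :, None], axis=2)[:, :, 0]
    child[:, :, 1] = np.take_along_axis(b, pick_b[:, :, None], axis=2)[:, :, 0]
    child.sort(axis=2)
    return child


def cross(parent_a: Profile, parent_b: Profile, rng: np.random.Generator) -> Profile:
    """Produce one child: one uniformly chosen allele from each parent per locus."""
    if parent_a.panel.loci != parent_b.panel.loci:
        raise ValueError("parents are typed on different marker panels")
    child = _cross_values(
        parent_a.values[None, :, :], parent_b.values[None, :, :], rng
    )[0]
    return Profile(
        f"{parent_a.profile_id}x{parent_b.profile_id}",
        parent_a.panel,
        child,
        (parent_a.profile_id, parent_b.profile_id),
        generation_tag="child",
    )


# ---------------------------------------------------------------------------
# one-step mutation


@dataclass(frozen=True)
class MutationSpec:
    """One-step mutation model for child-generation profiles.

    ``rate`` is the per-locus mutation probability per transmission (both
    allele columns together); the forensic consensus value 1e-3 translates to
    one mutation per 2,000 entries in each allele column. Under the
    ``deterministic-stride`` policy every ``round(2/rate)``-th entry of each
    column mutates, scanning top to bottom; under ``bernoulli`` each entry
    mutates independently with probability ``rate / 2``. A mutation shifts the
    allele by ``step`` repeat units, direction chosen uniformly, reflected
    upward when the result would be non-positive; the fractional part of
    microvariants is preserved.
    """

    rate: float = 1e-3
    step: float = 1.0
    policy: str = "deterministic-stride"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")
        if self.step < 1:
            raise ValueError(f"mutation step must be >= 1, got {self.step}")
        if self.policy not in ("deterministic-stride", "bernoulli"):
            raise ValueError(f"unknown mutation policy {self.policy!r}")


def _mutate_values(
    values: np.ndarray, spec: MutationSpec, rng: np.random.Generator
) -> np.ndarray:
    out = values.copy()
    n, L, _ = out.shape
    if spec.rate == 0 or n == 0:
        return out
    mask = np.zeros((n, L, 2), dtype=bool)
    if spec.policy == "deterministic-stride":
        stride = int(round(2.0 / spec.rate))
        for col in (0, 1):
            # scan each allele column top-to-bottom, mutating every stride-th
            # entry; the second column is offset by half a stride so the locus
            # as a whole mutates once per 1/rate profiles without ever placing
            # two mutations in the same profile
            start = stride - 1 - col * (stride // 2)
            hit_rows = np.arange(start, n, stride)
            mask[hit_rows, :, col] = True
    else:
        mask = rng.random(size=(n, L, 2)) < spec.rate / 2.0
    signs = np.where(rng.random(size=mask.shape) < 0.5, -1.0, 1.0)
    delta = np.where(mask, signs * spec.step, 0.0)
    mutated = out + delta
    # reflect to an upward step when the shifted allele would leave the scale
    bad = mask & (mutated <= 0)
    mutated[bad] = out[bad] + spec.step
    mutated.sort(axis=2)
    return mutated


def apply_one_step_mutation(
    profiles: "ProfileSet | Iterable[Profile]",
    spec: MutationSpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ProfileSet:
    """Return a mutated copy of child-generation profiles; input unmodified."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if not isinstance(profiles, ProfileSet):
        profiles = list(profiles)
        if not profiles:
            raise ValueError("no profiles to mutate")
        panel = profiles[0].panel
        values = np.stack([p.values for p in profiles])
        profiles = ProfileSet(
            panel,
            values,
            [p.profile_id for p in profiles],
            [p.parent_ids for p in profiles],
            profiles[0].generation_tag,
        )
    if len(profiles) == 0:
        raise ValueError("no profiles to mutate")
    return ProfileSet(
        profiles.panel,
        _mutate_values(profiles.values, spec, rng),
        profiles.ids,
        profiles.parents,
        profiles.generation_tag,
    )


# ---------------------------------------------------------------------------
# cohort


class SimulationCohort:
    """Founders, families, sib pairs and the four category pair sets."""

    def __init__(
        self,
        table: FrequencyTable,
        founders: ProfileSet,
        children: ProfileSet,
        family_children: np.ndarray,  # (n_fam, 4) indices into children
        family_parents: np.ndarray,  # (n_fam, 2) indices into founders
        sib_pairs: np.ndarray,  # (n_sib, 2) indices into children
        category_pairs: dict[KinshipCategory, PairSet],
        seed: int,
    ) -> None:
        self.table = table
        self.founders = founders
        self.children = children
        self.family_children = family_children
        self.family_parents = family_parents
        self.sib_pairs = sib_pairs
        self.category_pairs = category_pairs
        self.seed = seed

    @property
    def panel(self) -> MarkerPanel:
        return self.founders.panel

    @property
    def n_families(self) -> int:
        return self.family_parents.shape[0]

    def pairs(self, category: KinshipCategory | str) -> PairSet:
        return self.category_pairs[KinshipCategory(category)]

    def subset_markers(self, markers: Sequence[str]) -> "SimulationCohort":
        return SimulationCohort(
            self.table.subset(list(markers)) if set(markers) <= set(self.table.locus_names) else self.table,
            self.founders.subset_markers(markers),
            self.children.subset_markers(markers),
            self.family_children,
            self.family_parents,
            self.sib_pairs,
            {c: ps.subset_markers(markers) for c, ps in self.category_pairs.items()},
            self.seed,
        )

    def counts(self) -> dict[str, int]:
        return {
            "founders": len(self.founders),
            "families": self.n_families,
            "children": len(self.children),
            "NormalPaternity": len(self.pairs(KinshipCategory.NORMAL_PATERNITY)),
            "NormalSibs": len(self.pairs(KinshipCategory.NORMAL_SIBS)),
            "IncestPaternity": len(self.pairs(KinshipCategory.INCEST_PATERNITY)),
            "IncestSibs": len(self.pairs(KinshipCategory.INCEST_SIBS)),
        }


_SIB_COMBOS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def simulate_cohort(
    table: FrequencyTable, n_founders: int, seed: int = 0
) -> SimulationCohort:
    """Simulate the full four-category cohort from one frequency table.

    Founders are shuffled and paired adjacently into ``n_founders / 2``
    families of four children each. ``n_founders`` must be even; identical
    seeds reproduce identical cohorts.
    """
    if n_founders < 2 or n_founders % 2 != 0:
        raise ValueError(f"n_founders must be even and >= 2, got {n_founders}")
    rng = np.random.default_rng(seed)
    founders = sample_founders(table, n_founders, rng)
    panel = founders.panel
    n_fam = n_founders // 2

    order = rng.permutation(n_founders)
    family_parents = order.reshape(n_fam, 2)
    pa = founders.values[family_parents[:, 0]]
    pb = founders.values[family_parents[:, 1]]

    # four children per family, stored family-major
    child_vals = np.empty((n_fam, 4, len(panel), 2), dtype=float)
    for k in range(4):
        child_vals[:, k] = _cross_values(pa, pb, rng)
    children_flat = child_vals.reshape(n_fam * 4, len(panel), 2)
    child_ids = [f"C{f}_{k}" for f in range(n_fam) for k in range(4)]
    child_parents = [
        (founders.ids[family_parents[f, 0]], founders.ids[family_parents[f, 1]])
        for f in range(n_fam)
        for _ in range(4)
    ]
    children = ProfileSet(panel, children_flat, child_ids, child_parents, "child")
    family_children = np.arange(n_fam * 4).reshape(n_fam, 4)

    # NormalPaternity: each of the 2 parents paired with each of the 4 children
    par_idx = np.repeat(family_parents, 4, axis=0).reshape(n_fam, 2, 4)
    np_mother = family_parents[:, :, None].repeat(4, axis=2).reshape(-1)
    np_child = family_children[:, None, :].repeat(2, axis=1).reshape(-1)
    del par_idx
    fam8 = np.repeat(np.arange(n_fam), 8)
    np_pairs = PairSet(
        KinshipCategory.NORMAL_PATERNITY,
        panel,
        founders.values[np_mother],
        children.values[np_child],
        [founders.ids[i] for i in np_mother],
        [children.ids[i] for i in np_child],
        fam8,
    )

    # NormalSibs: the 6 unordered child pairs per family
    combos = np.array(_SIB_COMBOS)
    sib_i = family_children[:, combos[:, 0]].reshape(-1)
    sib_j = family_children[:, combos[:, 1]].reshape(-1)
    sib_pairs = np.stack([sib_i, sib_j], axis=1)
    fam6 = np.repeat(np.arange(n_fam), 6)
    ns_pairs = PairSet(
        KinshipCategory.NORMAL_SIBS,
        panel,
        children.values[sib_i],
        children.values[sib_j],
        [children.ids[i] for i in sib_i],
        [children.ids[i] for i in sib_j],
        fam6,
    )

    # IncestPaternity: offspring of each (parent, child) mating; the designated
    # mother is the younger-generation member (e.g. the daughter in
    # father-daughter incest)
    ip_child_vals = _cross_values(
        founders.values[np_mother], children.values[np_child], rng
    )
    ip_pairs = PairSet(
        KinshipCategory.INCEST_PATERNITY,
        panel,
        children.values[np_child],
        ip_child_vals,
        [children.ids[i] for i in np_child],
        [f"IP{i}" for i in range(len(np_child))],
        fam8,
    )

    # IncestSibs: offspring of each sib mating; mother = first-listed sibling
    is_child_vals = _cross_values(children.values[sib_i], children.values[sib_j], rng)
    is_pairs = PairSet(
        KinshipCategory.INCEST_SIBS,
        panel,
        children.values[sib_i],
        is_child_vals,
        [children.ids[i] for i in sib_i],
        [f"IS{i}" for i in range(len(sib_i))],
        fam6,
    )

    return SimulationCohort(
        table,
        founders,
        children,
        family_children,
        family_parents,
        sib_pairs,
        {
            KinshipCategory.NORMAL_PATERNITY: np_pairs,
            KinshipCategory.NORMAL_SIBS: ns_pairs,
            KinshipCategory.INCEST_PATERNITY: ip_pairs,
            KinshipCategory.INCEST_SIBS: is_pairs,
        },
        seed,
    )


def mutate_cohort_children(
    cohort: SimulationCohort, spec: MutationSpec, seed: int = 0
) -> SimulationCohort:
    """Apply the one-step mutation model to every child-generation profile.

    The child member of each category pair (the children of the normal
    families and the incest offspring) is mutated; founder profiles are not.
    Pair bookkeeping is preserved.
    """
    rng = np.random.default_rng(seed)
    children = apply_one_step_mutation(cohort.children, spec, rng)

    # rebuild pair sets against the mutated children arrays using the stored
    # index structure rather than per-id lookup
    family_children = cohort.family_children
    family_parents = cohort.family_parents
    np_mother = family_parents[:, :, None].repeat(4, axis=2).reshape(-1)
    np_child = family_children[:, None, :].repeat(2, axis=1).reshape(-1)
    sib_i = cohort.sib_pairs[:, 0]
    sib_j = cohort.sib_pairs[:, 1]

    old = cohort.category_pairs
    np_old = old[KinshipCategory.NORMAL_PATERNITY]
    ns_old = old[KinshipCategory.NORMAL_SIBS]
    ip_old = old[KinshipCategory.INCEST_PATERNITY]
    is_old = old[KinshipCategory.INCEST_SIBS]

    ip_child = apply_one_step_mutation(
        ProfileSet(cohort.panel, ip_old.child_values, ip_old.child_ids or [str(i) for i in range(len(ip_old))], generation_tag="incest_offspring"),
        spec,
        rng,
    ).values
    is_child = apply_one_step_mutation(
        ProfileSet(cohort.panel, is_old.child_values, is_old.child_ids or [str(i) for i in range(len(is_old))], generation_tag="incest_offspring"),
        spec,
        rng,
    ).values

    pairs = {
        KinshipCategory.NORMAL_PATERNITY: PairSet(
            KinshipCategory.NORMAL_PATERNITY,
            cohort.panel,
            cohort.founders.values[np_mother],
            children.values[np_child],
            np_old.mother_ids,
            np_old.child_ids,
            np_old.family,
        ),
        KinshipCategory.NORMAL_SIBS: PairSet(
            KinshipCategory.NORMAL_SIBS,
            cohort.panel,
            children.values[sib_i],
            children.values[sib_j],
            ns_old.mother_ids,
            ns_old.child_ids,
            ns_old.family,
        ),
        KinshipCategory.INCEST_PATERNITY: PairSet(
            KinshipCategory.INCEST_PATERNITY,
            cohort.panel,
            children.values[np_child],
            ip_child,
            ip_old.mother_ids,
            ip_old.child_ids,
            ip_old.family,
        ),
        KinshipCategory.INCEST_SIBS: PairSet(
            KinshipCategory.INCEST_SIBS,
            cohort.panel,
            children.values[sib_i],
            is_child,
            is_old.mother_ids,
            is_old.child_ids,
            is_old.family,
        ),
    }
    return SimulationCohort(
        cohort.table,
        cohort.founders,
        children,
        family_children,
        family_parents,
        cohort.sib_pairs,
        pairs,
        cohort.seed,
    )
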