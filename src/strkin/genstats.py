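"""Consanguinity statistics for STR profile pairs.

Profile similarity between two genotypes is the multiset-intersection size of
the two allele pairs, summed over loci and expressed as a percentage of the
2L allele slots: identical profiles score 100, profiles sharing no allele
score 0, and an un-mutated parent-child pair scores at least 50 because one
allele per locus is inherited. On realistic autosomal panels random-mating
parent-child pairs sit near 60% while mother-child pairs involving an
incest-conceived child run roughly ten points higher, driven by the extra
identity-by-descent alleles.

The module also provides the analytic oracles used to validate the simulator:
expected homozygosity under an inbreeding coefficient F,
``sum(p^2) + F * (1 - sum(p^2))``, and the exact expectation of pair
similarity for each relationship, obtained by enumerating founder allele
draws and Mendelian transmissions per locus (Monte Carlo with a reported
standard error when a locus has too many alleles to enumerate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .freqdb import FrequencyTable, LocusDistribution
from .pedsim import PairSet, Profile, ProfileSet

__all__ = [
    "SimilarityReport",
    "MarkerPanelStats",
    "profile_similarity",
    "pair_similarities",
    "similarity_report",
    "homozygosity_by_marker",
    "identical_heterozygous_fraction",
    "expected_homozygosity",
    "expected_pair_similarity",
]


# ---------------------------------------------------------------------------
# observed statistics


def _shared_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Multiset-intersection size of allele pairs, shape (n, L) in {0, 1, 2}.

    For two-element multisets the intersection size is the better of the two
    possible matchings, which avoids building actual multisets.
    """
    m1 = (a[..., 0] == b[..., 0]).astype(np.int8) + (a[..., 1] == b[..., 1])
    m2 = (a[..., 0] == b[..., 1]).astype(np.int8) + (a[..., 1] == b[..., 0])
    return np.maximum(m1, m2)


def pair_similarities(mother_values: np.ndarray, child_values: np.ndarray) -> np.ndarray:
    """Per-pair similarity percent for genotype arrays shaped (n, L, 2)."""
    if mother_values.shape != child_values.shape:
        raise ValueError("genotype arrays differ in shape")
    shared = _shared_counts(mother_values, child_values)
    L = mother_values.shape[1]
    return 100.0 * shared.sum(axis=1) / (2.0 * L)


def profile_similarity(a: Profile, b: Profile) -> float:
    """Similarity percent between two profiles on the same marker panel."""
    if a.panel.loci != b.panel.loci:
        raise ValueError("profiles are typed on different marker panels")
    return float(pair_similarities(a.values[None], b.values[None])[0])


@dataclass
class SimilarityReport:
    """Per-pair similarities with their category mean and standard error."""

    category: str
    similarities: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.similarities.mean())

    @property
    def se(self) -> float:
        n = len(self.similarities)
        return float(self.similarities.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    def __len__(self) -> int:
        return len(self.similarities)


def similarity_report(pairs: PairSet) -> SimilarityReport:
    return SimilarityReport(
        category=str(pairs.category.value),
        similarities=pair_similarities(pairs.mother_values, pairs.child_values),
    )


@dataclass
class MarkerPanelStats:
    """A per-locus fraction (homozygosity or identical-heterozygous rate)."""

    category: str
    loci: tuple[str, ...]
    fractions: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.loci, map(float, self.fractions)))

    @property
    def mean(self) -> float:
        return float(self.fractions.mean())


def homozygosity_by_marker(
    profiles: ProfileSet, category: str = ""
) -> MarkerPanelStats:
    """Fraction of profiles that are homozygous, per locus."""
    if len(profiles) == 0:
        raise ValueError("no profiles")
    hom = profiles.values[:, :, 0] == profiles.values[:, :, 1]
    return MarkerPanelStats(
        category or profiles.generation_tag, profiles.panel.loci, hom.mean(axis=0)
    )


def identical_heterozygous_fraction(pairs: PairSet) -> MarkerPanelStats:
    """Per-locus fraction of pairs that are both heterozygous with the same
    allele pair (sorted pairs are identical iff equal slot-wise)."""
    if len(pairs) == 0:
        raise ValueError("no pairs")
    a, b = pairs.mother_values, pairs.child_values
    het_a = a[:, :, 0] != a[:, :, 1]
    het_b = b[:, :, 0] != b[:, :, 1]
    same = (a[:, :, 0] == b[:, :, 0]) & (a[:, :, 1] == b[:, :, 1])
    frac = (het_a & het_b & same).mean(axis=0)
    return MarkerPanelStats(str(pairs.category.value), pairs.panel.loci, frac)


# ---------------------------------------------------------------------------
# analytic oracles


def expected_homozygosity(locus: LocusDistribution, F: float = 0.0) -> float:
    """Expected homozygosity ``sum(p^2) + F * (1 - sum(p^2))``.

    ``F`` is the inbreeding coefficient: 0 for random mating, 1/4 for
    offspring of parent-child or full-sib matings.
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"inbreeding coefficient must be in [0, 1], got {F}")
    if not locus.is_normalized:
        raise ValueError(f"locus {locus.locus_name!r} is not normalized")
    h = locus.expected_homozygosity()
    return h + F * (1.0 - h)


RELATIONSHIPS = (
    "unrelated",
    "parent-child",
    "sibling",
    "incest-paternity",
    "incest-sibs",
)


@dataclass
class ExpectedSimilarity:
    """Oracle result: expected similarity percent with its standard error
    (zero when every locus was enumerated exactly)."""

    relationship: str
    percent: float
    se: float
    per_locus: dict[str, float]


def _pair_configs(relationship: str) -> list[tuple]:
    """Transmission configurations for one locus.

    Founder allele draws are labelled f1, f2 (one founder) and m1, m2 (the
    other); each configuration fixes which of those alleles each transmitted
    slot copies, and all configurations at a given relationship are
    equiprobable. Each entry is (pair_x_slots, pair_y_slots) where a slot is a
    source index into the draw tuple (f1, f2, m1, m2).
    """
    F1, F2, M1, M2 = 0, 1, 2, 3
    configs = []
    if relationship == "unrelated":
        configs.append(((F1, F2), (M1, M2)))
    elif relationship == "parent-child":
        # pair = (mother M, child C); child takes one paternal, one maternal allele
        for cf in (F1, F2):
            for cm in (M1, M2):
                configs.append((((M1, M2)), (cf, cm)))
    elif relationship == "sibling":
        for a1 in (F1, F2):
            for b1 in (M1, M2):
                for a2 in (F1, F2):
                    for b2 in (M1, M2):
                        configs.append(((a1, b1), (a2, b2)))
    elif relationship == "incest-paternity":
        # daughter D of founders F, M; offspring O of father F x daughter D;
        # pair = (D, O)
        for df in (F1, F2):
            for dm in (M1, M2):
                for of in (F1, F2):
                    for od in (df, dm):  # O's second allele copies one of D's
                        configs.append((((df, dm)), (of, od)))
    elif relationship == "incest-sibs":
        # sibs S1, S2 of founders F, M; offspring O of S1 x S2; pair = (S1, O)
        for a1 in (F1, F2):
            for b1 in (M1, M2):
                for a2 in (F1, F2):
                    for b2 in (M1, M2):
                        for o1 in (a1, b1):
                            for o2 in (a2, b2):
                                configs.append(((a1, b1), (o1, o2)))
    else:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}"
        )
    return configs


def _enumerate_locus(locus: LocusDistribution, relationship: str) -> float:
    """Exact E[shared alleles]/2 at one locus by enumerating allele draws."""
    p = np.asarray(locus.frequencies, dtype=float)
    k = len(p)
    # joint probability of the four independent founder allele draws
    P = (
        p[:, None, None, None]
        * p[None, :, None, None]
        * p[None, None, :, None]
        * p[None, None, None, :]
    )
    idx = np.indices((k, k, k, k))  # draw index grids for (f1, f2, m1, m2)
    configs = _pair_configs(relationship)
    acc = 0.0
    for (x1, x2), (y1, y2) in configs:
        X1, X2 = idx[x1], idx[x2]
        Y1, Y2 = idx[y1], idx[y2]
        m1 = (X1 == Y1).astype(np.int8) + (X2 == Y2)
        m2 = (X1 == Y2).astype(np.int8) + (X2 == Y1)
        shared = np.maximum(m1, m2)
        acc += float((P * shared).sum())
    return acc / len(configs) / 2.0


def _simulate_locus(
    locus: LocusDistribution, relationship: str, n: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte Carlo fallback: mean and SE of shared-fraction at one locus."""
    p = np.asarray(locus.frequencies, dtype=float)
    vals = locus.values
    draws = rng.choice(vals, size=(n, 4), p=p)  # f1 f2 m1 m2
    configs = _pair_configs(relationship)
    pick = rng.integers(0, len(configs), size=n)
    x = np.empty((n, 2))
    y = np.empty((n, 2))
    cfg = np.array([[c[0][0], c[0][1], c[1][0], c[1][1]] for c in configs])
    chosen = cfg[pick]
    rows = np.arange(n)
    x[:, 0] = draws[rows, chosen[:, 0]]
    x[:, 1] = draws[rows, chosen[:, 1]]
    y[:, 0] = draws[rows, chosen[:, 2]]
    y[:, 1] = draws[rows, chosen[:, 3]]
    m1 = (x[:, 0] == y[:, 0]).astype(np.int8) + (x[:, 1] == y[:, 1])
    m2 = (x[:, 0] == y[:, 1]).astype(np.int8) + (x[:, 1] == y[:, 0])
    shared = np.maximum(m1, m2) / 2.0
    return float(shared.mean()), float(shared.std(ddof=1) / np.sqrt(n))


def expected_pair_similarity(
    table: FrequencyTable,
    relationship: str,
    max_enum_alleles: int = 30,
    mc_pairs: int = 200_000,
    seed: int = 0,
) -> ExpectedSimilarity:
    """Expected profile-similarity percent under a named relationship.

    Loci with at most ``max_enum_alleles`` alleles are enumerated exactly
    (the allele-draw grid is k^4, tractable for forensic-size loci); larger
    loci fall back to seeded Monte Carlo over ``mc_pairs`` transmissions and
    contribute to the reported standard error.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(
            f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}"
        )
    if not table.is_normalized:
        raise ValueError("table must be normalized")
    rng = np.random.default_rng(seed)
    per_locus: dict[str, float] = {}
    variances = []
    for locus in table.loci:
        if len(locus) <= max_enum_alleles:
            mean = _enumerate_locus(locus, relationship)
            var = 0.0
        else:
            mean, se = _simulate_locus(locus, relationship, mc_pairs, rng)
            var = se**2
        per_locus[locus.locus_name] = 100.0 * mean
        variances.append(var)
    L = len(table.loci)
    percent = float(np.mean(list(per_locus.values())))
    se = 100.0 * float(np.sqrt(np.sum(variances)) / L)
    return ExpectedSimilarity(relationship, percent, se, per_locus)
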