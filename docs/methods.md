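# Methods

## Population model and simulator

A population is a set of per-locus categorical allele distributions
(`FrequencyTable`). Alleles are STR repeat numbers kept as text labels with a
numeric shadow value, so microvariants such as TH01 9.3 survive round-trips
and still order and mutate numerically. Loci are treated as unlinked and
mutually independent, and genotype frequencies follow Hardy–Weinberg
equilibrium: a founder is two independent allele draws per locus. Both
assumptions are standard for autosomal forensic STR panels (the markers sit
on different chromosomes or far apart) and are what make the per-locus
enumeration oracles exact.

From `n` founders the cohort builder creates `n/2` families by a seeded
shuffle and adjacent pairing, four children per family via Mendelian
transmission (one uniformly chosen allele from each parent per locus), and
four category pair sets:

| category | construction | pairs per family |
|---|---|---|
| NormalPaternity | each parent × each child | 8 |
| NormalSibs | all unordered child pairs | 6 |
| IncestPaternity | offspring of each parent×child mating, paired with the younger-generation mate as mother | 8 |
| IncestSibs | offspring of each sib×sib mating, paired with the first-listed sibling as mother | 6 |

Parental sex is bookkeeping only — autosomal genotypes are symmetric in
parental origin — so "the daughter in father–daughter incest" is a naming
convention fixed for reproducibility, and all parent–child combinations are
mated rather than only father–daughter ones. Offspring of parent–child and
of full-sib matings both have inbreeding coefficient F = 1/4, which yields
the two analytic oracles used throughout the tests:

* expected homozygosity `Σp² + F(1 − Σp²)` per locus;
* expected pair similarity per relationship, computed exactly by enumerating
  the four founder allele draws (a k⁴ grid per locus) and every equiprobable
  transmission configuration. Loci with more than 30 alleles (above any real
  forensic locus) fall back to seeded Monte Carlo with a reported standard
  error.

Profile similarity itself is `100 · Σ_loci |multiset ∩ of the two allele
pairs| / (2L)`. Among simple candidates it is the only one consistent with a
~60% random-mating parent–child baseline: a "≥1 shared allele per locus"
score floors at 50%, genotype identity sits far lower. Identical profiles
score 100, disjoint ones 0, and an un-mutated parent–child pair at least 50.

## One-step mutation model

STR transmissions mutate at roughly 10⁻³ per locus, almost always by a
single repeat unit. `MutationSpec(rate, step, policy)` implements this with
the per-locus rate as the knob. Under the default `deterministic-stride`
policy each allele column is scanned top to bottom and every
`round(2/rate)`-th entry is shifted by ±`step` (sign uniform, reflected
upward at the low boundary, fractional part preserved), with the second
column offset by half a stride so a locus mutates once per `1/rate` profiles
and never twice in one profile. The stride policy makes the mutation count
exact and testable (2,000 profiles × 1 locus at rate 10⁻³ → exactly 2
events); the `bernoulli` policy (each entry independently at `rate/2`) is the
realistic alternative. Mutation is applied to child-generation profiles —
the family children and the incest offspring — never to founders.

## Datasets and the split

The **pair** design has one row per (mother, child) pair: all normal
parent–child pairs form the negative class, and equal seeded quotas from the
two incest categories (default: half the normal count from each) form the
balanced positive class. Features are the mother's then the child's
`<locus>_1/_2` columns — four categorical text columns per marker, 84 for a
21-marker panel. The **offspring-only** design keeps one row per child
profile: the child of every normal pairing plus the second member of each
sib pair against all incest offspring (350,000 per class at the 50,000
founder reference scale). Raw allele values are the features; engineered
statistics are deliberately not added, since the raw representation trains
better and keeps the model free of assumptions about which consanguinity
signal matters.

The default split is row-level, stratified by label, 90/5/5. **Caveat**: both
designs reuse each simulated individual across several rows (a child appears
in two parent–child pairs and three sib pairs), so a row-level split lets the
same profile inform training and test. `split_dataset(..., group="family")`
assigns whole source families to partitions instead, guaranteeing that no
profile crosses partitions. At 5,000 founders on the default synthetic table
the row-level split yields ~96% accuracy for both pair and offspring-only
models, while the leakage-free family split yields ~89% and ~82% — only
there does the expected "mother adds about five points over the child alone"
information gap become visible. The row-level split remains the default
because it is the protocol the reference results are defined on; the family
split is the appropriate choice when estimating generalization to new
families.

## Classifier

`train_classifier` fits a LightGBM gradient-boosted tree ensemble on the
categorical allele columns: binary log-loss objective, validation ROC AUC
monitoring, early stopping (default 50 rounds), `deterministic=True` and a
mandatory seed. Tuned defaults are 1,000 iterations, learning rate 0.1,
depth 10 (`num_leaves = 2^depth`, capped at 1,024); `grid_search` scores the
2×2×2 grid {500, 1000} × {0.01, 0.1} × {6, 10} on validation AUC with
deterministic tie-breaks (fewest iterations, then smallest depth). The
positive class is IncestKinship everywhere; `ModelMetrics` stores the 2×2
confusion matrix and derives every scalar from it (accuracy, balanced
accuracy, precision/PPV, recall/detection rate, specificity, NPV, F1,
FPR, FNR, MCC, Cohen's kappa), keeping the panel exactly self-consistent;
ROC AUC and the ROC/PR curves come from the ranked scores.
`benchmark_models` runs off-the-shelf sklearn/XGBoost/LightGBM learners with
library defaults on numerically encoded features; a learner whose import
fails (e.g. CatBoost when not installed) is skipped with a warning.
`feature_importance` sums per-column gains over each marker's four columns
and normalizes to 100; `pca_summary` is a standardized principal-component
decomposition of the numerically encoded feature table.

## Synthetic study conditions

The built-in generator emulates a population frequency table: per locus,
`alleles_per_locus` consecutive integer repeat numbers starting at a random
offset in [5, 20], frequencies from a symmetric Dirichlet. The defaults —
21 loci, 10 alleles, concentration 1.0 — give expected homozygosity
Σp² ≈ 2/(k+1) ≈ 0.18, i.e. locus diversity in the range of real autosomal
forensic panels, and similarity/homozygosity statistics land in the bands
reported for real general-population tables (parent–child ≈ 59%, incest
pairs ≈ 70%, incest-offspring homozygosity ≈ 39%). What the generator does
*not* emulate: microvariant alleles (integer repeats only), the skewed
unimodal allele-frequency shapes of particular real loci, population
substructure or linkage, and genotyping artifacts (dropout, stutter). Tests
passing on synthetic tables therefore demonstrate that the method recovers
the consanguinity signal implied by the model assumptions, not that a model
trained on synthetic data transfers to a specific real population — for
casework the classifier must be retrained on that population's frequency
table.

Reference problem sizes: structural checks run at the full 50,000-founder
scale; statistical oracle checks at 20,000 founders (3-standard-error
bands); classifier runs at 5,000 founders (40,000 pair rows), where test
accuracy is already within a point or two of the full-scale value. These
sizes were chosen so the whole suite re-runs comfortably on a single CPU.

## Numerical choices and degenerate inputs

Frequencies must be strictly positive; normalization is per locus (the only
reading that yields valid per-locus sampling distributions) to within 1e-9,
and the rare-allele filter takes a *threshold* (`frequency ≤ 0.002`) rather
than an enumerated value set, erroring if a locus would lose all alleles.
Allele pairs are stored sorted ascending (the smaller/larger column
convention); ties are genuine homozygotes. The similarity multiset
intersection uses the max-of-two-matchings identity, exact for pairs.
Seeds propagate through `numpy.random.default_rng`; every public entry point
that consumes randomness takes an explicit seed or Generator, and equal
seeds reproduce byte-identical cohorts, datasets and (with
`deterministic=True`) models.

## Known limitations

* Only two incest types (parent–child, full-sib) are simulated; avuncular or
  more distant consanguinity is out of scope, as is any multiclass incest
  subtyping.
* No likelihood-ratio kinship indices are computed; the classifier is a
  screening signal, not a weight of evidence.
* The one-step stride policy is a deterministic idealization; real mutation
  is stochastic and locus-dependent.
* X-chromosomal and SNP markers, linkage, and population substructure within
  one table are not modeled.
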