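"""End-to-end experiment runner: table -> cohort -> statistics -> model.

An :class:`ExperimentConfig` captures everything a run needs (frequency table
or synthetic-table spec, cohort size, marker panel, mutation model, dataset
design, split fractions, hyperparameters or grid, seed) and round-trips
through YAML. ``run_experiment`` writes every artifact under the output
directory so each reported number can be re-derived from the bundle's files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    assemble_offspring_only,
    assemble_pair_dataset,
    split_dataset,
)
from .freqdb import (
    FrequencyTable,
    filter_rare_alleles,
    normalize_frequencies,
    read_frequency_table,
    synth_frequency_table,
    write_frequency_table,
)
from .genstats import (
    homozygosity_by_marker,
    identical_heterozygous_fraction,
    similarity_report,
)
from .mlpipe import (
    Hyperparameters,
    evaluate,
    feature_importance,
    grid_search,
    train_classifier,
)
from .pedsim import KinshipCategory, MutationSpec, mutate_cohort_children, simulate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "report"]

logger = logging.getLogger("strkin")


@dataclass
class ExperimentConfig:
    """One reproducible experiment; everything is derived from the seed."""

    seed: int
    n_founders: int = 1000
    frequency_table: str | None = None  # path to a locus,allele,frequency CSV
    population_id: str = "synthetic"
    synth: dict = field(
        default_factory=lambda: {"n_loci": 21, "alleles_per_locus": 10, "concentration": 1.0}
    )
    filter_rare: float | None = None  # e.g. 0.002 to drop rare alleles
    markers: list[str] | None = None  # subset panel, None = full panel
    mutation: dict | None = None  # {"rate": 1e-3, "step": 1, "policy": ...}
    dataset: str = "pair"  # "pair" | "offspring-only"
    split: tuple[float, float, float] = (0.90, 0.05, 0.05)
    hyperparameters: dict | None = None  # None = tuned defaults
    grid: dict | None = None  # set to run a grid search instead
    similarity_pairs: int | None = None  # subsample per category, None = all

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.split = tuple(self.split)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["split"] = list(self.split)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _load_table(config: ExperimentConfig) -> FrequencyTable:
    if config.frequency_table:
        table = read_frequency_table(config.frequency_table, config.population_id)
    else:
        table = synth_frequency_table(
            seed=config.seed, population_id=config.population_id, **config.synth
        )
    table = normalize_frequencies(table)
    if config.filter_rare is not None:
        table = filter_rare_alleles(table, config.filter_rare)
    return table


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and write the result bundle.

    Bundle contents: the config, the (normalized, possibly filtered) frequency
    table, cohort counts, similarity/homozygosity/identical-heterozygous
    tables, the dataset manifest, the trained model, the metric panel with its
    confusion matrix, ROC/PR curve points, marker importances, and a run log.
    A failed run leaves an ``INCOMPLETE`` marker in the directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        import strkin

        config.to_yaml(out / "config.yaml")
        logger.info("strkin %s, seed %d", strkin.__version__, config.seed)

        table = _load_table(config)
        write_frequency_table(table, out / "frequency_table.csv")
        logger.info("frequency table: %s", table)

        cohort = simulate_cohort(table, config.n_founders, seed=config.seed)
        if config.markers:
            cohort = cohort.subset_markers(config.markers)
        if config.mutation:
            cohort = mutate_cohort_children(
                cohort, MutationSpec(**config.mutation), seed=config.seed + 1
            )
        counts = cohort.counts()
        (out / "cohort_counts.json").write_text(json.dumps(counts, indent=2))
        logger.info("cohort: %s", counts)

        _write_stats(cohort, config, out)

        if config.dataset == "pair":
            ds = assemble_pair_dataset(cohort, seed=config.seed)
        elif config.dataset == "offspring-only":
            ds = assemble_offspring_only(cohort, seed=config.seed)
        else:
            raise ValueError(f"unknown dataset design {config.dataset!r}")
        ds = split_dataset(ds, config.split, seed=config.seed)
        (out / "dataset_manifest.json").write_text(json.dumps(ds.manifest(), indent=2))
        logger.info("dataset: %s", ds.manifest())

        train = ds.partition("train")
        validation = ds.partition("validation")
        test = ds.partition("test")
        if config.grid:
            hp, scores = grid_search(train, validation, config.grid, seed=config.seed)
            scores.to_csv(out / "grid_scores.csv", index=False)
            logger.info("grid best: %s", hp)
        else:
            hp = Hyperparameters(**(config.hyperparameters or {}))
        model = train_classifier(train, validation, hp, seed=config.seed)
        model.save(out)
        metrics = evaluate(model, test)
        payload = {
            "confusion_matrix": metrics.confusion(),
            "metrics": metrics.scalars(),
            "best_iteration": model.best_iteration,
            "hyperparameters": dataclasses.asdict(hp),
        }
        (out / "metrics.json").write_text(json.dumps(payload, indent=2))
        if metrics.roc_points is not None:
            pd.DataFrame(metrics.roc_points, columns=["fpr", "tpr"]).to_csv(
                out / "roc_points.csv", index=False
            )
            pd.DataFrame(metrics.pr_points, columns=["recall", "precision"]).to_csv(
                out / "pr_points.csv", index=False
            )
        feature_importance(model).to_csv(out / "importances.csv", index=False)
        logger.info("test accuracy %.4f, AUC %.4f", metrics.accuracy, metrics.roc_auc)

        marker.unlink()
        logger.info("completed in %.1fs", time.time() - t0)
        return out
    except Exception:
        logger.exception("experiment failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_stats(cohort, config: ExperimentConfig, out: Path) -> None:
    """Similarity block and per-marker consanguinity statistics as flat tables."""
    rng = np.random.default_rng(config.seed + 2)
    sim_rows = []
    stat_rows = []
    for category in KinshipCategory:
        pairs = cohort.pairs(category)
        if config.similarity_pairs and config.similarity_pairs < len(pairs):
            pairs = pairs.sample(config.similarity_pairs, rng)
        rep = similarity_report(pairs)
        sim_rows.append(
            {
                "category": rep.category,
                "n_pairs": len(rep),
                "mean_similarity_pct": rep.mean,
                "se": rep.se,
            }
        )
        het = identical_heterozygous_fraction(pairs)
        stat_rows.extend(
            {
                "category": het.category,
                "locus": locus,
                "statistic": "identical_heterozygous_fraction",
                "value": value,
            }
            for locus, value in het.as_dict().items()
        )
    hom_sets = {
        "founders": cohort.founders,
        "IncestPaternityOffspring": _offspring_set(cohort, KinshipCategory.INCEST_PATERNITY),
        "IncestSibsOffspring": _offspring_set(cohort, KinshipCategory.INCEST_SIBS),
    }
    for name, profiles in hom_sets.items():
        hom = homozygosity_by_marker(profiles, category=name)
        stat_rows.extend(
            {
                "category": name,
                "locus": locus,
                "statistic": "homozygosity_fraction",
                "value": value,
            }
            for locus, value in hom.as_dict().items()
        )
    pd.DataFrame(sim_rows).to_csv(out / "similarity.csv", index=False)
    pd.DataFrame(stat_rows).to_csv(out / "marker_stats.csv", index=False)


def _offspring_set(cohort, category):
    from .pedsim import ProfileSet

    pairs = cohort.pairs(category)
    return ProfileSet(
        pairs.panel,
        pairs.child_values,
        pairs.child_ids or [str(i) for i in range(len(pairs))],
        generation_tag="incest_offspring",
    )


def report(bundle_dir: str | Path, top_markers: int = 20) -> str:
    """Human-readable summary of a completed result bundle."""
    out = Path(bundle_dir)
    if (out / "INCOMPLETE").exists():
        raise ValueError(f"bundle {out} is marked incomplete")
    metrics_path = out / "metrics.json"
    if not metrics_path.exists():
        raise FileNotFoundError(f"missing metrics file: {metrics_path}")
    payload = json.loads(metrics_path.read_text())
    lines = [f"strkin experiment report: {out}", ""]
    cm = payload["confusion_matrix"]
    lines.append("Confusion matrix (positive = IncestKinship):")
    lines.append(f"  TP {cm['tp']:>8}   FN {cm['fn']:>8}")
    lines.append(f"  FP {cm['fp']:>8}   TN {cm['tn']:>8}")
    lines.append("")
    lines.append("Metric panel:")
    for key, value in payload["metrics"].items():
        lines.append(f"  {key:>18}: {100 * value:6.2f}%")
    sim_path = out / "similarity.csv"
    if sim_path.exists():
        lines.append("")
        lines.append("Average profile similarity by kinship category:")
        sim = pd.read_csv(sim_path)
        for _, row in sim.iterrows():
            lines.append(
                f"  {row['category']:>16}: {row['mean_similarity_pct']:6.2f}% "
                f"(n={int(row['n_pairs'])}, SE {row['se']:.3f})"
            )
    imp_path = out / "importances.csv"
    if imp_path.exists():
        lines.append("")
        lines.append(f"Top {top_markers} markers by importance:")
        imp = pd.read_csv(imp_path).head(top_markers)
        for _, row in imp.iterrows():
            lines.append(f"  {row['marker']:>12}: {row['importance']:6.2f}")
    return "\n".join(lines)
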