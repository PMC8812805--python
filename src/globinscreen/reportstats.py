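"""Descriptive statistics, task groupings and end-to-end orchestration.

Covers the Spearman feature-clinical correlation matrix, a standardised PCA
overview, the binary task definitions (screening, beta vs non-beta, alpha vs
non-alpha) and the full simulate -> process -> features -> select -> train ->
evaluate pipeline driven by one configuration mapping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import globin_features, screenmodels, spectra_io, specproc, synthcohort
from .globin_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("hb_g_l", "hbf_pct", "hba2_pct")

TASKS = ("thal_vs_control", "beta_vs_nonbeta", "alpha_vs_nonalpha")

_GENOTYPE_MAPS = {
    # (task) -> genotype_group -> 1/0; control rows are always mapped via 'none'
    "beta_vs_nonbeta": {"beta": 1, "alphabeta": 1, "alpha": 0, "none": 0},
    "alpha_vs_nonalpha": {"alpha": 1, "alphabeta": 1, "beta": 0, "none": 0},
}


class GroupingError(ValueError):
    """A manifest row cannot be mapped to a binary task label."""


@dataclasses.dataclass(frozen=True)
class GroupingRule:
    """Maps (class_label, genotype_group) to a binary task label."""

    task: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise GroupingError(f"unknown task {self.task!r}; expected one of {TASKS}")

    def label(self, class_label: str, genotype_group: str) -> int:
        if self.task == "thal_vs_control":
            return 1 if class_label == "thalassaemia" else 0
        mapping = _GENOTYPE_MAPS[self.task]
        if genotype_group not in mapping:
            raise GroupingError(
                f"genotype_group {genotype_group!r} not mapped for task {self.task}"
            )
        return mapping[genotype_group]


def apply_grouping(manifest: pd.DataFrame, rule: GroupingRule) -> pd.Series:
    """Binary label column for the task; errors list every unmapped genotype."""
    if rule.task != "thal_vs_control":
        if "genotype_group" not in manifest.columns:
            raise GroupingError(f"task {rule.task} requires a genotype_group column")
        known = set(_GENOTYPE_MAPS[rule.task])
        bad = sorted(set(manifest["genotype_group"].unique()) - known)
        if bad:
            raise GroupingError(
                f"unmapped genotype_group values for task {rule.task}: {bad}"
            )
    labels = [
        rule.label(row["class_label"], row.get("genotype_group", "none"))
        for _, row in manifest.iterrows()
    ]
    out = pd.Series(labels, index=manifest.index, name="task_label")
    logger.info(
        "task %s: %d positive, %d negative", rule.task, int(out.sum()), int((1 - out).sum())
    )
    return out


def spearman_matrix(
    feature_table: pd.DataFrame,
    clinical_columns: Sequence[str] = CLINICAL_COLUMNS,
    feature_columns: Sequence[str] = FEATURE_NAMES,
    min_pairs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every (feature, clinical) pair.

    Cells with a constant column or fewer than ``min_pairs`` complete pairs
    are masked as NaN. p-values come from the large-sample t approximation.
    """
    rho = pd.DataFrame(index=list(feature_columns), columns=list(clinical_columns), dtype=float)
    pval = rho.copy()
    for f in feature_columns:
        for c in clinical_columns:
            x = feature_table[f].to_numpy(dtype=float)
            y = feature_table[c].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_pairs or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho.loc[f, c] = np.nan
                pval.loc[f, c] = np.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho.loc[f, c] = r
            pval.loc[f, c] = p
    return rho, pval


def pca_overview(
    feature_table: pd.DataFrame,
    feature_columns: Sequence[str] = FEATURE_NAMES,
    standardize: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores and explained-variance fractions.

    Features are z-scored first by default. Fractions sum to 1; score signs
    are arbitrary.
    """
    X = feature_table.loc[:, list(feature_columns)].to_numpy(dtype=float)
    keep = ~np.isnan(X).any(axis=1)
    X = X[keep]
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 complete samples")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    fractions = s**2 / np.sum(s**2)
    scores = u * s
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    score_df = pd.DataFrame(scores, columns=cols)
    score_df.insert(0, "sample_id", feature_table.loc[keep, "sample_id"].to_numpy())
    return score_df, fractions


# ---------------------------------------------------------------------------
# pipeline orchestration


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohorts": {
        "cohort1": {"n_per_class": {"control": 35, "alpha_thal": 12, "beta_thal": 12, "alphabeta_compound": 6}},
        "cohort2": {"n_per_class": {"control": 35, "alpha_thal": 12, "beta_thal": 12, "alphabeta_compound": 6}},
    },
    "acquisition": {"sampling_step": 2.0, "noise_sd": 0.25},
    "profiles": {},
    "tasks": {
        "thal_vs_control": {"selection": {"top_k": 5}},
        "beta_vs_nonbeta": {"selection": {"auc_min": 0.85}},
    },
    "methods": list(screenmodels.METHOD_NAMES),
    "threshold": 0.5,
    "split": {"ratio": [2, 1]},
    "write_spectra": False,
}


def load_config(source: str | Path | Mapping) -> dict:
    """Load a pipeline configuration from YAML/JSON or a mapping, applying defaults."""
    if isinstance(source, (str, Path)):
        import yaml

        with open(source, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
    else:
        loaded = dict(source)
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in loaded.items():
        if key in ("cohorts", "tasks"):
            config[key] = val  # replace wholesale
        elif isinstance(val, dict) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown pipeline configuration keys: {sorted(unknown)}")
    return config


def _build_profiles(config: dict) -> dict[str, synthcohort.DiseaseProfile]:
    profiles = synthcohort.default_profiles()
    for name, overrides in (config.get("profiles") or {}).items():
        base = dataclasses.asdict(profiles[name])
        base.update(overrides)
        profiles[name] = synthcohort.DiseaseProfile(**base)
    return profiles


def simulate_and_featurize(
    config: dict,
    cohort_id: str,
    seed: int,
    out_dir: Optional[Path] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort, process every spectrum and assemble its feature table.

    Returns (feature_table, manifest); the manifest gains a qc_flags column.
    """
    panel = synthcohort.GlobinPanel()
    profiles = _build_profiles(config)
    acq = synthcohort.AcquisitionModel(**{
        k: tuple(v) if k == "mz_range" else v
        for k, v in (config.get("acquisition") or {}).items()
    })
    n_per_class = config["cohorts"][cohort_id]["n_per_class"]
    spectra, manifest = synthcohort.simulate_cohort(
        panel, profiles, n_per_class, acq, seed=seed, cohort_id=cohort_id
    )
    vectors: dict[str, Optional[globin_features.FeatureVector]] = {}
    qc: list[str] = []
    for spectrum in spectra:
        result = specproc.process_spectrum(spectrum, panel)
        if result.ok:
            vectors[spectrum.sample_id] = globin_features.compute_features(result.assignments)
        else:
            vectors[spectrum.sample_id] = None
        qc.append(";".join(result.qc_flags))
        if out_dir is not None and config.get("write_spectra"):
            spectra_io.write_spectrum(spectrum, Path(out_dir) / "spectra" / f"{spectrum.sample_id}.txt")
    manifest = manifest.assign(qc_flags=qc)
    table = globin_features.assemble_feature_table(manifest, vectors)
    # carry clinical covariates for downstream correlation analyses
    table = table.merge(
        manifest[["sample_id", *CLINICAL_COLUMNS]], on="sample_id", how="left"
    )
    return table, manifest


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> dict:
    """Run the whole study on synthetic cohorts and write a report bundle.

    Stages: simulate both cohorts, process spectra into features, then for
    each configured task derive binary labels, split cohort 1 at the
    configured ratio, train all methods and evaluate on train/test/validation.
    Fully reproducible from (config, seed).
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    cohort_ids = list(config["cohorts"])
    if len(cohort_ids) != 2:
        raise ValueError(f"pipeline expects exactly 2 cohorts, got {cohort_ids}")
    tables: dict[str, pd.DataFrame] = {}
    manifests: dict[str, pd.DataFrame] = {}
    for i, cohort_id in enumerate(cohort_ids):
        try:
            table, manifest = simulate_and_featurize(
                config, cohort_id, seed=seed + 1000 * i, out_dir=out_dir
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'simulate+process' failed for {cohort_id}") from exc
        tables[cohort_id] = table
        manifests[cohort_id] = manifest
        spectra_io.write_feature_table(table, out_dir / f"features_{cohort_id}.csv")
        spectra_io.write_manifest(manifest, out_dir / f"manifest_{cohort_id}.csv")

    discovery, validation = cohort_ids
    bundle: dict = {"feature_tables": tables, "manifests": manifests, "reports": {}, "best": {}}
    for task, task_cfg in config["tasks"].items():
        rule = GroupingRule(task)
        disc = tables[discovery].copy()
        valid = tables[validation].copy()
        disc["task_label"] = apply_grouping(disc, rule).to_numpy()
        valid["task_label"] = apply_grouping(valid, rule).to_numpy()
        plan = screenmodels.stratified_split(
            disc, ratio=tuple(config["split"]["ratio"]), seed=seed, stratify_on="task_label"
        )
        train = disc[disc["sample_id"].isin(plan.train_ids)]
        test = disc[disc["sample_id"].isin(plan.test_ids)]
        try:
            reports, best = screenmodels.run_model_suite(
                train,
                test,
                valid,
                selection_rule=task_cfg.get("selection", {"top_k": 5}),
                methods=config["methods"],
                seed=seed,
                threshold=config["threshold"],
                label_column="task_label",
                positive_label=1,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'model suite' failed for task {task}") from exc
        bundle["reports"][task] = reports
        bundle["best"][task] = best
        spectra_io.write_model_report(reports, out_dir / f"reports_{task}.json")

    rho, pval = spearman_matrix(tables[discovery])
    rho.to_csv(out_dir / "spearman_rho.csv")
    pval.to_csv(out_dir / "spearman_p.csv")
    bundle["spearman_rho"] = rho
    spectra_io.write_run_record(out_dir, dict(config), seed)
    summary = {
        "tasks": {t: {"best_method": bundle["best"][t]} for t in bundle["reports"]},
        "cohorts": {c: int(len(tables[c])) for c in cohort_ids},
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
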