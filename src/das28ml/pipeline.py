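"""End-to-end orchestration: scoring, structure, augmentation, selection, stats.

``run_pipeline`` executes the full analysis sequence on a cohort table
(loaded from CSV or generated synthetically) and writes every interface
file plus a manifest with versions, seeds and a config hash:

1. scoring       — DAS28-CRP and activity stage per patient
2. staging       — remission-vs-active labels (low + moderate merged;
                   the moderate group is too small to model separately)
3. pca           — correlation PCA of the four z-standardized components
4. esom          — [0,100] scaling, ESOM training, U/P/U* matrices
5. clustering    — U*-basin clusters and outliers, cluster-vs-stage test
6. augmentation  — density-guided equalization of cluster sizes
7. selection     — remission-vs-active item distillation (d = 58) and
                   one-vs-rest cluster attribution (d = 4)
8. associations  — drug-class and stage association statistics
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import chi2_test, kruskal_wallis, quartile_rescale
from .augment import AugmentationPlan, equalize_clusters
from .cohort import CohortConfig, cohort_to_frame, generate_cohort, inject_outliers
from .joints import (
    COMPONENT_NAMES,
    CRP_COLUMN,
    FEATURE_NAMES_58,
    GH_COLUMN,
    SWOLLEN_COLUMNS,
    TENDER_COLUMNS,
)
from .score import StageThresholds, score_frame
from .selection import (
    CVScheme,
    cabc,
    cluster_membership_importance,
    nested_cv_evaluate,
    permutation_importance,
    split_holdout,
    tune_and_train,
)
from .structure import (
    ESOMConfig,
    assign_bmus,
    cluster_stage_association,
    extract_clusters,
    pca_project,
    scale_0_100,
    structure_matrices,
    train_esom,
)

logger = logging.getLogger("das28ml.pipeline")

STAGE_SEQUENCE = (
    "scoring",
    "staging",
    "pca",
    "esom",
    "clustering",
    "augmentation",
    "selection",
    "associations",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one cohort source: a CSV path or a synthetic
    :class:`~das28ml.cohort.CohortConfig`.  The global seed propagates to
    every stochastic stage that does not carry its own explicit seed.
    """

    cohort_csv: str | None = None
    cohort: CohortConfig | None = None
    esom: ESOMConfig = field(default_factory=ESOMConfig)
    augmentation: AugmentationPlan = field(default_factory=AugmentationPlan)
    cv: CVScheme = field(default_factory=CVScheme)
    thresholds: StageThresholds = field(default_factory=StageThresholds)
    importance_repeats: int = 50
    min_cluster_size: int = 3
    output_dir: str = "das28ml_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.cohort is None):
            raise PipelineError(
                "config error: provide exactly one cohort source (cohort_csv or cohort)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("cohort_csv", "output_dir", "seed", "importance_repeats", "min_cluster_size"):
            if key in raw:
                kwargs[key] = raw[key]
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw["cohort"])
        if "esom" in raw:
            kwargs["esom"] = ESOMConfig(**raw["esom"])
        if "augmentation" in raw:
            kwargs["augmentation"] = AugmentationPlan(**raw["augmentation"])
        if "cv" in raw:
            kwargs["cv"] = CVScheme(**raw["cv"])
        if "thresholds" in raw:
            kwargs["thresholds"] = StageThresholds(**raw["thresholds"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        payload = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_input(csv_path: str | Path) -> dict:
    """Schema check of a cohort CSV: required columns, ranges, missingness."""
    try:
        frame = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:  # surfaced with pandas' line diagnostics
        raise PipelineError(f"malformed CSV {csv_path}: {exc}") from exc
    issues: list[str] = []
    required = ["patient_id", *TENDER_COLUMNS, *SWOLLEN_COLUMNS, CRP_COLUMN, GH_COLUMN]
    missing = [c for c in required if c not in frame.columns]
    for col in missing:
        issues.append(f"missing column: {col}")
    for col in (*TENDER_COLUMNS, *SWOLLEN_COLUMNS):
        if col in frame.columns and not frame[col].isin([0, 1, True, False]).all():
            issues.append(f"non-binary flag values in {col}")
    if CRP_COLUMN in frame.columns:
        if frame[CRP_COLUMN].isna().any():
            issues.append(f"missing values in {CRP_COLUMN}")
        elif (frame[CRP_COLUMN] < 0).any():
            issues.append(f"negative values in {CRP_COLUMN}")
    if GH_COLUMN in frame.columns:
        bad = ((frame[GH_COLUMN] < 0) | (frame[GH_COLUMN] > 100)).sum()
        if bad:
            issues.append(f"{bad} values outside [0, 100] in {GH_COLUMN}")
    return {
        "n_rows": int(frame.shape[0]),
        "n_columns": int(frame.shape[1]),
        "missing_columns": missing,
        "issues": issues,
        "ok": not issues,
    }


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.cohort_csv is not None:
        report = validate_input(config.cohort_csv)
        if not report["ok"]:
            raise PipelineError(f"input validation failed: {report['issues']}")
        return pd.read_csv(config.cohort_csv)
    cohort = generate_cohort(config.cohort)
    cohort = inject_outliers(cohort, config.cohort)
    return cohort_to_frame(cohort)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis sequence; returns the manifest dict."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    results: dict = {}

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        elapsed = time.time() - t0
        logger.info("stage %-13s done in %.2fs", name, elapsed)
        manifest["stages"].append({"name": name, "seconds": round(elapsed, 3)})

    # -- scoring -----------------------------------------------------------
    def stage_scoring():
        cohort = _load_cohort(config)
        scored = score_frame(cohort, thresholds=config.thresholds)
        scored.to_csv(out_dir / "scored_cohort.csv", index=False)
        results["scored"] = scored

    run_stage("scoring", stage_scoring)

    # -- staging -----------------------------------------------------------
    def stage_staging():
        scored = results["scored"]
        results["y_active"] = (scored["stage"] != "remission").astype(int).to_numpy()
        counts = scored["stage"].value_counts().to_dict()
        manifest["stage_counts"] = {k: int(v) for k, v in counts.items()}

    run_stage("staging", stage_staging)

    # -- pca ---------------------------------------------------------------
    def stage_pca():
        comp = results["scored"][list(COMPONENT_NAMES)].to_numpy(dtype=float)
        pca = pca_project(comp)
        results["pca"] = pca
        pd.DataFrame(
            {
                "eigenvalue": pca.eigenvalues,
                "explained_variance_pct": 100 * pca.explained_variance_ratio,
            }
        ).to_csv(out_dir / "pca_eigenvalues.csv", index=False)
        pd.DataFrame(
            pca.contributions,
            index=list(COMPONENT_NAMES),
            columns=[f"PC{k + 1}" for k in range(len(COMPONENT_NAMES))],
        ).to_csv(out_dir / "pca_contributions.csv")

    run_stage("pca", stage_pca)

    # -- esom --------------------------------------------------------------
    def stage_esom():
        comp = results["scored"][list(COMPONENT_NAMES)].to_numpy(dtype=float)
        scaled, min_max = scale_0_100(comp)
        esom_cfg = dataclasses.replace(config.esom, seed=config.esom.seed or config.seed)
        model = train_esom(scaled, esom_cfg)
        model.input_scaling = min_max
        sm = structure_matrices(model, scaled)
        results.update(model=model, structure=sm, scaled=scaled)
        for name, grid in (("u", sm.u), ("p", sm.p), ("u_star", sm.u_star)):
            pd.DataFrame(grid).to_csv(out_dir / f"{name}_matrix.csv", index=False, header=False)
        with open(out_dir / "esom_meta.json", "w") as fh:
            json.dump(
                {
                    "config": dataclasses.asdict(esom_cfg),
                    "pareto_radius": sm.radius_r,
                    "input_scaling": min_max.tolist(),
                },
                fh,
                indent=2,
            )

    run_stage("esom", stage_esom)

    # -- clustering --------------------------------------------------------
    def stage_clustering():
        bmus = assign_bmus(results["model"], results["scaled"])
        assignment = extract_clusters(
            results["structure"].u_star,
            bmus,
            results["model"].config,
            min_cluster_size=config.min_cluster_size,
        )
        results["assignment"] = assignment
        assignment.to_frame(results["scored"]["patient_id"]).to_csv(
            out_dir / "cluster_assignment.csv", index=False
        )
        stages_arr = results["scored"]["stage"].to_numpy()
        try:
            assoc = cluster_stage_association(assignment, stages_arr)
            results["cluster_stage"] = {
                "chi2": assoc["chi2"],
                "df": assoc["df"],
                "p": assoc["p"],
            }
        except Exception as exc:
            logger.warning("cluster-vs-stage test skipped: %s", exc)
            results["cluster_stage"] = None
        manifest["cluster_sizes"] = {
            str(k): v for k, v in sorted(results["assignment"].cluster_sizes.items())
        }

    run_stage("clustering", stage_clustering)

    # -- augmentation ------------------------------------------------------
    def stage_augmentation():
        plan = dataclasses.replace(
            config.augmentation, seed=config.augmentation.seed or config.seed
        )
        augmented = equalize_clusters(
            results["model"],
            results["structure"],
            results["assignment"],
            results["scaled"],
            plan,
            patient_ids=results["scored"]["patient_id"],
            component_names=COMPONENT_NAMES,
        )
        results["augmented"] = augmented
        augmented.to_csv(out_dir / "augmented_components.csv", index=False)

    run_stage("augmentation", stage_augmentation)

    # -- selection ---------------------------------------------------------
    def stage_selection():
        scored = results["scored"]
        scheme = dataclasses.replace(config.cv, seed=config.cv.seed or config.seed)
        X58 = scored[list(FEATURE_NAMES_58)].astype(float)
        y = results["y_active"]
        X_pool, y_pool, X_val, y_val = split_holdout(X58, y, scheme)
        clf = tune_and_train(X_pool, y_pool, scheme)
        imp = permutation_importance(
            clf,
            X_pool,
            y_pool,
            feature_names=X58.columns,
            n_repeats=config.importance_repeats,
            seed=scheme.seed,
        )
        partition = cabc(
            imp.table["mean_importance"].to_numpy(), imp.table["feature"].tolist()
        )
        imp_out = imp.table.copy()
        imp_out["abc_set"] = [
            "A" if f in partition.a else ("B" if f in partition.b else "C")
            for f in imp_out["feature"]
        ]
        imp_out.to_csv(out_dir / "item_importance.csv", index=False)
        perf = {}
        for label, subset, permute in (
            ("full", None, False),
            ("reduced", partition.a, False),
            ("reduced_permuted", partition.a, True),
        ):
            dist = nested_cv_evaluate(
                X_pool, y_pool, X_val, y_val, scheme,
                feature_subset=subset, permute_features=permute,
            )
            perf[label] = dist.summary()
        results["selection"] = {"abc": partition.sets(), "performance": perf}
        # one-vs-rest cluster attribution on the augmented 4-component data
        aug = results["augmented"]
        results["cluster_attribution"] = cluster_membership_importance(
            aug[list(COMPONENT_NAMES)],
            aug["cluster"].to_numpy(),
            scheme,
            importance_repeats=config.importance_repeats,
        )
        with open(out_dir / "selection_performance.json", "w") as fh:
            json.dump(
                {
                    "abc_sets": partition.sets(),
                    "performance": perf,
                    "cluster_top_features": {
                        str(k): v["top_feature"]
                        for k, v in results["cluster_attribution"].items()
                    },
                    "scheme": dataclasses.asdict(scheme),
                },
                fh,
                indent=2,
            )

    run_stage("selection", stage_selection)

    # -- associations ------------------------------------------------------
    def stage_associations():
        scored = results["scored"]
        report: dict = {}
        for comp in COMPONENT_NAMES:
            labels = quartile_rescale(scored[comp].to_numpy(dtype=float))
            report[f"{comp}_quartile_counts"] = {
                str(k): int(v) for k, v in pd.Series(labels).value_counts().items()
            }
        if scored.get("drug_class") is not None and scored["drug_class"].notna().any():
            table = pd.crosstab(scored["drug_class"], scored["stage"])
            try:
                res = chi2_test(table)
                report["drug_vs_stage"] = {
                    "chi2": res["chi2"], "df": res["df"], "p": res["p"]
                }
            except Exception as exc:
                report["drug_vs_stage"] = {"skipped": str(exc)}
        if (
            scored.get("therapy_start_days") is not None
            and scored["therapy_start_days"].notna().any()
        ):
            groups = [
                scored.loc[scored["stage"] == s, "therapy_start_days"].dropna().to_numpy()
                for s in scored["stage"].unique()
            ]
            groups = [g for g in groups if g.size]
            if len(groups) >= 2:
                report["therapy_start_vs_stage"] = kruskal_wallis(*groups)
        if results.get("cluster_stage"):
            report["cluster_vs_stage"] = results["cluster_stage"]
        results["associations"] = report
        with open(out_dir / "associations.json", "w") as fh:
            json.dump(report, fh, indent=2)

    run_stage("associations", stage_associations)

    manifest["n_stages_completed"] = len(manifest["stages"])
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
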