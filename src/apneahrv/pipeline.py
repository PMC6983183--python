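"""End-to-end analysis pipeline behind a single YAML-configurable entry point.

Stages: cohort (synthetic generation or manifest loading) -> RR filtering ->
HRV feature tables per sensor x filter condition -> ordination with
vector/surface fitting of the clinical variables -> cut-off-sweep
classification -> report bundle (CSV/JSON tables, optional biplot, summary).
All outputs are deterministic functions of (config, seed); per-stage errors
are re-raised tagged with the stage name.
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

from .hrv_features import SpectralConfig, cohort_feature_table
from .ordination import fit_surface, fit_vector, pca, standardize_features
from .rr_filter import FilterConfig, filter_rr
from .rr_io import CohortManifest, read_manifest, read_rr
from .severity_classification import (
    ClassifierSpec,
    compare_conditions,
)
from .synthetic_cohort import SubjectRecord, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.12g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class ClassificationSettings:
    responses: tuple[str, ...] = ("ahi", "odi", "ess")
    classifiers: tuple[ClassifierSpec, ...] = (ClassifierSpec("svm"),)
    percentiles: tuple[int, ...] = tuple(range(10, 91, 5))
    folds: int = 10
    repeats: int = 5

    def __post_init__(self) -> None:
        self.classifiers = tuple(
            c if isinstance(c, ClassifierSpec)
            else ClassifierSpec(c["name"], c.get("hyperparameters", {}))
            for c in self.classifiers
        )
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"          # synthetic | manifest
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    manifest_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    classification: ClassificationSettings = field(default_factory=ClassificationSettings)
    conditions: tuple[tuple[str, bool], ...] = (
        ("belt", True), ("belt", False), ("patch", True), ("patch", False),
    )
    ordination_sensor: str = "belt"
    ordination_filtered: bool = True
    n_permutations: int = 999
    out_dir: str = "apneahrv_out"
    seed: int = 0
    log_level: str = "INFO"
    persist_rr: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "manifest"):
            raise ValueError("input_mode must be 'synthetic' or 'manifest'")
        if self.input_mode == "manifest" and not self.manifest_path:
            raise ValueError("manifest input_mode requires manifest_path")
        for sub, cls in (("synthetic", SyntheticConfig), ("filter", FilterConfig),
                         ("spectral", SpectralConfig),
                         ("classification", ClassificationSettings)):
            val = getattr(self, sub)
            if isinstance(val, dict):
                setattr(self, sub, cls(**val))
        self.conditions = tuple((s, bool(f)) for s, f in self.conditions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(yaml.safe_dump(enc(self), sort_keys=True))


def _load_cohort_from_manifest(path: str) -> tuple[list[SubjectRecord], CohortManifest]:
    manifest = read_manifest(path)
    base = Path(path).parent
    records = []
    for _, row in manifest.table.iterrows():
        recordings = {}
        for sensor in ("belt", "patch"):
            col = f"rr_{sensor}"
            if col in manifest.table.columns and isinstance(row[col], str) and row[col]:
                recordings[sensor] = read_rr(base / row[col])
        if not recordings:
            raise ValueError(f"subject {row['subject_id']}: no RR file path in manifest")
        records.append(SubjectRecord(subject_id=row["subject_id"],
                                     clinical=row.to_dict(), recordings=recordings))
    return records, manifest


def _biplot(ord_res, fits, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    s = ord_res.scores
    ax.scatter(s.iloc[:, 0], s.iloc[:, 1], s=12, facecolors="none", edgecolors="grey")
    scale = float(np.abs(s.iloc[:, :2].to_numpy()).max())
    for feat, row in ord_res.loadings.iterrows():
        ax.annotate(feat, (row.iloc[0] * scale, row.iloc[1] * scale), color="red")
        ax.arrow(0, 0, row.iloc[0] * scale * 0.9, row.iloc[1] * scale * 0.9,
                 color="red", alpha=0.5, head_width=0.02 * scale)
    for fit in fits:
        dx, dy = fit.direction * scale * 0.8
        ax.arrow(0, 0, dx, dy, color="blue", head_width=0.02 * scale)
        ax.annotate(f"{fit.variable} (p={fit.p_value:.3g})", (dx, dy), color="blue")
    ve = ord_res.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of the key in-memory results.

    Writes into ``config.out_dir``: the resolved config, the cohort manifest,
    per-condition feature tables and filter reports, ordination scores /
    loadings / fits, the tidy classification sweep table, and a
    human-readable summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "config_resolved.yaml")
    results: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = dt
                if exc is not None:
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
                logger.info("stage %s: done in %.1f s", name, dt)
                return False

        return _Stage()

    with stage("cohort"):
        if config.input_mode == "synthetic":
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            sensors = tuple(dict.fromkeys(s for s, _ in config.conditions))
            records, manifest = generate_cohort(syn, sensors=sensors)
            if config.persist_rr:
                from .synthetic_cohort import write_cohort

                write_cohort(records, manifest, out / "cohort")
        else:
            records, manifest = _load_cohort_from_manifest(config.manifest_path)
        manifest.table.to_csv(out / "manifest.csv", index=False,
                              float_format=_CSV_FLOAT)
        results["manifest"] = manifest

    with stage("features"):
        feature_tables: dict[tuple[str, bool], pd.DataFrame] = {}
        filter_reports: dict[str, dict] = {}
        for sensor, filtered in config.conditions:
            feats = cohort_feature_table(records, sensor, filtered,
                                         config.filter, config.spectral)
            feature_tables[(sensor, filtered)] = feats
            tag = f"{sensor}_{'filtered' if filtered else 'unfiltered'}"
            feats.to_csv(out / f"features_{tag}.csv", float_format=_CSV_FLOAT)
        for sensor in dict.fromkeys(s for s, _ in config.conditions):
            fr = [filter_rr(rec.recordings[sensor], config.filter)[1].to_dict()
                  for rec in records]
            agg = pd.DataFrame(fr).mean().to_dict()
            filter_reports[sensor] = agg
        (out / "filter_reports.json").write_text(
            json.dumps(filter_reports, indent=2, sort_keys=True) + "\n")
        results["feature_tables"] = feature_tables
        results["filter_reports"] = filter_reports

    with stage("ordination"):
        key = (config.ordination_sensor, config.ordination_filtered)
        if key not in feature_tables:
            key = next(iter(feature_tables))
        feats = feature_tables[key]
        ord_res = pca(standardize_features(feats))
        ord_res.scores.to_csv(out / "pca_scores.csv", float_format=_CSV_FLOAT)
        ord_res.loadings.to_csv(out / "pca_loadings.csv", float_format=_CSV_FLOAT)
        fits, surfaces = [], []
        for j, response in enumerate(config.classification.responses):
            y = manifest.response(response)
            fits.append(fit_vector(ord_res, y, name=response,
                                   n_perm=config.n_permutations,
                                   seed=config.seed + j))
            surfaces.append(fit_surface(ord_res, y, name=response))
        fit_json = {
            "variance_explained": ord_res.variance_explained.tolist(),
            "vector_fits": [
                {"variable": f.variable, "direction": f.direction.tolist(),
                 "r_squared": f.r_squared, "p_value": f.p_value,
                 "n_permutations": f.n_permutations} for f in fits
            ],
            "surface_fits": [
                {"variable": s.variable, "coefficients": s.coefficients.tolist(),
                 "r_squared": s.r_squared,
                 "isocline_levels": s.isocline_levels.tolist()} for s in surfaces
            ],
        }
        (out / "ordination_fits.json").write_text(
            json.dumps(fit_json, indent=2, sort_keys=True) + "\n")
        if config.make_plots:
            _biplot(ord_res, fits, out / "biplot.png")
        results["ordination"] = ord_res
        results["vector_fits"] = fits
        results["surface_fits"] = surfaces

    with stage("classification"):
        tidy, sweeps = compare_conditions(
            records, manifest,
            responses=config.classification.responses,
            specs=config.classification.classifiers,
            conditions=config.conditions,
            filter_config=config.filter,
            spectral_config=config.spectral,
            percentiles=config.classification.percentiles,
            folds=config.classification.folds,
            repeats=config.classification.repeats,
            seed=config.seed,
        )
        tidy.to_csv(out / "classification_sweeps.csv", index=False,
                    float_format=_CSV_FLOAT)
        optima = {
            f"{sensor}|{'filtered' if filt else 'unfiltered'}|{resp}|{clf}": {
                "optimal_cutoff": sw.optimal_cutoff,
                "optimal_percentile": sw.optimal_percentile,
                "auc": sw.auc,
                "auc_ci_95": list(sw.auc_ci_95),
            }
            for (sensor, filt, resp, clf), sw in sweeps.items()
        }
        (out / "classification_optima.json").write_text(
            json.dumps(optima, indent=2, sort_keys=True) + "\n")
        results["classification_table"] = tidy
        results["sweeps"] = sweeps

    with stage("summary"):
        cond_txt = ", ".join(
            "{}/{}".format(s, "filtered" if f else "unfiltered")
            for s, f in config.conditions
        )
        lines = [
            "apneahrv pipeline summary",
            f"subjects: {len(manifest)}",
            f"conditions: {cond_txt}",
            "",
            "filter removal fraction by sensor:",
        ]
        for sensor, rep in results["filter_reports"].items():
            lines.append(f"  {sensor}: {rep['fraction_removed']:.4f}")
        lines += ["", "vector fits (ordination of "
                  f"{key[0]}/{'filtered' if key[1] else 'unfiltered'} features):"]
        for f in results["vector_fits"]:
            lines.append(f"  {f.variable}: R2={f.r_squared:.3f} p={f.p_value:.4g}")
        lines += ["", "classification optima (response | condition | classifier):"]
        for k, v in sorted(optima.items()):
            lines.append(
                f"  {k}: cutoff={v['optimal_cutoff']:.3g} AUC={v['auc']:.3f} "
                f"[{v['auc_ci_95'][0]:.3f}, {v['auc_ci_95'][1]:.3f}]"
            )
        (out / "summary.txt").write_text("\n".join(lines) + "\n")

    logger.info("pipeline timings: %s",
                {k: round(v, 2) for k, v in timings.items()})
    return results
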