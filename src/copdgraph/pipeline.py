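"""Configuration-driven end-to-end pipeline with a reproducibility manifest.

One call runs: synthetic-cohort generation (optional), preprocessing
(sparse-category merging, variable filtering, KNN imputation), spirometry
variant selection, nested cross-validation with blanket extraction, and the
comparison models, writing every artifact as plain text (CSV/TSV/JSON) into
a run directory together with a content-addressed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .dataset import MixedDataset
from .mb import extract_mb
from .mgm import fit_mgm
from .fci import learn_pag
from .preprocess import (
    filter_variables,
    knn_impute,
    make_variable_sets,
    merge_sparse_categories,
)
from .predict import (
    alpha_grid,
    auroc,
    fit_elastic_net,
    fit_random_forest,
    nested_cv,
    roc_curve,
)
from .simulate import CohortSpec, make_copd_like

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of a pipeline run; the seed is mandatory."""

    out_dir: str
    seed: int
    # inputs: either an existing table+metadata, or a simulated cohort
    table: str | None = None
    metadata: str | None = None
    simulate: bool = True
    n_subjects: int = 2114
    n_observed: int = 30
    n_latent: int = 3
    mb_size: int = 6
    minority_rate: float = 0.203
    missing_rate: float = 0.05
    # preprocessing
    missing_max: float = 0.2
    min_category_count: int = 10
    corr_max: float = 0.9
    k_impute: int = 5
    # graph learning
    lam: float | None = None
    grid_min: float = 1e-5
    grid_max: float = 1e-1
    grid_n: int = 10
    max_cond: int = 3
    # modelling
    n_folds: int = 10
    variant: str = "limited_spirometry"
    models: tuple = ("logistic",)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")
        if self.variant not in ("limited_spirometry", "no_spirometry"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0 < self.grid_min < self.grid_max <= 1):
            raise ValueError("alpha grid bounds must satisfy 0 < min < max <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure is recorded in the manifest with the stage name and
    error message; downstream stages are skipped and the manifest's
    ``status`` reflects the failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": [],
        "artifacts": {},
        "warnings": [],
        "status": "ok",
    }

    def record(name):
        manifest["stages"].append(name)

    def fail(stage, err):
        manifest["status"] = f"failed at {stage}"
        manifest["error"] = str(err)
        logger.error("stage %s failed: %s", stage, err)

    try:
        if config.simulate:
            record("simulate")
            spec = CohortSpec(
                n_subjects=config.n_subjects,
                n_observed=config.n_observed,
                n_latent=config.n_latent,
                mb_size=config.mb_size,
                minority_rate=config.minority_rate,
                missing_rate=config.missing_rate,
                seed=config.seed,
            )
            data, dag, axes = make_copd_like(spec)
            data.write(out / "cohort.csv", out / "cohort_meta.csv")
            dag.write_edges(out / "true_graph.tsv")
        else:
            record("load")
            data = MixedDataset.read(config.table, config.metadata)
    except Exception as err:
        fail("simulate/load", err)
        return _finish(manifest, out)

    try:
        record("preprocess")
        data = merge_sparse_categories(data, config.min_category_count)
        data, report = filter_variables(
            data, config.missing_max, config.min_category_count, config.corr_max
        )
        report.to_json(out / "filter_report.json")
        if not data.is_complete():
            data = knn_impute(data, k=config.k_impute)
        limited, no_spiro = make_variable_sets(data)
        analysis = limited if config.variant == "limited_spirometry" else no_spiro
        analysis.write(out / "analysis.csv", out / "analysis_meta.csv")
    except Exception as err:
        fail("preprocess", err)
        return _finish(manifest, out)

    try:
        record("analyze")
        grid = alpha_grid(config.grid_n, config.grid_min, config.grid_max)
        res = nested_cv(
            analysis, grid, n_folds=config.n_folds, seed=config.seed,
            lam=config.lam, max_cond=config.max_cond,
        )
        pag = learn_pag(analysis, res.selected_alpha, lam=config.lam,
                        max_cond=config.max_cond)
        pag.write_tsv(out / "pag.tsv")
        _, skeleton = fit_mgm(analysis, lam=config.lam)
        skeleton.write_tsv(out / "skeleton.tsv")
        res.stability.to_json(out / "stability.json")
        res.stability.to_frame().to_csv(out / "stability.csv")
        res.fit.to_json(out / "fit_logistic.json")
        res.fit.coefficients_csv(out / "coefficients.csv")
        mb = res.final_mb
        (out / "markov_blanket.json").write_text(
            json.dumps(
                {"target": mb.target, "members": mb.members, "edges": mb.edges},
                indent=2,
            )
        )
        y = analysis.outcome_values()
        if mb.members:
            curve = roc_curve(res.fit.predict_risk(analysis), y)
            curve.to_csv(out / "roc_train.csv")
        for kind in config.models:
            if kind == "random_forest":
                fit = fit_random_forest(analysis, config.n_folds, config.seed)
                fit.to_json(out / "fit_random_forest.json")
            elif kind == "elastic_net":
                fit = fit_elastic_net(analysis, config.n_folds, config.seed)
                fit.to_json(out / "fit_elastic_net.json")
    except Exception as err:
        fail("analyze", err)
        return _finish(manifest, out)

    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
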