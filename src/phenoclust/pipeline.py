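"""End-to-end orchestration and run comparison.

A pipeline run takes either a preset synthetic cohort or a response CSV,
then executes preprocess -> item clustering -> model selection ->
participant grouping -> validation -> Gaussian mixture, writing plain
CSV/JSON/Newick artifacts stamped with the config hash and seed.  Runs
with the same config and seed produce byte-identical artifacts.
Discovery- and replication-style runs are always independent and only
compared post hoc via :func:`compare_runs`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .distances import jaccard_distances, simple_matching_distances
from .errors import ConfigError
from .hierarchy import (ClusterAssignment, agglomerate_ward, cut, merges_frame,
                        to_newick)
from .instruments import build_registry
from .mixture import classify, crosstab, select_by_bic
from .partition import aggregate_cluster_scores, kmeans
from .preprocess import binarize, impute_mode_of_m, read_responses, screen_items
from .selection import prepare_inputs, select_cluster_numbers
from .simulate import generate_cohort, generate_diagnosed_scores, preset
from .validation import (adjusted_rand, bootstrap_item_stability, normalized_mad,
                         random_assignment_null, spearman_matrix)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"
ARTIFACTS = (
    "item_dendrogram.newick",
    "item_merges.csv",
    "item_clusters.csv",
    "selection.json",
    "participant_groups.csv",
    "group_scores.csv",
    "validation.json",
    "gmm_bic.csv",
    "report.json",
)

_REPORT_REQUIRED: dict[str, type] = {
    "schema_version": str,
    "config": dict,
    "config_hash": str,
    "seed": int,
    "selected": dict,
    "artifacts": list,
    "warnings": list,
}


def validate_report(report: dict) -> None:
    """Check the report bundle against the versioned schema."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type "
                             f"{type(report[key]).__name__}, expected {typ.__name__}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema {report['schema_version']!r}")
    for key in ("k_i", "k_p"):
        if key not in report["selected"]:
            raise ValueError(f"report['selected'] missing {key!r}")


@dataclass
class PipelineConfig:
    preset: str | None = "discovery_like"
    input_path: str | None = None
    n_participants: int | None = None
    seed: int = 0
    dialect: str = "ward_d2"
    standardize: bool = False
    impute_m: int = 5
    elbow_range: tuple[int, int] = (2, 20)
    ki_range: tuple[int, int] = (3, 10)
    kp_range: tuple[int, int] = (3, 10)
    region_ki: tuple[int, int] = (3, 5)
    region_kp: tuple[int, int] = (3, 5)
    null_B: int = 199
    bootstrap_B: int = 50
    gmm_k_range: tuple[int, int] = (1, 9)
    gmm_structures: tuple[str, ...] = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")
    gmm_n_init: int = 5
    outdir: str = "phenoclust_out"

    def validate(self) -> None:
        if self.preset is None and self.input_path is None:
            raise ConfigError("either a preset name or an input path is required")
        for name in ("elbow_range", "ki_range", "kp_range", "region_ki",
                     "region_kp", "gmm_k_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is empty: ({lo}, {hi})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    """In-memory handles of one pipeline run plus its artifact directory."""

    config: PipelineConfig
    outdir: Path
    item_assignment: ClusterAssignment
    participant_assignment: ClusterAssignment
    selection: object
    report: dict
    scores: object = None
    warnings: list[str] = field(default_factory=list)


def _r(x: float | None, nd: int = 6):
    return None if x is None else round(float(x), nd)


def run_pipeline(cfg: PipelineConfig) -> RunBundle:
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    warnings: list[str] = []
    stage = "load"
    try:
        # ---- load or simulate -------------------------------------------
        truth = None
        if cfg.input_path is not None:
            registry = build_registry()
            rm = read_responses(cfg.input_path, registry)
        else:
            gen_cfg = preset(cfg.preset, n_participants=cfg.n_participants)
            rm, truth = generate_cohort(gen_cfg, seed=int(rng.integers(2**31)))

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        rm = impute_mode_of_m(rm, m=cfg.impute_m, seed=int(rng.integers(2**31)))
        bm = binarize(rm)
        bm = screen_items(bm)

        # ---- selection (steps 1-3) --------------------------------------
        stage = "selection"
        sel = select_cluster_numbers(
            bm,
            seed=int(rng.integers(2**31)),
            dialect=cfg.dialect,
            elbow_range=range(cfg.elbow_range[0], cfg.elbow_range[1] + 1),
            ki_range=range(cfg.ki_range[0], cfg.ki_range[1] + 1),
            kp_range=range(cfg.kp_range[0], cfg.kp_range[1] + 1),
            region_ki=range(cfg.region_ki[0], cfg.region_ki[1] + 1),
            region_kp=range(cfg.region_kp[0], cfg.region_kp[1] + 1),
            standardize=cfg.standardize,
        )
        warnings.extend(sel.warnings)

        # ---- item clustering artifacts ----------------------------------
        stage = "cluster-items"
        inputs = prepare_inputs(bm, cfg.dialect)
        item_assign = cut(inputs.item_dendro, sel.k_i)
        (out / "item_dendrogram.newick").write_text(to_newick(inputs.item_dendro))
        merges_frame(inputs.item_dendro).to_csv(out / "item_merges.csv", index=False)
        item_assign.to_frame().to_csv(out / "item_clusters.csv", index=False)
        sel.to_json(out / "selection.json")

        # ---- participant grouping ---------------------------------------
        stage = "cluster-participants"
        scores = aggregate_cluster_scores(bm, item_assign)
        part_assign, _, part_quality = kmeans(
            scores, sel.k_p, seed=int(rng.integers(2**31)),
            standardize=cfg.standardize,
        )
        part_assign.to_frame().to_csv(out / "participant_groups.csv", index=False)
        long = scores.data.copy()
        long["group"] = part_assign.cluster_ids
        long.reset_index().melt(
            id_vars=["pid", "group"], var_name="item_cluster", value_name="score"
        ).to_csv(out / "group_scores.csv", index=False)

        # ---- validation --------------------------------------------------
        stage = "validate"
        null = random_assignment_null(
            bm, item_assign, sel.k_p, B=cfg.null_B,
            seed=int(rng.integers(2**31)),
        )
        pd.DataFrame({"bt_ratio": null.draws}).to_csv(
            out / "null_draws.csv", index=False
        )
        cocluster = bootstrap_item_stability(
            bm, sel.k_i, B=cfg.bootstrap_B, seed=int(rng.integers(2**31)),
            dialect=cfg.dialect,
        )
        cocluster.to_csv(out / "cocluster.csv")
        dispersion = normalized_mad(scores)
        correlations = spearman_matrix(scores, part_assign)
        validation_payload = {
            "null": {
                "statistic": null.statistic_name,
                "observed": _r(null.observed),
                "empirical_p": _r(null.empirical_p),
                "p95": _r(null.percentile(95)),
                "B": cfg.null_B,
            },
            "normalized_mad": {k: _r(v)
                               for k, v in dispersion.normalized_mad.items()},
            "spearman_overall": {
                c: {c2: _r(v) for c2, v in row.items()}
                for c, row in correlations["overall"].to_dict().items()
            },
            "spearman_by_group": {
                str(g): {c: {c2: _r(v) for c2, v in row.items()}
                         for c, row in df.to_dict().items()}
                for g, df in correlations["by_group"].items()
            },
        }
        with open(out / "validation.json", "w") as fh:
            json.dump(validation_payload, fh, indent=2, sort_keys=True)

        # ---- Gaussian mixture stage --------------------------------------
        stage = "gmm"
        if truth is not None and truth.config.diagnosed is not None:
            gmm_scores, diagnosis, _ = generate_diagnosed_scores(
                truth.config, seed=int(rng.integers(2**31))
            )
        else:
            gmm_scores, diagnosis = scores, None
        bic = select_by_bic(
            gmm_scores.data,
            k_range=range(cfg.gmm_k_range[0], cfg.gmm_k_range[1] + 1),
            structures=cfg.gmm_structures,
            seed=int(rng.integers(2**31)),
            n_init=cfg.gmm_n_init,
        )
        bic.table.to_csv(out / "gmm_bic.csv", index=False)
        with open(out / "gmm_model.json", "w") as fh:
            json.dump(bic.best_model.to_dict(), fh, indent=2, sort_keys=True)
        if diagnosis is not None:
            _, hard = classify(bic.best_model, gmm_scores.data)
            crosstab(hard, diagnosis).to_csv(out / "gmm_diagnosis_crosstab.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "selected": {
            "k_i": sel.k_i,
            "k_p": sel.k_p,
            "gmm_k": bic.best[0],
            "gmm_structure": bic.best[1],
        },
        "quality": {
            "participant_kmeans_silhouette": _r(part_quality.mean_silhouette),
            "participant_kmeans_bt_ratio": _r(part_quality.bt_ratio),
            "null_empirical_p": _r(null.empirical_p),
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()
                            if p.name != "report.json"),
        "warnings": warnings,
    }
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return RunBundle(cfg, out, item_assign, part_assign, sel, report,
                     scores, warnings)


def _load_items(bundle) -> pd.DataFrame:
    if isinstance(bundle, RunBundle):
        return bundle.item_assignment.to_frame()
    return pd.read_csv(Path(bundle) / "item_clusters.csv")


def _load_selected(bundle) -> dict | None:
    if isinstance(bundle, RunBundle):
        return bundle.report["selected"]
    path = Path(bundle) / "report.json"
    if path.exists():
        return json.loads(path.read_text())["selected"]
    return None


def compare_runs(bundle_a, bundle_b) -> dict:
    """Compare item partitions of two runs (e.g. discovery vs replication).

    Clusters of run B are aligned to run A by maximum overlap (Hungarian
    assignment); the migration table lists items whose aligned cluster
    changed.  Also reports the adjusted Rand index and whether the two
    runs selected the same (k_i, k_p).
    """
    items_a, items_b = _load_items(bundle_a), _load_items(bundle_b)
    common = sorted(set(items_a["id"]) & set(items_b["id"]))
    if not common:
        raise ValueError("runs share no items; incompatible registries")
    map_a = dict(zip(items_a["id"], items_a["cluster"]))
    map_b = dict(zip(items_b["id"], items_b["cluster"]))
    a_ids = np.array([map_a[i] for i in common])
    b_ids = np.array([map_b[i] for i in common])
    from .hierarchy import relabel_by_first_appearance

    ca = relabel_by_first_appearance(a_ids, common)
    cb = relabel_by_first_appearance(b_ids, common)
    ari = adjusted_rand(ca, cb)

    overlap = np.zeros((ca.k, cb.k))
    np.add.at(overlap, (ca.cluster_ids - 1, cb.cluster_ids - 1), 1)
    rows, cols = linear_sum_assignment(-overlap)
    aligned = {c + 1: r + 1 for r, c in zip(rows, cols)}
    migrations = [
        {"item": item, "cluster_a": int(ai), "cluster_b_aligned": int(
            aligned.get(bi, -bi))}
        for item, ai, bi in zip(common, ca.cluster_ids, cb.cluster_ids)
        if aligned.get(bi) != ai
    ]
    sel_a, sel_b = _load_selected(bundle_a), _load_selected(bundle_b)
    agreement = None
    if sel_a and sel_b:
        agreement = {
            "k_i": sel_a["k_i"] == sel_b["k_i"],
            "k_p": sel_a["k_p"] == sel_b["k_p"],
        }
    return {
        "ari": ari,
        "n_common_items": len(common),
        "migrations": migrations,
        "n_migrations": len(migrations),
        "selected_agreement": agreement,
    }
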