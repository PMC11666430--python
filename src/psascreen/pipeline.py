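"""End-to-end screening study orchestration.

``run_screening_study`` realizes the full analysis flow on synthetic (or
user-supplied) cohorts: generate/load -> encode -> impute -> feature
screening -> five-model benchmark -> PSAII-style index construction from
the logistic odds ratios -> index evaluation on training / held-out /
external partitions -> combined triage.  Every stage's report is written
under the output directory together with a run manifest; the whole run is
deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bench import compare_models, default_grid, make_folds, small_grid, train_eval
from .cohort import MinMaxNormalizer, encode_categories, impute_missing, load_cohort
from .indices import IndexScorer, builtin_catalogue, construct_index_from_ors
from .metrics import evaluate_scores, select_cutoff
from .selection import SelectionConfig, screen_features
from .simulate import GeneratorConfig, generate_study, inject_missingness, load_catalogue
from .triage import StrategyRule, triage_table

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_screening_study", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "psascreen_run",
        "cohorts": {
            "source": "synthetic",
            "nhanes_like": {"pso": 574, "psa": 145},
            "chinese_like": {"pso": 98, "psa": 37},
            "dependence": "independence",
            "screening_aux": True,
            "missing_rate": 0.0,
        },
        "selection": {"auc_threshold": 0.6, "corr_threshold": 0.8,
                      "cv": 10, "rule": "1se", "n_penalties": 50},
        "bench": {"k": 5, "learners": ["LR", "KNN", "GBDT", "NN", "RF"],
                  "grid": "default"},
        "triage": {"psaii_threshold": 18.0, "topas_threshold": 7.0},
        "index_scale": 10.0,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_json_ready(payload), indent=2, sort_keys=True) + "\n")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageError(name, exc) from exc
    return wrap


def run_screening_study(config: dict | str | Path) -> dict:
    """Run the full screening study; returns the report bundle in memory.

    ``config`` is a mapping or a YAML path; missing keys fall back to
    :func:`default_config`.  Reports are written under ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- cohorts -----------------------------------------------------------
    cc = cfg["cohorts"]
    if cc["source"] == "synthetic":
        gen_cfg = GeneratorConfig(
            nhanes_sizes=cc["nhanes_like"], chinese_sizes=cc["chinese_like"],
            dependence=cc["dependence"], screening_aux=cc["screening_aux"],
            seed=seed,
        )
        nhanes, chinese = _stage("generate")(generate_study, gen_cfg)
    else:
        nhanes = _stage("load")(load_cohort, cc["nhanes_like"])
        chinese = _stage("load")(load_cohort, cc["chinese_like"])
        nhanes = _stage("encode")(encode_categories, nhanes)
        chinese = _stage("encode")(encode_categories, chinese)

    rate = float(cc.get("missing_rate", 0.0))
    if rate > 0:
        nhanes, _ = _stage("inject")(inject_missingness, nhanes, rate, seed + 1)
    if nhanes.isna().any().any():
        nhanes = _stage("impute")(impute_missing, nhanes, seed + 2)

    # external validation needs every model feature in both cohorts, so
    # candidate variables are the intersection of the two tables
    candidates = [c for c in nhanes.columns
                  if c not in ("subject_id", "cohort", "label", "arthralgia", "topas")
                  and c in chinese.columns]

    # --- feature screening (on a normalized view of the full training cohort)
    sel_cfg = SelectionConfig(seed=seed, **{
        k: v for k, v in cfg["selection"].items()
        if k in ("auc_threshold", "corr_threshold", "cv", "rule", "n_penalties")
    })
    norm = MinMaxNormalizer(columns=candidates).fit(nhanes)
    selection = _stage("select")(
        screen_features, norm.transform(nhanes), sel_cfg, candidates
    )
    features = selection.selected
    if not features:
        logger.warning("selection empty; falling back to flagged variables")
        features = selection.flagged or candidates
    _write_json(out_dir / "selection.json", selection.to_dict())

    # --- model benchmark ---------------------------------------------------
    bc = cfg["bench"]
    folds = make_folds(len(nhanes), int(bc["k"]), seed + 3)
    grid_fn = small_grid if bc.get("grid") == "small" else default_grid
    results = []
    for learner in bc["learners"]:
        results.append(_stage(f"bench:{learner}")(
            train_eval, learner, nhanes, features, folds, grid_fn(learner), seed
        ))
    panel = _stage("bench:panel")(compare_models, results, nhanes, chinese)
    panel.reset_index().to_csv(out_dir / "model_panel.csv", index=False)
    _write_json(out_dir / "model_panel.json",
                panel.reset_index().to_dict(orient="records"))

    # --- index construction from the logistic odds ratios ------------------
    lr = next((r for r in results if r.name == "LR"), None)
    constructed = None
    if lr is not None and lr.odds_ratios:
        serum = {s.name for s in load_catalogue("nhanes_like") if s.role == "serum"}
        eligible = [f for f in features if f in serum]
        try:
            constructed = construct_index_from_ors(
                lr.odds_ratios, eligible, float(cfg["index_scale"]), "constructed"
            )
        except ValueError as exc:
            logger.warning("index construction skipped: %s", exc)
        _write_json(out_dir / "logistic_weights.json",
                    {"coefficients": lr.coefficients, "odds_ratios": lr.odds_ratios,
                     "constructed_index": constructed.to_dict() if constructed else None})

    # --- catalogue indices on raw values ------------------------------------
    catalogue = builtin_catalogue()
    scorer = IndexScorer(catalogue + ([constructed] if constructed else []))
    nhanes_scored = _stage("score")(scorer.fit_transform, nhanes)
    chinese_scored = _stage("score")(scorer.transform, chinese)

    index_rows = []
    y = nhanes["label"].to_numpy()
    y_ext = chinese["label"].to_numpy()
    for defn in scorer.definitions_:
        s = nhanes_scored[defn.name].to_numpy()
        rep_train = _stage("evaluate")(
            evaluate_scores, s, y, None, defn.orientation, "delong", 0.95, seed
        )
        held = []
        for fold in range(1, folds.k + 1):
            tr = folds.assignments != fold
            te = ~tr
            cut = _stage("evaluate")(select_cutoff, s[tr], y[tr], defn.orientation)
            held.append(_stage("evaluate")(
                evaluate_scores, s[te], y[te], cut, defn.orientation, "delong", 0.95, seed
            ))
        s_ext = chinese_scored[defn.name].to_numpy()
        rep_ext = _stage("evaluate")(
            evaluate_scores, s_ext, y_ext, rep_train.cutoff, defn.orientation,
            "delong", 0.95, seed,
        )
        index_rows.append({
            "index": defn.name,
            "training": rep_train.to_dict(),
            "test_mean_auc": float(np.mean([h.auc for h in held])),
            "test": [h.to_dict() for h in held],
            "external": rep_ext.to_dict(),
        })
    _write_json(out_dir / "index_panel.json", index_rows)

    # --- triage -------------------------------------------------------------
    triage = None
    rule = StrategyRule(**cfg["triage"])
    if {"arthralgia", "topas"} <= set(chinese_scored.columns):
        triage = _stage("triage")(triage_table, chinese_scored, rule)
        triage.to_csv(out_dir / "triage.csv", index=False)
    else:
        logger.warning("triage skipped: arthralgia/topas columns unavailable")

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(_json_ready({k: v for k, v in cfg.items() if k != "out_dir"}),
                       sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
        "python": platform.python_version(),
        "n_nhanes": int(len(nhanes)),
        "n_chinese": int(len(chinese)),
        "selected_features": features,
    }
    _write_json(out_dir / "manifest.json", manifest)
    return {
        "selection": selection,
        "results": results,
        "panel": panel,
        "constructed_index": constructed,
        "index_panel": index_rows,
        "triage": triage,
        "manifest": manifest,
    }
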