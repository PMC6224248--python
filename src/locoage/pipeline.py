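"""End-to-end orchestration: simulate/ingest -> filter -> descriptors ->
spectral summaries -> biological age -> hazard models -> association table
-> group comparisons.

Each stage persists a compact artifact (CSV/JSON) in the output directory
and is skipped on rerun if its artifact already exists, so deleting a
downstream file and rerunning regenerates only the downstream stages.  All
randomness derives from the single ``seed`` entry of the config, and a
manifest records the seed, the resolved config and the artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioage as bioage_mod
from . import hazards as hazards_mod
from . import io as io_mod
from . import markov, spectral, synthetic

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline"]

logger = logging.getLogger("locoage")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n": 2000,
    "age_range": [40.0, 85.0],
    "track_minutes": 7 * 1440,
    "write_tracks": False,
    "generator": {},   # overrides for synthetic.GeneratorSpec fields
    "survival": {},    # overrides for synthetic.SurvivalSpec fields
    "filters": {"mean_low": 50.0, "mean_high": 5000.0},
    "pca": {"min_age": 40.0},
    "hazards": {"penalty": 0.01},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and original error."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def load_config(path=None) -> dict:
    """Default config, optionally overlaid with a YAML file (shallow-merged
    per section)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _descriptor_frame(tracks, scheme) -> pd.DataFrame:
    rows = []
    for t in tracks:
        seq = io_mod.state_sequence(t, scheme)
        tm = markov.estimate_transition_model(seq)
        desc = markov.log_descriptor(tm)
        row = {"participant_id": t.participant_id}
        row.update(dict(zip(markov.descriptor_names(scheme.n_states), desc)))
        row["neg_log_activity"] = io_mod.mean_log_activity(t)
        rows.append(row)
    return pd.DataFrame(rows)


def _spectral_frame(tracks, scheme) -> pd.DataFrame:
    rows = []
    for t in tracks:
        seq = io_mod.state_sequence(t, scheme)
        tm = markov.estimate_transition_model(seq)
        try:
            summ = spectral.summarize(tm, with_psd=False)
            lam_min = float(summ.eigenrates[0]) if summ.eigenrates.size else np.nan
            db = float(summ.db_score)
        except spectral.ReducibleChainError:
            lam_min, db = np.nan, np.nan
        rows.append(
            {"participant_id": t.participant_id,
             "lambda_min": lam_min, "db_score": db}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict, outdir, resume: bool = True) -> dict:
    """Run all stages; returns a dict of artifact paths plus the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    scheme = markov.DiscretizationScheme()
    gspec = synthetic.GeneratorSpec(**config.get("generator", {}))
    sspec = synthetic.SurvivalSpec(**config.get("survival", {}))
    paths = {
        name: out / fname
        for name, fname in [
            ("cohort", "cohort.csv"),
            ("tracks", "tracks.csv"),
            ("exclusions", "exclusions.json"),
            ("descriptors", "descriptors.csv"),
            ("spectral", "spectral.csv"),
            ("bioage_model", "bioage_model.json"),
            ("scores", "scores.csv"),
            ("hazards_model", "hazards_model.json"),
            ("gompertz", "gompertz_fit.json"),
            ("assoc", "assoc.csv"),
            ("groups", "groups.csv"),
            ("manifest", "manifest.json"),
        ]
    }

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    tracks = None
    try:
        need_tracks = not (
            resume and paths["descriptors"].exists() and paths["spectral"].exists()
        )
        if resume and paths["cohort"].exists() and not need_tracks:
            cohort = io_mod.read_cohort(paths["cohort"])
            logger.info("resume: loaded cohort (%d participants)", len(cohort))
        else:
            logger.info("simulating cohort of n=%d (seed=%d)", config["n"], seed)
            cohort, tracks = synthetic.simulate_cohort(
                int(config["n"]), gspec, sspec, seed=seed,
                age_range=tuple(config["age_range"]),
                track_minutes=int(config["track_minutes"]),
                scheme=scheme,
            )
            io_mod.write_cohort(cohort, paths["cohort"])
            if config.get("write_tracks"):
                io_mod.write_tracks(tracks, paths["tracks"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- filter + descriptors + spectral -------------------------------------
    stage = "descriptors"
    try:
        if resume and paths["descriptors"].exists() and paths["spectral"].exists():
            desc_df = pd.read_csv(paths["descriptors"])
            spec_df = pd.read_csv(paths["spectral"])
        else:
            f = config["filters"]
            retained, excl = io_mod.filter_participants(
                tracks, low=f["mean_low"], high=f["mean_high"]
            )
            kept = []
            for t in retained:
                seq = markov.discretize(t.counts, scheme)
                _, ok = io_mod.filter_days(t, seq)
                if ok:
                    kept.append(t)
                else:
                    excl.append({"participant_id": t.participant_id,
                                 "reason": "too_few_valid_days"})
            with open(paths["exclusions"], "w") as fh:
                json.dump(excl, fh, indent=2)
            logger.info("retained %d/%d participants", len(kept), len(tracks))
            desc_df = _descriptor_frame(kept, scheme)
            desc_df.to_csv(paths["descriptors"], index=False)
            spec_df = _spectral_frame(kept, scheme)
            spec_df.to_csv(paths["spectral"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    cohort_idx = cohort.set_index("participant_id")
    meta = cohort_idx.loc[desc_df["participant_id"]]
    dcols = markov.descriptor_names(scheme.n_states)
    X = desc_df[dcols].to_numpy()
    ages = meta["age"].to_numpy()
    genders = meta["gender"].to_numpy()

    # --- biological age -------------------------------------------------------
    stage = "bioage"
    try:
        if resume and paths["bioage_model"].exists() and paths["scores"].exists():
            model = bioage_mod.BioAgeModel.from_json(paths["bioage_model"])
            scores_df = pd.read_csv(paths["scores"])
        else:
            model = bioage_mod.fit_pca(
                X, ages, genders, min_age=config["pca"]["min_age"]
            )
            pc1 = bioage_mod.project(model, X)
            res = bioage_mod.detrend(pc1, ages, genders)
            model.detrend_coef = res.coef
            model.to_json(paths["bioage_model"])
            scores_df = pd.DataFrame(
                {"participant_id": desc_df["participant_id"],
                 "pc1": pc1, "baa": res.baa}
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- hazard models ----------------------------------------------------------
    stage = "hazards"
    try:
        if resume and paths["hazards_model"].exists() and paths["gompertz"].exists():
            hmodel = hazards_mod.HazardModel.from_json(paths["hazards_model"])
        else:
            hmodel = hazards_mod.fit_cox_ridge(
                X, genders,
                meta["followup_years"].to_numpy(),
                meta["delta_death"].to_numpy(),
                penalty=config["hazards"]["penalty"],
            )
            hmodel.to_json(paths["hazards_model"])
            gfit = hazards_mod.fit_cox_gompertz(
                ages,
                meta["followup_years"].to_numpy(),
                meta["delta_death"].to_numpy(),
            )
            with open(paths["gompertz"], "w") as fh:
                json.dump(
                    {"M0": gfit.M0, "Gamma": gfit.Gamma, "loglik": gfit.loglik,
                     "se_M0": gfit.se_M0, "se_Gamma": gfit.se_Gamma,
                     "doubling_time_years": hazards_mod.doubling_time(gfit.Gamma)},
                    fh, indent=2,
                )
        logmort = hazards_mod.predict_log_hazard(hmodel, X, genders)
        scores_df["logmort"] = logmort
        scores_df.to_csv(paths["scores"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- association table + group comparisons --------------------------------
    stage = "assoc"
    try:
        rows = []
        endpoints = {
            "mortality": ("followup_years", "delta_death"),
            "morbidity": ("followup_disease_years", "delta_disease"),
        }
        for name, score in [("Bioage PC1", scores_df["pc1"].to_numpy()),
                            ("LogMort", scores_df["logmort"].to_numpy())]:
            for ep, (tcol, ecol) in endpoints.items():
                if tcol not in meta.columns:
                    continue
                r = hazards_mod.assoc_test(
                    score, ages, genders,
                    meta[tcol].to_numpy(), meta[ecol].to_numpy(),
                )
                rows.append(
                    {"model": name, "endpoint": ep, "hr_per_sd": r.hr,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                     "n": r.n, "events": r.events}
                )
        pd.DataFrame(rows).to_csv(paths["assoc"], index=False)
        groups = hazards_mod.compare_groups(
            scores_df["baa"].to_numpy(), meta["smoking_status"].to_numpy()
        )
        groups["summary"].to_csv(paths["groups"], index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- manifest ---------------------------------------------------------------
    artifacts = {
        k: str(p) for k, p in paths.items() if p.exists() and k != "manifest"
    }
    manifest = {
        "seed": seed,
        "config": config,
        "artifacts": artifacts,
        "hashes": {k: _sha256(Path(p)) for k, p in artifacts.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"paths": {k: str(v) for k, v in paths.items()}, "manifest": manifest}
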