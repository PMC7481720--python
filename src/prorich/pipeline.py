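"""End-to-end orchestration: generate/ingest -> score -> exclude ->
measures -> regression -> power, with a reproducibility manifest.

Every stage writes a delimited text table (or JSON for the power report)
into the output directory; the manifest records the config, input
digests, per-stage row counts and timings so a run can be reproduced and
audited against the exclusion ledger.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import config as cfg
from .cohort import CohortConfig, generate_cohort, write_cohort
from .exclusions import run_cascade, summarize_cascade
from .measures import build_measures, table3, table4
from .power import PowerConfig, estimate_power, power_frame
from .regression import fit_omnibus, simple_effects
from .scoring import score_cohort

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(
    config: dict,
    outdir: str | Path,
    indir: str | Path | None = None,
) -> Path:
    """Run the analysis chain and write all outputs under *outdir*.

    If *indir* is given, trials.csv / demographics.csv / explicit.csv are
    read from there instead of being generated. Returns the output
    directory path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in config.items()},
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "stages": {},
        "row_counts": {},
        "input_digests": {},
    }
    t0 = time.time()

    def stage(name):
        def deco(fn):
            start = time.time()
            try:
                out = fn()
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = round(time.time() - start, 3)
            return out

        return deco

    # --- inputs -----------------------------------------------------------
    if indir is not None:
        indir = Path(indir)
        tables = {}
        for name in ("trials", "demographics", "explicit"):
            path = indir / f"{name}.csv"
            tables[name] = pd.read_csv(path)
            manifest["input_digests"][name] = _digest(path)
    else:

        @stage("simulate")
        def tables():
            cc = CohortConfig(
                n_participants=int(config["n_participants"]),
                prop_women=float(config["prop_women"]),
                income_education_corr=float(config["income_education_corr"]),
                coef_vector=cfg.coef_vector_from_config(config),
                residual_sd=config.get("residual_sd"),
                careless_rate=float(config.get("careless_rate", 0.0)),
                missing_income_rate=float(config.get("missing_income_rate", 0.0)),
                missing_education_rate=float(
                    config.get("missing_education_rate", 0.0)
                ),
                seed=int(config["seed"]),
            )
            t = generate_cohort(cc)
            write_cohort(t, outdir)
            for name in ("trials", "demographics", "explicit"):
                manifest["input_digests"][name] = _digest(outdir / f"{name}.csv")
            return t

    manifest["row_counts"]["participants_in"] = len(tables["demographics"])

    # --- exclusions (raw trials, before scoring-side trial removal) -------
    @stage("exclude")
    def report():
        rep = run_cascade(tables["trials"], tables["demographics"])
        rep.to_csv(outdir / "exclusions.csv", index=False)
        summary = summarize_cascade(rep)
        summary.to_csv(outdir / "exclusion_summary.csv", index=False)
        return rep

    retained_ids = report.loc[~report["excluded"], "participant_id"]
    manifest["row_counts"]["participants_retained"] = len(retained_ids)
    manifest["row_counts"]["participants_excluded"] = int(report["excluded"].sum())

    # --- D scores (all scoreable participants; analysis joins on retained)
    @stage("score")
    def scores():
        s = score_cohort(tables["trials"])
        s.to_csv(outdir / "scores.csv", index=False)
        return s

    # --- explicit measures ------------------------------------------------
    @stage("measures")
    def measures():
        m = build_measures(tables["explicit"])
        m = m[m["participant_id"].isin(retained_ids)]
        m.to_csv(outdir / "measures.csv", index=False)
        table3(m).to_csv(outdir / "table3.csv", index=False)
        retained_scores = scores[scores["participant_id"].isin(retained_ids)]
        table4(m, retained_scores).to_csv(outdir / "table4.csv", index=False)
        return m

    # --- omnibus regression + simple effects ------------------------------
    @stage("regress")
    def fit():
        analysis = (
            tables["demographics"]
            .merge(scores, on="participant_id")
            .loc[lambda df: df["participant_id"].isin(retained_ids)]
        )
        manifest["row_counts"]["analysis_n"] = len(analysis)
        f = fit_omnibus(
            analysis,
            outcome="d",
            vif_threshold=float(config["vif_threshold"]),
        )
        f.to_frame().to_csv(outdir / "model.csv", index=False)
        simple_effects(f).to_csv(outdir / "simple_effects.csv", index=False)
        return f

    # --- power -------------------------------------------------------------
    @stage("power")
    def power_results():
        pc = PowerConfig(
            coef_vector=cfg.coef_vector_from_config(config),
            prop_women=float(config["prop_women"]),
            income_education_corr=float(config["income_education_corr"]),
            residual_sd=config.get("residual_sd"),
            n_per_dataset=int(config["power_n"]),
            n_reps=int(config["n_reps"]),
            alpha=float(config["alpha"]),
            seed=int(config["seed"]),
        )
        res = estimate_power(pc)
        frame = power_frame(res)
        payload = {
            "seed": int(config["seed"]),
            "n_per_dataset": int(config["power_n"]),
            "n_reps": int(config["n_reps"]),
            "alpha": float(config["alpha"]),
            "tests": frame.to_dict(orient="records"),
        }
        (outdir / "power_report.json").write_text(json.dumps(payload, indent=2))
        return res

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return outdir
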