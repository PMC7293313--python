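"""Configuration, table validation, I/O and the end-to-end pipeline.

Stages chain simulate -> process -> hrv -> repeatability -> metrics ->
models. Every CSV written carries a header comment line recording the
master seed and a hash of the configuration, so any output can be
traced back to the exact run that produced it.
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
import yaml

from . import hrv as hrvmod
from . import ibi as ibimod
from . import inference, metrics, repeatability, synthetic

log = logging.getLogger("copingcolony")

__all__ = ["PipelineConfig", "run_pipeline", "validate_table",
           "write_csv", "read_csv"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    master_seed: int = 0
    # synthetic stage
    n_ibi_traces: int = 3
    ibi: synthetic.IBISimParams = field(default_factory=synthetic.IBISimParams)
    artefacts: synthetic.ArtefactSpec = field(
        default_factory=lambda: synthetic.ArtefactSpec(p_missed_beat=0.005,
                                                       p_extra_beat=0.005,
                                                       n_flats=1, n_stairs=1))
    colony: synthetic.ColonySimParams = field(default_factory=synthetic.ColonySimParams)
    # processing stage
    cleaning: ibimod.CleaningConfig = field(default_factory=ibimod.CleaningConfig)
    # repeatability stage
    min_seasons: int = 2
    n_boot: int = 1000
    # metrics stage
    log_offset: float = metrics.DEFAULT_LOG_OFFSET
    # models stage
    analysis: inference.AnalysisConfig = field(default_factory=inference.AnalysisConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(val, dict):
                for k2, v2 in val.items():
                    if not hasattr(cur, k2):
                        raise ValueError(f"unknown config key {key}.{k2}")
                    setattr(cur, k2, v2)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        def conv(o):
            if dataclasses.is_dataclass(o):
                return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(map(str, o)) if isinstance(o, (frozenset, set)) else list(o)
            return o
        return {f.name: conv(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: str | Path, *, seed: int,
              config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# copingcolony seed={seed} config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# schema validation


_SCHEMAS = {
    "ibi_trace": ["time_s", "ibi_ms"],
    "behaviour": ["start_s", "end_s", "state"],
    "captures": ["id", "year", "birthdate_doy", "pup_sex", "device",
                 "cap1_date", "cap1_mass_kg", "cap2_date", "cap2_mass_kg",
                 "pup1_mass_kg", "pup2_mass_kg"],
    "hrv_table": ["id", "year", "resting_hrv_ms", "n_windows"],
}


def validate_table(file: str | Path, schema_name: str) -> list[str]:
    """Check a CSV against a named schema; returns human-readable
    violations (missing columns, sign/ordering breaches, duplicate
    id-year rows) with 1-based data row numbers."""
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    try:
        df = read_csv(file)
    except OSError as exc:
        raise OSError(f"cannot read {file}: {exc}") from exc
    violations: list[str] = []
    missing = [c for c in _SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        violations.append(f"missing columns: {', '.join(missing)}")
        return violations

    def rows_where(mask, msg):
        for r in np.nonzero(np.asarray(mask))[0]:
            violations.append(f"row {r + 1}: {msg}")

    if schema_name == "ibi_trace":
        rows_where(df["ibi_ms"] <= 0, "ibi_ms must be positive")
        rows_where(df["time_s"].diff().fillna(1) <= 0,
                   "time_s must be strictly increasing")
    elif schema_name == "behaviour":
        rows_where(df["start_s"] >= df["end_s"], "start_s must be < end_s")
    elif schema_name == "captures":
        rows_where(df["cap2_date"] <= df["cap1_date"],
                   "cap2_date must be after cap1_date")
        rows_where(df["cap1_date"] < df["birthdate_doy"],
                   "cap1_date before birthdate")
        for c in ("cap1_mass_kg", "cap2_mass_kg", "pup1_mass_kg", "pup2_mass_kg"):
            rows_where(df[c] <= 0, f"{c} must be positive")
        dup = df.duplicated(subset=["id", "year"])
        rows_where(dup, "duplicate (id, year)")
    elif schema_name == "hrv_table":
        rows_where(df["resting_hrv_ms"] < 0, "resting_hrv_ms must be >= 0")
        dup = df.duplicated(subset=["id", "year"])
        rows_where(dup, "duplicate (id, year)")
    return violations


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the provenance
    manifest (also written to ``<out_dir>/manifest.json``).

    A stage failure is recorded in the manifest with a ``.failed``
    marker file and a nonzero ``exit_status``; completed stage outputs
    are retained.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.master_seed
    manifest: dict = {"version": __version__, "seed": seed,
                      "config_hash": chash, "stages": {}, "exit_status": 0}
    master = np.random.default_rng(seed)
    stage_seeds = {name: int(s.integers(2**31))
                   for name, s in zip(
                       ("simulate_ibi", "artefacts", "colony", "repeatability", "models"),
                       master.spawn(5))}

    def fail(stage, exc):
        log.error("stage %s failed: %s", stage, exc)
        (out / f"{stage}.failed").write_text(str(exc))
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["exit_status"] = 1

    # --- simulate ---------------------------------------------------------
    season_rows = []
    try:
        for t in range(config.n_ibi_traces):
            p = dataclasses.replace(config.ibi, seed=stage_seeds["simulate_ibi"] + t)
            trace, blog, _ = synthetic.simulate_ibi_trace(p)
            corrupted, ledger = synthetic.inject_artefacts(
                trace, dataclasses.replace(config.artefacts,
                                           seed=stage_seeds["artefacts"] + t))
            write_csv(corrupted.to_frame(), out / f"ibi_trace_{t}.csv",
                      seed=seed, config_hash=chash)
            write_csv(blog, out / f"behaviour_{t}.csv", seed=seed, config_hash=chash)
            # --- process + hrv --------------------------------------------
            _, windows = ibimod.process_trace(corrupted, blog, config.cleaning)
            qc = ibimod.windows_qc_frame(windows)
            write_csv(qc, out / f"qc_trace_{t}.csv", seed=seed, config_hash=chash)
            retained = qc[qc["retained"]]
            log.info("trace %d: %d/%d windows retained", t, len(retained), len(qc))
            srec = hrvmod.season_resting_hrv(retained["rmssd_ms"].tolist(),
                                             seal_id=f"T{t}", year=2013)
            season_rows.append(dict(id=srec.seal_id, year=srec.year,
                                    resting_hrv_ms=srec.resting_hrv,
                                    n_windows=srec.n_windows,
                                    insufficient_flag=srec.insufficient))
        manifest["stages"]["simulate_ibi"] = {"status": "ok",
                                              "n_traces": config.n_ibi_traces}
        manifest["stages"]["process"] = {"status": "ok",
                                         "n_season_rows": len(season_rows)}
    except Exception as exc:
        fail("process", exc)

    # --- colony -----------------------------------------------------------
    try:
        cparams = dataclasses.replace(config.colony, seed=stage_seeds["colony"])
        captures, hrv_table, truth = synthetic.simulate_colony(cparams)
        write_csv(captures, out / "captures.csv", seed=seed, config_hash=chash)
        write_csv(hrv_table, out / "hrv_seasons.csv", seed=seed, config_hash=chash)
        manifest["stages"]["colony"] = {
            "status": "ok", "n_rows": len(captures),
            "n_ids": int(captures["id"].nunique()),
            "true_repeatability": truth.true_repeatability}
    except Exception as exc:
        fail("colony", exc)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- repeatability ----------------------------------------------------
    try:
        rep = repeatability.estimate_repeatability(
            hrv_table, min_seasons=config.min_seasons,
            n_boot=config.n_boot, seed=stage_seeds["repeatability"])
        (out / "repeatability.json").write_text(json.dumps(rep.to_dict(), indent=2))
        ri = pd.DataFrame(sorted(rep.Ri.items()), columns=["id", "Ri"])
        write_csv(ri, out / "repeatability_Ri.csv", seed=seed, config_hash=chash)
        manifest["stages"]["repeatability"] = {"status": "ok", "R": rep.R,
                                               "n_ids": rep.n_ids}
    except Exception as exc:
        fail("repeatability", exc)

    # --- metrics ----------------------------------------------------------
    try:
        perf = metrics.performance_table(captures, eps=config.log_offset)
        ind = hrvmod.individual_hrv_table(hrv_table)
        table = metrics.build_analysis_table(perf, ind, eps=config.log_offset)
        write_csv(table, out / "analysis_table.csv", seed=seed, config_hash=chash)
        manifest["stages"]["metrics"] = {"status": "ok", "n_rows": len(table)}
    except Exception as exc:
        fail("metrics", exc)
        table = None

    # --- models -----------------------------------------------------------
    if table is not None:
        try:
            acfg = dataclasses.replace(config.analysis,
                                       seed=stage_seeds["models"])
            report = inference.run_analysis(table, acfg)
            (out / "models_report.json").write_text(
                json.dumps(report, indent=2, default=float))
            for resp, entry in report["responses"].items():
                if "confidence_set" in entry:
                    cs = pd.DataFrame(entry["confidence_set"] + [entry["null_model"]])
                    write_csv(cs, out / f"confidence_set_{resp}.csv",
                              seed=seed, config_hash=chash)
            manifest["stages"]["models"] = {
                "status": "ok",
                "n_responses": len(report["responses"])}
        except Exception as exc:
            fail("models", exc)

    manifest["n_completed_stages"] = sum(
        1 for s in manifest["stages"].values() if s.get("status") == "ok")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
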