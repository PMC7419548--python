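"""End-to-end pipeline: simulate -> features -> select -> fit -> stats -> report.

Each stage writes its outputs under the run directory and records itself in
``manifest.json`` together with a hash of the full configuration.  A stage is
skipped when its manifest entry and outputs already exist under the same
config hash; a downstream stage refuses to run on upstream outputs produced
under a different hash.  All randomness derives from the single root seed.
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

from . import endostats as es
from . import features as ft
from . import selection as sel
from . import simdata as sd
from . import twostage as ts

log = logging.getLogger("endomod")

STAGES = ("simulate", "features", "select", "fit", "stats", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "endomod_run"
    root_seed: int = 0
    stages: tuple[str, ...] = STAGES
    session: sd.SessionConfig = field(default_factory=sd.SessionConfig)
    filter_spec: ft.FilterSpec = field(default_factory=ft.FilterSpec)
    spectral_spec: ft.SpectralSpec = field(default_factory=ft.SpectralSpec)
    artifact_spec: ft.ArtifactSpec = field(default_factory=ft.ArtifactSpec)
    penalty: ts.PenaltyConfig = field(default_factory=ts.PenaltyConfig)
    permutation: es.PermutationSpec = field(default_factory=es.PermutationSpec)
    selection_threshold: float = 0.5
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"]["epoch_window_ms"] = list(self.session.epoch_window_ms)
        if self.session.electrode_coordinates is not None:
            d["session"]["electrode_coordinates"] = np.asarray(
                self.session.electrode_coordinates).tolist()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "session" in d:
            s = dict(d["session"])
            if "epoch_window_ms" in s:
                s["epoch_window_ms"] = tuple(s["epoch_window_ms"])
            if s.get("electrode_coordinates") is not None:
                s["electrode_coordinates"] = np.asarray(s["electrode_coordinates"])
            if "modulation_params" in s:
                s["modulation_params"] = sd.ModulationParams(**s["modulation_params"])
            d["session"] = sd.SessionConfig(**s)
        for key, typ in (
            ("filter_spec", ft.FilterSpec), ("spectral_spec", ft.SpectralSpec),
            ("artifact_spec", ft.ArtifactSpec), ("penalty", ts.PenaltyConfig),
            ("permutation", es.PermutationSpec),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for band in ("line_stop_band", "stp_pass_band", "bha_band"):
                    if band in sub:
                        sub[band] = tuple(sub[band])
                d[key] = typ(**sub)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("stages", None)         # which stages run does not alter outputs
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.record = {"stage": stage, "error": message}


def _derived_seeds(root_seed: int) -> dict:
    """Named integer sub-seeds, all below 2**31, from the root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(4) % (2**31)
    return {
        "session": int(state[0]),
        "cv": int(state[1]),
        "selection": int(state[2]),
        "permutation": int(state[3]),
    }


def _load_manifest(out: Path) -> dict:
    path = out / "manifest.json"
    if path.exists():
        with open(path) as f:
            return json.load(f)
    return {"stages": {}}


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _derived_seeds(config.root_seed)
    manifest = _load_manifest(out)
    manifest["config_hash"] = chash
    manifest["seeds"] = seeds
    with open(out / "config.json", "w") as f:
        json.dump(config.to_dict(), f, indent=2, default=str)

    def done(stage: str) -> bool:
        entry = manifest["stages"].get(stage)
        return bool(entry and entry.get("config_hash") == chash
                    and all(Path(p).exists() for p in entry.get("outputs", [])))

    def require(stage: str, *deps: str) -> None:
        for dep in deps:
            if not done(dep):
                raise StageError(
                    stage, f"upstream stage '{dep}' missing or produced under a "
                           f"different config hash")

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "config_hash": chash,
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.time() - t0, 3),
            "seed": seeds.get("session") if stage == "simulate" else seeds.get("cv"),
        }
        _write_manifest(out, manifest)

    session_dir = out / "session"
    feat_dir = out / "features"
    fit_dir = out / "fits"

    for stage in STAGES:
        if stage not in config.stages:
            continue
        if done(stage):
            log.info("stage %s: outputs up to date, skipping", stage)
            continue
        t0 = time.time()
        log.info("stage %s: running", stage)
        try:
            if stage == "simulate":
                cfg = dataclasses.replace(config.session, rng_seed=seeds["session"])
                session = sd.generate_session(cfg)
                sd.save_session(session, session_dir)
                record(stage, [session_dir / "traces.h5"], t0)

            elif stage == "features":
                require(stage, "simulate")
                session = sd.load_session(session_dir)
                outputs = []
                for e in range(session.config.n_electrodes):
                    fs = ft.build_feature_matrices(
                        session, e, config.filter_spec, config.spectral_spec,
                        config.artifact_spec)
                    outputs.append(ft.save_features(fs, feat_dir))
                pd.DataFrame({"feature_file": [str(p) for p in outputs]}).to_csv(
                    feat_dir / "feature_manifest.csv", index=False)
                record(stage, outputs, t0)

            elif stage == "select":
                require(stage, "features")
                session = sd.load_session(session_dir)
                fsets = [ft.load_features(p) for p in sorted(feat_dir.glob(
                    "features_*.h5"))]
                results = sel.select_electrodes(
                    fsets, session.trial_table,
                    threshold=config.selection_threshold,
                    seed=seeds["selection"])
                path = sel.save_selection(results, out)
                record(stage, [path], t0)

            elif stage == "fit":
                require(stage, "select")
                session = sd.load_session(session_dir)
                selection = pd.read_csv(out / "selection.csv")
                cat_by_trial = session.trial_table.set_index("trial_index")[
                    "category"]
                outputs = []
                for _, row in selection.iterrows():
                    if row["selected_category"] in ("", None) or pd.isna(
                            row["selected_category"]):
                        continue
                    eid = row["electrode_id"]
                    fs = ft.load_features(feat_dir / f"features_{eid}.h5")
                    labels = cat_by_trial.loc[fs.kept_trials].to_numpy()
                    y = (labels == int(row["selected_category"])).astype(int)
                    fit = ts.fit_two_stage(fs, y, config.penalty,
                                           cv_seed=seeds["cv"])
                    outputs.append(ts.save_fit(fit, fit_dir))
                    log.info("  electrode %s: d'_evk=%.3f d'_pre=%.3f", eid,
                             fit.dprime_evk, fit.dprime_pre)
                record(stage, outputs, t0)

            elif stage == "stats":
                require(stage, "fit")
                session = sd.load_session(session_dir)
                selection = pd.read_csv(out / "selection.csv")
                stats, mi_rows = [], {}
                sel_cat, coords = {}, {}
                for _, row in selection.iterrows():
                    if row["selected_category"] in ("", None) or pd.isna(
                            row["selected_category"]):
                        continue
                    eid = row["electrode_id"]
                    fit = _load_fit(fit_dir, eid)
                    fs = ft.load_features(feat_dir / f"features_{eid}.h5")
                    spec = dataclasses.replace(
                        config.permutation, rng_seed=seeds["permutation"])
                    stats.append(es.electrode_endostats(
                        fit, fs.X_pre, np.asarray(fs.pre_labels["kind"]),
                        session.trial_table, fs.kept_trials,
                        int(row["selected_category"]), spec))
                    mi_rows[eid] = pd.Series(fit.mi, index=fs.kept_trials)
                    sel_cat[eid] = int(row["selected_category"])
                    erow = session.electrode_table.set_index(
                        "electrode_id").loc[eid]
                    coords[eid] = erow[["x_mm", "y_mm", "z_mm"]].to_numpy(float)

                table = es.endostats_table(stats) if stats else pd.DataFrame()
                table.to_csv(out / "endostats.csv", index=False)
                cross = {}
                if len(mi_rows) >= 2:
                    mi_df = pd.DataFrame(mi_rows).dropna()
                    eids = list(mi_df.columns)
                    cross = es.cross_electrode_correlation(
                        mi_df[eids].to_numpy().T,
                        np.stack([coords[e] for e in eids]),
                        np.array([sel_cat[e] for e in eids]),
                        dataclasses.replace(config.permutation,
                                            rng_seed=seeds["permutation"]))
                with open(out / "endostats_summary.json", "w") as f:
                    json.dump({"cross_electrode": _jsonable(cross),
                               "n_electrodes": len(stats)}, f, indent=2)
                record(stage, [out / "endostats.csv",
                               out / "endostats_summary.json"], t0)

            elif stage == "report":
                require(stage, "stats")
                report = make_report(out)
                with open(out / "report.json", "w") as f:
                    json.dump(_jsonable(report), f, indent=2)
                record(stage, [out / "report.json"], t0)
        except StageError:
            raise
        except Exception as exc:  # halt with a machine-readable record
            raise StageError(stage, str(exc)) from exc
        log.info("stage %s: done in %.1f s", stage, time.time() - t0)

    return manifest


def _load_fit(fit_dir: Path, eid: str):
    import h5py

    with open(fit_dir / f"fit_{eid}.json") as f:
        meta = json.load(f)
    with h5py.File(fit_dir / f"fit_{eid}.h5", "r") as f:
        arrs = {k: f[k][...] for k in f.keys()}
    return ts.TwoStageFit(
        electrode_id=eid,
        y=arrs["y"],
        outer_assignments=np.asarray(meta["outer_assignments"]),
        fold_beta_evk=arrs["fold_beta_evk"],
        fold_intercept_evk=arrs["fold_intercept_evk"],
        fold_beta_pre=arrs["fold_beta_pre"],
        fold_intercept_pre=arrs["fold_intercept_pre"],
        lambda1=np.asarray(meta["lambda1"]),
        lambda2=np.asarray(meta["lambda2"]),
        mi=arrs["mi"],
        loadings_evk=arrs["loadings_evk"],
        decision_evk=np.zeros_like(arrs["mi"]),
        decision_pre=np.zeros_like(arrs["mi"]),
        dprime_evk=meta["dprime_evk"],
        dprime_pre=meta["dprime_pre"],
        inner_deviance_evk=np.zeros((0, 0)),
        inner_deviance_pre=np.zeros((0, 0)),
        converged=meta["converged"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def make_report(run_dir: str | Path) -> dict:
    """Summary tables for a completed run: per-category d' improvement,
    MI-RT correlations, quartile contrasts, cross-electrode correlations,
    autocorrelation exceedance."""
    run_dir = Path(run_dir)
    missing = [p for p in ("selection.csv", "endostats.csv",
                           "endostats_summary.json")
               if not (run_dir / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    selection = pd.read_csv(run_dir / "selection.csv")
    fits = []
    for path in sorted((run_dir / "fits").glob("fit_*.json")):
        with open(path) as f:
            fits.append(json.load(f))
    with open(run_dir / "endostats_summary.json") as f:
        summary = json.load(f)

    report: dict = {"n_selected_electrodes": len(fits)}
    if not fits:
        report["note"] = "0 selected electrodes"
        return report

    fit_df = pd.DataFrame(
        [{"electrode_id": f["electrode_id"], "dprime_evk": f["dprime_evk"],
          "dprime_pre": f["dprime_pre"], "delta_dprime": f["delta_dprime"]}
         for f in fits]
    )
    cat = selection.set_index("electrode_id")["selected_category"]
    fit_df["category"] = fit_df["electrode_id"].map(cat)
    report["dprime_by_category"] = (
        fit_df.groupby("category")[["dprime_evk", "dprime_pre", "delta_dprime"]]
        .mean().reset_index().to_dict(orient="records"))
    report["mean_dprime_evk"] = float(fit_df["dprime_evk"].mean())
    report["mean_dprime_pre"] = float(fit_df["dprime_pre"].mean())
    report["mean_delta_dprime"] = float(fit_df["delta_dprime"].mean())
    if len(fit_df) >= 2:
        report["delta_dprime_ttest"] = es.group_paired_ttest(
            fit_df["dprime_pre"].to_numpy(), fit_df["dprime_evk"].to_numpy())

    try:
        stats = pd.read_csv(run_dir / "endostats.csv")
    except pd.errors.EmptyDataError:
        stats = pd.DataFrame()
    if len(stats):
        for col in ("rho_preferred", "rho_nonpreferred",
                    "delta_rt_quartile_ms", "loading_rt_rho"):
            if col in stats:
                report[f"mean_{col}"] = float(stats[col].mean())
        for col in ("stbha_mean", "stbha_sd", "abs_stp_mean", "stp_sd"):
            if col in stats:
                report[f"quartile_contrast_{col}"] = float(stats[col].mean())
        if "lag1_significant" in stats:
            report["autocorr_exceedance_fraction"] = float(
                stats["lag1_significant"].mean())
    report["cross_electrode"] = summary.get("cross_electrode", {})
    return report
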