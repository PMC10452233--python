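"""End-to-end orchestration: simulate -> preprocess -> inverse -> pec ->
graph -> stats -> classify, with a provenance manifest and stage caching.

Every stage writes its outputs under the run directory and records a
signature (hash of its parameters chained with its upstream signature) in
manifest.json; re-running with an unchanged configuration skips cached
stages, while changing one stage's parameters invalidates exactly that
stage and everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import classify as clf_mod
from . import connectivity, io, stats, topology
from .bands import BANDS
from .inverse import InverseConfig, source_reconstruct
from .preprocess import epoch_and_baseline
from .synthetic import (GroupEffect, SimulationConfig, generate_cohort,
                        roi_labels)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "inverse", "pec", "graph", "stats",
          "classify"]


def default_run_config() -> dict:
    """Desk-scale default run: 3 x 5 subjects, beta-band coupling with the
    planted couplings halved in the CS group."""
    return {
        "seed": 0,
        "bands": ["beta"],
        "simulate": {
            "n_subjects_per_group": 5,
            "groups": ["HC", "CS", "SS"],
            "n_sensors": 32,
            "n_rois": 68,
            "dipoles_per_roi": 1,
            "fs": 256.0,
            "n_epochs": 20,
            "band": [13.0, 30.0],
            "coupling_spec": [[0, 5, 0.8], [10, 20, 0.8], [30, 40, 0.8]],
            "group_effects": {"CS": {"rho_scale": 0.5}},
            "snr": 3.0,
        },
        "preprocess": {"window": [-100.0, 500.0], "baseline": [-100.0, 0.0]},
        "inverse": {"delta": 0.01, "depth_weighting": True},
        "pec": {"env_lowpass": 2.0},
        "graph": {"density": 0.10, "n_random": 100},
        "stats": {"alpha": 0.05},
        "classify": {"fs_methods": ["Corr"], "classifiers": ["LR"],
                     "feature_grid": [1, 2, 5, 10, 20, 50],
                     "pairs": "first_vs_rest"},
    }


def load_run_config(path: str | Path) -> dict:
    """Merge a YAML config file over the defaults (one file = one run)."""
    cfg = default_run_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _signature(params: dict, upstream: str) -> str:
    blob = json.dumps(params, sort_keys=True, default=str) + upstream
    return hashlib.sha256(blob.encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(cfg: dict) -> SimulationConfig:
    s = dict(cfg["simulate"])
    effects = {g: GroupEffect(rho_scale=e.get("rho_scale", 1.0),
                              edges=tuple(map(tuple, e["edges"]))
                              if e.get("edges") else None)
               for g, e in s.pop("group_effects", {}).items()}
    return SimulationConfig(
        coupling_spec=tuple((int(i), int(j), float(r))
                            for i, j, r in s.pop("coupling_spec", [])),
        group_effects=effects, seed=cfg["seed"],
        groups=tuple(s.pop("groups", ("HC", "CS", "SS"))),
        band=tuple(s.pop("band", (13.0, 30.0))),
        **s)


class PipelineRun:
    """Stateful runner over a run directory with manifest-based caching."""

    def __init__(self, cfg: dict, outdir: str | Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else {"stages": {}})
        self.sim_config = _sim_config(cfg)
        self.bands = [BANDS[b] for b in cfg["bands"]]

    # -- caching machinery -------------------------------------------------
    def _cached(self, stage: str, sig: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry["signature"] != sig:
            return False
        return all((self.outdir / p).exists() for p in entry["outputs"])

    def _record(self, stage: str, sig: str, params: dict,
                outputs: list[Path], elapsed: float, seed: int) -> None:
        self.manifest["stages"][stage] = {
            "signature": sig, "params": params, "seed": seed,
            "elapsed_s": round(elapsed, 3),
            "outputs": {str(p.relative_to(self.outdir)): _hash_file(p)
                        for p in outputs}}
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _run_stage(self, stage: str, params: dict, upstream_sig: str,
                   compute) -> str:
        sig = _signature(params, upstream_sig)
        if self._cached(stage, sig):
            logger.info("stage %s: cached, skipping", stage)
            return sig
        t0 = time.time()
        outputs = compute()
        self._record(stage, sig, params, outputs, time.time() - t0,
                     self.cfg["seed"])
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)
        return sig

    # -- stages ------------------------------------------------------------
    def run(self) -> Path:
        cfg = self.cfg
        sig = self._run_stage("simulate", cfg["simulate"] | {"seed": cfg["seed"]},
                              "", self._simulate)
        sig = self._run_stage("preprocess", cfg["preprocess"]
                              | {"bands": cfg["bands"]}, sig, self._preprocess)
        sig = self._run_stage("inverse", cfg["inverse"], sig, self._inverse)
        sig = self._run_stage("pec", cfg["pec"], sig, self._pec)
        sig = self._run_stage("graph", cfg["graph"], sig, self._graph)
        sig = self._run_stage("stats", cfg["stats"], sig, self._stats)
        sig = self._run_stage("classify", cfg["classify"], sig, self._classify)
        return self.outdir

    def _subjects(self):
        subs, _ = io.load_cohort_subjects(self.outdir / "cohort")
        return subs

    def _simulate(self) -> list[Path]:
        cohort = generate_cohort(self.sim_config)
        return io.save_cohort(self.outdir / "cohort", cohort) + [
            self.outdir / "cohort" / "leadfield.h5"]

    def _preprocess(self) -> list[Path]:
        from .preprocess import average_reference, bandpass
        p = self.cfg["preprocess"]
        out = self.outdir / "preproc.h5"
        subs = self._subjects()
        with h5py.File(out, "w") as f:
            for rec in subs:
                x = average_reference(rec.continuous)
                for band in self.bands:
                    xb = bandpass(x, rec.fs, band.lo, band.hi)
                    ep = epoch_and_baseline(
                        xb, rec.fs, rec.onsets, window=tuple(p["window"]),
                        baseline=tuple(p["baseline"]), band=band.name)
                    f.create_dataset(f"{rec.subject_id}/{band.name}",
                                     data=ep.data)
            f.attrs["fs"] = subs[0].fs
        return [out]

    def _inverse(self) -> list[Path]:
        icfg = InverseConfig(delta=self.cfg["inverse"]["delta"],
                             depth_weighting=self.cfg["inverse"]
                             ["depth_weighting"])
        lf = io.load_leadfield(self.outdir / "cohort" / "leadfield.h5")
        labels = roi_labels(self.sim_config)
        out = self.outdir / "sources.h5"
        with h5py.File(self.outdir / "preproc.h5", "r") as fin, \
                h5py.File(out, "w") as fout:
            fs = float(fin.attrs["fs"])
            for sid in fin:
                for band in fin[sid]:
                    src = source_reconstruct(fin[sid][band][()], lf, labels,
                                             fs, icfg)
                    fout.create_dataset(f"{sid}/{band}", data=src.data)
            fout.attrs["fs"] = fs
        return [out]

    def _pec(self) -> list[Path]:
        labels = roi_labels(self.sim_config)
        env_lp = self.cfg["pec"]["env_lowpass"]
        subs = self._subjects()
        meta = {s.subject_id: s.group for s in subs}
        outputs = []
        mat_dir = self.outdir / "pec"
        mat_dir.mkdir(exist_ok=True)
        with h5py.File(self.outdir / "sources.h5", "r") as f:
            fs = float(f.attrs["fs"])
            for band in self.cfg["bands"]:
                mats, sids = [], []
                for sid in sorted(f):
                    pm = connectivity.subject_pec(
                        f[sid][band][()], labels, fs, band=None,
                        env_lowpass=env_lp, subject_id=sid)
                    pm.band = band
                    mats.append(pm)
                    sids.append(sid)
                    p = mat_dir / f"{sid}_{band}.tsv"
                    io.save_matrix_txt(p, pm.matrix)
                    outputs.append(p)
                feat = connectivity.features_table(mats)
                p = self.outdir / f"features_{band}.csv"
                io.save_features_csv(p, feat, sids, [meta[s] for s in sids])
                outputs.append(p)
        return outputs

    def _graph(self) -> list[Path]:
        g = self.cfg["graph"]
        records = []
        for band in self.cfg["bands"]:
            df = pd.read_csv(self.outdir / f"features_{band}.csv")
            n = self.sim_config.n_rois
            iu = np.triu_indices(n, k=1)
            for _, row in df.iterrows():
                w = np.zeros((n, n))
                w[iu] = row.iloc[2:].to_numpy(dtype=float)
                w += w.T
                m = topology.graph_metrics(w, density=g["density"],
                                           n_random=g["n_random"],
                                           seed=self.cfg["seed"])
                records.append({
                    "subject": row["subject"], "group": row["group"],
                    "band": band, "CC": m.CC, "L": m.L, "sigma": m.sigma,
                    "Eglobal": m.Eglobal, "Elocal": m.Elocal,
                    "unreachable_fraction": m.unreachable_fraction})
        out = self.outdir / "metrics.csv"
        stats.metrics_table(records).to_csv(out, index=False)
        return [out]

    def _stats(self) -> list[Path]:
        alpha = self.cfg["stats"]["alpha"]
        outputs = []
        for band in self.cfg["bands"]:
            df = pd.read_csv(self.outdir / f"features_{band}.csv")
            values = df.iloc[:, 2:].to_numpy(dtype=float)
            res = stats.anova_edgewise(values, df["group"].to_numpy(),
                                       alpha=alpha)
            p = self.outdir / f"edgewise_{band}.csv"
            res.to_csv(p, index=False)
            outputs.append(p)
            if self.sim_config.n_rois == 68:
                counts = stats.roi_group_summary(
                    res["significant"].to_numpy())
                p = self.outdir / f"roi_summary_{band}.tsv"
                io.save_matrix_txt(p, counts)
                outputs.append(p)
        metrics = pd.read_csv(self.outdir / "metrics.csv")
        rows = []
        for band in self.cfg["bands"]:
            sub = metrics[metrics["band"] == band]
            for metric in ["CC", "L", "sigma", "Eglobal", "Elocal"]:
                col = sub[metric].to_numpy(dtype=float)
                if not np.all(np.isfinite(col)):
                    continue
                r = stats.kruskal_wallis_with_posthoc(
                    col, sub["group"].to_numpy())
                rows.append({"band": band, "metric": metric,
                             "H": r.statistic, "p": r.p_raw})
        p = self.outdir / "metric_stats.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        outputs.append(p)
        return outputs

    def _classify(self) -> list[Path]:
        c = self.cfg["classify"]
        groups = list(self.sim_config.groups)
        pairs = [(groups[0], g) for g in groups[1:]]
        outputs = []
        for band in self.cfg["bands"]:
            df = pd.read_csv(self.outdir / f"features_{band}.csv")
            for ga, gb in pairs:
                sel = df["group"].isin([ga, gb])
                x = df.loc[sel].iloc[:, 2:].to_numpy(dtype=float)
                y = (df.loc[sel, "group"] == gb).astype(int).to_numpy() + 1
                grid = np.array([j for j in c["feature_grid"]
                                 if j <= x.shape[1]], dtype=int)
                results = {}
                for fs_m in c["fs_methods"]:
                    for clf in c["classifiers"]:
                        results[(fs_m, clf)] = clf_mod.run_loocv(
                            x, y, fs_m, clf, feature_grid=grid,
                            seed=self.cfg["seed"])
                table = clf_mod.summarize_grid(results)
                p = self.outdir / f"classify_{band}_{ga}_vs_{gb}.csv"
                table.to_csv(p, index=False)
                outputs.append(p)
                best = results[max(results, key=lambda k: results[k].accuracy)]
                payload = {
                    "band": band, "pair": [ga, gb],
                    "acc_cv": best.acc_cv.tolist(),
                    "feature_grid": best.feature_grid.tolist(),
                    "K": int(best.K),
                    "optimal_features": best.optimal_features.tolist(),
                    "confusion": best.confusion.tolist(),
                    "sensitivity": best.sensitivity,
                    "specificity": best.specificity}
                pj = self.outdir / f"classify_{band}_{ga}_vs_{gb}.json"
                pj.write_text(json.dumps(payload, indent=1))
                outputs.append(pj)
        return outputs


def run_pipeline(cfg: dict | str | Path, outdir: str | Path) -> Path:
    """Run (or resume) the full pipeline into `outdir`; returns the run dir."""
    if not isinstance(cfg, dict):
        cfg = load_run_config(cfg)
    return PipelineRun(cfg, outdir).run()
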