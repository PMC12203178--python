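"""End-to-end orchestration: simulate -> reconstruct -> ROI stats -> models.

The pipeline has two arms.  The *imaging* arm builds per-subject midbrain
phantoms from two value classes (healthy-like and Parkinson-like with raised
posteroventral susceptibility), simulates multi-echo data, reconstructs QSM
and R2* maps, extracts per-territory statistics and runs the baseline group
model on them.  The *cohort* arm generates the three-visit cohort table with
the paper-derived defaults and runs the longitudinal mixed models,
correlation families and demographics.  Every run writes tidy CSV reports
and a JSON manifest (config hash, seeds, per-output checksums) so identical
config + seed reproduces identical deterministic outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import io as nio
from . import roi as roi_mod
from . import stats as stats_mod
from .phantom import build_phantom, nigral_value_presets, simulate_echoes
from .qsm import StageError, reconstruct_qsm
from .r2star import fit_r2star

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "nigraq_out",
    "stages": {"imaging": True, "qsm": True, "r2star": True, "cohort_stats": True},
    "imaging": {
        "grid": 32,
        "n_per_class": 6,
        "classes": ["HV", "PD"],
        "noise_sd": 0.5,
        "subject_chi_sd": 0.005,  # between-subject jitter on nigral chi (ppm)
        "medi": {"lambda_reg": 1000.0, "edge_fraction": 0.3, "max_outer": 8, "cg_maxiter": 25},
    },
    "cohort": {
        "rois": ["posteroventral"],
        "stats_rois": ["posteroventral"],
        "correlation_pairs": [
            ["qsm_ppm", "r2s_hz"],
            ["qsm_ppm", "disease_duration_years"],
            ["qsm_ppm", "nm_cvol"],
            ["qsm_ppm", "dat_sbr_putamen"],
        ],
    },
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CONFIG)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(cfg, user)
        return cls(cfg)

    def validate(self) -> None:
        img = self.raw["imaging"]
        if img["grid"] < 32:
            raise ValueError("imaging.grid must be >= 32")
        if img["noise_sd"] < 0:
            raise ValueError("imaging.noise_sd must be >= 0")
        medi = img["medi"]
        if medi["lambda_reg"] <= 0:
            raise ValueError("medi.lambda_reg must be > 0")
        if not 0 < medi["edge_fraction"] < 1:
            raise ValueError("medi.edge_fraction must be in (0, 1)")

    @property
    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


def _deep_update(base: dict, upd: dict) -> None:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _imaging_arm(cfg: dict, seed: int, out: Path, manifest: dict) -> pd.DataFrame | None:
    img = cfg["imaging"]
    n_grid = int(img["grid"])
    shape = (n_grid,) * 3
    presets = nigral_value_presets()
    rng = np.random.default_rng(seed + 1)
    rows = []
    run_qsm = cfg["stages"].get("qsm", True)
    run_r2s = cfg["stages"].get("r2star", True)
    if not (run_qsm or run_r2s):
        return None
    sid = 0
    for cls in img["classes"]:
        base_vals = presets[cls]
        for _ in range(int(img["n_per_class"])):
            subj = f"{cls}{sid:03d}"
            sid += 1
            vals = {
                k: (
                    v[0] + (rng.normal(0.0, img["subject_chi_sd"]) if k != "tissue" else 0.0),
                    v[1],
                )
                for k, v in base_vals.items()
            }
            age = float(rng.normal(64.0, 9.0))
            sex = "M" if rng.random() < 0.55 else "F"
            phantom = build_phantom(values=vals, shape=shape, seed=seed + 100 + sid)
            echoes = simulate_echoes(
                phantom, noise_sd=float(img["noise_sd"]), seed=seed + 200 + sid
            )
            labels = phantom.labels
            if run_qsm:
                chi = reconstruct_qsm(
                    echoes, phantom.brain_mask, params={"medi": img["medi"]}
                )
                st = roi_mod.extract_roi_stats(chi.values, labels, "qsm_ppm",
                                               valid_mask=chi.mask)
                for _, r in st[st["side"] == "mean"].iterrows():
                    rows.append(
                        {"subject_id": subj, "group": cls, "visit_index": 1,
                         "time_years": 0.0, "age_baseline": age, "sex": sex,
                         "roi_name": r["roi"], "side": "mean",
                         "qsm_ppm": r["mean"], "r2s_hz": np.nan}
                    )
            if run_r2s:
                r2map = fit_r2star(np.abs(echoes.signal), echoes.echo_times,
                                   phantom.brain_mask)
                st = roi_mod.extract_roi_stats(r2map.values, labels, "r2s_hz",
                                               valid_mask=r2map.mask)
                for _, r in st[st["side"] == "mean"].iterrows():
                    hit = next(
                        (row for row in rows
                         if row["subject_id"] == subj and row["roi_name"] == r["roi"]),
                        None,
                    )
                    if hit is not None:
                        hit["r2s_hz"] = r["mean"]
                    else:
                        rows.append(
                            {"subject_id": subj, "group": cls, "visit_index": 1,
                             "time_years": 0.0, "age_baseline": age, "sex": sex,
                             "roi_name": r["roi"], "side": "mean",
                             "qsm_ppm": np.nan, "r2s_hz": r["mean"]}
                        )
    table = pd.DataFrame(rows)
    path = out / "imaging_roi_table.csv"
    table.to_csv(path, index=False, float_format="%.8g")
    manifest["outputs"]["imaging_roi_table.csv"] = nio.file_sha256(path)
    return table


def run_pipeline(config: PipelineConfig | dict, out_dir=None) -> dict:
    """Execute the configured stages; returns the run manifest.

    Stage failures halt the run with the stage name and the manifest of
    completed stages attached to the raised :class:`StageError`.
    """
    cfg = config.raw if isinstance(config, PipelineConfig) else config
    pc = PipelineConfig(cfg)
    pc.validate()
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": pc.config_hash,
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }

    imaging_table = None
    if cfg["stages"].get("imaging", True):
        t0 = time.time()
        try:
            imaging_table = _imaging_arm(cfg, seed, out, manifest)
        except StageError:
            manifest["stages"]["imaging"] = "failed"
            _write_manifest(out, manifest)
            raise
        manifest["stages"]["imaging"] = f"ok ({time.time() - t0:.1f}s)"

    if imaging_table is not None and cfg["stages"].get("qsm", True):
        base_rows = []
        for roi in ("posteroventral",):
            res = stats_mod.baseline_group_model(imaging_table, roi, "qsm_ppm")
            for _, r in res.contrasts.iterrows():
                base_rows.append(
                    {"roi": roi, "modality": "qsm_ppm", **r.to_dict(),
                     "F": res.f_stat, "p_group": res.p_group}
                )
        base = pd.DataFrame(base_rows)
        p = out / "imaging_baseline_model.csv"
        base.to_csv(p, index=False, float_format="%.8g")
        manifest["outputs"]["imaging_baseline_model.csv"] = nio.file_sha256(p)

    if cfg["stages"].get("cohort_stats", True):
        t0 = time.time()
        design = cohort_mod.default_design(seed=seed, rois=cfg["cohort"]["rois"])
        table, truth = cohort_mod.simulate_cohort(design)
        p = out / "cohort_table.csv"
        table.to_csv(p, index=False, float_format="%.8g")
        manifest["outputs"]["cohort_table.csv"] = nio.file_sha256(p)

        long_rows = []
        for roi in cfg["cohort"]["stats_rois"]:
            for modality in ("qsm_ppm", "r2s_hz"):
                if table[table["roi_name"] == roi][modality].notna().sum() == 0:
                    continue
                fit = stats_mod.fit_longitudinal_lmm(table, roi, modality)
                for _, r in fit.slopes.iterrows():
                    long_rows.append(
                        {"roi": roi, "modality": modality, **r.to_dict(),
                         "wald_group_p": fit.wald["Group"][2],
                         "wald_visit_p": fit.wald["Visit"][2],
                         "wald_interaction_p": fit.wald["Group:Visit"][2]}
                    )
        longdf = pd.DataFrame(long_rows)
        p = out / "longitudinal_model.csv"
        longdf.to_csv(p, index=False, float_format="%.8g")
        manifest["outputs"]["longitudinal_model.csv"] = nio.file_sha256(p)

        base1 = table[table["roi_name"] == "posteroventral"]
        corr = stats_mod.correlation_family(
            base1[(base1["visit_index"] == 1) & (base1["side"] == "mean")],
            [tuple(p_) for p_ in cfg["cohort"]["correlation_pairs"]],
            family_id="posteroventral_baseline",
        )
        p = out / "correlations.csv"
        corr.to_csv(p, index=False, float_format="%.8g")
        manifest["outputs"]["correlations.csv"] = nio.file_sha256(p)

        demo = stats_mod.demographics_tests(table)
        p = out / "demographics.json"
        p.write_text(json.dumps(demo, indent=2, default=float))
        manifest["outputs"]["demographics.json"] = nio.file_sha256(p)
        manifest["stages"]["cohort_stats"] = f"ok ({time.time() - t0:.1f}s)"

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
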