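"""End-to-end orchestration: synthesize -> per-eye metrics -> cohort -> statistics.

A single YAML-serializable config drives every stage; one master seed is
split into named sub-streams so reruns with the same config and seed are
bit-identical.  Each stage writes its artifacts under the output
directory and the run finishes with a manifest listing every artifact
and its content hash.  A stage failure is recorded in the manifest
without aborting the remaining stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cvi as cvi_mod
from . import lesions as lesions_mod
from . import stats as stats_mod
from . import synth, uwf
from .ringscan import count_vessels

__all__ = ["RunConfig", "default_config", "run_pipeline"]

STAGES = ("ring", "uwf", "cvi", "lesions", "stats")


def default_config() -> dict:
    """Defaults for a small synthetic end-to-end run.

    Group-level generative parameters follow the study conditions: DS
    eyes carry ~2.5 more peripapillary vessels, wider intercepts with
    faster taper, a lower choroidal luminal fraction (~0.41 vs ~0.50)
    and a higher peripheral lesion rate.
    """
    return {
        "seed": 0,
        "stages": list(STAGES),
        "cohort": {"n_per_group": 6},
        "ring": {"mean_vessels": {"CTRL": 16.5, "DS": 19.0}, "n_cols": 512,
                 "n_ciliary": 2, "snr": 30.0},
        "uwf": {"image_px": 1200, "pixel_scale_um": 12.0,
                "wi_mean": {"CTRL": 110.0, "DS": 128.0}, "wi_sd": 8.0,
                "wg_mean": {"CTRL": -3.2, "DS": -3.9}, "wg_sd": 0.4,
                "tort_amplitude_mm": {"CTRL": 0.12, "DS": 0.16},
                "interval_mm": 0.25},
        "cvi": {"luminal_fraction": {"CTRL": 0.50, "DS": 0.41},
                "fraction_sd": 0.03, "n_bscans": 7, "n_cols": 192,
                "n_rows": 220, "thickness_px": 80.0, "bscan_spacing_mm": 1.0,
                "scan_width_mm": 7.0, "scales": [4, 8, 16],
                "contrast": 80.0, "noise_sd": 10.0},
        "lesions": {"p_abnormal": {"CTRL": 0.09, "DS": 0.36},
                    "p_hemorrhage_given_abnormal": 0.4},
        "stats": {"fdr_families": {
            "vessel_count": ["vessel_count"],
            "widths": ["WGa_global", "WIa_global", "TORTa_global"],
            "abnormalities": ["any_abnormality"],
            "cvi": ["cvi_global"],
        }},
    }


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (see :func:`default_config`)."""

    config: dict

    def __post_init__(self) -> None:
        base = default_config()
        unknown = set(self.config) - set(base)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        merged = {}
        for key, default in base.items():
            val = self.config.get(key, default)
            if isinstance(default, dict) and isinstance(val, dict):
                bad = set(val) - set(default)
                if bad:
                    raise ValueError(f"unknown config field(s) in {key!r}: {sorted(bad)}")
                merged[key] = {**default, **val}
            else:
                merged[key] = val
        for stage in merged["stages"]:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        self.config = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.config, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _eye_frame(n_per_group: int, rng: np.random.Generator) -> pd.DataFrame:
    spec = synth.CohortSpec(n_per_group=n_per_group, outcomes=[],
                            seed=int(rng.integers(2 ** 31)))
    table, _ = synth.gen_cohort(spec)
    return table


def _stage_ring(eyes: pd.DataFrame, cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    out = []
    for _, eye in eyes.iterrows():
        n_true = max(int(rng.poisson(cfg["mean_vessels"][eye["group"]])), 0)
        scan, _ = synth.gen_ring_scan(
            n_true, n_ciliary=cfg["n_ciliary"], snr=cfg["snr"],
            n_cols=cfg["n_cols"], seed=int(rng.integers(2 ** 31)))
        res = count_vessels(scan)
        out.append({"vessel_count": res.count, "vessel_class": res.class_label})
    return pd.DataFrame(out, index=eyes.index)


def _stage_uwf(eyes: pd.DataFrame, cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    mm = cfg["pixel_scale_um"] / 1000.0
    out = []
    for _, eye in eyes.iterrows():
        g = eye["group"]
        vessels = []
        for quadrant in uwf.QUADRANTS:
            for vclass in ("arteriole", "venule"):
                wi = rng.normal(cfg["wi_mean"][g], cfg["wi_sd"])
                wg = rng.normal(cfg["wg_mean"][g], cfg["wg_sd"])
                vessels.append(synth.VesselTruth(
                    width_intercept_um=max(wi, 40.0),
                    width_gradient_um_per_mm=min(wg, -0.5),
                    tortuosity="sinusoid",
                    amplitude_mm=max(rng.normal(cfg["tort_amplitude_mm"][g], 0.03),
                                     0.02),
                    periods=int(rng.integers(2, 5)),
                    quadrant=quadrant, vessel_class=vclass,
                    length_mm=min(6.0, (cfg["image_px"] / 2 * mm - 1.2) / 1.5)))
        scene, _ = synth.gen_vessel_scene(
            vessels, image_shape=(cfg["image_px"], cfg["image_px"]),
            pixel_scale_um=cfg["pixel_scale_um"],
            seed=int(rng.integers(2 ** 31)))
        records = []
        for cl in scene.centerlines:
            profile = uwf.sample_widths_along_path(scene, cl.vessel_id,
                                                   interval_mm=cfg["interval_mm"])
            wg_hat, wi_hat = uwf.fit_width_model(profile)
            tort = uwf.tortuosity_density(cl.points, mm_per_px=mm)
            records.append({"vessel_class": cl.vessel_class, "quadrant": cl.quadrant,
                            "WG": wg_hat, "WI": wi_hat, "TORT": tort})
        agg = uwf.aggregate_vessel_metrics(pd.DataFrame(records))
        roi = uwf.build_roi_masks(scene.vessel_map.shape, scene.landmarks,
                                  pixel_scale_um=cfg["pixel_scale_um"])
        row = {}
        for scope in ("temporal", "nasal", "global"):
            for vclass, tag in (("arteriole", "a"), ("venule", "v")):
                for metric in ("WG", "WI", "TORT"):
                    row[f"{metric}{tag}_{scope}"] = agg.loc[(vclass, scope), metric]
        for name, mask in (("standard", roi.standard), ("posterior", roi.posterior),
                           ("midperiphery", roi.midperiphery)):
            try:
                row[f"FD_{name}"] = uwf.sandbox_fd(
                    scene.vessel_map, mask, seed=int(rng.integers(2 ** 31)))
            except ValueError:
                row[f"FD_{name}"] = np.nan
        out.append(row)
    return pd.DataFrame(out, index=eyes.index)


def _stage_cvi(eyes: pd.DataFrame, cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    out = []
    for _, eye in eyes.iterrows():
        frac = float(np.clip(rng.normal(cfg["luminal_fraction"][eye["group"]],
                                        cfg["fraction_sd"]), 0.1, 0.7))
        volume, _ = synth.gen_choroid_volume(
            n_bscans=cfg["n_bscans"], luminal_fraction=frac,
            contrast=cfg["contrast"], noise_sd=cfg["noise_sd"],
            n_cols=cfg["n_cols"], n_rows=cfg["n_rows"],
            thickness_px=cfg["thickness_px"],
            bscan_spacing_mm=cfg["bscan_spacing_mm"],
            scan_width_mm=cfg["scan_width_mm"],
            seed=int(rng.integers(2 ** 31)))
        _, cvi_map, global_cvi = cvi_mod.volume_cvi(volume,
                                                    scales=tuple(cfg["scales"]))
        sectors = cvi_mod.etdrs_sector_stats(cvi_map, (0.0, 0.0))
        out.append({"cvi_global": 100.0 * global_cvi,
                    "cvi_cc": 100.0 * sectors["CC"],
                    "cvi_inner_ring": 100.0 * sectors["inner_ring"],
                    "cvi_outer_ring": 100.0 * sectors["outer_ring"]})
    return pd.DataFrame(out, index=eyes.index)


def _stage_lesions(eyes: pd.DataFrame, cfg: dict,
                   rng: np.random.Generator) -> pd.DataFrame:
    out = []
    for _, eye in eyes.iterrows():
        lesion_list = []
        if rng.random() < cfg["p_abnormal"][eye["group"]]:
            n = int(rng.integers(1, 4))
            for _ in range(n):
                kind = ("hemorrhage"
                        if rng.random() < cfg["p_hemorrhage_given_abnormal"]
                        else "microaneurysm")
                r = rng.uniform(16.0, 24.0)              # far periphery
                theta = rng.uniform(0, 2 * np.pi)
                lesion_list.append(lesions_mod.LesionRecord(
                    kind, float(r * np.cos(theta)), float(r * np.sin(theta))))
        pheno = lesions_mod.phenotype_eye(lesion_list)
        out.append({"any_abnormality": int(pheno.any_abnormality),
                    "phenotype": pheno.group,
                    "n_lesions": len(lesion_list)})
    return pd.DataFrame(out, index=eyes.index)


def _stage_stats(cohort: pd.DataFrame, cfg: dict, outdir: Path) -> list[Path]:
    outcomes: dict[str, str] = {}
    for fam_members in cfg["fdr_families"].values():
        for name in fam_members:
            if name in cohort.columns:
                outcomes[name] = ("binomial"
                                  if set(cohort[name].dropna().unique()) <= {0, 1}
                                  else "gaussian")
    table = stats_mod.outcome_table(cohort, outcomes,
                                    fdr_families=cfg["fdr_families"])
    path = outdir / "gee_results.csv"
    table.to_csv(path, index=False)
    desc_rows = []
    for name in outcomes:
        d = stats_mod.descriptive_table(cohort, name,
                                        categorical=outcomes[name] == "binomial")
        d.insert(0, "outcome", name)
        desc_rows.append(d)
    desc_path = outdir / "descriptives.csv"
    pd.concat(desc_rows).to_csv(desc_path, index=False)
    return [path, desc_path]


def run_pipeline(config: RunConfig | dict, outdir) -> dict:
    """Run the configured stages and return the manifest dict.

    The manifest maps artifact paths to content hashes and records any
    stage error; it is also written to ``manifest.json`` in ``outdir``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    cfg = config.config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("cohort", *STAGES),
        np.random.SeedSequence(cfg["seed"]).generate_state(1 + len(STAGES)))}

    eyes = _eye_frame(cfg["cohort"]["n_per_group"], streams["cohort"])
    artifacts: list[Path] = []
    errors: dict[str, str] = {}
    stage_fns = {"ring": _stage_ring, "uwf": _stage_uwf, "cvi": _stage_cvi,
                 "lesions": _stage_lesions}
    for stage in cfg["stages"]:
        if stage == "stats":
            continue
        try:
            cols = stage_fns[stage](eyes, cfg[stage], streams[stage])
            eyes = pd.concat([eyes, cols], axis=1)
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            errors[stage] = "".join(traceback.format_exception_only(exc)).strip()

    cohort_path = outdir / "cohort.csv"
    eyes.to_csv(cohort_path, index=False)
    artifacts.append(cohort_path)

    if "stats" in cfg["stages"]:
        try:
            artifacts.extend(_stage_stats(eyes, cfg["stats"], outdir))
        except Exception as exc:  # noqa: BLE001
            errors["stats"] = "".join(traceback.format_exception_only(exc)).strip()

    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    artifacts.append(config_path)

    manifest = {
        "seed": cfg["seed"],
        "stages": cfg["stages"],
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "errors": errors,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
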