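"""Pipeline orchestration: simulate -> segment -> fit -> train -> solve -> check.

A run is described by a small YAML/dict config (versioned schema).  Each
stage reads its inputs from the run directory, writes its artifacts
there, and records content hashes in a JSON run report, so deterministic
stages reproduce identical hashes on rerun and every stochastic stage has
an explicit seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geom
from .cube import load_cube, save_cube
from .imaging import SpectralClassSegmenter, roi_mask_from_box, sum_roi
from .lineshape import (
    DEFAULT_PEAK_CENTERS,
    VoigtPeak,
    extract_chi_magnitude,
    fit_multipeak,
)
from .solver import OrientationRegressor, TwoSheetObservation, solve, train_solver
from .synth import GenerationRanges, Sheet, SheetScene, gen_cube, gen_training_set
from .tensor import POLARIZATIONS, HyperpolarizabilityC7

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "demo_config", "rhombus_vertices"]

log = logging.getLogger("vsfgorient")

SCHEMA_VERSION = 1
STAGES = ("simulate", "segment", "fit", "train", "solve", "check_geometry")


class PipelineError(RuntimeError):
    """A user-correctable pipeline failure (bad config, missing artifact)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str = "runs/out"
    stages: tuple = ()
    seeds: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    solve: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise PipelineError(
                f"unsupported schema_version {version}; this build reads {SCHEMA_VERSION}"
            )
        stages = tuple(raw.pop("stages", ()))
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys {sorted(bad)}")
        return cls(stages=stages, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def rhombus_vertices(center, size, aspect=0.6, rotation_deg=0.0) -> np.ndarray:
    """Rhombic sheet footprint: half-diagonals ``size`` and ``aspect*size``."""
    cx, cy = center
    d1, d2 = float(size), float(size) * float(aspect)
    pts = np.array([[d1, 0.0], [0.0, d2], [-d1, 0.0], [0.0, -d2]])
    a = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ rot.T + np.array([cx, cy])


def _sheet_from_cfg(cfg: dict, idx: int) -> Sheet:
    beta = cfg.get("beta")
    kwargs = {}
    if beta is not None:
        kwargs["beta"] = HyperpolarizabilityC7.from_array(np.asarray(beta, dtype=float))
    return Sheet(
        vertices=rhombus_vertices(
            cfg.get("center", (32, 32)),
            cfg.get("size", 18),
            cfg.get("aspect", 0.6),
            cfg.get("phi_deg", 0.0),
        ),
        phi_deg=float(cfg.get("phi_deg", 0.0)),
        theta_deg=float(cfg.get("theta_deg", 23.0)),
        amplitude_scale=float(cfg.get("scale", 1.0)),
        sheet_id=cfg.get("sheet_id", f"sheet{idx + 1}"),
        **kwargs,
    )


def _scene_from_cfg(cfg: dict) -> SheetScene:
    sheets = [_sheet_from_cfg(s, i) for i, s in enumerate(cfg.get("sheets", []))]
    kwargs = {}
    for key in ("baseline", "target_snr", "reference_polarization"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "wavenumber" in cfg:
        w = cfg["wavenumber"]
        kwargs["wavenumber"] = np.arange(w[0], w[1] + 1e-9, w[2])
    return SheetScene(sheets=sheets, shape=tuple(cfg.get("shape", (64, 64))), **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _rle_encode(labels: np.ndarray) -> dict:
    flat = labels.ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    return {
        "shape": list(labels.shape),
        "values": flat[starts].astype(int).tolist(),
        "lengths": lengths.astype(int).tolist(),
    }


def _rle_decode(payload: dict) -> np.ndarray:
    flat = np.repeat(np.array(payload["values"]), np.array(payload["lengths"]))
    return flat.reshape(payload["shape"])


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": SCHEMA_VERSION, "stages": {}, "artifacts": {}}

    def record(name: str, *paths: Path, **numbers):
        entry = {"artifacts": {}, **numbers}
        for p in paths:
            digest = _sha256(p)
            entry["artifacts"][p.name] = digest
            report["artifacts"][p.name] = digest
        report["stages"][name] = entry

    for stage in config.stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            seed = int(config.seeds.get("simulate", 0))
            scene = _scene_from_cfg(config.scene)
            cube = gen_cube(scene, seed=seed)
            cube_path = out / "cube.h5"
            save_cube(cube, cube_path)
            record("simulate", cube_path, seed=seed, n_sheets=len(scene.sheets))

        elif stage == "segment":
            cube = load_cube(_require(out / "cube.h5", "simulate"))
            seed = int(config.seeds.get("segment", 0))
            k = int(config.segment.get("n_classes", len(cube.meta.get("sheets", [])) + 1))
            seg = SpectralClassSegmenter(
                n_classes=max(k, 2),
                polarization=config.segment.get("polarization", "SSS"),
                random_state=seed,
            ).fit(cube)
            labels_path = out / "labels.json"
            with open(labels_path, "w") as fh:
                json.dump(
                    {
                        "rle": _rle_encode(seg.labels_),
                        "pixel_counts": seg.pixel_counts_.tolist(),
                        "no_structure": bool(seg.no_structure_),
                        "seed": seed,
                    },
                    fh,
                )
            record(
                "segment", labels_path, seed=seed,
                no_structure=bool(seg.no_structure_),
                pixel_counts=seg.pixel_counts_.tolist(),
            )

        elif stage == "fit":
            cube = load_cube(_require(out / "cube.h5", "simulate"))
            with open(_require(out / "labels.json", "segment")) as fh:
                labels = _rle_decode(json.load(fh)["rle"])
            sheets_meta = cube.meta.get("sheets", [])
            boxes = config.fit.get("boxes")
            if boxes is None:
                # emulate manual analysis boxes from the sheet footprints
                boxes = []
                for sm in sheets_meta:
                    v = np.asarray(sm["vertices"])
                    boxes.append(
                        [
                            int(np.floor(v[:, 1].min())), int(np.ceil(v[:, 1].max())) + 1,
                            int(np.floor(v[:, 0].min())), int(np.ceil(v[:, 0].max())) + 1,
                        ]
                    )
            rows = []
            reports = []
            foreground = labels > 0
            for si, box in enumerate(boxes):
                mask = roi_mask_from_box(labels.shape, box, foreground)
                for pol in POLARIZATIONS:
                    spec = sum_roi(cube, mask, pol)
                    peaks = [
                        VoigtPeak(center=c, gaussian_width=6.0, lorentzian_width=4.0,
                                  amplitude=float(np.ptp(spec.intensity)) * (1.0 if c == 2910.0 else 0.3))
                        for c in DEFAULT_PEAK_CENTERS
                    ]
                    fit = fit_multipeak(spec, peaks, baseline=float(np.median(spec.intensity)))
                    chi = extract_chi_magnitude(fit)
                    rows.append((f"sheet{si + 1}", pol, chi, spec.provenance["n_pixels"]))
                    reports.append({"sheet": f"sheet{si + 1}", "polarization": pol, **fit.report()})
            import pandas as pd

            chi_path = out / "chi.csv"
            pd.DataFrame(rows, columns=["sheet_id", "polarization", "value", "n_pixels"]).to_csv(
                chi_path, index=False
            )
            fits_path = out / "fit_reports.json"
            with open(fits_path, "w") as fh:
                json.dump(reports, fh, indent=1)
            record("fit", chi_path, fits_path, n_sheets=len(boxes))

        elif stage == "train":
            seed = int(config.seeds.get("train", 0))
            n = int(config.train.get("n_samples", 100000))
            ranges = GenerationRanges(
                delta_phi_deg=float(config.solve.get("delta_phi_deg", 60.0))
            )
            training = gen_training_set(n, seed=seed, ranges=ranges)
            est = train_solver(
                training,
                epochs=int(config.train.get("epochs", 1000)),
                batch_size=int(config.train.get("batch_size", 100)),
                random_state=seed,
            )
            model_path = out / "model.npz"
            est.save(model_path)
            record(
                "train", model_path, Path(str(model_path) + ".json"),
                seed=seed, n_samples=n,
                final_train_loss=est.loss_curve_[-1],
                final_validation_loss=est.validation_curve_[-1] if est.validation_curve_ else None,
            )

        elif stage == "solve":
            import pandas as pd

            chi = pd.read_csv(_require(out / "chi.csv", "fit"))
            model = OrientationRegressor.load(_require(out / "model.npz", "train"))
            sheet_ids = sorted(chi["sheet_id"].unique())[:2]
            if len(sheet_ids) < 2:
                raise PipelineError("solve needs susceptibilities for two sheets")
            mags = []
            for sid in sheet_ids:
                sub = chi[chi["sheet_id"] == sid].set_index("polarization")
                mags.extend(float(sub.loc[p, "value"]) for p in POLARIZATIONS)
            obs = TwoSheetObservation(
                magnitudes=np.array(mags),
                delta_phi_deg=float(config.solve.get("delta_phi_deg", 60.0)),
                metadata={"sheet_ids": sheet_ids},
            )
            sol = solve(obs, model, top_k=int(config.solve.get("top_k", 5)))
            sol_path = out / "solution.json"
            sol.to_json(sol_path)
            numbers = {
                "theta_deg": sol.theta_deg,
                "phi1_deg": sol.phi1_deg,
                "susceptibility_mse": sol.susceptibility_mse,
            }
            cube_path = out / "cube.h5"
            if cube_path.exists():
                true_theta = [
                    s["theta_deg"] for s in load_cube(cube_path).meta.get("sheets", [])
                ]
                if true_theta:
                    numbers["true_theta_deg"] = true_theta[0]
                    numbers["theta_error_deg"] = abs(sol.theta_deg - true_theta[0])
            record("solve", sol_path, **numbers)

        elif stage == "check_geometry":
            gcfg = config.geometry
            result = {}
            if "h_observed" in gcfg and "h_upright" in gcfg:
                result["tilt_from_heights_deg"] = geom.tilt_from_heights(
                    float(gcfg["h_observed"]), float(gcfg["h_upright"])
                )
            tilt = gcfg.get("tilt_deg")
            if tilt is None and (out / "solution.json").exists():
                with open(out / "solution.json") as fh:
                    tilt = json.load(fh)["theta_deg"]
            if tilt is not None:
                model = geom.PackingModel(
                    lattice_spacing=float(gcfg.get("lattice_spacing", 1.52)),
                    diameter=float(gcfg.get("diameter", 1.25)),
                    height=float(gcfg.get("height", 1.55)),
                    tilt_deg=float(tilt),
                )
                cls, gap = geom.steric_class(model)
                result.update({"tilt_deg": float(tilt), "steric_class": cls, "gap_nm": gap})
            geo_path = out / "geometry.json"
            with open(geo_path, "w") as fh:
                json.dump(result, fh, indent=2)
            record("check_geometry", geo_path, **result)

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def demo_config(out_dir: str = "runs/demo", seed: int = 0) -> RunConfig:
    """Bundled demonstration: full synthetic round trip at a known tilt."""
    return RunConfig.from_dict(
        {
            "out_dir": out_dir,
            "stages": list(STAGES),
            "seeds": {"simulate": seed, "segment": seed + 1, "train": seed + 2},
            "scene": {
                "shape": [72, 72],
                "target_snr": 56,
                "sheets": [
                    {"phi_deg": 10.0, "theta_deg": 23.0, "center": [20, 36],
                     "size": 16, "aspect": 0.6, "scale": 1.0},
                    {"phi_deg": 70.0, "theta_deg": 23.0, "center": [52, 36],
                     "size": 17, "aspect": 0.6, "scale": 1.3},
                ],
            },
            "segment": {"n_classes": 2},
            "train": {"n_samples": 40000, "epochs": 120, "batch_size": 100},
            "solve": {"delta_phi_deg": 60.0},
            "geometry": {"h_observed": 2.9, "h_upright": 3.1},
        }
    )
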