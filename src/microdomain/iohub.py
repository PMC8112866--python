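"""File I/O, run configuration, and the reproducible pipeline driver.

Images travel as TIFF (one page per channel) with the pixel size and
channel names stored as a JSON image description; tables as CSV; fit
results and summaries as JSON. A :class:`RunConfig` is the single source
of truth for a pipeline run: every stage's parameters plus one master
seed, from which per-stage seeds are derived deterministically, so that a
rerun with the same configuration reproduces every stochastic output
bit-identically. Unknown configuration keys are rejected before any stage
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ConfigError, ImageField, MicrodomainError

__all__ = [
    "read_image",
    "write_image",
    "save_calibration",
    "load_calibration",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def write_image(path: Union[str, Path], fields: Union[ImageField, Sequence[ImageField]]) -> Path:
    """Write one or more channels to a multi-page TIFF with metadata.

    The pixel size (um/px) and channel names are stored as a JSON image
    description so that :func:`read_image` round-trips them.
    """
    path = Path(path)
    if isinstance(fields, ImageField):
        fields = [fields]
    sizes = {f.pixel_size_um for f in fields}
    if len(sizes) != 1:
        raise ConfigError("all channels in one file must share a pixel size")
    stack = np.stack([f.pixels for f in fields]).astype(np.float32)
    meta = {
        "pixel_size_um": fields[0].pixel_size_um,
        "channels": [f.channel_name for f in fields],
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta), photometric="minisblack")
    return path


def read_image(
    path: Union[str, Path], pixel_size_um: Optional[float] = None
) -> list[ImageField]:
    """Read a single- or multi-page TIFF as a list of channels.

    The pixel size comes from the JSON description written by
    :func:`write_image`, from the TIFF resolution tags, or from the
    ``pixel_size_um`` override — in that priority order for metadata, with
    the override always winning when given. Raises :class:`ConfigError`
    when no pixel size can be determined.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        meta: dict[str, Any] = {}
        desc = tif.pages[0].description
        if desc:
            try:
                parsed = json.loads(desc)
                if isinstance(parsed, dict):
                    meta = parsed
            except (json.JSONDecodeError, TypeError):
                pass
        if pixel_size_um is None:
            pixel_size_um = meta.get("pixel_size_um")
        if pixel_size_um is None:
            # fall back to resolution tags only when a physical unit is set
            tags = tif.pages[0].tags
            unit_um = {2: 25400.0, 3: 10000.0}  # inch, centimetre
            if "XResolution" in tags and "ResolutionUnit" in tags:
                unit = unit_um.get(int(tags["ResolutionUnit"].value))
                num, den = tags["XResolution"].value
                if unit and num:
                    pixel_size_um = den / num * unit
    if pixel_size_um is None:
        raise ConfigError(f"{path}: no pixel size in metadata and no override given")
    if data.ndim == 2:
        data = data[None]
    names = meta.get("channels", [""] * data.shape[0])
    return [
        ImageField(plane, float(pixel_size_um), channel_name=str(name))
        for plane, name in zip(data, names)
    ]


def save_calibration(path: Union[str, Path], calib) -> Path:
    """Store a CalibrationResult as JSON."""
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "single_intensity_mean": calib.single_intensity_mean,
                "single_intensity_sd": calib.single_intensity_sd,
                "n_spots": calib.n_spots,
            },
            indent=2,
        )
    )
    return path


def load_calibration(path: Union[str, Path]):
    """Load a CalibrationResult from JSON."""
    from .quant import CalibrationResult

    d = json.loads(Path(path).read_text())
    return CalibrationResult(**d)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_STAGE_KEYS = {
    "dslb": {"sim", "calibration_sim", "quant"},
    "guv": {"sim", "analysis"},
    "coloc": {"sim", "threshold_A", "threshold_B"},
    "frap": {"n_traces", "sim_in", "sim_out"},
}
_TOP_KEYS = {"seed", "out_dir", "stages"} | set(_STAGE_KEYS)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Stage parameter dictionaries hold keyword overrides for the
    corresponding simulation/analysis dataclasses; the per-stage seeds are
    derived from the master ``seed`` and are not user-settable.
    """

    seed: int
    out_dir: str = "results"
    stages: list[str] = field(default_factory=lambda: ["dslb", "guv"])
    dslb: dict = field(default_factory=dict)
    guv: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)
    frap: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("configuration requires a 'seed'")
        cfg = cls(
            seed=int(raw["seed"]),
            out_dir=str(raw.get("out_dir", "results")),
            stages=list(raw.get("stages", ["dslb", "guv"])),
            dslb=dict(raw.get("dslb", {})),
            guv=dict(raw.get("guv", {})),
            coloc=dict(raw.get("coloc", {})),
            frap=dict(raw.get("frap", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        """Reject unknown stages, stage keys, and parameter names."""
        from . import simgen
        from .quant import QuantParams

        for stage in self.stages:
            if stage not in _STAGE_KEYS:
                raise ConfigError(f"unknown stage {stage!r}")
        for stage, allowed in _STAGE_KEYS.items():
            section = getattr(self, stage)
            unknown = set(section) - allowed
            if unknown:
                raise ConfigError(f"unknown keys in section {stage!r}: {sorted(unknown)}")
        # dry-construct every parameter object so bad keys fail before any run
        try:
            simgen.FieldSimParams(seed=0, **self.dslb.get("sim", {}))
            simgen.FieldSimParams(seed=0, **self.dslb.get("calibration_sim", {}))
            QuantParams(**self.dslb.get("quant", {}))
            simgen.GUVSimParams(seed=0, **self.guv.get("sim", {}))
            simgen.ColocSimParams(seed=0, **self.coloc.get("sim", {}))
            simgen.FRAPSimParams(seed=0, **self.frap.get("sim_in", {}))
            simgen.FRAPSimParams(seed=0, **self.frap.get("sim_out", {}))
        except TypeError as exc:
            raise ConfigError(f"invalid stage parameter: {exc}") from exc
        analysis_allowed = {
            "cluster_threshold_factor",
            "min_radius_um",
            "max_radius_um",
            "ring_halfwidth_um",
            "min_cluster_area_px",
        }
        unknown = set(self.guv.get("analysis", {})) - analysis_allowed
        if unknown:
            raise ConfigError(f"unknown GUV analysis keys: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def stage_seed(self, label: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        key = int(hashlib.sha256(label.encode()).hexdigest()[:8], 16)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))

    @property
    def seed_registry(self) -> dict[str, int]:
        labels = [
            "dslb_field",
            "dslb_calibration",
            "guv_set",
            "coloc_pair",
            "frap_in",
            "frap_out",
        ]
        return {lab: self.stage_seed(lab) for lab in labels}


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

class PipelineStageError(MicrodomainError):
    """A pipeline stage failed; the stage name is carried in the message."""


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Execute the configured stages and write a results bundle.

    Every output file carries the configuration hash in the manifest;
    rerunning with an identical configuration reproduces all stochastic
    outputs bit-identically. A stage failure aborts the run with
    :class:`PipelineStageError` naming the stage; the manifest then marks
    the run incomplete.
    """
    from . import coloc as coloc_mod
    from . import simgen
    from .frap import compare_plateaus, fit_recovery, normalize_trace
    from .guv import analyze_guv_dataset
    from .quant import QuantParams, calibrate_single_molecule, quantify_field
    from .stats import fit_lognormal, fit_poisson

    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg = config.seed_registry
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed_registry": reg,
        "stages": {},
        "status": "incomplete",
    }
    results: dict[str, Any] = {}
    stage = ""
    try:
        if "dslb" in config.stages:
            stage = "dslb"
            calib_defaults = dict(n_singles=200, single_intensity_cv=0.0, noise_model="none")
            calib_defaults.update(config.dslb.get("calibration_sim", {}))
            calib_params = simgen.FieldSimParams(seed=reg["dslb_calibration"], **calib_defaults)
            calib_img, _ = simgen.simulate_dslb_field(calib_params)
            qp = QuantParams(**config.dslb.get("quant", {}))
            calib = calibrate_single_molecule(calib_img, psf_sigma_px=qp.psf_sigma_px)
            save_calibration(out / "calibration.json", calib)

            sim_defaults = dict(n_singles=100, n_trimers=30, n_clusters=15)
            sim_defaults.update(config.dslb.get("sim", {}))
            params = simgen.FieldSimParams(seed=reg["dslb_field"], **sim_defaults)
            image, truth = simgen.simulate_dslb_field(params)
            write_image(out / "dslb_field.tif", image)
            truth.emitters.to_csv(out / "dslb_truth.csv", index=False)
            quantification = quantify_field(image, calib, qp)
            quantification.spots_dataframe().to_csv(out / "dslb_spots.csv", index=False)
            _write_json(
                out / "dslb_field.json",
                {
                    "total_intensity": quantification.total_intensity,
                    "clustered_intensity": quantification.clustered_intensity,
                    "clustered_fraction": quantification.clustered_fraction,
                    "n_spots": len(quantification.spots),
                },
            )
            sizes = [s.molecules for s in quantification.spots if s.is_cluster]
            if len(sizes) >= 3:
                ln = fit_lognormal(sizes)
                _write_json(
                    out / "dslb_lognormal.json",
                    {
                        "mu_log": ln.mu_log,
                        "sigma_log": ln.sigma_log,
                        "mean_arith": ln.mean_arith,
                        "median_arith": ln.median_arith,
                        "ks_p": ln.ks_p,
                        "n": ln.n,
                    },
                )
            manifest["stages"]["dslb"] = {
                "clustered_fraction": quantification.clustered_fraction
            }
            results["dslb"] = quantification

        if "guv" in config.stages:
            stage = "guv"
            gparams = simgen.GUVSimParams(seed=reg["guv_set"], **config.guv.get("sim", {}))
            pairs, truth_g = simgen.simulate_guv_set(gparams)
            for i, (mem, pro) in enumerate(pairs):
                write_image(out / f"guv_field_{i:03d}.tif", [mem, pro])
            truth_g.liposomes.to_csv(out / "guv_truth.csv", index=False)
            records, summary = analyze_guv_dataset(pairs, **config.guv.get("analysis", {}))
            pd.DataFrame(
                [
                    dict(
                        liposome_id=r.liposome_id,
                        center_row_px=r.center_px[0],
                        center_col_px=r.center_px[1],
                        radius_um=r.radius_um,
                        cluster_count=r.cluster_count,
                        cluster_areas_um2=";".join(f"{a:.6g}" for a in r.cluster_areas_um2),
                    )
                    for r in records
                ]
            ).to_csv(out / "guv_liposomes.csv", index=False)
            pd.DataFrame({"cluster_count": summary.counts}).to_csv(
                out / "guv_counts.csv", index=False
            )
            fit = fit_poisson(summary.counts) if summary.counts else None
            _write_json(
                out / "guv_summary.json",
                {
                    "n_liposomes": summary.n_liposomes,
                    "fraction_cluster_positive": summary.fraction_cluster_positive,
                    "mean_cluster_area_um2": summary.mean_cluster_area_um2,
                    "sd_cluster_area_um2": summary.sd_cluster_area_um2,
                    "lambda_hat": fit.lambda_hat if fit else None,
                    "lambda_ci95": list(fit.ci95) if fit else None,
                },
            )
            manifest["stages"]["guv"] = {
                "n_liposomes": summary.n_liposomes,
                "lambda_hat": fit.lambda_hat if fit else None,
            }
            results["guv"] = (records, summary, fit)

        if "coloc" in config.stages:
            stage = "coloc"
            cparams = simgen.ColocSimParams(seed=reg["coloc_pair"], **config.coloc.get("sim", {}))
            im_a, im_b, truth_c = simgen.simulate_coloc_pair(cparams)
            write_image(out / "coloc_pair.tif", [im_a, im_b])
            spec_a = coloc_mod.ThresholdSpec(**config.coloc.get("threshold_A", {}))
            spec_b = coloc_mod.ThresholdSpec(**config.coloc.get("threshold_B", {}))
            res = coloc_mod.manders_coefficients(im_a, im_b, spec_a, spec_b)
            _write_json(
                out / "coloc.json",
                {
                    "m1": res.m1,
                    "m2": res.m2,
                    "overlap_area_fraction_AonB": res.overlap_area_fraction_AonB,
                    "overlap_area_fraction_BonA": res.overlap_area_fraction_BonA,
                    "truth_overlap_fraction": truth_c.overlap_fraction,
                },
            )
            manifest["stages"]["coloc"] = {"m1": res.m1, "m2": res.m2}
            results["coloc"] = res

        if "frap" in config.stages:
            stage = "frap"
            n_traces = int(config.frap.get("n_traces", 5))
            fits = {}
            for side, seed_label in (("in", "frap_in"), ("out", "frap_out")):
                overrides = dict(config.frap.get(f"sim_{side}", {}))
                if side == "in":
                    overrides.setdefault("mobile_fraction", 0.74)
                overrides.setdefault("noise_sd", 0.02)
                base = reg[seed_label]
                group = []
                rows = []
                for i in range(n_traces):
                    p = simgen.FRAPSimParams(seed=(base + i) % (2**31), **overrides)
                    trace, _ = simgen.simulate_frap_trace(p)
                    fitres = fit_recovery(normalize_trace(trace))
                    group.append(fitres)
                    rows.append(dict(trace=i, y_max=fitres.y_max, tau_s=fitres.tau_s))
                fits[side] = group
                pd.DataFrame(rows).to_csv(out / f"frap_fits_{side}.csv", index=False)
            comparison = compare_plateaus(fits["in"], fits["out"])
            _write_json(
                out / "frap_compare.json",
                {
                    "y_max_in_mean": float(np.mean([f.y_max for f in fits["in"]])),
                    "y_max_out_mean": float(np.mean([f.y_max for f in fits["out"]])),
                    "p_values": comparison.p_values,
                },
            )
            manifest["stages"]["frap"] = {"p_values": comparison.p_values}
            results["frap"] = (fits, comparison)

    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(out / "manifest.json", manifest)
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    _write_json(out / "manifest.json", manifest)
    results["manifest"] = manifest
    return results
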