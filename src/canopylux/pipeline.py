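"""End-to-end orchestration: images -> canopy metrics -> radiation dose ->
flavonol profiles -> statistics, with covariate joins.

The run is driven by a :class:`RunConfig` (usually loaded from YAML).  One
hemispherical image corresponds to one berry sample per ``sample_id``; all
tables join on that key (inner join, dropped rows logged, never imputed).
Outputs are deterministic given identical inputs: floats are written with a
fixed format and every table carries provenance columns (config hash,
package version, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .canopy_metrics import ZenithBandSet, compute_metrics
from .flavonol import SampleMeta, aglycone_profile, profiles_to_frame, quantify, Calibration, read_peak_table
from .hemi_image import binarize_blue, read_geometry_csv, read_image, read_mask_png
from .solar import RadiationConfig, accumulate_radiation, read_met_csv
from .stats import anova_lsd, pearson_modified, segmented_fit

__all__ = ["RunConfig", "run_exposure", "run_profile_analysis", "run_pipeline"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    geometry: str
    met: str
    images: str | None = None
    masks: str | None = None
    peaks: str | None = None
    covariates: str | None = None
    start_date: dt.date = dt.date(2017, 7, 24)
    end_date: dt.date = dt.date(2017, 9, 9)
    threshold_mode: str = "fixed"
    threshold: float = 128.0
    radiation: RadiationConfig = field(
        default_factory=lambda: RadiationConfig(
            latitude=38.428, longitude=-122.409, utc_offset=-8.0
        )
    )
    response_factor: float = 1000.0
    pairs: list[tuple[str, str]] = field(default_factory=list)
    dose_pairs: list[tuple[str, str]] = field(default_factory=list)
    coords: tuple[str, str] | None = None
    group_col: str | None = None
    group_responses: list[str] = field(default_factory=list)
    out_dir: str = "canopylux_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rad = raw.pop("radiation", {})
        for key in ("start_date", "end_date"):
            if key in raw and not isinstance(raw[key], dt.date):
                raw[key] = dt.date.fromisoformat(str(raw[key]))
        cfg = cls(**{k: v for k, v in raw.items() if k != "radiation"})
        if rad:
            cfg.radiation = RadiationConfig(**rad)
        cfg.pairs = [tuple(p) for p in cfg.pairs]
        cfg.dose_pairs = [tuple(p) for p in cfg.dose_pairs]
        if cfg.coords is not None:
            cfg.coords = tuple(cfg.coords)
        return cfg

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.hash()
    df["package_version"] = __version__
    df["seed"] = config.seed
    return df


def _load_masks(config: RunConfig):
    geoms = read_geometry_csv(config.geometry)
    masks = []
    if config.masks:
        for sid, geom in geoms.items():
            path = Path(config.masks) / f"{sid}.png"
            if not path.exists():
                masks.append((sid, None, f"mask file missing: {path.name}"))
                continue
            try:
                masks.append((sid, read_mask_png(path, geom, sid), None))
            except Exception as exc:  # pragma: no cover - defensive
                masks.append((sid, None, str(exc)))
    elif config.images:
        for sid, geom in geoms.items():
            found = None
            for ext in (".png", ".jpg", ".jpeg"):
                p = Path(config.images) / f"{sid}{ext}"
                if p.exists():
                    found = p
                    break
            if found is None:
                masks.append((sid, None, "image file missing"))
                continue
            try:
                img = read_image(found)
                masks.append(
                    (sid, binarize_blue(img, geom, config.threshold_mode,
                                        config.threshold, source_id=sid), None)
                )
            except Exception as exc:
                masks.append((sid, None, str(exc)))
    else:
        raise ValueError("config needs either an images or a masks directory")
    if not masks:
        raise ValueError("empty image set")
    return masks


def run_exposure(config: RunConfig) -> pd.DataFrame:
    """Per-sample canopy metrics and accumulated radiation dose.

    One row per image in geometry-file order; rows that fail are kept with
    an ``error`` message so a single bad photograph never aborts a campaign.
    """
    met = read_met_csv(config.met)
    rows = []
    for sid, mask, err in _load_masks(config):
        row: dict = {"source_id": sid, "error": err}
        if mask is not None:
            try:
                m = compute_metrics(mask)
                row.update(porosity=m.porosity, lai=m.lai,
                           **{f"t{i+1}": t for i, t in enumerate(m.gap_fractions)})
                summary = accumulate_radiation(
                    mask, config.radiation, met, config.start_date, config.end_date
                )
                row.update(direct_MJ=summary.direct_MJ, diffuse_MJ=summary.diffuse_MJ,
                           total_MJ=summary.total_MJ)
            except Exception as exc:
                row["error"] = str(exc)
                logger.error("exposure failed for %s: %s", sid, exc)
        rows.append(row)
    return _provenance(pd.DataFrame(rows), config)


def _load_profiles(config: RunConfig, covariates: pd.DataFrame | None) -> pd.DataFrame:
    peaks_by_sample = read_peak_table(config.peaks)
    calib = Calibration(response_factor=config.response_factor)
    meta_by_sample: dict[str, SampleMeta] = {}
    if covariates is not None and "extract_volume_mL" in covariates.columns:
        for rec in covariates.to_dict("records"):
            meta_by_sample[str(rec["sample_id"])] = SampleMeta(
                sample_id=str(rec["sample_id"]),
                aliquot_mass=float(rec.get("aliquot_mass_mg", 50.0)),
                extract_volume=float(rec["extract_volume_mL"]),
                skin_dry_mass_per_berry=float(rec["skin_dry_mass_per_berry_mg"]),
            )
    profiles = []
    for sid, peaks in peaks_by_sample.items():
        conc = quantify(peaks, calib)
        meta = meta_by_sample.get(sid, SampleMeta(sample_id=sid))
        profiles.append(aglycone_profile(conc, meta))
    return profiles_to_frame(profiles)


def _join(config: RunConfig, exposure: pd.DataFrame) -> pd.DataFrame:
    df = exposure.rename(columns={"source_id": "sample_id"})
    if config.peaks:
        cov = pd.read_csv(config.covariates) if config.covariates else None
        prof = _load_profiles(config, cov)
        before = len(df)
        df = df.merge(prof, on="sample_id", how="inner")
        logger.info("profile join kept %d/%d rows", len(df), before)
    if config.covariates:
        cov = pd.read_csv(config.covariates)
        cov["sample_id"] = cov["sample_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        before = len(df)
        df = df.merge(cov, on="sample_id", how="inner")
        logger.info("covariate join kept %d/%d rows", len(df), before)
    if "pruning_weight" in df.columns:
        pw = df["pruning_weight"].astype(float)
        df["inverse_pruning_weight"] = np.where(pw > 0, 1.0 / pw, np.nan)
    return df


def analyze_pairs(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]],
    dose_pairs: list[tuple[str, str]] = (),
    coords: tuple[str, str] | None = None,
    group_col: str | None = None,
    group_responses: list[str] = (),
    alpha: float = 0.05,
) -> dict:
    """Correlations (spatially corrected when coords exist), breakpoint fits
    for dose pairs, and ANOVA-LSD for grouped responses, on one joined table.

    Each pair uses pairwise-complete observations; the per-pair n is
    reported.  Pairs with a constant variable are flagged undefined rather
    than dropped silently.
    """
    results: dict = {"correlations": [], "segmented": [], "anova": []}
    have_coords = coords is not None and all(c in data.columns for c in coords)
    for xcol, ycol in pairs:
        sub = data[[xcol, ycol] + (list(coords) if have_coords else [])].dropna()
        rec = {"x": xcol, "y": ycol, "n": len(sub)}
        if len(sub) < 4:
            rec["status"] = "fewer than 4 matched rows"
        elif sub[xcol].std() == 0 or sub[ycol].std() == 0:
            rec["status"] = "undefined (constant variable)"
        else:
            cr = pearson_modified(
                sub[xcol], sub[ycol],
                coords=sub[list(coords)].to_numpy() if have_coords else None,
            )
            rec.update(status="ok", r=cr.r, p=cr.p_value,
                       effective_n=cr.effective_n, corrected=cr.corrected)
        results["correlations"].append(rec)
    for xcol, ycol in dose_pairs:
        sub = data[[xcol, ycol]].dropna()
        rec = {"x": xcol, "y": ycol, "n": len(sub)}
        if len(sub) < 6 or sub[xcol].std() == 0:
            rec["status"] = "insufficient data for a breakpoint fit"
        else:
            fit = segmented_fit(sub[xcol].to_numpy(), sub[ycol].to_numpy())
            rec.update(status="ok", psi=fit.psi, psi_se=fit.psi_se,
                       slope_left=fit.slope_left, slope_right=fit.slope_right,
                       converged=fit.converged, method=fit.method)
        results["segmented"].append(rec)
    if group_col and group_col in data.columns:
        for resp in group_responses:
            sub = data[[group_col, resp]].dropna()
            res = anova_lsd(sub[resp].to_numpy(), sub[group_col].to_numpy(), alpha)
            results["anova"].append(
                {
                    "response": resp, "F": res.F, "p": res.p,
                    "means": res.means, "se": res.se, "letters": res.letters,
                    "alpha": alpha, "n": len(sub),
                }
            )
    return results


def _write_report(results: dict, config: RunConfig, out: Path) -> None:
    lines = [
        f"canopylux {__version__} analysis report",
        f"config hash: {config.hash()}  seed: {config.seed}",
        f"window: {config.start_date} .. {config.end_date}",
        f"threshold: {config.threshold_mode} {config.threshold}",
        f"radiation: {config.radiation}",
        "",
    ]
    for rec in results["correlations"]:
        if rec.get("status") == "ok":
            kind = "spatially corrected" if rec["corrected"] else "classical"
            lines.append(
                f"corr {rec['x']} ~ {rec['y']}: r={rec['r']:.3f} p={rec['p']:.4g} "
                f"n={rec['n']} eff_n={rec['effective_n']:.1f} ({kind})"
            )
        else:
            lines.append(f"corr {rec['x']} ~ {rec['y']}: {rec['status']}")
    for rec in results["segmented"]:
        if rec.get("status") == "ok":
            lines.append(
                f"breakpoint {rec['x']} -> {rec['y']}: psi={rec['psi']:.1f} "
                f"(se {rec['psi_se']:.2g}) slopes {rec['slope_left']:.4g} / "
                f"{rec['slope_right']:.4g} [{rec['method']}]"
            )
        else:
            lines.append(f"breakpoint {rec['x']} -> {rec['y']}: {rec['status']}")
    for rec in results["anova"]:
        means = ", ".join(
            f"{g}={m:.3g}{rec['letters'][g]}" for g, m in rec["means"].items()
        )
        lines.append(f"anova {rec['response']}: F={rec['F']:.3g} p={rec['p']:.4g} {means}")
    out.write_text("\n".join(lines) + "\n")


def run_profile_analysis(
    config: RunConfig, exposure: pd.DataFrame | None = None
) -> dict:
    """Join exposure, profiles and covariates and run the configured stats.

    Writes joined.csv, correlations.csv, results.json and report.txt under
    ``config.out_dir`` and returns the results dict.
    """
    if exposure is None:
        exposure = run_exposure(config)
    data = _join(config, exposure)
    if len(data) < 4:
        raise ValueError("join produced fewer than 4 matched rows")
    results = analyze_pairs(
        data,
        pairs=config.pairs,
        dose_pairs=config.dose_pairs,
        coords=config.coords,
        group_col=config.group_col,
        group_responses=config.group_responses,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _provenance(data, config).to_csv(out / "joined.csv", index=False,
                                     float_format=FLOAT_FORMAT)
    pd.DataFrame(results["correlations"]).to_csv(
        out / "correlations.csv", index=False, float_format=FLOAT_FORMAT
    )
    (out / "results.json").write_text(json.dumps(results, indent=2, default=float))
    _write_report(results, config, out / "report.txt")
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Full run: exposure table then profile analysis; writes exposure.csv."""
    exposure = run_exposure(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure.to_csv(out / "exposure.csv", index=False, float_format=FLOAT_FORMAT)
    return run_profile_analysis(config, exposure)
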