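"""Synthetic inputs for every pipeline stage.

No field photographs, met records or chromatograms ship with the package;
these generators produce statistically controlled stand-ins so each stage
is testable end to end:

* fisheye sky masks — ``bernoulli`` mode draws each pixel independently
  with a known per-band sky probability (an analytic oracle for the
  gap-fraction estimators); ``discs`` mode scatters opaque angular discs
  over the hemisphere (a Boolean clumping model closer to real canopies);
* daily met series bounded above by the clear-sky envelope, cloudiness
  drawn from a Beta distribution;
* piecewise-linear dose-response data with a known breakpoint, defaulting
  to the ripening-window anchors 544.2 MJ/m2 (% kaempferol) and
  560.2 MJ/m2 (total flavonols);
* HPLC peak tables that round-trip through the flavonol module to exact
  target percentages.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy_metrics import ZenithBandSet
from .flavonol import CLASSES, PeakRecord, QUERCETIN_GLYCOSIDES
from .hemi_image import FisheyeGeometry, SkyMask, fov_valid_mask, pixel_to_direction
from .solar import MeteoDay, RadiationConfig, clear_sky_day_total

__all__ = [
    "MaskGenConfig",
    "ResponseSimConfig",
    "HEALDSBURG_PROFILE",
    "gen_mask",
    "gen_met_series",
    "gen_response",
    "gen_peak_table",
    "default_geometry",
]

#: Six-class percentage profile built from the Healdsburg Cabernet Sauvignon
#: site averages (% kaempferol 5.40, % quercetin 51.5, % myricetin 31.7);
#: the remaining 11.4% is split equally across the methylated classes.
HEALDSBURG_PROFILE: dict[str, float] = {
    "kaempferol": 5.40,
    "quercetin": 51.5,
    "myricetin": 31.7,
    "isorhamnetin": 3.8,
    "laricitrin": 3.8,
    "syringetin": 3.8,
}


def default_geometry(size: int = 201) -> FisheyeGeometry:
    """A centred fisheye geometry filling a size x size image."""
    c = (size - 1) / 2.0
    return FisheyeGeometry(center_row=c, center_col=c, radius_px=c)


@dataclass(frozen=True)
class MaskGenConfig:
    """Configuration for :func:`gen_mask`.

    bernoulli mode: each valid pixel is sky with its zenith band's
    probability (pixels between bands take the nearest band's value).
    discs mode: sky everywhere except inside randomly placed opaque angular
    discs; disc count is Poisson with mean density x visible solid angle,
    centres uniform over the visible spherical cap.
    """

    mode: str = "bernoulli"
    band_probs: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)
    disc_density: float = 2.0  # expected discs per steradian
    disc_radius_deg: float = 6.0
    size: int = 201
    geometry: FisheyeGeometry | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bernoulli", "discs"):
            raise ValueError("mode must be 'bernoulli' or 'discs'")
        if any(not 0 <= p <= 1 for p in self.band_probs):
            raise ValueError("band probabilities must lie in [0, 1]")
        if self.disc_density < 0 or self.disc_radius_deg <= 0:
            raise ValueError("disc density must be >= 0 and radius positive")

    def resolved_geometry(self) -> FisheyeGeometry:
        geom = self.geometry or default_geometry(self.size)
        if geom.radius_px > (self.size - 1) / 2.0 + 1e-9:
            raise ValueError("geometry radius exceeds the requested image size")
        return geom


def _pixel_angles(size: int, geom: FisheyeGeometry):
    valid = fov_valid_mask((size, size), geom)
    rows, cols = np.nonzero(valid)
    zen, az = pixel_to_direction(rows, cols, geom, strict=False)
    return valid, rows, cols, zen, az


def gen_mask(config: MaskGenConfig, bands: ZenithBandSet | None = None) -> SkyMask:
    """Generate a synthetic SkyMask; reproducible per seed."""
    geom = config.resolved_geometry()
    rng = np.random.default_rng(config.seed)
    valid, rows, cols, zen, az = _pixel_angles(config.size, geom)
    grid = np.zeros((config.size, config.size), dtype=bool)

    if config.mode == "bernoulli":
        bands = bands or ZenithBandSet()
        if len(config.band_probs) != len(bands.centers):
            raise ValueError("band_probs length must match the band set")
        centers = np.asarray(bands.centers)
        nearest = np.argmin(np.abs(zen[:, None] - centers[None, :]), axis=1)
        probs = np.asarray(config.band_probs)[nearest]
        sky = rng.random(zen.size) < probs
    else:  # discs
        # visible cap solid angle: 2*pi*(1 - cos(max_zenith))
        cos_max = np.cos(np.radians(geom.max_zenith))
        omega = 2.0 * np.pi * (1.0 - cos_max)
        k = rng.poisson(config.disc_density * omega)
        sky = np.ones(zen.size, dtype=bool)
        if k > 0:
            cz = rng.uniform(cos_max, 1.0, size=k)  # uniform on the cap
            caz = rng.uniform(0.0, 360.0, size=k)
            czen = np.degrees(np.arccos(cz))
            pv = _unit(zen, az)
            cv = _unit(czen, caz)
            cos_r = np.cos(np.radians(config.disc_radius_deg))
            covered = (pv @ cv.T >= cos_r).any(axis=1)
            sky = ~covered
    grid[rows, cols] = sky
    return SkyMask(grid=grid, valid=valid, geometry=geom,
                   source_id=f"synthetic-{config.mode}-{config.seed}")


def _unit(zen_deg, az_deg):
    z = np.radians(zen_deg)
    a = np.radians(az_deg)
    return np.stack([np.sin(z) * np.sin(a), np.sin(z) * np.cos(a), np.cos(z)], axis=-1)


def gen_met_series(
    start: dt.date,
    end: dt.date,
    config: RadiationConfig,
    cloud_beta: tuple[float, float] | None = (8.0, 2.0),
    seed: int = 0,
) -> list[MeteoDay]:
    """Daily measured-global series over [start, end] inclusive.

    Each day's value is the open-site clear-sky daily total multiplied by a
    Beta-distributed cloudiness factor in (0, 1]; ``cloud_beta=None`` means
    cloudless (factor exactly 1), so the series equals the clear-sky
    envelope.
    """
    if end < start:
        raise ValueError("end before start")
    rng = np.random.default_rng(seed)
    out = []
    d = start
    while d <= end:
        clear = clear_sky_day_total(d, config)
        factor = 1.0 if cloud_beta is None else float(rng.beta(*cloud_beta))
        out.append(MeteoDay(date=d, measured_global=clear * factor))
        d += dt.timedelta(days=1)
    return out


@dataclass(frozen=True)
class ResponseSimConfig:
    """Piecewise-linear dose-response with a known breakpoint.

    Defaults follow the ripening-window study conditions: breakpoint
    544.2 MJ/m2 (the % kaempferol anchor; use 560.2 for total flavonols),
    48 clusters, doses spanning 300-700 MJ/m2, slope 0.01 %/MJ below and
    0.05 %/MJ above the break, Gaussian noise of 0.5 percentage points
    (about 10% CV of the response range).
    """

    psi_true: float = 544.2
    slope_below: float = 0.01
    slope_above: float = 0.05
    intercept: float = 2.0
    noise_sd: float = 0.5
    n: int = 48
    dose_range: tuple[float, float] = (300.0, 700.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dose_range[0] < self.psi_true < self.dose_range[1]:
            raise ValueError("dose range must straddle psi_true")
        if self.n < 10:
            raise ValueError("need n >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def piecewise_response(dose, config: ResponseSimConfig):
    """Noise-free piecewise-linear mean response."""
    dose = np.asarray(dose, dtype=float)
    below = config.intercept + config.slope_below * dose
    above = (
        config.intercept
        + config.slope_below * config.psi_true
        + config.slope_above * (dose - config.psi_true)
    )
    return np.where(dose <= config.psi_true, below, above)


def gen_response(config: ResponseSimConfig) -> pd.DataFrame:
    """(dose, response) table: uniform doses + piecewise mean + Gaussian noise."""
    rng = np.random.default_rng(config.seed)
    dose = rng.uniform(*config.dose_range, size=config.n)
    resp = piecewise_response(dose, config) + rng.normal(0.0, config.noise_sd, config.n)
    return pd.DataFrame({"dose": dose, "response": resp})


def gen_peak_table(
    target_percentages: dict[str, float] | None = None,
    total_area: float = 1e5,
    seed: int | None = None,
    jitter_sd: float = 0.0,
    quercetin_split: tuple[float, float, float] = (0.2, 0.3, 0.5),
    sample_id: str = "",
) -> list[PeakRecord]:
    """Peak table whose class areas realise the target profile exactly.

    The quercetin class is split across its three glycosides by
    ``quercetin_split`` (galactoside, glucuronide, glucoside); the split is
    irrelevant to class-level outputs.  Optional lognormal jitter perturbs
    areas multiplicatively (percentages then only approximate).
    """
    pct = dict(target_percentages or HEALDSBURG_PROFILE)
    if set(pct) != set(CLASSES):
        raise ValueError(f"need exactly the classes {CLASSES}")
    if abs(sum(pct.values()) - 100.0) > 1e-6:
        raise ValueError("percentages must sum to 100")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if abs(sum(quercetin_split) - 1.0) > 1e-9:
        raise ValueError("quercetin_split must sum to 1")
    rng = np.random.default_rng(seed)
    rts = {  # plausible elution order at 365 nm, minutes
        "myricetin-3-O-glucoside": 14.2,
        "quercetin-3-O-galactoside": 17.8,
        "quercetin-3-O-glucuronide": 18.4,
        "quercetin-3-O-glucoside": 19.1,
        "laricitrin-3-O-glucoside": 20.6,
        "kaempferol-3-O-glucoside": 22.9,
        "isorhamnetin-3-O-glucoside": 23.7,
        "syringetin-3-O-glucoside": 24.8,
    }
    single = {
        "kaempferol": "kaempferol-3-O-glucoside",
        "myricetin": "myricetin-3-O-glucoside",
        "isorhamnetin": "isorhamnetin-3-O-glucoside",
        "laricitrin": "laricitrin-3-O-glucoside",
        "syringetin": "syringetin-3-O-glucoside",
    }
    peaks = []

    def add(compound: str, area: float) -> None:
        if jitter_sd > 0:
            area *= float(rng.lognormal(0.0, jitter_sd))
        peaks.append(PeakRecord(compound=compound, area=area,
                                retention_time=rts[compound], sample_id=sample_id))

    for cls, pct_v in pct.items():
        area = total_area * pct_v / 100.0
        if cls == "quercetin":
            for comp, frac in zip(QUERCETIN_GLYCOSIDES, quercetin_split):
                add(comp, area * frac)
        else:
            add(single[cls], area)
    peaks.sort(key=lambda p: p.retention_time)
    return peaks
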