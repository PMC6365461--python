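"""Canopy porosity, zenith-band gap fractions and the five-ring LAI inversion.

Porosity is the fraction of valid fisheye pixels classified as sky.  Gap
fractions are the same quantity restricted to five 13-degree-wide zenith
bands centred at 7, 23, 38, 53 and 68 degrees — the ring layout of
commercial plant canopy analyzers.  Leaf area index (here including
non-leafy vegetation such as shoots and wires) is estimated by the classic
weighted log-inversion of the band transmittances,

    LAI = 2 * sum_i W_i * (-ln T_i),

with ring weights W = (0.034, 0.104, 0.160, 0.218, 0.494) absorbing the
path-length and solid-angle factors of the analyzer convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemi_image import SkyMask, pixel_to_direction

__all__ = [
    "ZenithBandSet",
    "CanopyMetrics",
    "porosity",
    "band_gap_fractions",
    "estimate_lai",
    "compute_metrics",
    "metrics_table",
]

DEFAULT_CENTERS = (7.0, 23.0, 38.0, 53.0, 68.0)
DEFAULT_WEIGHTS = (0.034, 0.104, 0.160, 0.218, 0.494)


@dataclass(frozen=True)
class ZenithBandSet:
    """Five analyzer rings: band centres (deg), common width (deg), weights."""

    centers: tuple[float, ...] = DEFAULT_CENTERS
    width: float = 13.0
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    normalize_weights: bool = False

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.weights):
            raise ValueError("centers and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all weights must be positive")
        edges = sorted(self.edges)
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            if hi1 > lo2:
                raise ValueError("zenith bands overlap")

    @property
    def edges(self) -> list[tuple[float, float]]:
        h = self.width / 2.0
        return [(c - h, c + h) for c in self.centers]

    @property
    def effective_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum() if self.normalize_weights else w

    def assign(self, zenith: np.ndarray) -> np.ndarray:
        """Band index per zenith angle (half-open [low, high)); -1 outside."""
        zenith = np.asarray(zenith, dtype=float)
        out = np.full(zenith.shape, -1, dtype=int)
        for i, (lo, hi) in enumerate(self.edges):
            out[(zenith >= lo) & (zenith < hi)] = i
        return out


@dataclass
class CanopyMetrics:
    porosity: float
    gap_fractions: np.ndarray
    lai: float
    band_pixel_counts: np.ndarray
    floor: float
    source_id: str = ""


def porosity(mask: SkyMask) -> float:
    """Sky pixels / valid pixels, in [0, 1]."""
    return mask.sky_fraction


def _mask_zenith(mask: SkyMask) -> np.ndarray:
    rows, cols = np.nonzero(mask.valid)
    zen, _ = pixel_to_direction(rows, cols, mask.geometry, strict=False)
    return zen


def band_gap_fractions(
    mask: SkyMask, bands: ZenithBandSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band sky fraction T_i and valid-pixel count per band.

    Band membership is decided by each valid pixel's zenith angle; a band
    containing no valid pixel (geometry too small for the outer rings) is an
    error naming the band.
    """
    bands = bands or ZenithBandSet()
    zen = _mask_zenith(mask)
    sky = mask.grid[mask.valid]
    idx = bands.assign(zen)
    k = len(bands.centers)
    counts = np.zeros(k, dtype=int)
    gaps = np.zeros(k, dtype=float)
    for i in range(k):
        sel = idx == i
        counts[i] = sel.sum()
        if counts[i] == 0:
            lo, hi = bands.edges[i]
            raise ValueError(
                f"zenith band {i + 1} ({lo}-{hi} deg) contains no valid pixel"
            )
        gaps[i] = sky[sel].mean()
    return gaps, counts


def estimate_lai(
    gap_fractions,
    bands: ZenithBandSet | None = None,
    floor: float = 1e-6,
) -> float:
    """Five-ring LAI inversion, 2 * sum_i W_i * (-ln max(T_i, floor)).

    ``floor`` clamps zero gap fractions before the log (an unclamped zero
    would be infinite LAI); callers computing from a mask use 1/band-pixel-
    count, the smallest resolvable transmittance.
    """
    bands = bands or ZenithBandSet()
    t = np.asarray(gap_fractions, dtype=float)
    if t.shape != (len(bands.centers),):
        raise ValueError(f"expected {len(bands.centers)} gap fractions")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("gap fractions must lie in [0, 1]")
    if floor <= 0:
        raise ValueError("floor must be positive")
    w = bands.effective_weights
    return float(2.0 * np.sum(w * -np.log(np.maximum(t, floor))))


def compute_metrics(
    mask: SkyMask, bands: ZenithBandSet | None = None, floor: float | None = None
) -> CanopyMetrics:
    """Porosity, gap fractions and LAI for one mask.

    When ``floor`` is None it defaults per mask to 1 / min(band pixel count).
    """
    bands = bands or ZenithBandSet()
    gaps, counts = band_gap_fractions(mask, bands)
    eff_floor = floor if floor is not None else 1.0 / counts.min()
    return CanopyMetrics(
        porosity=porosity(mask),
        gap_fractions=gaps,
        lai=estimate_lai(gaps, bands, eff_floor),
        band_pixel_counts=counts,
        floor=eff_floor,
        source_id=mask.source_id,
    )


def metrics_table(masks, bands: ZenithBandSet | None = None) -> pd.DataFrame:
    """Batch metrics for an iterable of SkyMasks, one row per mask."""
    rows = []
    for m in masks:
        met = compute_metrics(m, bands)
        row = {"source_id": met.source_id, "porosity": met.porosity}
        for i, t in enumerate(met.gap_fractions, start=1):
            row[f"t{i}"] = t
        row["lai"] = met.lai
        row["threshold"] = m.threshold
        rows.append(row)
    return pd.DataFrame(rows)
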