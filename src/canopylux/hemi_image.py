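"""Fisheye sky/canopy segmentation and pixel–direction geometry.

Hemispherical ("fisheye") photographs taken from the fruit zone looking up
record which sky directions are open and which are blocked by canopy.  This
module reads 8-bit RGB imagery, thresholds the blue channel into a binary
sky mask (sky is bright in blue; vegetation is dark), and maps pixels to sky
directions under an equidistant (equi-angular) fisheye projection, in which
radial distance from the optical centre is proportional to zenith angle.

Conventions shared across the package:

* zenith angle: degrees from vertical; a 150-degree lens sees zenith 0-75.
* azimuth: compass bearing, 0 = north, clockwise, degrees in [0, 360).
* pixels outside the field-of-view circle are invalid and never enter any
  statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FisheyeGeometry",
    "SkyMask",
    "OutsideFieldOfView",
    "binarize_blue",
    "pooled_otsu_threshold",
    "otsu_threshold",
    "pixel_to_direction",
    "direction_to_pixel",
    "read_geometry_csv",
    "read_image",
    "read_mask_png",
    "write_mask_png",
]

GEOMETRY_COLUMNS = [
    "source_id",
    "center_row",
    "center_col",
    "radius_px",
    "max_zenith",
    "azimuth_offset",
]


class OutsideFieldOfView(ValueError):
    """A pixel or direction falls outside the lens field of view."""


@dataclass(frozen=True)
class FisheyeGeometry:
    """Optical geometry of one hemispherical image.

    Parameters
    ----------
    center_row, center_col : float
        Pixel coordinates of the optical axis.
    radius_px : float
        Pixels from the centre to the edge of the field of view.
    max_zenith : float
        Zenith angle (degrees) imaged at ``radius_px``.  Default 75, i.e.
        half of a 150-degree field of view; the 75-90 degree ring is unseen
        and treated as blocked downstream.
    azimuth_offset : float
        Compass azimuth (degrees) of the image "up" direction.
    """

    center_row: float
    center_col: float
    radius_px: float
    max_zenith: float = 75.0
    azimuth_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if not 0 < self.max_zenith <= 90:
            raise ValueError("max_zenith must be in (0, 90]")
        if not 0 <= self.azimuth_offset < 360:
            raise ValueError("azimuth_offset must be in [0, 360)")


@dataclass
class SkyMask:
    """Binary sky/canopy grid with its projection geometry.

    ``grid`` is True where the pixel saw sky; ``valid`` is True inside the
    field-of-view circle.  ``threshold`` records the effective blue-channel
    threshold used, for audit.
    """

    grid: np.ndarray
    valid: np.ndarray
    geometry: FisheyeGeometry
    source_id: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.grid.shape != self.valid.shape:
            raise ValueError("grid and valid must have identical shapes")
        # invalid pixels carry no information; normalise them to canopy
        self.grid = self.grid & self.valid

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def sky_fraction(self) -> float:
        n = self.n_valid
        if n == 0:
            raise ValueError("mask has no valid pixels")
        return float((self.grid & self.valid).sum() / n)

    def flipped(self) -> "SkyMask":
        """Return the mask with sky and canopy exchanged (valid region only)."""
        return SkyMask(
            grid=~self.grid & self.valid,
            valid=self.valid,
            geometry=self.geometry,
            source_id=self.source_id,
            threshold=self.threshold,
        )


def fov_valid_mask(shape: tuple[int, int], geometry: FisheyeGeometry) -> np.ndarray:
    """Boolean array, True for pixels inside the field-of-view circle."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    rr = rows - geometry.center_row
    cc = cols - geometry.center_col
    return rr * rr + cc * cc <= geometry.radius_px**2


def _check_circle_in_bounds(shape: tuple[int, int], geometry: FisheyeGeometry) -> None:
    r = geometry.radius_px
    if (
        geometry.center_row - r < -0.5
        or geometry.center_col - r < -0.5
        or geometry.center_row + r > shape[0] - 0.5
        or geometry.center_col + r > shape[1] - 0.5
    ):
        raise ValueError("field-of-view circle exceeds image bounds")


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu threshold over 8-bit values for the rule sky = (value >= t).

    Maximises the between-class variance w0*w1*(mu1-mu0)^2 over all 256
    candidate thresholds; ties broken toward the smaller threshold.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("no pixels to threshold")
    hist = np.bincount(values.astype(np.int64), minlength=256).astype(float)
    total = hist.sum()
    bins = np.arange(256, dtype=float)
    # class 0: value < t, class 1: value >= t, for t = 0..255
    cum0 = np.concatenate([[0.0], np.cumsum(hist)])[:256]  # counts below t
    sum0 = np.concatenate([[0.0], np.cumsum(hist * bins)])[:256]
    w0 = cum0 / total
    w1 = 1.0 - w0
    grand = float((hist * bins).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(cum0 > 0, sum0 / cum0, 0.0)
        mu1 = np.where(total - cum0 > 0, (grand - sum0) / (total - cum0), 0.0)
    between = w0 * w1 * (mu1 - mu0) ** 2
    return int(np.argmax(between))


def pooled_otsu_threshold(blues: list[np.ndarray]) -> int:
    """Otsu threshold on the pooled blue histogram of an image set.

    One shared threshold for a campaign keeps the classification rule
    identical across all images.
    """
    return otsu_threshold(np.concatenate([np.asarray(b).ravel() for b in blues]))


def binarize_blue(
    image: np.ndarray,
    geometry: FisheyeGeometry,
    mode: str = "fixed",
    threshold: float | None = 128,
    source_id: str = "",
) -> SkyMask:
    """Threshold the blue channel of an RGB fisheye image into a SkyMask.

    A pixel is sky iff its blue value >= the effective threshold.  With
    ``mode="fixed"`` the supplied threshold is used as-is; with
    ``mode="otsu"`` the threshold is computed from the valid-region blue
    histogram (for a whole campaign prefer :func:`pooled_otsu_threshold`
    and ``mode="fixed"`` so every image uses the same rule).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image with three channels")
    _check_circle_in_bounds(image.shape[:2], geometry)
    valid = fov_valid_mask(image.shape[:2], geometry)
    blue = image[..., 2]
    if mode == "fixed":
        if threshold is None:
            raise ValueError("fixed mode requires a threshold")
        if not 0 <= threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")
        eff = float(threshold)
    elif mode == "otsu":
        eff = float(otsu_threshold(blue[valid]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    grid = blue >= eff
    return SkyMask(grid=grid, valid=valid, geometry=geometry, source_id=source_id, threshold=eff)


def pixel_to_direction(
    row, col, geometry: FisheyeGeometry, *, strict: bool = True
):
    """Map pixel coordinates to a (zenith, azimuth) sky direction in degrees.

    Equidistant projection: zenith = max_zenith * r / radius_px.  Azimuth is
    the compass bearing of the pixel's image direction (image "up" maps to
    ``azimuth_offset``).  The centre pixel returns azimuth 0 by convention.
    Accepts scalars or arrays.
    """
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    dr = row - geometry.center_row
    dc = col - geometry.center_col
    rad = np.hypot(dr, dc)
    if strict and np.any(rad > geometry.radius_px * (1 + 1e-9)):
        raise OutsideFieldOfView("pixel outside the field-of-view circle")
    zenith = geometry.max_zenith * rad / geometry.radius_px
    bearing = np.degrees(np.arctan2(dc, -dr))  # clockwise from image up
    azimuth = np.where(rad == 0, 0.0, (bearing + geometry.azimuth_offset) % 360.0)
    if zenith.ndim == 0:
        return float(zenith), float(azimuth)
    return zenith, azimuth


def direction_to_pixel(zenith, azimuth, geometry: FisheyeGeometry):
    """Inverse of :func:`pixel_to_direction`; raises OutsideFieldOfView
    when zenith exceeds ``max_zenith`` (callers treat that ring as blocked)."""
    zenith = np.asarray(zenith, dtype=float)
    azimuth = np.asarray(azimuth, dtype=float)
    if np.any(zenith < 0) or np.any(zenith > geometry.max_zenith * (1 + 1e-12)):
        raise OutsideFieldOfView(
            f"zenith beyond max_zenith={geometry.max_zenith} is outside the field of view"
        )
    rad = geometry.radius_px * zenith / geometry.max_zenith
    bearing = np.radians(azimuth - geometry.azimuth_offset)
    row = geometry.center_row - rad * np.cos(bearing)
    col = geometry.center_col + rad * np.sin(bearing)
    if row.ndim == 0:
        return float(row), float(col)
    return row, col


# ---------------------------------------------------------------------------
# I/O

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/JPEG as an (H, W, 3) uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: grayscale image, expected RGB")
    return arr[..., :3]


def read_geometry_csv(path: str | Path) -> dict[str, FisheyeGeometry]:
    """Read a per-image geometry sidecar CSV keyed by source_id."""
    df = pd.read_csv(path)
    missing = set(GEOMETRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"geometry CSV missing columns: {sorted(missing)}")
    out: dict[str, FisheyeGeometry] = {}
    for rec in df.to_dict("records"):
        out[str(rec["source_id"])] = FisheyeGeometry(
            center_row=float(rec["center_row"]),
            center_col=float(rec["center_col"]),
            radius_px=float(rec["radius_px"]),
            max_zenith=float(rec["max_zenith"]),
            azimuth_offset=float(rec["azimuth_offset"]),
        )
    return out


_CANOPY, _INVALID, _SKY = 0, 128, 255


def write_mask_png(mask: SkyMask, path: str | Path, audit: bool = True) -> None:
    """Write a mask PNG (0 canopy, 255 sky, 128 invalid) plus a JSON audit."""
    img = np.full(mask.shape, _CANOPY, dtype=np.uint8)
    img[~mask.valid] = _INVALID
    img[mask.grid & mask.valid] = _SKY
    path = Path(path)
    iio.imwrite(path, img)
    if audit:
        record = {
            "source_id": mask.source_id,
            "threshold": mask.threshold,
            "sky_fraction": mask.sky_fraction,
            "n_valid": mask.n_valid,
        }
        path.with_suffix(".json").write_text(json.dumps(record, indent=2))


def read_mask_png(
    path: str | Path, geometry: FisheyeGeometry, source_id: str = ""
) -> SkyMask:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    valid = (arr != _INVALID) & fov_valid_mask(arr.shape, geometry)
    return SkyMask(grid=arr == _SKY, valid=valid, geometry=geometry,
                   source_id=source_id or Path(path).stem)
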