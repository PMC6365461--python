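"""HPLC-DAD flavonol quantification and aglycone profile percentages.

Grape-skin flavonols are detected at 365 nm and quantified against a single
quercetin-3-O-glucoside external standard, so every concentration is in
quercetin-3-O-glucoside equivalents (QGE).  Per-compound molar response
factors are deliberately not applied: single-standard quantification is the
literature convention and keeps profiles comparable across studies.

The profile groups glycosides by aglycone into six classes — kaempferol,
quercetin (galactoside + glucuronide + glucoside), myricetin, and the
methylated aglycones isorhamnetin, laricitrin and syringetin — and reports
each as a percentage of the six-class total.  Percentages need no sample
metadata; per-berry contents additionally require the extract volume and
the skin dry mass per berry, which must be supplied explicitly (never
defaulted, so per-berry numbers are never fabricated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "Calibration",
    "SampleMeta",
    "FlavonolProfile",
    "CLASSES",
    "COMPOUND_CLASS",
    "quantify",
    "aglycone_profile",
    "methylated_share",
    "read_peak_table",
    "profiles_to_frame",
]

CLASSES = (
    "kaempferol",
    "quercetin",
    "myricetin",
    "isorhamnetin",
    "laricitrin",
    "syringetin",
)

# compound -> aglycone class; "laricitin" accepted as a common variant spelling
COMPOUND_CLASS: dict[str, str] = {
    "myricetin-3-O-glucoside": "myricetin",
    "quercetin-3-O-galactoside": "quercetin",
    "quercetin-3-O-glucuronide": "quercetin",
    "quercetin-3-O-glucoside": "quercetin",
    "kaempferol-3-O-glucoside": "kaempferol",
    "isorhamnetin-3-O-glucoside": "isorhamnetin",
    "laricitrin-3-O-glucoside": "laricitrin",
    "laricitin-3-O-glucoside": "laricitrin",
    "syringetin-3-O-glucoside": "syringetin",
}

QUERCETIN_GLYCOSIDES = (
    "quercetin-3-O-galactoside",
    "quercetin-3-O-glucuronide",
    "quercetin-3-O-glucoside",
)


@dataclass(frozen=True)
class PeakRecord:
    """One integrated 365 nm peak."""

    compound: str
    area: float
    retention_time: float = float("nan")
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.compound not in COMPOUND_CLASS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


@dataclass(frozen=True)
class Calibration:
    """Single-point response factor: area units per mg/L of the standard."""

    response_factor: float

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError("response_factor must be positive")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str = ""
    aliquot_mass: float = 50.0  # mg dry skin powder extracted
    extract_volume: float | None = None  # mL
    skin_dry_mass_per_berry: float | None = None  # mg
    berry_weight: float | None = None  # g
    tss: float | None = None  # degrees Brix

    def __post_init__(self) -> None:
        for name in ("aliquot_mass", "extract_volume", "skin_dry_mass_per_berry"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")


@dataclass
class FlavonolProfile:
    """Six-class percentages plus (optionally) per-berry QGE contents."""

    percentages: dict[str, float]
    mg_per_berry: dict[str, float] | None = None
    total_mg_per_berry: float | None = None
    sample_id: str = ""


def quantify(peaks: list[PeakRecord], calib: Calibration) -> dict[str, float]:
    """Peak areas to per-compound mg/L (QGE); multiple peaks per compound sum."""
    conc: dict[str, float] = {}
    for p in peaks:
        conc[p.compound] = conc.get(p.compound, 0.0) + p.area / calib.response_factor
    return conc


def _class_concentrations(concentrations: dict[str, float]) -> dict[str, float]:
    by_class = {c: 0.0 for c in CLASSES}
    for compound, conc in concentrations.items():
        if compound not in COMPOUND_CLASS:
            raise ValueError(f"unknown compound {compound!r}")
        if conc < 0:
            raise ValueError("negative concentration")
        by_class[COMPOUND_CLASS[compound]] += conc
    return by_class


def aglycone_profile(
    concentrations: dict[str, float], meta: SampleMeta | None = None
) -> FlavonolProfile:
    """Class percentages (and per-berry contents when meta is complete).

    Per-berry content of a class with concentration C mg/L:
    C x extract_volume(L) x skin_dry_mass_per_berry / aliquot_mass — the
    extract represents ``aliquot_mass`` mg of skin; one berry carries
    ``skin_dry_mass_per_berry`` mg of skin.
    """
    by_class = _class_concentrations(concentrations)
    total = sum(by_class.values())
    if total <= 0:
        raise ValueError("all concentrations zero: profile undefined")
    pct = {c: 100.0 * v / total for c, v in by_class.items()}

    mg_per_berry = None
    total_per_berry = None
    if (
        meta is not None
        and meta.extract_volume is not None
        and meta.skin_dry_mass_per_berry is not None
    ):
        scale = (meta.extract_volume / 1000.0) * (
            meta.skin_dry_mass_per_berry / meta.aliquot_mass
        )
        mg_per_berry = {c: v * scale for c, v in by_class.items()}
        total_per_berry = sum(mg_per_berry.values())
    return FlavonolProfile(
        percentages=pct,
        mg_per_berry=mg_per_berry,
        total_mg_per_berry=total_per_berry,
        sample_id=meta.sample_id if meta is not None else "",
    )


def methylated_share(profile: FlavonolProfile) -> float:
    """Percentage of methylated aglycones (isorhamnetin+laricitrin+syringetin)."""
    p = profile.percentages
    return p["isorhamnetin"] + p["laricitrin"] + p["syringetin"]


# ---------------------------------------------------------------------------
# tabular I/O

def read_peak_table(path: str | Path) -> dict[str, list[PeakRecord]]:
    """Read a peak CSV (sample_id, compound, rt_min, area) grouped by sample."""
    df = pd.read_csv(path)
    need = {"sample_id", "compound", "area"}
    if not need <= set(df.columns):
        raise ValueError(f"peak table needs columns {sorted(need)}")
    out: dict[str, list[PeakRecord]] = {}
    for rec in df.to_dict("records"):
        out.setdefault(str(rec["sample_id"]), []).append(
            PeakRecord(
                compound=str(rec["compound"]),
                area=float(rec["area"]),
                retention_time=float(rec.get("rt_min", float("nan"))),
                sample_id=str(rec["sample_id"]),
            )
        )
    return out


def profiles_to_frame(profiles: list[FlavonolProfile]) -> pd.DataFrame:
    """One row per sample: six percentage columns + total_mg_per_berry."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        for c in CLASSES:
            row[f"pct_{c}"] = p.percentages[c]
        row["total_mg_per_berry"] = (
            p.total_mg_per_berry if p.total_mg_per_berry is not None else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
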