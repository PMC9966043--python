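"""Derived ocular biometry: spherical equivalent, vitreous chamber depth,
Bennett crystalline lens power, refraction averaging and eye averaging.

Units follow the conventions of clinical biometry reports: all axial
segments in millimetres except central corneal thickness (CCT) and
choroidal thickness (ChT), which are recorded in micrometres; dioptric
quantities (refraction, corneal power, lens power) in diopters.

The long-format measurement table expected by :func:`derive_table` has one
row per participant x eye x visit with columns::

    pid, site, arm, month, eye, al_mm, cct_um, acd_mm, lt_mm, cht_um,
    k1_d, k2_d, sphere_d, cylinder_d, quality

Missing values are blank/NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InconsistentBiometryError,
    InvalidMeasurementError,
    OpticsDomainError,
    SchemaError,
)

#: Autorefractor readings below this quality score are discarded.
QUALITY_CUTOFF = 7.0

#: Required columns of the raw long-format measurement table.
RAW_COLUMNS = [
    "pid", "site", "arm", "month", "eye",
    "al_mm", "cct_um", "acd_mm", "lt_mm", "cht_um",
    "k1_d", "k2_d", "sphere_d", "cylinder_d", "quality",
]

#: Outcome columns of the derived, eye-averaged analysis table.
OUTCOME_COLUMNS = [
    "al_mm", "cct_um", "acd_mm", "lt_mm", "vcd_mm",
    "cht_um", "se_d", "km_d", "lp_d",
]


@dataclass(frozen=True)
class RefractionReading:
    """A single autorefractor reading.

    Cylinder is normalized to the minus-cylinder convention on
    construction, so ``cylinder <= 0`` always holds afterwards.
    """

    sphere: float
    cylinder: float
    axis: float = 0.0
    quality: float = 10.0

    def __post_init__(self):
        if self.cylinder > 0:
            # plus-cylinder transposition: S+C, -C, axis+90
            object.__setattr__(self, "sphere", self.sphere + self.cylinder)
            object.__setattr__(self, "cylinder", -self.cylinder)
            object.__setattr__(self, "axis", (self.axis + 90.0) % 180.0)


@dataclass(frozen=True)
class BennettConstants:
    """Principal-plane constants for Bennett's lens-power formula.

    ``c1`` and ``c2`` place the crystalline lens' principal planes as
    fractions of lens thickness; the defaults are Bennett's original
    schematic-eye values.  ``n`` is the refractive index of aqueous and
    vitreous humours.  ``vertex_mm`` optionally transposes the refraction
    from the spectacle plane to the corneal plane (0 = refraction already
    at the corneal plane).
    """

    c1: float = 0.596
    c2: float = 0.358
    n: float = 4.0 / 3.0
    vertex_mm: float = 0.0

    def __post_init__(self):
        if not (0 < self.c1 < 1 and 0 < self.c2 < 1):
            raise InvalidMeasurementError("c1, c2 must lie in (0, 1)")
        if self.n <= 1:
            raise InvalidMeasurementError("refractive index must exceed 1")


@dataclass
class BiometricPanel:
    """Measured plus derived biometrics of one eye at one visit."""

    al_mm: float
    cct_um: float
    acd_mm: float
    lt_mm: float
    cht_um: float = math.nan
    k1_d: float = math.nan
    k2_d: float = math.nan
    sphere_d: float = math.nan
    cylinder_d: float = math.nan
    # derived
    se_d: float = field(default=math.nan, init=False)
    vcd_mm: float = field(default=math.nan, init=False)
    km_d: float = field(default=math.nan, init=False)
    lp_d: float = field(default=math.nan, init=False)

    def derive(self, constants: BennettConstants | None = None) -> "BiometricPanel":
        """Fill in SE, VCD, Km and Bennett lens power from the measured fields."""
        constants = constants or BennettConstants()
        self.se_d = spherical_equivalent(self.sphere_d, self.cylinder_d)
        self.vcd_mm = vitreous_chamber_depth(self.al_mm, self.cct_um, self.acd_mm, self.lt_mm)
        self.km_d = (self.k1_d + self.k2_d) / 2.0
        if math.isfinite(self.se_d) and math.isfinite(self.km_d):
            self.lp_d = bennett_lens_power(
                self.se_d, self.km_d, self.al_mm, self.acd_mm,
                self.cct_um, self.lt_mm, constants,
            )
        return self


def spherical_equivalent(sphere, cylinder):
    """Spherical equivalent: sphere plus half the cylinder power (D).

    Scalars raise :class:`InvalidMeasurementError` on non-finite input;
    array input propagates NaN (missing) elementwise.
    """
    sphere = np.asarray(sphere, dtype=float)
    cylinder = np.asarray(cylinder, dtype=float)
    if sphere.ndim == 0 and cylinder.ndim == 0:
        if not (np.isfinite(sphere) and np.isfinite(cylinder)):
            raise InvalidMeasurementError("non-finite refraction input")
        return float(sphere + cylinder / 2.0)
    return sphere + cylinder / 2.0


def average_refraction(readings: Iterable[RefractionReading]) -> RefractionReading | None:
    """Average autorefractor readings that pass the quality cut-off (>= 7).

    Returns the component-wise mean of sphere and cylinder over the
    qualifying readings, or ``None`` (missing-value marker) when no
    reading qualifies.
    """
    ok = [r for r in readings if r.quality >= QUALITY_CUTOFF]
    if not ok:
        return None
    sph = float(np.mean([r.sphere for r in ok]))
    cyl = float(np.mean([r.cylinder for r in ok]))
    axis = float(np.mean([r.axis for r in ok]))
    qual = float(max(r.quality for r in ok))
    return RefractionReading(sphere=sph, cylinder=cyl, axis=axis, quality=qual)


def vitreous_chamber_depth(al_mm, cct_um, acd_mm, lt_mm):
    """Vitreous chamber depth (mm): axial length minus the distance from
    corneal epithelium to the posterior lens surface (CCT + ACD + LT).

    CCT is supplied in micrometres and converted internally.
    """
    al = np.asarray(al_mm, dtype=float)
    vcd = al - np.asarray(cct_um, dtype=float) / 1000.0 \
        - np.asarray(acd_mm, dtype=float) - np.asarray(lt_mm, dtype=float)
    if al.ndim == 0:
        if not np.isfinite(vcd):
            raise InvalidMeasurementError("non-finite biometry input")
        if vcd <= 0:
            raise InconsistentBiometryError(
                f"VCD = {float(vcd):.4f} mm <= 0: segments exceed axial length"
            )
        return float(vcd)
    bad = np.isfinite(vcd) & (vcd <= 0)
    if bad.any():
        raise InconsistentBiometryError(
            f"{int(bad.sum())} record(s) with non-positive vitreous chamber depth"
        )
    return vcd


def bennett_lens_power(se_d, km_d, al_mm, acd_mm, cct_um, lt_mm,
                       constants: BennettConstants | None = None):
    """Equivalent crystalline lens power (D) by Bennett's paraxial method.

    The lens is replaced by a thin lens between two principal planes
    located ``c1*LT`` behind the anterior lens surface and ``c2*LT`` in
    front of the posterior surface.  With ACD re-referenced to the corneal
    epithelium (``ACD_epi = CCT/1000 + ACD``), the corneal-plane vergence
    ``SE_c + Km`` is propagated through ``d1 = ACD_epi + c1*LT`` of medium
    ``n``, and the lens must supply the exit vergence ``1000*n/d2`` that
    focuses on the retina across ``d2 = (AL - ACD_epi - LT) + c2*LT``.
    """
    c = constants or BennettConstants()
    se = np.asarray(se_d, dtype=float)
    km = np.asarray(km_d, dtype=float)
    al = np.asarray(al_mm, dtype=float)
    acd = np.asarray(acd_mm, dtype=float)
    cct = np.asarray(cct_um, dtype=float)
    lt = np.asarray(lt_mm, dtype=float)

    if c.vertex_mm:
        # spectacle plane -> corneal plane transposition
        se = se / (1.0 - (c.vertex_mm / 1000.0) * se)

    acd_epi = cct / 1000.0 + acd
    d1 = acd_epi + c.c1 * lt
    d2 = (al - acd_epi - lt) + c.c2 * lt
    k = 1000.0 * c.n
    denom = k - d1 * (se + km)
    scalar = se.ndim == 0 and km.ndim == 0 and al.ndim == 0
    if scalar:
        if d2 <= 0 or denom <= 0:
            raise OpticsDomainError("vergence propagation out of domain (d2 or denominator <= 0)")
    else:
        bad = (np.isfinite(d2) & (d2 <= 0)) | (np.isfinite(denom) & (denom <= 0))
        if bad.any():
            raise OpticsDomainError(
                f"{int(bad.sum())} record(s) out of the paraxial domain"
            )
    s1 = k * (se + km) / denom
    s2 = k / d2
    lp = s2 - s1
    return float(lp) if scalar else lp


def average_eyes(od, os_):
    """Average a parameter over the two eyes.

    A single available eye is returned as-is; both missing returns NaN
    (missing-value marker).  NaN encodes 'missing'.
    """
    vals = [v for v in (od, os_) if v is not None and np.isfinite(v)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def validate_schema(df: pd.DataFrame, columns: Sequence[str] = RAW_COLUMNS) -> None:
    """Raise :class:`SchemaError` naming any missing required column."""
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"input table is missing required column(s): {missing}")


def derive_table(df: pd.DataFrame,
                 constants: BennettConstants | None = None) -> pd.DataFrame:
    """Add derived columns (se_d, vcd_mm, km_d, lp_d) to a raw long table.

    Rows with missing inputs get missing derived values; rows whose
    measured segments are physically inconsistent raise.
    """
    validate_schema(df)
    out = df.copy()
    out["se_d"] = spherical_equivalent(out["sphere_d"].to_numpy(),
                                       out["cylinder_d"].to_numpy())
    out["vcd_mm"] = vitreous_chamber_depth(
        out["al_mm"].to_numpy(), out["cct_um"].to_numpy(),
        out["acd_mm"].to_numpy(), out["lt_mm"].to_numpy(),
    )
    out["km_d"] = (out["k1_d"].to_numpy() + out["k2_d"].to_numpy()) / 2.0
    out["lp_d"] = bennett_lens_power(
        out["se_d"].to_numpy(), out["km_d"].to_numpy(), out["al_mm"].to_numpy(),
        out["acd_mm"].to_numpy(), out["cct_um"].to_numpy(), out["lt_mm"].to_numpy(),
        constants,
    )
    return out


def average_eyes_table(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a derived long table to one row per participant x visit.

    Each outcome is the mean over available eyes (single-eye fallback);
    `site` and `arm` are constant within participant and carried through.
    """
    needed = ["pid", "site", "arm", "month"] + [c for c in OUTCOME_COLUMNS if c in df.columns]
    validate_schema(df, [c for c in needed if c not in OUTCOME_COLUMNS] + ["al_mm"])
    cols = [c for c in OUTCOME_COLUMNS if c in df.columns]
    grouped = (
        df.groupby(["pid", "site", "arm", "month"], sort=True, dropna=False)[cols]
        .mean()  # skipna=True: one missing eye falls back to the other
        .reset_index()
    )
    return grouped


def changes_from_baseline(avg: pd.DataFrame, visit: int,
                          outcomes: Sequence[str] = ("se_d", "al_mm", "lp_d", "cht_um"),
                          baseline_month: int = 0) -> pd.DataFrame:
    """Participant-wise change scores (visit minus baseline) for `outcomes`.

    Returns one row per participant having both visits, with columns
    ``d_<outcome>`` plus pid/site/arm.  Used by the mediation stage.
    """
    base = avg[avg["month"] == baseline_month].set_index("pid")
    fup = avg[avg["month"] == visit].set_index("pid")
    common = base.index.intersection(fup.index)
    rows = {"pid": common,
            "site": base.loc[common, "site"].to_numpy(),
            "arm": base.loc[common, "arm"].to_numpy()}
    for c in outcomes:
        rows[f"d_{c}"] = (fup.loc[common, c] - base.loc[common, c]).to_numpy()
    return pd.DataFrame(rows).reset_index(drop=True)
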