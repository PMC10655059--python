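"""Soil-profile data model and arithmetic.

A sampling campaign yields one :class:`SoilProfile`: the mass activity of a
single radionuclide (here ¹³⁷Cs) measured by gamma spectroscopy in uniform
depth slices — in the reference configuration six 5-cm layers down to 30 cm.
From a profile this module derives

* per-layer *fractional contributions* ``R_z = A_z / T`` where ``T`` is the
  sum of the per-layer mass activities (explicitly *not* the bulk 0–30 cm
  activity),
* the areal *deposition* (inventory) in kBq/m² via the soil density and the
  layer thickness, and
* decay *backdating* of activities to a common reference date, by default
  the Chernobyl accident (1986-04-26).

Profiles round-trip through a commented CSV/TSV format readable by pandas.
"""

from __future__ import annotations

import datetime as _dt
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHERNOBYL_DATE",
    "CS137_HALF_LIFE_Y",
    "DAYS_PER_YEAR",
    "Layer",
    "SoilProfile",
    "FractionVector",
    "years_between",
    "fractional_contributions",
    "backdate_activity",
    "total_deposition",
    "deposition_report",
    "read_profiles",
    "write_profiles",
]

#: Reference date all backdating defaults to: the Chernobyl accident.
CHERNOBYL_DATE = _dt.date(1986, 4, 26)

#: Default ¹³⁷Cs half-life in years (configurable on every profile).
CS137_HALF_LIFE_Y = 30.08

#: Fractional-year convention used throughout.
DAYS_PER_YEAR = 365.25


def years_between(start: _dt.date, end: _dt.date) -> float:
    """Elapsed time from *start* to *end* in fractional years (365.25 d/y)."""
    return (end - start).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class Layer:
    """One depth slice: half-open interval [top_cm, bottom_cm) positive-down.

    ``activity`` is the mass activity in Bq/kg; ``rel_sigma`` its relative
    standard uncertainty (dimensionless fraction, e.g. 0.10 for 10%).
    """

    top_cm: float
    bottom_cm: float
    activity: float
    rel_sigma: float = 0.10

    def __post_init__(self) -> None:
        if self.bottom_cm <= self.top_cm:
            raise ValueError(
                f"layer bottom ({self.bottom_cm} cm) must lie below top ({self.top_cm} cm)"
            )
        if self.activity < 0:
            raise ValueError(f"negative mass activity: {self.activity} Bq/kg")
        if self.rel_sigma < 0:
            raise ValueError(f"negative relative uncertainty: {self.rel_sigma}")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm


@dataclass
class SoilProfile:
    """One sampling campaign: date, ordered layers, soil density, half-life.

    Layers must be contiguous, non-overlapping, ordered top-down and of
    uniform thickness (5 cm in the reference configuration).
    """

    sample_date: _dt.date
    layers: list[Layer]
    density_g_cm3: float = 1.3
    half_life_y: float = CS137_HALF_LIFE_Y
    reference_date: _dt.date = CHERNOBYL_DATE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile must contain at least one layer")
        if self.density_g_cm3 <= 0:
            raise ValueError("soil density must be positive")
        if self.half_life_y <= 0:
            raise ValueError("half-life must be positive")
        thick = self.layers[0].thickness_cm
        for prev, cur in zip(self.layers, self.layers[1:]):
            if not math.isclose(cur.top_cm, prev.bottom_cm, abs_tol=1e-9):
                raise ValueError(
                    f"layers not contiguous: [{prev.top_cm}, {prev.bottom_cm}) then "
                    f"[{cur.top_cm}, {cur.bottom_cm})"
                )
        for lay in self.layers:
            if not math.isclose(lay.thickness_cm, thick, rel_tol=1e-9):
                raise ValueError("layer thickness must be uniform within a profile")

    @property
    def activities(self) -> np.ndarray:
        """Per-layer mass activities in Bq/kg, top-down."""
        return np.array([lay.activity for lay in self.layers], dtype=float)

    @property
    def layer_thickness_cm(self) -> float:
        return self.layers[0].thickness_cm

    @property
    def t_years(self) -> float:
        """Years elapsed since the reference date (fractional, 365.25 d/y)."""
        return years_between(self.reference_date, self.sample_date)


@dataclass(frozen=True)
class FractionVector:
    """Per-layer fractional contributions at time ``t`` (years since reference).

    When derived from a measured profile the entries sum to 1 by construction;
    when produced by model propagation the sum may fall below the initial sum
    because activity leaks below the deepest modelled layer.
    """

    t: float
    r: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.r):
            raise ValueError("fractional contributions must be non-negative")

    def __len__(self) -> int:
        return len(self.r)

    def __iter__(self):
        return iter(self.r)

    def __getitem__(self, i):
        return self.r[i]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self.r))

    def renormalized(self) -> "FractionVector":
        """A view scaled to sum 1 — a *measurement-like* ratio vector.

        Model output deliberately leaks mass; use this only where a quantity
        defined as a ratio of simultaneous measurements is wanted.
        """
        s = self.total
        if s <= 0:
            raise ValueError("cannot renormalize an all-zero fraction vector")
        return FractionVector(self.t, tuple(x / s for x in self.r))


def fractional_contributions(profile: SoilProfile) -> FractionVector:
    """Per-layer share of the summed mass activity, ``R_z = A_z / T``.

    ``T`` is the sum of the per-layer activities. Raises ``ValueError`` on an
    all-zero profile (the ratio is undefined).
    """
    a = profile.activities
    total = a.sum()
    if total <= 0:
        raise ValueError("empty profile: total activity is zero, R_z undefined")
    return FractionVector(profile.t_years, tuple(a / total))


def backdate_activity(activity: float, elapsed_years: float, half_life_y: float = CS137_HALF_LIFE_Y) -> float:
    """Correct a measured activity back to the reference date.

    Multiplies by ``2**(elapsed / half_life)``, undoing the decay accumulated
    over ``elapsed_years``. Negative elapsed time is rejected — a measurement
    cannot precede the reference date it is being corrected to.
    """
    if elapsed_years < 0:
        raise ValueError("measurement precedes reference date (negative elapsed time)")
    if half_life_y <= 0:
        raise ValueError("half-life must be positive")
    return activity * 2.0 ** (elapsed_years / half_life_y)


def decay_activity(activity: float, elapsed_years: float, half_life_y: float = CS137_HALF_LIFE_Y) -> float:
    """Forward radioactive decay over ``elapsed_years`` (inverse of backdating)."""
    if elapsed_years < 0:
        raise ValueError("elapsed time must be non-negative")
    if half_life_y <= 0:
        raise ValueError("half-life must be positive")
    return activity * 2.0 ** (-elapsed_years / half_life_y)


def total_deposition(profile: SoilProfile, backdated: bool = False) -> float:
    """Areal deposition (inventory) of the profile in kBq/m².

    Each layer contributes ``A_z [Bq/kg] × density [kg/m³] × thickness [m]``;
    the per-layer areal mass loading is computed from density and thickness,
    never hard-coded. With ``backdated=True`` the result is corrected to the
    profile's reference date.
    """
    if profile.density_g_cm3 is None or profile.density_g_cm3 <= 0:
        raise ValueError("profile density not configured")
    rho_kg_m3 = profile.density_g_cm3 * 1000.0
    thickness_m = profile.layer_thickness_cm / 100.0
    dep_bq_m2 = profile.activities.sum() * rho_kg_m3 * thickness_m
    if backdated:
        dep_bq_m2 = backdate_activity(dep_bq_m2, profile.t_years, profile.half_life_y)
    return dep_bq_m2 / 1000.0


def deposition_report(profiles: Sequence[SoilProfile]) -> pd.DataFrame:
    """One row per profile: date, elapsed years, deposition as-measured and backdated."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "date": p.sample_date.isoformat(),
                "t_years": round(p.t_years, 4),
                "deposition_kBq_m2": total_deposition(p),
                "deposition_backdated_kBq_m2": total_deposition(p, backdated=True),
            }
        )
    return pd.DataFrame(rows, columns=["date", "t_years", "deposition_kBq_m2", "deposition_backdated_kBq_m2"])


_COLUMNS = ["date", "top_cm", "bottom_cm", "activity_Bq_per_kg", "rel_sigma"]


def read_profiles(
    path,
    density_g_cm3: float = 1.3,
    half_life_y: float = CS137_HALF_LIFE_Y,
    reference_date: _dt.date = CHERNOBYL_DATE,
) -> list[SoilProfile]:
    """Read profiles from a delimited text table, one row per layer.

    Expected header: ``date, top_cm, bottom_cm, activity_Bq_per_kg, rel_sigma``
    (comma or tab separated; ``#`` comment lines allowed). Rows sharing a date
    form one profile. An empty file yields an empty list.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first = line
                break
    if not first:
        return []
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    if df.empty:
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing} (found {list(df.columns)})")
    profiles: list[SoilProfile] = []
    for date_str, group in df.groupby("date", sort=True):
        try:
            date = _dt.date.fromisoformat(str(date_str))
        except ValueError as exc:
            line = int(group.index[0]) + 2  # header + 1-based
            raise ValueError(f"unparsable date {date_str!r} near line {line}: {exc}") from None
        group = group.sort_values("top_cm")
        layers = []
        for idx, row in group.iterrows():
            try:
                layers.append(
                    Layer(
                        top_cm=float(row["top_cm"]),
                        bottom_cm=float(row["bottom_cm"]),
                        activity=float(row["activity_Bq_per_kg"]),
                        rel_sigma=float(row["rel_sigma"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"malformed layer row at line {int(idx) + 2}: {exc}") from None
        try:
            profiles.append(
                SoilProfile(
                    sample_date=date,
                    layers=layers,
                    density_g_cm3=density_g_cm3,
                    half_life_y=half_life_y,
                    reference_date=reference_date,
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid profile dated {date}: {exc}") from None
    return profiles


def write_profiles(profiles: Iterable[SoilProfile], path, header_lines: Sequence[str] = ()) -> None:
    """Write profiles to CSV in the format :func:`read_profiles` accepts.

    ``header_lines`` are emitted as ``#``-prefixed comments (provenance).
    """
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    rows = []
    for p in profiles:
        for lay in p.layers:
            rows.append(
                {
                    "date": p.sample_date.isoformat(),
                    "top_cm": lay.top_cm,
                    "bottom_cm": lay.bottom_cm,
                    "activity_Bq_per_kg": repr(lay.activity),
                    "rel_sigma": lay.rel_sigma,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(buf, index=False)
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
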