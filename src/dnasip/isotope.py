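"""Isotope mass balance for :sup:`13`C-substrate assimilation.

Converts δ¹³C measurements of particulate organic carbon (POC) into the
mass of microbially assimilated ¹³C, blank-corrected assimilation rates,
and the ¹³C share of the POC pool.

Conventions
-----------
δ¹³C is expressed in per mil (‰) against the VPDB standard.  ``R``
denotes the ¹³C/¹²C *atom ratio* — the VPDB reference value 0.0112372 is
sometimes called an "atomic percent" in the literature but is used
algebraically as an atom ratio throughout, and that is how it is
implemented here.  Masses are µg C per litre of incubated seawater,
times in days, rates in µg L⁻¹ d⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: ¹³C/¹²C atom ratio of the Vienna Peedee Belemnite reference.
R_VPDB = 0.0112372


class Treatment(str, Enum):
    """Incubation treatment: ¹³C-labelled substrate or ¹²C blank."""

    LABELED = "labeled"
    BLANK = "blank"


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of the isotope system.

    Parameters
    ----------
    r_vpdb : float
        ¹³C/¹²C atom ratio of the VPDB reference (dimensionless).
    """

    r_vpdb: float = R_VPDB

    def __post_init__(self) -> None:
        if self.r_vpdb <= 0:
            raise ValueError("r_vpdb must be positive")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One incubation observation of the POC pool.

    Attributes
    ----------
    delta13c_poc : float
        δ¹³C of POC in ‰ vs VPDB; must be ≥ −1000 (atom ratio ≥ 0).
    m_poc : float
        POC mass in µg C per litre of incubated seawater (≥ 0).
    t : float
        Incubation time in days (> 0 for rate computation).
    treatment : Treatment
        ``labeled`` (¹³C substrate) or ``blank`` (¹²C substrate).
    label : str
        Free-text sample identifier (site/depth/substrate).
    """

    delta13c_poc: float
    m_poc: float
    t: float
    treatment: Treatment = Treatment.LABELED
    label: str = ""

    def __post_init__(self) -> None:
        if self.delta13c_poc < -1000:
            raise ValueError(
                f"delta13c_poc={self.delta13c_poc} < -1000 implies a negative atom ratio"
            )
        if self.m_poc < 0:
            raise ValueError("m_poc must be non-negative")


def delta_to_ratio(delta13c: float, r_ref: float = R_VPDB):
    """Convert δ¹³C (‰) to the ¹³C/¹²C atom ratio.

    ``R_sample = (δ¹³C/1000 + 1) × R_ref``.
    """
    delta13c = np.asarray(delta13c, dtype=float)
    if np.any(delta13c < -1000):
        raise ValueError("delta13c < -1000 per mil implies a negative atom ratio")
    if r_ref <= 0:
        raise ValueError("r_ref must be positive")
    out = (delta13c / 1000.0 + 1.0) * r_ref
    return out.item() if out.ndim == 0 else out


def ratio_to_delta(r_sample: float, r_ref: float = R_VPDB):
    """Convert a ¹³C/¹²C atom ratio back to δ¹³C (‰); inverse of
    :func:`delta_to_ratio`."""
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(r_sample < 0):
        raise ValueError("atom ratio must be non-negative")
    if r_ref <= 0:
        raise ValueError("r_ref must be positive")
    out = (r_sample / r_ref - 1.0) * 1000.0
    return out.item() if out.ndim == 0 else out


def mass_13c(m_poc: float, r_sample: float):
    """Mass of ¹³C (µg L⁻¹) in a POC pool of mass ``m_poc`` with atom
    ratio ``r_sample``.

    ``m(¹³C) = 13·m_POC·R / (13·R + 12)`` — the mass fraction of ¹³C
    given atom ratio R and isotope masses 13 and 12.
    """
    m_poc = np.asarray(m_poc, dtype=float)
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(m_poc < 0) or np.any(r_sample < 0):
        raise ValueError("m_poc and r_sample must be non-negative")
    out = 13.0 * m_poc * r_sample / (13.0 * r_sample + 12.0)
    return out.item() if out.ndim == 0 else out


def assimilation_rate(m13c_sample: float, m13c_blank: float, t: float):
    """Blank-corrected ¹³C assimilation rate (µg L⁻¹ d⁻¹).

    ``(m_sample(¹³C) − m_blank(¹³C)) / t``.  A negative result is
    returned with a warning (measurement noise), not clamped.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("incubation time t must be positive")
    out = (np.asarray(m13c_sample, float) - np.asarray(m13c_blank, float)) / t
    if np.any(np.asarray(out) < 0):
        warnings.warn(
            "negative blank-corrected assimilation rate (blank exceeds sample); "
            "returned as-is",
            stacklevel=2,
        )
    return out.item() if out.ndim == 0 else out


def percent_13c_in_poc(m13c_sample: float, m13c_blank: float, m_poc: float):
    """Blank-corrected share of ¹³C in the POC pool, as a fraction.

    ``(m_sample(¹³C) − m_blank(¹³C)) / m_POC``.  Multiply by 100 to
    report percent.
    """
    m_poc = np.asarray(m_poc, dtype=float)
    if np.any(m_poc <= 0):
        raise ValueError("m_poc must be positive")
    out = (np.asarray(m13c_sample, float) - np.asarray(m13c_blank, float)) / m_poc
    return out.item() if out.ndim == 0 else out


def measurement_mass_13c(m: IsotopeMeasurement, constants: IsotopeConstants | None = None) -> float:
    """¹³C mass (µg L⁻¹) of one measurement via the δ → R → mass chain."""
    c = constants or IsotopeConstants()
    return mass_13c(m.m_poc, delta_to_ratio(m.delta13c_poc, c.r_vpdb))


def rates_from_measurements(
    measurements: Iterable[IsotopeMeasurement],
    constants: IsotopeConstants | None = None,
) -> pd.DataFrame:
    """Pair labelled and blank incubations and compute rates.

    Measurements are grouped by (label, t); each group must contain one
    ``labeled`` and one ``blank`` observation.  Returns a table with one
    row per pair: sample label, time, assimilation rate and the percent
    of ¹³C in the POC pool.
    """
    c = constants or IsotopeConstants()
    rows = []
    groups: dict[tuple[str, float], dict[Treatment, IsotopeMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.label, m.t), {})[Treatment(m.treatment)] = m
    for (label, t), pair in sorted(groups.items()):
        if Treatment.LABELED not in pair or Treatment.BLANK not in pair:
            missing = (
                Treatment.BLANK if Treatment.BLANK not in pair else Treatment.LABELED
            )
            raise ValueError(f"sample {label!r} at t={t}: missing {missing.value} incubation")
        lab, blk = pair[Treatment.LABELED], pair[Treatment.BLANK]
        m13_lab = measurement_mass_13c(lab, c)
        m13_blk = measurement_mass_13c(blk, c)
        rows.append(
            {
                "sample": label,
                "time_days": t,
                "m13c_sample_ug_l": m13_lab,
                "m13c_blank_ug_l": m13_blk,
                "assimilation_rate_ug_l_d": assimilation_rate(m13_lab, m13_blk, t),
                "percent_13c": 100.0 * percent_13c_in_poc(m13_lab, m13_blk, lab.m_poc),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

ISOTOPE_CSV_COLUMNS = [
    "sample",
    "treatment",
    "delta13c_poc_permil",
    "m_poc_ug_per_l",
    "time_days",
]


def read_isotope_table(path: str | Path) -> list[IsotopeMeasurement]:
    """Read an isotope measurement CSV (columns: sample, treatment,
    delta13c_poc_permil, m_poc_ug_per_l, time_days)."""
    df = pd.read_csv(path)
    missing = set(ISOTOPE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            IsotopeMeasurement(
                delta13c_poc=float(row["delta13c_poc_permil"]),
                m_poc=float(row["m_poc_ug_per_l"]),
                t=float(row["time_days"]),
                treatment=Treatment(str(row["treatment"])),
                label=str(row["sample"]),
            )
        )
    return out


def write_isotope_table(measurements: Iterable[IsotopeMeasurement], path: str | Path) -> None:
    """Write measurements in the CSV layout read by :func:`read_isotope_table`."""
    pd.DataFrame(
        [
            {
                "sample": m.label,
                "treatment": Treatment(m.treatment).value,
                "delta13c_poc_permil": m.delta13c_poc,
                "m_poc_ug_per_l": m.m_poc,
                "time_days": m.t,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def write_rate_table(rates: pd.DataFrame, path: str | Path, substrate: str = "") -> None:
    """Write the per-sample rate results TSV."""
    df = rates.copy()
    df.insert(1, "substrate", substrate)
    df[["sample", "substrate", "time_days", "assimilation_rate_ug_l_d", "percent_13c"]].to_csv(
        path, sep="\t", index=False
    )
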