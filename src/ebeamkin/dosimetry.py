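"""Fricke ferrous-sulfate dosimetry and charge-to-dose session calibration.

The Fricke dosimeter infers absorbed dose from the radiation-induced
oxidation Fe2+ -> Fe3+, read out as the optical-density change ``deltaS`` at
304 nm:

    D [Gy] = k * deltaS / (rho * G(Fe3+) * l * epsilon)

with k = 9.65e6 (a coefficient absorbing the unit conversions), solution
density rho (g/cm^3), radiation-chemical yield G(Fe3+) (ions per 100 eV),
optical path l (cm) and extinction coefficient epsilon (L mol^-1 cm^-1).

Session dosimetry is bridged to routine operation through the charge
deposited on the sample support plate: the dose is proportional to the
collected charge, so a zero-intercept regression over logged sessions gives
a Gy-per-nC calibration that predicts doses for new charges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DomainError, FormatError, ValidationError

__all__ = [
    "FrickeParams",
    "IrradiationSession",
    "CalibrationResult",
    "fricke_dose",
    "calibrate_charge_to_dose",
    "predict_dose",
    "read_sessions",
    "write_sessions",
    "load_bundled_sessions",
    "gy_to_kgy",
    "kgy_to_gy",
]


def gy_to_kgy(dose_gy: float) -> float:
    return dose_gy / 1000.0


def kgy_to_gy(dose_kgy: float) -> float:
    return dose_kgy * 1000.0


@dataclass(frozen=True)
class FrickeParams:
    """Constants of the Fricke dose equation plus the measured deltaS.

    Defaults are the standard values for irradiation with accelerated
    electrons up to 10 MeV.
    """

    delta_s: float = 0.0
    k: float = 9.65e6
    rho: float = 1.024  # g/cm^3
    g_fe3: float = 15.6  # ions per 100 eV
    l: float = 1.0  # cm
    epsilon: float = 2160.0  # L / (mol cm)

    def __post_init__(self) -> None:
        if self.delta_s < 0:
            raise ValidationError("deltaS must be >= 0")
        for name in ("k", "rho", "g_fe3", "l", "epsilon"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


def fricke_dose(params: FrickeParams) -> float:
    """Absorbed dose in Gy from the Fricke optical-density change.

    Exactly linear and homogeneous in ``delta_s``.
    """
    denom = params.rho * params.g_fe3 * params.l * params.epsilon
    if denom == 0:
        raise DomainError("zero denominator in Fricke dose equation")
    return params.k * params.delta_s / denom


@dataclass(frozen=True)
class IrradiationSession:
    """One logged irradiation session (averaged over its repeats)."""

    session_id: str
    time_s: float
    charge_nC: float
    dose_Gy: float
    current_nA: float | None = None

    def __post_init__(self) -> None:
        for name in ("time_s", "charge_nC", "dose_Gy"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.current_nA is not None and self.current_nA < 0:
            raise ValidationError("current_nA must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    """Zero-intercept charge-to-dose calibration."""

    slope_gy_per_nc: float
    sessions: tuple[IrradiationSession, ...]
    residuals_gy: np.ndarray = field(repr=False)

    @property
    def rmse_gy(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_gy**2)))

    def predict(self, charge_nc) -> float | np.ndarray:
        return predict_dose(charge_nc, self.slope_gy_per_nc)

    def summary(self) -> str:
        lines = [
            "Charge-to-dose calibration (zero intercept)",
            "=" * 44,
            f"n sessions:      {len(self.sessions)}",
            f"slope (Gy/nC):   {self.slope_gy_per_nc:.6g}",
            f"RMSE (Gy):       {self.rmse_gy:.4g}",
        ]
        for s, r in zip(self.sessions, self.residuals_gy):
            lines.append(
                f"  session {s.session_id}: charge {s.charge_nC:g} nC, "
                f"dose {s.dose_Gy:g} Gy, residual {r:+.3g} Gy"
            )
        return "\n".join(lines)


def calibrate_charge_to_dose(sessions: Sequence[IrradiationSession]) -> CalibrationResult:
    """Least-squares slope of dose on charge through the origin.

    The physics forces D = 0 at Q = 0, hence no intercept:
    slope = sum(Q*D) / sum(Q^2).
    """
    sessions = tuple(sessions)
    q = np.array([s.charge_nC for s in sessions], dtype=float)
    d = np.array([s.dose_Gy for s in sessions], dtype=float)
    if q.size == 0 or not (q > 0).any():
        raise ValidationError("need at least one session with positive charge")
    slope = float(q @ d) / float(q @ q)
    resid = d - slope * q
    return CalibrationResult(slope_gy_per_nc=slope, sessions=sessions, residuals_gy=resid)


def predict_dose(charge_nc, slope_gy_per_nc: float) -> float | np.ndarray:
    """Dose (Gy) predicted for a plate charge (nC): slope * charge."""
    if slope_gy_per_nc <= 0:
        raise DomainError("calibration slope must be positive")
    q = np.asarray(charge_nc, dtype=float)
    if np.any(q < 0):
        raise DomainError("charge must be non-negative")
    out = slope_gy_per_nc * q
    return float(out) if out.ndim == 0 else out


SESSIONS_HEADER = ("session_id", "time_s", "current_nA", "charge_nC", "dose_Gy")


def read_sessions(path) -> tuple[IrradiationSession, ...]:
    """Read session logs from CSV (header: session_id,time_s,current_nA,charge_nC,dose_Gy)."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = tuple(h.strip() for h in next(reader))
        except StopIteration:
            raise FormatError("empty sessions file") from None
        if header != SESSIONS_HEADER:
            raise FormatError(
                f"sessions header must be {','.join(SESSIONS_HEADER)}"
            )
        out = []
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            sid, t, cur, q, d = (c.strip() for c in row)
            out.append(
                IrradiationSession(
                    session_id=sid,
                    time_s=float(t),
                    current_nA=float(cur) if cur else None,
                    charge_nC=float(q),
                    dose_Gy=float(d),
                )
            )
    return tuple(out)


def write_sessions(sessions: Sequence[IrradiationSession], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SESSIONS_HEADER)
        for s in sessions:
            writer.writerow(
                [
                    s.session_id,
                    repr(float(s.time_s)),
                    "" if s.current_nA is None else repr(float(s.current_nA)),
                    repr(float(s.charge_nC)),
                    repr(float(s.dose_Gy)),
                ]
            )


def load_bundled_sessions() -> tuple[IrradiationSession, ...]:
    """The four averaged irradiation sessions shipped with the package."""
    from importlib.resources import as_file, files

    src = files("ebeamkin.data").joinpath("irradiation_sessions.csv")
    with as_file(src) as path:
        return read_sessions(path)
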