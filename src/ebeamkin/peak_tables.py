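"""Data model and I/O for dose-series peak-area observations.

The central container is :class:`PeakTable`, an ordered collection of
:class:`Observation` rows in long format: one LC-MS peak area per
(analyte, absorbed dose, replicate) triplet.  Doses are absorbed doses in
kGy; areas are instrument peak areas in arbitrary units.  "Not detected"
measurements (below the limit of detection) are carried as *censored*
observations with area 0, written to CSV as the literal string ``ND``.

The CSV dialect is fixed: UTF-8, comma separated, header exactly
``dose_kGy,replicate,analyte,mz,rt_min,area``.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ValidationError

__all__ = [
    "Observation",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "normalize_to_dose0",
    "CSV_HEADER",
]

#: Exact header line of the peak-table CSV dialect.
CSV_HEADER = ("dose_kGy", "replicate", "analyte", "mz", "rt_min", "area")

#: Literal used in the ``area`` column for below-LOD ("not detected") rows.
ND = "ND"


@dataclass(frozen=True)
class Observation:
    """One peak-area measurement.

    Parameters
    ----------
    dose_kGy : float
        Absorbed dose in kGy (>= 0).
    replicate : int
        1-based replicate index.
    analyte : str
        Analyte identifier: an antibiotic name (``"tetracycline"``) or the
        accurate-mass label of a degradation product (``"461.1549"``).
    mz : float
        Accurate mass (m/z) of the monitored ion; ``nan`` if unknown.
    rt_min : float or None
        Retention time in minutes; optional.
    area : float
        Non-negative peak area in arbitrary units; 0 when censored.
    censored : bool
        True for "not detected" rows (area below the limit of detection).
    """

    dose_kGy: float
    replicate: int
    analyte: str
    mz: float = math.nan
    rt_min: float | None = None
    area: float = 0.0
    censored: bool = False

    def __post_init__(self) -> None:
        if self.dose_kGy < 0:
            raise ValidationError(f"negative dose {self.dose_kGy!r} for {self.analyte!r}")
        if self.area < 0:
            raise ValidationError(f"negative area {self.area!r} for {self.analyte!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate index must be >= 1, got {self.replicate!r}")
        if self.censored and self.area != 0.0:
            raise ValidationError("censored observations must carry area 0")
        if not isinstance(self.analyte, str) or not self.analyte:
            raise ValidationError("analyte must be a non-empty string")

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.analyte, self.dose_kGy, self.replicate)


@dataclass(frozen=True)
class PeakTable:
    """Ordered collection of :class:`Observation` with free-form metadata.

    Invariant: (analyte, dose, replicate) triplets are unique.
    """

    observations: tuple[Observation, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        seen: set[tuple[str, float, int]] = set()
        for obs in self.observations:
            if obs.key in seen:
                raise ValidationError(
                    f"duplicate (analyte, dose, replicate) triplet {obs.key!r}"
                )
            seen.add(obs.key)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def analytes(self) -> tuple[str, ...]:
        """Analyte identifiers in first-appearance order."""
        out: list[str] = []
        for obs in self.observations:
            if obs.analyte not in out:
                out.append(obs.analyte)
        return tuple(out)

    def subset(self, analyte: str) -> "PeakTable":
        """Rows of a single analyte, preserving order and metadata."""
        rows = tuple(o for o in self.observations if o.analyte == analyte)
        return PeakTable(rows, dict(self.metadata))

    def arrays(
        self, analyte: str, include_censored: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """(dose, area) arrays for one analyte; censored rows contribute 0."""
        rows = [
            o
            for o in self.observations
            if o.analyte == analyte and (include_censored or not o.censored)
        ]
        dose = np.array([o.dose_kGy for o in rows], dtype=float)
        area = np.array([o.area for o in rows], dtype=float)
        return dose, area

    def to_frame(self) -> pd.DataFrame:
        """Long-format :class:`pandas.DataFrame` view of the table."""
        return pd.DataFrame(
            {
                "dose_kGy": [o.dose_kGy for o in self.observations],
                "replicate": [o.replicate for o in self.observations],
                "analyte": [o.analyte for o in self.observations],
                "mz": [o.mz for o in self.observations],
                "rt_min": [o.rt_min for o in self.observations],
                "area": [o.area for o in self.observations],
                "censored": [o.censored for o in self.observations],
            }
        )


def _format_number(x: float) -> str:
    """Format a float for CSV round-tripping at full precision."""
    if x != x:  # nan
        return ""
    return repr(float(x))


def _parse_float(text: str, column: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(
            f"line {line_no}: cannot parse {column}={text!r} as a number"
        ) from exc


def read_peak_table(path) -> PeakTable:
    """Read a peak table from CSV.

    The header must match :data:`CSV_HEADER` exactly.  ``ND`` in the area
    column yields a censored observation with area 0; an empty ``rt_min`` or
    ``mz`` field yields ``None`` / ``nan``.

    Raises
    ------
    FormatError
        Missing/misnamed column or unparsable field.
    ValidationError
        Duplicate (analyte, dose, replicate) triplet, negative dose or area.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_peak_table_stream(fh)


def _read_peak_table_stream(fh) -> PeakTable:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty file: missing header line") from None
    if tuple(h.strip() for h in header) != CSV_HEADER:
        missing = [c for c in CSV_HEADER if c not in header]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        raise FormatError(
            f"header must be exactly {','.join(CSV_HEADER)}, got {','.join(header)}"
        )
    observations: list[Observation] = []
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(CSV_HEADER):
            raise FormatError(
                f"line {line_no}: expected {len(CSV_HEADER)} fields, got {len(row)}"
            )
        dose_s, rep_s, analyte, mz_s, rt_s, area_s = (c.strip() for c in row)
        dose = _parse_float(dose_s, "dose_kGy", line_no)
        try:
            rep = int(rep_s)
        except ValueError as exc:
            raise FormatError(f"line {line_no}: bad replicate {rep_s!r}") from exc
        mz = _parse_float(mz_s, "mz", line_no) if mz_s else math.nan
        rt = _parse_float(rt_s, "rt_min", line_no) if rt_s else None
        if area_s.upper() == ND:
            area, censored = 0.0, True
        else:
            area, censored = _parse_float(area_s, "area", line_no), False
        observations.append(
            Observation(
                dose_kGy=dose,
                replicate=rep,
                analyte=analyte,
                mz=mz,
                rt_min=rt,
                area=area,
                censored=censored,
            )
        )
    return PeakTable(tuple(observations))


def write_peak_table(table: PeakTable, path) -> None:
    """Write a peak table to CSV.

    Floats are written with ``repr`` so a read/write cycle is the identity and
    a write/read/write cycle is byte-identical.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_peak_table_stream(table, fh)


def _write_peak_table_stream(table: PeakTable, fh) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for o in table.observations:
        writer.writerow(
            [
                _format_number(o.dose_kGy),
                str(o.replicate),
                o.analyte,
                _format_number(o.mz),
                "" if o.rt_min is None else _format_number(o.rt_min),
                ND if o.censored else _format_number(o.area),
            ]
        )


def peak_table_to_csv(table: PeakTable) -> str:
    """CSV text of *table* (same dialect as :func:`write_peak_table`)."""
    buf = io.StringIO()
    _write_peak_table_stream(table, buf)
    return buf.getvalue()


def _dose0_mean(table: PeakTable, analyte: str) -> float:
    areas = [
        o.area
        for o in table.observations
        if o.analyte == analyte and o.dose_kGy == 0.0 and not o.censored
    ]
    if not areas:
        raise InsufficientDataError(
            f"analyte {analyte!r} has no non-censored dose-0 observation"
        )
    return float(np.mean(areas))


def normalize_to_dose0(
    table: PeakTable, analyte: str, products: Sequence[str] = ()
) -> PeakTable:
    """Rescale areas so the mean dose-0 area of *analyte* equals 100.

    The same scale factor is applied to the analytes listed in *products*
    (degradation products of the same parent), putting parent and products on
    a common relative-concentration scale ("rel. un.").  Other analytes are
    left untouched.  The operation is idempotent and scale-invariant.
    """
    factor = 100.0 / _dose0_mean(table, analyte)
    targets = {analyte, *products}
    rows = tuple(
        replace(o, area=o.area * factor) if o.analyte in targets else o
        for o in table.observations
    )
    return PeakTable(rows, dict(table.metadata))
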