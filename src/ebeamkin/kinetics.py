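"""Closed-form dose-response kinetics of antibiotic radiolysis.

Under electron-beam irradiation the parent antibiotic decays exponentially
with absorbed dose D (kGy),

    C_a(D) = C0 * exp(-alpha * D),

where ``alpha`` (kGy^-1) is the decomposition rate per unit dose.  A
degradation product accumulates from the parent and is itself destroyed by
the beam; with a threshold dose ``D0`` below which the product is absent,
its concentration is the Heaviside-gated solution of

    dC_p/dD = -beta * C_p + k * C0 * exp(-alpha * D),   C_p(D0) = 0,

namely

    C_p(D) = H(D - D0) * k*C0/(beta-alpha)
             * [exp(-alpha*D) - exp((beta-alpha)*D0) * exp(-beta*D)],

with the removable singularity at ``beta == alpha`` filled by the analytic
limit ``k*C0*(D - D0)*exp(-beta*D)``.  All rates are per kGy; concentrations
are on the relative scale where the unirradiated parent is 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError, ValidationError
from .peak_tables import Observation, PeakTable

__all__ = [
    "AntibioticKinetics",
    "ProductKinetics",
    "ModelRegistry",
    "antibiotic_concentration",
    "product_concentration",
    "removal_percent",
    "product_peak_dose",
    "simulate_noiseless",
    "load_table3_registry",
]


def _check_dose(dose) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DomainError("absorbed dose must be non-negative")
    return d


def _maybe_scalar(arr: np.ndarray, dose) -> float | np.ndarray:
    if np.isscalar(dose) or getattr(dose, "ndim", None) == 0:
        return float(arr)
    return arr


@dataclass(frozen=True)
class AntibioticKinetics:
    """Exponential decay law of a parent antibiotic.

    Parameters
    ----------
    c0 : float
        Initial relative concentration (rel. un.), > 0; 100 on the paper scale.
    alpha : float
        Decomposition rate per kGy, >= 0.
    """

    c0: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValidationError(f"c0 must be > 0, got {self.c0!r}")
        if self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha!r}")

    def concentration(self, dose) -> float | np.ndarray:
        """C_a(D) = C0 exp(-alpha D) at dose D (kGy)."""
        d = _check_dose(dose)
        return _maybe_scalar(self.c0 * np.exp(-self.alpha * d), dose)

    def removal_percent(self, dose) -> float | np.ndarray:
        """Removal 100*(1 - exp(-alpha D)) in percent, in [0, 100)."""
        d = _check_dose(dose)
        return _maybe_scalar(100.0 * -np.expm1(-self.alpha * d), dose)


@dataclass(frozen=True)
class ProductKinetics:
    """Formation/decay law of a degradation product tied to its parent.

    Parameters
    ----------
    beta : float
        Decomposition rate of the product per kGy, >= 0.
    d0 : float
        Threshold dose (kGy) below which the product is absent, >= 0.
    k : float
        Formation coefficient per kGy (fraction of decomposing parent
        molecules converted into this product), >= 0.
    parent : AntibioticKinetics
        Decay law of the parent antibiotic supplying C0 and alpha.
    """

    beta: float
    d0: float
    k: float
    parent: AntibioticKinetics

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta!r}")
        if self.d0 < 0:
            raise ValidationError(f"d0 must be >= 0, got {self.d0!r}")
        if self.k < 0:
            raise ValidationError(f"k must be >= 0, got {self.k!r}")

    def concentration(self, dose) -> float | np.ndarray:
        """C_p(D); exactly 0 for D <= D0, continuous at D0."""
        d = _check_dose(dose)
        a, b = self.parent.alpha, self.beta
        kc0 = self.k * self.parent.c0
        if b == a:
            vals = kc0 * (d - self.d0) * np.exp(-b * d)
        else:
            # exp(-b D) * e^{(b-a)D0} * expm1((b-a)(D-D0)) / (b-a):
            # cancellation-free also for |b - a| << 1.
            vals = (
                kc0
                * np.exp(-b * d + (b - a) * self.d0)
                * np.expm1((b - a) * (d - self.d0))
                / (b - a)
            )
        vals = np.where(d > self.d0, vals, 0.0)
        return _maybe_scalar(vals, dose)

    def peak_dose(self) -> float:
        """Dose D* (kGy) maximizing C_p.

        D* = D0 + ln(beta/alpha)/(beta - alpha) for beta != alpha and
        D* = D0 + 1/alpha in the limit beta -> alpha.  When either rate is
        zero the concentration approaches its supremum only asymptotically
        and ``inf`` is returned.
        """
        a, b = self.parent.alpha, self.beta
        if self.k == 0:
            raise DomainError("peak dose undefined: formation coefficient k is 0")
        if a == 0 and b == 0:
            raise DomainError("peak dose undefined: alpha = beta = 0")
        if a == 0 or b == 0:
            return math.inf
        if a == b:
            return self.d0 + 1.0 / a
        # log1p form: ln(b/a)/(b-a) loses all precision when b-a is at the
        # ULP level, while log1p((b-a)/a) degrades gracefully to 1/a
        return self.d0 + math.log1p((b - a) / a) / (b - a)


# ---------------------------------------------------------------------------
# Functional aliases

def antibiotic_concentration(model: AntibioticKinetics, dose):
    """Parent-antibiotic concentration C_a(D)."""
    return model.concentration(dose)


def product_concentration(model: ProductKinetics, dose):
    """Degradation-product concentration C_p(D)."""
    return model.concentration(dose)


def removal_percent(model: AntibioticKinetics, dose):
    """Percent removal of the parent antibiotic at dose D."""
    return model.removal_percent(dose)


def product_peak_dose(model: ProductKinetics) -> float:
    """Dose at which the product concentration is maximal."""
    return model.peak_dose()


# ---------------------------------------------------------------------------
# Model registry and noiseless simulation

@dataclass
class ModelRegistry:
    """Named kinetic models: parent antibiotics and their products.

    ``annotations`` may carry per-analyte metadata used when emitting peak
    tables (``mz``, ``rt_min``).  Iteration order is insertion order and is
    part of the contract (simulations are deterministic).
    """

    antibiotics: dict[str, AntibioticKinetics] = field(default_factory=dict)
    products: dict[str, ProductKinetics] = field(default_factory=dict)
    parent_of: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, dict] = field(default_factory=dict)

    def analytes(self) -> tuple[str, ...]:
        return tuple(self.antibiotics) + tuple(self.products)

    def model(self, analyte: str) -> AntibioticKinetics | ProductKinetics:
        if analyte in self.antibiotics:
            return self.antibiotics[analyte]
        if analyte in self.products:
            return self.products[analyte]
        raise KeyError(analyte)

    def role(self, analyte: str) -> str:
        if analyte in self.antibiotics:
            return "antibiotic"
        if analyte in self.products:
            return "product"
        raise KeyError(analyte)

    def products_of(self, antibiotic: str) -> tuple[str, ...]:
        return tuple(p for p, a in self.parent_of.items() if a == antibiotic)

    # -- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        entries = []
        for name, m in self.antibiotics.items():
            entry = {"analyte": name, "role": "antibiotic", "C0": m.c0, "alpha": m.alpha}
            entry.update(self.annotations.get(name, {}))
            entries.append(entry)
        for name, m in self.products.items():
            entry = {
                "analyte": name,
                "role": "product",
                "parent": self.parent_of[name],
                "beta": m.beta,
                "D0": m.d0,
                "k": m.k,
            }
            entry.update(self.annotations.get(name, {}))
            entries.append(entry)
        return json.dumps({"analytes": entries}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelRegistry":
        doc = json.loads(text)
        reg = cls()
        deferred: list[dict] = []
        for entry in doc["analytes"]:
            role = entry.get("role")
            name = str(entry["analyte"])
            ann = {
                key: entry[key] for key in ("mz", "rt_min") if key in entry
            }
            if ann:
                reg.annotations[name] = ann
            if role == "antibiotic":
                reg.antibiotics[name] = AntibioticKinetics(
                    c0=float(entry.get("C0", 100.0)), alpha=float(entry["alpha"])
                )
            elif role == "product":
                deferred.append(entry)
            else:
                raise ValidationError(f"unknown role {role!r} for analyte {name!r}")
        for entry in deferred:
            name = str(entry["analyte"])
            parent = str(entry["parent"])
            if parent not in reg.antibiotics:
                raise ValidationError(
                    f"product {name!r} references unknown parent {parent!r}"
                )
            reg.products[name] = ProductKinetics(
                beta=float(entry["beta"]),
                d0=float(entry["D0"]),
                k=float(entry["k"]),
                parent=reg.antibiotics[parent],
            )
            reg.parent_of[name] = parent
        return reg

    @classmethod
    def from_file(cls, path) -> "ModelRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def load_table3_registry() -> ModelRegistry:
    """Bundled registry of fitted dose-response coefficients for the seven
    antibiotics and their fourteen modeled degradation products."""
    from importlib.resources import files

    text = files("ebeamkin.data").joinpath("dose_response_models.json").read_text()
    return ModelRegistry.from_json(text)


def simulate_noiseless(
    registry: ModelRegistry, doses: Sequence[float]
) -> PeakTable:
    """Deterministic forward evaluation of every model on a dose grid.

    One replicate per (analyte, dose); the area equals the model
    concentration exactly.  Used as the ground truth of fitting tests.
    """
    d = _check_dose(np.asarray(list(doses), dtype=float))
    rows: list[Observation] = []
    for name in registry.analytes():
        model = registry.model(name)
        ann = registry.annotations.get(name, {})
        mz = float(ann.get("mz", math.nan))
        rt = ann.get("rt_min")
        for dose in d:
            rows.append(
                Observation(
                    dose_kGy=float(dose),
                    replicate=1,
                    analyte=name,
                    mz=mz,
                    rt_min=None if rt is None else float(rt),
                    area=float(model.concentration(float(dose))),
                )
            )
    return PeakTable(tuple(rows), {"source": "simulate_noiseless"})
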