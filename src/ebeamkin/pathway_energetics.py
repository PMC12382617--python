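"""Degradation-product catalogue, bond-dissociation energetics and marker ranking.

The quantum-chemical energies shipped here (C-H bond-dissociation energies of
tetracycline per carbon position, and per-pathway reaction energies) are
bundled data from DFT calculations; this module implements only the
arithmetic on top of them: reaction energy differences, minimum-energy site
selection, ionization-event bookkeeping along transformation pathways, and
the ranking of degradation products as candidate markers of parent
degradation (fewer ionization events => earlier-appearing, more reliable
marker).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .exceptions import LedgerError

__all__ = [
    "SpeciesRecord",
    "BdeTable",
    "TransformationStep",
    "Pathway",
    "PathwayLedger",
    "MarkerCandidate",
    "reaction_energy",
    "min_energy_site",
    "count_ionization_events",
    "rank_markers",
    "load_pathway_ledger",
    "REACTION_TYPES",
]

#: Recognized radiation-induced transformation types.
REACTION_TYPES = frozenset(
    {
        "hydroxylation",
        "demethylation",
        "deaminomethylation",
        "deamination",
        "dehydroxylation",
        "H-elimination",
        "H-addition",
        "amination",
        "methyl-elimination",
    }
)

#: Detection doses used in the irradiation design (kGy).
_DETECTION_DOSES = {0.1, 1.0, 3.0, 7.0}


@dataclass(frozen=True)
class SpeciesRecord:
    """One identified degradation product.

    ``table_dose_kGy`` and ``text_dose_kGy`` are both kept because the
    catalogued detection dose and the narrative detection dose disagree for
    one product; consumers choose which reading to trust.
    """

    name: str
    formula: str
    mz: float
    rt_min: tuple[float, ...]
    table_dose_kGy: float
    text_dose_kGy: float
    parent: str

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise LedgerError(f"{self.name}: m/z must be > 0")
        for dose in (self.table_dose_kGy, self.text_dose_kGy):
            if dose not in _DETECTION_DOSES:
                raise LedgerError(
                    f"{self.name}: detection dose {dose} not in {sorted(_DETECTION_DOSES)}"
                )


@dataclass(frozen=True)
class BdeTable:
    """C-H bond-dissociation energies per carbon position.

    ``entries`` maps a position label (``"C19"``) to a pair
    ``(dE, dG)`` in kcal/mol: the total-energy and Gibbs-energy change of
    homolytic C-H cleavage.
    """

    entries: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for pos, (de, dg) in self.entries.items():
            if not (math.isfinite(de) and math.isfinite(dg) and de > 0 and dg > 0):
                raise LedgerError(f"non-finite or non-positive energy at {pos}")

    def energy(self, position: str, which: str = "dE") -> float:
        de, dg = self.entries[position]
        return de if which == "dE" else dg

    def min_energy_site(self, which: str = "dE") -> tuple[str, float]:
        """Position with the lowest dissociation energy.

        Ties break deterministically by carbon number (C4 < C5 < ... < C19).
        """
        if not self.entries:
            raise LedgerError("empty bond-dissociation table")
        if which not in ("dE", "dG"):
            raise ValueError("which must be 'dE' or 'dG'")

        def sort_key(pos: str) -> tuple[float, int]:
            return (self.energy(pos, which), int(pos.lstrip("C")))

        best = min(self.entries, key=sort_key)
        return best, self.energy(best, which)


@dataclass(frozen=True)
class TransformationStep:
    """One chemical event along a pathway with its ionization bookkeeping."""

    reaction: str
    site: str | None = None
    delta_e_kcal_mol: float | None = None
    direct_ionizations: int = 0
    indirect_ionizations: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if self.reaction not in REACTION_TYPES:
            raise LedgerError(f"unknown reaction type {self.reaction!r}")
        if self.direct_ionizations < 0 or self.indirect_ionizations < 0:
            raise LedgerError("ionization counts must be >= 0")
        if self.direct_ionizations + self.indirect_ionizations == 0:
            raise LedgerError("each step must carry at least one ionization event")


@dataclass(frozen=True)
class Pathway:
    """Ordered transformation steps from a parent antibiotic to one product."""

    parent: str
    product: str
    steps: tuple[TransformationStep, ...]
    total_energy_change_kcal_mol: float | None = None
    uncertain: bool = False

    def __post_init__(self) -> None:
        if len(self.steps) == 0:
            raise LedgerError(f"pathway to {self.product!r} has no steps")


@dataclass(frozen=True)
class PathwayLedger:
    """Bundled species, energies and pathways plus narrative energy notes."""

    species: Mapping[str, SpeciesRecord]
    bde: BdeTable
    pathways: Mapping[str, Pathway]
    narrative_energies: Mapping[str, float] = field(default_factory=dict)

    def pathway(self, product: str) -> Pathway:
        return self.pathways[product]


def reaction_energy(products_energy: float, reactants_energy: float) -> float:
    """Energy change products - reactants (kcal/mol); negative = released."""
    return products_energy - reactants_energy


def min_energy_site(table: BdeTable, which: str = "dE") -> tuple[str, float]:
    """Position and energy of the weakest C-H bond."""
    return table.min_energy_site(which)


def count_ionization_events(pathway: Pathway) -> tuple[int, int, int]:
    """(direct, indirect, total) ionization events summed over the steps."""
    direct = sum(s.direct_ionizations for s in pathway.steps)
    indirect = sum(s.indirect_ionizations for s in pathway.steps)
    return direct, indirect, direct + indirect


@dataclass(frozen=True)
class MarkerCandidate:
    """A degradation product considered as a marker of parent degradation."""

    species: SpeciesRecord
    pathway: Pathway
    fitted_d0_kGy: float | None = None


def rank_markers(candidates: Iterable[MarkerCandidate]) -> list[MarkerCandidate]:
    """Rank candidate markers: fewest total ionization events first.

    Ties break by detection dose (catalogue value), then by the fitted
    threshold dose; the ordering is total and independent of input order.
    """
    cands = list(candidates)
    if not cands:
        raise LedgerError("need at least one candidate marker")

    def key(c: MarkerCandidate):
        total = count_ionization_events(c.pathway)[2]
        d0 = c.fitted_d0_kGy if c.fitted_d0_kGy is not None else math.inf
        return (total, c.species.table_dose_kGy, d0, c.species.name)

    return sorted(cands, key=key)


# ---------------------------------------------------------------------------
# Ledger I/O


def _load_ledger_doc(doc: dict) -> PathwayLedger:
    try:
        species = {}
        for s in doc["species"]:
            rec = SpeciesRecord(
                name=str(s["name"]),
                formula=str(s["formula"]),
                mz=float(s["mz"]),
                rt_min=tuple(float(x) for x in s["rt_min"]),
                table_dose_kGy=float(s["table_dose_kGy"]),
                text_dose_kGy=float(s["text_dose_kGy"]),
                parent=str(s["parent"]),
            )
            species[rec.name] = rec
        bde = BdeTable(
            {
                pos: (float(v["dE"]), float(v["dG"]))
                for pos, v in doc["bde_table"]["positions"].items()
            }
        )
        pathways = {}
        for p in doc["pathways"]:
            steps = tuple(
                TransformationStep(
                    reaction=str(st["reaction"]),
                    site=st.get("site"),
                    delta_e_kcal_mol=(
                        None
                        if st.get("delta_e_kcal_mol") is None
                        else float(st["delta_e_kcal_mol"])
                    ),
                    direct_ionizations=int(st.get("direct_ionizations", 0)),
                    indirect_ionizations=int(st.get("indirect_ionizations", 0)),
                    note=str(st.get("note", "")),
                )
                for st in p["steps"]
            )
            pw = Pathway(
                parent=str(p["parent"]),
                product=str(p["product"]),
                steps=steps,
                total_energy_change_kcal_mol=(
                    None
                    if p.get("total_energy_change_kcal_mol") is None
                    else float(p["total_energy_change_kcal_mol"])
                ),
                uncertain=bool(p.get("uncertain", False)),
            )
            if pw.product not in species:
                raise LedgerError(f"pathway references unknown species {pw.product!r}")
            pathways[pw.product] = pw
        narrative = {
            k: float(v) for k, v in doc.get("narrative_energies_kcal_mol", {}).items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise LedgerError(f"malformed ledger: {exc}") from exc
    return PathwayLedger(
        species=species, bde=bde, pathways=pathways, narrative_energies=narrative
    )


def load_pathway_ledger(path=None) -> PathwayLedger:
    """Load and validate a pathway/energetics ledger (bundled one by default)."""
    if path is None:
        from importlib.resources import files

        text = files("ebeamkin.data").joinpath("tetracycline_pathway_ledger.json").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _load_ledger_doc(json.loads(text))


def marker_candidates(
    ledger: PathwayLedger,
    fitted_d0: Mapping[str, float] | None = None,
    parent: str | None = None,
) -> list[MarkerCandidate]:
    """Build marker candidates for every ledgered pathway.

    ``fitted_d0`` maps species name (or its m/z label) to a fitted threshold
    dose from :mod:`ebeamkin.fitting`.
    """
    fitted_d0 = fitted_d0 or {}
    out = []
    for name, pw in ledger.pathways.items():
        if parent is not None and pw.parent != parent:
            continue
        sp = ledger.species[name]
        d0 = fitted_d0.get(name, fitted_d0.get(f"{sp.mz:.4f}"))
        out.append(MarkerCandidate(species=sp, pathway=pw, fitted_d0_kGy=d0))
    return out
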