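"""Culture measurement tables, unit conversions, and net-change vectors.

Observations are cumulative net metabolite changes over a 7-day incubation
of a serum-bottle culture: accumulation positive, consumption negative, all
amounts in mmol except cellulose (mg) and residual soluble sugars (umol,
header-declared).  H2S entries are inferred from measured sulfate
consumption (1:1), so the H2S column doubles as sulfate consumed.

The endpoint measurements of all 13 community compositions (mono / bi /
tri / quad cultures, with and without daily sulfate addition) ship as the
bundled fixture ``table1.csv`` as means with standard errors over
triplicates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants

from .stoichiometry import METABOLITES, SPECIES, CommunityModel, assemble_model

__all__ = [
    "ANHYDROGLUCOSE_G_PER_MOL",
    "GLUCOSE_G_PER_MOL",
    "CultureObservation",
    "TimeSeriesObservation",
    "glucose_from_cellulose",
    "headspace_moles",
    "load_observations",
    "write_observations",
    "load_table1",
    "get_culture",
    "net_change_vector",
    "model_for",
]

#: Anhydroglucose monomer mass (g/mol): cellulose mass per glucose equivalent.
ANHYDROGLUCOSE_G_PER_MOL = 162.14
#: Free glucose mass (g/mol); alternative cellulose conversion basis.
GLUCOSE_G_PER_MOL = 180.16

# fixture/CSV dialect: metabolite columns and their units
_MMOL_COLS = {"ch4": "ch4_mmol", "co2": "co2_mmol", "h2": "h2_mmol",
              "h2s": "h2s_mmol", "acetate": "acetate_mmol",
              "lactate": "lactate_mmol"}
_UMOL_COLS = {"glucose": "glucose_umol", "cellobiose": "cellobiose_umol"}
_REQUIRED = (
    ["culture_id", *SPECIES, "sulfate", "replicate", "cellulose_mg"]
    + list(_MMOL_COLS.values()) + list(_UMOL_COLS.values())
)


def glucose_from_cellulose(
    mass_mg: float, monomer_mass: float = ANHYDROGLUCOSE_G_PER_MOL
) -> float:
    """mmol of glucose equivalents in ``mass_mg`` of cellulose.

    The default basis is the anhydroglucose monomer (162.14 g/mol): the
    model's glucose is a proxy for cellulose carbon, so the water taken up
    on hydrolysis is not counted.  Pass ``monomer_mass=GLUCOSE_G_PER_MOL``
    for the free-glucose basis.
    """
    if mass_mg < 0:
        raise ValueError(f"cellulose mass must be >= 0, got {mass_mg}")
    return mass_mg / monomer_mass


def headspace_moles(
    pressure_kpa: float,
    volume_l: float,
    temperature_k: float,
    mole_fraction: float,
) -> float:
    """mmol of one gas in a serum-bottle headspace, by the ideal gas law.

    ``n = x * P V / (R T)`` with P in kPa, V in L, T in K.
    """
    if pressure_kpa <= 0 or volume_l <= 0 or temperature_k <= 0:
        raise ValueError("pressure, volume and temperature must be > 0")
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError(f"mole fraction must be in [0, 1], got {mole_fraction}")
    mol = mole_fraction * pressure_kpa * 1e3 * volume_l * 1e-3 / (
        constants.R * temperature_k
    )
    return mol * 1e3


@dataclass
class CultureObservation:
    """Net metabolite changes (mmol) for one culture (one replicate or mean).

    ``net_change`` is signed: accumulation positive, consumption negative.
    The H2S entry equals sulfate consumed.  ``uncertainty`` carries standard
    errors on the same keys (cellulose SE under ``cellulose``, in mg).
    """

    culture_id: str
    species_present: frozenset[str]
    sulfate_added: bool
    replicate: str
    cellulose_consumed_mg: float
    net_change: dict[str, float]
    uncertainty: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.species_present = frozenset(self.species_present)
        unknown = self.species_present - set(SPECIES)
        if unknown:
            raise ValueError(
                f"{self.culture_id}: unknown species label(s) {sorted(unknown)}"
            )
        if self.cellulose_consumed_mg < 0:
            raise ValueError(f"{self.culture_id}: cellulose consumed < 0")
        for m in ("ch4", "h2s"):
            if self.net_change.get(m, 0.0) < 0:
                raise ValueError(f"{self.culture_id}: {m} accumulation < 0")

    @property
    def sulfate_consumed_mmol(self) -> float:
        """Sulfate consumed, inferred 1:1 from H2S accumulation."""
        return self.net_change.get("h2s", 0.0)


@dataclass
class TimeSeriesObservation:
    """Daily cumulative net changes (mmol) for one culture over days 1..7."""

    culture_id: str
    days: tuple[int, ...]
    cumulative: dict[str, np.ndarray]  # metabolite -> per-day cumulative mmol
    species_present: frozenset[str] = frozenset({"Rc"})
    sulfate_added: bool = False

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        self.cumulative = {m: np.asarray(v, float) for m, v in self.cumulative.items()}
        for m, v in self.cumulative.items():
            if v.shape != (len(self.days),):
                raise ValueError(f"{self.culture_id}: {m} trajectory length mismatch")

    def endpoint(self) -> dict[str, float]:
        return {m: float(v[-1]) for m, v in self.cumulative.items()}


def _parse_row(row: pd.Series, idx) -> CultureObservation:
    try:
        species = frozenset(s for s in SPECIES if int(row[s]) == 1)
        net = {m: float(row[c]) for m, c in _MMOL_COLS.items()}
        net.update({m: float(row[c]) / 1000.0 for m, c in _UMOL_COLS.items()})
        unc = {}
        for m, c in {**_MMOL_COLS, **_UMOL_COLS}.items():
            se_col = f"se_{c}"
            if se_col in row.index and pd.notna(row[se_col]):
                scale = 1000.0 if c.endswith("_umol") else 1.0
                unc[m] = float(row[se_col]) / scale
        if "se_cellulose_mg" in row.index and pd.notna(row["se_cellulose_mg"]):
            unc["cellulose"] = float(row["se_cellulose_mg"])
        return CultureObservation(
            culture_id=str(row["culture_id"]),
            species_present=species,
            sulfate_added=bool(int(row["sulfate"])),
            replicate=str(row["replicate"]),
            cellulose_consumed_mg=float(row["cellulose_mg"]),
            net_change=net,
            uncertainty=unc or None,
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"row {idx}: {exc}") from exc


def load_observations(path: str | Path | io.IOBase) -> list[CultureObservation]:
    """Read culture observations from the documented CSV dialect.

    One row per culture x replicate; umol columns are converted to mmol.
    Raises a descriptive error (with row index) on missing columns,
    non-numeric cells, or unknown species labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"observation table is missing column(s) {missing}")
    if df.empty:
        raise ValueError("observation table contains no rows")
    return [_parse_row(row, idx) for idx, row in df.iterrows()]


def write_observations(
    observations: Sequence[CultureObservation], path: str | Path
) -> None:
    """Write observations back to the CSV dialect read by ``load_observations``.

    Round-trips every numeric field to full precision.
    """
    rows = []
    for o in observations:
        row: dict[str, object] = {"culture_id": o.culture_id}
        for s in SPECIES:
            row[s] = int(s in o.species_present)
        row["sulfate"] = int(o.sulfate_added)
        row["replicate"] = o.replicate
        row["cellulose_mg"] = repr(o.cellulose_consumed_mg)
        for m, c in _MMOL_COLS.items():
            row[c] = repr(o.net_change.get(m, 0.0))
        for m, c in _UMOL_COLS.items():
            row[c] = repr(o.net_change.get(m, 0.0) * 1000.0)
        unc = o.uncertainty or {}
        row["se_cellulose_mg"] = repr(unc.get("cellulose", 0.0))
        for m, c in _MMOL_COLS.items():
            row[f"se_{c}"] = repr(unc.get(m, 0.0))
        for m, c in _UMOL_COLS.items():
            row[f"se_{c}"] = repr(unc.get(m, 0.0) * 1000.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_table1() -> list[CultureObservation]:
    """The bundled endpoint fixture: all 13 cultures as means with SEs."""
    with resources.files("synflux.data").joinpath("table1.csv").open("rb") as fh:
        return load_observations(fh)


def get_culture(
    observations: Sequence[CultureObservation],
    species: str | Sequence[str] | None = None,
    sulfate: bool | None = None,
    culture_id: str | None = None,
) -> CultureObservation:
    """Select one culture by id, or by composition and sulfate flag."""
    hits = list(observations)
    if culture_id is not None:
        hits = [o for o in hits if o.culture_id == culture_id]
    if species is not None:
        wanted = frozenset([species]) if isinstance(species, str) else frozenset(species)
        hits = [o for o in hits if o.species_present == wanted]
    if sulfate is not None:
        hits = [o for o in hits if o.sulfate_added == sulfate]
    if len(hits) != 1:
        raise LookupError(
            f"expected exactly one matching culture, found {len(hits)}"
        )
    return hits[0]


def net_change_vector(
    observation: CultureObservation,
    model: CommunityModel,
    monomer_mass: float = ANHYDROGLUCOSE_G_PER_MOL,
) -> pd.Series:
    """Signed net-change vector (mmol) aligned to ``model.metabolite_order``.

    The glucose entry combines cellulose consumed (as glucose equivalents,
    negative) with residual soluble glucose; the H2S entry is the inferred
    sulfate consumption; sulfate itself is carried as its (negative)
    consumption; CO2 is carried but excluded from the objective by the
    model's fitted mask.
    """
    values = {}
    for m in model.metabolite_order:
        if m == "glucose":
            values[m] = (
                -glucose_from_cellulose(observation.cellulose_consumed_mg, monomer_mass)
                + observation.net_change.get("glucose", 0.0)
            )
        elif m == "sulfate":
            values[m] = -observation.sulfate_consumed_mmol
        else:
            if m not in observation.net_change and METABOLITES[m].fitted:
                raise ValueError(
                    f"{observation.culture_id}: missing fitted metabolite {m!r}"
                )
            values[m] = observation.net_change.get(m, 0.0)
    return pd.Series([values[m] for m in model.metabolite_order],
                     index=list(model.metabolite_order), dtype=float)


def model_for(observation: CultureObservation) -> CommunityModel:
    """Assemble the active community model for one observation."""
    return assemble_model(observation.species_present, observation.sulfate_added)
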