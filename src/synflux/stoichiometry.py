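"""Metabolites, overall reactions, and community model assembly.

The community is a defined four-species anaerobic food web degrading
cellulose to methane: a cellulolytic fermenter (Rc, *Ruminiclostridium
cellulolyticum*), a hydrogenotrophic methanogen (Mh, *Methanospirillum
hungatei*), an acetoclastic methanogen (Mc, *Methanosaeta concilii*), and a
sulfate reducer (Dv, *Desulfovibrio vulgaris*).  Each species is summarised
by one to three *overall* reactions written per mole of limiting substrate
turnover ("extent", mmol).  Water, protons and charge are untracked: they
are unmeasured and cancel out of every fitted observable.

Every reaction conserves carbon atoms and electron equivalents.  Electron
equivalents count electrons released on complete oxidation to CO2, with the
sulfate->sulfide couple carrying 8 (so H2S, like CH4 and acetate, is an
8-electron product).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SPECIES",
    "Metabolite",
    "Reaction",
    "CommunityModel",
    "METABOLITES",
    "FITTED_METABOLITES",
    "default_reaction_set",
    "assemble_model",
    "stoich_matrix",
    "metabolite_table",
    "reactions_to_yaml",
    "reactions_from_yaml",
]

#: The four community members, in registry order.
SPECIES: tuple[str, ...] = ("Rc", "Mh", "Mc", "Dv")


@dataclass(frozen=True)
class Metabolite:
    """A tracked chemical species.

    Parameters
    ----------
    id : str
        Short lowercase name ("glucose", "h2", ...).
    carbon_atoms : int
        Carbon atoms per molecule.
    electron_equivalents : int
        Electrons released on complete oxidation to CO2 (sulfate->sulfide
        carries 8).
    phase : str
        One of ``gas``, ``liquid``, ``solid``.
    fitted : bool
        Whether this metabolite enters the least-squares objective.
    """

    id: str
    carbon_atoms: int
    electron_equivalents: int
    phase: str
    fitted: bool = False

    def __post_init__(self) -> None:
        if self.carbon_atoms < 0 or self.electron_equivalents < 0:
            raise ValueError(f"{self.id}: atom and electron counts must be >= 0")
        if self.phase not in ("gas", "liquid", "solid"):
            raise ValueError(f"{self.id}: unknown phase {self.phase!r}")


def _build_metabolite_registry() -> dict[str, Metabolite]:
    mets = [
        # id, C, e-, phase, fitted
        Metabolite("glucose", 6, 24, "liquid", True),
        Metabolite("acetate", 2, 8, "liquid", True),
        Metabolite("lactate", 3, 12, "liquid", True),
        Metabolite("h2", 0, 2, "gas", True),
        Metabolite("ch4", 1, 8, "gas", True),
        Metabolite("h2s", 0, 8, "gas", True),
        Metabolite("co2", 1, 0, "gas", False),
        Metabolite("sulfate", 0, 0, "liquid", False),
        # ethanol is excluded from the reaction set (negligible carbon flux)
        # but kept for carbon/electron balance accounting
        Metabolite("ethanol", 2, 12, "liquid", False),
        Metabolite("cellobiose", 12, 48, "liquid", False),
    ]
    return {m.id: m for m in mets}


#: Registry of all tracked metabolites, keyed by id.
METABOLITES: dict[str, Metabolite] = _build_metabolite_registry()

#: Metabolites entering the fitting objective, in model row order.
FITTED_METABOLITES: tuple[str, ...] = tuple(
    m.id for m in METABOLITES.values() if m.fitted
)

#: Default row order of community models (fitted first, then carried).
DEFAULT_METABOLITE_ORDER: tuple[str, ...] = (
    "glucose", "acetate", "lactate", "h2", "ch4", "h2s", "co2", "sulfate",
)


@dataclass(frozen=True)
class Reaction:
    """A species-attributed overall reaction.

    ``stoichiometry`` maps metabolite id to the signed coefficient per unit
    extent (negative = consumed).  Conservation of carbon and electron
    equivalents is enforced at construction.
    """

    id: str
    species: str
    stoichiometry: Mapping[str, float]
    requires_sulfate: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"{self.id}: unknown species {self.species!r}")
        unknown = set(self.stoichiometry) - set(METABOLITES)
        if unknown:
            raise ValueError(f"{self.id}: unknown metabolites {sorted(unknown)}")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        c = self.carbon_imbalance()
        e = self.electron_imbalance()
        if abs(c) > 1e-9:
            raise ValueError(f"{self.id}: carbon imbalance {c:+g}")
        if abs(e) > 1e-9:
            raise ValueError(f"{self.id}: electron imbalance {e:+g}")

    def carbon_imbalance(self) -> float:
        return sum(
            coeff * METABOLITES[m].carbon_atoms
            for m, coeff in self.stoichiometry.items()
        )

    def electron_imbalance(self) -> float:
        return sum(
            coeff * METABOLITES[m].electron_equivalents
            for m, coeff in self.stoichiometry.items()
        )


def default_reaction_set() -> list[Reaction]:
    """The seven overall reactions of the full community model.

    Two for Rc (glucose fermentation routes), three for Dv (hydrogenic and
    two sulfidogenic oxidations), one per methanogen.  Coefficients are per
    mole of extent; water and protons untracked.
    """
    return [
        Reaction(
            "rc_lactate_fermentation", "Rc",
            {"glucose": -1, "lactate": 2},
        ),
        Reaction(
            "rc_acetogenesis", "Rc",
            {"glucose": -1, "acetate": 2, "co2": 2, "h2": 4},
        ),
        Reaction(
            "dv_hydrogenic_lactate_oxidation", "Dv",
            {"lactate": -1, "acetate": 1, "co2": 1, "h2": 2},
        ),
        Reaction(
            "dv_sulfidogenic_lactate_oxidation", "Dv",
            {"lactate": -2, "sulfate": -1, "acetate": 2, "co2": 2, "h2s": 1},
            requires_sulfate=True,
        ),
        Reaction(
            "dv_sulfidogenic_h2_oxidation", "Dv",
            {"h2": -4, "sulfate": -1, "h2s": 1},
            requires_sulfate=True,
        ),
        Reaction(
            "mh_hydrogenotrophic_methanogenesis", "Mh",
            {"h2": -4, "co2": -1, "ch4": 1},
        ),
        Reaction(
            "mc_acetoclastic_methanogenesis", "Mc",
            {"acetate": -1, "ch4": 1, "co2": 1},
        ),
    ]


@dataclass(frozen=True)
class CommunityModel:
    """The condition-specific active reaction set.

    Built by :func:`assemble_model`; reactions keep registry order so the
    stoichiometric matrix layout is deterministic.
    """

    reactions: tuple[Reaction, ...]
    species_present: frozenset[str]
    sulfate_present: bool
    metabolite_order: tuple[str, ...] = DEFAULT_METABOLITE_ORDER

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "species_present", frozenset(self.species_present))
        object.__setattr__(self, "metabolite_order", tuple(self.metabolite_order))
        for r in self.reactions:
            if r.species not in self.species_present:
                raise ValueError(
                    f"reaction {r.id} attributed to absent species {r.species}"
                )
            if r.requires_sulfate and not self.sulfate_present:
                raise ValueError(f"reaction {r.id} requires sulfate")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    @property
    def fitted_mask(self) -> pd.Series:
        """Boolean mask over ``metabolite_order``: rows in the objective."""
        return pd.Series(
            [METABOLITES[m].fitted for m in self.metabolite_order],
            index=list(self.metabolite_order),
        )

    @property
    def stoich(self) -> pd.DataFrame:
        return stoich_matrix(self)

    def reactions_of(self, species: str) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.species == species)


def assemble_model(
    species_present: Iterable[str],
    sulfate_present: bool,
    reactions: Sequence[Reaction] | None = None,
    metabolite_order: Sequence[str] = DEFAULT_METABOLITE_ORDER,
) -> CommunityModel:
    """Filter the reaction registry down to the active set for one culture.

    Reactions are dropped when their species is absent or when they require
    sulfate in a sulfate-free condition.  Rc must be present: cellulose is
    the sole carbon source and Rc the only primary fermenter.
    """
    present = frozenset(species_present)
    unknown = present - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}; expected {SPECIES}")
    if "Rc" not in present:
        raise ValueError(
            "no primary fermenter: Rc must be present (cellulose is the only substrate)"
        )
    registry = list(reactions) if reactions is not None else default_reaction_set()
    active = tuple(
        r for r in registry
        if r.species in present and (sulfate_present or not r.requires_sulfate)
    )
    return CommunityModel(active, present, sulfate_present, tuple(metabolite_order))


def stoich_matrix(model: CommunityModel) -> pd.DataFrame:
    """Stoichiometric matrix S (metabolites x reactions) of the model.

    Entry (m, r) is the signed coefficient of metabolite m in reaction r;
    rows follow ``metabolite_order``, columns follow reaction order.
    """
    data = {
        r.id: [r.stoichiometry.get(m, 0.0) for m in model.metabolite_order]
        for r in model.reactions
    }
    return pd.DataFrame(data, index=list(model.metabolite_order), dtype=float)


def metabolite_table() -> pd.DataFrame:
    """Registry as a table (id, carbon, electron equivalents, phase, fitted)."""
    return pd.DataFrame(
        [
            {
                "id": m.id,
                "carbon_atoms": m.carbon_atoms,
                "electron_equivalents": m.electron_equivalents,
                "phase": m.phase,
                "fitted": m.fitted,
            }
            for m in METABOLITES.values()
        ]
    ).set_index("id")


def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "species": r.species,
        "stoichiometry": dict(r.stoichiometry),
        "requires_sulfate": r.requires_sulfate,
    }


def reactions_to_yaml(reactions: Sequence[Reaction], path: str | Path) -> None:
    """Serialize a reaction registry to YAML (or JSON if path ends .json)."""
    payload = [_reaction_to_dict(r) for r in reactions]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def reactions_from_yaml(path: str | Path) -> list[Reaction]:
    """Load a reaction registry from YAML/JSON written by ``reactions_to_yaml``."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [
        Reaction(
            d["id"], d["species"], d["stoichiometry"],
            bool(d.get("requires_sulfate", False)),
        )
        for d in payload
    ]
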