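"""Producer->consumer cross-feeding fluxes from a fitted extent vector.

A fitted flux distribution determines, for every species, how much of each
metabolite it produced and consumed (per-reaction stoichiometry times
extent).  In a well-mixed serum bottle every exchanged intermediate (H2,
acetate, lactate, CO2) passes through a single shared pool, so each
consumer's intake is attributed to producers proportionally to their
production shares — the unique symmetric allocation.  Residual accumulation
(production minus consumption) flows to an ``environment`` sink node;
externally supplied substrates (glucose from cellulose, sulfate from the
medium) flow from ``environment`` to their consumers.  Mass balance then
holds exactly per metabolite.

CO2 edges are model-derived rather than measurement-constrained: CO2 is
carried by the stoichiometry but not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fluxfit import FluxDistributionSet
from .stoichiometry import SPECIES, CommunityModel

__all__ = [
    "ENVIRONMENT",
    "CrossFeedingFlux",
    "species_production_consumption",
    "crossfeed_graph",
    "crossfeed_ranges",
    "edges_to_frame",
    "edges_to_csv",
    "edges_to_dot",
]

#: Name of the shared-pool sink/source node.
ENVIRONMENT = "environment"

_AMOUNT_ATOL = 1e-9


@dataclass(frozen=True)
class CrossFeedingFlux:
    """One producer->consumer transfer of a metabolite (mmol >= 0)."""

    metabolite: str
    producer: str
    consumer: str
    amount: float

    def __post_init__(self) -> None:
        if self.amount < -_AMOUNT_ATOL:
            raise ValueError(f"negative cross-feeding amount {self.amount}")
        if self.producer == self.consumer:
            raise ValueError(f"self-edge {self.producer}->{self.consumer}")


def _extent_array(model: CommunityModel, extents) -> np.ndarray:
    if isinstance(extents, Mapping) or isinstance(extents, pd.Series):
        x = np.array([float(extents[rid]) for rid in model.reaction_ids])
    else:
        x = np.asarray(extents, float)
        if x.shape != (len(model.reactions),):
            raise ValueError("extent vector length does not match the model")
    if np.any(x < -_AMOUNT_ATOL):
        raise ValueError("extents must be >= 0")
    return np.clip(x, 0.0, None)


def species_production_consumption(
    model: CommunityModel, extents
) -> pd.DataFrame:
    """Per-species, per-metabolite produced and consumed mmol.

    Returns a frame indexed by (species, metabolite) with columns
    ``produced`` and ``consumed``; ``produced - consumed`` is the species'
    net contribution to the shared pool.
    """
    x = _extent_array(model, extents)
    rows = []
    present = [s for s in SPECIES if s in model.species_present]
    for s in present:
        prod = {m: 0.0 for m in model.metabolite_order}
        cons = {m: 0.0 for m in model.metabolite_order}
        for r, xr in zip(model.reactions, x):
            if r.species != s:
                continue
            for m, coeff in r.stoichiometry.items():
                if coeff > 0:
                    prod[m] += coeff * xr
                else:
                    cons[m] += -coeff * xr
        for m in model.metabolite_order:
            rows.append({"species": s, "metabolite": m,
                         "produced": prod[m], "consumed": cons[m]})
    return pd.DataFrame(rows).set_index(["species", "metabolite"])


def crossfeed_graph(
    model: CommunityModel,
    extents,
    initial: Mapping[str, float] | None = None,
    atol: float = 1e-9,
) -> list[CrossFeedingFlux]:
    """Edge list of the cross-feeding graph for one flux distribution.

    For each metabolite, consumer intake is attributed to producers in
    proportion to production shares; surplus production goes to the
    ``environment`` node and externally supplied intake comes from it.
    ``initial`` declares metabolite amounts available from the medium
    beyond species production (glucose and sulfate are always treated as
    environment-supplied).  Consumption exceeding production plus initial
    availability raises, flagging an infeasible extent vector.
    """
    table = species_production_consumption(model, extents)
    initial = dict(initial or {})
    # substrates supplied by the bottle rather than by community members
    external_ok = {"glucose", "sulfate"} | set(initial)
    edges: list[CrossFeedingFlux] = []
    for m in model.metabolite_order:
        sub = table.xs(m, level="metabolite")
        # within-species recycling is netted out before pool attribution,
        # so every species is a net producer or a net consumer of m
        net = sub["produced"] - sub["consumed"]
        producers = net[net > atol]
        consumers = -net[net < -atol]
        total_prod = float(producers.sum())
        total_cons = float(consumers.sum())
        if total_prod < atol and total_cons < atol:
            continue
        env_in = max(total_cons - total_prod, 0.0)
        env_out = max(total_prod - total_cons, 0.0)
        if env_in > atol and m not in external_ok:
            available = total_prod + initial.get(m, 0.0)
            if total_cons > available + atol:
                raise ValueError(
                    f"infeasible extent vector: {m} consumption "
                    f"{total_cons:.4g} mmol exceeds production + initial "
                    f"availability {available:.4g} mmol"
                )
            env_in = min(env_in, initial.get(m, 0.0))
        sources = dict(producers.items())
        if env_in > atol:
            sources[ENVIRONMENT] = env_in
        sinks = dict(consumers.items())
        if env_out > atol:
            sinks[ENVIRONMENT] = env_out
        total = sum(sources.values())
        if total <= atol:
            continue
        # proportional bipartite allocation: source j feeds sink k in
        # proportion to both shares; conservation holds per node
        for producer, p in sources.items():
            for consumer, c in sinks.items():
                amount = p * c / total
                if amount > atol and producer != consumer:
                    edges.append(CrossFeedingFlux(m, producer, consumer, amount))
    return edges


def edge_amount(
    edges: Sequence[CrossFeedingFlux], metabolite: str, producer: str, consumer: str
) -> float:
    """Total amount on one (metabolite, producer, consumer) edge."""
    return sum(
        e.amount for e in edges
        if e.metabolite == metabolite and e.producer == producer
        and e.consumer == consumer
    )


def crossfeed_ranges(
    model: CommunityModel, distributions: FluxDistributionSet,
    initial: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-edge amount ranges over an equal-fit distribution set.

    Rows are all edges appearing in any member's graph; columns give the
    best-fit amount and the min/max over the set (0 when an edge is absent
    from a member).
    """
    member_edges = [
        crossfeed_graph(model, d.extents, initial) for d in distributions.distributions
    ]
    keys = sorted(
        {(e.metabolite, e.producer, e.consumer) for edges in member_edges
         for e in edges}
    )
    rows = []
    for key in keys:
        amounts = [edge_amount(edges, *key) for edges in member_edges]
        rows.append({
            "metabolite": key[0], "producer": key[1], "consumer": key[2],
            "best": amounts[0], "min": min(amounts), "max": max(amounts),
        })
    return pd.DataFrame(rows)


def edges_to_frame(edges: Sequence[CrossFeedingFlux]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"metabolite": e.metabolite, "producer": e.producer,
          "consumer": e.consumer, "mmol": e.amount} for e in edges]
    )


def edges_to_csv(edges: Sequence[CrossFeedingFlux], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, index=False)


def edges_to_dot(edges: Sequence[CrossFeedingFlux]) -> str:
    """DOT-format digraph of the cross-feeding edges (amounts as labels)."""
    lines = ["digraph crossfeeding {", "  rankdir=LR;"]
    for e in edges:
        lines.append(
            f'  "{e.producer}" -> "{e.consumer}" '
            f'[label="{e.metabolite} {e.amount:.3f} mmol"];'
        )
    lines.append("}")
    return "\n".join(lines)
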