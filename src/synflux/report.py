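"""End-to-end analysis runs and machine-readable reports.

``run_full_analysis`` ties the stages together for one quad-culture
condition: assemble the condition's community model, fit extents to the
endpoint net changes, scan pathway exclusions for equal-fit distributions,
derive the cross-feeding graph (with per-edge ranges over the equal-fit
set), tabulate the tertiary-synergy comparisons over all 13 cultures, and
compute carbon/electron balance sheets.  Reports regenerate byte-identically
from the same inputs (the pipeline is deterministic; the timestamp is the
only varying field).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import metadata as _im
from pathlib import Path
from typing import Any, Sequence


from .crossfeeding import crossfeed_graph, crossfeed_ranges
from .fluxfit import CommunityFluxModel, FluxDistributionSet
from .observations import (
    CultureObservation,
    get_culture,
    load_observations,
    load_table1,
)
from .synergy import (
    additive_expectation,
    carbon_balance,
    classify_synergy,
    electron_balance,
    phenotype_from_observation,
)

__all__ = ["RunReport", "run_full_analysis", "synergy_table"]

CONDITIONS = ("control", "sulfate")


def _version() -> str:
    try:
        return _im.version("synflux")
    except _im.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _digest(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunReport:
    """Full result set of one condition's analysis; serialises to JSON."""

    condition: str
    input_digest: str | None
    model_description: dict[str, Any]
    fit: dict[str, Any]
    distribution_set: dict[str, Any]
    crossfeeding: list[dict[str, Any]]
    synergy: list[dict[str, Any]]
    balances: dict[str, Any]
    tool_version: str = field(default_factory=_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def synergy_table(observations: Sequence[CultureObservation]) -> list[dict[str, Any]]:
    """The two canonical tertiary-synergy comparisons plus their inputs.

    * methane: quad-culture vs the sum of the two Dv-containing tri-culture
      values (sum-of-values scheme, all in mmol CH4);
    * cellulose: quad-culture vs mono-culture plus the three bi-culture
      increments (sum-of-increments scheme, mg).
    """
    rows = []
    quad = get_culture(observations, species=("Rc", "Mh", "Mc", "Dv"), sulfate=False)
    mono = get_culture(observations, species="Rc", sulfate=False)

    ch4_obs = phenotype_from_observation(quad, "ch4")
    tri_dv = [
        phenotype_from_observation(
            get_culture(observations, species=s, sulfate=False), "ch4")
        for s in (("Rc", "Mc", "Dv"), ("Rc", "Mh", "Dv"))
    ]
    exp = additive_expectation(tri_dv, "sum-of-values")
    res = classify_synergy(ch4_obs, exp)
    rows.append({"phenotype": "ch4", "units": "mmol",
                 "scheme": "sum-of-values", **asdict(res)})

    cel_obs = phenotype_from_observation(quad, "cellulose")
    cel_base = phenotype_from_observation(mono, "cellulose")
    bis = [
        phenotype_from_observation(
            get_culture(observations, species=s, sulfate=False), "cellulose")
        for s in (("Rc", "Mc"), ("Rc", "Mh"), ("Rc", "Dv"))
    ]
    exp = additive_expectation(bis, "sum-of-increments", baseline=cel_base)
    res = classify_synergy(cel_obs, exp)
    rows.append({"phenotype": "cellulose", "units": "mg",
                 "scheme": "sum-of-increments", **asdict(res)})
    return rows


def _distribution_payload(scan: FluxDistributionSet) -> dict[str, Any]:
    return {
        "n_distributions": scan.n_distributions,
        "tolerance": scan.tolerance,
        "scan_log_nrmse": {k: float(v) for k, v in scan.scan_log.items()},
        "extents": [
            {rid: float(v) for rid, v in d.extents.items()}
            for d in scan.distributions
        ],
        "ranges": {
            rid: [float(row["min"]), float(row["max"])]
            for rid, row in scan.ranges.iterrows()
        },
    }


def run_full_analysis(
    obs_path: str | Path | None = None,
    condition: str = "control",
    tolerance: float = 0.05,
    seed: int | None = None,
) -> RunReport:
    """One-command reproduction of the full quad-culture analysis.

    ``condition`` selects the quad-culture row ("control" or "sulfate") of
    the observation table (the bundled 13-culture fixture by default).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    observations = (
        load_table1() if obs_path is None else load_observations(obs_path)
    )
    sulfate = condition == "sulfate"
    quad = get_culture(
        observations, species=("Rc", "Mh", "Mc", "Dv"), sulfate=sulfate
    )
    fm = CommunityFluxModel.from_observation(quad)
    scan = fm.exclusion_scan(tolerance)
    best = scan.best
    edges = crossfeed_graph(fm.community, best.extents)
    ranges = crossfeed_ranges(fm.community, scan)

    cb = carbon_balance(quad)
    eb = electron_balance(quad)

    return RunReport(
        condition=condition,
        input_digest=_digest(obs_path),
        model_description={
            "species": sorted(fm.community.species_present),
            "sulfate_present": fm.community.sulfate_present,
            "n_reactions": len(fm.community.reactions),
            "reactions": list(fm.community.reaction_ids),
            "units": "extents mmol; net changes mmol; cellulose mg",
        },
        fit={
            "extents_mmol": {rid: float(v) for rid, v in best.extents.items()},
            "predicted_mmol": {m: float(v) for m, v in best.predicted.items()},
            "r_squared": float(best.r_squared),
            "nrmse": {k: float(v) for k, v in best.nrmse_all().items()},
            # species-level derived fluxes, units spelled out: sulfate
            # reduction is reported both as mmol sulfate turned over and as
            # mmol H2-equivalents (4 e- pairs per sulfate)
            "derived_fluxes": {
                "dv_sulfate_reduced_mmol_sulfate": float(
                    best.extents.get("dv_sulfidogenic_lactate_oxidation", 0.0)
                    + best.extents.get("dv_sulfidogenic_h2_oxidation", 0.0)
                ),
                "dv_sulfate_reduced_mmol_h2_equivalents": float(4 * (
                    best.extents.get("dv_sulfidogenic_lactate_oxidation", 0.0)
                    + best.extents.get("dv_sulfidogenic_h2_oxidation", 0.0)
                )),
                "dv_h2_consumed_mmol": float(
                    4 * best.extents.get("dv_sulfidogenic_h2_oxidation", 0.0)
                ),
                "dv_h2_produced_mmol": float(
                    2 * best.extents.get("dv_hydrogenic_lactate_oxidation", 0.0)
                ),
                "rc_h2_produced_mmol": float(
                    4 * best.extents.get("rc_acetogenesis", 0.0)
                ),
            },
        },
        distribution_set=_distribution_payload(scan),
        crossfeeding=ranges.to_dict(orient="records"),
        synergy=synergy_table(observations),
        balances={
            "carbon_mmol": cb.table["carbon_mmol"].to_dict(),
            "carbon_fraction": cb.table["fraction"].to_dict(),
            "electron_mmol": eb.table["electron_mmol"].to_dict(),
            "electron_fraction": eb.table["fraction"].to_dict(),
        },
        seed=seed,
    )
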