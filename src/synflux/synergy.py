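"""Higher-order (tertiary) synergy comparisons and carbon/electron balances.

A community phenotype (methane produced, cellulose degraded, ...) shows a
*tertiary* interaction when the multi-species culture deviates from the
additive expectation built from its sub-communities: positive synergy when
the whole exceeds the sum, negative when it falls short, additive when the
deviation is within propagated measurement uncertainty.  Two additive
schemes are used for the two canonical comparisons:

* ``sum-of-values`` — the expectation is the plain sum of the subset
  phenotype values (methane of the quad-culture vs the sum of the two
  Dv-containing tri-cultures);
* ``sum-of-increments`` — the expectation is the baseline plus the sum of
  each subset's increment over the baseline (cellulose degraded by the
  quad-culture vs mono-culture plus the three bi-culture increments).

Balances express the fermentation product spectrum in carbon mmol and
electron mmol (electron equivalents on the complete-oxidation basis, with
sulfate->sulfide carrying 8), as fractions of the recovered product totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .observations import CultureObservation
from .stoichiometry import METABOLITES

__all__ = [
    "PhenotypeValue",
    "SynergyResult",
    "BalanceSheet",
    "increment",
    "additive_expectation",
    "classify_synergy",
    "carbon_balance",
    "electron_balance",
    "inferred_h2_production",
    "phenotype_from_observation",
]

#: Products included in the balance sheets, in display order.
BALANCE_PRODUCTS = ("ch4", "co2", "acetate", "lactate", "ethanol", "h2", "h2s")


@dataclass(frozen=True)
class PhenotypeValue:
    """One phenotype measurement: value with standard error and units."""

    phenotype: str
    units: str
    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class SynergyResult:
    """Observed vs additive-expectation comparison of one phenotype."""

    phenotype: str
    units: str
    observed: float
    expectation: float
    difference: float
    relative_difference_pct: float | None
    classification: str  # positive | negative | additive
    uncertainty: float


def _check_same(a: PhenotypeValue, b: PhenotypeValue) -> None:
    if a.phenotype != b.phenotype or a.units != b.units:
        raise ValueError(
            f"phenotype/unit mismatch: {a.phenotype} [{a.units}] vs "
            f"{b.phenotype} [{b.units}]"
        )


def increment(culture: PhenotypeValue, baseline: PhenotypeValue) -> PhenotypeValue:
    """culture - baseline, with root-sum-square uncertainty propagation."""
    _check_same(culture, baseline)
    return PhenotypeValue(
        culture.phenotype, culture.units,
        culture.value - baseline.value,
        math.hypot(culture.se, baseline.se),
    )


def additive_expectation(
    values: Sequence[PhenotypeValue],
    scheme: str = "sum-of-values",
    baseline: PhenotypeValue | None = None,
) -> PhenotypeValue:
    """Additive (no-interaction) expectation of a phenotype.

    ``sum-of-values`` sums the subset values directly; ``sum-of-increments``
    adds each subset's increment over ``baseline`` to the baseline value.
    Uncertainties combine by root-sum-square, treating cultures as
    independent.
    """
    values = list(values)
    if not values:
        raise ValueError("additive expectation of an empty input")
    for v in values[1:]:
        _check_same(values[0], v)
    if scheme == "sum-of-values":
        return PhenotypeValue(
            values[0].phenotype, values[0].units,
            sum(v.value for v in values),
            math.sqrt(sum(v.se**2 for v in values)),
        )
    if scheme == "sum-of-increments":
        if baseline is None:
            raise ValueError("sum-of-increments requires a baseline")
        _check_same(values[0], baseline)
        incs = [increment(v, baseline) for v in values]
        return PhenotypeValue(
            baseline.phenotype, baseline.units,
            baseline.value + sum(i.value for i in incs),
            math.sqrt(baseline.se**2 + sum(i.se**2 for i in incs)),
        )
    raise ValueError(
        f"unknown scheme {scheme!r}; expected 'sum-of-values' or 'sum-of-increments'"
    )


def classify_synergy(
    observed: PhenotypeValue,
    expectation: PhenotypeValue,
    uncertainty: float | None = None,
) -> SynergyResult:
    """Compare an observed phenotype with its additive expectation.

    Positive (negative) synergy when the observed value exceeds (falls
    short of) the expectation by more than the propagated uncertainty of
    the difference; additive otherwise.
    """
    _check_same(observed, expectation)
    diff = observed.value - expectation.value
    unc = uncertainty if uncertainty is not None \
        else math.hypot(observed.se, expectation.se)
    if abs(diff) <= unc:
        cls = "additive"
    else:
        cls = "positive" if diff > 0 else "negative"
    rel = None if expectation.value == 0 else 100.0 * diff / expectation.value
    return SynergyResult(
        phenotype=observed.phenotype, units=observed.units,
        observed=observed.value, expectation=expectation.value,
        difference=diff, relative_difference_pct=rel,
        classification=cls, uncertainty=unc,
    )


@dataclass
class BalanceSheet:
    """Per-product carbon or electron mmol with fractions of the total."""

    currency: str  # "carbon" | "electron"
    table: pd.DataFrame  # index product; columns amount_mmol, <currency>_mmol, fraction

    @property
    def total(self) -> float:
        return float(self.table.iloc[:, 1].sum())

    def fraction(self, product: str) -> float:
        return float(self.table.loc[product, "fraction"])


def _balance(
    amounts: Mapping[str, float], currency: str, per_molecule: str
) -> BalanceSheet:
    rows = {}
    for product, amount in amounts.items():
        if product not in METABOLITES:
            raise KeyError(f"unknown product {product!r}")
        if amount < 0:
            continue  # consumed species are not fermentation products
        weight = getattr(METABOLITES[product], per_molecule)
        rows[product] = {"amount_mmol": amount,
                         f"{currency}_mmol": amount * weight}
    table = pd.DataFrame(rows).T
    if table.empty:
        table = pd.DataFrame(columns=["amount_mmol", f"{currency}_mmol"], dtype=float)
    if table.empty or table[f"{currency}_mmol"].sum() == 0:
        table["fraction"] = np.nan  # fractions undefined for an empty sheet
    else:
        table["fraction"] = (
            table[f"{currency}_mmol"] / table[f"{currency}_mmol"].sum()
        )
    return BalanceSheet(currency, table)


def _product_amounts(
    observation: CultureObservation, products: Sequence[str]
) -> dict[str, float]:
    return {
        p: observation.net_change.get(p, 0.0)
        for p in products
        if p in observation.net_change
    }


def carbon_balance(
    observation: CultureObservation | Mapping[str, float],
    products: Sequence[str] = BALANCE_PRODUCTS,
) -> BalanceSheet:
    """Carbon mmol per fermentation product, with fractions of the total."""
    amounts = observation if isinstance(observation, Mapping) \
        else _product_amounts(observation, products)
    return _balance(amounts, "carbon", "carbon_atoms")


def electron_balance(
    observation: CultureObservation | Mapping[str, float],
    products: Sequence[str] = BALANCE_PRODUCTS,
) -> BalanceSheet:
    """Electron mmol per fermentation product (complete-oxidation basis)."""
    amounts = observation if isinstance(observation, Mapping) \
        else _product_amounts(observation, products)
    return _balance(amounts, "electron", "electron_equivalents")


def inferred_h2_production(observation: CultureObservation) -> float:
    """Total H2 produced, mmol: accumulation plus 4 x CH4 (methanogen intake).

    In a culture whose only H2 sink is hydrogenotrophic methanogenesis,
    the fermenters must have produced the accumulated H2 plus four H2 per
    CH4 formed.
    """
    return (
        observation.net_change.get("h2", 0.0)
        + 4.0 * observation.net_change.get("ch4", 0.0)
    )


_PHENOTYPE_UNITS = {"cellulose": "mg"}


def phenotype_from_observation(
    observation: CultureObservation, phenotype: str
) -> PhenotypeValue:
    """Extract a phenotype (metabolite accumulation or cellulose) with SE."""
    unc = observation.uncertainty or {}
    if phenotype == "cellulose":
        return PhenotypeValue(
            "cellulose", "mg", observation.cellulose_consumed_mg,
            unc.get("cellulose", 0.0),
        )
    if phenotype not in observation.net_change:
        raise KeyError(
            f"{observation.culture_id}: no phenotype {phenotype!r}"
        )
    return PhenotypeValue(
        phenotype, _PHENOTYPE_UNITS.get(phenotype, "mmol"),
        observation.net_change[phenotype], unc.get(phenotype, 0.0),
    )
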