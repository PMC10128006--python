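"""Non-negative reaction-extent fitting and flux-degeneracy analysis.

The estimator solves

    min_x || W (S x - y) ||_2   subject to   x >= 0,  x_r = 0 for excluded r

where S is the community stoichiometric matrix, y the observed net-change
vector, and W a diagonal weight matrix (1 on fitted metabolites, 0 on
carried ones by default).  The problem is convex and solved with the
Lawson-Hanson active-set NNLS algorithm, which returns a *vertex* (basic
feasible) solution.  That choice matters: several reaction routes in this
community are stoichiometrically redundant (fermenting glucose to lactate
and then oxidising the lactate hydrogenically is observationally identical
to direct hydrogenic acetogenesis), so the least-squares optimum can be a
face of the feasible cone rather than a point.  Vertex solutions make the
leave-one-out exclusion scan enumerate the distinct corners of that face —
the "equal-fit flux distributions" — instead of arbitrary interior points.

Flux variability over the equal-fit set is quantified two ways:

* :meth:`CommunityFluxModel.exclusion_scan` — refit with each reaction
  forced to zero, keep refits whose NRMSE is within a relative tolerance of
  the best, and report per-reaction extent ranges over the distinct
  solutions (the discrete, publication-style view);
* :meth:`CommunityFluxModel.flux_range` — minimise/maximise an extent (or a
  linear functional of extents, e.g. a species' H2 production) subject to
  the residual norm staying within a slack of the optimum (the continuous,
  flux-variability-analysis view; an LP on the optimal face at zero slack).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize, nnls

from .observations import CultureObservation, model_for, net_change_vector
from .stoichiometry import CommunityModel

__all__ = [
    "CommunityFluxModel",
    "FluxFitResults",
    "FluxDistributionSet",
    "NRMSE_CONVENTIONS",
    "fit_extents",
    "fit_daily_extents",
    "goodness_of_fit",
    "exclusion_scan",
    "flux_range",
]

#: Supported NRMSE normalizations: RMSE divided by ...
NRMSE_CONVENTIONS = ("mean", "range", "max", "sd")


def _nrmse_denominator(y: np.ndarray, convention: str) -> float:
    if convention == "mean":
        return float(np.mean(np.abs(y)))
    if convention == "range":
        return float(np.max(y) - np.min(y))
    if convention == "max":
        return float(np.max(np.abs(y)))
    if convention == "sd":
        return float(np.std(y))
    raise ValueError(
        f"unknown NRMSE convention {convention!r}; expected one of {NRMSE_CONVENTIONS}"
    )


@dataclass
class FluxFitResults:
    """Fitted non-negative reaction extents and fit diagnostics.

    Attributes
    ----------
    extents : pd.Series
        Reaction extents (mmol), >= 0, indexed by reaction id.
    predicted : pd.Series
        S x over the full metabolite order.
    residuals : pd.Series
        predicted - observed on fitted (weight > 0) metabolites.
    r_squared, nrmse : float
        Goodness of fit over fitted metabolites; ``nrmse`` uses the model's
        default convention (RMSE / mean |y|).
    excluded : frozenset
        Reaction ids forced to zero in this fit.
    """

    model: "CommunityFluxModel"
    extents: pd.Series
    predicted: pd.Series
    residuals: pd.Series
    r_squared: float
    nrmse: float
    excluded: frozenset[str] = frozenset()

    @property
    def residual_norm(self) -> float:
        """Weighted residual 2-norm (the minimised objective)."""
        return float(np.linalg.norm(self.residuals.to_numpy()))

    def nrmse_under(self, convention: str) -> float:
        """NRMSE under an alternative normalization convention."""
        r = self.residuals.to_numpy()
        y = self.model.y_fitted.to_numpy()
        denom = _nrmse_denominator(y, convention)
        if denom == 0:
            raise ZeroDivisionError("degenerate observations: zero NRMSE denominator")
        return float(np.sqrt(np.mean(r**2)) / denom)

    def nrmse_all(self) -> dict[str, float]:
        return {c: self.nrmse_under(c) for c in NRMSE_CONVENTIONS}

    def nrmse_per_metabolite(self, convention: str = "mean") -> pd.Series:
        """Per-metabolite normalized absolute error (one endpoint each).

        The pooled ``nrmse`` is the default view; the mean of this series
        is the per-metabolite-averaged variant.
        """
        y = self.model.y_fitted.to_numpy()
        denom = _nrmse_denominator(y, convention)
        if denom == 0:
            raise ZeroDivisionError("degenerate observations: zero NRMSE denominator")
        return self.residuals.abs() / denom

    def species_extents(self, species: str) -> pd.Series:
        ids = [r.id for r in self.model.community.reactions if r.species == species]
        return self.extents.loc[ids]

    def summary(self) -> str:
        """Human-readable report of the fit."""
        lines = []
        com = self.model.community
        cond = "sulfate" if com.sulfate_present else "control"
        lines.append("Community flux fit")
        lines.append("=" * 66)
        lines.append(
            f"species: {'+'.join(sorted(com.species_present))}   condition: {cond}"
            f"   reactions: {len(com.reactions)}"
        )
        if self.excluded:
            lines.append(f"excluded: {', '.join(sorted(self.excluded))}")
        lines.append(f"R^2 = {self.r_squared:.4f}   NRMSE (mean-|y|) = {self.nrmse:.4f}")
        lines.append("-" * 66)
        lines.append(f"{'reaction':<38}{'species':<9}{'extent (mmol)':>14}")
        for r in com.reactions:
            lines.append(f"{r.id:<38}{r.species:<9}{self.extents[r.id]:>14.4f}")
        lines.append("-" * 66)
        lines.append(f"{'metabolite':<12}{'observed':>12}{'predicted':>12}{'fitted':>9}")
        fitted = self.model.weights > 0
        for m in com.metabolite_order:
            flag = "yes" if fitted[m] else "no"
            lines.append(
                f"{m:<12}{self.model.y[m]:>12.4f}{self.predicted[m]:>12.4f}{flag:>9}"
            )
        return "\n".join(lines)


@dataclass
class FluxDistributionSet:
    """Equal-fit flux distributions found by the exclusion scan.

    ``best`` is the unconstrained fit; ``alternatives`` the distinct
    leave-one-out refits with statistically equal fit; ``ranges`` brackets
    every member's extents; ``scan_log`` records each excluded-model NRMSE.
    """

    best: FluxFitResults
    alternatives: list[FluxFitResults]
    ranges: pd.DataFrame  # index: reaction id, columns: min, max
    scan_log: dict[str, float]
    tolerance: float

    @property
    def n_distributions(self) -> int:
        return 1 + len(self.alternatives)

    @property
    def distributions(self) -> list[FluxFitResults]:
        return [self.best, *self.alternatives]

    def extent_range(self, reaction_id: str) -> tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["min"]), float(row["max"])

    def summary(self) -> str:
        lines = [
            "Exclusion scan (leave-one-out refits)",
            "=" * 66,
            f"equal-fit tolerance: {self.tolerance:.0%} relative NRMSE",
            f"distinct equal-fit flux distributions: {self.n_distributions}",
            "-" * 66,
            f"{'excluded reaction':<38}{'NRMSE':>10}{'equal fit':>12}",
        ]
        best = self.best.nrmse
        for rid, nr in self.scan_log.items():
            eq = "yes" if nr <= (1.0 + self.tolerance) * best else "no"
            lines.append(f"{rid:<38}{nr:>10.4f}{eq:>12}")
        lines.append("-" * 66)
        lines.append(f"{'reaction':<38}{'min':>10}{'max':>10}")
        for rid, row in self.ranges.iterrows():
            lines.append(f"{rid:<38}{row['min']:>10.4f}{row['max']:>10.4f}")
        return "\n".join(lines)


class CommunityFluxModel:
    """Least-squares model of one culture's net metabolite changes.

    Parameters
    ----------
    community : CommunityModel
        The condition-specific active reaction set.
    y : pd.Series or array-like
        Net-change vector aligned to ``community.metabolite_order`` (mmol).
    weights : array-like, optional
        Per-metabolite weights in the objective.  Default: 1 on fitted
        metabolites (glucose, acetate, lactate, H2, CH4, H2S), 0 on carried
        ones (CO2, sulfate).  Pass ``1/se**2``-style weights for
        uncertainty weighting.

    Examples
    --------
    >>> from synflux import load_table1, get_culture, CommunityFluxModel
    >>> obs = get_culture(load_table1(), culture_id="quad")
    >>> res = CommunityFluxModel.from_observation(obs).fit()
    >>> res.r_squared > 0.9
    True
    """

    def __init__(
        self,
        community: CommunityModel,
        y,
        weights=None,
    ) -> None:
        self.community = community
        order = list(community.metabolite_order)
        y = pd.Series(np.asarray(y, float), index=order) if not isinstance(y, pd.Series) \
            else y.reindex(order)
        if y.isna().any():
            raise ValueError("y does not cover the model's metabolite order")
        if len(y) != len(order):
            raise ValueError("y length does not match the metabolite order")
        self.y = y.astype(float)
        if weights is None:
            w = community.fitted_mask.astype(float).to_numpy()
        else:
            w = np.asarray(weights, float)
            if w.shape != (len(order),):
                raise ValueError("weights length does not match the metabolite order")
            if np.any(w < 0):
                raise ValueError("weights must be >= 0")
        if not np.any(w > 0):
            raise ValueError("all-zero weight vector: nothing to fit")
        self.weights = pd.Series(w, index=order)
        self.S = community.stoich  # metabolites x reactions

    # ------------------------------------------------------------------ #
    @classmethod
    def from_observation(
        cls,
        observation: CultureObservation,
        community: CommunityModel | None = None,
        weights=None,
        se_weighting: bool = False,
        monomer_mass: float | None = None,
    ) -> "CommunityFluxModel":
        """Build the model from a culture observation.

        The community model is assembled from the observation's species set
        and sulfate flag unless given explicitly.  With ``se_weighting``,
        fitted metabolites are weighted by 1/SE^2 (normalised to mean 1).
        """
        community = community if community is not None else model_for(observation)
        kwargs = {} if monomer_mass is None else {"monomer_mass": monomer_mass}
        y = net_change_vector(observation, community, **kwargs)
        if se_weighting:
            if not observation.uncertainty:
                raise ValueError("se_weighting requested but observation has no SEs")
            w = community.fitted_mask.astype(float).copy()
            for m in community.metabolite_order:
                if w[m] > 0:
                    se = observation.uncertainty.get(m, np.nan)
                    w[m] = 1.0 / se**2 if se and np.isfinite(se) else 0.0
            pos = w[w > 0]
            w[w > 0] = pos / pos.mean()
            weights = w.to_numpy()
        return cls(community, y, weights)

    # ------------------------------------------------------------------ #
    @property
    def y_fitted(self) -> pd.Series:
        """Observed values on fitted (weight > 0) metabolites."""
        return self.y[self.weights > 0]

    def _check_excluded(self, excluded: Iterable[str]) -> frozenset[str]:
        excluded = frozenset(excluded)
        unknown = excluded - set(self.community.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reaction id(s) in excluded: {sorted(unknown)}")
        return excluded

    def fit(self, excluded: Iterable[str] = ()) -> FluxFitResults:
        """Solve the weighted NNLS problem; deterministic (no randomness)."""
        excluded = self._check_excluded(excluded)
        rids = list(self.community.reaction_ids)
        keep = [i for i, rid in enumerate(rids) if rid not in excluded]
        w = self.weights.to_numpy()
        rows = w > 0
        sw = np.sqrt(w[rows])
        A = self.S.to_numpy()[np.ix_(rows, keep)] * sw[:, None]
        b = self.y.to_numpy()[rows] * sw
        if A.size:
            x_sub, _ = nnls(A, b)
        else:
            x_sub = np.zeros(0)
        x = np.zeros(len(rids))
        x[keep] = x_sub
        extents = pd.Series(x, index=rids)
        predicted = pd.Series(self.S.to_numpy() @ x,
                              index=list(self.community.metabolite_order))
        residuals = (predicted - self.y)[self.weights > 0]
        r2, nr = goodness_of_fit_arrays(
            predicted[self.weights > 0].to_numpy(), self.y_fitted.to_numpy()
        )
        return FluxFitResults(
            model=self, extents=extents, predicted=predicted, residuals=residuals,
            r_squared=r2, nrmse=nr, excluded=excluded,
        )

    # ------------------------------------------------------------------ #
    def exclusion_scan(
        self,
        tolerance: float = 0.05,
        excluded: Iterable[str] = (),
        dedup_atol: float = 1e-6,
    ) -> FluxDistributionSet:
        """Leave-one-out degeneracy scan.

        Each reaction is sequentially forced to zero and the model refit; a
        refit is an alternative equal-fit distribution when its NRMSE is
        within ``tolerance`` (relative) of the best fit and its extent
        vector differs from solutions already found.
        """
        if len(self.community.reactions) < 1:
            raise ValueError("model has no reactions")
        base_excluded = self._check_excluded(excluded)
        best = self.fit(base_excluded)
        limit = (1.0 + tolerance) * best.nrmse
        scan_log: dict[str, float] = {}
        solutions = [best]
        for rid in self.community.reaction_ids:
            if rid in base_excluded:
                continue
            alt = self.fit(base_excluded | {rid})
            scan_log[rid] = alt.nrmse
            if alt.nrmse <= limit + 1e-12:
                if not any(
                    np.allclose(alt.extents.to_numpy(), s.extents.to_numpy(),
                                atol=dedup_atol)
                    for s in solutions
                ):
                    solutions.append(alt)
        members = np.vstack([s.extents.to_numpy() for s in solutions])
        ranges = pd.DataFrame(
            {"min": members.min(axis=0), "max": members.max(axis=0)},
            index=list(self.community.reaction_ids),
        )
        return FluxDistributionSet(
            best=best, alternatives=solutions[1:], ranges=ranges,
            scan_log=scan_log, tolerance=tolerance,
        )

    # ------------------------------------------------------------------ #
    def flux_range(
        self,
        reaction: str | Mapping[str, float],
        slack: float = 0.0,
        excluded: Iterable[str] = (),
    ) -> tuple[float, float]:
        """Min/max of an extent (or linear functional) over near-optimal fits.

        ``reaction`` is a reaction id, or a mapping reaction id -> weight
        defining a linear functional c.x (e.g. H2 produced by Dv =
        2 x extent of hydrogenic lactate oxidation).  The feasible set is
        ``{x >= 0 : ||W(Sx - y)|| <= (1 + slack) * best}``; at zero slack
        this is the optimal face, characterised exactly by the normal
        equations of the projection, and the bounds are solved as two LPs.
        """
        if slack < 0:
            raise ValueError(f"slack must be >= 0, got {slack}")
        excluded = self._check_excluded(excluded)
        rids = list(self.community.reaction_ids)
        if isinstance(reaction, str):
            if reaction not in rids:
                raise KeyError(f"unknown reaction id {reaction!r}")
            c = np.array([1.0 if rid == reaction else 0.0 for rid in rids])
        else:
            unknown = set(reaction) - set(rids)
            if unknown:
                raise KeyError(f"unknown reaction id(s) {sorted(unknown)}")
            c = np.array([float(reaction.get(rid, 0.0)) for rid in rids])
        best = self.fit(excluded)
        w = self.weights.to_numpy()
        rows = w > 0
        sw = np.sqrt(w[rows])
        A = self.S.to_numpy()[rows] * sw[:, None]  # weighted S, all reactions
        b = self.y.to_numpy()[rows] * sw
        x_best = best.extents.to_numpy()
        bounds = [(0.0, 0.0) if rid in excluded else (0.0, None) for rid in rids]

        if slack == 0.0:
            # optimal face: A x equals the unique projection A x_best
            target = A @ x_best
            eps = 1e-9 * max(1.0, float(np.linalg.norm(target)))
            A_ub = np.vstack([A, -A])
            b_ub = np.concatenate([target + eps, -target + eps])
            out = []
            for sign in (+1.0, -1.0):
                res = linprog(sign * c, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
                              method="highs")
                if not res.success:
                    raise RuntimeError(f"flux range LP failed: {res.message}")
                out.append(sign * res.fun)
            lo, hi = out
            return float(min(lo, hi)), float(max(lo, hi))

        # positive slack: linear objective under one quadratic constraint
        radius = ((1.0 + slack) * max(best.residual_norm, 1e-12)) ** 2
        cons = [
            {"type": "ineq",
             "fun": lambda x: radius - float(np.sum((A @ x - b) ** 2)),
             "jac": lambda x: -2.0 * A.T @ (A @ x - b)},
        ]
        out = []
        for sign in (+1.0, -1.0):
            res = minimize(
                lambda x, s=sign: s * float(c @ x),
                x_best,
                jac=lambda x, s=sign: s * c,
                bounds=bounds, constraints=cons, method="SLSQP",
                options={"maxiter": 500, "ftol": 1e-12},
            )
            if not res.success:
                raise RuntimeError(f"flux range optimisation failed: {res.message}")
            out.append(sign * res.fun)
        lo, hi = out
        return float(min(lo, hi)), float(max(lo, hi))

    def species_flux_range(
        self,
        species: str,
        metabolite: str,
        direction: str = "production",
        slack: float = 0.0,
        excluded: Iterable[str] = (),
    ) -> tuple[float, float]:
        """Range of a species' production or consumption of one metabolite.

        Wraps :meth:`flux_range` with the functional
        ``sum_r max(+/-coeff_rm, 0) * x_r`` over the species' reactions.
        """
        if direction not in ("production", "consumption"):
            raise ValueError("direction must be 'production' or 'consumption'")
        sgn = 1.0 if direction == "production" else -1.0
        functional = {
            r.id: max(sgn * r.stoichiometry.get(metabolite, 0.0), 0.0)
            for r in self.community.reactions
            if r.species == species
        }
        if not any(functional.values()):
            return (0.0, 0.0)
        return self.flux_range(functional, slack=slack, excluded=excluded)


# ---------------------------------------------------------------------- #
# functional wrappers (spec-facing surface)

def goodness_of_fit_arrays(predicted: np.ndarray, y: np.ndarray,
                           convention: str = "mean") -> tuple[float, float]:
    if y.size < 2:
        raise ValueError("R^2 undefined with fewer than 2 fitted metabolites")
    resid = predicted - y
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    denom = _nrmse_denominator(y, convention)
    nrmse = float(np.sqrt(np.mean(resid**2)) / denom) if denom > 0 else np.inf
    return r2, nrmse


def fit_extents(
    model: CommunityModel, y, weights=None, excluded: Iterable[str] = ()
) -> FluxFitResults:
    """Fit non-negative reaction extents to a net-change vector."""
    return CommunityFluxModel(model, y, weights).fit(excluded)


def goodness_of_fit(fit: FluxFitResults, y=None,
                    convention: str = "mean") -> tuple[float, float]:
    """(R^2, NRMSE) of a fit over its fitted metabolites."""
    if y is not None:
        y = pd.Series(np.asarray(y, float),
                      index=list(fit.model.community.metabolite_order)) \
            if not isinstance(y, pd.Series) else y
        yf = y[fit.model.weights > 0].to_numpy()
    else:
        yf = fit.model.y_fitted.to_numpy()
    pf = fit.predicted[fit.model.weights > 0].to_numpy()
    return goodness_of_fit_arrays(pf, yf, convention)


def fit_daily_extents(
    model: CommunityModel, timeseries, weights=None
) -> tuple[pd.Series, pd.DataFrame]:
    """Fit extents to daily-cumulative trajectories, day increment by day.

    Each day's net-change increment is fitted independently (non-negative
    daily extents, so cumulative extents are monotone); the totals are the
    summed daily extents.  Returns ``(total_extents, per_day)`` with
    ``per_day`` indexed by day.  This is the optional daily mode; endpoint
    fitting is the default throughout the package.
    """
    days = list(timeseries.days)
    order = list(model.metabolite_order)
    rows = []
    prev = np.zeros(len(order))
    for d_idx, day in enumerate(days):
        y_d = np.array([
            timeseries.cumulative[m][d_idx] if m in timeseries.cumulative
            else 0.0
            for m in order
        ])
        fit = CommunityFluxModel(model, y_d - prev, weights).fit()
        rows.append(fit.extents.rename(day))
        prev = y_d
    per_day = pd.DataFrame(rows)
    per_day.index.name = "day"
    return per_day.sum(axis=0), per_day


def exclusion_scan(
    model: CommunityModel, y, tolerance: float = 0.05, weights=None
) -> FluxDistributionSet:
    """Leave-one-out degeneracy scan of a community model against data."""
    return CommunityFluxModel(model, y, weights).exclusion_scan(tolerance)


def flux_range(
    model: CommunityModel, y, reaction, slack: float = 0.0, weights=None
) -> tuple[float, float]:
    """Min/max extent of ``reaction`` over near-optimal non-negative fits."""
    return CommunityFluxModel(model, y, weights).flux_range(reaction, slack)
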