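"""Extent estimation, fit statistics, degeneracy scan, and flux ranges."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from synflux.fluxfit import (
    CommunityFluxModel,
    exclusion_scan,
    fit_extents,
    flux_range,
    goodness_of_fit,
)
from synflux.stoichiometry import (
    CommunityModel,
    Reaction,
    assemble_model,
    default_reaction_set,
)

QUAD = ("Rc", "Mh", "Mc", "Dv")


def grid_search_objective(S, y, w, lo, hi, step):
    """Independent brute-force oracle: best ||W(Sx - y)|| over an extent grid.

    Enumerates every extent combination at the given resolution (only
    usable for <= 3 reactions); returns (best objective, best x).
    """
    axes = [
        np.arange(max(l, 0.0), h + step / 2, step)
        for l, h in zip(np.atleast_1d(lo), np.atleast_1d(hi))
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)  # points x reactions
    R = (X @ S.T - y) * np.sqrt(w)
    obj = np.einsum("ij,ij->i", R, R)
    k = int(np.argmin(obj))
    return float(np.sqrt(obj[k])), X[k]


def refined_grid_search(S, y, w, grid_max, step=0.001, coarse=0.01):
    """Exhaustive coarse grid, then exhaustive 0.001-step box around the
    coarse optimum — still independent of the NNLS path."""
    n = S.shape[1]
    _, x0 = grid_search_objective(
        S, y, w, np.zeros(n), np.full(n, grid_max), coarse
    )
    return grid_search_objective(S, y, w, x0 - 1.5 * coarse, x0 + 1.5 * coarse, step)


def rc_model():
    """Two-reaction mono-culture model (identifiable)."""
    return assemble_model(("Rc",), sulfate_present=False)


def toy_y(model, extents):
    x = np.array([extents.get(rid, 0.0) for rid in model.reaction_ids])
    return pd.Series(model.stoich.to_numpy() @ x,
                     index=list(model.metabolite_order))


class TestFitExtents:
    def test_exact_data_recovery_control_model(self, control_community):
        x_star = {"rc_lactate_fermentation": 0.3, "rc_acetogenesis": 0.7,
                  "dv_hydrogenic_lactate_oxidation": 0.1}
        y = toy_y(control_community, x_star)
        fit = fit_extents(control_community, y)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(
            fit.predicted.to_numpy(), y.to_numpy(), atol=1e-9
        )

    def test_matches_grid_search_oracle(self):
        """NNLS equals exhaustive search at 0.001 mmol resolution."""
        model = rc_model()
        x_star = {"rc_lactate_fermentation": 0.25, "rc_acetogenesis": 0.4}
        y = toy_y(model, x_star)
        fit = fit_extents(model, y)
        w = model.fitted_mask.astype(float).to_numpy()
        obj_oracle, x_oracle = grid_search_objective(
            model.stoich.to_numpy(), y.to_numpy(), w,
            np.zeros(2), np.full(2, 0.8), 0.001,
        )
        assert fit.residual_norm <= obj_oracle + 1e-9
        np.testing.assert_allclose(
            fit.extents.to_numpy(), x_oracle, atol=1.5e-3
        )

    def test_matches_grid_search_oracle_noisy_three_reactions(self):
        """Oracle equivalence holds off the exact-solution manifold too."""
        model = assemble_model(("Rc", "Mh"), sulfate_present=False)
        rng = np.random.default_rng(7)
        y = toy_y(model, {"rc_lactate_fermentation": 0.2,
                          "rc_acetogenesis": 0.5,
                          "mh_hydrogenotrophic_methanogenesis": 0.3})
        y += pd.Series(rng.normal(0, 0.05, len(y)), index=y.index)
        fit = fit_extents(model, y)
        w = model.fitted_mask.astype(float).to_numpy()
        obj_oracle, _ = refined_grid_search(
            model.stoich.to_numpy(), y.to_numpy(), w, grid_max=0.9
        )
        # grid resolution limits the oracle, so NNLS may only be better
        assert fit.residual_norm <= obj_oracle + 1e-9
        assert obj_oracle - fit.residual_norm < 5e-3

    def test_quad_control_fit_quality(self, control_model):
        fit = control_model.fit()
        assert fit.r_squared > 0.9
        assert abs(fit.predicted["ch4"] - 1.37) < 3 * fit.nrmse

    def test_excluded_reactions_stay_zero(self, sulfate_model):
        fit = sulfate_model.fit(excluded={"dv_sulfidogenic_h2_oxidation"})
        assert fit.extents["dv_sulfidogenic_h2_oxidation"] == 0.0
        assert fit.excluded == {"dv_sulfidogenic_h2_oxidation"}

    def test_dimension_mismatch_rejected(self, control_community):
        with pytest.raises(ValueError):
            CommunityFluxModel(control_community, np.zeros(3))
        with pytest.raises(ValueError, match="all-zero"):
            CommunityFluxModel(
                control_community,
                np.zeros(len(control_community.metabolite_order)),
                weights=np.zeros(len(control_community.metabolite_order)),
            )

    def test_monotone_fit_quality(self, quad_control):
        """Adding a reaction column never worsens the best residual norm."""
        small = assemble_model(("Rc", "Mh", "Mc"), False)
        big = assemble_model(QUAD, False)
        fit_small = CommunityFluxModel.from_observation(
            quad_control, community=small).fit()
        fit_big = CommunityFluxModel.from_observation(
            quad_control, community=big).fit()
        assert fit_big.residual_norm <= fit_small.residual_norm + 1e-12

    @given(c=st.floats(0.1, 50.0, allow_nan=False))
    def test_scale_equivariance(self, c, control_community):
        y = toy_y(control_community, {"rc_acetogenesis": 0.6,
                                      "mc_acetoclastic_methanogenesis": 0.4})
        y = y + pd.Series(0.05, index=y.index)  # make it a non-exact target
        f1 = fit_extents(control_community, y)
        f2 = fit_extents(control_community, c * y)
        np.testing.assert_allclose(
            f2.extents.to_numpy(), c * f1.extents.to_numpy(), rtol=1e-6, atol=1e-9
        )
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-9)
        assert f2.nrmse == pytest.approx(f1.nrmse, rel=1e-6)


class TestGoodnessOfFit:
    def test_perfect_fit(self, control_community):
        y = toy_y(control_community, {"rc_acetogenesis": 0.5})
        fit = fit_extents(control_community, y)
        r2, nrmse = goodness_of_fit(fit)
        assert r2 == pytest.approx(1.0)
        assert nrmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction_gives_zero_r2(self, control_community):
        """Predicting the mean of y is the R^2 = 0 reference."""
        from synflux.fluxfit import goodness_of_fit_arrays

        y = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = goodness_of_fit_arrays(np.full(4, y.mean()), y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_single_point_r2_undefined(self):
        from synflux.fluxfit import goodness_of_fit_arrays

        with pytest.raises(ValueError, match="fewer than 2"):
            goodness_of_fit_arrays(np.array([1.0]), np.array([1.0]))

    def test_convention_menu(self, control_model):
        fit = control_model.fit()
        all_n = fit.nrmse_all()
        assert set(all_n) == {"mean", "range", "max", "sd"}
        assert fit.nrmse == pytest.approx(all_n["mean"])
        assert all(v >= 0 for v in all_n.values())
        with pytest.raises(ValueError, match="convention"):
            fit.nrmse_under("median")


def duplicated_column_model():
    """Two Dv reactions with identical net stoichiometry (pure degeneracy)."""
    twin_a = Reaction("dv_route_a", "Dv",
                      {"lactate": -1, "acetate": 1, "co2": 1, "h2": 2})
    twin_b = Reaction("dv_route_b", "Dv",
                      {"lactate": -1, "acetate": 1, "co2": 1, "h2": 2})
    feeder = Reaction("rc_lactate_fermentation", "Rc",
                      {"glucose": -1, "lactate": 2})
    return CommunityModel((feeder, twin_a, twin_b), frozenset({"Rc", "Dv"}), False)


class TestExclusionScan:
    def test_identifiable_model_single_distribution(self):
        model = assemble_model(("Rc", "Mh", "Mc"), False)
        y = toy_y(model, {"rc_lactate_fermentation": 0.2,
                          "rc_acetogenesis": 0.6,
                          "mh_hydrogenotrophic_methanogenesis": 0.4,
                          "mc_acetoclastic_methanogenesis": 0.3})
        scan = exclusion_scan(model, y, tolerance=0.05)
        assert scan.n_distributions == 1
        assert (scan.ranges["min"] == scan.ranges["max"]).all()

    def test_redundant_routes_detected_in_control_fit(self, control_model):
        """Lactate-route + Dv oxidation duplicates direct acetogenesis."""
        scan = control_model.exclusion_scan(0.05)
        assert scan.n_distributions >= 2
        lo, hi = scan.extent_range("rc_acetogenesis")
        assert hi - lo > 0.5  # poorly constrained Rc/Dv split

    def test_quad_distribution_counts(self, control_model, sulfate_model):
        """Equal-fit distribution counts for the two quad conditions."""
        assert control_model.exclusion_scan(0.05).n_distributions == 2
        assert sulfate_model.exclusion_scan(0.05).n_distributions == 3

    def test_invariants(self, sulfate_model):
        scan = sulfate_model.exclusion_scan(0.05)
        best = scan.best.nrmse
        for alt in scan.alternatives:
            assert best <= alt.nrmse + 1e-12
            for rid in scan.ranges.index:
                lo, hi = scan.extent_range(rid)
                assert lo - 1e-9 <= alt.extents[rid] <= hi + 1e-9


class TestFluxRange:
    def test_identifiable_point_range(self):
        model = rc_model()
        y = toy_y(model, {"rc_lactate_fermentation": 0.3, "rc_acetogenesis": 0.5})
        lo, hi = flux_range(model, y, "rc_acetogenesis", slack=0.0)
        assert lo == pytest.approx(hi, abs=1e-6)
        assert lo == pytest.approx(0.5, abs=1e-6)

    def test_duplicated_columns_full_range(self):
        """Two identical columns with total extent c give [0, c] each."""
        model = duplicated_column_model()
        y = toy_y(model, {"rc_lactate_fermentation": 0.5,
                          "dv_route_a": 0.4, "dv_route_b": 0.3})
        for rid in ("dv_route_a", "dv_route_b"):
            lo, hi = flux_range(model, y, rid, slack=0.0)
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(0.7, abs=1e-6)

    def test_metabolite_level_wrapper(self, sulfate_model):
        lo, hi = sulfate_model.species_flux_range("Dv", "h2", "consumption")
        # 4 x sulfidogenic H2-oxidation extent, free along the degenerate face
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(4 * 0.8167, abs=2e-3)

    def test_positive_slack_widens_range(self, control_model):
        lo0, hi0 = control_model.flux_range("mc_acetoclastic_methanogenesis", 0.0)
        lo1, hi1 = control_model.flux_range("mc_acetoclastic_methanogenesis", 0.10)
        assert lo1 <= lo0 + 1e-9 and hi1 >= hi0 - 1e-9
        assert hi1 - lo1 > hi0 - lo0

    def test_negative_slack_rejected(self, control_model):
        with pytest.raises(ValueError, match="slack"):
            control_model.flux_range("rc_acetogenesis", slack=-0.1)


def test_conservation_of_fitted_predictions(control_model, sulfate_model):
    """Predictions inherit zero carbon/electron imbalance from the reactions."""
    from synflux.stoichiometry import METABOLITES

    for fm in (control_model, sulfate_model):
        fit = fm.fit()
        order = fm.community.metabolite_order
        carbons = np.array([METABOLITES[m].carbon_atoms for m in order])
        electrons = np.array([METABOLITES[m].electron_equivalents for m in order])
        assert abs(carbons @ fit.predicted.to_numpy()) < 1e-9
        assert abs(electrons @ fit.predicted.to_numpy()) < 1e-9


def test_summary_mentions_key_fields(control_model):
    text = control_model.fit().summary()
    assert "R^2" in text and "NRMSE" in text and "mc_acetoclastic" in text
    scan_text = control_model.exclusion_scan().summary()
    assert "equal-fit" in scan_text
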