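"""Logistic GLM and donor bootstrap: oracles, invariants, error contracts."""

import numpy as np
import pandas as pd
import pytest

from cytoboot import (
    CellTable,
    ModelSpec,
    bootstrap_glm,
    effects_table_export,
    fit_logistic,
    generate_study,
    standardize_markers,
    two_group_nk_config,
)
from cytoboot.glm import MarkerEffectTable, ScalingRecord, effects_table_import
from cytoboot.errors import AnalysisError, ContractError, ModelError
from cytoboot.pipeline import arcsinh_transform


def _arcsinh_table(values, channels, donor="d", group="control"):
    meta = pd.DataFrame({"donor": donor, "group": group}, index=range(len(values)))
    return CellTable(
        values=np.asarray(values, dtype=float),
        channel_names=channels,
        cell_meta=meta,
        scale_state="arcsinh",
        cofactor=5.0,
    )


class TestStandardize:
    def test_hand_computed_population_sd(self):
        t = _arcsinh_table([[1.0], [2.0], [3.0]], ["M"])
        X, rec = standardize_markers(t, ["M"])
        expected = (np.array([1.0, 2.0, 3.0]) - 2.0) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(X[:, 0], expected)
        np.testing.assert_allclose(X[:, 0], [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_constant_marker_dropped_and_recorded(self):
        t = _arcsinh_table([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], ["M", "K"])
        with pytest.warns(UserWarning, match="K"):
            X, rec = standardize_markers(t, ["M", "K"])
        assert rec.dropped == ["K"]
        assert rec.markers == ["M"]
        assert X.shape == (3, 1)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = _arcsinh_table(rng.normal(2, 1, (40, 2)), ["A", "B"])
        X1, _ = standardize_markers(t, ["A", "B"])
        t2 = _arcsinh_table(X1, ["A", "B"])
        X2, _ = standardize_markers(t2, ["A", "B"])
        np.testing.assert_allclose(X1, X2, atol=1e-12)

    def test_all_constant_is_model_error(self):
        t = _arcsinh_table([[1.0], [1.0]], ["M"])
        with pytest.warns(UserWarning), pytest.raises(ModelError):
            standardize_markers(t, ["M"])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = np.ones((4, 1))
        y = np.array([1.0, 1.0, 1.0, 0.0])
        fit = fit_logistic(X, y)
        assert fit.intercept == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.converged

    def test_symmetric_predictor_gives_zero(self):
        X = np.column_stack([np.ones(4), [1.0, 2.0, 1.0, 2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        eta = 0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], ref.params, atol=1e-6
        )

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            fit_logistic(np.ones((3, 1)), np.ones(3))

    def test_separation_flagged(self):
        X = np.column_stack([np.ones(6), [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = fit_logistic(X, y)
        assert fit.separated
        assert np.all(np.isfinite(fit.coefficients))


def _study(effects=None, seed=0, n_donors=5, cells=200, n_markers=4):
    cfg = two_group_nk_config(
        n_donors_per_group=n_donors, cells_per_donor=cells, n_markers=n_markers,
        tau=0.3, effects=effects, seed=seed,
    )
    tables, design, _ = generate_study(cfg)
    return {d: arcsinh_transform(t) for d, t in tables.items()}, design, cfg


class TestBootstrapGLM:
    def test_no_bootstrap_gives_point_estimates_only(self):
        tables, design, cfg = _study()
        spec = ModelSpec(contrast=("control", "pregnant"), markers=cfg.marker_names, n_boot=0)
        met = bootstrap_glm(tables, design, spec)
        assert met.table["ci_low"].isna().all()
        assert not met.table["significant"].any()
        assert (met.table["direction"] == "none").all()

    def test_percentile_ci_brackets_bootstrap_median(self):
        tables, design, cfg = _study(effects={"CD38": 0.4}, seed=3)
        spec = ModelSpec(contrast=("control", "pregnant"), markers=cfg.marker_names, n_boot=100, seed=4)
        met = bootstrap_glm(tables, design, spec)
        med = np.median(met.bootstrap_estimates, axis=0)
        assert (met.table["ci_low"].to_numpy() <= med + 1e-12).all()
        assert (med <= met.table["ci_high"].to_numpy() + 1e-12).all()

    def test_estimates_invariant_to_donor_and_cell_order(self):
        tables, design, cfg = _study(seed=9)
        spec = ModelSpec(contrast=("control", "pregnant"), markers=cfg.marker_names, n_boot=25, seed=2)
        met1 = bootstrap_glm(tables, design, spec)
        # reversed donor insertion order, cells reversed within each donor
        rev = {}
        for d in reversed(list(tables)):
            t = tables[d]
            rev[d] = t.subset(np.arange(t.n_cells)[::-1])
        met2 = bootstrap_glm(rev, design, spec)
        # donor order is bitwise-irrelevant; cell order within a donor only
        # perturbs float summation order, so agreement is to rounding error
        np.testing.assert_allclose(met1.table["estimate"], met2.table["estimate"], atol=1e-10)
        np.testing.assert_allclose(met1.table["ci_low"], met2.table["ci_low"], atol=1e-10)

    def test_paired_contrast_uses_complete_pairs(self):
        from cytoboot import default_config

        cfg = default_config(n_donors_per_group=4, cells_per_donor=300, seed=6)
        tables, design, _ = generate_study(cfg)
        tables = {d: arcsinh_transform(t) for d, t in tables.items()}
        markers = ["CD38", "NKp46", "NKG2D"]
        spec = ModelSpec(
            contrast=("postpartum", "pregnant"), markers=markers, n_boot=30, seed=1, paired=True
        )
        met = bootstrap_glm(tables, design, spec)
        assert set(met.table.index) == set(markers)

    def test_donor_heterogeneity_widens_cis(self):
        """Larger tau -> wider bootstrap intervals (the point of the donor bootstrap)."""
        def width(tau):
            cfg = two_group_nk_config(
                n_donors_per_group=8, cells_per_donor=300, n_markers=3, tau=tau, seed=12
            )
            tables, design, _ = generate_study(cfg)
            tables = {d: arcsinh_transform(t) for d, t in tables.items()}
            spec = ModelSpec(contrast=("control", "pregnant"), markers=cfg.marker_names, n_boot=100, seed=13)
            met = bootstrap_glm(tables, design, spec)
            return float((met.table["ci_high"] - met.table["ci_low"]).mean())

        assert width(1.0) > width(0.05)

    def test_too_many_separated_resamples_aborts(self):
        """A marker constant within donors but split by group separates every refit."""
        rng = np.random.default_rng(0)
        tables = {}
        rows = []
        for i, (donor, group) in enumerate(
            [("c1", "control"), ("c2", "control"), ("p1", "pregnant"), ("p2", "pregnant")]
        ):
            sep = 0.0 if group == "control" else 1.0
            vals = np.column_stack([np.full(30, sep), rng.normal(2, 0.5, 30)])
            tables[donor] = _arcsinh_table(vals, ["SEP", "OK"], donor=donor, group=group)
            rows.append((donor, group))
        design_df = pd.DataFrame(
            {"group": [g for _, g in rows], "cohort": "discovery"},
            index=pd.Index([d for d, _ in rows], name="donor"),
        )
        from cytoboot import StudyDesign

        design = StudyDesign(donors=design_df)
        spec = ModelSpec(contrast=("control", "pregnant"), markers=["SEP", "OK"], n_boot=20, seed=0)
        with pytest.raises(AnalysisError):
            bootstrap_glm(tables, design, spec)

    def test_missing_group_rejected(self):
        tables, design, cfg = _study()
        spec = ModelSpec(contrast=("control", "postpartum"), markers=cfg.marker_names)
        with pytest.raises(ContractError):
            bootstrap_glm(tables, design, spec)


class TestEffectsExport:
    def _met(self, estimates, markers):
        n = len(markers)
        table = pd.DataFrame(
            {
                "estimate": estimates,
                "ci_low": np.array(estimates) - 0.1,
                "ci_high": np.array(estimates) + 0.1,
                "significant": [False] * n,
                "direction": ["none"] * n,
            },
            index=pd.Index(markers, name="marker"),
        )
        return MarkerEffectTable(
            table=table, contrast=("control", "pregnant"), n_boot=0, ci_level=0.95,
            seed=0, n_failed_resamples=0,
            scaling=ScalingRecord(markers=markers, means=np.zeros(n), sds=np.ones(n)),
        )

    def test_ascending_order(self):
        out = effects_table_export(self._met([0.4, -0.2], ["A", "B"]))
        assert list(out["marker"]) == ["B", "A"]

    def test_ties_alphabetical(self):
        out = effects_table_export(self._met([0.3, 0.3, -0.1], ["Z", "A", "M"]))
        assert list(out["marker"]) == ["M", "A", "Z"]

    def test_round_trip(self, tmp_path):
        met = self._met([0.4, -0.2], ["A", "B"])
        out = effects_table_export(met)
        path = tmp_path / "effects.csv"
        out.to_csv(path, index=False)
        back = effects_table_import(pd.read_csv(path), ("control", "pregnant"))
        merged = back.table.loc[met.table.index]
        pd.testing.assert_frame_equal(merged, met.table, check_dtype=False)
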