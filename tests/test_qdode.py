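import numpy as np
import pytest

from idopnet.expression import ExpressionIndex, ExpressionMatrix
from idopnet.qdode import QdODE, fit_null, fit_qdode, parabolic_weights


def make_matrix(vals, ei=None):
    m, n = np.asarray(vals).shape
    x = ExpressionMatrix([f"g{j+1}" for j in range(m)],
                         [f"s{i+1}" for i in range(n)], np.asarray(vals, float))
    e = None if ei is None else ExpressionIndex(ei=np.asarray(ei, float),
                                                order=np.arange(n))
    return x, e


class TestWeights:
    def test_parabolic_weights_satisfy_boundary_conditions(self):
        e = np.linspace(1, 10, 20)
        z = parabolic_weights(e)
        assert z[0] == 0 and z[-1] == 0
        assert (z >= 0).all() and z.max() == pytest.approx(1.0)


class TestSingleTargetFits:
    def test_constant_rate_gene_recovers_linear_mean(self):
        # dM/dE = c  =>  mu(E) = init + c (E - E1); noiseless
        ei = np.linspace(1, 10, 30)
        y = 4.0 + 0.8 * (ei - 1.0)
        x, e = make_matrix([y], ei)
        res = QdODE(x, ei=e).fit_null()
        dec = res.decompose("g1", ei)
        np.testing.assert_allclose(dec["total"], y, atol=1e-6)
        assert res.models["g1"].init_value == pytest.approx(4.0, abs=1e-6)

    def test_null_model_has_no_regulators_anywhere(self, planted_single_edge):
        res = fit_null(planted_single_edge.x, ei=planted_single_edge.ei)
        assert all(len(m.regulators) == 0 for m in res.models.values())

    def test_full_loglik_at_least_null_loglik(self, planted_single_edge):
        sim = planted_single_edge
        engine = QdODE(sim.x, ei=sim.ei)
        full = engine.fit(n_lambda=6)
        null = engine.fit_null()
        assert full.loglik >= null.loglik - 1e-9
        assert full.lr_against(null) >= -1e-9


class TestSelection:
    def test_planted_driver_detected(self, planted_single_edge):
        sim = planted_single_edge
        sel = QdODE(sim.x, ei=sim.ei).select_regulators(
            "g1", n_lambda=8, criterion="ebic", ebic_gamma=1.0
        )
        assert "g2" in sel.regulators

    def test_regulators_exclude_target(self, planted_single_edge):
        sim = planted_single_edge
        engine = QdODE(sim.x, ei=sim.ei)
        for g in engine.gene_ids:
            sel = engine.select_regulators(g, n_lambda=5)
            assert g not in sel.regulators

    def test_active_count_non_increasing_in_lambda(self, planted_single_edge):
        sim = planted_single_edge
        sel = QdODE(sim.x, ei=sim.ei).select_regulators("g1", n_lambda=10)
        trace = sel.criterion_trace.sort_values("lambda", ascending=False)
        counts = trace["n_active"].to_numpy()
        assert all(a <= b for a, b in zip(counts[:-1], counts[1:]))

    def test_max_regulators_cap_enforced(self, planted_single_edge):
        sim = planted_single_edge
        sel = QdODE(sim.x, ei=sim.ei).select_regulators(
            "g1", n_lambda=8, max_regulators=1
        )
        assert len(sel.regulators) <= 1

    def test_unknown_target_raises(self, planted_single_edge):
        with pytest.raises(KeyError):
            QdODE(planted_single_edge.x, ei=planted_single_edge.ei).select_regulators("nope")


class TestDecomposition:
    @pytest.fixture
    def fitted(self, planted_single_edge):
        sim = planted_single_edge
        engine = QdODE(sim.x, ei=sim.ei)
        return engine.fit(n_lambda=8, criterion="ebic", ebic_gamma=1.0)

    def test_additivity_on_fitted_system(self, fitted):
        grid = np.linspace(fitted.e[0], fitted.e[-1], 50)
        for g in fitted.gene_ids:
            dec = fitted.decompose(g, grid)
            dep = dec[[c for c in dec if c.startswith("dep:")]].sum(axis=1)
            recon = fitted.models[g].init_value + dec["independent"] + dep
            np.testing.assert_allclose(dec["total"], recon, atol=1e-8)

    def test_no_regulator_target_has_zero_dependent_part(self, fitted):
        for g in fitted.gene_ids:
            if not fitted.models[g].regulators:
                dec = fitted.decompose(g, np.linspace(fitted.e[0], fitted.e[-1], 10))
                dep_cols = [c for c in dec if c.startswith("dep:")]
                assert not dep_cols
                break
        else:
            pytest.skip("every target acquired regulators")

    def test_components_vanish_at_first_ei(self, fitted):
        e1 = fitted.e[0]
        for g in fitted.gene_ids:
            assert fitted.independent_amount(g, [e1])[0] == pytest.approx(0.0, abs=1e-9)
            for r in fitted.models[g].regulators:
                assert fitted.dependent_amount(g, r, [e1])[0] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_grid_requires_flag(self, fitted):
        with pytest.raises(ValueError, match="extrapolate"):
            fitted.decompose("g1", [fitted.e[-1] + 5.0])
        dec = fitted.decompose("g1", [fitted.e[-1] + 5.0], extrapolate=True)
        assert np.isfinite(dec["total"]).all()

    def test_unknown_target_raises(self, fitted):
        with pytest.raises(KeyError):
            fitted.decompose("nope", [fitted.e[0]])


class TestResultsObject:
    def test_summary_mentions_every_gene(self, planted_single_edge):
        sim = planted_single_edge
        res = fit_qdode(sim.x, ei=sim.ei, n_lambda=5)
        text = res.summary()
        for g in res.gene_ids:
            assert g in text

    def test_serialization_roundtrip_fields(self, tmp_path, planted_single_edge):
        import json

        sim = planted_single_edge
        res = fit_qdode(sim.x, ei=sim.ei, n_lambda=5)
        path = tmp_path / "model.json"
        res.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["gene_ids"] == res.gene_ids
        assert doc["loglik"] == pytest.approx(res.loglik)
        for g in res.gene_ids:
            assert doc["targets"][g]["regulators"] == res.models[g].regulators

    def test_sigma_cross_is_symmetric_psd_diagonal_matches(self, planted_single_edge):
        sim = planted_single_edge
        res = fit_qdode(sim.x, ei=sim.ei, n_lambda=5)
        S = res.sigma_cross
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert (np.linalg.eigvalsh(S) >= -1e-10).all()
        for i, g in enumerate(res.gene_ids):
            assert S[i, i] == pytest.approx(res.models[g].sigma2, rel=1e-6)

    def test_ei_tie_jitter_makes_axis_strictly_increasing(self):
        vals = np.array([[1.0, 1.0, 2.0, 3.0, 4.0, 5.0],
                         [2.0, 2.0, 1.0, 2.0, 3.0, 4.0]])  # EI ties at 3
        x, _ = make_matrix(vals)
        engine = QdODE(x, n_interior_smooth=0)
        assert (np.diff(engine.e) > 0).all()


class TestAr1Residuals:
    def test_rho_estimated_from_subject_time_metadata(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        n_subj, n_time = 12, 4
        n = n_subj * n_time
        meta = pd.DataFrame({
            "subject": np.repeat([f"p{i}" for i in range(n_subj)], n_time),
            "time_label": np.tile(np.arange(n_time), n_subj),
        }, index=[f"s{i+1}" for i in range(n)])
        # residual noise strongly correlated within subject across times
        noise = np.zeros((2, n))
        for s in range(n_subj):
            block = slice(s * n_time, (s + 1) * n_time)
            e = rng.normal(0, 1)
            ar = [e := 0.8 * e + rng.normal(0, 0.6) for _ in range(n_time)]
            noise[0, block] = ar
            noise[1, block] = rng.normal(0, 1, n_time)
        ei = np.linspace(1, 10, n)
        vals = np.vstack([5 + 0.2 * ei, 4 + 0.1 * ei]) + noise
        x = ExpressionMatrix([f"g{j}" for j in range(2)],
                             [f"s{i+1}" for i in range(n)], vals, metadata=meta)
        e = ExpressionIndex(ei=ei, order=np.arange(n))
        res = QdODE(x, ei=e).fit(n_lambda=4, cov="ar1_time")
        assert res.rho > 0.2  # gene-1 residuals are AR-correlated in time
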