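"""Quasi-dynamic ODE (qdODE) system: regulator selection and likelihood fit.

Each gene's expression along the expression-index axis decomposes into an
independent (endogenous) component and dependent components contributed
by a sparse set of regulators:

    y_j(E) = a_j(E) + sum_{j' in regulators(j)} G_{j|j'}(M_{j'}(E)) + e_j(E)

where a_j is the target's independent expression curve (a B-spline over
EI) and G_{j|j'} is a B-spline function of the regulator's expression, so
the dependent amount tracks the regulator wherever it goes.  The EI
derivatives g_j = da_j/dE and g_{j|j'} = dG_{j|j'}/dE recover the
quasi-dynamic ODE view: rates of expression change per unit EI.  All
components are normalized to zero at the first (lowest-EI) sample, so
network edges vanish at E_1 and grow along the EI axis.

Fitting proceeds per target in two stages: a weighted group LASSO (one
coefficient group per candidate regulator; the target's own EI basis
unpenalized) selects the incoming links at a BIC-chosen penalty, then a
Gaussian maximum-likelihood refit on the selected support yields the
coefficients, residual variance and the log-likelihood used by the
network-wise significance test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import SplineBasis, SmoothCurve, build_basis
from .expression import ExpressionIndex, ExpressionMatrix, compute_expression_index, reorder_by_ei
from .grouplasso import group_lasso_path, lambda_max, solve_group_lasso

__all__ = [
    "QdODE",
    "QdODEResults",
    "TargetModel",
    "RegulatorSelection",
    "select_regulators",
    "fit_qdode",
    "fit_null",
    "decompose_expression",
    "parabolic_weights",
]


def parabolic_weights(e: np.ndarray) -> np.ndarray:
    """Default selection weight z(E) = (E - E_1)(E_N - E), scaled to max 1.

    Non-negative with z(E_1) = z(E_N) = 0, as the weighted selection
    criterion requires.
    """
    e = np.asarray(e, dtype=float)
    z = (e - e[0]) * (e[-1] - e)
    m = z.max()
    return z / m if m > 0 else z


@dataclass
class RegulatorSelection:
    """Group-LASSO outcome for one target gene."""

    target: str
    regulators: list[str]
    lam: float
    criterion_trace: pd.DataFrame
    coef_groups: dict[str, np.ndarray]
    entry_lambda: dict[str, float] = field(default_factory=dict)


@dataclass
class TargetModel:
    """Fitted qdODE for one target: coefficients, variance, likelihood."""

    target: str
    regulators: list[str]
    init_value: float
    theta_indep: np.ndarray
    theta_dep: dict[str, np.ndarray]
    sigma2: float
    loglik: float
    fitted: np.ndarray
    residuals: np.ndarray
    n_interior_indep: int


class QdODE:
    """Quasi-dynamic ODE model of a genes x samples expression matrix.

    Parameters
    ----------
    x : ExpressionMatrix
        Expression data; samples are EI-ordered internally.
    ei : ExpressionIndex, optional
        Precomputed expression index (recomputed from ``x`` when omitted,
        e.g. to keep a gene-level EI after module aggregation).
    degree : int
        B-spline degree of the independent (EI) curves; default cubic.
    n_interior : int or "auto"
        Interior knots of the independent basis; ``"auto"`` picks per
        target from {0,1,2,3} by BIC of the independent-only fit.
    dep_degree, n_interior_dep : int
        Degree and interior knots of each regulator's dependent basis.
        The default (linear, no interior knots) keeps the dependency
        terms low-complexity, which is what makes them distinguishable
        from the flexible independent curve; raise for curvier
        regulatory responses.
    n_interior_smooth : int, optional
        Interior knots of the per-gene smoothing splines used to evaluate
        curves at off-sample EIs.
    """

    def __init__(
        self,
        x: ExpressionMatrix,
        ei: ExpressionIndex | None = None,
        degree: int = 3,
        n_interior: int | str = 0,
        dep_degree: int = 1,
        n_interior_dep: int = 0,
        n_interior_smooth: int | None = None,
    ):
        if ei is None:
            ei = compute_expression_index(x)
        self.x = reorder_by_ei(x, ei)
        e_sorted = np.asarray(ei.sorted_ei, dtype=float)
        # deterministic tie-jitter so the EI axis is strictly increasing
        if np.any(np.diff(e_sorted) <= 0):
            span = max(e_sorted[-1] - e_sorted[0], 1.0)
            e_sorted = e_sorted + 1e-9 * span * np.arange(len(e_sorted))
        self.e = e_sorted
        self.ei = ei
        self.gene_ids = list(self.x.gene_ids)
        self.degree = degree
        self.n_interior = n_interior
        self.dep_degree = dep_degree
        self.n_interior_dep = n_interior_dep
        n = len(self.e)
        if n_interior_smooth is None:
            n_interior_smooth = max(0, min(3, n - degree - 2))
        smooth_basis = build_basis(
            ExpressionIndex(ei=self.e, order=np.arange(n)),
            degree=max(degree, 2), n_interior=n_interior_smooth,
        )
        # per-gene smoothed curves (off-sample evaluation) and dependent
        # design blocks B(y_g) centered to vanish at the first sample
        self.curves: dict[str, SmoothCurve] = {}
        self.bases: dict[str, SplineBasis] = {}
        self.columns: dict[str, np.ndarray] = {}
        for g, y in zip(self.gene_ids, self.x.values):
            self.curves[g] = SmoothCurve(smooth_basis, self.e, y)
            basis = self._value_basis(y, dep_degree, n_interior_dep)
            self.bases[g] = basis
            D = basis.design(y)
            self.columns[g] = D - D[0]
        self._indep: dict[str, tuple[SplineBasis, np.ndarray, int]] = {}

    @staticmethod
    def _value_basis(values: np.ndarray, degree: int, n_interior: int) -> SplineBasis:
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi - lo < 1e-12:  # (near-)constant gene: widen so the basis is valid
            lo, hi = lo - 0.5, hi + 0.5
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(values, qs) if n_interior else np.empty(0)
        interior = np.clip(interior, lo + 1e-12, hi - 1e-12)
        return SplineBasis(degree=degree, interior_knots=interior, boundary=(lo, hi))

    # -- independent (EI) basis, possibly per-target BIC choice ------------
    def indep_columns(self, target: str) -> tuple[SplineBasis, np.ndarray, int]:
        if target in self._indep:
            return self._indep[target]
        n = len(self.e)
        eidx = ExpressionIndex(ei=self.e, order=np.arange(n))
        if self.n_interior == "auto":
            y = self.x.values[self.gene_ids.index(target)]
            best = None
            for k in (0, 1, 2, 3):
                if n <= self.degree + k + 2:
                    break
                basis = build_basis(eidx, degree=self.degree, n_interior=k)
                X = basis.design(self.e)
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ coef) ** 2))
                bic = n * np.log(max(rss, 1e-300) / n) + X.shape[1] * np.log(n)
                if best is None or bic < best[0]:
                    best = (bic, basis, X, k)
            _, basis, X, k = best
        else:
            k = int(self.n_interior)
            basis = build_basis(eidx, degree=self.degree, n_interior=k)
            X = basis.design(self.e)
        self._indep[target] = (basis, X, k)
        return self._indep[target]

    # -- stage 1: regulator selection --------------------------------------
    def select_regulators(
        self,
        target: str,
        lambda_grid: np.ndarray | str = "auto",
        n_lambda: int = 10,
        weights: np.ndarray | None = None,
        criterion: str = "bic",
        ebic_gamma: float = 0.5,
        adaptive: bool = False,
        candidates: list[str] | None = None,
        max_regulators: int | None = None,
    ) -> RegulatorSelection:
        """Penalized weighted least squares selecting the incoming links of
        ``target``; the BIC (or extended-BIC) minimizing penalty wins.

        ``max_regulators`` caps the admissible incoming-link count
        (default: number of candidates minus one).  The cap keeps the
        sparsity premise d_j << m and, crucially, excludes the one exactly
        degenerate solution that exists whenever the EI equals the sum of
        the modeled genes (each gene is then an exact linear combination
        of EI and *all* other genes)."""
        if target not in self.gene_ids:
            raise KeyError(f"unknown target {target!r}")
        n = len(self.e)
        y = self.x.values[self.gene_ids.index(target)]
        if weights is None:
            weights = parabolic_weights(self.e)
        others = [g for g in (candidates or self.gene_ids) if g != target]
        _, A, _ = self.indep_columns(target)
        blocks = [A] + [self.columns[g] for g in others]
        X = np.column_stack(blocks)
        n_unpen = A.shape[1]
        unpen = np.arange(n_unpen)
        groups, start = [], n_unpen
        for g in others:
            nb = self.columns[g].shape[1]
            groups.append(np.arange(start, start + nb))
            start += nb

        group_weights = None
        if adaptive:
            init = solve_group_lasso(X, y, groups, unpen, lam=0.0, weights=weights)
            norms = np.array([np.linalg.norm(init.coef[idx]) for idx in groups])
            group_weights = 1.0 / np.maximum(norms, 1e-8)
            group_weights /= group_weights.min()

        if isinstance(lambda_grid, str):
            lmax = lambda_max(X, y, groups, unpen, weights, group_weights)
            if lmax <= 0:
                lambda_grid = np.array([0.0])
            else:
                lambda_grid = np.geomspace(lmax * 1.0001, lmax * 0.01, n_lambda)
        lambda_grid = np.asarray(lambda_grid, dtype=float)

        fits = group_lasso_path(X, y, groups, unpen, lambda_grid, weights, group_weights)
        n_eff = int((weights > 0).sum())
        if max_regulators is None:
            max_regulators = max(len(groups) - 1, 1)
        rss_floor = n_eff * max(float(np.var(y)), 1e-12) * 1e-10
        rows = []
        for lam, fit in zip(lambda_grid, fits):
            r = y - X @ fit.coef
            rss = float(np.sum(weights * r**2))
            active = fit.active_groups(tol=1e-10)
            df = n_unpen + sum(len(groups[g]) for g in active)
            bic = n_eff * np.log(max(rss, rss_floor) / n_eff) + df * np.log(n_eff)
            if criterion == "ebic":
                bic += 2 * ebic_gamma * len(active) * np.log(max(len(groups), 1))
            rows.append({"lambda": lam, "bic": bic, "df": df, "n_active": len(active)})
        trace = pd.DataFrame(rows)
        admissible = trace.index[trace["n_active"] <= max_regulators]
        best = int(trace.loc[admissible, "bic"].idxmin())
        fit = fits[best]
        active = fit.active_groups(tol=1e-10)
        regulators = [others[g] for g in active]
        coef_groups = {others[g]: fit.coef[groups[g]].copy() for g in active}
        # path entry penalty per candidate edge (used as the ROC score)
        entry = {}
        for g, name in enumerate(others):
            lams = [
                float(lam) for lam, f in zip(lambda_grid, fits)
                if np.linalg.norm(f.coef[groups[g]]) > 1e-10
            ]
            entry[name] = max(lams) if lams else 0.0
        return RegulatorSelection(
            target=target, regulators=regulators, lam=float(lambda_grid[best]),
            criterion_trace=trace, coef_groups=coef_groups, entry_lambda=entry,
        )

    # -- stage 2: maximum-likelihood refit ---------------------------------
    def _fit_target(self, target: str, regulators: list[str]) -> TargetModel:
        n = len(self.e)
        y = self.x.values[self.gene_ids.index(target)]
        _, A, k = self.indep_columns(target)
        X = np.column_stack([A] + [self.columns[g] for g in regulators])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        resid = y - fitted
        sigma2 = float(max(np.mean(resid**2), 1e-12))
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        nb_a = A.shape[1]
        theta_indep = coef[:nb_a]
        theta_dep, start = {}, nb_a
        for g in regulators:
            nb = self.columns[g].shape[1]
            theta_dep[g] = coef[start : start + nb]
            start += nb
        basis_a, _, _ = self.indep_columns(target)
        init = float(basis_a.design(self.e[:1])[0] @ theta_indep)
        return TargetModel(
            target=target, regulators=list(regulators), init_value=init,
            theta_indep=theta_indep, theta_dep=theta_dep, sigma2=sigma2,
            loglik=float(loglik), fitted=fitted, residuals=resid, n_interior_indep=k,
        )

    def fit(
        self,
        lambda_grid: np.ndarray | str = "auto",
        n_lambda: int = 10,
        criterion: str = "bic",
        ebic_gamma: float = 0.5,
        adaptive: bool = False,
        cov: str = "independent",
        selections: list[RegulatorSelection] | None = None,
        max_regulators: int | None = None,
    ) -> "QdODEResults":
        """Select regulators for every target and fit the sparse system."""
        if selections is None:
            selections = [
                self.select_regulators(
                    g, lambda_grid=lambda_grid, n_lambda=n_lambda,
                    criterion=criterion, ebic_gamma=ebic_gamma, adaptive=adaptive,
                    max_regulators=max_regulators,
                )
                for g in self.gene_ids
            ]
        sel_map = {s.target: s for s in selections}
        missing = [g for g in self.gene_ids if g not in sel_map]
        if missing:
            raise ValueError(f"selections missing target(s): {missing}")
        models = {g: self._fit_target(g, sel_map[g].regulators) for g in self.gene_ids}
        return QdODEResults(self, models, sel_map, cov=cov)

    def fit_null(self, cov: str = "independent") -> "QdODEResults":
        """Reduced (independence) system: every target fitted without regulators."""
        sel_map = {
            g: RegulatorSelection(
                target=g, regulators=[], lam=np.inf,
                criterion_trace=pd.DataFrame(), coef_groups={},
            )
            for g in self.gene_ids
        }
        models = {g: self._fit_target(g, []) for g in self.gene_ids}
        return QdODEResults(self, models, sel_map, cov="independent")


class QdODEResults:
    """Fitted qdODE system: per-target models, covariances, likelihood.

    Networks, perturbation deltas and expression decompositions are all
    read off this object; see :mod:`idopnet.networks`.
    """

    def __init__(
        self,
        model: QdODE,
        models: dict[str, TargetModel],
        selections: dict[str, RegulatorSelection],
        cov: str = "independent",
    ):
        self.model = model
        self.models = models
        self.selections = selections
        self.cov_spec = cov
        self.gene_ids = list(model.gene_ids)
        R = np.vstack([models[g].residuals for g in self.gene_ids])
        self.sigma_cross = (R @ R.T) / R.shape[1]  # post-hoc residual (co)variances
        self.rho = 0.0
        if cov == "ar1_time":
            self.rho = self._estimate_rho(R)
        self.loglik = float(sum(models[g].loglik for g in self.gene_ids))

    # AR(1) correlation of residuals across time points within a subject
    def _estimate_rho(self, R: np.ndarray) -> float:
        meta = self.model.x.metadata
        if meta is None or "subject" not in meta or "time_label" not in meta:
            return 0.0
        pairs_a, pairs_b = [], []
        subj = meta["subject"].to_numpy()
        time = meta["time_label"].to_numpy()
        for s in pd.unique(subj):
            idx = np.where(subj == s)[0]
            idx = idx[np.argsort(time[idx])]
            for a, b in zip(idx[:-1], idx[1:]):
                pairs_a.append(R[:, a])
                pairs_b.append(R[:, b])
        if not pairs_a:
            return 0.0
        a = np.concatenate(pairs_a)
        b = np.concatenate(pairs_b)
        denom = float(np.sqrt(np.sum(a * a) * np.sum(b * b)))
        return float(np.sum(a * b) / denom) if denom > 0 else 0.0

    @property
    def e(self) -> np.ndarray:
        return self.model.e

    @property
    def n_params(self) -> int:
        tot = 0
        for g in self.gene_ids:
            m = self.models[g]
            tot += len(m.theta_indep) + sum(len(v) for v in m.theta_dep.values()) + 1
        return tot

    def independent_amount(self, gene: str, e_points) -> np.ndarray:
        """G_j(E) = a_j(E) - a_j(E_1): endogenous expression gained since E_1."""
        m = self.models[gene]
        basis, _, _ = self.model.indep_columns(gene)
        e_points = np.atleast_1d(np.asarray(e_points, dtype=float))
        B = basis.design(e_points) - basis.design(self.e[:1])
        return B @ m.theta_indep

    def dependent_amount(self, target: str, regulator: str, e_points) -> np.ndarray:
        """G_{j|j'}(E): the regulator's fitted contribution, zero at E_1.

        Exact at the sample EIs (where the fitted component is defined by
        the regulator's observed expression) and linearly interpolated in
        between; beyond the sampled range the boundary value is held.
        """
        m = self.models[target]
        e_points = np.atleast_1d(np.asarray(e_points, dtype=float))
        if regulator not in m.theta_dep:
            return np.zeros(e_points.shape)
        at_samples = self.model.columns[regulator] @ m.theta_dep[regulator]
        return np.interp(e_points, self.e, at_samples)

    def dependent_rate(self, target: str, regulator: str, e_points, h: float | None = None):
        """g_{j|j'}(E) = dG_{j|j'}/dE by central differences on the smoothed curve."""
        e_points = np.atleast_1d(np.asarray(e_points, dtype=float))
        if h is None:
            h = (self.e[-1] - self.e[0]) / 1000.0
        up = self.dependent_amount(target, regulator, e_points + h)
        dn = self.dependent_amount(target, regulator, e_points - h)
        return (up - dn) / (2 * h)

    def decompose(
        self, target: str, e_grid: np.ndarray, extrapolate: bool = False
    ) -> pd.DataFrame:
        """Additive decomposition total = init + G_j + sum_j' G_{j|j'}.

        The sign of a dependent column classifies the regulator's action at
        that EI: positive = promotion, negative = inhibition, zero = neutral.
        """
        if target not in self.models:
            raise KeyError(f"unknown target {target!r}")
        e_grid = np.atleast_1d(np.asarray(e_grid, dtype=float))
        lo, hi = self.e[0], self.e[-1]
        if not extrapolate and ((e_grid < lo - 1e-12).any() or (e_grid > hi + 1e-12).any()):
            raise ValueError(
                "e_grid outside the fitted EI range; pass extrapolate=True to allow"
            )
        m = self.models[target]
        out = pd.DataFrame({"E": e_grid})
        out["independent"] = self.independent_amount(target, e_grid)
        for reg in m.regulators:
            out[f"dep:{reg}"] = self.dependent_amount(target, reg, e_grid)
        dep_cols = [c for c in out.columns if c.startswith("dep:")]
        out["total"] = m.init_value + out["independent"] + out[dep_cols].sum(axis=1)
        return out

    def lr_against(self, null: "QdODEResults") -> float:
        """2 * (loglik_full - loglik_null) against a reduced system."""
        return 2.0 * (self.loglik - null.loglik)

    def summary(self) -> str:
        lines = [
            "qdODE system fit",
            "================",
            f"genes: {len(self.gene_ids)}   samples: {len(self.e)}   "
            f"EI range: [{self.e[0]:.4g}, {self.e[-1]:.4g}]",
            f"total log-likelihood: {self.loglik:.4f}   covariance: {self.cov_spec}"
            + (f" (rho={self.rho:.3f})" if self.cov_spec == "ar1_time" else ""),
            "",
            f"{'target':>12} {'d_j':>4} {'sigma2':>10} {'loglik':>10}  regulators",
        ]
        for g in self.gene_ids:
            m = self.models[g]
            lines.append(
                f"{g:>12} {len(m.regulators):>4} {m.sigma2:>10.4g} "
                f"{m.loglik:>10.3f}  {','.join(m.regulators) or '-'}"
            )
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        doc = {
            "schema": "idopnet/qdode-results/1",
            "gene_ids": self.gene_ids,
            "e": self.e.tolist(),
            "cov": self.cov_spec,
            "rho": self.rho,
            "loglik": self.loglik,
            "targets": {},
        }
        for g in self.gene_ids:
            m = self.models[g]
            doc["targets"][g] = {
                "regulators": m.regulators,
                "init_value": m.init_value,
                "theta_indep": m.theta_indep.tolist(),
                "theta_dep": {k: v.tolist() for k, v in m.theta_dep.items()},
                "sigma2": m.sigma2,
                "loglik": m.loglik,
                "lambda": float(self.selections[g].lam),
            }
        return doc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# functional wrappers mirroring the pipeline stages


def select_regulators(x: ExpressionMatrix, target: str, **kwargs) -> RegulatorSelection:
    return QdODE(x).select_regulators(target, **kwargs)


def fit_qdode(x: ExpressionMatrix, ei: ExpressionIndex | None = None, **kwargs) -> QdODEResults:
    fit_kwargs = {
        k: kwargs.pop(k)
        for k in ("lambda_grid", "n_lambda", "criterion", "ebic_gamma", "adaptive", "cov", "selections")
        if k in kwargs
    }
    return QdODE(x, ei=ei, **kwargs).fit(**fit_kwargs)


def fit_null(x: ExpressionMatrix, ei: ExpressionIndex | None = None, **kwargs) -> QdODEResults:
    return QdODE(x, ei=ei, **kwargs).fit_null()


def decompose_expression(results: QdODEResults, target: str, e_grid, **kw) -> pd.DataFrame:
    return results.decompose(target, e_grid, **kw)
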