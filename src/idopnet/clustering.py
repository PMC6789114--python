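"""Functional clustering of genes into modules by EI-varying pattern.

Genes are grouped with a finite mixture model: component k claims that a
gene's expression follows the mean curve alpha_k * EI**beta_k (the same
power-law family the allometry diagnostics use) with gene-wise
independent Gaussian residuals of component-specific variance.  The
mixture is fitted by EM with seeded restarts; the number of modules is
chosen by AIC over a grid of K.  Aggregating member genes (mean by
default, sum for EI-conservation workflows) yields the module-level
matrix on which networks are reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .allometry import fit_power_law
from .expression import ExpressionIndex, ExpressionMatrix

__all__ = [
    "CurveMixture",
    "CurveMixtureResults",
    "fit_mixture",
    "select_k_by_aic",
    "aggregate_modules",
]


class EmptyClusterError(RuntimeError):
    pass


@dataclass
class CurveMixtureResults:
    """Module assignment: posteriors, mean-curve parameters, AIC."""

    n_modules: int
    labels: dict[str, int]
    posterior: np.ndarray  # (m, K), rows sum to 1
    module_curves: list[tuple[float, float]]  # (alpha_k, beta_k)
    sigma2: np.ndarray  # (K,)
    weights: np.ndarray  # mixing proportions
    loglik: float
    aic: float
    loglik_trace: np.ndarray
    aic_trace: pd.DataFrame | None = None

    @property
    def label_array(self) -> np.ndarray:
        return np.asarray(list(self.labels.values()))

    def assignment_frame(self) -> pd.DataFrame:
        genes = list(self.labels)
        return pd.DataFrame({
            "gene_id": genes,
            "module": [f"M{self.labels[g] + 1}" for g in genes],
            "max_posterior": self.posterior.max(axis=1),
        }).set_index("gene_id")


def _fit_component_curve(e: np.ndarray, profile: np.ndarray, p0: tuple[float, float]):
    """Weighted-mean-profile power fit: argmin sum_i (profile_i - a e_i^b)^2."""

    def resid(p):
        return profile - np.exp(p[0]) * e ** p[1]

    la0 = np.log(max(p0[0], 1e-12))
    sol = least_squares(resid, x0=np.array([la0, p0[1]]), method="lm", max_nfev=200)
    return float(np.exp(sol.x[0])), float(sol.x[1])


class CurveMixture:
    """Finite mixture of power-law mean curves over the EI axis.

    Parameters
    ----------
    x : ExpressionMatrix
        EI-ordered expression (m genes x N samples).
    e : ExpressionIndex, optional
        Recomputed from ``x`` when omitted; EIs must be positive.
    """

    def __init__(self, x: ExpressionMatrix, e: ExpressionIndex | None = None):
        from .expression import compute_expression_index

        self.x = x
        self.e = e if e is not None else compute_expression_index(x)
        self.ei = np.asarray(self.e.sorted_ei if e is None else self.e.ei, dtype=float)
        if e is None:
            self.ei = np.asarray(self.e.ei, dtype=float)
        if (self.ei <= 0).any():
            raise ValueError("EI must be positive for power-law mean curves")

    # per-gene log density under component k
    def _loglik_matrix(self, curves, sigma2) -> np.ndarray:
        Y = self.x.values
        n = Y.shape[1]
        out = np.empty((Y.shape[0], len(curves)))
        for k, ((a, b), s2) in enumerate(zip(curves, sigma2)):
            mu = a * self.ei**b
            sq = ((Y - mu) ** 2).sum(axis=1)
            out[:, k] = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * sq / s2
        return out

    def _init_params(self, K: int, rng: np.random.Generator):
        feats = []
        for y in self.x.values:
            f = fit_power_law(y, ExpressionIndex(ei=self.ei, order=np.arange(len(self.ei))))
            feats.append((np.log(max(f.alpha, 1e-12)), f.beta))
        feats = np.asarray(feats)
        m = len(feats)
        centers = feats[rng.choice(m, size=K, replace=m < K)]
        curves = [(float(np.exp(la)), float(b)) for la, b in centers]
        resid = self.x.values - self.x.values.mean(axis=0, keepdims=True)
        s2 = max(float(resid.var()), 1e-6)
        return curves, np.full(K, s2), np.full(K, 1.0 / K)

    def fit(
        self,
        K: int,
        seed: int = 0,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 200,
        max_restarts: int = 5,
    ) -> CurveMixtureResults:
        """EM fit with ``n_init`` seeded restarts; best local optimum wins."""
        m = self.x.n_genes
        if K > m:
            raise ValueError(f"K={K} exceeds number of genes m={m}")
        if K < 1:
            raise ValueError("K must be >= 1")
        best = None
        ss = np.random.SeedSequence(seed)
        for init_seed in ss.generate_state(n_init):
            for attempt in range(max_restarts):
                rng = np.random.default_rng(int(init_seed) + attempt)
                try:
                    res = self._em(K, rng, tol, max_iter)
                except EmptyClusterError:
                    continue
                if best is None or res.loglik > best.loglik:
                    best = res
                break
        if best is None:
            raise EmptyClusterError(
                f"EM produced an empty module for K={K} in every restart"
            )
        return best

    def _em(self, K, rng, tol, max_iter) -> CurveMixtureResults:
        curves, sigma2, weights = self._init_params(K, rng)
        Y = self.x.values
        m, n = Y.shape
        trace = []
        prev = -np.inf
        for _ in range(max_iter):
            logp = self._loglik_matrix(curves, sigma2) + np.log(weights)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])
            Rk = resp.sum(axis=0)
            if (Rk < 1e-8).any():
                raise EmptyClusterError("empty module during EM")
            weights = Rk / m
            for k in range(K):
                profile = (resp[:, k] @ Y) / Rk[k]
                curves[k] = _fit_component_curve(self.ei, profile, curves[k])
                mu = curves[k][0] * self.ei ** curves[k][1]
                sq = ((Y - mu) ** 2).sum(axis=1)
                sigma2[k] = max(float((resp[:, k] @ sq) / (n * Rk[k])), 1e-10)
            if ll - prev < tol * max(abs(ll), 1.0) and ll >= prev - 1e-8:
                break
            prev = ll
        logp = self._loglik_matrix(curves, sigma2) + np.log(weights)
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        hard = resp.argmax(axis=1)
        if len(np.unique(hard)) < K:
            raise EmptyClusterError("module with no assigned gene")
        n_params = 3 * K + (K - 1)  # per-module curve (2) + variance, plus mixing
        aic = -2 * ll + 2 * n_params
        labels = {g: int(h) for g, h in zip(self.x.gene_ids, hard)}
        return CurveMixtureResults(
            n_modules=K, labels=labels, posterior=resp, module_curves=list(curves),
            sigma2=sigma2.copy(), weights=weights.copy(), loglik=ll, aic=float(aic),
            loglik_trace=np.asarray(trace),
        )

    def fit_select(
        self, k_grid, seed: int = 0, **fit_kwargs
    ) -> CurveMixtureResults:
        """Fit every K in ``k_grid`` and return the AIC-minimizing solution."""
        k_grid = list(k_grid)
        if not k_grid:
            raise ValueError("k_grid must be non-empty")
        rows, fits = [], {}
        for K in k_grid:
            try:
                fit = self.fit(K, seed=seed, **fit_kwargs)
            except EmptyClusterError:
                continue
            fits[K] = fit
            rows.append({"K": K, "aic": fit.aic, "loglik": fit.loglik})
        if not fits:
            raise EmptyClusterError("no K in the grid produced a valid fit")
        trace = pd.DataFrame(rows)
        best_k = int(trace.loc[trace["aic"].idxmin(), "K"])
        best = fits[best_k]
        best.aic_trace = trace
        return best


def fit_mixture(
    x: ExpressionMatrix, e: ExpressionIndex | None, K: int, seed: int = 0, **kw
) -> CurveMixtureResults:
    return CurveMixture(x, e).fit(K, seed=seed, **kw)


def select_k_by_aic(
    x: ExpressionMatrix, e: ExpressionIndex | None, k_grid, seed: int = 0, **kw
) -> CurveMixtureResults:
    return CurveMixture(x, e).fit_select(k_grid, seed=seed, **kw)


def aggregate_modules(
    x: ExpressionMatrix, assignment: CurveMixtureResults, how: str = "mean"
) -> ExpressionMatrix:
    """Module-level expression: mean (default) or sum of member genes.

    With ``how="sum"`` the module-level EI equals the gene-level EI
    (conservation), which matters when the EI is recomputed after
    aggregation.
    """
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    labels = assignment.labels
    rows, ids = [], []
    for k in range(assignment.n_modules):
        members = [g for g in x.gene_ids if labels.get(g) == k]
        if not members:
            raise EmptyClusterError(f"module {k} has no member genes")
        idx = [x.gene_ids.index(g) for g in members]
        block = x.values[idx]
        rows.append(block.sum(axis=0) if how == "sum" else block.mean(axis=0))
        ids.append(f"M{k + 1}")
    return ExpressionMatrix(ids, list(x.sample_ids), np.vstack(rows), x.metadata)
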