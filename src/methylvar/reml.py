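"""Variance components by restricted maximum likelihood on relationship matrices.

The infinitesimal-model counterpart of the mixture regression: the trait
covariance is modelled as ``V = Σ_k σ²_k K_k + σ²_e I`` with ``K_k`` an
omics (ORM) or genomic (GRM) relationship matrix, and the restricted
likelihood is maximized by average-information (AI) Newton steps with EM
fallback whenever an AI step would leave the parameter space.  Estimates
are reported as fractions of the phenotypic variance with delta-method
standard errors from the inverse AI matrix.

``BivariateRemlModel`` implements the cross-group decomposition used to
ask whether marker effects are shared between two groups (e.g. the sexes):
the trait in group 1 and group 2 are treated as two traits observed on
disjoint individuals, with cross-group covariance ``r·σ₁·σ₂·K₁₂`` on the
cross block of the relationship matrix.  The likelihood-ratio test of
``r = 1`` uses the boundary mixture ½·χ²₀ + ½·χ²₁.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .preprocess import RelationshipMatrix

__all__ = [
    "RemlFit",
    "BivariateFit",
    "RemlModel",
    "BivariateRemlModel",
    "fit_reml",
    "fit_bivariate_sex",
]


@dataclass
class RemlFit:
    """Variance-component estimates on the phenotypic-fraction scale."""

    component_names: list
    var_frac: dict  # component (+'residual') -> fraction of Var(y)
    se: dict
    ci95: dict  # component -> (lo, hi), estimate +/- 1.96 SE
    var_components: dict  # raw variances, original phenotype scale
    loglik: float
    n_iter_used: int
    converged: bool
    boundary: list = field(default_factory=list)  # components pinned at 0

    def summary(self) -> str:
        lines = ["REML variance components (fractions of phenotypic variance)", ""]
        lines.append(f"{'component':<12}{'frac':>8}{'SE':>8}{'95% CI':>18}")
        for c in self.component_names + ["residual"]:
            lo, hi = self.ci95[c]
            flag = " (boundary)" if c in self.boundary else ""
            lines.append(
                f"{c:<12}{self.var_frac[c]:>8.3f}{self.se[c]:>8.3f}"
                f"{f'[{lo:.3f}, {hi:.3f}]':>18}{flag}"
            )
        lines.append("")
        lines.append(f"logL = {self.loglik:.4f}; iterations = {self.n_iter_used}; "
                     f"converged = {self.converged}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "component_names": list(self.component_names),
            "var_frac": {k: float(v) for k, v in self.var_frac.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "ci95": {k: [float(v[0]), float(v[1])] for k, v in self.ci95.items()},
            "var_components": {k: float(v) for k, v in self.var_components.items()},
            "loglik": float(self.loglik),
            "n_iter_used": int(self.n_iter_used),
            "converged": bool(self.converged),
            "boundary": list(self.boundary),
        }


@dataclass
class BivariateFit:
    var_frac_group1: float
    var_frac_group2: float
    r_corr: float
    se_r: float
    p_r_eq_1: float
    loglik: float
    group_labels: tuple = ("group1", "group2")

    def summary(self) -> str:
        return (
            "Bivariate REML cross-group decomposition\n"
            f"  {self.group_labels[0]}: fraction = {self.var_frac_group1:.3f}\n"
            f"  {self.group_labels[1]}: fraction = {self.var_frac_group2:.3f}\n"
            f"  r = {self.r_corr:.3f} (SE {self.se_r:.3f}), "
            f"p(r = 1) = {self.p_r_eq_1:.3g}"
        )

    def to_dict(self) -> dict:
        return {
            "var_frac_group1": float(self.var_frac_group1),
            "var_frac_group2": float(self.var_frac_group2),
            "r_corr": float(self.r_corr),
            "se_r": float(self.se_r),
            "p_r_eq_1": float(self.p_r_eq_1),
            "loglik": float(self.loglik),
            "group_labels": list(self.group_labels),
        }


def _as_kernel(k) -> np.ndarray:
    return k.values if isinstance(k, RelationshipMatrix) else np.asarray(k, dtype=float)


class RemlModel:
    """``y ~ N(Xb, Σ_k σ²_k K_k + σ²_e I)`` fitted by AI-REML.

    ``kernels`` maps component names to relationship matrices; ``X``
    (optional fixed-effect design, intercept added automatically) is
    absorbed by the REML projection.
    """

    def __init__(self, y, kernels: dict, X: np.ndarray | None = None,
                 add_intercept: bool = True):
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        self.component_names = list(kernels.keys())
        self.K = [_as_kernel(k) for k in kernels.values()]
        for name, K in zip(self.component_names, self.K):
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} is not n x n")
            self._check_identifiable(name, K)
        if X is None:
            self.X = np.ones((n, 1))
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            if add_intercept:
                X = np.column_stack([np.ones(n), X])
            self.X = X

    @staticmethod
    def _check_identifiable(name: str, K: np.ndarray) -> None:
        # K proportional to I makes sigma^2_k and sigma^2_e aliased
        d = K.diagonal()
        off = K - np.diag(d)
        scale = max(np.abs(d).max(), 1e-12)
        if np.abs(off).max() < 1e-8 * scale and np.ptp(d) < 1e-8 * scale:
            raise ValueError(
                f"kernel {name!r} is (numerically) proportional to the identity: "
                "its variance component is not identifiable from the residual"
            )

    # ------------------------------------------------------------------
    def _projection(self, theta):
        n = len(self.y)
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.K):
            V += t * K
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return None
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        VX = Vinv @ self.X
        XtVX = self.X.T @ VX
        cx = linalg.cho_factor(XtVX, check_finite=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
        P = Vinv - VX @ linalg.cho_solve(cx, VX.T, check_finite=False)
        Py = P @ self.y
        ll = -0.5 * (logdetV + logdetX + float(self.y @ Py))
        return P, Py, ll

    def loglik(self, theta) -> float:
        """Restricted log-likelihood (up to a constant) at raw variances."""
        out = self._projection(np.asarray(theta, dtype=float))
        if out is None:
            return -np.inf
        return out[2]

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 100, tol_ll: float = 1e-8,
            tol_par: float = 1e-6, n_em_start: int = 2) -> RemlFit:
        y, n = self.y, len(self.y)
        vary = y.var(ddof=1)
        m = len(self.K)
        theta = np.full(m + 1, vary / (m + 1))
        floor = 1e-8 * vary
        kernels = self.K + [np.eye(n)]

        ll_old = -np.inf
        AI = np.eye(m + 1)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            out = self._projection(theta)
            if out is None:
                theta = np.maximum(theta * 0.5, floor)
                continue
            P, Py, ll = out
            traces = np.empty(m + 1)
            KPy = np.empty((m + 1, n))
            for k, K in enumerate(kernels):
                KPy[k] = K @ Py
                traces[k] = float(np.einsum("ij,ji->", P, K)) if k < m else float(np.trace(P))
            score = 0.5 * (KPy @ Py - traces)
            PKPy = P @ KPy.T  # n x (m+1)
            AI = 0.5 * (KPy @ PKPy)
            try:
                step = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                step = None
            proposal = theta + step if (step is not None and it > n_em_start) else None
            if proposal is not None and np.all(np.isfinite(proposal)):
                # components the AI step drives negative are boundary
                # candidates: pin them and keep the AI move for the rest
                # (a pure EM fallback only crawls toward the boundary)
                proposal = np.where(proposal < 0, floor, proposal)
            else:
                # EM update: always respects the parameter space
                proposal = theta + theta**2 * (KPy @ Py - traces) / n
            proposal = np.maximum(proposal, floor)
            delta = np.max(np.abs(proposal - theta)) / max(vary, 1e-12)
            theta = proposal
            if abs(ll - ll_old) < tol_ll or delta < tol_par:
                converged = True
                ll_old = ll
                break
            ll_old = ll
        if not converged:
            raise RuntimeError(
                f"AI-REML did not converge in {max_iter} iterations "
                f"(last logL = {ll_old:.6f})"
            )

        # final quantities at the solution
        out = self._projection(theta)
        P, Py, ll = out
        KPy = np.empty((m + 1, n))
        for k, K in enumerate(kernels):
            KPy[k] = K @ Py
        AI = 0.5 * (KPy @ (P @ KPy.T))
        try:
            cov_theta = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov_theta = np.linalg.pinv(AI)

        boundary = [self.component_names[k] for k in range(m) if theta[k] <= floor * 1.01]
        total = theta.sum()
        frac = theta / total
        # delta method for f_k = theta_k / sum(theta)
        J = (np.eye(m + 1) * total - theta[:, None]) / total**2
        cov_frac = J @ cov_theta @ J.T
        se = np.sqrt(np.maximum(np.diag(cov_frac), 0.0))

        names = self.component_names + ["residual"]
        var_frac = {c: float(np.clip(frac[k], 0.0, 1.0)) for k, c in enumerate(names)}
        return RemlFit(
            component_names=self.component_names,
            var_frac=var_frac,
            se={c: float(se[k]) for k, c in enumerate(names)},
            ci95={
                c: (float(frac[k] - 1.96 * se[k]), float(frac[k] + 1.96 * se[k]))
                for k, c in enumerate(names)
            },
            var_components={c: float(theta[k]) for k, c in enumerate(names)},
            loglik=float(ll),
            n_iter_used=it,
            converged=converged,
            boundary=boundary,
        )


class BivariateRemlModel:
    """Cross-group variance decomposition on one relationship matrix.

    The trait in each group is a separate trait observed on disjoint
    individuals; the cross-block covariance is ``r·σ₁·σ₂·K₁₂``.  Each
    group has its own marker variance and residual variance and its own
    intercept.
    """

    def __init__(self, y, group: np.ndarray, rel, min_per_group: int = 50,
                 group_labels: tuple = ("group1", "group2")):
        y = np.asarray(y, dtype=float)
        group = np.asarray(group)
        K = _as_kernel(rel)
        levels = np.unique(group)
        if len(levels) != 2:
            raise ValueError("exactly two groups are required (both must be present)")
        i1, i2 = np.flatnonzero(group == levels[0]), np.flatnonzero(group == levels[1])
        if min(len(i1), len(i2)) < min_per_group:
            raise ValueError(f"need at least {min_per_group} individuals per group")
        order = np.concatenate([i1, i2])
        self.n1 = len(i1)
        self.y = y[order] - np.concatenate(
            [np.full(len(i1), y[i1].mean()), np.full(len(i2), y[i2].mean())]
        )
        self.K = K[np.ix_(order, order)]
        self.group_labels = tuple(group_labels)

    def _nll(self, params, r_fixed=None):
        n = len(self.y)
        n1 = self.n1
        if r_fixed is None:
            lv1, lv2, le1, le2, z = params
            r = np.tanh(z)
        else:
            lv1, lv2, le1, le2 = params
            r = r_fixed
        s1, s2, e1, e2 = np.exp((lv1, lv2, le1, le2))
        V = np.empty((n, n))
        V[:n1, :n1] = s1 * self.K[:n1, :n1]
        V[n1:, n1:] = s2 * self.K[n1:, n1:]
        V[:n1, n1:] = r * np.sqrt(s1 * s2) * self.K[:n1, n1:]
        V[n1:, :n1] = V[:n1, n1:].T
        V[:n1, :n1] += e1 * np.eye(n1)
        V[n1:, n1:] += e2 * np.eye(n - n1)
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        alpha = linalg.cho_solve((c, low), self.y, check_finite=False)
        # group means were removed; the REML correction for the two
        # intercepts is absorbed into logdet(X'V^-1 X)
        X = np.zeros((n, 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        VX = linalg.cho_solve((c, low), X, check_finite=False)
        sign, logdetX = np.linalg.slogdet(X.T @ VX)
        if sign <= 0:
            return 1e10
        return 0.5 * (logdet + logdetX + float(self.y @ alpha))

    def fit(self) -> BivariateFit:
        vary = self.y.var(ddof=1)
        x0 = np.log([vary / 2, vary / 2, vary / 2, vary / 2])
        best = None
        for z0 in (np.arctanh(0.5), np.arctanh(-0.5)):
            cand = optimize.minimize(self._nll, np.append(x0, z0), method="Nelder-Mead",
                                     options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
            if best is None or cand.fun < best.fun:
                best = cand
        res = optimize.minimize(self._nll, best.x, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
        lv1, lv2, le1, le2, z = res.x
        r = float(np.tanh(z))
        s1, s2, e1, e2 = np.exp((lv1, lv2, le1, le2))

        # SE of r by delta method from a central-difference Hessian
        H = _num_hessian(self._nll, res.x)
        se_r = np.nan
        try:
            cov = np.linalg.inv(H)
            if cov[4, 4] > 0:
                se_r = float(np.sqrt(cov[4, 4])) * (1.0 - r**2)
        except np.linalg.LinAlgError:
            pass
        if not np.isfinite(se_r) or se_r <= 0 or se_r > 1.5:
            # near the |r| = 1 boundary (or when the z-scale Hessian is
            # ill-conditioned) fall back to profile-likelihood curvature in r
            se_r = self._profile_se_r(res.x, r)

        res1 = optimize.minimize(lambda p: self._nll(p, r_fixed=1.0), res.x[:4],
                                 method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
        lrt = max(0.0, 2.0 * (res1.fun - res.fun))
        # r = 1 sits on the boundary: 0.5 chi2_0 + 0.5 chi2_1 mixture
        p_val = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 0 else 1.0

        return BivariateFit(
            var_frac_group1=float(s1 / (s1 + e1)),
            var_frac_group2=float(s2 / (s2 + e2)),
            r_corr=r,
            se_r=float(se_r),
            p_r_eq_1=float(p_val),
            loglik=float(-res.fun),
            group_labels=self.group_labels,
        )


    def _profile_se_r(self, x_opt, r_hat, h: float = 0.02) -> float:
        """SE from the curvature of the r-profile restricted likelihood."""
        r0 = float(np.clip(r_hat, -1.0 + 2 * h, 1.0 - 2 * h))

        def prof(r):
            res = optimize.minimize(lambda p: self._nll(p, r_fixed=r), x_opt[:4],
                                    method="Nelder-Mead",
                                    options={"maxiter": 2000, "xatol": 1e-7,
                                             "fatol": 1e-10})
            return res.fun

        d2 = (prof(r0 + h) - 2.0 * prof(r0) + prof(r0 - h)) / (h * h)
        return float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan


def _num_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)
    for i in range(m):
        for j in range(i, m):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


# ----------------------------------------------------------------------
# functional surface


def fit_reml(y, rels: dict, covariates=None, **kwargs) -> RemlFit:
    """Convenience wrapper around :class:`RemlModel`."""
    return RemlModel(y, rels, X=covariates).fit(**kwargs)


def fit_bivariate_sex(y, sex, rel, **kwargs) -> BivariateFit:
    """Cross-sex shared-effect decomposition (female/male as two traits)."""
    sex = np.asarray(sex)
    levels = np.unique(sex)
    if len(levels) != 2:
        raise ValueError("both sexes must be present")
    labels = tuple(f"sex_{v}" for v in levels)
    return BivariateRemlModel(y, sex, rel, group_labels=labels, **kwargs).fit()
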