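"""REML variance-component estimation for additive(-dominance) mixed models.

Model A:  y = Xb + u + e,          u ~ N(0, G sigma_a^2), e ~ N(0, I sigma_e^2)
Model AD: y = Xb + u + v + e,      v ~ N(0, D sigma_d^2)

Estimation is average-information (AI) REML with EM fallback steps when the
AI update leaves the parameter space or decreases the restricted
likelihood.  Components are constrained to be at least 1e-8 * var(y);
boundary solutions and weak identifiability (near-singular AI matrix) are
flagged rather than raised.

The public surface follows the statsmodels convention: build a
:class:`VarianceComponentModel` from data, call :meth:`fit`, and read the
returned :class:`VarianceComponentResults` (estimates, standard errors,
log-likelihood, ``summary()``).  ``fit_model_a``/``fit_model_ad`` are thin
functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import RelationshipMatrix

_MAX_ITER = 200
_LL_TOL = 1e-8


def design_matrix(pheno: pd.DataFrame, factors=("group", "rack")) -> np.ndarray:
    """Fixed-effect design with intercept and reference-coded factors.

    Redundant (collinear) columns are dropped via pivoted QR with a log of
    how many were removed.
    """
    cols = [np.ones(len(pheno))]
    for f in factors:
        dummies = pd.get_dummies(pheno[f].astype(str), drop_first=True)
        cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
    X = np.column_stack(cols)
    return drop_collinear(X)


def drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Drop columns that are linearly dependent on earlier ones."""
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * diag.max()))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        return X[:, keep]
    return X


@dataclass
class VarianceComponentResults:
    """REML estimates with uncertainties and fit diagnostics."""

    model: "VarianceComponentModel"
    components: dict            # name -> estimate (trait units^2)
    se: dict                    # name -> standard error (from inverse AI)
    loglik: float
    converged: bool
    n_iterations: int
    flags: list = field(default_factory=list)

    @property
    def sigma_p2(self) -> float:
        return float(sum(self.components.values()))

    @property
    def ratios(self) -> dict:
        """Variance ratios sigma_x^2 / sigma_p^2 (plus total genetic)."""
        sp = self.sigma_p2
        out = {f"{k}/sigma_p2": v / sp for k, v in self.components.items()}
        genetic = sum(v for k, v in self.components.items() if k != "sigma_e2")
        out["sigma_G2/sigma_p2"] = genetic / sp
        return out

    def summary(self) -> str:
        lines = [
            "Variance component estimation (AI-REML)",
            f"  model: {self.model.name}   n = {self.model.n}   "
            f"fixed-effect rank = {self.model.X.shape[1]}",
            f"  restricted log-likelihood: {self.loglik:.6f}",
            f"  converged: {self.converged} in {self.n_iterations} iterations",
        ]
        sp = self.sigma_p2
        lines.append(f"  {'component':<12}{'estimate':>14}{'SE':>12}{'ratio':>10}")
        for k, v in self.components.items():
            lines.append(f"  {k:<12}{v:>14.4f}{self.se.get(k, float('nan')):>12.4f}"
                         f"{v / sp:>10.3f}")
        lines.append(f"  {'sigma_p2':<12}{sp:>14.4f}")
        if self.flags:
            lines.append("  flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"components": self.components, "se": self.se,
                "sigma_p2": self.sigma_p2, "ratios": self.ratios,
                "loglik": self.loglik, "converged": self.converged,
                "n_iterations": self.n_iterations, "flags": self.flags}


class VarianceComponentModel:
    """Linear mixed model with named random covariance structures.

    Parameters
    ----------
    y : array (n,)
        Trait vector.
    X : array (n, p)
        Fixed-effect design (full column rank; collinear columns dropped).
    covariances : dict of name -> (n, n) ndarray
        One PSD covariance structure per genetic random effect
        (e.g. ``{"sigma_a2": G}`` or ``{"sigma_a2": G, "sigma_d2": D}``);
        the residual identity component ``sigma_e2`` is always appended.
    """

    def __init__(self, y, X, covariances: dict, name: str = "custom"):
        self.y = np.asarray(y, float).ravel()
        self.n = len(self.y)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("X and y have different lengths")
        self.X = drop_collinear(X)
        self.names = list(covariances) + ["sigma_e2"]
        self.K = []
        for k, mat in covariances.items():
            mat = mat.values if isinstance(mat, RelationshipMatrix) else np.asarray(mat, float)
            if mat.shape != (self.n, self.n):
                raise ValueError(f"covariance {k} has shape {mat.shape}, expected "
                                 f"({self.n}, {self.n})")
            self.K.append(mat)
        self.K.append(np.eye(self.n))
        self.name = name

    # -- restricted likelihood machinery ----------------------------------

    def _V(self, theta: np.ndarray) -> np.ndarray:
        V = theta[-1] * self.K[-1]
        for t, K in zip(theta[:-1], self.K[:-1]):
            V = V + t * K
        return V

    def _reml_pieces(self, theta: np.ndarray):
        """Return (loglik, P, Py) or (None, None, None) if V not PD."""
        V = self._V(theta)
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None, None, None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        XtVinv = self.X.T @ Vinv
        XtVinvX = XtVinv @ self.X
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return None, None, None
        B = np.linalg.solve(XtVinvX, XtVinv)
        P = Vinv - XtVinv.T @ B
        Py = P @ self.y
        n, p = self.n, self.X.shape[1]
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ Py)
                     + (n - p) * np.log(2.0 * np.pi))
        return ll, P, Py

    def loglike(self, theta) -> float:
        """Restricted log-likelihood at the given component values."""
        ll, _, _ = self._reml_pieces(np.asarray(theta, float))
        if ll is None:
            raise linalg.LinAlgError("V singular at the supplied components")
        return ll

    # -- fitting -----------------------------------------------------------

    def fit(self, start=None, max_iter: int = _MAX_ITER,
            tol: float = _LL_TOL) -> VarianceComponentResults:
        """AI-REML fit from one or several starting points.

        Without an explicit ``start``, several spread-out starting values
        are tried and the solution with the highest restricted likelihood
        kept — the surface can have boundary local optima when a component
        is weakly identified.
        """
        m = len(self.K)
        vary = float(np.var(self.y))
        if start is not None:
            starts = [np.asarray(start, float)]
        else:
            starts = [np.full(m, vary / m)]
        best = None
        for s in starts:
            cand = self._fit_single(s, max_iter, tol)
            if cand is None:
                continue
            if best is None or cand.loglik > best.loglik:
                best = cand
        if best is None:
            raise linalg.LinAlgError("could not initialize REML")
        return best

    def _fit_single(self, start, max_iter: int,
                    tol: float) -> VarianceComponentResults | None:
        m = len(self.K)
        vary = float(np.var(self.y))
        bound = 1e-8 * vary if vary > 0 else 1e-12
        theta = np.maximum(np.asarray(start, float).copy(), bound)
        flags: list[str] = []

        ll, P, Py = self._reml_pieces(theta)
        if ll is None:
            return None

        converged = False
        ai = np.eye(m)
        free = np.ones(m, bool)  # components not fixed at the lower bound
        at_bound_count = np.zeros(m, int)
        it = 0
        for it in range(1, max_iter + 1):
            KPy = [K @ Py for K in self.K]
            traces = np.array([float(np.sum(P * K)) for K in self.K])
            quads = np.array([float(Py @ v) for v in KPy])
            score = -0.5 * (traces - quads)
            PKPy = [P @ v for v in KPy]
            ai = 0.5 * np.array([[float(KPy[i] @ PKPy[j]) for j in range(m)]
                                 for i in range(m)])

            # components pinned at the bound re-enter only if the
            # likelihood gradient points inward
            free = free | (score > 0)
            fidx = np.flatnonzero(free)
            delta = np.zeros(m)
            try:
                delta[fidx] = np.linalg.solve(ai[np.ix_(fidx, fidx)], score[fidx])
            except np.linalg.LinAlgError:
                delta[fidx] = score[fidx] / np.maximum(np.diag(ai)[fidx], 1e-12)

            accepted = False
            for step in (1.0, 0.5, 0.1):
                cand = np.maximum(theta + step * delta, bound)
                cand[~free] = bound
                ll_new, P_new, Py_new = self._reml_pieces(cand)
                if ll_new is not None and ll_new >= ll - 1e-10:
                    accepted = True
                    break
            if not accepted:
                # EM update: theta_i + theta_i^2/n (y'PK_iPy - tr(PK_i))
                cand = theta + theta**2 / self.n * (quads - traces)
                cand = np.maximum(cand, bound)
                cand[~free] = bound
                ll_new, P_new, Py_new = self._reml_pieces(cand)
                if ll_new is None or ll_new < ll - 1e-6:
                    flags.append("update_failed")
                    break
            change = ll_new - ll
            theta, ll, P, Py = cand, ll_new, P_new, Py_new

            # pin components that keep collapsing to the bound with an
            # outward gradient, so the remaining ones converge quickly
            hit = theta <= bound * (1 + 1e-9)
            at_bound_count = np.where(hit, at_bound_count + 1, 0)
            free &= ~((at_bound_count >= 2) & (score <= 0))
            if abs(change) < tol:
                converged = True
                break

        if not converged and "update_failed" not in flags:
            flags.append("max_iterations")
        if np.any(theta <= bound * (1 + 1e-6)):
            flags.append("boundary")
        # weak identifiability: AI matrix close to singular
        try:
            cond = np.linalg.cond(ai)
        except np.linalg.LinAlgError:
            cond = np.inf
        se = {}
        if np.isfinite(cond) and cond < 1e8:
            ai_inv = np.linalg.inv(ai)
            se = {name: float(np.sqrt(max(ai_inv[i, i], 0.0)))
                  for i, name in enumerate(self.names)}
        else:
            flags.append("weak identifiability")
            se = {name: float("nan") for name in self.names}

        return VarianceComponentResults(
            model=self,
            components={name: float(t) for name, t in zip(self.names, theta)},
            se=se, loglik=float(ll), converged=converged,
            n_iterations=it, flags=flags)


def fit_model_a(y, X, G) -> VarianceComponentResults:
    """REML fit of the additive model y = Xb + u + e with u ~ N(0, G sigma_a^2)."""
    return VarianceComponentModel(y, X, {"sigma_a2": G}, name="A").fit()


def fit_model_ad(y, X, G, D) -> VarianceComponentResults:
    """REML fit of the additive-dominance model y = Xb + u + v + e.

    Model AD nests model A at sigma_d2 = 0, so in addition to the default
    starting points the optimizer is seeded from the model-A solution;
    the reported optimum therefore never falls below model A's restricted
    likelihood (up to convergence tolerance).
    """
    res_a = fit_model_a(y, X, G)
    model = VarianceComponentModel(y, X, {"sigma_a2": G, "sigma_d2": D},
                                   name="AD")
    vary = float(np.var(model.y))
    seed_a = np.array([res_a.components["sigma_a2"], 1e-8 * vary,
                       res_a.components["sigma_e2"]])
    best = model.fit()
    from_a = model.fit(start=seed_a)
    return from_a if from_a.loglik > best.loglik else best


def likelihood_profile(y, X, matrices: dict, grid) -> pd.DataFrame:
    """Evaluate the restricted log-likelihood on a grid of component values.

    ``matrices`` maps component names to covariance structures (the residual
    identity is appended automatically); ``grid`` is an iterable of
    component vectors in the same order, each including the residual last.
    Grid points where V is singular are marked invalid.  Serves as a direct
    (non-iterative) oracle for the REML optimizer.
    """
    model = VarianceComponentModel(y, X, matrices, name="profile")
    rows = []
    for point in grid:
        point = np.asarray(point, float)
        try:
            ll = model.loglike(point)
            valid = True
        except linalg.LinAlgError:
            ll, valid = float("nan"), False
        rows.append({**{n: v for n, v in zip(model.names, point)},
                     "loglik": ll, "valid": valid})
    return pd.DataFrame(rows)


def results_table(results: dict, trait_order=None) -> pd.DataFrame:
    """Stack per-trait/model results into a table of ratios (in %) and sigma_p2."""
    rows = []
    for (trait, model_name), res in results.items():
        r = res.ratios
        rows.append({
            "trait": trait, "model": model_name,
            "sigma_a2/sigma_p2_pct": 100 * r.get("sigma_a2/sigma_p2", np.nan),
            "sigma_d2/sigma_p2_pct": 100 * r.get("sigma_d2/sigma_p2", np.nan),
            "sigma_G2/sigma_p2_pct": 100 * r["sigma_G2/sigma_p2"],
            "sigma_p2": res.sigma_p2,
            "converged": res.converged})
    df = pd.DataFrame(rows)
    if trait_order is not None:
        df["trait"] = pd.Categorical(df["trait"], trait_order, ordered=True)
        df = df.sort_values(["trait", "model"]).reset_index(drop=True)
    return df
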