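"""Monotone cubic regression spline linking GN score to detection probability.

Metabolites with high GN scores are more likely to be measured in a
metabolomic profile and to be called differential. This module fits that
selection curve: a cubic regression spline with k knots (default 6)
placed at quantiles of the GN-score distribution, estimated by penalized
constrained least squares

    minimize ||Y - X beta||^2 + lambda * beta' S beta
    subject to the fitted curve being nondecreasing in GN,

where Y is the binary differential-label vector over the M network
metabolites, X the spline model matrix, and S the curvature penalty
(integrated squared second derivative). The fitted probability Yhat is
clamped into [0, 1] and the combined global nonequivalence and bias
(CGNB) score is C = 1 - Yhat: high C marks pathway-specific metabolites
that are hard to detect and hard to compensate for.

The spline is parameterized by its values at the knots with natural
boundary conditions (linear extrapolation outside the knot range), so
beta_i is the curve height at knot i; the basis spans constants, which
keeps the degenerate all-zero / all-one label cases exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, LinearConstraint

from .network_io import MetaboliteNetwork

logger = logging.getLogger(__name__)

DEFAULT_KNOTS = 6
_GRID_POINTS = 200
_LAMBDA_GRID = np.logspace(-6.0, 6.0, 40)


def make_labels(net: MetaboliteNetwork, interesting: set[str]) -> dict[str, int]:
    """Binary label per network metabolite: 1 if interesting, else 0."""
    nodes = net.nodes
    hit = interesting & nodes
    missing = len(interesting - nodes)
    if missing:
        logger.info("%d interesting metabolites absent from the network", missing)
    if not hit:
        raise ValueError("no interesting metabolites in network")
    return {n: (1 if n in hit else 0) for n in net.node_list()}


@dataclass
class SplineBasis:
    """Natural cubic regression spline on fixed knots, parameterized by knot values.

    ``design_matrix(x)`` maps the coefficient vector (curve heights at the
    knots) linearly to curve values at ``x``; ``penalty`` is the k x k
    positive-semidefinite matrix of the integrated squared second
    derivative. Twice continuously differentiable inside the knot range,
    linear outside (natural boundary conditions).
    """

    knots: np.ndarray
    _gamma_map: np.ndarray = field(init=False, repr=False)
    penalty: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        t = np.asarray(self.knots, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("need at least 3 strictly increasing knots")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = t
        k = len(t)
        h = np.diff(t)
        # Green-Silverman band matrices: gamma_interior = R^{-1} Q^T g
        q = np.zeros((k, k - 2))
        r = np.zeros((k - 2, k - 2))
        for j in range(k - 2):
            q[j, j] = 1.0 / h[j]
            q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
            q[j + 2, j] = 1.0 / h[j + 1]
            r[j, j] = (h[j] + h[j + 1]) / 3.0
            if j + 1 < k - 2:
                r[j, j + 1] = r[j + 1, j] = h[j + 1] / 6.0
        f = np.linalg.solve(r, q.T)  # (k-2) x k
        gamma = np.zeros((k, k))
        gamma[1:-1, :] = f  # second derivatives at knots as linear map of g
        self._gamma_map = gamma
        self.penalty = q @ f  # integral of s''(x)^2 = g' (Q R^{-1} Q^T) g

    @property
    def k(self) -> int:
        return len(self.knots)

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Rows phi(x_j, .) mapping knot values to spline values at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        t, k, gamma = self.knots, self.k, self._gamma_map
        h = np.diff(t)
        out = np.zeros((len(x), k))
        eye = np.eye(k)

        # boundary slopes (linear maps of g) for natural extrapolation
        d_left = (eye[1] - eye[0]) / h[0] - (h[0] / 6.0) * gamma[1]
        d_right = (eye[k - 1] - eye[k - 2]) / h[-1] + (h[-1] / 6.0) * gamma[k - 2]

        lo = x < t[0]
        hi = x > t[-1]
        mid = ~(lo | hi)
        if lo.any():
            out[lo] = eye[0] + np.outer(x[lo] - t[0], d_left)
        if hi.any():
            out[hi] = eye[k - 1] + np.outer(x[hi] - t[-1], d_right)
        if mid.any():
            xm = x[mid]
            i = np.clip(np.searchsorted(t, xm, side="right") - 1, 0, k - 2)
            hi_ = h[i]
            a = (t[i + 1] - xm) / hi_
            b = (xm - t[i]) / hi_
            c = (a**3 - a) * hi_**2 / 6.0
            d = (b**3 - b) * hi_**2 / 6.0
            out[mid] = (
                a[:, None] * eye[i]
                + b[:, None] * eye[i + 1]
                + c[:, None] * gamma[i]
                + d[:, None] * gamma[i + 1]
            )
        return out


def build_basis(gn: dict[str, float], k: int = DEFAULT_KNOTS) -> SplineBasis:
    """Knots at the (i-1)/(k-1) quantiles of the GN-score distribution.

    Duplicate knots (heavy ties in GN) are collapsed with k reduced and a
    warning; constant GN scores are a degenerate covariate and an error.
    """
    values = np.asarray(list(gn.values()), dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("GN scores are constant: degenerate covariate")
    if len(np.unique(values)) < k:
        raise ValueError(f"need at least {k} distinct GN values")
    knots = np.quantile(values, np.linspace(0.0, 1.0, k))
    unique = np.unique(knots)
    if len(unique) < len(knots):
        logger.warning("collapsed %d duplicate knots", len(knots) - len(unique))
    if len(unique) < 3:
        raise ValueError("fewer than 3 distinct knots after collapsing duplicates")
    return SplineBasis(unique)


@dataclass
class BiasFit:
    """Fitted monotone selection curve and derived CGNB scores.

    Results object of :class:`MonotoneBiasModel` / :func:`fit_monotone_spline`.
    ``beta`` are the curve heights at the knots, ``fitted`` the clamped
    selection probabilities Yhat per metabolite, ``cgnb`` the scores
    C = 1 - Yhat, ``residuals`` the raw (unclamped) residuals Y - X beta.
    """

    basis: SplineBasis
    beta: np.ndarray
    lambda_: float
    fitted: dict[str, float]
    cgnb: dict[str, float]
    residuals: dict[str, float]
    gn: dict[str, float]
    labels: dict[str, int]

    @property
    def penalty(self) -> np.ndarray:
        return self.basis.penalty

    def predict(self, x) -> np.ndarray:
        """Clamped fitted selection probability at arbitrary GN scores."""
        raw = self.basis.design_matrix(np.asarray(x, dtype=float)) @ self.beta
        return np.clip(raw, 0.0, 1.0)

    def summary(self) -> str:
        n1 = sum(self.labels.values())
        lines = [
            "Monotone spline bias fit",
            f"  metabolites: {len(self.labels)}  (interesting: {n1})",
            f"  knots: {np.array2string(self.basis.knots, precision=4)}",
            f"  beta:  {np.array2string(self.beta, precision=4)}",
            f"  lambda: {self.lambda_:.4g}",
            f"  fitted range: [{min(self.fitted.values()):.4f}, "
            f"{max(self.fitted.values()):.4f}]",
        ]
        return "\n".join(lines)


def _solve_penalized(xtx, xty, s, lam):
    return np.linalg.solve(xtx + lam * s, xty)


def _gcv_lambda(x, y, s):
    """Generalized cross-validation over a fixed logarithmic lambda grid.

    Computed on the unconstrained ridge path; the monotonicity constraint
    is applied afterwards at the selected lambda.
    """
    n = len(y)
    xtx = x.T @ x
    xty = x.T @ y
    best_lam, best_score = _LAMBDA_GRID[0], np.inf
    for lam in _LAMBDA_GRID:
        a = xtx + lam * s
        try:
            beta = np.linalg.solve(a, xty)
            trace_h = np.trace(np.linalg.solve(a, xtx))
        except np.linalg.LinAlgError:
            continue
        rss = float(np.sum((y - x @ beta) ** 2))
        denom = n - trace_h
        if denom <= 0:
            continue
        score = n * rss / denom**2
        if score < best_score:
            best_score, best_lam = score, lam
    return best_lam


def _polish_active_set(beta, h, c, constraints):
    """Refine an approximate QP solution by an exact KKT solve on the active set.

    SLSQP leaves O(1e-8) constraint slack; re-solving the equality-
    constrained problem on the (near-)active constraints removes it. The
    polished point is kept only if it stays feasible and improves the
    objective, so this can never make the solution worse.
    """
    slack = constraints @ beta
    scale = max(1.0, float(np.abs(slack).max()))
    active = constraints[slack <= 1e-6 * scale]
    if active.shape[0] == 0:
        return beta
    k = len(beta)
    m = active.shape[0]
    kkt = np.block([[h, active.T], [active, np.zeros((m, m))]])
    rhs = np.concatenate([c, np.zeros(m)])
    try:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    except np.linalg.LinAlgError:
        return beta
    cand = sol[:k]
    feasible = (constraints @ cand).min() >= -1e-12
    def obj(b):
        return 0.5 * b @ h @ b - c @ b
    if feasible and obj(cand) <= obj(beta) + 1e-12:
        return cand
    return beta


def fit_monotone_spline(
    basis: SplineBasis,
    gn: dict[str, float],
    labels: dict[str, int],
    lambda_strategy="gcv",
) -> BiasFit:
    """Penalized least squares with a nondecreasing-curve constraint.

    The monotonicity constraint is enforced as first-difference
    inequalities of the fitted curve on a 200-point grid spanning the GN
    range, solved as a quadratic program. ``lambda_strategy`` is either
    the string ``"gcv"`` or a fixed nonnegative smoothing parameter.
    """
    nodes = list(gn.keys())
    if set(labels) != set(nodes):
        raise ValueError("labels must be defined on exactly the GN table's metabolites")
    x_gn = np.asarray([gn[n] for n in nodes], dtype=float)
    y = np.asarray([labels[n] for n in nodes], dtype=float)
    x = basis.design_matrix(x_gn)
    k = basis.k
    if len(y) < k:
        raise ValueError(f"fewer observations ({len(y)}) than coefficients ({k})")
    s = basis.penalty

    if lambda_strategy == "gcv":
        lam = _gcv_lambda(x, y, s)
    else:
        lam = float(lambda_strategy)
        if lam < 0:
            raise ValueError("lambda must be >= 0")

    xtx = x.T @ x
    xty = x.T @ y
    # ridge regularisation floor keeps the system solvable when lam == 0
    # and X is rank deficient; negligible otherwise
    h = xtx + lam * s + 1e-12 * np.eye(k)

    grid = np.linspace(x_gn.min(), x_gn.max(), _GRID_POINTS)
    g_design = basis.design_matrix(grid)
    diff = np.diff(g_design, axis=0)  # (grid-1) x k rows of first differences

    beta = np.linalg.solve(h, xty)
    tol = 1e-10 * max(1.0, float(np.abs(diff @ beta).max()))
    if np.all(diff @ beta >= -tol):
        beta_hat = beta
    else:
        # quadratic program: 0.5 b'Hb - c'b  s.t.  diff @ b >= 0
        def obj(b):
            return 0.5 * b @ h @ b - xty @ b

        def jac(b):
            return h @ b - xty

        start = np.full(k, float(y.mean()))  # constants are always feasible
        res = minimize(
            obj,
            start,
            jac=jac,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda b: diff @ b, "jac": lambda b: diff}],
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if not res.success:
            res = minimize(
                obj,
                start,
                jac=jac,
                hess=lambda b: h,
                method="trust-constr",
                constraints=[LinearConstraint(diff, 0.0, np.inf)],
                options={"maxiter": 2000, "gtol": 1e-12, "xtol": 1e-14},
            )
            if not res.success:
                raise RuntimeError(f"monotone QP failed to converge: {res.message}")
        beta_hat = _polish_active_set(res.x, h, xty, diff)
        viol = float((diff @ beta_hat).min())
        if viol < -1e-8:
            raise RuntimeError(f"monotonicity violated after QP (min diff {viol:.3g})")

    raw = x @ beta_hat
    fitted = np.clip(raw, 0.0, 1.0)
    return BiasFit(
        basis=basis,
        beta=beta_hat,
        lambda_=lam,
        fitted={n: float(v) for n, v in zip(nodes, fitted)},
        cgnb={n: float(1.0 - v) for n, v in zip(nodes, fitted)},
        residuals={n: float(r) for n, r in zip(nodes, y - raw)},
        gn=dict(gn),
        labels={n: int(v) for n, v in zip(nodes, y)},
    )


def cgnb(fit: BiasFit) -> dict[str, float]:
    """CGNB scores C = 1 - Yhat per metabolite."""
    return dict(fit.cgnb)


class MonotoneBiasModel:
    """Model object: GN scores + binary labels -> monotone selection curve.

    Parameters
    ----------
    gn : mapping metabolite id -> GN score.
    labels : mapping metabolite id -> {0, 1}; 1 marks interesting
        (differential) metabolites. Must cover exactly the GN table.
    k : number of spline knots (quantile-placed), default 6.
    """

    def __init__(self, gn: dict[str, float], labels: dict[str, int], k: int = DEFAULT_KNOTS):
        self.gn = dict(gn)
        self.labels = dict(labels)
        self.k = k
        self.basis = build_basis(self.gn, k)

    @classmethod
    def from_network(
        cls, net: MetaboliteNetwork, gn: dict[str, float], interesting: set[str], k: int = DEFAULT_KNOTS
    ) -> "MonotoneBiasModel":
        return cls(gn, make_labels(net, interesting), k)

    def fit(self, lambda_strategy="gcv") -> BiasFit:
        return fit_monotone_spline(self.basis, self.gn, self.labels, lambda_strategy)


def write_cgnb(fit: BiasFit, path) -> None:
    """CGNB table TSV: metabolite_id, gn_score, fitted_prob, cgnb."""
    with open(path, "w") as fh:
        fh.write("metabolite_id\tgn_score\tfitted_prob\tcgnb\n")
        for n in sorted(fit.gn, key=int):
            fh.write(
                f"{n}\t{fit.gn[n]:.10g}\t{fit.fitted[n]:.10g}\t{fit.cgnb[n]:.10g}\n"
            )
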