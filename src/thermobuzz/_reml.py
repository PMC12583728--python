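"""REML machinery for linear mixed models with crossed random intercepts.

The models fitted throughout this package have the structure

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, s2_k I),  e ~ N(0, s2_e I),

with a small number of crossed grouping factors (species, caste), each
contributing a random intercept per level.  Because the total number of
random-effect columns q is tiny (tens) while n is a few hundred, all
V-inverse quantities are computed through the Woodbury identity on a q x q
core matrix, which makes a full REML fit a few milliseconds — fast enough
for the bootstrap resampling loops used downstream.

The Satterthwaite denominator degrees of freedom are computed from the
observed information of the REML criterion in the variance parameters
(numeric Hessian) and a numeric gradient of the contrast variance, the same
construction used for mixed-model t/F tests in the mixed-modelling
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)
# variance ratios below this (relative to residual) are treated as boundary
_SINGULAR_RATIO = 1e-6


@dataclass
class RandomStructure:
    """Indicator design for crossed random intercepts.

    ``z_index[k]`` maps each observation to a level code of factor ``k``;
    ``names[k]`` is the factor name; ``n_levels[k]`` its level count.
    """

    names: list[str]
    z_index: list[np.ndarray]
    n_levels: list[int]

    @classmethod
    def from_frame(cls, data, factors: list[str]) -> "RandomStructure":
        names, idx, nlev = [], [], []
        for f in factors:
            levels, inv = np.unique(np.asarray(data[f]), return_inverse=True)
            names.append(f)
            idx.append(inv.astype(np.int64))
            nlev.append(len(levels))
        return cls(names, idx, nlev)

    def z_matrix(self, n: int | None = None) -> np.ndarray:
        if n is None:
            n = len(self.z_index[0]) if self.z_index else 0
        cols = []
        for inv, q in zip(self.z_index, self.n_levels):
            z = np.zeros((n, q))
            z[np.arange(n), inv] = 1.0
            cols.append(z)
        return np.hstack(cols) if cols else np.zeros((n, 0))

    @property
    def block_sizes(self) -> list[int]:
        return list(self.n_levels)


@dataclass
class RemlResult:
    """A fitted crossed-random-intercept mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float                      # residual variance
    vcomp: dict[str, float]            # variance per grouping factor
    loglik: float                      # REML log-likelihood at the optimum
    converged: bool
    singular: bool                     # any variance component at boundary
    n: int
    p: int
    theta: np.ndarray = field(repr=False, default=None)       # (s2_1..K, s2_e)
    theta_cov: np.ndarray = field(repr=False, default=None)
    _core: "_WoodburyCore" = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


class _WoodburyCore:
    """Sufficient statistics and profiled criteria for one (y, X, Z) triple."""

    def __init__(self, y: np.ndarray, X: np.ndarray, struct: RandomStructure):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        self.y, self.X, self.struct = y, X, struct
        self.n, self.p = X.shape
        Z = struct.z_matrix(self.n)
        self.q = Z.shape[1]
        self.blocks = struct.block_sizes
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        """Per-column variance ratio from per-block ratios."""
        return np.repeat(gamma, self.blocks)

    def gls_pieces(self, gamma: np.ndarray):
        """Return (XtVX, XtVy, yVy, logdetV0) for V0 = I + Z diag(g) Z'."""
        g = self._expand(np.asarray(gamma, float))
        if self.q == 0 or np.all(g <= 0):
            return self.XtX, self.Xty, self.yty, 0.0
        s = np.sqrt(np.clip(g, 0.0, None))
        M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        cf = np.linalg.cholesky(M)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(cf))))
        A = s[:, None] * self.ZtX
        a = s * self.Zty
        MiA = np.linalg.solve(M, A)
        Mia = np.linalg.solve(M, a)
        XtVX = self.XtX - A.T @ MiA
        XtVy = self.Xty - A.T @ Mia
        yVy = self.yty - float(a @ Mia)
        return XtVX, XtVy, yVy, logdetV0

    def profiled_reml(self, log_gamma: np.ndarray) -> float:
        """Negative REML criterion profiled over beta and residual variance."""
        gamma = np.exp(np.asarray(log_gamma, float))
        XtVX, XtVy, yVy, logdetV0 = self.gls_pieces(gamma)
        try:
            cf = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - float(beta @ XtVy)
        if rss <= 0:
            return np.inf
        nmp = self.n - self.p
        s2 = rss / nmp
        logdetXtVX = 2.0 * float(np.sum(np.log(np.diag(cf))))
        return 0.5 * (nmp * (np.log(s2) + 1.0 + _LOG2PI) + logdetV0 + logdetXtVX)

    def reml_at_theta(self, theta: np.ndarray) -> float:
        """REML log-likelihood at explicit variances theta = (s2_1..K, s2_e)."""
        theta = np.asarray(theta, float)
        s2_e = theta[-1]
        if s2_e <= 0 or np.any(theta[:-1] < 0):
            return -np.inf
        gamma = theta[:-1] / s2_e
        XtVX, XtVy, yVy, logdetV0 = self.gls_pieces(gamma)
        try:
            cf = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return -np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - float(beta @ XtVy)
        nmp = self.n - self.p
        logdetXtVX = 2.0 * float(np.sum(np.log(np.diag(cf))))
        return -0.5 * (
            nmp * np.log(s2_e)
            + logdetV0
            + logdetXtVX
            + rss / s2_e
            + nmp * _LOG2PI
        )

    def cov_beta_at_theta(self, theta: np.ndarray) -> np.ndarray:
        s2_e = theta[-1]
        gamma = np.clip(theta[:-1], 0.0, None) / s2_e
        XtVX = self.gls_pieces(gamma)[0]
        return s2_e * np.linalg.inv(XtVX)

    def profiled_ml(self, log_gamma: np.ndarray) -> float:
        """Negative ML criterion (for likelihood-based AIC comparisons)."""
        gamma = np.exp(np.asarray(log_gamma, float))
        XtVX, XtVy, yVy, logdetV0 = self.gls_pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - float(beta @ XtVy)
        if rss <= 0:
            return np.inf
        s2 = rss / self.n
        return 0.5 * (self.n * (np.log(s2) + 1.0 + _LOG2PI) + logdetV0)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    struct: RandomStructure,
    method: str = "reml",
    start_log_gamma: np.ndarray | None = None,
    xatol: float = 1e-8,
) -> RemlResult:
    """Fit the crossed-random-intercept model by (RE)ML.

    The 1–2 dimensional profiled criterion is minimised over log variance
    ratios with Nelder–Mead from a neutral start; ratios driven to the
    lower bound are reported as boundary (singular) components.
    """
    core = _WoodburyCore(y, X, struct)
    K = len(core.blocks)
    objective = core.profiled_reml if method == "reml" else core.profiled_ml
    if K == 0:
        res_x = np.zeros(0)
        converged = True
    else:
        start = np.zeros(K) if start_log_gamma is None else np.asarray(start_log_gamma, float)
        opt = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": xatol * 1e-2, "maxiter": 2000},
        )
        res_x, converged = opt.x, bool(opt.success)
    gamma = np.exp(res_x)
    gamma[gamma < _SINGULAR_RATIO] = 0.0
    singular = bool(np.any(gamma == 0.0)) and K > 0

    XtVX, XtVy, yVy, _ = core.gls_pieces(gamma)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = yVy - float(beta @ XtVy)
    denom = core.n - core.p if method == "reml" else core.n
    s2_e = rss / denom
    cov_beta = s2_e * np.linalg.inv(XtVX)
    theta = np.append(gamma * s2_e, s2_e)
    loglik = core.reml_at_theta(theta) if method == "reml" else -core.profiled_ml(np.log(np.clip(gamma, 1e-300, None)))
    vcomp = {nm: float(v) for nm, v in zip(struct.names, theta[:-1])}
    return RemlResult(
        beta=beta, cov_beta=cov_beta, sigma2=float(s2_e), vcomp=vcomp,
        loglik=float(loglik), converged=converged, singular=singular,
        n=core.n, p=core.p, theta=theta, theta_cov=None, _core=core,
    )


def theta_covariance(fit: RemlResult) -> np.ndarray:
    """Covariance of the variance parameters from the observed information.

    Central-difference Hessian of the REML log-likelihood at the optimum;
    boundary components get a zero row/column (their uncertainty does not
    enter the Satterthwaite sum).
    """
    if fit.theta_cov is not None:
        return fit.theta_cov
    core = fit._core
    theta = fit.theta
    m = len(theta)
    free = [i for i in range(m) if theta[i] > 0]
    H = np.zeros((m, m))
    h = np.array([max(1e-7, 1e-4 * abs(t)) for t in theta])

    def f(t):
        return core.reml_at_theta(t)

    for ii, i in enumerate(free):
        for j in free[ii:]:
            ti = theta.copy()
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                if tm[i] <= 0:
                    tm[i] = theta[i] / 2.0
                val = (f(tp) - 2.0 * f(theta) + f(tm)) / ((tp[i] - theta[i]) * (theta[i] - tm[i]))
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h[i]; tpp[j] += h[j]
                tpm[i] += h[i]; tpm[j] -= h[j]
                tmp[i] -= h[i]; tmp[j] += h[j]
                tmm[i] -= h[i]; tmm[j] -= h[j]
                val = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    cov = np.zeros((m, m))
    if free:
        sub = -H[np.ix_(free, free)]
        try:
            sub_inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            sub_inv = np.linalg.pinv(sub)
        cov[np.ix_(free, free)] = sub_inv
    fit.theta_cov = cov
    return cov


def satterthwaite_df(fit: RemlResult, contrast: np.ndarray) -> float:
    """Satterthwaite denominator df for a single contrast l'beta.

    df = 2 g^2 / (grad_g' Cov(theta) grad_g) with g(theta) = l' C(theta) l.
    Variance components estimated on the boundary contribute no
    uncertainty (their covariance rows are zero), matching the reference
    mixed-model implementations; if no variance parameter is free the df
    degenerates to inf and callers fall back to Wald chi-square tests.
    """
    core = fit._core
    l = np.asarray(contrast, float)
    cov_t = theta_covariance(fit)
    theta = fit.theta

    def g(t):
        return float(l @ core.cov_beta_at_theta(t) @ l)

    m = len(theta)
    grad = np.zeros(m)
    for i in range(m):
        h = max(1e-7, 1e-4 * abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, theta[i] / 2.0)
        grad[i] = (g(tp) - g(tm)) / (tp[i] - tm[i])
    g0 = g(theta)
    denom = float(grad @ cov_t @ grad)
    if denom <= 0:
        return np.inf
    df = 2.0 * g0 * g0 / denom
    return float(df)


def satterthwaite_f(fit: RemlResult, L: np.ndarray) -> tuple[float, float, float]:
    """Type III style F test of L beta = 0 with Satterthwaite denominator df.

    Multi-row L uses the eigencontrast combination: the contrast variance
    matrix is diagonalised, each eigencontrast gets its own Satterthwaite
    df, and the dfs are pooled so the F statistic keeps its first moment.
    Returns (F, df_num, df_den).
    """
    L = np.atleast_2d(np.asarray(L, float))
    qdf = np.linalg.matrix_rank(L)
    LCL = L @ fit.cov_beta @ L.T
    Lb = L @ fit.beta
    F = float(Lb @ np.linalg.solve(LCL, Lb)) / qdf
    if qdf == 1:
        return F, 1.0, satterthwaite_df(fit, L[0])
    # eigencontrast pooling
    w, P = np.linalg.eigh(LCL)
    keep = w > 1e-12 * w.max()
    nus = []
    for vec in P.T[keep]:
        nus.append(satterthwaite_df(fit, vec @ L))
    nus = np.asarray(nus)
    finite = nus[np.isfinite(nus) & (nus > 2.0)]
    if len(finite) < len(nus) or len(finite) == 0:
        return F, float(qdf), np.inf
    E = float(np.sum(finite / (finite - 2.0)))
    df_den = 2.0 * E / (E - qdf) if E > qdf else np.inf
    return F, float(qdf), df_den
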