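"""Linear (mixed) models for per-bee buzz properties.

Fits the field-analysis model family: a response (per-bee mean fundamental
frequency, peak acceleration, or buzz duration) against mass, temperature
(optionally with a quadratic term), and distribution class, with species
and caste as crossed random intercepts.  When no random intercepts are
requested the same code path reduces exactly to ordinary least squares,
which is how the caste-complete subset models are fitted.

Categorical fixed effects always use sum-to-zero contrasts: Type III
(marginal) F tests are contrast-dependent and only meaningful under a
sum-to-zero parameterisation, so this is fixed rather than configurable.
Denominator degrees of freedom use the Satterthwaite approximation; for
singular fits (a variance component on the boundary) large-sample Wald
chi-square tests are reported and labelled as such.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from ._reml import RandomStructure, RemlResult, fit_reml, satterthwaite_f

logger = logging.getLogger(__name__)

CATEGORICAL_WRAP = "C({col}, Sum)"


@dataclass
class ModelSpec:
    """Declarative description of one model.

    ``fixed_terms`` are formula terms (patsy syntax); bare names of
    categorical columns are automatically wrapped in sum-to-zero contrast
    coding.  ``random_intercepts`` lists grouping columns; empty means OLS.
    """

    response: str
    fixed_terms: list[str]
    random_intercepts: list[str] = field(default_factory=list)
    data_filter: str | None = None

    def formula(self, data: pd.DataFrame) -> str:
        cats = [c for c in data.columns
                if data[c].dtype == object or isinstance(data[c].dtype, pd.CategoricalDtype)]
        terms = [_wrap_categoricals(t, cats) for t in self.fixed_terms]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"


def _wrap_categoricals(term: str, cat_cols: list[str]) -> str:
    out = term
    for c in cat_cols:
        # leave alone if already wrapped in a function call
        out = re.sub(rf"(?<![\w.(]){re.escape(c)}(?![\w.(])", CATEGORICAL_WRAP.format(col=c), out)
    return out


@dataclass
class LmmFit:
    """A fitted model with everything downstream stages need."""

    spec: ModelSpec
    coefficients: pd.DataFrame          # index: coefficient name; est, se
    varcomps: dict[str, float]
    residual_var: float
    conditional_r2: float
    n_bees: int
    converged: bool
    singular: bool
    loglik: float
    reml: RemlResult = field(repr=False)
    design_info: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    n_dropped: int = 0

    @property
    def beta(self) -> np.ndarray:
        return self.reml.beta

    @property
    def cov_beta(self) -> np.ndarray:
        return self.reml.cov_beta

    def _coef_name(self, pattern: str) -> str:
        names = list(self.coefficients.index)
        if pattern in names:
            return pattern
        norm = pattern.replace(" ", "")
        exact = [n for n in names if n.replace(" ", "") == norm]
        if exact:
            return exact[0]
        hits = [n for n in names if pattern in n]
        if not hits:
            raise KeyError(f"no coefficient matching {pattern!r}")
        return hits[0]

    def coef(self, pattern: str) -> float:
        """Coefficient by exact (whitespace-insensitive) or substring name."""
        return float(self.coefficients.loc[self._coef_name(pattern), "estimate"])

    def wald_ci(self, pattern: str, level: float = 0.95) -> tuple[float, float]:
        name = self._coef_name(pattern)
        est = float(self.coefficients.loc[name, "estimate"])
        se = float(self.coefficients.loc[name, "se"])
        z = stats.norm.ppf(0.5 + level / 2.0)
        return est - z * se, est + z * se


def fit_model(spec: ModelSpec, data: pd.DataFrame, **reml_kwargs) -> LmmFit:
    """Fit ``spec`` to per-bee data by REML (or OLS when no random terms).

    Rows with missing values in any used column are dropped with a logged
    count (e.g. queens without a mass measurement when mass is a predictor).
    """
    cols = _columns_used(spec, data)
    usable = data.dropna(subset=[c for c in cols if c in data.columns])
    n_dropped = len(data) - len(usable)
    if n_dropped:
        logger.info("fit_model: dropped %d rows with missing values in %s",
                    n_dropped, cols)
    ymat, X = patsy.dmatrices(spec.formula(usable), usable, return_type="dataframe")
    y = np.asarray(ymat).ravel()
    struct = RandomStructure.from_frame(usable, spec.random_intercepts)
    for nm, q in zip(struct.names, struct.n_levels):
        if q < 2:
            raise ValueError(f"random grouping {nm!r} has fewer than 2 levels")
    res = fit_reml(y, np.asarray(X), struct, **reml_kwargs)
    coefs = pd.DataFrame(
        {"estimate": res.beta, "se": res.se}, index=list(X.columns)
    )
    fit = LmmFit(
        spec=spec, coefficients=coefs, varcomps=res.vcomp,
        residual_var=res.sigma2, conditional_r2=np.nan, n_bees=len(usable),
        converged=res.converged, singular=res.singular, loglik=res.loglik,
        reml=res, design_info=X.design_info, data=usable, n_dropped=n_dropped,
    )
    fit.conditional_r2 = conditional_r2(fit)
    return fit


def _columns_used(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    names = set()
    for t in spec.fixed_terms + [spec.response] + spec.random_intercepts:
        names.update(re.findall(r"[A-Za-z_]\w*", t))
    return [c for c in data.columns if c in names]


def type3_table(fit: LmmFit) -> pd.DataFrame:
    """Type III marginal F tests per fixed-effect term.

    Under sum-to-zero contrasts the marginal test of each term's
    coefficient block is the Type III test.  Satterthwaite denominator df;
    for OLS fits the construction recovers the classical residual df
    exactly, and for singular mixed fits large-sample Wald chi-square
    p-values are reported (method column says which).
    """
    di = fit.design_info
    rows = []
    p_tot = len(fit.beta)
    for term, slc in di.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(p_tot)[slc]
        L = np.zeros((len(idx), p_tot))
        L[np.arange(len(idx)), idx] = 1.0
        F, dfn, dfd = satterthwaite_f(fit.reml, L)
        if np.isfinite(dfd):
            p = stats.f.sf(F, dfn, dfd)
            method = "satterthwaite"
        else:
            p = stats.chi2.sf(F * dfn, dfn)
            method = "wald-chi2"
        rows.append((term, F, dfn, dfd, p, method))
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p", "method"])


def conditional_r2(fit: LmmFit) -> float:
    """Nakagawa–Schielzeth conditional R-squared.

    (var_fixed + sum var_random) / (var_fixed + sum var_random + var_resid)
    with var_fixed the variance of the fixed-effect linear predictor over
    the modelled data.
    """
    eta = fit.reml._core.X @ fit.beta
    var_f = float(np.var(eta))
    var_r = float(sum(fit.varcomps.values()))
    denom = var_f + var_r + fit.residual_var
    return (var_f + var_r) / denom if denom > 0 else 0.0


def stepwise_reduce(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    optional_terms: list[str] | None = None,
) -> tuple[ModelSpec, list[dict]]:
    """Backward-eliminate non-significant interaction (then optional) terms.

    At each step the least significant interaction with Type III p > alpha
    is removed and the model refitted; once no removable interaction
    remains, the same rule is applied to ``optional_terms`` (e.g. a
    quadratic temperature term or a location effect).  Main effects are
    never removed.  Returns the final spec and a removal log.
    """
    optional_terms = list(optional_terms or [])
    current = replace(spec, fixed_terms=list(spec.fixed_terms))
    log: list[dict] = []

    def removable(terms: list[str], phase: str) -> list[str]:
        if phase == "interaction":
            return [t for t in terms if ":" in t or "*" in t]
        return [t for t in terms if t in optional_terms]

    for phase in ("interaction", "optional"):
        while True:
            cands = removable(current.fixed_terms, phase)
            if not cands:
                break
            fit = fit_model(current, data)
            t3 = type3_table(fit).set_index("term")
            # match spec terms to design terms by name normalisation
            pvals = {}
            for t in cands:
                key = _match_term(t, list(t3.index), data)
                if key is not None:
                    pvals[t] = float(t3.loc[key, "p"])
            if not pvals:
                break
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= alpha:
                break
            current.fixed_terms.remove(worst)
            log.append({"phase": phase, "removed": worst, "p": pvals[worst]})
        if not current.fixed_terms:
            break
    return current, log


def _match_term(term: str, design_terms: list[str], data: pd.DataFrame) -> str | None:
    cats = [c for c in data.columns
            if data[c].dtype == object or isinstance(data[c].dtype, pd.CategoricalDtype)]
    wrapped = _wrap_categoricals(term, cats).replace(" ", "")
    plain = term.replace(" ", "")
    for dt in design_terms:
        dt_norm = dt.replace(" ", "")
        if dt_norm in (wrapped, plain):
            return dt
        if set(dt_norm.split(":")) == set(wrapped.split(":")):
            return dt
    return None


def model_aic(fit: LmmFit) -> float:
    """Gaussian ML AIC: refit by maximum likelihood at the spec, count
    fixed effects + variance parameters."""
    ml = fit_model(fit.spec, fit.data, method="ml")
    k = len(ml.beta) + len(ml.varcomps) + 1
    return float(-2.0 * ml.loglik + 2 * k)
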