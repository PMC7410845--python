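"""Binomial-logit mixed models with crossed random intercepts.

Fits models of the form

    logit P(y = 1) = X beta + sum_k Z_k u_k,   u_k ~ N(0, sigma_k^2 I)

by the Laplace approximation: for candidate variance components the joint
penalized log-likelihood is maximized over (beta, u) with Newton steps, and
the marginal likelihood is approximated at the joint mode.  The variance
components are then profiled with a derivative-free outer optimization.
This matches the default estimation strategy of lme4::glmer (nAGQ = 1),
against which the implementation is validated in the test-suite.

Wald statistics are reported for the fixed effects: standard errors come
from the Schur complement of the joint Hessian at the optimum, z = beta/se,
and p-values are two-sided normal.

The model sizes this package fits (tens of participants, a handful of tone
categories, thousands of Bernoulli trials) keep all matrices small, so the
implementation is dense throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_INNER_TOL = 1e-6
_MAX_ABS_COEF = 15.0  # |logit| beyond this flags quasi-separation


@dataclass
class MixedModelFit:
    """Summary of a mixed-model fit (binomial GLMM or linear LMM).

    ``params``/``bse``/``z``/``p`` are indexed by term name; variance
    components are per grouping factor (plus ``residual`` for linear
    models).  ``diagnostics`` collects human-readable warnings
    (separation, non-convergence, singular fits); ``converged`` is False
    whenever estimation could not be trusted.
    """

    formula: str
    params: pd.Series
    bse: pd.Series
    z: pd.Series
    p: pd.Series
    converged: bool
    vc: dict
    reference_levels: dict = field(default_factory=dict)
    diagnostics: list = field(default_factory=list)
    method: str = "laplace-glmm"
    n_obs: int = 0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.z, "p": self.p}
        )

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "method": self.method,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "terms": self.summary_frame().to_dict(orient="index"),
            "variance_components": self.vc,
            "reference_levels": dict(self.reference_levels),
            "diagnostics": list(self.diagnostics),
        }


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def build_design(
    data: pd.DataFrame,
    terms: list[str],
    reference_levels: dict | None = None,
) -> pd.DataFrame:
    """Treatment-coded fixed-effects design matrix with intercept.

    ``terms`` may be column names (categorical columns are dummy-coded
    against their reference level, numeric columns enter as-is) or
    two-way interactions written ``"a:b"`` (elementwise products of the
    coded columns).
    """
    refs = dict(reference_levels or {})
    coded: dict[str, pd.DataFrame] = {}

    def code(term: str) -> pd.DataFrame:
        if term in coded:
            return coded[term]
        col = data[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = str(refs.get(term, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {term!r}")
            refs[term] = ref
            block = pd.DataFrame(
                {
                    f"{term}[{lev}]": (col.astype(str) == lev).astype(float)
                    for lev in levels
                    if lev != ref
                }
            )
        else:
            block = pd.DataFrame({term: col.astype(float)})
        coded[term] = block
        return block

    parts = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            left, right = code(a), code(b)
            inter = {}
            for la in left.columns:
                for lb in right.columns:
                    inter[f"{la}:{lb}"] = left[la].to_numpy() * right[lb].to_numpy()
            parts.append(pd.DataFrame(inter, index=data.index))
        else:
            parts.append(code(term).set_index(data.index))
    X = pd.concat(parts, axis=1)
    X.attrs["reference_levels"] = refs
    return X


def _random_effects_matrix(data: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[int], list[str]]:
    blocks, sizes = [], []
    for fac in factors:
        codes, levels = pd.factorize(data[fac].astype(str), sort=True)
        if len(levels) < 2:
            raise ValueError(f"grouping factor {fac!r} needs >= 2 levels")
        Z = np.zeros((len(data), len(levels)))
        Z[np.arange(len(data)), codes] = 1.0
        blocks.append(Z)
        sizes.append(len(levels))
    return np.hstack(blocks), sizes, list(factors)


# ---------------------------------------------------------------------------
# Laplace fit
# ---------------------------------------------------------------------------

def fit_binomial_glmm(
    data: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    random_factors: list[str],
    reference_levels: dict | None = None,
) -> MixedModelFit:
    """Fit a binomial-logit GLMM with random intercepts by Laplace.

    Non-convergence or (quasi-)separation never raises; the returned fit
    carries ``converged = False`` and a diagnostic message instead.
    """
    y = data[response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    X_df = build_design(data, fixed_terms, reference_levels)
    refs = X_df.attrs["reference_levels"]
    X = X_df.to_numpy()
    Z, sizes, factors = _random_effects_matrix(data, random_factors)
    n, p = X.shape
    q = Z.shape[1]
    A = np.hstack([X, Z])
    term_names = list(X_df.columns)

    diagnostics: list[str] = []
    if y.min() == y.max():
        diagnostics.append(
            "complete separation: all outcomes identical; coefficients unidentified"
        )
        nan = pd.Series(np.nan, index=term_names)
        return MixedModelFit(
            formula=_formula_string(response, fixed_terms, random_factors),
            params=nan,
            bse=nan,
            z=nan,
            p=nan,
            converged=False,
            vc={f: np.nan for f in factors},
            reference_levels=refs,
            diagnostics=diagnostics,
            n_obs=n,
        )

    factor_index = np.concatenate(
        [np.full(sz, k) for k, sz in enumerate(sizes)]
    )

    def penalized_mode(sigma2: np.ndarray, coef0: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Newton maximization of the joint penalized log-likelihood."""
        pen_diag = np.concatenate(
            [np.zeros(p), 1.0 / sigma2[factor_index]]
        )
        coef = coef0.copy()

        def objective(c: np.ndarray) -> float:
            eta = A @ c
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            return ll - 0.5 * np.sum(pen_diag * c * c)

        obj = objective(coef)
        for _ in range(100):
            eta = A @ coef
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            grad = A.T @ (y - mu) - pen_diag * coef
            H = (A * w[:, None]).T @ A
            H[np.diag_indices_from(H)] += pen_diag
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving keeps the Newton iteration monotone
            t = 1.0
            for _ in range(30):
                new = coef + t * step
                new_obj = objective(new)
                if new_obj >= obj - 1e-12:
                    break
                t *= 0.5
            coef, prev_obj, obj = new, obj, new_obj
            if np.max(np.abs(t * step)) < _INNER_TOL:
                break
        eta = A @ coef
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        return coef, w, obj

    def neg_laplace(log_s2: np.ndarray, state: dict) -> float:
        sigma2 = np.exp(np.clip(log_s2, -12.0, 6.0))
        coef, w, pen_ll = penalized_mode(sigma2, state["coef"])
        state["coef"] = coef
        Zw = Z * w[:, None]
        Huu = Z.T @ Zw
        Huu[np.diag_indices_from(Huu)] += 1.0 / sigma2[factor_index]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf
        log_l = (
            pen_ll
            - 0.5 * np.sum(np.array(sizes) * np.log(sigma2))
            - 0.5 * logdet
        )
        return -log_l

    state = {"coef": np.zeros(p + q)}
    x0 = np.full(len(sizes), np.log(0.25))
    res = optimize.minimize(
        neg_laplace,
        x0,
        args=(state,),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400},
    )
    sigma2 = np.exp(np.clip(res.x, -12.0, 6.0))
    coef, w, _ = penalized_mode(sigma2, state["coef"])
    beta, u = coef[:p], coef[p:]

    # Wald covariance of beta: Schur complement of the joint Hessian
    Xw = X * w[:, None]
    Zw = Z * w[:, None]
    Hbb = Xw.T @ X
    Hbu = Xw.T @ Z
    Huu = Zw.T @ Z
    Huu[np.diag_indices_from(Huu)] += 1.0 / sigma2[factor_index]
    try:
        cov = np.linalg.inv(Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T))
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        diagnostics.append("singular Hessian: standard errors unavailable")

    converged = bool(res.success) and np.all(np.isfinite(bse))
    if not res.success:
        diagnostics.append("variance-component optimization did not converge")
    if np.any(np.abs(beta) > _MAX_ABS_COEF):
        diagnostics.append("quasi-separation: |coefficient| > 15 on the logit scale")
        converged = False
    if np.any(sigma2 < 1e-5):
        diagnostics.append("singular fit: a variance component collapsed to ~0")

    params = pd.Series(beta, index=term_names)
    bse_s = pd.Series(bse, index=term_names)
    zval = params / bse_s
    pval = pd.Series(2 * stats.norm.sf(np.abs(zval)), index=term_names)
    return MixedModelFit(
        formula=_formula_string(response, fixed_terms, random_factors),
        params=params,
        bse=bse_s,
        z=zval,
        p=pval,
        converged=converged,
        vc={f: float(s) for f, s in zip(factors, sigma2)},
        reference_levels=refs,
        diagnostics=diagnostics,
        n_obs=n,
    )


def _formula_string(response: str, fixed: list[str], random: list[str]) -> str:
    rhs = " + ".join(fixed) + "".join(f" + (1 | {g})" for g in random)
    return f"{response} ~ {rhs}"
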