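"""Univariate and bivariate ACE/AE Cholesky twin models fit by FIML.

The classical twin design decomposes phenotypic (co)variance into additive
genetic (A), shared/common environmental (C) and non-shared environmental (E)
sources.  Each component covariance is parameterized as ``L @ L.T`` with ``L``
lower triangular (the biometric Cholesky decomposition), which keeps every
component matrix positive semidefinite by construction.  For a pair of twins
the expected ``2p x 2p`` covariance of the stacked observation vector is::

    within-twin block   AA' + CC' + EE'
    cross-twin block    r * AA' + CC'      r = 1 (MZ), 0.5 (DZ)

Estimation is full-information maximum likelihood (FIML): each family
contributes the multivariate-normal log density of its *observed* sub-vector,
so incomplete pairs (singletons, item missingness) are used without imputation.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit``, results in trailing-underscore attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .cohort import TwinCohort, zygosity_factor

_LOG_2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start yields a usable maximum."""


# ---------------------------------------------------------------------------
# expected covariance
# ---------------------------------------------------------------------------

def expected_covariance(A, C, E, zygosity: str) -> np.ndarray:
    """Expected 2p x 2p twin-pair covariance under Cholesky path matrices.

    Parameters
    ----------
    A, E : (p, p) lower-triangular path matrices; ``C`` may be None (AE model).
    zygosity : "MZ" or "DZ".
    """
    factor = zygosity_factor(zygosity)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    E = np.atleast_2d(np.asarray(E, dtype=float))
    C = np.zeros_like(A) if C is None else np.atleast_2d(np.asarray(C, dtype=float))
    for M in (A, C, E):
        if not np.isfinite(M).all():
            raise ValueError("path matrices must be finite")
    AA, CC, EE = A @ A.T, C @ C.T, E @ E.T
    within = AA + CC + EE
    cross = factor * AA + CC
    return np.block([[within, cross], [cross, within]])


# ---------------------------------------------------------------------------
# sufficient statistics for FIML
# ---------------------------------------------------------------------------

@dataclass
class _PatternStats:
    """Per (zygosity, missingness-pattern) sufficient statistics."""

    zygosity: str
    observed: np.ndarray          # indices into the 2p stacked vector
    n: int
    mean: np.ndarray
    scatter: np.ndarray           # sum of outer products about `mean`


def pattern_statistics(X: np.ndarray, zygosity: np.ndarray) -> list[_PatternStats]:
    """Group rows of ``X`` (n, 2p; NaN = missing) by zygosity and missingness,
    returning count/mean/scatter per group.  The FIML log-likelihood is then
    O(number of patterns) per evaluation, independent of sample size."""
    X = np.asarray(X, dtype=float)
    obs_mask = np.isfinite(X)
    out: list[_PatternStats] = []
    for z in ("MZ", "DZ"):
        zi = np.asarray(zygosity) == z
        if not zi.any():
            continue
        Xz, Mz = X[zi], obs_mask[zi]
        _, inverse = np.unique(Mz, axis=0, return_inverse=True)
        for g in np.unique(inverse):
            rows = Xz[inverse == g]
            obs = np.flatnonzero(Mz[inverse == g][0])
            if obs.size == 0:
                continue
            sub = rows[:, obs]
            m = sub.mean(axis=0)
            d = sub - m
            out.append(_PatternStats(z, obs, sub.shape[0], m, d.T @ d))
    return out


def _loglik_from_stats(stats_list, sigma_by_zyg, mu) -> float:
    total = 0.0
    for st in stats_list:
        sig = sigma_by_zyg[st.zygosity][np.ix_(st.observed, st.observed)]
        try:
            cf = cho_factor(sig, lower=True, check_finite=False)
        except (LinAlgError, ValueError):
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        diff = st.mean - mu[st.observed]
        quad = st.n * diff @ cho_solve(cf, diff, check_finite=False)
        tr = np.trace(cho_solve(cf, st.scatter, check_finite=False))
        d = st.observed.size
        total += -0.5 * (st.n * (d * _LOG_2PI + logdet) + tr + quad)
    return total


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def _lower_mask(p: int) -> np.ndarray:
    return np.tril(np.ones((p, p), dtype=bool))


class CholeskyTwinModel(BaseEstimator):
    """ACE/AE twin Cholesky model estimated by FIML.

    Parameters
    ----------
    components : {"ACE", "AE"}
        Whether a shared-environment (C) component is included.  Ignored when
        ``free_c`` is given explicitly.
    free_a, free_c, free_e : bool array of shape (p, p), optional
        Free/fixed pattern over the lower-triangular path entries.  ``None``
        means all lower-triangular entries free (for C: all free under "ACE",
        all fixed at zero under "AE").  Fixed entries keep the values in
        ``fixed_a``/``fixed_c``/``fixed_e`` (zero by default).
    fixed_a, fixed_c, fixed_e : array of shape (p, p), optional
        Values of fixed path entries.
    n_starts : int
        Number of optimizer starts; the first is moment-based (Falconer-style
        estimates from observed twin covariances), the rest are jittered.
    jitter : float
        Relative scale of the start jitter.
    random_state : int or None
        Seed for the start jitter.
    tol : float
        Log-likelihood convergence tolerance passed to the optimizer.

    Attributes
    ----------
    a_, c_, e_ : fitted path matrices (``c_`` is None for AE models).
    means_ : fitted means (equated across twin order and zygosity).
    loglik_ : maximized FIML log-likelihood.
    n_free_ : number of free parameters (free paths + p means).
    standardized_a_, standardized_c_, standardized_e_ : paths divided by each
        row-variable's total (model-implied) standard deviation.
    rg_, rc_, re_ : genetic / shared- / non-shared-environmental correlations
        (p = 2 only; NaN when the corresponding variance is zero).
    bivariate_heritability_, bivariate_c_, bivariate_environmentality_ :
        components of the implied phenotypic correlation (p = 2 only).
    implied_phenotypic_correlation_ : their sum, = S12 / sqrt(S11 S22).
    converged_ : whether the best start reported optimizer success.
    """

    def __init__(self, components="AE", free_a=None, free_c=None, free_e=None,
                 fixed_a=None, fixed_c=None, fixed_e=None,
                 n_starts=5, jitter=0.1, random_state=None, tol=1e-8):
        self.components = components
        self.free_a = free_a
        self.free_c = free_c
        self.free_e = free_e
        self.fixed_a = fixed_a
        self.fixed_c = fixed_c
        self.fixed_e = fixed_e
        self.n_starts = n_starts
        self.jitter = jitter
        self.random_state = random_state
        self.tol = tol

    # -- free/fixed patterns ----------------------------------------------
    def _masks(self, p: int):
        tri = _lower_mask(p)

        def prep(mask, default_on):
            if mask is None:
                return tri.copy() if default_on else np.zeros((p, p), dtype=bool)
            m = np.asarray(mask, dtype=bool)
            if m.shape != (p, p):
                raise ValueError(f"free pattern must be {p}x{p}")
            if (m & ~tri).any():
                raise ValueError("free pattern must be lower triangular")
            return m

        if self.components not in ("ACE", "AE"):
            raise ValueError("components must be 'ACE' or 'AE'")
        has_c = self.components == "ACE" or self.free_c is not None
        return (prep(self.free_a, True),
                prep(self.free_c, has_c),
                prep(self.free_e, True))

    def _fixed(self, p: int):
        def prep(v):
            if v is None:
                return np.zeros((p, p))
            v = np.asarray(v, dtype=float)
            if v.shape != (p, p):
                raise ValueError(f"fixed values must be {p}x{p}")
            return v
        return prep(self.fixed_a), prep(self.fixed_c), prep(self.fixed_e)

    # -- data handling -----------------------------------------------------
    @staticmethod
    def _as_arrays(X, zygosity):
        if isinstance(X, TwinCohort):
            return X.stacked(), X.zygosity
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n_pairs, 2p)")
        if zygosity is None:
            raise ValueError("zygosity labels are required with array input")
        return X, np.asarray(zygosity, dtype=object)

    # -- parameter packing -------------------------------------------------
    def _unpack(self, x, p, masks, fixed):
        mats = []
        k = 0
        for mask, fx in zip(masks, fixed):
            M = fx.copy()
            nf = int(mask.sum())
            M[mask] = x[k:k + nf]
            k += nf
            mats.append(M)
        mu_p = x[k:k + p]
        return mats, mu_p

    def _neg_loglik(self, x, p, masks, fixed, stats_list):
        (A, C, E), mu_p = self._unpack(x, p, masks, fixed)
        mu = np.concatenate([mu_p, mu_p])
        sig = {z: expected_covariance(A, C, E, z) for z in ("MZ", "DZ")}
        ll = _loglik_from_stats(stats_list, sig, mu)
        return 1e10 if not np.isfinite(ll) else -ll

    # -- moment-based start ------------------------------------------------
    @staticmethod
    def _psd_clip(M, floor):
        M = 0.5 * (M + M.T)
        w, v = np.linalg.eigh(M)
        w = np.clip(w, floor, None)
        return (v * w) @ v.T

    def _moment_start(self, X, zygosity, p):
        import pandas as pd

        both = pd.DataFrame(np.vstack([X[:, :p], X[:, p:]]))
        sw = both.cov(min_periods=2).to_numpy()
        mu0 = both.mean().to_numpy()
        sw = np.where(np.isfinite(sw), sw, 0.0)
        mu0 = np.where(np.isfinite(mu0), mu0, 0.0)
        scale = float(np.mean(np.sqrt(np.clip(np.diag(sw), 1e-12, None))))

        def cross_cov(z):
            zi = np.asarray(zygosity) == z
            t1, t2 = X[zi, :p], X[zi, p:]
            ok = np.isfinite(t1).all(axis=1) & np.isfinite(t2).all(axis=1)
            if ok.sum() < 3:
                return 0.25 * sw
            a, b = t1[ok] - t1[ok].mean(0), t2[ok] - t2[ok].mean(0)
            c = a.T @ b / ok.sum()
            return 0.5 * (c + c.T)

        cmz, cdz = cross_cov("MZ"), cross_cov("DZ")
        floor = 1e-6 * max(scale ** 2, 1e-12)
        A0 = self._psd_clip(2.0 * (cmz - cdz), floor)
        C0 = self._psd_clip(2.0 * cdz - cmz, floor)
        E0 = self._psd_clip(sw - A0 - C0, floor)
        starts = []
        for M in (A0, C0, E0):
            try:
                starts.append(np.linalg.cholesky(M + floor * np.eye(p)))
            except LinAlgError:
                starts.append(np.sqrt(floor) * np.eye(p))
        return starts, mu0, scale

    # -- fitting -----------------------------------------------------------
    def fit(self, X, zygosity=None, x0=None):
        """Fit by FIML.

        Parameters
        ----------
        X : TwinCohort or array of shape (n_pairs, 2p)
            Stacked twin-pair observations, NaN = missing.
        zygosity : array of "MZ"/"DZ", required for array input.
        x0 : optional explicit start vector (free paths then means), used as
            the first start (warm start for vertex-wise scans).
        """
        X, zyg = self._as_arrays(X, zygosity)
        p = X.shape[1] // 2
        masks = self._masks(p)
        fixed = self._fixed(p)
        col_var = np.nanvar(np.vstack([X[:, :p], X[:, p:]]), axis=0)
        if np.any(col_var < 1e-12):
            raise ValueError("zero-variance variable; model not identified")
        stats_list = pattern_statistics(X, zyg)
        self._fit_from_stats(stats_list, p, masks, fixed, X=X, zygosity=zyg, x0=x0)
        return self

    def _fit_from_stats(self, stats_list, p, masks=None, fixed=None,
                        X=None, zygosity=None, x0=None):
        masks = self._masks(p) if masks is None else masks
        fixed = self._fixed(p) if fixed is None else fixed
        n_free_paths = int(sum(m.sum() for m in masks))
        if n_free_paths == 0:
            raise ValueError("model specification has no free paths")
        rng = np.random.default_rng(self.random_state)

        if X is not None:
            (A0, C0, E0), mu0, scale = self._moment_start(X, zygosity, p)
        else:
            A0 = C0 = E0 = 0.5 * np.eye(p)
            mu0, scale = np.zeros(p), 1.0
        base = np.concatenate([A0[masks[0]], C0[masks[1]], E0[masks[2]], mu0])

        starts = [base if x0 is None else np.asarray(x0, dtype=float)]
        for _ in range(max(0, int(self.n_starts) - 1)):
            starts.append(base + rng.normal(0.0, self.jitter * max(scale, 1e-6),
                                            size=base.size))

        best = None
        any_ok = False
        for s in starts:
            try:
                res = optimize.minimize(
                    self._neg_loglik, s, args=(p, masks, fixed, stats_list),
                    method="L-BFGS-B",
                    options={"maxiter": 1000, "ftol": self.tol, "gtol": 1e-6},
                )
            except (LinAlgError, ValueError):
                continue
            if not np.isfinite(res.fun) or res.fun >= 1e9:
                continue
            any_ok = True
            if best is None or res.fun < best.fun:
                best = res
        if not any_ok:
            raise ConvergenceError("all optimizer starts failed to converge")

        (A, C, E), mu_p = self._unpack(best.x, p, masks, fixed)
        # LL' is invariant to flipping a column's sign: normalize diagonals >= 0
        for M in (A, C, E):
            for j in range(p):
                if M[j, j] < 0:
                    M[:, j] *= -1.0
        has_c = masks[1].any() or np.any(fixed[1] != 0.0)
        self.n_variables_ = p
        self.free_a_, self.free_c_, self.free_e_ = masks
        self.a_, self.c_, self.e_ = A, (C if has_c else None), E
        self._c_mat = C
        self.means_ = mu_p
        self.loglik_ = float(-best.fun)
        self.n_free_ = n_free_paths + p
        self.converged_ = bool(best.success)
        self._stats = stats_list
        self._derive()
        return self

    # -- derived quantities ------------------------------------------------
    def _derive(self):
        A, C, E = self.a_, self._c_mat, self.e_
        AA, CC, EE = A @ A.T, C @ C.T, E @ E.T
        S = AA + CC + EE
        sd = np.sqrt(np.diag(S))
        self.implied_within_covariance_ = S
        self.standardized_a_ = A / sd[:, None]
        self.standardized_c_ = C / sd[:, None]
        self.standardized_e_ = E / sd[:, None]
        self.variance_shares_ = np.column_stack(
            [np.diag(M) / np.diag(S) for M in (AA, CC, EE)]
        )

        def comp_corr(G):
            if G[0, 0] <= 0 or G[1, 1] <= 0:
                return float("nan")
            return float(G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]))

        if self.n_variables_ == 2:
            self.rg_ = comp_corr(AA)
            self.rc_ = comp_corr(CC) if self.c_ is not None else None
            self.re_ = comp_corr(EE)
            denom = math.sqrt(S[0, 0] * S[1, 1])
            if denom <= 0:
                self.bivariate_heritability_ = float("nan")
                self.bivariate_c_ = float("nan")
                self.bivariate_environmentality_ = float("nan")
                self.implied_phenotypic_correlation_ = float("nan")
            else:
                self.bivariate_heritability_ = float(AA[0, 1] / denom)
                self.bivariate_c_ = float(CC[0, 1] / denom)
                self.bivariate_environmentality_ = float(EE[0, 1] / denom)
                self.implied_phenotypic_correlation_ = float(S[0, 1] / denom)
        else:
            self.rg_ = self.rc_ = self.re_ = None
            self.bivariate_heritability_ = None
            self.bivariate_c_ = None
            self.bivariate_environmentality_ = None
            self.implied_phenotypic_correlation_ = None

    def loglikelihood(self, X=None, zygosity=None) -> float:
        """FIML log-likelihood of the fitted model (on new data if given)."""
        if X is None:
            return self.loglik_
        X, zyg = self._as_arrays(X, zygosity)
        stats_list = pattern_statistics(X, zyg)
        mu = np.concatenate([self.means_, self.means_])
        sig = {z: expected_covariance(self.a_, self._c_mat, self.e_, z)
               for z in ("MZ", "DZ")}
        return _loglik_from_stats(stats_list, sig, mu)

    def summary_table(self):
        """Per-path estimates and standardized estimates as a DataFrame."""
        import pandas as pd

        rows = []
        mats = {"A": (self.a_, self.standardized_a_, self.free_a_),
                "C": (self._c_mat, self.standardized_c_, self.free_c_),
                "E": (self.e_, self.standardized_e_, self.free_e_)}
        for comp, (M, Ms, mask) in mats.items():
            if comp == "C" and self.c_ is None:
                continue
            for i in range(self.n_variables_):
                for j in range(i + 1):
                    rows.append({
                        "component": comp, "path": f"{comp.lower()}{i + 1}{j + 1}",
                        "free": bool(mask[i, j]),
                        "estimate": M[i, j], "standardized": Ms[i, j],
                    })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------

def fiml_loglik(model: CholeskyTwinModel, cohort, zygosity=None) -> float:
    """FIML log-likelihood of a fitted model on a cohort (see estimator)."""
    return model.loglikelihood(cohort, zygosity)


def fit_model(cohort, spec: CholeskyTwinModel | None = None,
              n_starts: int = 5, seed=None, **spec_kwargs) -> CholeskyTwinModel:
    """Fit a Cholesky twin model to a cohort; returns the fitted estimator.

    ``spec`` is an unfitted :class:`CholeskyTwinModel` carrying the free/fixed
    pattern; keyword arguments build one if it is omitted.
    """
    from sklearn.base import clone

    model = clone(spec) if spec is not None else CholeskyTwinModel(**spec_kwargs)
    model.set_params(n_starts=n_starts, random_state=seed)
    return model.fit(cohort)


def genetic_correlation(fit: CholeskyTwinModel) -> float:
    """Genetic correlation rG = (AA')12 / sqrt((AA')11 (AA')22); for p = 2 this
    is a11*a21 / sqrt(a11^2 (a21^2 + a22^2)).  NaN if either trait has zero
    genetic variance."""
    return fit.rg_


def environmental_correlation(fit: CholeskyTwinModel) -> float:
    """Non-shared environmental correlation (same formula on the E paths)."""
    return fit.re_


def bivariate_heritability(fit: CholeskyTwinModel) -> float:
    """Genetic contribution to the phenotypic correlation: the product of the
    standardized paths a11 and a21, i.e. (AA')12 / sqrt(S11 S22)."""
    return fit.bivariate_heritability_


def lr_test(full: CholeskyTwinModel, reduced: CholeskyTwinModel):
    """Likelihood-ratio (chi-square difference) test of nested Cholesky models.

    Returns ``(chi2, df, p)``; chi2 is clipped at zero and the p-value comes
    from the chi-square upper tail with df = difference in free parameters.
    """
    if full.n_variables_ != reduced.n_variables_:
        raise ValueError("models have different numbers of phenotypes")
    for mf, mr in zip((full.free_a_, full.free_c_, full.free_e_),
                      (reduced.free_a_, reduced.free_c_, reduced.free_e_)):
        if (mr & ~mf).any():
            raise ValueError("reduced model is not nested in the full model")
    df = full.n_free_ - reduced.n_free_
    chi2 = max(0.0, 2.0 * (full.loglik_ - reduced.loglik_))
    if df == 0:
        p = 1.0 if chi2 < 1e-6 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def model_df(n_free_params: int, p: int, n_groups: int = 2) -> int:
    """Degrees of freedom versus the per-zygosity-group saturated model.

    Each group contributes 2p observed means and 2p(2p+1)/2 covariances; the
    fitted model spends its free paths plus p means (equated across twin order
    and zygosity).
    """
    df = n_groups * (2 * p + p * (2 * p + 1)) - n_free_params
    if df < 0:
        raise ValueError("negative degrees of freedom")
    return df


# ---------------------------------------------------------------------------
# saturated / independence baselines and fit indices
# ---------------------------------------------------------------------------

def _group_closed_form_loglik(rows: np.ndarray) -> float | None:
    """Closed-form saturated log-likelihood for complete rows, else None."""
    if not np.isfinite(rows).all():
        return None
    n, d = rows.shape
    mu = rows.mean(axis=0)
    dev = rows - mu
    S = dev.T @ dev / n
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return None
    return -0.5 * n * (d * _LOG_2PI + logdet + d)


def fit_saturated(X, zygosity=None):
    """Saturated two-group model: free mean vector and free covariance per
    zygosity group.  Returns ``(loglik, n_params)``.

    Complete-data groups use the closed-form MLE; groups with missing entries
    maximize the FIML likelihood over a Cholesky factor of the covariance.
    """
    X, zyg = CholeskyTwinModel._as_arrays(X, zygosity)
    d = X.shape[1]
    total, n_params = 0.0, 0
    tri = _lower_mask(d)
    for z in np.unique(zyg):
        rows = X[np.asarray(zyg) == z]
        n_params += d + d * (d + 1) // 2
        ll = _group_closed_form_loglik(rows)
        if ll is not None:
            total += ll
            continue
        stats_list = pattern_statistics(rows, np.array([z] * len(rows), dtype=object))

        col_mu = np.nanmean(rows, axis=0)
        col_sd = np.nanstd(rows, axis=0)
        L0 = np.diag(np.clip(col_sd, 1e-3, None))

        def neg(x, _z=z, _stats=stats_list, _mu0=col_mu):
            L = np.zeros((d, d))
            L[tri] = x[: tri.sum()]
            mu = x[tri.sum():]
            sig = {_z: L @ L.T}
            ll = _loglik_from_stats(_stats, sig, mu)
            return 1e10 if not np.isfinite(ll) else -ll

        x0 = np.concatenate([L0[tri], col_mu])
        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-10})
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            raise ConvergenceError("saturated model failed to converge")
        total += -res.fun
    return float(total), n_params


def fit_independence(X, zygosity=None):
    """Independence baseline: free per-group means and variances, all
    covariances zero.  With a diagonal covariance the likelihood factorizes
    over variables, so per-column observed means/variances are the FIML MLE.
    Returns ``(loglik, n_params)``."""
    X, zyg = CholeskyTwinModel._as_arrays(X, zygosity)
    total, n_params = 0.0, 0
    for z in np.unique(zyg):
        rows = X[np.asarray(zyg) == z]
        for j in range(rows.shape[1]):
            col = rows[:, j]
            col = col[np.isfinite(col)]
            n_params += 2
            if col.size == 0:
                continue
            var = max(col.var(), 1e-12)
            total += -0.5 * col.size * (_LOG_2PI + math.log(var) + 1.0)
    return float(total), n_params


@dataclass
class FitIndices:
    """Chi-square vs saturated model plus approximate-fit indices."""

    chi2: float
    df: int
    p_value: float
    rmsea: float
    tli: float | None
    cfi: float | None
    chi2_baseline: float | None = None
    df_baseline: int | None = None


def fit_indices(model_fit: CholeskyTwinModel, X, zygosity=None,
                n: int | None = None, n_groups: int = 2) -> FitIndices:
    """Absolute and incremental fit of a fitted model against the saturated
    and independence baselines on the same cohort.

    ``n`` is the number of independent units (families); it defaults to the
    number of pairs in the cohort.  RMSEA uses ``sqrt(max(0, (chi2-df)/(df*(n-1))))``
    with no multi-group adjustment.
    """
    Xa, zyg = CholeskyTwinModel._as_arrays(X, zygosity)
    if n is None:
        n = Xa.shape[0]
    p = model_fit.n_variables_
    ll_sat, _ = fit_saturated(Xa, zyg)
    ll_ind, n_ind = fit_independence(Xa, zyg)
    chi2 = max(0.0, 2.0 * (ll_sat - model_fit.loglik_))
    df = model_df(model_fit.n_free_, p, n_groups)
    chi2_b = max(0.0, 2.0 * (ll_sat - ll_ind))
    df_b = n_groups * (2 * p + p * (2 * p + 1)) - n_ind
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 < 1e-6 else 0.0)
    rmsea = math.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))) if df > 0 else 0.0
    if df_b <= 0 or chi2_b <= df_b:
        tli = cfi = None
    else:
        cfi = 1.0 - max(0.0, chi2 - df) / max(0.0, chi2_b - df_b)
        rb = chi2_b / df_b
        rm = chi2 / df if df > 0 else 0.0
        tli = (rb - rm) / (rb - 1.0)
    return FitIndices(chi2, df, p_value, rmsea, tli, cfi, chi2_b, df_b)
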