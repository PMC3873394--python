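"""Pedigree mixed linear model solved through Henderson's mixed model
equations.

The model is

    y = X b + Z a + e,   a ~ N(0, A sigma2_a),   e ~ N(0, W sigma2_e)

where y are EBV "phenotypes" of the observed individuals, a is the
polygenic effect of every pedigree member with A the additive relationship
matrix, and W is diagonal with W_ii = 1/REL_i — the residual variance of an
EBV is inversely proportional to its reliability.  Fixed effects b (an
intercept plus SNP dosage, genotype-class indicators, or haplotype
dosages) are estimated BLUE, polygenic effects BLUP, and the sampling
covariance of b comes from the fixed-effect block of the inverse
coefficient matrix.

The public surface follows the Model / Results convention: construct a
:class:`PedigreeMixedLM`, call :meth:`~PedigreeMixedLM.fit`, and read
estimates, standard errors and Wald tests off the
:class:`PedigreeMixedLMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .io import Pedigree
from .kinship import inverse_relationship_matrix


@dataclass
class VarianceComponents:
    """Additive (sigma2_a), residual (sigma2_e) and phenotypic (sigma2_p)
    variances for one trait.  sigma2_p scales variance-explained reporting
    and defaults to sigma2_a + sigma2_e."""

    var_a: float
    var_e: float
    var_p: float | None = None

    def __post_init__(self) -> None:
        if self.var_a <= 0 or self.var_e <= 0:
            raise ValueError("variance components must be positive")
        if self.var_p is None:
            self.var_p = self.var_a + self.var_e
        if self.var_p <= 0:
            raise ValueError("phenotypic variance must be positive")

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio sigma2_e / sigma2_a entering the MME."""
        return self.var_e / self.var_a


class PedigreeMixedLM:
    """Weighted mixed regression with a pedigree polygenic effect.

    Parameters
    ----------
    endog : (n_obs,) response vector (EBVs of the observed individuals).
    exog : (n_obs, p) fixed-effect design; must have full column rank.
    a_inv : (q, q) inverse additive relationship matrix over the pedigree.
    vc : variance components for the trait.
    reliabilities : (n_obs,) EBV reliabilities in (0, 1]; residual precision
        of observation i is REL_i / sigma2_e.
    obs_index : (n_obs,) positions of the observed individuals within the
        pedigree order used to build ``a_inv``.
    """

    def __init__(self, endog, exog, a_inv, vc: VarianceComponents,
                 reliabilities, obs_index, exog_names: Sequence[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.a_inv = np.asarray(a_inv, dtype=float)
        self.vc = vc
        self.reliabilities = np.asarray(reliabilities, dtype=float)
        self.obs_index = np.asarray(obs_index, dtype=int)
        n, p = self.exog.shape
        if self.endog.shape[0] != n or self.reliabilities.shape[0] != n \
                or self.obs_index.shape[0] != n:
            raise ValueError("endog, exog, reliabilities, obs_index must align")
        if np.any(self.reliabilities <= 0) or np.any(self.reliabilities > 1):
            raise ValueError("reliabilities must lie in (0, 1]")
        if np.linalg.matrix_rank(self.exog) < p:
            raise ValueError("fixed-effect design is rank deficient")
        self.exog_names = list(exog_names) if exog_names else \
            [f"x{k}" for k in range(p)]

    @classmethod
    def from_pedigree(cls, ped: Pedigree, ids: Sequence[str], endog, exog,
                      vc: VarianceComponents, reliabilities,
                      exog_names: Sequence[str] | None = None,
                      a_inv: np.ndarray | None = None) -> "PedigreeMixedLM":
        """Build the model from a pedigree and the observed individuals' ids."""
        if a_inv is None:
            a_inv = inverse_relationship_matrix(ped)
        return cls(endog, exog, a_inv, vc, reliabilities,
                   obs_index=ped.index_of(list(ids)), exog_names=exog_names)

    def fit(self) -> "PedigreeMixedLMResults":
        """Solve the MME and return a results object.

        The coefficient matrix is

            [ X' R^-1 X        X' R^-1 Z              ]
            [ Z' R^-1 X        Z' R^-1 Z + A^-1/s2a   ]

        with R^-1 = diag(REL)/s2e and Z the observation-to-individual
        incidence; the fixed block of its inverse is Cov(b_hat).
        """
        X, y = self.exog, self.endog
        n, p = X.shape
        q = self.a_inv.shape[0]
        rinv = self.reliabilities / self.vc.var_e  # per-observation precision

        XtR = X.T * rinv                       # p x n
        C11 = XtR @ X
        # Z'R^-1 terms accumulate per pedigree individual
        zr = np.zeros(q)
        np.add.at(zr, self.obs_index, rinv)
        C12 = np.zeros((p, q))
        for k in range(p):
            np.add.at(C12[k], self.obs_index, X[:, k] * rinv)
        C22 = self.a_inv / self.vc.var_a
        C22[np.arange(q), np.arange(q)] += zr
        C = np.block([[C11, C12], [C12.T, C22]])
        rhs = np.concatenate([XtR @ y, np.bincount(self.obs_index,
                                                   weights=y * rinv, minlength=q)])
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        # fixed-effect covariance: first p columns of C^-1
        eye_p = np.zeros((p + q, p))
        eye_p[:p, :p] = np.eye(p)
        cov_fixed = linalg.cho_solve(cf, eye_p, check_finite=False)[:p]
        cov_fixed = (cov_fixed + cov_fixed.T) / 2.0
        return PedigreeMixedLMResults(self, sol[:p], cov_fixed, sol[p:])


@dataclass
class PedigreeMixedLMResults:
    """Fitted fixed effects, their sampling covariance, and polygenic BLUPs."""

    model: PedigreeMixedLM
    params: np.ndarray
    cov_params_: np.ndarray
    blups: np.ndarray

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_))

    def cov_params(self) -> np.ndarray:
        return self.cov_params_

    def wald_test(self, indices: Sequence[int] | int) -> tuple[float, int, float]:
        """Joint Wald chi-square that the selected fixed effects are zero.

        Returns (chisq, df, p); a single index gives the df = 1 test
        chisq = (b/se)^2.
        """
        idx = np.atleast_1d(np.asarray(indices, dtype=int))
        b = self.params[idx]
        V = self.cov_params_[np.ix_(idx, idx)]
        chisq = float(b @ linalg.solve(V, b, assume_a="pos"))
        df = len(idx)
        return chisq, df, float(stats.chi2.sf(chisq, df))

    def summary(self) -> str:
        lines = ["Pedigree mixed linear model (Henderson MME)",
                 f"  n obs = {len(self.model.endog)}, "
                 f"n pedigree = {self.model.a_inv.shape[0]}",
                 f"  sigma2_a = {self.model.vc.var_a:g}, "
                 f"sigma2_e = {self.model.vc.var_e:g}, "
                 f"lambda = {self.model.vc.lambda_:g}",
                 f"  {'term':<16}{'estimate':>12}{'se':>12}{'z':>9}"]
        for name, b, se in zip(self.model.exog_names, self.params, self.bse):
            z = b / se if se > 0 else np.nan
            lines.append(f"  {name:<16}{b:>12.5g}{se:>12.5g}{z:>9.3f}")
        return "\n".join(lines)


def solve_mme(y, fixed_design, a_inv, lambda_: float, weights,
              obs_index=None, var_e: float = 1.0) -> PedigreeMixedLMResults:
    """Functional entry point mirroring the Model/Results path.

    ``lambda_`` is sigma2_e/sigma2_a and ``weights`` are the reliabilities
    REL_i (residual variance of observation i is sigma2_e / REL_i).  When
    ``obs_index`` is omitted, observations map one-to-one onto pedigree
    members in order.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y, dtype=float)
    if obs_index is None:
        obs_index = np.arange(len(y))
    vc = VarianceComponents(var_a=var_e / lambda_, var_e=var_e)
    model = PedigreeMixedLM(y, fixed_design, a_inv, vc, weights, obs_index)
    return model.fit()


def estimate_variance_components(y, fixed_design, A, weights,
                                 obs_index=None) -> VarianceComponents:
    """Optional REML estimator of (sigma2_a, sigma2_e).

    Maximises the restricted log-likelihood by explicit construction of
    V = Z A Z' s2a + diag(1/REL) s2e, so it is intended for moderate n
    (hundreds to a few thousand observations) — e.g. calibrating a
    synthetic dataset.  Production variance components should come from
    the national evaluation that produced the EBVs.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    n, p = X.shape
    w = np.asarray(weights, dtype=float)
    if obs_index is None:
        obs_index = np.arange(n)
    Aobs = A[np.ix_(obs_index, obs_index)]
    Winv_diag = 1.0 / w

    def neg_restricted_ll(theta):
        va, ve = np.exp(theta)
        V = Aobs * va + np.diag(Winv_diag * ve)
        try:
            cf = linalg.cho_factor(V, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
        Vinv_X = linalg.cho_solve(cf, X, check_finite=False)
        Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
        XtVX = X.T @ Vinv_X
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
        resid_form = y @ Vinv_y - (X.T @ Vinv_y) @ beta  # y' P y
        return 0.5 * (logdet_v + logdet_x + resid_form)

    s2 = float(np.var(y))
    res = minimize(neg_restricted_ll, x0=np.log([s2 / 2, s2 / 2]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500})
    va, ve = np.exp(res.x)
    return VarianceComponents(var_a=float(va), var_e=float(ve))


def direct_gls(y, fixed_design, A, var_a: float, var_e: float, weights,
               obs_index=None) -> tuple[np.ndarray, np.ndarray]:
    """Reference generalized-least-squares fit by explicit V inversion.

    V = Z A Z' sigma2_a + diag(1/REL) sigma2_e.  Feasible only for small n;
    serves as the independent check on the MME path.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(fixed_design, dtype=float))
    n = len(y)
    if obs_index is None:
        obs_index = np.arange(n)
    Aobs = A[np.ix_(obs_index, obs_index)]
    V = Aobs * var_a + np.diag(var_e / np.asarray(weights, dtype=float))
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    cov = np.linalg.inv(XtVX)
    beta = cov @ (X.T @ Vinv @ y)
    return beta, cov
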