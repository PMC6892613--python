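"""REML variance-component estimation for kinship-based mixed models.

All models here have the form

    y = X beta + sum_k u_k,   u_k ~ N(0, sigma2_k V_k),

with y the L observations (segregant replicates or segregant means), X a
fixed-effect design (intercept, or one indicator per cross in joint models),
and each V_k an L x L covariance structure: Z K Z' for a segregant-level
kinship K carried to observations by the replicate incidence Z, Z Z' for
segregant repeatability, or the identity for residual measurement error.

Estimation is Newton–Raphson with the expected (Fisher) information and
step-halving, so the restricted likelihood increases monotonically.
Components are constrained non-negative by clamping at zero (active-set:
a clamped component is released if its score turns positive).  Standard
errors are square roots of the diagonal of the inverse Fisher information at
convergence, and derived quantities (variance shares, the non-additive to
additive ratio) carry delta-method standard errors from the same matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import KinshipMatrix, GenotypeMatrix, MarkerBins, \
    build_partitioned_kinships, hadamard, standardize_markers, gower_center

__all__ = [
    "VCModelSpec",
    "VCFit",
    "reml_fit",
    "reml_loglik",
    "additive_model",
    "epistatic_model",
    "nonadditive_ratio",
    "joint_maf_partition_model",
    "variance_share",
    "replicate_incidence",
]


@dataclass
class VCModelSpec:
    """Fixed-effect design plus an ordered list of named covariance kernels."""

    X: np.ndarray                        # L x p fixed-effect design
    kernels: list[tuple[str, np.ndarray]]  # name -> L x L PSD structure

    def __post_init__(self) -> None:
        L = self.X.shape[0]
        for name, V in self.kernels:
            if V.shape != (L, L):
                raise ValueError(f"kernel {name!r} has shape {V.shape}, expected {(L, L)}")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is singular")


@dataclass
class VCFit:
    names: list[str]
    sigma2: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    fisher: np.ndarray                   # information matrix at convergence
    beta: np.ndarray

    def component(self, name: str) -> float:
        return float(self.sigma2[self.names.index(name)])

    def as_dict(self) -> dict:
        return {
            "sigma2": dict(zip(self.names, self.sigma2.tolist())),
            "se": dict(zip(self.names, self.se.tolist())),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def replicate_incidence(n_segregants: int, n_replicates: int) -> np.ndarray:
    """Incidence Z mapping L = n * replicates observations to n segregants."""
    return np.kron(np.eye(n_segregants), np.ones((n_replicates, 1)))


def reml_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Dense restricted log-likelihood (Harville form).

    Includes the +log|X'X|/2 constant, so the value equals the log-density of
    any orthonormal basis of error contrasts K'y ~ N(0, K'VK).
    """
    n, p = X.shape
    sign, ldV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.solve(V, np.eye(n))
    XtViX = X.T @ Vi @ X
    sign2, ldX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    _, ldXX = np.linalg.slogdet(X.T @ X)
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y))
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX - ldXX + quad)


def _pmatrix(X: np.ndarray, V: np.ndarray):
    n = V.shape[0]
    Vi = np.linalg.solve(V, np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    M = np.linalg.solve(XtViX, ViX.T)
    P = Vi - ViX @ M
    return Vi, P, XtViX, M


def reml_fit(y: np.ndarray, spec: VCModelSpec, tol: float = 1e-6,
             max_iter: int = 100, constrain: bool = True,
             jitter: float = 1e-8) -> VCFit:
    """Fisher-scoring REML with step-halving and non-negativity clamping.

    Initialization splits the phenotypic variance equally across components.
    Convergence requires the free-component score norm to fall below ``tol``
    scaled by sample size, or the relative restricted-likelihood change to
    fall below 1e-8.  A non-convergent fit is returned with a warning and
    ``converged=False``.
    """
    y = np.asarray(y, float)
    X = np.asarray(spec.X, float)
    L = len(y)
    ks = [np.asarray(V, float) for _, V in spec.kernels]
    names = [name for name, _ in spec.kernels]
    K = len(ks)
    vary = float(np.var(y)) or 1.0
    s2 = np.full(K, vary / K)
    active = np.zeros(K, dtype=bool)     # clamped at zero

    def build_V(s):
        V = sum(si * Vi for si, Vi in zip(s, ks))
        return V + jitter * vary * np.eye(L)

    ll = reml_loglik(y, X, build_V(s2))
    converged = False
    it = 0
    score = np.zeros(K)
    info = np.eye(K)
    for it in range(1, max_iter + 1):
        V = build_V(s2)
        try:
            Vi, P, XtViX, M = _pmatrix(X, V)
        except np.linalg.LinAlgError:
            break
        Py = P @ y
        PVk = [P if _is_identity(Vk) else P @ Vk for Vk in ks]
        score = np.array([
            -0.5 * (np.trace(PVk[k]) - Py @ ks[k] @ Py) for k in range(K)
        ])
        info = 0.5 * np.array([[np.sum(PVk[j] * PVk[k].T) for k in range(K)]
                               for j in range(K)])
        if constrain:
            active = active & (score <= 0)   # release clamped comps with + score
        free = ~active
        # convergence check on free components
        if np.max(np.abs(score[free])) < tol * max(1.0, L / 100.0):
            converged = True
            break
        try:
            step = np.zeros(K)
            step[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            step = np.zeros(K)
            step[free] = score[free] / np.maximum(np.diag(info)[free], 1e-12)
        # step-halving on the restricted likelihood
        improved = False
        for _ in range(30):
            s_new = s2 + step
            if constrain:
                s_new = np.where(active, 0.0, np.maximum(s_new, 0.0))
            ll_new = reml_loglik(y, X, build_V(s_new))
            if ll_new >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True             # no uphill direction left
            break
        if constrain:
            newly = (s_new <= 0) & free
            active |= newly
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        s2, ll = s_new, ll_new
        if rel < 1e-10:
            converged = True
            break
    else:
        warnings.warn("REML did not converge within max_iter")

    # final information and SEs at the solution
    V = build_V(s2)
    Vi, P, XtViX, M = _pmatrix(X, V)
    PVk = [P if _is_identity(Vk) else P @ Vk for Vk in ks]
    info = 0.5 * np.array([[np.sum(PVk[j] * PVk[k].T) for k in range(K)]
                           for j in range(K)])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    beta = M @ y
    ll = reml_loglik(y, X, V)
    return VCFit(names=names, sigma2=s2, se=se, loglik=ll, converged=converged,
                 n_iter=it, fisher=info, beta=beta)


def _is_identity(V: np.ndarray) -> bool:
    n = V.shape[0]
    d = V.ravel()[:: n + 1]
    if not np.all(d == 1.0):
        return False
    return V.ravel()[1] == 0.0 and np.count_nonzero(V) == n


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def additive_model(y: np.ndarray, K_A: KinshipMatrix, tol: float = 1e-6) -> VCFit:
    """Two-component fit y = a + e with a ~ N(0, sigma2_A * A).

    The phenotype is standardized to mean 0 / variance 1 before fitting.
    Narrow-sense heritability is sigma2_A / (sigma2_A + sigma2_E).
    """
    y = np.asarray(y, float)
    y = (y - y.mean()) / y.std()
    L = len(y)
    spec = VCModelSpec(X=np.ones((L, 1)),
                       kernels=[("A", K_A.values), ("E", np.eye(L))])
    return reml_fit(y, spec, tol=tol)


def heritability(fit: VCFit) -> tuple[float, float]:
    """(h2, se) for an additive_model fit, via the delta method."""
    return variance_share(fit, ["A"], denominator=["A", "E"])


def epistatic_model(y_obs: np.ndarray, Z: np.ndarray, K_QTL: KinshipMatrix,
                    K_A: KinshipMatrix, reduced: bool = False,
                    X: np.ndarray | None = None, tol: float = 1e-6) -> VCFit:
    """Seven-component additive + pairwise-epistatic + repeatability model.

    Components: detected-QTL kinship (AQTL), genome-wide kinship (A), the
    Hadamard epistasis kernels AQTL∘AQTL, AQTL∘A and A∘A, segregant
    repeatability (ZZ'), and observation-level residual.  ``reduced=True``
    omits the QTL-involving epistasis kernels (AQTL∘AQTL and AQTL∘A).
    """
    y_obs = np.asarray(y_obs, float)
    L = len(y_obs)
    if X is None:
        X = np.ones((L, 1))
    lift = lambda K: Z @ K @ Z.T
    kernels = [("AQTL", lift(K_QTL.values)), ("A", lift(K_A.values))]
    if not reduced:
        kernels += [("AQTLxAQTL", lift(hadamard(K_QTL, K_QTL).values)),
                    ("AQTLxA", lift(hadamard(K_QTL, K_A).values))]
    kernels += [("AxA", lift(hadamard(K_A, K_A).values)),
                ("R", Z @ Z.T),
                ("EV", np.eye(L))]
    return reml_fit(y_obs, VCModelSpec(X=X, kernels=kernels), tol=tol)


def nonadditive_ratio(fit: VCFit) -> float:
    """Summed pairwise-interaction variance over summed additive variance."""
    inter = [n for n in fit.names if "x" in n]
    addit = [n for n in fit.names if n in ("AQTL", "A")]
    num = sum(fit.component(n) for n in inter)
    den = sum(fit.component(n) for n in addit)
    if den <= 0:
        return float("nan")
    return num / den


def joint_maf_partition_model(y_all: np.ndarray, cross_ids: np.ndarray,
                              kinships: list[KinshipMatrix],
                              names: list[str] | None = None,
                              tol: float = 1e-6) -> VCFit:
    """Allele-frequency-partitioned joint model y = X beta + sum_b u_b + e.

    ``X`` holds one fixed effect per cross (variants confounded with a cross
    are absorbed there); one Gower-centered kinship per MAF bin.  Phenotypes
    are segregant-level values concatenated across crosses.
    """
    y_all = np.asarray(y_all, float)
    cross_ids = np.asarray(cross_ids)
    levels = pd.unique(cross_ids)
    X = np.column_stack([(cross_ids == c).astype(float) for c in levels])
    L = len(y_all)
    if names is None:
        names = [f"bin{b}" for b in range(len(kinships))]
    kernels = [(nm, K.values) for nm, K in zip(names, kinships)]
    kernels.append(("EV", np.eye(L)))
    return reml_fit(y_all, VCModelSpec(X=X, kernels=kernels), tol=tol)


def variance_share(fit: VCFit, numerator: list[str],
                   denominator: list[str] | None = None) -> tuple[float, float]:
    """Share of variance in ``numerator`` components, with delta-method SE.

    The denominator defaults to every genetic component (residual-type
    components EV/E and repeatability R excluded).  Returns (share, se);
    share is NaN when the denominator total is not positive.
    """
    if denominator is None:
        denominator = [n for n in fit.names if n not in ("EV", "E", "R")]
    for n in numerator + denominator:
        if n not in fit.names:
            raise KeyError(f"component {n!r} not in fit")
    a = sum(fit.component(n) for n in numerator)
    t = sum(fit.component(n) for n in denominator)
    if t <= 0:
        return float("nan"), float("nan")
    share = a / t
    g = np.zeros(len(fit.names))
    for i, n in enumerate(fit.names):
        g[i] = ((n in numerator) * t - a * (n in denominator)) / t**2
    cov = np.linalg.pinv(fit.fisher)
    se = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return float(share), se
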