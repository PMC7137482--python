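"""Bivariate mixed models, the pleiotropy decision rule, and the
two-GRM variance partition.

The bivariate model per lead SNP is

    [y1; y2] = [mu1 1; mu2 1] + [beta1 m; beta2 m] + [u1; u2] + [e1; e2]

with polygenic effects u ~ N(0, G (x) A) — G the 2x2 polygenic covariance,
A the additive (here genomic) relationship matrix — and independent
residuals e ~ N(0, diag(se1^2, se2^2) (x) I).  It is fit by average-
information REML.  After one eigendecomposition A = U S U', rotating each
trait's data by U decouples the observations into n independent 2-vectors
with covariance s_i G + diag(se1^2, se2^2), so every REML iteration is
O(n).  Allele-substitution effects are estimated by GLS at the converged
components and tested per trait with Wald statistics against a standard
normal.

A lead SNP is declared pleiotropic when it is genome-wide significant for
at least one trait of the pair and also passes the pairwise threshold
alpha / (number of traits x number of unique lead SNPs) for the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assoc import GRM, ThresholdSpec

__all__ = [
    "BivariateModelSpec",
    "BivariateFit",
    "PleiotropyVerdict",
    "fit_bivariate_reml",
    "restricted_loglik",
    "classify_pleiotropy",
    "variance_partition_two_grm",
    "VariancePartition",
]

_GCORR_BOUND = 0.999
_VAR_FLOOR = 1e-8


@dataclass
class BivariateModelSpec:
    """Data for one bivariate lead-SNP fit (complete cases, Z = identity)."""

    y1: np.ndarray
    y2: np.ndarray
    m: np.ndarray | None  # lead-SNP dosages; None fits the null model
    a: np.ndarray         # relationship matrix
    traits: tuple[str, str] = ("trait1", "trait2")

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)
        a = self.a.matrix if isinstance(self.a, GRM) else self.a
        self.a = np.asarray(a, dtype=float)
        n = len(self.y1)
        if len(self.y2) != n or (self.m is not None and len(self.m) != n):
            raise ValueError("y1, y2 and m must index the same samples")
        if self.a.shape != (n, n):
            raise ValueError("relationship matrix does not match sample count")
        if n < 50:
            raise ValueError("need >= 50 complete-case samples")


@dataclass
class BivariateFit:
    beta: tuple[float, float]          # (beta1, beta2); (nan, nan) for null fits
    beta_se: tuple[float, float]
    p_wald: tuple[float, float]
    mu: tuple[float, float]
    g: np.ndarray                      # 2x2 polygenic covariance
    resid_var: tuple[float, float]
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool                     # |genetic correlation| pinned at 0.999
    confounded: bool                   # A indistinguishable from identity
    trajectory: list[float] = field(default_factory=list)

    @property
    def genetic_correlation(self) -> float:
        g11, g22 = self.g[0, 0], self.g[1, 1]
        if g11 <= 0 or g22 <= 0:
            return float("nan")
        return float(self.g[0, 1] / math.sqrt(g11 * g22))


class _Rotated:
    """Model data rotated by the eigenvectors of A (per-block 2x2 form)."""

    def __init__(self, spec: BivariateModelSpec, eig=None):
        # eig: optional precomputed (eigenvalues, eigenvectors) of A, so a
        # panel-wide decomposition can be shared across many lead-SNP fits
        s, u = np.linalg.eigh(spec.a) if eig is None else eig
        self.s = np.maximum(s, 0.0)
        self.y1 = u.T @ spec.y1
        self.y2 = u.T @ spec.y2
        n = len(self.y1)
        one = u.T @ np.ones(n)
        if spec.m is None:
            f1 = np.zeros((n, 2))
            f2 = np.zeros((n, 2))
            f1[:, 0] = one
            f2[:, 1] = one
        else:
            mm = u.T @ spec.m
            f1 = np.zeros((n, 4))
            f2 = np.zeros((n, 4))
            f1[:, 0] = one
            f2[:, 1] = one
            f1[:, 2] = mm
            f2[:, 3] = mm
        self.f1, self.f2 = f1, f2
        self.n = n
        self.p = f1.shape[1]


def _sigma_inv(rot: _Rotated, theta: np.ndarray):
    """Per-block inverse of s_i G + diag(e1, e2); returns (a, b, c, logdet)."""
    g11, g12, g22, e1, e2 = theta
    s = rot.s
    s11 = s * g11 + e1
    s12 = s * g12
    s22 = s * g22 + e2
    det = s11 * s22 - s12**2
    if np.any(det <= 0) or np.any(s11 <= 0) or np.any(s22 <= 0):
        return None
    return s22 / det, -s12 / det, s11 / det, float(np.log(det).sum())


def _core(rot: _Rotated, theta: np.ndarray):
    """Shared REML quantities at theta; None when theta is inadmissible."""
    inv = _sigma_inv(rot, theta)
    if inv is None:
        return None
    a, b, c, logdet = inv
    f1, f2, y1, y2 = rot.f1, rot.f2, rot.y1, rot.y2
    b1 = a[:, None] * f1 + b[:, None] * f2      # rows of V^-1 X, trait 1
    b2 = b[:, None] * f1 + c[:, None] * f2
    xtvx = f1.T @ b1 + f2.T @ b2
    xtvy = b1.T @ y1 + b2.T @ y2
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return None
    bhat = np.linalg.solve(xtvx, xtvy)
    p1 = a * y1 + b * y2 - b1 @ bhat            # Py, trait-1 block
    p2 = b * y1 + c * y2 - b2 @ bhat
    ypy = float(y1 @ p1 + y2 @ p2)
    ll = -0.5 * (logdet + logdet_x + ypy)
    xtvx_inv = np.linalg.inv(xtvx)
    tr_p_e = (
        float(a.sum()) - float(np.trace(xtvx_inv @ (b1.T @ b1))),
        float(c.sum()) - float(np.trace(xtvx_inv @ (b2.T @ b2))),
    )
    return dict(a=a, b=b, c=c, b1=b1, b2=b2, xtvx=xtvx, bhat=bhat,
                p1=p1, p2=p2, loglik=ll, tr_p_e=tr_p_e)


def restricted_loglik(spec: BivariateModelSpec, theta) -> float:
    """Restricted log-likelihood (constant terms dropped) at
    theta = (g11, g12, g22, sigma_e1^2, sigma_e2^2).

    Returns -inf outside the parameter space (G not PSD or a residual
    variance <= 0)."""
    theta = np.asarray(theta, dtype=float)
    g11, g12, g22, e1, e2 = theta
    if e1 <= 0 or e2 <= 0 or g11 < 0 or g22 < 0 \
            or g12**2 > g11 * g22 * (1 + 1e-9) + 1e-300:
        return -np.inf
    core = _core(_Rotated(spec), np.asarray(theta, dtype=float))
    if core is None:
        return -np.inf
    return core["loglik"]


def _derivatives(rot: _Rotated, core: dict):
    """REML gradient and average-information matrix at the current theta."""
    s = rot.s
    a, b, c = core["a"], core["b"], core["c"]
    b1, b2 = core["b1"], core["b2"]
    p1, p2 = core["p1"], core["p2"]
    xtvx = core["xtvx"]
    f1, f2 = rot.f1, rot.f2

    # q_j = V_j P y per component, as (trait1, trait2) blocks
    qs = [
        (s * p1, np.zeros_like(p1)),        # g11
        (s * p2, s * p1),                   # g12
        (np.zeros_like(p1), s * p2),        # g22
        (p1, np.zeros_like(p1)),            # e1
        (np.zeros_like(p2), p2),            # e2
    ]
    # tr(V^-1 V_j)
    tr_vinv = np.array([
        float((s * a).sum()),
        2.0 * float((s * b).sum()),
        float((s * c).sum()),
        float(a.sum()),
        float(c.sum()),
    ])
    # tr((X'V^-1X)^-1 X'V^-1 V_j V^-1 X)
    sb1 = s[:, None] * b1
    sb2 = s[:, None] * b2
    ms = [
        b1.T @ sb1,
        b1.T @ sb2 + b2.T @ sb1,
        b2.T @ sb2,
        b1.T @ b1,
        b2.T @ b2,
    ]
    xtvx_inv = np.linalg.inv(xtvx)
    tr_p = tr_vinv - np.array([float(np.trace(xtvx_inv @ m)) for m in ms])
    ypvjpy = np.array([
        float(p1 @ (s * p1)),
        2.0 * float(p1 @ (s * p2)),
        float(p2 @ (s * p2)),
        float(p1 @ p1),
        float(p2 @ p2),
    ])
    grad = -0.5 * (tr_p - ypvjpy)

    # P q_k for the AI matrix
    pq = []
    for q1, q2 in qs:
        t1 = a * q1 + b * q2
        t2 = b * q1 + c * q2
        w = np.linalg.solve(xtvx, f1.T @ t1 + f2.T @ t2)
        pq.append((t1 - b1 @ w, t2 - b2 @ w))
    ai = np.empty((5, 5))
    for j in range(5):
        for k in range(j, 5):
            val = 0.5 * float(qs[j][0] @ pq[k][0] + qs[j][1] @ pq[k][1])
            ai[j, k] = ai[k, j] = val
    return grad, ai


def _em_step(rot: _Rotated, core: dict, theta: np.ndarray) -> np.ndarray:
    """One EM-REML update; keeps G PSD by construction.

    G_new averages the conditional second moments of the per-block
    polygenic effects scaled by the eigenvalue; blocks with a zero
    eigenvalue carry no information about G and are excluded.  Residual
    variances use the standard gradient form of the EM update.
    """
    s = rot.s
    g = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    a, b, c = core["a"], core["b"], core["c"]
    b1, b2 = core["b1"], core["b2"]
    p1, p2 = core["p1"], core["p2"]
    xtvx_inv = np.linalg.inv(core["xtvx"])
    pos = s > 1e-12 * max(1.0, s.max())
    q = int(pos.sum())
    # diagonal 2x2 blocks of P: W_ii = Sigma_i^-1 - B_i (X'V^-1X)^-1 B_i'
    w11 = a - np.einsum("ij,jk,ik->i", b1, xtvx_inv, b1)
    w12 = b - np.einsum("ij,jk,ik->i", b1, xtvx_inv, b2)
    w22 = c - np.einsum("ij,jk,ik->i", b2, xtvx_inv, b2)
    g11, g12, g22 = theta[0], theta[1], theta[2]
    u1 = s * (g11 * p1 + g12 * p2)           # BLUP of the rotated u
    u2 = s * (g12 * p1 + g22 * p2)
    gwg11 = g11**2 * w11 + 2 * g11 * g12 * w12 + g12**2 * w22
    gwg12 = g11 * g12 * w11 + (g11 * g22 + g12**2) * w12 + g12 * g22 * w22
    gwg22 = g12**2 * w11 + 2 * g12 * g22 * w12 + g22**2 * w22
    sp = s[pos]
    g_new = np.array([
        [(u1[pos] ** 2 / sp + g11 - sp * gwg11[pos]).mean(),
         (u1[pos] * u2[pos] / sp + g12 - sp * gwg12[pos]).mean()],
        [0.0,
         (u2[pos] ** 2 / sp + g22 - sp * gwg22[pos]).mean()],
    ])
    g_new[1, 0] = g_new[0, 1]
    n = rot.n
    e1, e2 = theta[3], theta[4]
    # gradient-form EM for the residuals (V_j = E_jj x I)
    grad_e1 = -0.5 * (core["tr_p_e"][0] - float(p1 @ p1))
    grad_e2 = -0.5 * (core["tr_p_e"][1] - float(p2 @ p2))
    e1_new = e1 + 2.0 * e1**2 / n * grad_e1
    e2_new = e2 + 2.0 * e2**2 / n * grad_e2
    return np.array([g_new[0, 0], g_new[0, 1], g_new[1, 1],
                     max(e1_new, 1e-12), max(e2_new, 1e-12)])


def _to_phi(theta: np.ndarray) -> np.ndarray:
    """Map (g11, g12, g22, e1, e2) to the unconstrained working scale
    (l11, l21, l22, log e1, log e2) with G = LL'."""
    g11, g12, g22, e1, e2 = theta
    l11 = math.sqrt(max(g11, 0.0))
    l21 = g12 / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(g22 - l21**2, 0.0))
    return np.array([l11, l21, l22, math.log(e1), math.log(e2)])


def _to_theta(phi: np.ndarray, e_floor: float) -> np.ndarray:
    l11, l21, l22, le1, le2 = phi
    return np.array([
        l11**2, l11 * l21, l21**2 + l22**2,
        max(math.exp(min(le1, 700.0)), e_floor),
        max(math.exp(min(le2, 700.0)), e_floor),
    ])


def _jacobian(phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """d theta / d phi for the Cholesky-log working scale."""
    l11, l21, l22 = phi[0], phi[1], phi[2]
    j = np.zeros((5, 5))
    j[0, 0] = 2 * l11
    j[1, 0] = l21
    j[1, 1] = l11
    j[2, 1] = 2 * l21
    j[2, 2] = 2 * l22
    j[3, 3] = theta[3]
    j[4, 4] = theta[4]
    return j


def fit_bivariate_reml(
    spec: BivariateModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    eig=None,
) -> BivariateFit:
    """AI-REML fit of the bivariate lead-SNP model.

    Starts at G = 0.5 diag(phenotypic variances) with zero covariance and
    residuals at half the phenotypic variances.  The average-information
    step is taken on an unconstrained working scale (Cholesky factor of G,
    log residual variances), so G stays positive semi-definite and the fit
    can reach boundary optima (|genetic correlation| -> 1, flagged) without
    leaving the parameter space.  Steps that would decrease the restricted
    likelihood are halved; if the AI step stalls an EM-REML step (monotone
    by construction) is taken instead.  Convergence is declared when
    neither step changes the restricted log-likelihood by >= ``tol``.
    """
    rot = _Rotated(spec, eig=eig)
    v1, v2 = spec.y1.var(), spec.y2.var()
    scale = 0.5 * (v1 + v2)
    theta = np.array([0.5 * v1, 0.0, 0.5 * v2, 0.5 * v1, 0.5 * v2])
    confounded = bool(np.ptp(rot.s) < 1e-8 * max(1.0, rot.s.max()))
    core = _core(rot, theta)
    if core is None:
        raise RuntimeError("initial variance components inadmissible")
    trajectory = [core["loglik"]]
    converged = False
    boundary = False
    n_iter = 0
    e_floor = _VAR_FLOOR * scale

    def admissible(th: np.ndarray) -> bool:
        g11, g12, g22, e1, e2 = th
        return (e1 >= e_floor and e2 >= e_floor and g11 >= 0.0 and g22 >= 0.0
                and g12**2 <= g11 * g22 * (1 + 1e-12))

    prev_theta = None
    for n_iter in range(1, max_iter + 1):
        grad, ai = _derivatives(rot, core)
        best_ll = core["loglik"]
        # candidate 1: AI step on the variance-component scale (step-halved
        # to stay in the PSD cone)
        ridge = 1e-8 * max(1.0, float(np.abs(np.diag(ai)).max()))
        try:
            step = np.linalg.solve(ai + ridge * np.eye(5), grad)
        except np.linalg.LinAlgError:
            step = grad / max(1.0, np.abs(grad).max())
        candidates = []
        frac = 1.0
        for _ in range(20):
            cand = theta + frac * step
            if admissible(cand):
                candidates.append(cand)
            frac *= 0.5
        # candidate 2: the same AI step mapped through the unconstrained
        # working scale (Cholesky of G, log residuals) — reaches boundary
        # optima that the raw step overshoots
        phi = _to_phi(theta)
        j = _jacobian(phi, theta)
        grad_phi = j.T @ grad
        # include the curvature of the transformation so the working-scale
        # step is a genuine Newton step:  -H_phi = J' AI J - sum_i grad_i D2(theta_i)
        curv = np.zeros((5, 5))
        curv[0, 0] = 2 * grad[0]
        curv[0, 1] = curv[1, 0] = grad[1]
        curv[1, 1] = 2 * grad[2]
        curv[2, 2] = 2 * grad[2]
        curv[3, 3] = grad[3] * theta[3]
        curv[4, 4] = grad[4] * theta[4]
        ai_phi = j.T @ ai @ j - curv
        ridge_p = 1e-8 * max(1.0, float(np.abs(np.diag(ai_phi)).max()))
        try:
            step_phi = np.linalg.solve(ai_phi + ridge_p * np.eye(5), grad_phi)
        except np.linalg.LinAlgError:
            step_phi = grad_phi / max(1.0, np.abs(grad_phi).max())
        frac = 1.0
        for _ in range(20):
            candidates.append(_to_theta(phi + frac * step_phi, e_floor))
            frac *= 0.5
        # candidate 3: EM-REML step (monotone, interior by construction)
        em = _em_step(rot, core, theta)
        em[3] = max(em[3], e_floor)
        em[4] = max(em[4], e_floor)
        if admissible(em):
            candidates.append(em)
        # candidate 4: extrapolation along the last accepted move, which
        # accelerates the crawl along a curved boundary ridge
        if prev_theta is not None:
            direction = theta - prev_theta
            for k in (2.0, 4.0, 8.0, 16.0):
                cand = theta + k * direction
                if admissible(cand):
                    candidates.append(cand)
        best_cand, best_core = None, None
        for cand in candidates:
            cc = _core(rot, cand)
            if cc is not None and (best_core is None
                                   or cc["loglik"] > best_core["loglik"]):
                best_cand, best_core = cand, cc
        if best_core is None or best_core["loglik"] < best_ll + tol:
            converged = True
            if best_core is not None and best_core["loglik"] > best_ll:
                theta, core = best_cand, best_core
            trajectory.append(core["loglik"])
            break
        prev_theta = theta
        theta, core = best_cand, best_core
        trajectory.append(core["loglik"])
    if not converged:
        raise RuntimeError(
            f"bivariate AI-REML did not converge in {max_iter} iterations; "
            f"trajectory tail {trajectory[-5:]}"
        )
    g = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    if g[0, 0] > 0 and g[1, 1] > 0:
        if abs(g[0, 1]) >= _GCORR_BOUND * math.sqrt(g[0, 0] * g[1, 1]) - 1e-12:
            boundary = True
    bhat = core["bhat"]
    cov_b = np.linalg.inv(core["xtvx"])
    if spec.m is None:
        beta = (float("nan"), float("nan"))
        beta_se = (float("nan"), float("nan"))
        p_wald = (float("nan"), float("nan"))
    else:
        beta = (float(bhat[2]), float(bhat[3]))
        beta_se = (float(math.sqrt(cov_b[2, 2])), float(math.sqrt(cov_b[3, 3])))
        z = (beta[0] / beta_se[0], beta[1] / beta_se[1])
        p_wald = tuple(
            float(np.clip(2 * stats.norm.sf(abs(zz)), 1e-300, 1.0)) for zz in z
        )
    return BivariateFit(
        beta=beta,
        beta_se=beta_se,
        p_wald=p_wald,
        mu=(float(bhat[0]), float(bhat[1])),
        g=g,
        resid_var=(float(theta[3]), float(theta[4])),
        loglik=core["loglik"],
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        confounded=confounded,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# pleiotropy decision rule


@dataclass(frozen=True)
class PleiotropyVerdict:
    variant_id: str
    traits: tuple[str, str]
    p1: float
    p2: float
    genomewide: ThresholdSpec
    pairwise: ThresholdSpec
    verdict: str  # 'pleiotropic' | 'single-trait' | 'not-significant'


def classify_pleiotropy(
    fit: BivariateFit,
    genomewide: ThresholdSpec,
    pairwise: ThresholdSpec,
    variant_id: str = "",
    traits: tuple[str, str] = ("trait1", "trait2"),
) -> PleiotropyVerdict:
    """Apply the pleiotropy decision rule to a bivariate fit.

    pleiotropic: genome-wide significance for at least one trait AND the
    other trait passing the pairwise threshold alpha/(T x L); single-trait:
    genome-wide for one trait only; not-significant otherwise.
    """
    p1, p2 = fit.p_wald
    if not (np.isfinite(p1) and np.isfinite(p2)):
        raise ValueError("both Wald p-values must be finite")
    if min(p1, p2) < genomewide.p_thresh:
        if max(p1, p2) < pairwise.p_thresh:
            verdict = "pleiotropic"
        else:
            verdict = "single-trait"
    else:
        verdict = "not-significant"
    return PleiotropyVerdict(
        variant_id=variant_id,
        traits=tuple(traits),
        p1=p1, p2=p2,
        genomewide=genomewide, pairwise=pairwise,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# two-GRM variance partition


@dataclass
class VariancePartition:
    v_lead: float
    v_background: float
    v_residual: float
    fraction_of_total: float       # v_lead / (v_lead + v_background + v_resid)
    fraction_of_genetic: float     # v_lead / (v_lead + v_background)
    se: np.ndarray                 # asymptotic SEs of (v_lead, v_bg, v_resid)
    fraction_se: float             # delta-method SE of fraction_of_total
    loglik: float
    n_iter: int


def variance_partition_two_grm(
    y: np.ndarray,
    grm_lead: GRM,
    grm_background: GRM,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> VariancePartition:
    """Three-component REML: y = mu + g_lead + g_background + e.

    ``grm_lead`` is built from the lead SNPs only and ``grm_background``
    from all remaining SNPs outside a window around each lead; the lead
    fraction of phenotypic variance mirrors the V(lead SNP)/V(DRP) summary.
    Components are kept non-negative; SEs come from the inverse average-
    information matrix at convergence.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k1 = grm_lead.matrix if isinstance(grm_lead, GRM) else np.asarray(grm_lead)
    k2 = (grm_background.matrix if isinstance(grm_background, GRM)
          else np.asarray(grm_background))
    if k1.shape != (n, n) or k2.shape != (n, n):
        raise ValueError("GRMs do not match phenotype length")
    for name, k in (("lead", k1), ("background", k2)):
        if np.allclose(k, 0.0):
            raise ValueError(f"{name} GRM is all zeros (no variants)")
    x = np.ones((n, 1))
    mats = [k1, k2, np.eye(n)]
    vy = y.var()
    theta = np.array([0.1 * vy, 0.4 * vy, 0.5 * vy])
    floor = _VAR_FLOOR * vy

    def core(th):
        v = th[0] * k1 + th[1] * k2 + th[2] * np.eye(n)
        try:
            cf = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * float(np.log(np.diag(cf)).sum())
        vinv_y = np.linalg.solve(v, y)  # could reuse cf; n is modest
        vinv_x = np.linalg.solve(v, x)
        xtvx = x.T @ vinv_x
        bhat = np.linalg.solve(xtvx, x.T @ vinv_y)
        py = vinv_y - vinv_x @ bhat
        ll = -0.5 * (logdet + float(np.linalg.slogdet(xtvx)[1]) + float(y @ py))
        return dict(v=v, py=py, vinv_x=vinv_x, xtvx=xtvx, loglik=ll)

    c = core(theta)
    if c is None:
        raise RuntimeError("initial components inadmissible")
    trajectory = [c["loglik"]]
    ai = np.eye(3)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        py = c["py"]
        v = c["v"]
        vinv_x, xtvx = c["vinv_x"], c["xtvx"]
        xtvx_inv = np.linalg.inv(xtvx)
        grad = np.empty(3)
        qs = []
        for j, kj in enumerate(mats):
            vinv_kj = np.linalg.solve(v, kj)
            tr_vinv = float(np.trace(vinv_kj))
            mj = vinv_x.T @ kj @ vinv_x
            tr_p = tr_vinv - float(np.trace(xtvx_inv @ mj))
            qj = kj @ py
            grad[j] = -0.5 * (tr_p - float(py @ qj))
            qs.append(qj)
        ai = np.empty((3, 3))
        for j in range(3):
            t = np.linalg.solve(v, qs[j])
            w = np.linalg.solve(xtvx, x.T @ t)
            pq = t - vinv_x @ w
            for k in range(j, 3):
                ai[j, k] = ai[k, j] = 0.5 * float(qs[k] @ pq)
        try:
            step = np.linalg.solve(ai + 1e-10 * np.eye(3) * max(1.0, ai.max()), grad)
        except np.linalg.LinAlgError:
            step = grad / max(1.0, np.abs(grad).max())
        accepted = False
        frac = 1.0
        for _ in range(40):
            cand = theta + frac * step
            cand = np.maximum(cand, [0.0, 0.0, floor])
            cc = core(cand)
            if cc is not None and cc["loglik"] >= c["loglik"] - 1e-12:
                theta, c = cand, cc
                accepted = True
                break
            frac *= 0.5
        if not accepted:
            break
        trajectory.append(c["loglik"])
        if abs(trajectory[-1] - trajectory[-2]) < tol:
            break
    else:
        raise RuntimeError(
            f"two-GRM REML did not converge in {max_iter} iterations"
        )
    total = float(theta.sum())
    genetic = float(theta[0] + theta[1])
    try:
        cov_theta = np.linalg.inv(ai)
        se = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
        # delta method for f = t0 / (t0 + t1 + t2)
        gvec = np.array([
            (total - theta[0]) / total**2, -theta[0] / total**2,
            -theta[0] / total**2,
        ])
        f_se = float(np.sqrt(max(gvec @ cov_theta @ gvec, 0.0)))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
        f_se = float("nan")
    return VariancePartition(
        v_lead=float(theta[0]),
        v_background=float(theta[1]),
        v_residual=float(theta[2]),
        fraction_of_total=float(theta[0] / total),
        fraction_of_genetic=float(theta[0] / genetic) if genetic > 0 else float("nan"),
        se=se,
        fraction_se=f_se,
        loglik=c["loglik"],
        n_iter=n_iter,
    )
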