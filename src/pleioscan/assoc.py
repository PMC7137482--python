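"""Variant QC, genomic relationships and single-trait mixed-model GWAS.

The association scan follows the two-step mixed-linear-model convention:
variance components are estimated once per kinship matrix under the null
(no SNP) model by REML on the eigendecomposition of the GRM, then every
SNP is tested by generalized least squares with the components held fixed.
Kinship is built leave-one-chromosome-out (LOCO) so that the tested SNP's
own chromosome contributes nothing to the polygenic covariance — fitting a
SNP both as a fixed effect and inside the GRM double-counts it and costs
power.  Independent signals on a chromosome are resolved by iteratively
adding the dosage of each discovered lead SNP as a covariate and
rescanning until nothing passes the Bonferroni threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ioformats import GenotypePanel

__all__ = [
    "GRM",
    "ThresholdSpec",
    "LeadSNP",
    "LeadSNPSet",
    "NullLMMFit",
    "filter_variants",
    "compute_grm",
    "fit_null_lmm",
    "gwas_scan",
    "bonferroni_threshold",
    "conditional_lead_scan",
    "hwe_chisq",
]

_P_FLOOR = 1e-300  # keep p in (0, 1] under extreme signals


@dataclass
class GRM:
    """Genomic relationship matrix (GCTA form, standardized dosages)."""

    matrix: np.ndarray
    kind: str  # 'full' | 'loco(<chrom>)' | 'lead-snps' | 'background-excluded'
    n_variants: int
    samples: list[str]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues clipped at zero)."""
        if not hasattr(self, "_eig"):
            d, u = np.linalg.eigh(self.matrix)
            self._eig = (np.maximum(d, 0.0), u)
        return self._eig


@dataclass(frozen=True)
class ThresholdSpec:
    """Bonferroni family-wise significance threshold."""

    alpha: float
    m: int
    p_thresh: float
    neglog10_thresh: float


@dataclass(frozen=True)
class LeadSNP:
    chrom: str
    id: str
    pos: int
    round_index: int
    p: float


@dataclass
class LeadSNPSet:
    """Ordered conditional-discovery results, one entry per lead SNP."""

    leads: list[LeadSNP] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [l.id for l in self.leads]

    def for_chrom(self, chrom: str) -> list[LeadSNP]:
        return [l for l in self.leads if l.chrom == str(chrom)]

    def __len__(self) -> int:
        return len(self.leads)


# ---------------------------------------------------------------------------
# QC


def hwe_chisq(n_ref: int, n_het: int, n_alt: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    Returns ``(chi2, p)``.  Monomorphic counts give chi2 = 0, p = 1.
    """
    n = n_ref + n_het + n_alt
    if n == 0:
        raise ValueError("no genotypes")
    q = (2 * n_alt + n_het) / (2 * n)  # ALT frequency
    if q in (0.0, 1.0):
        return 0.0, 1.0
    exp = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypePanel, dict]:
    """Remove variants with MAF < maf_min or HWE p < hwe_alpha.

    Monomorphic variants are always removed and counted separately.
    The report gives counts per filter; a variant failing several filters
    is counted once, by the first rule that catches it
    (monomorphic -> MAF -> HWE).
    """
    hard = np.rint(panel.dosages).astype(int)
    n_ref = (hard == 0).sum(axis=0)
    n_het = (hard == 1).sum(axis=0)
    n_alt = (hard == 2).sum(axis=0)
    maf = panel.maf()
    mono = maf == 0.0
    low_maf = (~mono) & (maf < maf_min)
    hwe_fail = np.zeros(panel.n_variants, dtype=bool)
    for j in np.flatnonzero(~mono & ~low_maf):
        _, p = hwe_chisq(int(n_ref[j]), int(n_het[j]), int(n_alt[j]))
        hwe_fail[j] = p < hwe_alpha
    keep = ~(mono | low_maf | hwe_fail)
    report = {
        "n_input": panel.n_variants,
        "n_monomorphic": int(mono.sum()),
        "n_maf": int(low_maf.sum()),
        "n_hwe": int(hwe_fail.sum()),
        "n_kept": int(keep.sum()),
        "maf_min": maf_min,
        "hwe_alpha": hwe_alpha,
    }
    return panel.subset_variants(keep), report


# ---------------------------------------------------------------------------
# GRM


def compute_grm(panel: GenotypePanel, exclude_chrom: str | None = None) -> GRM:
    """GRM(j,k) = (1/M') sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i)).

    ``p_i`` is the ALT frequency; monomorphic variants are skipped.  With
    ``exclude_chrom`` every variant on that chromosome is left out
    (leave-one-chromosome-out kinship).
    """
    sub = panel if exclude_chrom is None else panel.exclude_chrom(exclude_chrom)
    p = sub.alt_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError(
            "fewer than 2 polymorphic variants remain"
            + (f" after excluding chromosome {exclude_chrom}" if exclude_chrom else "")
        )
    x = sub.dosages[:, poly]
    p = p[poly]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    kind = "full" if exclude_chrom is None else f"loco({exclude_chrom})"
    return GRM(z @ z.T / m, kind, m, list(panel.samples))


def loco_kinships(panel: GenotypePanel) -> dict[str, GRM]:
    """All leave-one-chromosome-out GRMs in one pass.

    The full cross-product is accumulated once; each chromosome's
    contribution is then subtracted, so the whole set costs about two
    full-GRM builds instead of one per chromosome.  The result is
    bit-compatible with ``compute_grm(panel, exclude_chrom=c)``.
    """
    p = panel.alt_freq()
    poly = (p > 0) & (p < 1)
    z = (panel.dosages[:, poly] - 2 * p[poly]) / np.sqrt(
        2 * p[poly] * (1 - p[poly])
    )
    chrom = panel.variants["chrom"].astype(str).to_numpy()[poly]
    full = z @ z.T
    m_total = z.shape[1]
    out: dict[str, GRM] = {}
    for c in panel.chromosomes():
        on = chrom == c
        m_out = int(m_total - on.sum())
        if m_out < 2:
            raise ValueError(
                f"fewer than 2 polymorphic variants remain after excluding "
                f"chromosome {c}"
            )
        zc = z[:, on]
        out[c] = GRM((full - zc @ zc.T) / m_out, f"loco({c})", m_out,
                     list(panel.samples))
    return out


# ---------------------------------------------------------------------------
# null LMM (REML via eigendecomposition)


@dataclass
class NullLMMFit:
    """REML variance components of y = mu + g + e with g ~ N(0, sigma_g^2 K)."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    h2_se: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    confounded: bool  # GRM indistinguishable from identity

    @property
    def total_var(self) -> float:
        return self.sigma_g2 + self.sigma_e2


def _reml_profile(h2: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray):
    """Restricted log-likelihood profiled over the total variance.

    Returns (loglik, s2_total) for weights w = h2*d + (1-h2).
    """
    n = len(ystar)
    w = h2 * d + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf, np.nan
    xtx = (xstar**2 / w).sum()
    xty = (xstar * ystar / w).sum()
    yty = (ystar**2 / w).sum()
    ypy = yty - xty**2 / xtx
    if ypy <= 0:
        return -np.inf, np.nan
    s2 = ypy / (n - 1)
    ll = -0.5 * (
        np.log(w).sum() + (n - 1) * np.log(s2) + np.log(xtx) + (n - 1)
    )
    return float(ll), float(s2)


def fit_null_lmm(y: np.ndarray, grm: GRM) -> NullLMMFit:
    """REML fit of the null (no-SNP) mixed model via GRM eigendecomposition.

    The heritability is profiled on [0, 0.999] with total variance
    concentrated out; components are non-negative by construction.  The SE
    of h2 comes from the observed information (numerical second
    derivative) at the optimum.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 samples")
    if grm.matrix.shape != (n, n):
        raise ValueError("GRM does not match sample count")
    d, u = grm.eig()
    ystar = u.T @ y
    xstar = u.T @ np.ones(n)
    confounded = bool(np.ptp(d) < 1e-8 * max(1.0, d.max()))

    def neg(h2: float) -> float:
        return -_reml_profile(h2, d, ystar, xstar)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(0.0, 0.999), method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"REML failed to converge; last iterate h2={res.x}")
    h2 = float(res.x)
    ll, s2 = _reml_profile(h2, d, ystar, xstar)
    # observed information on h2 by central differences
    eps = 1e-4
    lo, hi = max(h2 - eps, 0.0), min(h2 + eps, 0.999)
    f0, fl, fh = -neg(h2), -neg(lo), -neg(hi)
    curv = -(fl - 2 * f0 + fh) / ((hi - lo) / 2) ** 2
    h2_se = float(1.0 / math.sqrt(curv)) if curv > 0 else float("inf")
    return NullLMMFit(
        sigma_g2=h2 * s2,
        sigma_e2=(1 - h2) * s2,
        h2=h2,
        loglik=ll,
        h2_se=h2_se,
        eigvals=d,
        eigvecs=u,
        confounded=confounded,
    )


# ---------------------------------------------------------------------------
# GWAS scan


def bonferroni_threshold(alpha: float, m: int) -> ThresholdSpec:
    """Family-wise threshold p < alpha / M for M tests."""
    if m < 1:
        raise ValueError("M must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p = alpha / m
    return ThresholdSpec(alpha=alpha, m=m, p_thresh=p, neglog10_thresh=-math.log10(p))


def _scan_block(
    x: np.ndarray,
    y: np.ndarray,
    covs: np.ndarray,
    weights: np.ndarray,
    use_t_dist: bool,
    rescale_residual: bool = True,
    fixed_s2: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """GLS scan of the columns of x given covariates and V-weights.

    Works in the whitened space (columns already rotated by the GRM
    eigenvectors).  With ``rescale_residual`` the residual scale is
    re-estimated per SNP, so the identity-GRM, zero-genetic-variance case
    reduces exactly to OLS; without it the SE uses the fixed covariance
    ``fixed_s2 * V`` from the null fit, which makes the test exactly
    invariant to covariates orthogonal to the SNP in the V-metric.
    Returns (beta, se, t, p, skipped) where skipped marks SNPs collinear
    with the covariates.
    """
    n, m = x.shape
    sw = 1.0 / np.sqrt(weights)
    xt = x * sw[:, None]
    yt = y * sw
    ct = covs * sw[:, None]
    k = ct.shape[1]
    ctc = ct.T @ ct
    cty = np.linalg.solve(ctc, ct.T @ yt)
    yperp = yt - ct @ cty
    ctx = np.linalg.solve(ctc, ct.T @ xt)
    xperp = xt - ct @ ctx
    xx = (xperp**2).sum(axis=0)
    xtot = (xt**2).sum(axis=0)
    skipped = xx <= 1e-3 * np.maximum(xtot, 1e-30)  # r2 with covariates > 0.999
    xx_safe = np.where(skipped | (xx == 0), 1.0, xx)
    beta = (xperp * yperp[:, None]).sum(axis=0) / xx_safe
    dof = n - k - 1
    if rescale_residual:
        rss = (yperp**2).sum() - beta**2 * xx_safe
        s2 = np.maximum(rss, 0.0) / dof
    else:
        s2 = fixed_s2
    se = np.sqrt(s2 / xx_safe)
    se = np.where(se > 0, se, np.nan)
    t = beta / se
    if use_t_dist:
        p = 2 * stats.t.sf(np.abs(t), df=dof)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    p = np.clip(p, _P_FLOOR, 1.0)
    return beta, se, t, p, skipped


def _neglog10_from_t(t: np.ndarray, dof: int, use_t_dist: bool) -> np.ndarray:
    if use_t_dist:
        logp = np.log(2) + stats.t.logsf(np.abs(t), df=dof)
    else:
        logp = np.log(2) + stats.norm.logsf(np.abs(t))
    return -logp / np.log(10)


def gwas_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    loco: bool = True,
    covariate_dosages: list[np.ndarray] | None = None,
    grm: GRM | None = None,
    null_fit: NullLMMFit | None = None,
    mixed: bool = True,
    use_t_dist: bool = False,
    chroms: list[str] | None = None,
    kinships: dict[str, GRM] | None = None,
    rescale_residual: bool = True,
) -> pd.DataFrame:
    """Single-trait association scan; returns a summary-statistic table.

    With ``loco=True`` a separate GRM and null REML fit is produced per
    chromosome, excluding that chromosome's variants.  ``grm``/``null_fit``
    override the kinship (then ``loco`` is ignored); ``mixed=False`` drops
    the polygenic term entirely (plain least-squares scan).  SNPs collinear
    with a covariate (r^2 > 0.999) are skipped and reported with NaN
    statistics.

    The output has the fixed summary-statistic columns plus ``neglog10p``
    (computed in log space, exact far beyond float underflow).
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match panel")
    covs = [np.ones(n)]
    if covariate_dosages:
        covs += [np.asarray(c, dtype=float) for c in covariate_dosages]
    c_raw = np.column_stack(covs)

    frames = []
    todo = chroms if chroms is not None else panel.chromosomes()
    if mixed and loco and grm is None and null_fit is None and kinships is None:
        kinships = loco_kinships(panel)
    global_fit = None
    if mixed and not loco and grm is None and null_fit is None:
        global_fit = fit_null_lmm(y, compute_grm(panel))
    for chrom in todo:
        sub = panel.restrict_chrom(chrom)
        if sub.n_variants == 0:
            continue
        if not mixed:
            weights = np.ones(n)
            u = None
        else:
            if null_fit is not None:
                fit = null_fit
            elif global_fit is not None:
                fit = global_fit
            elif kinships is not None:
                fit = fit_null_lmm(y, kinships[chrom])
            else:
                fit = fit_null_lmm(y, grm)
            tot = fit.total_var
            weights = (fit.sigma_g2 * fit.eigvals + fit.sigma_e2) / tot
            u = fit.eigvecs
        if u is not None:
            x = u.T @ sub.dosages
            yy = u.T @ y
            cc = u.T @ c_raw
            fixed_s2 = fit.total_var
        else:
            x, yy, cc = sub.dosages, y, c_raw
            fixed_s2 = 1.0
        beta, se, t, p, skipped = _scan_block(
            x, yy, cc, weights, use_t_dist,
            rescale_residual=rescale_residual, fixed_s2=fixed_s2,
        )
        dof = n - cc.shape[1] - 1
        neglog = _neglog10_from_t(t, dof, use_t_dist)
        eaf = sub.alt_freq()
        out = sub.variants.copy()
        out["effect_allele"] = out.pop("alt")
        out["other_allele"] = out.pop("ref")
        out["eaf"] = eaf
        out["beta"] = beta
        out["se"] = se
        out["t"] = t
        out["p"] = p
        out["n"] = n
        out["neglog10p"] = neglog
        if skipped.any():
            out.loc[skipped, ["beta", "se", "t", "neglog10p"]] = np.nan
            out.loc[skipped, "p"] = 1.0
        frames.append(out)
    cols = ["chrom", "pos", "id", "effect_allele", "other_allele",
            "eaf", "beta", "se", "t", "p", "n", "neglog10p"]
    return pd.concat(frames, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# conditional lead-SNP scan


def conditional_lead_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    threshold: ThresholdSpec,
    loco: bool = True,
    mixed: bool = True,
    refit_components: bool = False,
    max_rounds: int = 20,
    use_t_dist: bool = False,
    kinships: dict[str, GRM] | None = None,
) -> LeadSNPSet:
    """Iterative conditional discovery of independent lead SNPs.

    Per chromosome: scan, take the most significant SNP if it beats the
    threshold (ties broken by smaller position), append its dosage to the
    covariate list, rescan; stop when nothing passes.  Variance components
    stay fixed at the null fit unless ``refit_components`` is set.
    """
    leads: list[LeadSNP] = []
    if mixed and loco and kinships is None:
        kinships = loco_kinships(panel)
    global_grm = None
    if mixed and not loco:
        global_grm = compute_grm(panel)
    for chrom in panel.chromosomes():
        fit = None
        if mixed:
            k = kinships[chrom] if loco else global_grm
            fit = fit_null_lmm(y, k)
        covs: list[np.ndarray] = []
        for rnd in range(1, max_rounds + 2):
            if rnd > max_rounds:
                raise RuntimeError(
                    f"more than {max_rounds} leads on chromosome {chrom}; "
                    "likely collinearity pathology"
                )
            stats_df = gwas_scan(
                panel, y,
                covariate_dosages=covs or None,
                null_fit=fit, mixed=mixed,
                use_t_dist=use_t_dist, chroms=[chrom],
            )
            if refit_components and mixed and covs:
                # re-estimate components treating lead dosages as regressed out
                fit = fit_null_lmm(_residualize(y, covs), k)
            ok = stats_df["p"] < threshold.p_thresh
            if not ok.any():
                break
            cand = stats_df[ok].sort_values(
                ["neglog10p", "pos"], ascending=[False, True], kind="stable"
            )
            top = cand.iloc[0]
            leads.append(
                LeadSNP(chrom=str(top.chrom), id=str(top.id), pos=int(top.pos),
                        round_index=rnd, p=float(top.p))
            )
            covs.append(panel.dosages[:, panel.variant_index(str(top.id))].copy())
    return LeadSNPSet(leads)


def _residualize(y: np.ndarray, covs: list[np.ndarray]) -> np.ndarray:
    c = np.column_stack([np.ones(len(y))] + covs)
    b, *_ = np.linalg.lstsq(c, y, rcond=None)
    return y - c @ b
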