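"""Multi-trait chi-square meta-analysis of GWAS summary statistics.

For variant i with per-trait signed t statistics t_i, the multi-trait
statistic is the quadratic form chi2_MT,i = t_i' V^-1 t_i, compared to a
chi-square with as many degrees of freedom as traits.  V is the
between-trait correlation matrix of the t statistics, estimated over
near-null variants (|t| below a cutoff for every trait) so that large QTL
do not inflate it, and shrunk toward the identity just enough to keep it
well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ThresholdSpec

__all__ = [
    "TraitCorrelationMatrix",
    "estimate_trait_correlation",
    "multitrait_chisq",
    "meta_scan",
    "join_tables",
]

_COND_MAX = 1e6


def _truncated_corr_map(cutoff: float, grid: int = 41, nodes: int = 64):
    """Correlation of a standard bivariate normal doubly truncated to the
    square |x|, |y| < cutoff, tabulated over the true correlation.

    Restricting the V estimate to near-null t statistics attenuates the
    correlation (|t| < 2 shrinks rho = 0.5 to ~0.42); this map lets the
    estimator invert that attenuation.
    """
    x, w = np.polynomial.legendre.leggauss(nodes)
    x = x * cutoff
    w = w * cutoff
    xx, yy = np.meshgrid(x, x)
    ww = np.outer(w, w)
    rhos = np.linspace(-0.999, 0.999, grid)
    out = np.empty(grid)
    for i, r in enumerate(rhos):
        det = 1.0 - r * r
        f = np.exp(-(xx**2 - 2 * r * xx * yy + yy**2) / (2 * det)) / (
            2 * np.pi * np.sqrt(det))
        mxy = float((ww * xx * yy * f).sum())
        mx2 = float((ww * xx**2 * f).sum())
        out[i] = mxy / mx2
    return rhos, out


_TRUNC_MAPS: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _debias_truncated(r_obs: float, cutoff: float) -> float:
    """Invert the truncation attenuation of a correlation estimate."""
    if cutoff not in _TRUNC_MAPS:
        _TRUNC_MAPS[cutoff] = _truncated_corr_map(cutoff)
    rhos, trunc = _TRUNC_MAPS[cutoff]
    if r_obs <= trunc[0]:
        return -1.0
    if r_obs >= trunc[-1]:
        return 1.0
    return float(np.interp(r_obs, trunc, rhos))


@dataclass
class TraitCorrelationMatrix:
    """T x T between-trait correlation matrix used inside chi2_MT."""

    traits: list[str]
    matrix: np.ndarray
    shrinkage: float
    condition_number: float
    degenerate: bool = False  # any off-diagonal at +/- 1

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def join_tables(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, np.ndarray]:
    """Inner-join summary tables on (chrom, pos, id); returns (meta, t matrix).

    ``meta`` carries the shared variant index columns; the t matrix is
    (n_variants, n_traits).
    """
    key = ["chrom", "pos", "id"]
    base = tables[0][key + ["t"]].rename(columns={"t": "t0"})
    for i, tab in enumerate(tables[1:], start=1):
        base = base.merge(
            tab[key + ["t"]].rename(columns={"t": f"t{i}"}),
            on=key, how="inner",
        )
    tmat = base[[f"t{i}" for i in range(len(tables))]].to_numpy(dtype=float)
    keep = np.isfinite(tmat).all(axis=1)
    return base.loc[keep, key].reset_index(drop=True), tmat[keep]


def estimate_trait_correlation(
    tables: list[pd.DataFrame],
    max_abs_t: float | None = 2.0,
    traits: list[str] | None = None,
    min_variants: int = 1000,
) -> TraitCorrelationMatrix:
    """Pearson correlation of signed t statistics across shared variants.

    Variants where any trait has |t| >= ``max_abs_t`` are excluded
    (``None`` disables the cutoff), so that large QTL do not inflate the
    estimate; the attenuation this truncation causes under the null is
    inverted through the tabulated truncated-normal correlation map.  The
    estimate is shrunk toward the identity, V <- (1-lambda) V + lambda I
    with the smallest lambda in {0, 0.01, 0.02, ...} giving condition
    number <= 1e6.
    """
    if traits is None:
        traits = [f"trait{i + 1}" for i in range(len(tables))]
    _, tmat = join_tables(tables)
    if tmat.shape[0] < min_variants:
        raise ValueError(
            f"only {tmat.shape[0]} shared variants; need >= {min_variants}"
        )
    if max_abs_t is not None:
        tmat = tmat[(np.abs(tmat) < max_abs_t).all(axis=1)]
    if np.any(tmat.std(axis=0) == 0):
        raise ValueError("a trait has constant t statistics")
    v = np.corrcoef(tmat.T)
    v = np.atleast_2d(v)
    if max_abs_t is not None:
        t_dim = len(traits)
        for i in range(t_dim):
            for k in range(i + 1, t_dim):
                rho = _debias_truncated(float(v[i, k]), float(max_abs_t))
                v[i, k] = v[k, i] = rho
    off = v[~np.eye(len(traits), dtype=bool)]
    degenerate = bool(off.size and np.any(np.abs(off) >= 1.0 - 1e-12))
    lam = 0.0
    while True:
        shrunk = (1 - lam) * v + lam * np.eye(len(traits))
        w = np.linalg.eigvalsh(shrunk)
        if w.min() > 0 and w.max() / w.min() <= _COND_MAX:
            break
        lam = round(lam + 0.01, 10)
        if lam > 1:
            raise RuntimeError("shrinkage failed to produce a PD matrix")
    return TraitCorrelationMatrix(
        traits=list(traits),
        matrix=shrunk,
        shrinkage=lam,
        condition_number=float(w.max() / w.min()),
        degenerate=degenerate,
    )


def multitrait_chisq(
    t_vec: np.ndarray, v: TraitCorrelationMatrix | np.ndarray
) -> tuple[float, float]:
    """chi2_MT = t' V^-1 t with df = number of traits; returns (chi2, p)."""
    vm = v.matrix if isinstance(v, TraitCorrelationMatrix) else np.asarray(v)
    t = np.asarray(t_vec, dtype=float)
    if t.shape != (vm.shape[0],):
        raise ValueError(f"t vector length {t.shape} does not match V {vm.shape}")
    chi2 = float(t @ np.linalg.solve(vm, t))
    return chi2, float(stats.chi2.sf(chi2, df=len(t)))


def meta_scan(
    tables: list[pd.DataFrame],
    v: TraitCorrelationMatrix,
    threshold: ThresholdSpec,
    clump_radius_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide chi2_MT scan plus greedy distance-clumped meta lead SNPs.

    Returns ``(results, leads)``.  ``results`` has one row per shared
    variant with chi2_mt, df, p and neglog10p; ``leads`` is the subset
    chosen by repeatedly taking the most significant remaining variant
    with p < threshold and masking +/- clump_radius_bp around it.
    """
    meta, tmat = join_tables(tables)
    vinv = v.inverse
    chi2 = np.einsum("ij,jk,ik->i", tmat, vinv, tmat)
    df = len(tables)
    out = meta.copy()
    for i in range(df):
        out[f"t_{v.traits[i]}"] = tmat[:, i]
    out["chi2_mt"] = chi2
    out["df"] = df
    out["p"] = np.clip(stats.chi2.sf(chi2, df=df), 1e-300, 1.0)
    out["neglog10p"] = -stats.chi2.logsf(chi2, df=df) / np.log(10)

    lead_rows = []
    masked = np.zeros(len(out), dtype=bool)
    chrom = out["chrom"].astype(str).to_numpy()
    pos = out["pos"].to_numpy()
    order = np.argsort(-out["neglog10p"].to_numpy(), kind="stable")
    for j in order:
        if masked[j] or out["p"].iat[j] >= threshold.p_thresh:
            continue
        lead_rows.append(j)
        masked |= (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= clump_radius_bp)
    leads = out.iloc[lead_rows].reset_index(drop=True)
    return out, leads
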