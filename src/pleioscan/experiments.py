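"""Benchmark experiments exercising the pipeline under known truth.

Each function simulates a cohort with a known causal architecture, runs
the relevant pipeline stages, and measures a calibration or recovery
property: null calibration of the multi-trait statistic, the power
advantage of the multi-trait test over single-trait scans, recovery of a
simulated genetic correlation by cross-trait LD-score regression,
recovery of the lead-SNP variance fraction by the two-GRM partition, and
the discrimination between a pleiotropic variant and a linked pair in the
bivariate model.

Problem sizes are chosen so the whole battery runs on one CPU in minutes;
where a scenario mirrors a larger cohort, effect sizes are scaled to
preserve the per-variant non-centrality (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as spstats

from . import assoc, bivar, ldsc, metamulti, simdata

__all__ = [
    "null_calibration",
    "meta_power",
    "rg_recovery",
    "partition_recovery",
    "scenario_discrimination",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _sumstat_tables(panel, ys, **scan_kw):
    return [assoc.gwas_scan(panel, y, **scan_kw) for y in ys]


def null_calibration(
    seed: int,
    n_samples: int = 2000,
    n_variants: int = 10_000,
    n_traits: int = 3,
    resid_corr: float = 0.5,
) -> dict:
    """Global null with correlated traits: chi2_MT distribution and type-I error.

    Simulates unlinked variants and pure-noise traits with the given
    residual correlation, runs the LOCO mixed-model scan per trait,
    estimates V, and compares chi2_MT with the chi-square reference by a
    Kolmogorov-Smirnov test.  The single-trait type-I error at p < 0.05 is
    measured on the first trait.
    """
    s_geno, s_pheno = _seeds(seed, 2)
    n_chrom = 5
    per_chrom = n_variants // (n_chrom * 4)
    specs = [
        simdata.LDBlockSpec(n_blocks=per_chrom, snps_per_block=4,
                            block_span_bp=20_000, within_block_r2=0.0,
                            chrom=str(c + 1))
        for c in range(n_chrom)
    ]
    panel = simdata.simulate_genotypes(specs, n_samples, s_geno)
    rng = np.random.default_rng(s_pheno)
    corr = np.full((n_traits, n_traits), resid_corr)
    np.fill_diagonal(corr, 1.0)
    ys = (rng.standard_normal((n_samples, n_traits))
          @ np.linalg.cholesky(corr).T).T
    kin = assoc.loco_kinships(panel)
    tables = _sumstat_tables(panel, ys, loco=True, kinships=kin)
    # no near-null restriction here: under a global null every variant is
    # null, and estimating V from the same t matrix makes the quadratic
    # form self-normalizing (the restriction is a guard against QTL, which
    # this diagnostic has none of)
    v = metamulti.estimate_trait_correlation(tables, max_abs_t=None)
    _, tmat = metamulti.join_tables(tables)
    chi2 = np.einsum("ij,jk,ik->i", tmat, v.inverse, tmat)
    ks = spstats.kstest(chi2, spstats.chi2(df=n_traits).cdf)
    type1 = float((tables[0]["p"] < 0.05).mean())
    return {
        "ks_p": float(ks.pvalue),
        "type1_rate": type1,
        "n_variants": len(tables[0]),
        "n_samples": n_samples,
    }


def meta_power(
    seed: int,
    n_samples: int = 2000,
    n_variants: int = 2000,
    n_causal_per_cohort: int = 20,
    n_cohorts: int = 10,
    var_per_causal: float = 0.01,
    resid_corr: float = 0.5,
) -> dict:
    """Detection rate of pleiotropic variants: multi-trait vs best single-trait.

    Each cohort carries unlinked causal variants with equal effects on all
    three traits plus residual correlation; detection is at the Bonferroni
    threshold for the scanned variants.  Rates are pooled over
    ``n_cohorts * n_causal_per_cohort`` causal variants; the single-trait
    reference is the best-performing individual trait scan (the multi-trait
    test is compared against running each single-trait GWAS, not against a
    min-p combination of them).
    """
    seeds = _seeds(seed, n_cohorts)
    thr = assoc.bonferroni_threshold(0.05, n_variants)
    corr = np.full((3, 3), resid_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    multi_hits = total = 0
    single_hits = np.zeros(3)
    for s in seeds:
        s_geno, s_y = _seeds(s, 2)
        spec = simdata.LDBlockSpec(
            n_blocks=n_variants // 4, snps_per_block=4, block_span_bp=20_000,
            within_block_r2=0.0)
        panel = simdata.simulate_genotypes(spec, n_samples, s_geno)
        rng = np.random.default_rng(s_y)
        causal = rng.choice(panel.n_variants, size=n_causal_per_cohort,
                            replace=False)
        x = panel.dosages[:, causal]
        xs = (x - x.mean(0)) / x.std(0)
        resid_var = 1.0 - n_causal_per_cohort * var_per_causal
        g = xs @ np.full(n_causal_per_cohort, np.sqrt(var_per_causal))
        e = rng.standard_normal((n_samples, 3)) @ chol.T * np.sqrt(resid_var)
        ys = (g[:, None] + e).T  # equal effect on all three traits
        tables = _sumstat_tables(panel, ys, mixed=False)
        v = metamulti.estimate_trait_correlation(
            tables, min_variants=min(1000, n_variants))
        meta, _ = metamulti.meta_scan(tables, v, thr)
        meta_p = meta.set_index("id")["p"]
        single_p = np.column_stack(
            [t.set_index("id")["p"].reindex(meta_p.index) for t in tables]
        )
        causal_ids = panel.variants["id"].iloc[causal]
        loc = meta_p.index.get_indexer(causal_ids)
        multi_hits += int((meta_p.to_numpy()[loc] < thr.p_thresh).sum())
        single_hits += (single_p[loc] < thr.p_thresh).sum(axis=0)
        total += n_causal_per_cohort
    return {
        "multi_rate": multi_hits / total,
        "best_single_rate": float(single_hits.max() / total),
        "n_causal": total,
        "n_samples": n_samples,
    }


def rg_recovery(
    seed: int,
    rg_true: float = 0.78,
    h2: float = 0.5,
    n_samples: int = 1500,
    n_rep: int = 50,
) -> dict:
    """Cross-trait LDSC coverage of a simulated genetic correlation.

    One panel with heterogeneous LD (so LD scores vary) is reused across
    replicates; each replicate draws fresh shared causal effects with the
    target correlation and fresh noise, scans both traits, and checks
    whether rg_true lies within 2 jackknife SEs of the estimate.
    """
    s_geno, s_rep = _seeds(seed, 2)
    specs = [
        simdata.LDBlockSpec(n_blocks=80, snps_per_block=10,
                            block_span_bp=50_000, within_block_r2=r,
                            chrom=str(i + 1))
        for i, r in enumerate([0.0, 0.3, 0.6, 0.9])
    ]
    panel = simdata.simulate_genotypes(specs, n_samples, s_geno)
    scores = ldsc.compute_ld_scores(panel)
    poly = simdata.PolygenicSpec(
        g_cov=h2 * np.array([[1.0, rg_true], [rg_true, 1.0]]),
        residual_var=np.array([1.0 - h2, 1.0 - h2]),
        n_background=2400,
    )
    arch = simdata.CausalArchitecture(traits=["T1", "T2"], loci=[])
    covered = 0
    estimates = []
    for rep, s in enumerate(_seeds(s_rep, n_rep)):
        tp = simdata.simulate_phenotypes(panel, arch, poly, s)
        tables = _sumstat_tables(panel, [tp.trait("T1"), tp.trait("T2")],
                                 mixed=False)
        fit = ldsc.ldsc_rg(tables[0], tables[1], scores)
        estimates.append(fit.estimate)
        if (not fit.undefined
                and abs(fit.estimate - rg_true) <= 2 * fit.estimate_se):
            covered += 1
    return {
        "cover_rate": covered / n_rep,
        "mean_rg": float(np.mean(estimates)),
        "n_rep": n_rep,
        "n_samples": n_samples,
    }


def partition_recovery(
    seed: int,
    n_samples: int = 800,
    n_rep: int = 25,
    lead_fraction: float = 0.25,
    background_fraction: float = 0.25,
) -> dict:
    """Two-GRM partition coverage of the simulated lead-SNP variance fraction.

    Five lead SNPs jointly explain ``lead_fraction`` of phenotypic
    variance; a polygenic background outside a +/- 1.25 Mb window around
    each lead explains ``background_fraction``.  Coverage counts replicates
    where the true fraction is within 2 SEs of the REML estimate.
    """
    s_geno, s_rep = _seeds(seed, 2)
    specs = [
        simdata.LDBlockSpec(n_blocks=60, snps_per_block=5,
                            block_span_bp=50_000, within_block_r2=0.2,
                            chrom=str(c + 1))
        for c in range(4)
    ]
    panel = simdata.simulate_genotypes(specs, n_samples, s_geno)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    # one lead per chromosome plus a distant second lead on chromosome 1
    lead_idx = []
    for c in ("1", "2", "3", "4"):
        lead_idx.append(int(np.flatnonzero(chrom == c)[10]))
    lead_idx.append(int(np.flatnonzero(chrom == "1")[-10]))
    keep = np.ones(panel.n_variants, dtype=bool)
    keep[lead_idx] = False
    for j in lead_idx:
        keep &= ~((chrom == chrom[j]) & (np.abs(pos - pos[j]) <= 1_250_000))
    x = panel.dosages
    xs = (x - x.mean(0)) / np.where(x.std(0) > 0, x.std(0), 1.0)
    g_lead = assoc.GRM(xs[:, lead_idx] @ xs[:, lead_idx].T / len(lead_idx),
                       "lead-snps", len(lead_idx), panel.samples)
    g_bg = assoc.GRM(xs[:, keep] @ xs[:, keep].T / int(keep.sum()),
                     "background-excluded", int(keep.sum()), panel.samples)
    covered = 0
    fracs = []
    resid_sd = np.sqrt(1.0 - lead_fraction - background_fraction)
    for s in _seeds(s_rep, n_rep):
        rng = np.random.default_rng(s)
        g_l = xs[:, lead_idx] @ rng.standard_normal(len(lead_idx))
        g_l *= np.sqrt(lead_fraction) / g_l.std()
        g_b = xs[:, keep] @ rng.standard_normal(int(keep.sum()))
        g_b *= np.sqrt(background_fraction) / g_b.std()
        y = g_l + g_b + rng.standard_normal(n_samples) * resid_sd
        vp = bivar.variance_partition_two_grm(y, g_lead, g_bg)
        fracs.append(vp.fraction_of_total)
        if abs(vp.fraction_of_total - lead_fraction) <= 2 * vp.fraction_se:
            covered += 1
    return {
        "cover_rate": covered / n_rep,
        "mean_fraction": float(np.mean(fracs)),
        "true_fraction": lead_fraction,
        "n_rep": n_rep,
        "n_samples": n_samples,
    }


def scenario_discrimination(
    seed: int,
    n_samples: int = 800,
    n_rep: int = 60,
    var_causal: float = 0.0375,
    h2_background: float = 0.3,
    linked_r2: float = 0.3,
) -> dict:
    """Pleiotropic vs linked-pair verdict rates in the bivariate model.

    Pleiotropic scenario: one variant with equal effects on both traits.
    Linked scenario: two variants in LD (r2 ~ ``linked_r2``), each
    affecting one trait.  Both are tested with the bivariate fit and the
    decision rule (genome-wide threshold for the scanned panel; pairwise
    threshold 0.05 / (4 traits x the unique-lead count of the study
    design).  ``var_causal`` reproduces the per-variant non-centrality of
    a cohort of ~3000 with 1%-variance QTL at this sample size.
    """
    s_geno, s_rep = _seeds(seed, 2)
    specs = [
        simdata.LDBlockSpec(n_blocks=50, snps_per_block=5,
                            block_span_bp=20_000, within_block_r2=linked_r2,
                            chrom=str(c + 1))
        for c in range(4)
    ]
    panel = simdata.simulate_genotypes(specs, n_samples, s_geno)
    grm = assoc.compute_grm(panel)
    eig = grm.eig()
    d, u = eig
    a_chol = u * np.sqrt(d)
    gw = assoc.bonferroni_threshold(0.05, panel.n_variants)
    pair = assoc.bonferroni_threshold(0.05, 4 * 106)
    j_shared = 102          # a mid-block variant on chromosome 1
    j_a, j_b = 102, 103     # adjacent variants within one block
    x_shared = panel.dosages[:, j_shared]
    x_a = panel.dosages[:, j_a]
    x_b = panel.dosages[:, j_b]
    resid_sd = np.sqrt(1.0 - var_causal - h2_background)

    def causal_beta(x):
        return np.sqrt(var_causal) / x.std()

    def fit_verdict(y1, y2, m):
        spec = bivar.BivariateModelSpec(y1=y1, y2=y2, m=m, a=grm)
        fit = bivar.fit_bivariate_reml(spec, eig=eig)
        return bivar.classify_pleiotropy(fit, gw, pair).verdict

    pleio_hits = 0
    linked_hits_a = linked_hits_b = 0
    for s in _seeds(s_rep, n_rep):
        rng = np.random.default_rng(s)
        ug = a_chol @ rng.standard_normal((n_samples, 2)) * np.sqrt(h2_background)
        e = rng.standard_normal((n_samples, 2)) * resid_sd
        # pleiotropic: the same variant drives both traits
        y1 = causal_beta(x_shared) * x_shared + ug[:, 0] + e[:, 0]
        y2 = causal_beta(x_shared) * x_shared + ug[:, 1] + e[:, 1]
        pleio_hits += fit_verdict(y1, y2, x_shared) == "pleiotropic"
        # linked: two variants in LD, one per trait (fresh noise)
        ug2 = a_chol @ rng.standard_normal((n_samples, 2)) * np.sqrt(h2_background)
        e2 = rng.standard_normal((n_samples, 2)) * resid_sd
        z1 = causal_beta(x_a) * x_a + ug2[:, 0] + e2[:, 0]
        z2 = causal_beta(x_b) * x_b + ug2[:, 1] + e2[:, 1]
        linked_hits_a += fit_verdict(z1, z2, x_a) == "pleiotropic"
        linked_hits_b += fit_verdict(z1, z2, x_b) == "pleiotropic"
    pleio_rate = pleio_hits / n_rep
    linked_rate = max(linked_hits_a, linked_hits_b) / n_rep
    return {
        "pleiotropic_rate": pleio_rate,
        "linked_rate": linked_rate,
        "gap": pleio_rate - linked_rate,
        "achieved_r2": float(np.corrcoef(x_a, x_b)[0, 1] ** 2),
        "n_rep": n_rep,
        "n_samples": n_samples,
    }
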