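"""QC filters, GRM construction, mixed-model scan and conditional leads."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

import pleioscan as ps
from pleioscan import assoc
from pleioscan.ioformats import GenotypePanel


def _panel_from_matrix(x, chrom="1"):
    n, m = x.shape
    variants = pd.DataFrame({
        "chrom": [chrom] * m, "pos": np.arange(1, m + 1) * 100,
        "id": [f"v{j}" for j in range(m)],
        "ref": ["A"] * m, "alt": ["C"] * m,
    })
    return GenotypePanel([f"s{i}" for i in range(n)], variants,
                         np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# QC


def test_hwe_exact_proportions_retained():
    chi2, p = assoc.hwe_chisq(25, 50, 25)
    assert chi2 == pytest.approx(0.0)
    x = np.repeat([0, 1, 2], [25, 50, 25])[:, None]
    kept, report = assoc.filter_variants(_panel_from_matrix(x), hwe_alpha=1e-6)
    assert kept.n_variants == 1 and report["n_hwe"] == 0


def test_hwe_extreme_deviation_removed():
    chi2, _ = assoc.hwe_chisq(50, 0, 50)
    assert chi2 == pytest.approx(100.0)  # (25^2/25 + 50^2/50 + 25^2/25)
    x = np.repeat([0, 2], [50, 50])[:, None]
    kept, report = assoc.filter_variants(_panel_from_matrix(x), hwe_alpha=1e-6)
    assert kept.n_variants == 0 and report["n_hwe"] == 1


def test_maf_counting_and_threshold():
    x = np.array([[0.0], [1.0], [2.0], [2.0]])
    panel = _panel_from_matrix(x)
    assert panel.alt_freq()[0] == pytest.approx(0.625)
    assert panel.maf()[0] == pytest.approx(0.375)
    kept, _ = assoc.filter_variants(panel, maf_min=0.01, hwe_alpha=1e-30)
    assert kept.n_variants == 1


def test_monomorphic_always_removed_and_flagged():
    x = np.column_stack([np.zeros(100), np.repeat([0, 1, 2], [25, 50, 25])])
    kept, report = assoc.filter_variants(_panel_from_matrix(x))
    assert kept.n_variants == 1
    assert report["n_monomorphic"] == 1


def test_filter_is_idempotent(small_panel):
    once, _ = assoc.filter_variants(small_panel, maf_min=0.05)
    twice, report = assoc.filter_variants(once, maf_min=0.05)
    assert twice.n_variants == once.n_variants
    assert report["n_kept"] == report["n_input"]


# ---------------------------------------------------------------------------
# GRM


def test_duplicated_sample_has_matching_relationship(small_panel):
    x = np.vstack([small_panel.dosages, small_panel.dosages[:1]])
    panel = _panel_from_matrix(x)
    g = assoc.compute_grm(panel).matrix
    n = small_panel.n_samples
    assert g[0, n] == pytest.approx(g[0, 0])
    assert g[0, n] == pytest.approx(g[n, n])


def test_mean_offdiagonal_near_zero_for_unrelated():
    spec = ps.LDBlockSpec(n_blocks=2500, snps_per_block=4, block_span_bp=1000,
                          within_block_r2=0.0)
    panel = ps.simulate_genotypes(spec, 100, seed=42)
    grm = assoc.compute_grm(panel)
    off = grm.matrix[np.triu_indices(100, k=1)]
    assert abs(off.mean()) < 3.0 / np.sqrt(grm.n_variants)
    assert 0.8 < np.diag(grm.matrix).mean() < 1.2


def test_loco_equals_chromosome_deletion(small_panel):
    loco = assoc.compute_grm(small_panel, exclude_chrom="2")
    deleted = assoc.compute_grm(small_panel.exclude_chrom("2"))
    assert np.allclose(loco.matrix, deleted.matrix)
    assert loco.n_variants == deleted.n_variants
    kin = assoc.loco_kinships(small_panel)
    assert np.allclose(kin["2"].matrix, deleted.matrix)


def test_loco_excluding_everything_errors():
    spec = ps.LDBlockSpec(n_blocks=3, snps_per_block=2, block_span_bp=1000,
                          within_block_r2=0.0)
    panel = ps.simulate_genotypes(spec, 50, seed=1)
    with pytest.raises(ValueError, match="fewer than 2"):
        assoc.compute_grm(panel, exclude_chrom="1")


# ---------------------------------------------------------------------------
# null LMM


def test_null_h2_near_zero_under_no_genetics(small_grm, rng):
    """With no genetic signal the boundary estimate stays near zero."""
    n = small_grm.matrix.shape[0]
    hits = 0
    for _ in range(50):
        fit = assoc.fit_null_lmm(rng.standard_normal(n), small_grm)
        hits += fit.h2 < 0.05
    assert hits >= 45


def test_high_h2_recovered_from_pure_breeding_values(small_grm, rng):
    d, u = small_grm.eig()
    n = len(d)
    y = u @ (np.sqrt(d) * rng.standard_normal(n)) + 1e-3 * rng.standard_normal(n)
    fit = assoc.fit_null_lmm(y, small_grm)
    assert fit.h2 > 0.95


def test_identity_grm_flags_confounding(rng):
    n = 200
    grm = assoc.GRM(np.eye(n), "full", 1, [str(i) for i in range(n)])
    y = rng.standard_normal(n) * 2.0
    fit = assoc.fit_null_lmm(y, grm)
    assert fit.confounded
    assert fit.total_var == pytest.approx(y.var(ddof=1), rel=0.05)


# ---------------------------------------------------------------------------
# scan


def test_gls_identity_zero_vg_equals_ols(small_panel, rng):
    """Mixed-model machinery with K=I and sigma_g=0 reduces to OLS."""
    n = small_panel.n_samples
    y = rng.standard_normal(n)
    grm = assoc.GRM(np.eye(n), "full", 1, small_panel.samples)
    null_fit = assoc.NullLMMFit(
        sigma_g2=0.0, sigma_e2=1.0, h2=0.0, loglik=0.0, h2_se=1.0,
        eigvals=np.ones(n), eigvecs=np.eye(n), confounded=True,
    )
    mixed = assoc.gwas_scan(small_panel, y, null_fit=null_fit, chroms=["1"])
    plain = assoc.gwas_scan(small_panel, y, mixed=False, chroms=["1"])
    for col in ("beta", "se", "t", "p"):
        assert np.allclose(mixed[col], plain[col], rtol=1e-8)
    # cross-check one SNP against an independent OLS fit
    x = small_panel.dosages[:, 7]
    ols = spstats.linregress(x, y)
    assert mixed["beta"].iloc[7] == pytest.approx(ols.slope, rel=1e-8)
    assert mixed["se"].iloc[7] == pytest.approx(ols.stderr, rel=1e-8)


def test_orthogonal_covariate_leaves_t_unchanged(small_panel, rng):
    n = small_panel.n_samples
    y = rng.standard_normal(n)
    x0 = small_panel.dosages[:, 0]
    c = rng.standard_normal(n)
    d = np.column_stack([np.ones(n), x0])
    c = c - d @ np.linalg.lstsq(d, c, rcond=None)[0]
    base = assoc.gwas_scan(small_panel, y, mixed=False,
                           rescale_residual=False, chroms=["1"])
    cond = assoc.gwas_scan(small_panel, y, mixed=False, rescale_residual=False,
                           covariate_dosages=[c], chroms=["1"])
    t0, t1 = base["t"].iloc[0], cond["t"].iloc[0]
    assert abs(t1 - t0) / abs(t0) < 1e-6


def test_collinear_covariate_skips_snp(small_panel, rng):
    y = rng.standard_normal(small_panel.n_samples)
    x0 = small_panel.dosages[:, 0]
    out = assoc.gwas_scan(small_panel, y, mixed=False,
                          covariate_dosages=[x0], chroms=["1"])
    assert np.isnan(out["beta"].iloc[0])
    assert out["p"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# thresholds


def test_bonferroni_threshold_values():
    spec = assoc.bonferroni_threshold(0.05, 15_360_000)
    assert round(spec.neglog10_thresh, 1) == 8.5
    assert assoc.bonferroni_threshold(0.05, 1).neglog10_thresh == pytest.approx(
        1.301, abs=5e-4)
    assert assoc.bonferroni_threshold(0.05, 424).p_thresh == pytest.approx(
        1.18e-4, rel=5e-3)
    assert 10 ** (-spec.neglog10_thresh) == pytest.approx(spec.p_thresh,
                                                          rel=1e-12)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        assoc.bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        assoc.bonferroni_threshold(1.5, 10)


# ---------------------------------------------------------------------------
# conditional scan


@pytest.fixture(scope="module")
def scan_panel():
    specs = [
        ps.LDBlockSpec(n_blocks=30, snps_per_block=5, block_span_bp=50_000,
                       within_block_r2=0.5, chrom="1"),
        ps.LDBlockSpec(n_blocks=30, snps_per_block=5, block_span_bp=50_000,
                       within_block_r2=0.5, chrom="2"),
    ]
    return ps.simulate_genotypes(specs, 1200, seed=77)


@pytest.fixture(scope="module")
def scan_kinships(scan_panel):
    return assoc.loco_kinships(scan_panel)


def test_null_trait_yields_no_leads(scan_panel, scan_kinships, rng):
    thr = assoc.bonferroni_threshold(0.05, scan_panel.n_variants)
    y = rng.standard_normal(scan_panel.n_samples)
    leads = assoc.conditional_lead_scan(scan_panel, y, thr,
                                        kinships=scan_kinships)
    assert len(leads) == 0


def test_single_causal_snp_found_in_its_block(scan_panel, scan_kinships):
    """One causal SNP (NCP ~ 50): exactly one lead, inside the causal block."""
    thr = assoc.bonferroni_threshold(0.05, scan_panel.n_variants)
    n = scan_panel.n_samples
    causal_j = 62  # mid-chromosome-1 block
    x = scan_panel.dosages[:, causal_j]
    beta = np.sqrt(0.04 / x.var())
    block = causal_j // 5
    ok = 0
    n_rep = 20
    for rep in range(n_rep):
        rr = np.random.default_rng(500 + rep)
        y = beta * x + rr.standard_normal(n)
        leads = assoc.conditional_lead_scan(scan_panel, y, thr,
                                            kinships=scan_kinships)
        chrom1 = leads.for_chrom("1")
        in_block = [l for l in chrom1
                    if scan_panel.variant_index(l.id) // 5 == block]
        ok += len(chrom1) == 1 and len(in_block) == 1
    assert ok >= 0.9 * n_rep


def test_two_distant_causal_snps_give_two_leads(scan_panel, scan_kinships):
    thr = assoc.bonferroni_threshold(0.05, scan_panel.n_variants)
    n = scan_panel.n_samples
    j1, j2 = 10, 140  # ~2.6 Mb apart on chromosome 1, unlinked blocks
    x1 = scan_panel.dosages[:, j1]
    x2 = scan_panel.dosages[:, j2]
    b1 = np.sqrt(0.04 / x1.var())
    b2 = np.sqrt(0.04 / x2.var())
    ok = 0
    n_rep = 20
    for rep in range(n_rep):
        rr = np.random.default_rng(900 + rep)
        y = b1 * x1 + b2 * x2 + rr.standard_normal(n)
        leads = assoc.conditional_lead_scan(scan_panel, y, thr,
                                            kinships=scan_kinships)
        ok += len(leads.for_chrom("1")) == 2
    assert ok >= 0.8 * n_rep


def test_lead_rounds_strictly_increase(scan_panel, scan_kinships):
    thr = assoc.bonferroni_threshold(0.05, scan_panel.n_variants)
    n = scan_panel.n_samples
    x1 = scan_panel.dosages[:, 10]
    x2 = scan_panel.dosages[:, 140]
    rr = np.random.default_rng(7)
    y = 0.4 * x1 + 0.4 * x2 + rr.standard_normal(n)
    leads = assoc.conditional_lead_scan(scan_panel, y, thr,
                                        kinships=scan_kinships)
    rounds = [l.round_index for l in leads.for_chrom("1")]
    assert rounds == sorted(rounds)
    assert len(set(rounds)) == len(rounds)
    for l in leads.leads:
        assert l.p < thr.p_thresh
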