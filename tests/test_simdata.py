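"""Synthetic cohort generator: LD structure, determinism, variance accounting."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan import assoc, simdata


def _adjacent_r2(panel, snps_per_block):
    out = []
    for b in range(panel.n_variants // snps_per_block):
        for j in range(snps_per_block - 1):
            a = panel.dosages[:, b * snps_per_block + j]
            c = panel.dosages[:, b * snps_per_block + j + 1]
            out.append(np.corrcoef(a, c)[0, 1] ** 2)
    return np.array(out)


def test_perfect_ld_duplicates_columns():
    spec = ps.LDBlockSpec(n_blocks=1, snps_per_block=2, block_span_bp=1000,
                          within_block_r2=1.0, maf_range=(0.3, 0.3))
    panel = ps.simulate_genotypes(spec, 200, seed=1)
    assert np.array_equal(panel.dosages[:, 0], panel.dosages[:, 1])


def test_zero_r2_blocks_are_independent():
    spec = ps.LDBlockSpec(n_blocks=10, snps_per_block=2, block_span_bp=5000,
                          within_block_r2=0.0)
    panel = ps.simulate_genotypes(spec, 5000, seed=2)
    r = np.corrcoef(panel.dosages.T)
    off = r[np.triu_indices_from(r, k=1)] ** 2
    assert off.mean() < 0.01  # E[r2] ~ 1/n for independent loci


@pytest.mark.parametrize("target", [0.2, 0.5, 0.8])
def test_adjacent_r2_hits_target(target):
    spec = ps.LDBlockSpec(n_blocks=20, snps_per_block=5, block_span_bp=20_000,
                          within_block_r2=target)
    panel = ps.simulate_genotypes(spec, 2000, seed=3)
    assert abs(_adjacent_r2(panel, 5).mean() - target) < 0.1


def test_same_seed_bit_identical():
    spec = ps.LDBlockSpec(n_blocks=5, snps_per_block=4, block_span_bp=10_000,
                          within_block_r2=0.4)
    a = ps.simulate_genotypes(spec, 300, seed=9)
    b = ps.simulate_genotypes(spec, 300, seed=9)
    assert np.array_equal(a.dosages, b.dosages)
    assert a.variants.equals(b.variants)
    arch = ps.CausalArchitecture(traits=["T"], loci=[])
    poly = ps.PolygenicSpec(g_cov=np.array([[0.4]]), residual_var=np.array([0.6]),
                            n_background=10)
    pa = ps.simulate_phenotypes(a, arch, poly, seed=4)
    pb = ps.simulate_phenotypes(b, arch, poly, seed=4)
    assert np.array_equal(pa.values.to_numpy(), pb.values.to_numpy())


def test_maf_within_three_binomial_se():
    p = 0.3
    spec = ps.LDBlockSpec(n_blocks=30, snps_per_block=3, block_span_bp=10_000,
                          within_block_r2=0.5, maf_range=(p, p))
    n = 3000
    panel = ps.simulate_genotypes(spec, n, seed=5)
    se = np.sqrt(p * (1 - p) / (2 * n))
    assert np.all(np.abs(panel.alt_freq() - p) < 3 * se + 1e-12)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ps.LDBlockSpec(n_blocks=1, snps_per_block=2, block_span_bp=100,
                       within_block_r2=1.5)
    with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
        ps.LDBlockSpec(n_blocks=1, snps_per_block=2, block_span_bp=100,
                       within_block_r2=0.5, maf_range=(0.4, 0.6))
    with pytest.raises(ValueError, match="n_samples"):
        ps.simulate_genotypes(
            ps.LDBlockSpec(n_blocks=1, snps_per_block=2, block_span_bp=100,
                           within_block_r2=0.5), 1, seed=0)


def test_pure_noise_variance_matches_residual(small_panel):
    arch = ps.CausalArchitecture(traits=["T1", "T2"], loci=[])
    poly = ps.PolygenicSpec(g_cov=np.zeros((2, 2)),
                            residual_var=np.array([1.0, 2.0]), n_background=0)
    tp = ps.simulate_phenotypes(small_panel, arch, poly, seed=6)
    n = small_panel.n_samples
    for trait, s2 in (("T1", 1.0), ("T2", 2.0)):
        v = tp.trait(trait).var(ddof=1)
        se = s2 * np.sqrt(2.0 / (n - 1))  # chi-square sampling bound
        assert abs(v - s2) < 3 * se


def test_breeding_value_correlation_recovered():
    spec = ps.LDBlockSpec(n_blocks=300, snps_per_block=4, block_span_bp=20_000,
                          within_block_r2=0.3)
    panel = ps.simulate_genotypes(spec, 2000, seed=7)
    rho = 0.78
    poly = ps.PolygenicSpec(
        g_cov=np.array([[1.0, rho], [rho, 1.0]]),
        residual_var=np.array([1.0, 1.0]),
        n_background=1000,
    )
    arch = ps.CausalArchitecture(traits=["A", "B"], loci=[])
    _, comp = ps.simulate_phenotypes(panel, arch, poly, seed=8, full_output=True)
    tbv = comp["tbv"]
    r = np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1]
    assert abs(r - rho) < 0.05


def test_pleiotropic_snp_variance_explained(small_panel):
    vid = small_panel.variants.at[0, "id"]
    p = small_panel.alt_freq()[0]
    locus = ps.CausalLocus(scenario="pleiotropic",
                           effects={vid: {"A": 0.5, "B": 0.5}})
    arch = ps.CausalArchitecture(traits=["A", "B"], loci=[locus])
    poly = ps.PolygenicSpec(g_cov=np.zeros((2, 2)),
                            residual_var=np.array([1.0, 1.0]), n_background=0)
    _, comp = ps.simulate_phenotypes(small_panel, arch, poly, seed=9,
                                     full_output=True)
    expected = 2 * p * (1 - p) * 0.25  # var(beta * x) for binomial dosage
    for t in range(2):
        assert comp["causal"][:, t].var() == pytest.approx(expected, rel=0.2)


def test_causal_architecture_invariants():
    with pytest.raises(ValueError, match="pleiotropic"):
        ps.CausalLocus(scenario="pleiotropic", effects={"v1": {"A": 0.5}})
    with pytest.raises(ValueError, match="linked pair"):
        ps.CausalLocus(scenario="linked-pair",
                       effects={"v1": {"A": 0.5}, "v2": {"A": 0.3}})
    ps.CausalLocus(scenario="linked-pair",
                   effects={"v1": {"A": 0.5}, "v2": {"B": 0.3}}, target_r2=0.3)
    with pytest.raises(KeyError):
        arch = ps.CausalArchitecture(
            traits=["A"],
            loci=[ps.CausalLocus(scenario="single-trait",
                                 effects={"nope": {"A": 1.0}})],
        )
        spec = ps.LDBlockSpec(n_blocks=1, snps_per_block=2, block_span_bp=100,
                              within_block_r2=0.0)
        arch.effect_matrix(ps.simulate_genotypes(spec, 10, seed=0))


def test_non_psd_polygenic_cov_rejected():
    with pytest.raises(ValueError, match="positive semi-definite"):
        ps.PolygenicSpec(g_cov=np.array([[1.0, 2.0], [2.0, 1.0]]),
                         residual_var=np.array([1.0, 1.0]))


def test_linked_pair_achieved_r2_reported():
    spec = ps.LDBlockSpec(n_blocks=2, snps_per_block=2, block_span_bp=5000,
                          within_block_r2=0.3, maf_range=(0.3, 0.3))
    panel = ps.simulate_genotypes(spec, 3000, seed=10)
    ids = panel.variants["id"].tolist()
    r2 = ps.achieved_r2(panel, ids[0], ids[1])
    assert abs(r2 - 0.3) < 0.1


def test_greml_recovers_simulated_heritability(tmp_path):
    """GREML on simulated data covers the realized h2 within 2 SE >= 90%."""
    spec = ps.LDBlockSpec(n_blocks=150, snps_per_block=4, block_span_bp=20_000,
                          within_block_r2=0.2)
    panel = ps.simulate_genotypes(spec, 500, seed=11)
    grm = assoc.compute_grm(panel)
    arch = ps.CausalArchitecture(traits=["T"], loci=[])
    poly = ps.PolygenicSpec(g_cov=np.array([[0.5]]), residual_var=np.array([0.5]),
                            n_background=400)
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        tp, comp = ps.simulate_phenotypes(panel, arch, poly, seed=1000 + rep,
                                          full_output=True)
        y = tp.trait("T")
        realized = comp["polygenic"][:, 0].var() / y.var()
        fit = assoc.fit_null_lmm(y, grm)
        if abs(fit.h2 - realized) <= 2 * fit.h2_se:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_truth_table_round_trip(tmp_path, small_panel):
    vid = small_panel.variants.at[3, "id"]
    arch = ps.CausalArchitecture(
        traits=["A", "B"],
        loci=[ps.CausalLocus(scenario="pleiotropic",
                             effects={vid: {"A": 0.2, "B": -0.1}})],
    )
    path = tmp_path / "truth.tsv"
    simdata.write_truth_table(arch, small_panel, path)
    df = pd.read_csv(path, sep="\t")
    assert set(df["trait"]) == {"A", "B"}
    assert (df["id"] == vid).all()


def test_drp_reliability_noise_variance():
    # var(noise) = var(TBV) (1 - r2) / r2
    assert simdata.drp_noise_variance(2.0, 0.9) == pytest.approx(2.0 / 9)
    assert simdata.drp_noise_variance(1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        simdata.drp_noise_variance(1.0, 0.0)
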