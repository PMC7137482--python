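"""Synthetic cohorts with known pleiotropic / linked causal architecture.

The generator emulates the features of a dense dairy-cattle mapping cohort
that the downstream stages rely on: LD-block genotype structure, a handful
of traits with a specified genetic covariance, causal variants that are
either shared across traits (pleiotropy) or distinct-but-linked, and a
polygenic background.  Phenotypes play the role of de-regressed proofs
(DRP): high-reliability pseudo-phenotypes equal to the true breeding value
plus independent noise.

Genotypes are built per LD block from a pool of simulated haplotypes: the
first variant of a block is drawn at the block allele frequency and each
subsequent variant copies its left neighbour with probability sqrt(r2) and
is redrawn at the allele frequency otherwise.  For variants sharing an
allele frequency this yields adjacent-pair dosage correlations of r2
without any external reference panel.  Blocks share a single allele
frequency so the target r2 is always attainable; across blocks haplotypes
are independent, so expected between-block r2 is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioformats import GenotypePanel, TraitPanel, VARIANT_COLUMNS

__all__ = [
    "LDBlockSpec",
    "CausalLocus",
    "CausalArchitecture",
    "PolygenicSpec",
    "simulate_genotypes",
    "simulate_phenotypes",
    "achieved_r2",
    "write_truth_table",
]


@dataclass(frozen=True)
class LDBlockSpec:
    """Layout of one simulated chromosome made of non-overlapping LD blocks.

    Parameters
    ----------
    n_blocks, snps_per_block : int
        Number of blocks and variants per block.
    block_span_bp : int
        Physical span of each block; blocks are laid head-to-tail with a
        one-span gap, so spans never overlap.
    within_block_r2 : float
        Target squared dosage correlation of adjacent variants in a block,
        in [0, 1].
    maf_range : tuple of float
        Allele frequencies are drawn uniformly from this interval,
        one per block; must lie in (0, 0.5].
    chrom : str
        Chromosome label for the emitted variants.
    """

    n_blocks: int
    snps_per_block: int
    block_span_bp: int
    within_block_r2: float
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.snps_per_block < 1:
            raise ValueError("need at least one block and one SNP per block")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError(
                f"within_block_r2={self.within_block_r2} outside [0, 1]"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if self.block_span_bp < self.snps_per_block:
            raise ValueError("block span too small for the number of SNPs")


@dataclass
class CausalLocus:
    """One causal signal: a shared variant, a linked pair, or a single-trait hit.

    ``effects`` maps variant id -> {trait: allele-substitution effect}.
    """

    scenario: str  # 'pleiotropic' | 'linked-pair' | 'single-trait'
    effects: dict[str, dict[str, float]]
    target_r2: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in {"pleiotropic", "linked-pair", "single-trait"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        nonzero = {
            v: [t for t, b in tb.items() if b != 0.0]
            for v, tb in self.effects.items()
        }
        if self.scenario == "pleiotropic":
            if len(self.effects) != 1 or len(next(iter(nonzero.values()))) < 2:
                raise ValueError(
                    "a pleiotropic locus is ONE variant with nonzero effect "
                    "on >= 2 traits"
                )
        elif self.scenario == "linked-pair":
            traits = [tuple(ts) for ts in nonzero.values()]
            if len(self.effects) != 2 or any(len(ts) != 1 for ts in traits) \
                    or traits[0] == traits[1]:
                raise ValueError(
                    "a linked pair is two variants, each affecting exactly "
                    "one distinct trait"
                )
        else:
            if len(self.effects) != 1 or len(next(iter(nonzero.values()))) != 1:
                raise ValueError("a single-trait locus affects exactly one trait")

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(self.effects)


@dataclass
class CausalArchitecture:
    """Collection of causal loci over a named set of traits."""

    traits: list[str]
    loci: list[CausalLocus] = field(default_factory=list)

    def effect_matrix(self, panel: GenotypePanel) -> np.ndarray:
        """(n_variants, n_traits) matrix of allele-substitution effects.

        Raises ``KeyError`` if any causal variant id is absent from the panel.
        """
        beta = np.zeros((panel.n_variants, len(self.traits)))
        for locus in self.loci:
            for vid, per_trait in locus.effects.items():
                j = panel.variant_index(vid)
                for trait, b in per_trait.items():
                    beta[j, self.traits.index(trait)] += b
        return beta

    def causal_ids(self) -> list[str]:
        return [v for locus in self.loci for v in locus.variant_ids]


@dataclass
class PolygenicSpec:
    """Polygenic background: trait genetic covariance and residual variances.

    ``g_cov`` is the T x T genetic covariance of the background breeding
    values; ``residual_var`` the per-trait residual (DRP noise) variances;
    ``n_background`` the number of background causal variants drawn from
    the panel.
    """

    g_cov: np.ndarray
    residual_var: np.ndarray
    n_background: int = 1000

    def __post_init__(self) -> None:
        self.g_cov = np.asarray(self.g_cov, dtype=float)
        self.residual_var = np.asarray(self.residual_var, dtype=float)
        if self.g_cov.shape != (len(self.residual_var),) * 2:
            raise ValueError("g_cov shape does not match residual_var length")
        if not np.allclose(self.g_cov, self.g_cov.T):
            raise ValueError("g_cov must be symmetric")
        w = np.linalg.eigvalsh(self.g_cov)
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ValueError("g_cov must be positive semi-definite")
        if np.any(self.residual_var <= 0):
            raise ValueError("residual variances must be positive")


def _simulate_chromosome(
    spec: LDBlockSpec, n_samples: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    copy_p = float(np.sqrt(spec.within_block_r2))
    n_hap = 2 * n_samples
    records = []
    columns = []
    for b in range(spec.n_blocks):
        p = rng.uniform(*spec.maf_range)
        start = b * 2 * spec.block_span_bp + 1
        pos = start + np.sort(
            rng.choice(spec.block_span_bp, size=spec.snps_per_block, replace=False)
        )
        hap = np.empty((n_hap, spec.snps_per_block), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < p
        for j in range(1, spec.snps_per_block):
            copy = rng.random(n_hap) < copy_p
            fresh = rng.random(n_hap) < p
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dose = hap[0::2] + hap[1::2]
        columns.append(dose.astype(float))
        for k, bp in enumerate(pos):
            records.append(
                (spec.chrom, int(bp), f"{spec.chrom}:{int(bp)}", "A", "C")
            )
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return variants, np.concatenate(columns, axis=1)


def simulate_genotypes(
    spec: LDBlockSpec | list[LDBlockSpec],
    n_samples: int,
    seed: int,
) -> GenotypePanel:
    """Simulate hard genotypes (doses in {0,1,2}) with block LD structure.

    A list of specs yields a multi-chromosome panel, one chromosome per
    spec (labels must be distinct).  Identical seeds give bit-identical
    panels.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    specs = [spec] if isinstance(spec, LDBlockSpec) else list(spec)
    labels = [s.chrom for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("chromosome labels of the specs must be distinct")
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    frames, blocks = [], []
    for s, ss in zip(specs, streams):
        variants, dose = _simulate_chromosome(s, n_samples, np.random.default_rng(ss))
        frames.append(variants)
        blocks.append(dose)
    samples = [f"s{i:05d}" for i in range(n_samples)]
    return GenotypePanel(
        samples, pd.concat(frames, ignore_index=True), np.concatenate(blocks, axis=1)
    )


def achieved_r2(panel: GenotypePanel, id_a: str, id_b: str) -> float:
    """Realized squared dosage correlation between two panel variants."""
    xa = panel.dosages[:, panel.variant_index(id_a)]
    xb = panel.dosages[:, panel.variant_index(id_b)]
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def drp_noise_variance(tbv_var: float, reliability: float = 0.9) -> float:
    """Noise variance of a DRP with the given reliability.

    A de-regressed proof with reliability r2 satisfies
    var(noise) = var(TBV) * (1 - r2) / r2.
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError("reliability must be in (0, 1]")
    return tbv_var * (1.0 - reliability) / reliability


def simulate_phenotypes(
    panel: GenotypePanel,
    arch: CausalArchitecture,
    poly: PolygenicSpec,
    seed: int,
    full_output: bool = False,
):
    """Simulate phenotypes y_t = sum_k beta_kt x_k + u_t + e_t.

    The polygenic term u is built from ``poly.n_background`` variants drawn
    from the panel (excluding causal variants) with per-variant effects on
    standardized doses drawn jointly across traits; each trait's u column
    is then rescaled so its sample variance equals the specified genetic
    variance, which keeps the trait-trait correlations at their targets
    while pinning the realized variance decomposition.  Residuals are
    independent Gaussians with the specified variances.

    With ``full_output=True`` returns ``(TraitPanel, dict)`` where the dict
    carries the true breeding values (causal + polygenic), the polygenic
    part alone and the background variant indices.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = len(arch.traits)
    n = panel.n_samples
    beta = arch.effect_matrix(panel)  # raises on unknown causal ids
    g_causal = panel.dosages @ beta

    # polygenic background on standardized doses
    u = np.zeros((n, T))
    bg_idx = np.array([], dtype=int)
    if poly.n_background > 0 and np.any(np.diag(poly.g_cov) > 0):
        causal = {panel.variant_index(v) for v in arch.causal_ids()}
        candidates = np.array(
            [j for j in range(panel.n_variants) if j not in causal]
        )
        if len(candidates) < poly.n_background:
            raise ValueError(
                f"panel has only {len(candidates)} non-causal variants for "
                f"{poly.n_background} background effects"
            )
        bg_idx = np.sort(
            rng.choice(candidates, size=poly.n_background, replace=False)
        )
        x = panel.dosages[:, bg_idx]
        sd = x.std(axis=0)
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        m_bg = x.shape[1]
        chol = np.linalg.cholesky(
            poly.g_cov + 1e-12 * np.eye(T) * max(1.0, np.trace(poly.g_cov))
        )
        alpha = rng.standard_normal((m_bg, T)) @ chol.T / np.sqrt(m_bg)
        u = x @ alpha
        # pin realized per-trait polygenic variance to the specification
        for t in range(T):
            target = poly.g_cov[t, t]
            realized = u[:, t].var()
            if target > 0 and realized > 0:
                u[:, t] *= np.sqrt(target / realized)
            elif target == 0:
                u[:, t] = 0.0

    e = rng.standard_normal((n, T)) * np.sqrt(poly.residual_var)
    y = g_causal + u + e
    tp = TraitPanel(list(panel.samples), pd.DataFrame(y, columns=arch.traits))
    if not full_output:
        return tp
    return tp, {
        "tbv": g_causal + u,
        "polygenic": u,
        "causal": g_causal,
        "residual": e,
        "background_index": bg_idx,
    }


def write_truth_table(arch: CausalArchitecture, panel: GenotypePanel, path) -> None:
    """Causal-architecture truth table as TSV for test harnesses."""
    rows = []
    for i, locus in enumerate(arch.loci):
        for vid, per_trait in locus.effects.items():
            row = panel.variants.iloc[panel.variant_index(vid)]
            for trait, b in per_trait.items():
                rows.append(
                    dict(
                        locus=i,
                        scenario=locus.scenario,
                        id=vid,
                        chrom=row.chrom,
                        pos=row.pos,
                        trait=trait,
                        beta=b,
                        target_r2="" if locus.target_r2 is None else locus.target_r2,
                    )
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
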