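"""Readers and writers for the on-disk artifacts of the pipeline.

All genomic coordinates are 1-based inclusive internally (the VCF
convention); BED export converts to 0-based half-open.  The effect allele
of every summary statistic is the ALT allele and effect sizes are per ALT
dose, which removes allele-flip ambiguity inside the pipeline.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "TraitPanel",
    "SUMSTAT_COLUMNS",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_phenotypes",
    "write_phenotypes",
    "read_sumstats",
    "write_sumstats",
    "validate_sumstats",
    "write_regions",
    "read_regions",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

#: fixed dialect of the summary-statistic TSV; extra columns pass through.
SUMSTAT_COLUMNS = [
    "chrom", "pos", "id", "effect_allele", "other_allele",
    "eaf", "beta", "se", "t", "p", "n",
]


def _log(msg: str) -> None:
    print(f"[pleioscan] {msg}", file=sys.stderr)


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix with 1-based variant coordinates.

    Parameters
    ----------
    samples : list of str
        Sample identifiers (rows of ``dosages``).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based and strictly increasing within a chromosome.
    dosages : numpy.ndarray
        ``(n_samples, n_variants)`` ALT-allele dose matrix, entries in
        ``[0, 2]``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency, mean(dose)/2."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency (ALT frequency folded to <= 0.5)."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypePanel(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def exclude_chrom(self, chrom: str) -> "GenotypePanel":
        return self.subset_variants(
            (self.variants["chrom"].astype(str) != str(chrom)).to_numpy()
        )

    def restrict_chrom(self, chrom: str) -> "GenotypePanel":
        return self.subset_variants(
            (self.variants["chrom"].astype(str) == str(chrom)).to_numpy()
        )

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"].astype(str)))

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero((self.variants["id"] == variant_id).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"variant {variant_id!r}: {len(hits)} matches")
        return int(hits[0])


@dataclass
class TraitPanel:
    """Per-sample phenotypes for one or more traits (DRP-like values)."""

    samples: list[str]
    values: pd.DataFrame  # one column per trait, index-free

    def __post_init__(self) -> None:
        self.values = self.values.reset_index(drop=True)
        if len(self.values) != len(self.samples):
            raise ValueError("phenotype rows do not match samples")
        if self.values.isna().any().any():
            raise ValueError("missing phenotype values; complete cases required")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# genotype I/O


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write hard genotypes as an uncompressed VCF 4.2 with GT fields.

    Dosages are rounded to the nearest integer allele count.
    """
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        hard = np.rint(panel.dosages).astype(int)
        for j, row in panel.variants.iterrows():
            calls = "\t".join(gt_codes[int(g)] for g in hard[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    """Flat dosage TSV: variant metadata columns then one column per sample."""
    df = panel.variants.copy()
    dose = pd.DataFrame(
        panel.dosages.T, columns=panel.samples, index=df.index
    )
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, doses = [], []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        if np.any(gt == 2):
            raise ValueError(f"missing genotype at {var.CHROM}:{var.POS}")
        dose = np.where(gt == 3, 2.0, gt)
        records.append((str(var.CHROM), int(var.POS), var.ID or f"{var.CHROM}:{var.POS}",
                        var.REF, var.ALT[0]))
        doses.append(dose)
    if n_multiallelic:
        _log(f"read_genotypes: rejected {n_multiallelic} multi-allelic records")
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    _check_chrom_blocks(variants)
    return GenotypePanel(samples, variants, np.column_stack(doses) if doses else
                         np.empty((len(samples), 0)))


def _read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV lacks columns {missing}")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    variants = df[VARIANT_COLUMNS].copy()
    _check_chrom_blocks(variants)
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypePanel(samples, variants, dosages)


def _check_chrom_blocks(variants: pd.DataFrame) -> None:
    """Chromosomes must appear in contiguous blocks (no interleaving)."""
    chroms = variants["chrom"].astype(str).to_numpy()
    seen: set[str] = set()
    prev = None
    for c in chroms:
        if c != prev:
            if c in seen:
                raise ValueError(f"mixed chromosome sort order: {c} interleaved")
            seen.add(c)
            prev = c


def read_genotypes(path, format: str = "vcf") -> GenotypePanel:
    """Read a genotype panel from ``vcf`` or ``dosage-tsv``.

    Multi-allelic VCF records are rejected (count logged); GT is converted
    to an ALT-allele dose.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype I/O


def write_phenotypes(panel: TraitPanel, path) -> None:
    out = panel.values.copy()
    out.insert(0, "sample", panel.samples)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> TraitPanel:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError("phenotype TSV must have a 'sample' column")
    return TraitPanel(df["sample"].tolist(), df.drop(columns="sample"))


# ---------------------------------------------------------------------------
# summary statistics


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistic table against the fixed dialect.

    Checks p in (0, 1], se > 0, t = beta/se (1e-10 relative) and
    (chrom, pos) sort order.  Returns the frame unchanged on success.
    """
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics lack columns {missing}")
    if not ((df["p"] > 0) & (df["p"] <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    if not (df["se"] > 0).all():
        raise ValueError("standard errors must be positive")
    resid = np.abs(df["t"] - df["beta"] / df["se"])
    scale = np.maximum(np.abs(df["t"]), 1e-30)
    if np.any(resid / scale > 1e-10):
        raise ValueError("t does not equal beta/se")
    key = df[["chrom", "pos"]].astype({"chrom": str})
    if not key.equals(key.sort_values(["chrom", "pos"], kind="stable")):
        raise ValueError("rows must be sorted by (chrom, pos)")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_sumstats(df)


# ---------------------------------------------------------------------------
# QTL regions (BED export)


def write_regions(regions, path) -> None:
    """Write QTL regions as BED (0-based half-open).

    An internal 1-based inclusive interval [s, e] is emitted as (s-1, e).
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlead_id\tlead_pos\tlead_neglogp\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.lead_id}"
                f"\t{r.lead_pos}\t{r.lead_neglogp:.6g}\n"
            )


def read_regions(path):
    from .regions import QTLRegion

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, lead_id, lead_pos, neglogp = line.rstrip("\n").split("\t")
            out.append(
                QTLRegion(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    lead_id=lead_id,
                    lead_pos=int(lead_pos),
                    lead_neglogp=float(neglogp),
                )
            )
    return out
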