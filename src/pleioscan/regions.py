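"""QTL-region definition around lead SNPs and cross-trait overlap reports.

A QTL region is the interval around a genome-wide-significant lead SNP
bounded by the furthest variants whose -log10(p) is no less than 3 units
below the lead's, with each boundary clipped at 0.25 Mb from the lead.
The boundary search runs first, then the cap is applied.  Intervals are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QTLRegion",
    "define_qtl_region",
    "call_regions",
    "overlap_regions",
]


@dataclass(frozen=True)
class QTLRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    lead_id: str
    lead_pos: int
    lead_neglogp: float

    def __post_init__(self) -> None:
        if not self.start <= self.lead_pos <= self.end:
            raise ValueError("region must contain its lead SNP")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def _neglog10p(stats: pd.DataFrame) -> np.ndarray:
    if "neglog10p" in stats.columns:
        return stats["neglog10p"].to_numpy(dtype=float)
    return -np.log10(stats["p"].to_numpy(dtype=float))


def define_qtl_region(
    stats: pd.DataFrame,
    lead_id: str,
    threshold_neglog10: float = 8.5,
    cap_bp: int = 250_000,
    drop: float = 3.0,
) -> QTLRegion:
    """Region around one lead SNP from a single-chromosome summary table.

    Boundary SNPs are the furthest left/right variants with
    -log10(p) >= lead - drop (inclusive); each boundary is then clipped to
    ``lead_pos +/- cap_bp``.
    """
    chroms = stats["chrom"].astype(str).unique()
    if len(chroms) != 1:
        raise ValueError("stats must be restricted to one chromosome")
    pos = stats["pos"].to_numpy(dtype=int)
    if len(np.unique(pos)) != len(pos):
        raise ValueError("duplicate positions in summary statistics")
    hit = np.flatnonzero((stats["id"] == lead_id).to_numpy())
    if len(hit) != 1:
        raise KeyError(f"lead {lead_id!r}: {len(hit)} matches")
    j = int(hit[0])
    neglog = _neglog10p(stats)
    lead_nl = float(neglog[j])
    if not lead_nl > threshold_neglog10:
        raise ValueError(
            f"lead {lead_id} has -log10(p) = {lead_nl:.3f}, below the "
            f"genome-wide threshold {threshold_neglog10}"
        )
    lead_pos = int(pos[j])
    qual = neglog >= lead_nl - drop
    start = int(pos[qual].min())
    end = int(pos[qual].max())
    start = max(start, lead_pos - cap_bp)
    end = min(end, lead_pos + cap_bp)
    return QTLRegion(
        chrom=str(chroms[0]), start=start, end=end,
        lead_id=lead_id, lead_pos=lead_pos, lead_neglogp=lead_nl,
    )


def call_regions(
    stats: pd.DataFrame,
    leads,
    threshold_neglog10: float = 8.5,
    cap_bp: int = 250_000,
    drop: float = 3.0,
) -> list[QTLRegion]:
    """One region per lead SNP.  Overlapping regions are NOT merged.

    ``leads`` is a LeadSNPSet or any iterable of objects with ``chrom`` and
    ``id`` attributes.
    """
    entries = getattr(leads, "leads", leads)
    out = []
    for lead in entries:
        sub = stats[stats["chrom"].astype(str) == str(lead.chrom)]
        out.append(
            define_qtl_region(
                sub, lead.id,
                threshold_neglog10=threshold_neglog10,
                cap_bp=cap_bp, drop=drop,
            )
        )
    return out


def overlap_regions(
    regions_a: list[QTLRegion], regions_b: list[QTLRegion]
) -> list[tuple[tuple[str, int, int], QTLRegion, QTLRegion]]:
    """All pairwise intersections, 1-based inclusive interval arithmetic.

    Returns ``((chrom, start, end), region_a, region_b)`` triples; empty
    when every pair is disjoint.  Single-base touches count ([200,300] vs
    [300,400] intersect at [300,300]).
    """
    out = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chrom != rb.chrom:
                continue
            s = max(ra.start, rb.start)
            e = min(ra.end, rb.end)
            if s <= e:
                out.append(((ra.chrom, s, e), ra, rb))
    return out
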