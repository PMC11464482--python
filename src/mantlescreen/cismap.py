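"""Detection of lncRNA-coding cis-regulatory modules by genomic proximity.

A cis module is one differentially expressed lncRNA plus every
differentially expressed coding gene on the same chromosome within the
pairing window (100 kb by default). Distance is the gap between the
closest span edges (0 if the spans overlap), the weakest assumption
consistent with "within 100 kb up- or downstream"; TSS-to-TSS mode is
available. Strand is recorded but never used as a filter — regulator and
target may lie in either orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Mapping, Sequence

import pandas as pd

from .formats import FormatError, GeneModel, write_bed

__all__ = ["CisModule", "pair_within_window", "module_report", "modules_table"]

DEFAULT_WINDOW = 100_000


@dataclass
class CisModule:
    """One lncRNA with its windowed coding partners.

    partners are (coding GeneModel, signed distance bp, orientation)
    sorted by |distance|; distance < 0 means the coding gene lies 5' of
    the lncRNA on the + strand axis.
    """

    lncRNA: GeneModel
    partners: list[tuple[GeneModel, int, str]]
    window: int

    @property
    def chrom(self) -> str:
        return self.lncRNA.chrom

    @property
    def span(self) -> tuple[int, int]:
        """lncRNA-to-farthest-partner footprint (1-based inclusive)."""
        starts = [self.lncRNA.start] + [g.start for g, _, _ in self.partners]
        ends = [self.lncRNA.end] + [g.end for g, _, _ in self.partners]
        return min(starts), max(ends)

    @property
    def name(self) -> str:
        return f"module_{self.lncRNA.gene_id}"


def edge_distance(a: GeneModel, b: GeneModel) -> int:
    """Signed gap between closest span edges of b relative to a.

    0 if the spans overlap; negative if b lies entirely 5' of a on the
    + strand axis. Symmetric in magnitude: |d(a,b)| == |d(b,a)|.
    """
    if b.start > a.end:
        return b.start - a.end
    if b.end < a.start:
        return -(a.start - b.end)
    return 0


def tss_distance(a: GeneModel, b: GeneModel) -> int:
    """Signed TSS-to-TSS distance of b relative to a (strand-aware TSS)."""
    tss_a = a.start if a.strand == "+" else a.end
    tss_b = b.start if b.strand == "+" else b.end
    return tss_b - tss_a


def pair_within_window(
    lnc_genes: Sequence[GeneModel],
    coding_genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    mode: str = "edge",
) -> list[CisModule]:
    """Pair DE lncRNAs with DE coding genes within ``window`` bp.

    A coding gene is a partner iff it lies on the same chromosome and its
    distance (edge gap by default, TSS offset in 'tss' mode) is at most
    ``window``; lncRNAs with no partner are omitted. Output is sorted by
    (chrom, lncRNA start), partners by (|distance|, gene id).
    """
    if mode not in {"edge", "tss"}:
        raise FormatError(f"unknown distance mode {mode!r}")
    dist = edge_distance if mode == "edge" else tss_distance
    for g in list(lnc_genes) + list(coding_genes):
        if not isinstance(g, GeneModel):
            raise FormatError(f"gene {g!r} lacks coordinates")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    modules: list[CisModule] = []
    for lnc in sorted(lnc_genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        partners = []
        for cg in by_chrom.get(lnc.chrom, ()):
            d = dist(lnc, cg)
            if abs(d) <= window:
                orient = "same" if cg.strand == lnc.strand else "opposite"
                partners.append((cg, d, orient))
        if partners:
            partners.sort(key=lambda t: (abs(t[1]), t[0].gene_id))
            modules.append(CisModule(lncRNA=lnc, partners=partners, window=window))
    return modules


def modules_table(modules: Sequence[CisModule]) -> pd.DataFrame:
    """Flat table of modules: one row per lncRNA-partner pair."""
    rows = []
    for m in modules:
        for cg, d, orient in m.partners:
            rows.append(
                {
                    "module": m.name,
                    "lncRNA": m.lncRNA.gene_id,
                    "chrom": m.chrom,
                    "lnc_start": m.lncRNA.start,
                    "lnc_end": m.lncRNA.end,
                    "lnc_strand": m.lncRNA.strand,
                    "partner": cg.gene_id,
                    "partner_start": cg.start,
                    "partner_end": cg.end,
                    "partner_strand": cg.strand,
                    "distance": d,
                    "orientation": orient,
                    "window": m.window,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "module", "lncRNA", "chrom", "lnc_start", "lnc_end", "lnc_strand",
            "partner", "partner_start", "partner_end", "partner_strand",
            "distance", "orientation", "window",
        ],
    )


def module_report(
    modules: Sequence[CisModule],
    all_genes: Sequence[GeneModel],
    de_status: Mapping[str, str] | None = None,
    flank: int = 50_000,
    bed_path=None,
) -> pd.DataFrame:
    """Neighbourhood table behind a gene-arrow diagram, plus optional BED.

    For every module, lists all annotated genes overlapping the module
    footprint extended by ``flank`` bp on each side, with positions in Mb,
    strand, biotype, role (lncRNA / partner / neighbour) and valve-bias
    class (from ``de_status``, gene id -> class).
    """
    de_status = dict(de_status or {})
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    spans = []
    for m in modules:
        lo, hi = m.span
        lo_f, hi_f = max(1, lo - flank), hi + flank
        partner_ids = {g.gene_id for g, _, _ in m.partners}
        for g in sorted(by_chrom.get(m.chrom, ()), key=lambda g: g.start):
            if g.end < lo_f or g.start > hi_f:
                continue
            if g.gene_id == m.lncRNA.gene_id:
                role = "lncRNA"
            elif g.gene_id in partner_ids:
                role = "partner"
            else:
                role = "neighbour"
            rows.append(
                {
                    "module": m.name,
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "pos_mb": round(g.start / 1e6, 4),
                    "strand": g.strand,
                    "biotype": g.biotype,
                    "role": role,
                    "bias_class": de_status.get(g.gene_id, "ns"),
                }
            )
        spans.append(
            SimpleNamespace(chrom=m.chrom, start=lo, end=hi, name=m.name, strand=".")
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "module", "gene_id", "chrom", "start", "end", "pos_mb",
            "strand", "biotype", "role", "bias_class",
        ],
    )
    if bed_path is not None:
        write_bed(spans, bed_path)
    return table
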