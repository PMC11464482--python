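"""Orthologue anchors, collinear block chaining, and module conservation.

Anchors are reciprocal best hits between two gene sets, from supplied
blast-tabular hits or from internal Smith-Waterman protein alignments
(BLOSUM62, affine gaps open 11 / extend 1, with a seed k-mer prefilter so
only plausible pairs are aligned). Blocks are maximum-score chains of
anchors over gene-rank coordinates: extending a chain adds the per-anchor
match score k and pays a penalty per skipped rank, with rank gaps capped
at m on both genomes; chains with at least s anchors are reported. s = 5,
k = 50, m = 20 and an e-value ceiling of 1e-5 are the defaults.

A cis module counts as conserved in a target genome when a partner coding
gene's orthologue lies inside a collinear block and a lncRNA orthologue —
a locus in the pairing window around that orthologue whose transcript
aligns to the source lncRNA at >= 50 % identity over >= 200 nt and itself
passes the non-coding checks — exists there.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .cismap import CisModule
from .formats import FormatError, GeneModel, HitRecord
from .screen import verify_lncrna

__all__ = [
    "SyntenyParams",
    "AnchorPair",
    "CollinearBlock",
    "ConservedModule",
    "align_proteins",
    "all_vs_all_hits",
    "call_anchors",
    "chain_collinear",
    "find_conserved_modules",
    "anchors_table",
    "blocks_table",
    "conserved_table",
    "block_links",
]

# Ungapped Karlin-Altschul constants for the BLOSUM62 e-value proxy
KA_K = 0.041
KA_LAMBDA = 0.267


@dataclass(frozen=True)
class SyntenyParams:
    min_anchors: int = 5  # s: minimum anchors per reported block
    match_score: float = 50.0  # k: score contributed by each anchor
    max_gap: int = 20  # m: maximum skipped ranks between consecutive anchors
    evalue_max: float = 1e-5  # e: anchor hit e-value ceiling
    gap_penalty: float = 1.0  # per skipped rank on either genome

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise FormatError("min_anchors must be >= 2")
        if self.max_gap < 0:
            raise FormatError("max_gap must be >= 0")
        if self.evalue_max <= 0:
            raise FormatError("evalue_max must be > 0")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: GeneModel
    gene_b: GeneModel
    score: float
    evalue: float


@dataclass
class CollinearBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: str  # 'same' | 'inverted'
    score: float


@dataclass
class ConservedModule:
    module: str
    lncRNA: str
    target_species: str
    status: str  # conserved | no_anchor | not_in_block | no_lncRNA_orthologue
    block_id: str | None = None
    partner: str | None = None
    partner_orthologue: str | None = None
    lnc_orthologue: str | None = None
    identity: float = float("nan")
    aligned_length: int = 0

    @property
    def conserved(self) -> bool:
        return self.status == "conserved"


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # NCBI convention "open 11, extend 1": a gap of length k costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _evalue_proxy(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def _alignment_stats(alignment) -> tuple[float, int]:
    """(percent identity, aligned columns) of one pairwise alignment."""
    counts = alignment.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    if ncols == 0:
        return 0.0, 0
    return 100.0 * counts.identities / ncols, ncols


def align_proteins(seq_a: str, seq_b: str) -> dict:
    """Local protein alignment with an e-value proxy.

    Smith-Waterman, BLOSUM62, affine gaps (open 11, extend 1). The e-value
    proxy is the ungapped Karlin-Altschul formula K*m*n*exp(-lambda*S) with
    K = 0.041, lambda = 0.267; when real aligner tabular output is
    available its e-values are used instead (see call_anchors).
    """
    if not seq_a or not seq_b:
        raise FormatError("empty protein sequence")
    aligner = _protein_aligner()
    alignments = aligner.align(seq_a, seq_b)
    score = alignments.score
    identity, ncols = _alignment_stats(alignments[0]) if score > 0 else (0.0, 0)
    return {
        "score": float(score),
        "evalue": _evalue_proxy(score, len(seq_a), len(seq_b)),
        "percent_identity": identity,
        "alignment_length": ncols,
    }


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    kmer: int = 5,
    min_shared_kmers: int = 2,
    evalue_max: float = 1e-3,
) -> list[HitRecord]:
    """Seeded all-vs-all protein hits between two proteomes.

    A pair is aligned only if the sequences share at least
    ``min_shared_kmers`` distinct exact k-mers (the seed-and-extend
    shortcut every fast aligner uses); pairs passing ``evalue_max`` are
    reported as 12-column-style hit records.
    """
    index: dict[str, list[str]] = {}
    for bid, seq in proteins_b.items():
        for km in _kmers(seq, kmer):
            index.setdefault(km, []).append(bid)
    aligner = _protein_aligner()
    hits: list[HitRecord] = []
    for aid in sorted(proteins_a):
        seq_a = proteins_a[aid]
        shared: Counter = Counter()
        for km in _kmers(seq_a, kmer):
            for bid in index.get(km, ()):
                shared[bid] += 1
        for bid in sorted(b for b, c in shared.items() if c >= min_shared_kmers):
            seq_b = proteins_b[bid]
            score = aligner.score(seq_a, seq_b)
            ev = _evalue_proxy(score, len(seq_a), len(seq_b))
            if ev > evalue_max:
                continue
            # identity from the global edit distance: cheap and exact for
            # the substitution-only divergence of close orthologues
            ncols = max(len(seq_a), len(seq_b))
            dist = edlib.align(seq_a, seq_b, task="distance", mode="NW")[
                "editDistance"
            ]
            identity = 100.0 * (ncols - dist) / ncols
            hits.append(
                HitRecord(
                    query_id=aid,
                    subject_id=bid,
                    percent_identity=max(identity, 0.0),
                    alignment_length=ncols,
                    evalue=ev,
                    bitscore=float(score),
                )
            )
    return hits


def _best_by(hits: Sequence[HitRecord], key_attr: str) -> dict[str, HitRecord]:
    """Best hit per gene: max bitscore, ties by identity then subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        key = getattr(h, key_attr)
        cur = best.get(key)
        if cur is None:
            best[key] = h
            continue
        a = (h.bitscore, h.percent_identity)
        b = (cur.bitscore, cur.percent_identity)
        other = "subject_id" if key_attr == "query_id" else "query_id"
        if a > b or (a == b and getattr(h, other) < getattr(cur, other)):
            best[key] = h
    return best


def call_anchors(
    hits: Sequence[HitRecord],
    genes_a: Sequence[GeneModel],
    genes_b: Sequence[GeneModel],
    params: SyntenyParams = SyntenyParams(),
) -> list[AnchorPair]:
    """Reciprocal-best-hit orthologue anchors below the e-value ceiling."""
    idx_a = {g.gene_id: g for g in genes_a}
    idx_b = {g.gene_id: g for g in genes_b}
    kept = []
    for h in hits:
        if h.query_id not in idx_a:
            raise FormatError(f"hit gene {h.query_id!r} absent from annotation A")
        if h.subject_id not in idx_b:
            raise FormatError(f"hit gene {h.subject_id!r} absent from annotation B")
        if h.evalue < params.evalue_max:
            kept.append(h)
    best_a = _best_by(kept, "query_id")
    best_b = _best_by(kept, "subject_id")
    anchors = []
    for aid, h in sorted(best_a.items()):
        back = best_b.get(h.subject_id)
        if back is not None and back.query_id == aid:
            anchors.append(
                AnchorPair(
                    gene_a=idx_a[aid],
                    gene_b=idx_b[h.subject_id],
                    score=h.bitscore,
                    evalue=h.evalue,
                )
            )
    return anchors


def _best_chain(
    anchors: list[AnchorPair], params: SyntenyParams, orientation: str
) -> tuple[float, list[AnchorPair]]:
    """Maximum-score collinear chain in one orientation (DP over anchors).

    Chain score = k * len(chain) - gap_penalty * (skipped ranks on A +
    skipped ranks on B summed over consecutive steps); both per-step gaps
    must be <= m. Returns (score, chain); an empty input gives (-inf, []).
    """
    if not anchors:
        return float("-inf"), []
    sign = 1 if orientation == "same" else -1
    order = sorted(
        anchors, key=lambda a: (a.gene_a.rank, sign * a.gene_b.rank)
    )
    n = len(order)
    k, m, gp = params.match_score, params.max_gap, params.gap_penalty
    dp = [k] * n
    parent = [-1] * n
    for j in range(n):
        aj, bj = order[j].gene_a.rank, order[j].gene_b.rank
        for i in range(j):
            ai, bi = order[i].gene_a.rank, order[i].gene_b.rank
            if aj <= ai:
                continue
            if sign * (bj - bi) <= 0:
                continue
            gap_a = aj - ai - 1
            gap_b = abs(bj - bi) - 1
            if gap_a > m or gap_b > m:
                continue
            cand = dp[i] + k - gp * (gap_a + gap_b)
            if cand > dp[j]:
                dp[j] = cand
                parent[j] = i
    best_j = max(range(n), key=lambda j: (dp[j], -order[j].gene_a.rank))
    chain = []
    j = best_j
    while j != -1:
        chain.append(order[j])
        j = parent[j]
    chain.reverse()
    return dp[best_j], chain


def chain_collinear(
    anchors: Sequence[AnchorPair], params: SyntenyParams = SyntenyParams()
) -> list[CollinearBlock]:
    """Collinear blocks by DP chaining with greedy disjoint extraction.

    Per chromosome pair, the best chain over both orientations is
    extracted, its anchors removed, and the search repeated until no chain
    reaches ``min_anchors``. Blocks are anchor-disjoint and reported in a
    deterministic order (chromA, chromB, first rank).
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.gene_a.chrom, a.gene_b.chrom), []).append(a)
    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(groups):
        remaining = list(groups[(ca, cb)])
        while len(remaining) >= params.min_anchors:
            best = None
            for orientation in ("same", "inverted"):
                score, chain = _best_chain(remaining, params, orientation)
                if len(chain) < params.min_anchors:
                    continue
                key = (score, orientation == "same", -chain[0].gene_a.rank)
                if best is None or key > best[0]:
                    best = (key, score, chain, orientation)
            if best is None:
                break
            _, score, chain, orientation = best
            blocks.append(
                CollinearBlock(
                    block_id="",
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=chain,
                    orientation=orientation,
                    score=score,
                )
            )
            used = {id(a) for a in chain}
            remaining = [a for a in remaining if id(a) not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0].gene_a.rank))
    for i, b in enumerate(blocks):
        b.block_id = f"block_{i:04d}"
    return blocks


def find_conserved_modules(
    modules: Sequence[CisModule],
    blocks: Sequence[CollinearBlock],
    target_species: str,
    target_genes: Sequence[GeneModel],
    target_transcripts: Mapping[str, str],
    lnc_sequences: Mapping[str, str],
    anchors: Sequence[AnchorPair] | None = None,
    window: int = 100_000,
    id_min: float = 50.0,
    len_min: int = 200,
    orf_max: int = 100,
) -> list[ConservedModule]:
    """Test each cis module for conservation in a target genome.

    For every module, the partner coding genes are looked up among the
    anchors (taken from the blocks if not given); a partner orthologue
    inside a collinear block defines the orthologous locus. The source
    lncRNA transcript is then locally aligned (blastn-like scoring)
    against every annotated transcript within ``window`` bp of that locus;
    the module is conserved iff some locus aligns at >= ``id_min`` %
    identity over >= ``len_min`` nt and that locus passes the non-coding
    checks. Modules failing a step carry a reason code instead.
    """
    if anchors is None:
        anchors = [a for b in blocks for a in b.anchors]
    anchor_by_a: dict[str, AnchorPair] = {}
    for a in anchors:
        anchor_by_a.setdefault(a.gene_a.gene_id, a)
    block_of: dict[tuple[str, str], str] = {}
    for b in blocks:
        for a in b.anchors:
            block_of[(a.gene_a.gene_id, a.gene_b.gene_id)] = b.block_id
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in target_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    aligner = _nucleotide_aligner()

    out: list[ConservedModule] = []
    for mod in modules:
        lnc_id = mod.lncRNA.gene_id
        if lnc_id not in lnc_sequences:
            raise FormatError(f"no sequence for lncRNA {lnc_id!r}")
        lnc_seq = lnc_sequences[lnc_id]
        anchored = [
            (cg, anchor_by_a[cg.gene_id])
            for cg, _, _ in mod.partners
            if cg.gene_id in anchor_by_a
        ]
        if not anchored:
            out.append(
                ConservedModule(mod.name, lnc_id, target_species, "no_anchor")
            )
            continue
        in_block = [
            (cg, anc, block_of[(cg.gene_id, anc.gene_b.gene_id)])
            for cg, anc in anchored
            if (cg.gene_id, anc.gene_b.gene_id) in block_of
        ]
        if not in_block:
            out.append(
                ConservedModule(
                    mod.name, lnc_id, target_species, "not_in_block",
                    partner=anchored[0][0].gene_id,
                    partner_orthologue=anchored[0][1].gene_b.gene_id,
                )
            )
            continue
        found = None
        for cg, anc, block_id in in_block:
            locus = anc.gene_b
            for tg in by_chrom.get(locus.chrom, ()):
                if tg.biotype != "lncRNA":
                    continue  # the orthologue must itself be a non-coding locus
                if tg.start > locus.end + window or tg.end < locus.start - window:
                    continue
                tseq = target_transcripts.get(tg.gene_id)
                if not tseq:
                    continue
                score = aligner.score(lnc_seq, tseq)
                if score <= 0:
                    continue
                identity, ncols = _alignment_stats(aligner.align(lnc_seq, tseq)[0])
                if identity < id_min or ncols < len_min:
                    continue
                if not verify_lncrna(tg.gene_id, tseq, orf_max=orf_max).verdict:
                    continue
                found = ConservedModule(
                    mod.name, lnc_id, target_species, "conserved",
                    block_id=block_id,
                    partner=cg.gene_id,
                    partner_orthologue=locus.gene_id,
                    lnc_orthologue=tg.gene_id,
                    identity=identity,
                    aligned_length=ncols,
                )
                break
            if found:
                break
        if found:
            out.append(found)
        else:
            cg, anc, block_id = in_block[0]
            out.append(
                ConservedModule(
                    mod.name, lnc_id, target_species, "no_lncRNA_orthologue",
                    block_id=block_id,
                    partner=cg.gene_id,
                    partner_orthologue=anc.gene_b.gene_id,
                )
            )
    return out


def anchors_table(anchors: Sequence[AnchorPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [a.gene_a.gene_id for a in anchors],
            "chrom_a": [a.gene_a.chrom for a in anchors],
            "rank_a": [a.gene_a.rank for a in anchors],
            "gene_b": [a.gene_b.gene_id for a in anchors],
            "chrom_b": [a.gene_b.chrom for a in anchors],
            "rank_b": [a.gene_b.rank for a in anchors],
            "score": [a.score for a in anchors],
            "evalue": [a.evalue for a in anchors],
        }
    )


def blocks_table(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for i, a in enumerate(b.anchors):
            rows.append(
                {
                    "block_id": b.block_id,
                    "chrom_a": b.chrom_a,
                    "chrom_b": b.chrom_b,
                    "orientation": b.orientation,
                    "score": b.score,
                    "n_anchors": len(b.anchors),
                    "position": i,
                    "gene_a": a.gene_a.gene_id,
                    "gene_b": a.gene_b.gene_id,
                    "rank_a": a.gene_a.rank,
                    "rank_b": a.gene_b.rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "chrom_b", "orientation", "score",
            "n_anchors", "position", "gene_a", "gene_b", "rank_a", "rank_b",
        ],
    )


def block_links(blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Dual-synteny link table (one row per block, bp spans on both sides)."""
    rows = []
    for b in blocks:
        sa = [a.gene_a for a in b.anchors]
        sb = [a.gene_b for a in b.anchors]
        rows.append(
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "start_a": min(g.start for g in sa),
                "end_a": max(g.end for g in sa),
                "chrom_b": b.chrom_b,
                "start_b": min(g.start for g in sb),
                "end_b": max(g.end for g in sb),
                "orientation": b.orientation,
                "n_anchors": len(b.anchors),
                "score": b.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "start_a", "end_a",
            "chrom_b", "start_b", "end_b", "orientation", "n_anchors", "score",
        ],
    )


def conserved_table(records: Sequence[ConservedModule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module": [r.module for r in records],
            "lncRNA": [r.lncRNA for r in records],
            "target_species": [r.target_species for r in records],
            "status": [r.status for r in records],
            "block_id": [r.block_id or "" for r in records],
            "partner": [r.partner or "" for r in records],
            "partner_orthologue": [r.partner_orthologue or "" for r in records],
            "lnc_orthologue": [r.lnc_orthologue or "" for r in records],
            "identity": [r.identity for r in records],
            "aligned_length": [r.aligned_length for r in records],
        }
    )
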