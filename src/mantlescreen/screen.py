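"""Screening of candidate biomineralization lncRNAs and protein comparisons.

Three expression criteria select candidate shell-formation lncRNAs from the
set of valve-biased non-coding genes:

1. mantle abundance — more than 70 % of the cross-tissue expression share
   (FPKM) falls in the mantle;
2. asymmetric-stage abundance — more than 70 % of the cross-stage share
   falls in the post-symmetry larval stages (pediveliger, spat, juvenile),
   when the two valves first diverge in shape;
3. damage response — significant differential expression between damaged
   and control mantle at one or more timepoints of a 21-day shell
   damage-repair time course.

The default candidate rule is the intersection of all three. The module
also re-checks lncRNA authenticity (length > 200 nt, no long ORF, no
protein-domain hit), compares domain repertoires across species, and runs
a simple gapped-motif enrichment (fixed residues with X wildcards, e.g.
LGXXGXXG) between valve-biased protein sets.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust, nb_wald_test
from .formats import ExpressionPanel, FormatError

__all__ = [
    "LncVerification",
    "CandidateLncRNA",
    "MotifResult",
    "longest_orf_codons",
    "verify_lncrna",
    "mantle_fraction",
    "mantle_fraction_table",
    "asym_stage_fraction",
    "asym_stage_fraction_table",
    "damage_response",
    "damage_responsive",
    "combine_candidacy",
    "shared_domain_sets",
    "motif_enrichment",
    "smp_crossref",
    "VENN_REGIONS",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VENN_REGIONS = (
    "mantle",
    "stage",
    "damage",
    "mantle&stage",
    "mantle&damage",
    "stage&damage",
    "mantle&stage&damage",
)


@dataclass(frozen=True)
class LncVerification:
    transcript_id: str
    length_nt: int
    longest_orf_codons: int
    has_domain_hit: bool
    verdict: bool


@dataclass
class CandidateLncRNA:
    gene_id: str
    mantle_fraction: float
    asym_stage_fraction: float
    damage_responsive: bool
    criteria_set: frozenset = field(default_factory=frozenset)
    is_candidate: bool = False


@dataclass(frozen=True)
class MotifResult:
    pattern: str
    count_flat: int
    total_flat: int
    count_round: int
    total_round: int
    odds_ratio: float
    p: float
    padj: float = float("nan")


def longest_orf_codons(seq: str) -> int:
    """Length in codons (excluding the stop) of the longest ATG->stop ORF.

    Both strands, all three frames, standard genetic code; an ORF must end
    at an in-frame stop codon within the sequence.
    """
    seq = seq.upper()
    best = 0
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        for frame in range(3):
            open_at = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if open_at is not None:
                        best = max(best, (i - open_at) // 3)
                        open_at = None
                elif codon == "ATG" and open_at is None:
                    open_at = i
    return best


def verify_lncrna(
    transcript_id: str,
    sequence: str,
    has_domain_hit: bool = False,
    orf_max: int = 100,
    min_length: int = 200,
) -> LncVerification:
    """Reconfirm non-coding authenticity of a transcript.

    verdict is true iff length > ``min_length`` nt, the longest ORF is
    shorter than ``orf_max`` codons, and there is no protein-domain hit.
    """
    if not sequence:
        raise FormatError(f"transcript {transcript_id!r}: empty sequence")
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise FormatError(
            f"transcript {transcript_id!r}: non-nucleotide characters {sorted(bad)}"
        )
    orf = longest_orf_codons(sequence)
    verdict = len(sequence) > min_length and orf < orf_max and not has_domain_hit
    return LncVerification(
        transcript_id=transcript_id,
        length_nt=len(sequence),
        longest_orf_codons=orf,
        has_domain_hit=has_domain_hit,
        verdict=verdict,
    )


def _per_group_means(panel: ExpressionPanel, attr: str) -> pd.DataFrame:
    """Mean FPKM per gene per metadata group (tissue or stage)."""
    groups: dict[str, list[str]] = {}
    for s in panel.samples:
        groups.setdefault(getattr(s, attr), []).append(s.sample_id)
    cols = {}
    for name, ids in sorted(groups.items()):
        cols[name] = panel.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def mantle_fraction_table(
    panel: ExpressionPanel, mantle_tissue: str = "mantle", tau: float = 0.7
) -> pd.DataFrame:
    """Mantle expression share for every gene of a multi-tissue FPKM panel.

    fraction = mantle per-tissue mean / sum of per-tissue means. Each
    tissue contributes its mean once, so unequal replicate numbers do not
    tilt the denominator. Genes silent everywhere get fraction NaN and
    fail the criterion.
    """
    by_tissue = _per_group_means(panel, "tissue")
    if mantle_tissue not in by_tissue.columns:
        raise FormatError(f"no {mantle_tissue!r} samples in panel")
    if by_tissue.shape[1] < 2:
        raise FormatError("need at least one tissue besides the mantle")
    total = by_tissue.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = by_tissue[mantle_tissue] / total
    frac = frac.where(total > 0)
    return pd.DataFrame(
        {"fraction": frac, "passes": (frac > tau).fillna(False), "defined": total > 0}
    )


def mantle_fraction(
    panel: ExpressionPanel, gene_id: str, mantle_tissue: str = "mantle",
    tau: float = 0.7,
) -> tuple[float, bool]:
    """Mantle share and pass flag for one gene (see mantle_fraction_table)."""
    tab = mantle_fraction_table(panel, mantle_tissue=mantle_tissue, tau=tau)
    if gene_id not in tab.index:
        raise KeyError(gene_id)
    row = tab.loc[gene_id]
    return float(row["fraction"]), bool(row["passes"])


def asym_stage_fraction_table(
    panel: ExpressionPanel,
    asym_stages: Sequence[str] = ("pediveliger", "spat", "juvenile"),
    tau: float = 0.7,
) -> pd.DataFrame:
    """Asymmetric-stage expression share across a larval-stage FPKM panel.

    fraction = sum of per-stage means over the asymmetric stages / sum of
    per-stage means over all stages.
    """
    by_stage = _per_group_means(panel, "stage")
    asym = [s for s in by_stage.columns if s in set(asym_stages)]
    if not asym:
        raise FormatError("no asymmetric-stage samples in panel")
    if len(asym) == by_stage.shape[1]:
        raise FormatError("no symmetric-stage samples in panel")
    total = by_stage.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = by_stage[asym].sum(axis=1) / total
    frac = frac.where(total > 0)
    return pd.DataFrame(
        {"fraction": frac, "passes": (frac > tau).fillna(False), "defined": total > 0}
    )


def asym_stage_fraction(
    panel: ExpressionPanel,
    gene_id: str,
    asym_stages: Sequence[str] = ("pediveliger", "spat", "juvenile"),
    tau: float = 0.7,
) -> tuple[float, bool]:
    tab = asym_stage_fraction_table(panel, asym_stages=asym_stages, tau=tau)
    if gene_id not in tab.index:
        raise KeyError(gene_id)
    row = tab.loc[gene_id]
    return float(row["fraction"]), bool(row["passes"])


def damage_response(
    panel: ExpressionPanel, alpha: float = 0.05, lfc_min: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Damaged-vs-control differential expression per timepoint.

    Returns (long table with gene_id, timepoint, log2fc, p, padj;
    per-gene boolean Series: significant at >= 1 timepoint). Timepoints
    lacking >= 2 replicates of either condition are skipped with a warning.
    """
    timepoints = sorted(
        {s.timepoint for s in panel.samples if s.timepoint is not None}
    )
    rows = []
    responsive = pd.Series(False, index=panel.values.index)
    for tp in timepoints:
        damaged = panel.select(timepoint=tp, condition="damaged")
        control = panel.select(timepoint=tp, condition="control")
        if len(damaged) < 2 or len(control) < 2:
            warnings.warn(
                f"timepoint {tp}: fewer than 2 replicates of damaged or "
                f"control; skipped",
                stacklevel=2,
            )
            continue
        res = nb_wald_test(panel, damaged, control)
        hit = (res["padj"] < alpha) & (res["log2fc"].abs() >= lfc_min)
        responsive |= hit
        sub = res[["log2fc", "p", "padj"]].copy()
        sub.insert(0, "timepoint", tp)
        sub.insert(0, "gene_id", sub.index)
        rows.append(sub.reset_index(drop=True))
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["gene_id", "timepoint", "log2fc", "p", "padj"])
    )
    return table, responsive


def damage_responsive(
    panel: ExpressionPanel, gene_id: str, alpha: float = 0.05, lfc_min: float = 1.0
) -> tuple[bool, pd.DataFrame]:
    """Per-gene damage responsiveness plus its per-timepoint DE table."""
    table, flags = damage_response(panel, alpha=alpha, lfc_min=lfc_min)
    if gene_id not in flags.index:
        raise KeyError(gene_id)
    return bool(flags[gene_id]), table[table["gene_id"] == gene_id].reset_index(
        drop=True
    )


def combine_candidacy(
    criteria: pd.DataFrame, rule: str = "intersection", min_criteria: int = 3
) -> tuple[list[CandidateLncRNA], dict[str, int]]:
    """Combine the three screening criteria into candidate calls.

    ``criteria`` is indexed by gene id with boolean columns crit_mantle,
    crit_stage, crit_damage and (optionally) numeric mantle_fraction /
    asym_stage_fraction columns. ``rule`` is 'intersection' (all three,
    default), 'union', or 'threshold' (>= min_criteria). Returns candidate
    records plus exclusive Venn-region counts over the 7 non-empty
    intersections.
    """
    if rule not in {"intersection", "union", "threshold"}:
        raise FormatError(f"unknown candidacy rule {rule!r}")
    need = {"crit_mantle", "crit_stage", "crit_damage"}
    if not need.issubset(criteria.columns):
        raise FormatError(f"criteria table must have columns {sorted(need)}")
    venn = {region: 0 for region in VENN_REGIONS}
    out: list[CandidateLncRNA] = []
    for gid, row in criteria.iterrows():
        members = []
        if row["crit_mantle"]:
            members.append("mantle")
        if row["crit_stage"]:
            members.append("stage")
        if row["crit_damage"]:
            members.append("damage")
        cset = frozenset(members)
        if members:
            venn["&".join(members)] += 1
        n = len(members)
        is_cand = {
            "intersection": n == 3,
            "union": n >= 1,
            "threshold": n >= min_criteria,
        }[rule]
        out.append(
            CandidateLncRNA(
                gene_id=gid,
                mantle_fraction=float(row.get("mantle_fraction", np.nan)),
                asym_stage_fraction=float(row.get("asym_stage_fraction", np.nan)),
                damage_responsive=bool(row["crit_damage"]),
                criteria_set=cset,
                is_candidate=is_cand,
            )
        )
    return out, venn


def shared_domain_sets(
    domains_by_species: Mapping[str, Iterable],
    shared_in: Sequence[str],
    absent_from: Sequence[str] = (),
) -> set:
    """Domains present in every species of ``shared_in`` and in none of
    ``absent_from`` (e.g. domains restricted to the asymmetric species)."""
    if not shared_in:
        raise FormatError("shared_in must name at least one species")
    sets = {sp: set(v) for sp, v in domains_by_species.items()}
    for sp in list(shared_in) + list(absent_from):
        if sp not in sets:
            raise FormatError(f"species {sp!r} not supplied")
    result = set.intersection(*(sets[sp] for sp in shared_in))
    for sp in absent_from:
        result -= sets[sp]
    return result


def _window_patterns(window: str, min_anchored: int):
    """All gapped patterns of this window: first and last residue fixed,
    plus any interior subset, with >= min_anchored fixed positions."""
    L = len(window)
    interior = range(1, L - 1)
    need = max(min_anchored - 2, 0)
    for r in range(need, L - 1):
        for combo in itertools.combinations(interior, r):
            fixed = {0, L - 1, *combo}
            yield "".join(
                window[i] if i in fixed else "X" for i in range(L)
            )


def _protein_pattern_set(seq: str, length: int, min_anchored: int) -> set[str]:
    out: set[str] = set()
    for i in range(len(seq) - length + 1):
        out.update(_window_patterns(seq[i : i + length], min_anchored))
    return out


def motif_enrichment(
    flat_proteins: Mapping[str, str],
    round_proteins: Mapping[str, str],
    length: int = 8,
    min_anchored: int = 3,
    min_count: int = 2,
    max_patterns: int = 2_000_000,
) -> list[MotifResult]:
    """Gapped-motif enrichment between valve-biased protein sets.

    Patterns are windows of ``length`` residues with the first and last
    position fixed, at least ``min_anchored`` fixed residues in total, and
    X wildcards elsewhere (the LGXXGXXG form). Every pattern occurring in
    the data is counted once per protein (match multiplicity ignored);
    patterns seen in fewer than ``min_count`` proteins overall are not
    tested. Each tested pattern gets a two-sided Fisher exact p on the
    (matching, non-matching) x (flat, round) table, BH-adjusted across
    patterns; results are ranked by padj, then descending odds ratio,
    then pattern.
    """
    if not flat_proteins or not round_proteins:
        raise FormatError("both protein sets must be non-empty")
    if min_anchored < 3:
        raise FormatError("min_anchored must be >= 3")

    flat_sets = [
        _protein_pattern_set(seq.upper(), length, min_anchored)
        for seq in flat_proteins.values()
    ]
    round_sets = [
        _protein_pattern_set(seq.upper(), length, min_anchored)
        for seq in round_proteins.values()
    ]
    counts: Counter = Counter()
    for s in flat_sets + round_sets:
        counts.update(s)
    if len(counts) > max_patterns:
        raise FormatError(
            f"pattern space too large ({len(counts)} > {max_patterns}); "
            f"raise min_anchored or shorten the window"
        )
    flat_counts: Counter = Counter()
    for s in flat_sets:
        flat_counts.update(s)

    n_flat, n_round = len(flat_sets), len(round_sets)
    tested = [pat for pat, c in counts.items() if c >= min_count]
    results = []
    cache: dict[tuple, tuple[float, float]] = {}
    for pat in tested:
        a = flat_counts[pat]
        c = counts[pat] - a
        key = (a, c)
        if key not in cache:
            table = [[a, n_flat - a], [c, n_round - c]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            cache[key] = (odds, p)
        odds, p = cache[key]
        results.append(
            MotifResult(
                pattern=pat,
                count_flat=a,
                total_flat=n_flat,
                count_round=c,
                total_round=n_round,
                odds_ratio=float(odds),
                p=float(p),
            )
        )
    if not results:
        return []
    padj = bh_adjust([r.p for r in results])
    results = [
        MotifResult(
            pattern=r.pattern,
            count_flat=r.count_flat,
            total_flat=r.total_flat,
            count_round=r.count_round,
            total_round=r.total_round,
            odds_ratio=r.odds_ratio,
            p=r.p,
            padj=float(q),
        )
        for r, q in zip(results, padj)
    ]
    results.sort(key=lambda r: (r.padj, -r.odds_ratio, r.pattern))
    return results


def smp_crossref(
    de_coding_genes: Sequence[str],
    shell_proteome_ids: Iterable[str],
    secreted_genes: Iterable[str],
    asym_domain_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-reference valve-biased coding genes with the shell proteome.

    Flags each gene as secreted / SMP (shell matrix protein, i.e. present
    in the shell-proteome id list) / carrying a domain specific to the
    asymmetric mantle, and returns the 7-region Venn partition. Proteome
    ids absent from the gene set raise a warning and are ignored.
    """
    genes = list(de_coding_genes)
    gene_set = set(genes)
    smp = set(shell_proteome_ids)
    stray = sorted(smp - gene_set)
    if stray:
        warnings.warn(
            f"{len(stray)} shell-proteome ids not in the DE gene set "
            f"(e.g. {stray[:3]}); ignored",
            stacklevel=2,
        )
    secreted = set(secreted_genes)
    asym = set(asym_domain_genes)
    df = pd.DataFrame(
        {
            "secreted": [g in secreted for g in genes],
            "SMP": [g in smp for g in genes],
            "asym_domain": [g in asym for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    regions = (
        "secreted", "SMP", "asym_domain",
        "secreted&SMP", "secreted&asym_domain", "SMP&asym_domain",
        "secreted&SMP&asym_domain",
    )
    venn = {r: 0 for r in regions}
    for _, row in df.iterrows():
        members = [c for c in ("secreted", "SMP", "asym_domain") if row[c]]
        if members:
            venn["&".join(members)] += 1
    return df, venn
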