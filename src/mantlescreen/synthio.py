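"""Synthetic multi-species genomes, orthologies, and expression panels.

The generator emulates the study design the pipeline is built for: an
ancestral bivalve-like genome is laid out gene by gene, derived species
are produced by segmental inversions, translocations, random gene loss and
sequence divergence, and lncRNA-coding cis modules are planted at known
positions — copied collinearly (with an intact >= 5-gene neighbourhood)
into the species in which they are "conserved". Expression panels are
drawn from a negative binomial with variance mu + alpha*mu^2: two-valve
mantle replicates with an excess of flat-biased genes, a multi-tissue
panel, a larval-stage panel, and a 21-day damage-repair time course.

Planted module genes are strongly flat-valve-specific and abundant, as
befits candidate biomineralization genes; planted candidate lncRNAs carry
>= 80 % of their cross-tissue expression in the mantle, >= 80 % of their
cross-stage expression in the post-metamorphosis stages, and a 4-fold
damage induction at days 3 and 7. Background lncRNA sequence turns over
completely between species (lncRNA sequence conservation is the exception,
not the rule), so only planted module lncRNAs have recognisable
orthologues; that is the planted truth the conservation stage is scored
against.

Everything is driven by one integer seed: identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import (
    ExpressionPanel,
    FormatError,
    GeneModel,
    SampleMeta,
    write_counts,
    write_gff3,
)

__all__ = [
    "SimConfig",
    "SimGenome",
    "SimulatedGenomes",
    "TruthTable",
    "simulate_genomes",
    "plant_cis_modules",
    "simulate_expression",
    "simulate",
    "write_truth",
    "read_truth",
    "write_fasta",
    "write_run",
    "invert_segment",
    "translocate_segment",
]

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

# Stop-codon cassette carrying stops in all three frames of both strands;
# written into lncRNA transcripts at regular spacing to cap ORF length.
_STOP_CASSETTE = "TAAATAAATAAATTTATTTATTTA"
_CASSETTE_SPACING = 120


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic data generator."""

    seed: int = 0
    n_species: int = 3
    n_chroms: int = 5
    genes_per_chrom: int = 400
    intergenic_mean: int = 8000  # bp, exponential gaps between genes
    frac_lncRNA: float = 0.10  # background lncRNA gene fraction
    n_planted_modules: int = 12
    n_conserved_modules: int = 8  # planted collinearly in the target species
    conserved_in: int = 2  # number of target species carrying each
    module_span: int = 50_000  # bp, max lncRNA-partner separation (< window)
    n_rearrangements: int = 2  # inversions + translocations per derived species
    gene_loss_frac: float = 0.05
    protein_divergence: float = 0.10  # i.i.d. substitution rate, orthologues
    transcript_divergence: float = 0.10  # coding + planted lncRNA transcripts
    nb_mean_log_range: tuple[float, float] = (10.0, 1000.0)
    nb_dispersion: float = 0.1  # alpha in var = mu + alpha*mu^2
    bias_log2fc: float = 2.0  # background valve-biased effect size
    module_bias_log2fc: float = 4.0  # planted module genes (side-specific)
    frac_flat_biased: float = 0.05
    frac_round_biased: float = 0.02
    replicates: int = 3  # mantle valve replicates (pools of individuals)
    tissues: tuple[str, ...] = (
        "mantle", "gill", "muscle", "gonad", "digestive_gland",
    )
    tissue_replicates: int = 3
    sym_stages: tuple[str, ...] = ("trochophore", "d_larva", "veliger")
    asym_stages: tuple[str, ...] = ("pediveliger", "spat", "juvenile")
    stage_replicates: int = 3
    damage_timepoints: tuple[int, ...] = (0, 1, 3, 7, 14, 21)
    damage_replicates: int = 3
    damage_response_fold: float = 4.0
    damage_response_days: tuple[int, ...] = (3, 7)
    n_decoys_per_criterion: int = 2
    library_size_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise FormatError("n_species must be >= 2")
        for frac in (self.frac_lncRNA, self.frac_flat_biased, self.frac_round_biased):
            if not 0 <= frac <= 1:
                raise FormatError("fractions must lie in [0, 1]")
        if self.frac_flat_biased + self.frac_round_biased > 1:
            raise FormatError("biased fractions must sum to <= 1")
        if self.nb_dispersion <= 0:
            raise FormatError("nb_dispersion must be > 0")
        if self.genes_per_chrom < 2 * self.n_planted_modules:
            raise FormatError(
                "genes_per_chrom must be at least twice n_planted_modules"
            )
        if self.n_conserved_modules > self.n_planted_modules:
            raise FormatError("n_conserved_modules exceeds n_planted_modules")
        if self.conserved_in > self.n_species - 1:
            raise FormatError("conserved_in exceeds the number of target species")
        if self.module_span >= 100_000:
            raise FormatError("module_span must stay below the pairing window")


@dataclass
class SimGenome:
    """One species: ordered gene entries per chromosome plus sequences.

    Each entry is a dict with keys aid (ancestral id, None for planted
    lncRNAs), gid (species gene id), length, strand, biotype and gap
    (intergenic gap before the gene). Coordinates and ranks are derived
    by ``annotation()``.
    """

    species: str
    chroms: dict[str, list[dict]]
    proteins: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)

    def annotation(self) -> list[GeneModel]:
        genes = []
        for chrom in sorted(self.chroms):
            pos = 0
            for rank, e in enumerate(self.chroms[chrom]):
                start = pos + e["gap"] + 1
                end = start + e["length"] - 1
                pos = end
                genes.append(
                    GeneModel(
                        gene_id=e["gid"],
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=e["strand"],
                        biotype=e["biotype"],
                        rank=rank,
                    )
                )
        return genes

    def gene_lengths(self) -> pd.Series:
        data = {
            e["gid"]: e["length"] for c in self.chroms.values() for e in c
        }
        return pd.Series(data, name="length")


@dataclass
class SimulatedGenomes:
    genomes: dict[str, SimGenome]
    ortho: dict[str, dict[str, str]]  # ancestral id -> species -> gene id
    source: str  # reference species name


@dataclass
class TruthTable:
    """Planted truth: per-gene effects and per-module conservation."""

    genes: pd.DataFrame  # indexed by source gene id
    modules: pd.DataFrame  # indexed by module id


# ---------------------------------------------------------------------------
# sequence helpers

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _DNA[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return _AA[rng.integers(0, 20, n)].tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: np.ndarray) -> str:
    """i.i.d. substitutions at ``rate`` of sites, always to a different letter."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    n = int(mask.sum())
    if n:
        lut = {b: i for i, b in enumerate(alphabet.tolist())}
        idx = np.array([lut[b] for b in arr[mask].tolist()])
        shift = rng.integers(1, len(alphabet), n)
        arr[mask] = alphabet[(idx + shift) % len(alphabet)]
    return arr.tobytes().decode("ascii")


def _lnc_transcript(rng: np.random.Generator, n: int) -> str:
    """Random DNA with stop cassettes so no strand carries a long ORF."""
    seq = list(_random_dna(rng, n))
    for pos in range(0, n - len(_STOP_CASSETTE) + 1, _CASSETTE_SPACING):
        seq[pos : pos + len(_STOP_CASSETTE)] = _STOP_CASSETTE
    return "".join(seq)


# ---------------------------------------------------------------------------
# rearrangement operators (pure, unit-testable)

def invert_segment(entries: list[dict], start: int, length: int) -> list[dict]:
    """Reverse a contiguous segment of gene order and flip its strands."""
    out = list(entries)
    seg = [dict(e) for e in out[start : start + length]][::-1]
    for e in seg:
        e["strand"] = "-" if e["strand"] == "+" else "+"
    out[start : start + length] = seg
    return out


def translocate_segment(
    chroms: dict[str, list[dict]],
    src_chrom: str,
    start: int,
    length: int,
    dst_chrom: str,
    dst_pos: int,
) -> dict[str, list[dict]]:
    """Move a contiguous segment of genes to another position/chromosome."""
    out = {c: list(v) for c, v in chroms.items()}
    seg = out[src_chrom][start : start + length]
    del out[src_chrom][start : start + length]
    out[dst_chrom][dst_pos:dst_pos] = seg
    return out


# ---------------------------------------------------------------------------
# genome simulation

def simulate_genomes(cfg: SimConfig) -> SimulatedGenomes:
    """Ancestor plus derived species with rearrangements, loss, divergence."""
    rng = np.random.default_rng([cfg.seed, 11])
    species = [f"sp{i}" for i in range(cfg.n_species)]
    source = species[0]

    # Ancestral layout and sequences
    anc_chroms: dict[str, list[dict]] = {}
    anc_protein: dict[str, str] = {}
    anc_transcript: dict[str, str] = {}
    counter = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        entries = []
        for _ in range(cfg.genes_per_chrom):
            aid = f"g{counter:05d}"
            counter += 1
            is_lnc = rng.random() < cfg.frac_lncRNA
            length = int(
                rng.integers(400, 1501) if is_lnc else rng.integers(500, 3001)
            )
            entries.append(
                {
                    "aid": aid,
                    "gid": aid,
                    "length": length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "biotype": "lncRNA" if is_lnc else "coding",
                    "gap": max(200, int(rng.exponential(cfg.intergenic_mean))),
                }
            )
            if is_lnc:
                anc_transcript[aid] = _lnc_transcript(rng, length)
            else:
                anc_protein[aid] = _random_protein(rng, int(rng.integers(100, 401)))
                anc_transcript[aid] = _random_dna(rng, length)
        anc_chroms[chrom] = entries

    genomes: dict[str, SimGenome] = {}
    ortho: dict[str, dict[str, str]] = {aid: {} for aid in anc_transcript}

    for si, sp in enumerate(species):
        chroms = {c: [dict(e) for e in v] for c, v in anc_chroms.items()}
        if si > 0:  # derived species: rearrange then lose genes
            for r in range(cfg.n_rearrangements):
                if r % 2 == 0:
                    chrom = f"chr{int(rng.integers(0, cfg.n_chroms)) + 1}"
                    n = len(chroms[chrom])
                    length = int(rng.integers(10, min(51, n)))
                    start = int(rng.integers(0, n - length + 1))
                    chroms[chrom] = invert_segment(chroms[chrom], start, length)
                else:
                    src = f"chr{int(rng.integers(0, cfg.n_chroms)) + 1}"
                    n = len(chroms[src])
                    length = int(rng.integers(5, min(21, n)))
                    start = int(rng.integers(0, n - length + 1))
                    dst = f"chr{int(rng.integers(0, cfg.n_chroms)) + 1}"
                    limit = len(chroms[dst]) - (length if dst == src else 0)
                    dst_pos = int(rng.integers(0, max(1, limit + 1)))
                    chroms = translocate_segment(chroms, src, start, length, dst, dst_pos)
            if cfg.gene_loss_frac > 0:
                for chrom in sorted(chroms):
                    keep_mask = rng.random(len(chroms[chrom])) >= cfg.gene_loss_frac
                    chroms[chrom] = [
                        e for e, keep in zip(chroms[chrom], keep_mask) if keep
                    ]
        genome = SimGenome(species=sp, chroms=chroms)
        for chrom in sorted(chroms):
            for e in chroms[chrom]:
                aid = e["aid"]
                gid = f"{sp}_{aid}"
                e["gid"] = gid
                ortho[aid][sp] = gid
                if si == 0:
                    if e["biotype"] == "coding":
                        genome.proteins[gid] = anc_protein[aid]
                    genome.transcripts[gid] = anc_transcript[aid]
                else:
                    if e["biotype"] == "coding":
                        genome.proteins[gid] = _mutate(
                            anc_protein[aid], cfg.protein_divergence, rng, _AA
                        )
                        genome.transcripts[gid] = _mutate(
                            anc_transcript[aid], cfg.transcript_divergence, rng, _DNA
                        )
                    else:
                        # Background lncRNA sequence turns over completely
                        # between species: only planted module lncRNAs keep
                        # recognisable orthologues, so truth-table negative
                        # conservation labels are exact by construction
                        genome.transcripts[gid] = _lnc_transcript(
                            rng, e["length"]
                        )
        genomes[sp] = genome
    return SimulatedGenomes(genomes=genomes, ortho=ortho, source=source)


# ---------------------------------------------------------------------------
# module planting

def _position_index(genome: SimGenome) -> dict[str, tuple[str, int]]:
    idx = {}
    for chrom in sorted(genome.chroms):
        for i, e in enumerate(genome.chroms[chrom]):
            if e["aid"] is not None:
                idx[e["aid"]] = (chrom, i)
    return idx


def _neighbourhood_intact(
    window_aids: list[str], posmap: dict[str, tuple[str, int]], min_present: int
) -> bool:
    """True if the surviving orthologues of a gene window are contiguous,
    co-chromosomal and collinear (possibly inverted) in the target."""
    present = [posmap[a] for a in window_aids if a in posmap]
    if len(present) < min_present:
        return False
    chroms = {c for c, _ in present}
    if len(chroms) != 1:
        return False
    pos = [i for _, i in present]
    if max(pos) - min(pos) != len(pos) - 1:
        return False
    diffs = np.diff(pos)
    return bool((diffs > 0).all() or (diffs < 0).all())


def plant_cis_modules(
    cfg: SimConfig, sim: SimulatedGenomes
) -> tuple[SimulatedGenomes, TruthTable]:
    """Insert lncRNA-coding modules into the source (and target) genomes.

    Each module is one new lncRNA gene placed within ``module_span`` of
    one or two coding partner genes at a site whose 15-gene neighbourhood
    is intact and collinear in every species the module is conserved in.
    Modules are mutually separated by at least 40 gene positions. The
    genomes are modified in place; the planted truth is returned.
    """
    rng = np.random.default_rng([cfg.seed, 17])
    species = list(sim.genomes)
    targets_all = species[1:]
    src = sim.genomes[sim.source]
    posmaps = {sp: _position_index(sim.genomes[sp]) for sp in targets_all}

    # Candidate anchor sites in source order
    candidates = []
    for chrom in sorted(src.chroms):
        entries = src.chroms[chrom]
        for j in range(10, len(entries) - 10):
            if entries[j]["biotype"] == "coding":
                candidates.append((chrom, j))
    order = rng.permutation(len(candidates))

    def targets_ok(chrom: str, j: int, targets: Sequence[str]) -> bool:
        entries = src.chroms[chrom]
        window = [
            e["aid"] for e in entries[j - 7 : j + 8] if e["aid"] is not None
        ]
        anchor_aid = entries[j]["aid"]
        for sp in targets:
            if anchor_aid not in posmaps[sp]:
                return False
            if not _neighbourhood_intact(window, posmaps[sp], min_present=11):
                return False
        return True

    chosen: list[tuple[str, int]] = []
    used: dict[str, list[int]] = {}

    def pick(targets: Sequence[str]) -> tuple[str, int] | None:
        for k in order:
            chrom, j = candidates[k]
            if any(abs(j - u) < 40 for u in used.get(chrom, ())):
                continue
            if (chrom, j) in chosen:
                continue
            if targets and not targets_ok(chrom, j, targets):
                continue
            chosen.append((chrom, j))
            used.setdefault(chrom, []).append(j)
            return chrom, j
        return None

    gene_rows: dict[str, dict] = {}
    module_rows = []
    planted_sites = []  # (module idx, chrom, anchor j, targets)
    for i in range(cfg.n_planted_modules):
        conserved = i < cfg.n_conserved_modules
        targets = targets_all[: cfg.conserved_in] if conserved else []
        site = pick(targets)
        if site is None:
            raise FormatError(
                "insufficient intergenic space: no suitable planting site "
                f"for module {i} (need intact collinear neighbourhoods)"
            )
        planted_sites.append((i, site[0], site[1], targets))

    # Insert from high index to low per chromosome so indices stay valid
    planted_sites.sort(key=lambda t: (t[1], -t[2]))
    for i, chrom, j, targets in planted_sites:
        entries = src.chroms[chrom]
        anchor = entries[j]
        lnc_len = int(rng.integers(600, 1201))
        lnc_seq = _lnc_transcript(rng, lnc_len)
        gap = int(rng.integers(2000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        lnc_gid = f"{sim.source}_lnc{i:02d}"
        entry = {
            "aid": None,
            "gid": lnc_gid,
            "length": lnc_len,
            "strand": strand,
            "biotype": "lncRNA",
            "gap": gap,
        }
        entries.insert(j + 1, entry)
        src.transcripts[lnc_gid] = lnc_seq

        partners = [anchor["gid"]]
        # Second partner: preceding coding gene, if it stays inside the span
        prev = entries[j - 1]
        if prev["biotype"] == "coding":
            dist2 = anchor["gap"] + anchor["length"] + gap
            if dist2 <= cfg.module_span:
                partners.append(prev["gid"])

        lnc_by_species = {sim.source: lnc_gid}
        for sp in targets:
            tgt = sim.genomes[sp]
            anchor_aid = anchor["aid"]
            tchrom, tpos = _position_index(tgt)[anchor_aid]
            t_gid = f"{sp}_lnc{i:02d}"
            tgt.chroms[tchrom].insert(
                tpos + 1,
                {
                    "aid": None,
                    "gid": t_gid,
                    "length": lnc_len,
                    "strand": strand,
                    "biotype": "lncRNA",
                    "gap": int(rng.integers(2000, 20_001)),
                },
            )
            tgt.transcripts[t_gid] = _mutate(
                lnc_seq, cfg.transcript_divergence, rng, _DNA
            )
            lnc_by_species[sp] = t_gid

        module_id = f"module_{i:02d}"
        module_rows.append(
            {
                "module_id": module_id,
                "lnc_source": lnc_gid,
                "partners": ";".join(partners),
                "conserved_in": ";".join(targets),
                "lnc_by_species": ";".join(
                    f"{sp}={gid}" for sp, gid in lnc_by_species.items()
                ),
            }
        )
        gene_rows[lnc_gid] = {
            "bias_class": "flat_specific",
            "is_module_gene": True,
            "module_id": module_id,
            "is_candidate_lnc": True,
            "crit_mantle": True,
            "crit_stage": True,
            "crit_damage": True,
        }
        for pg in partners:
            gene_rows[pg] = {
                "bias_class": "flat_specific",
                "is_module_gene": True,
                "module_id": module_id,
                "is_candidate_lnc": False,
                "crit_mantle": False,
                "crit_stage": False,
                "crit_damage": False,
            }

    # Full per-gene truth over the (now final) source annotation
    all_rows = []
    for g in src.annotation():
        base = gene_rows.get(
            g.gene_id,
            {
                "bias_class": "ns",
                "is_module_gene": False,
                "module_id": "",
                "is_candidate_lnc": False,
                "crit_mantle": False,
                "crit_stage": False,
                "crit_damage": False,
            },
        )
        all_rows.append({"gene_id": g.gene_id, "biotype": g.biotype, **base})
    genes_df = pd.DataFrame(all_rows).set_index("gene_id")
    modules_df = (
        pd.DataFrame(module_rows).set_index("module_id").sort_index()
        if module_rows
        else pd.DataFrame(
            columns=["lnc_source", "partners", "conserved_in", "lnc_by_species"]
        )
    )
    return sim, TruthTable(genes=genes_df, modules=modules_df)


# ---------------------------------------------------------------------------
# expression simulation

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """Negative binomial with variance mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.clip(mean, 1e-8, None)
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mean))


def simulate_expression(
    cfg: SimConfig, sim: SimulatedGenomes, truth: TruthTable
) -> dict[str, ExpressionPanel]:
    """Count panels for the source species; updates truth in place.

    Returns {'mantle', 'tissue', 'stage', 'damage'} panels. Background
    valve-biased genes (and the per-criterion decoy lncRNAs) are chosen
    here and recorded in the truth table.
    """
    if cfg.nb_dispersion <= 0:
        raise FormatError("nb_dispersion must be > 0")
    rng = np.random.default_rng([cfg.seed, 29])
    src = sim.genomes[sim.source]
    genes = [g.gene_id for g in src.annotation()]
    n = len(genes)
    gidx = pd.Index(genes, name="gene_id")
    truth_genes = truth.genes.reindex(gidx)
    if truth_genes["bias_class"].isna().any():
        raise FormatError("truth table does not cover the source annotation")

    lo, hi = cfg.nb_mean_log_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    is_module = truth_genes["is_module_gene"].to_numpy(dtype=bool)
    # Module genes are abundant mantle genes: redraw from the upper range
    mu[is_module] = np.exp(
        rng.uniform(np.log(max(lo, 50.0)), np.log(hi), int(is_module.sum()))
    )

    # Background valve bias (decoy lncRNAs are made flat-biased too, so
    # they enter the DE-lncRNA screen and exercise the Venn regions)
    is_lnc = (truth_genes["biotype"] == "lncRNA").to_numpy(dtype=bool)
    eligible = np.flatnonzero(~is_module)
    lnc_eligible = np.flatnonzero(is_lnc & ~is_module)
    k = cfg.n_decoys_per_criterion
    decoys = rng.choice(lnc_eligible, size=min(3 * k, len(lnc_eligible)), replace=False)
    decoy_mantle, decoy_stage, decoy_damage = decoys[:k], decoys[k : 2 * k], decoys[2 * k :]
    mu[decoys] = np.exp(
        rng.uniform(np.log(max(lo, 50.0)), np.log(hi), len(decoys))
    )

    remaining = np.setdiff1d(eligible, decoys)
    n_flat = int(round(cfg.frac_flat_biased * n))
    n_round = int(round(cfg.frac_round_biased * n))
    picked = rng.choice(remaining, size=min(n_flat + n_round, len(remaining)), replace=False)
    flat_idx, round_idx = picked[:n_flat], picked[n_flat:]

    bias = np.zeros(n)
    bias[flat_idx] = cfg.bias_log2fc
    bias[round_idx] = -cfg.bias_log2fc
    bias[decoys] = cfg.bias_log2fc
    flat_mu = mu * 2.0 ** (bias / 2.0)
    round_mu = mu * 2.0 ** (-bias / 2.0)
    # Planted module genes: abundant in the flat valve, silent in the round
    flat_mu[is_module] = mu[is_module]
    round_mu[is_module] = mu[is_module] * 2.0 ** (-cfg.module_bias_log2fc)

    classes = truth_genes["bias_class"].to_numpy(dtype=object)
    classes[flat_idx] = "flat_biased"
    classes[round_idx] = "round_biased"
    classes[decoys] = "flat_biased"
    truth.genes.loc[gidx, "bias_class"] = classes
    for arr, col in (
        (decoy_mantle, "crit_mantle"),
        (decoy_stage, "crit_stage"),
        (decoy_damage, "crit_damage"),
    ):
        truth.genes.loc[gidx[arr], col] = True

    alpha = cfg.nb_dispersion
    sigma = cfg.library_size_sigma

    def build_panel(mean_cols: list[np.ndarray], metas: list[SampleMeta]) -> ExpressionPanel:
        lib = np.exp(rng.normal(0.0, sigma, len(metas)))
        counts = np.column_stack(
            [_nb_draw(rng, m * lf, alpha) for m, lf in zip(mean_cols, lib)]
        )
        df = pd.DataFrame(counts, index=gidx, columns=[s.sample_id for s in metas])
        return ExpressionPanel(df, metas, unit="counts")

    sp = sim.source
    # 1. two-valve mantle panel
    metas, means = [], []
    for valve, m in (("flat", flat_mu), ("round", round_mu)):
        for r in range(1, cfg.replicates + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"mantle_{valve}_r{r}", species=sp, valve=valve,
                    tissue="mantle", replicate=r,
                )
            )
            means.append(m)
    mantle_panel = build_panel(means, metas)

    # 2. multi-tissue panel (mantle criterion)
    crit_mantle = truth_genes["crit_mantle"].to_numpy(dtype=bool)
    crit_mantle[decoy_mantle] = True
    metas, means = [], []
    for tissue in cfg.tissues:
        factor = np.exp(rng.normal(0.0, 0.5, n))
        m = mu * factor
        if tissue == "mantle":
            m[crit_mantle] = mu[crit_mantle]
        else:
            m[crit_mantle] = mu[crit_mantle] / 16.0 * np.exp(
                rng.normal(0.0, 0.2, int(crit_mantle.sum()))
            )
        for r in range(1, cfg.tissue_replicates + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"tissue_{tissue}_r{r}", species=sp,
                    tissue=tissue, replicate=r,
                )
            )
            means.append(m)
    tissue_panel = build_panel(means, metas)

    # 3. larval-stage panel (asymmetric-stage criterion)
    crit_stage = truth_genes["crit_stage"].to_numpy(dtype=bool)
    crit_stage[decoy_stage] = True
    metas, means = [], []
    for stage in cfg.sym_stages + cfg.asym_stages:
        factor = np.exp(rng.normal(0.0, 0.5, n))
        m = mu * factor
        if stage in cfg.asym_stages:
            m[crit_stage] = mu[crit_stage]
        else:
            m[crit_stage] = mu[crit_stage] / 12.0 * np.exp(
                rng.normal(0.0, 0.2, int(crit_stage.sum()))
            )
        for r in range(1, cfg.stage_replicates + 1):
            metas.append(
                SampleMeta(
                    sample_id=f"stage_{stage}_r{r}", species=sp,
                    tissue="larva", stage=stage, replicate=r,
                )
            )
            means.append(m)
    stage_panel = build_panel(means, metas)

    # 4. damage-repair time course (damage criterion)
    crit_damage = truth_genes["crit_damage"].to_numpy(dtype=bool)
    crit_damage[decoy_damage] = True
    metas, means = [], []
    for tp in cfg.damage_timepoints:
        for cond in ("control", "damaged"):
            m = mu.copy()
            if cond == "damaged" and tp in cfg.damage_response_days:
                m[crit_damage] = mu[crit_damage] * cfg.damage_response_fold
            for r in range(1, cfg.damage_replicates + 1):
                metas.append(
                    SampleMeta(
                        sample_id=f"damage_d{tp:02d}_{cond}_r{r}", species=sp,
                        tissue="mantle", timepoint=tp, condition=cond,
                        replicate=r,
                    )
                )
                means.append(m)
    damage_panel = build_panel(means, metas)

    return {
        "mantle": mantle_panel,
        "tissue": tissue_panel,
        "stage": stage_panel,
        "damage": damage_panel,
    }


@dataclass
class SimulationResult:
    config: SimConfig
    genomes: SimulatedGenomes
    truth: TruthTable
    panels: dict[str, ExpressionPanel]


def simulate(cfg: SimConfig) -> SimulationResult:
    """Genomes + planted modules + expression panels in one call."""
    sim = simulate_genomes(cfg)
    sim, truth = plant_cis_modules(cfg, sim)
    panels = simulate_expression(cfg, sim, truth)
    return SimulationResult(config=cfg, genomes=sim, truth=truth, panels=panels)


# ---------------------------------------------------------------------------
# truth + run-directory I/O

_GENE_COLS = [
    "biotype", "bias_class", "is_module_gene", "module_id",
    "is_candidate_lnc", "crit_mantle", "crit_stage", "crit_damage",
]
_MODULE_COLS = ["lnc_source", "partners", "conserved_in", "lnc_by_species"]


def write_truth(truth: TruthTable, path) -> None:
    """Single-TSV lossless dump of the truth table (gene and module rows)."""
    rows = []
    for gid, r in truth.genes.iterrows():
        rows.append({"record_type": "gene", "id": gid, **{c: r[c] for c in _GENE_COLS}})
    for mid, r in truth.modules.iterrows():
        rows.append(
            {"record_type": "module", "id": mid, **{c: r[c] for c in _MODULE_COLS}}
        )
    cols = ["record_type", "id"] + _GENE_COLS + _MODULE_COLS
    df = pd.DataFrame(rows).reindex(columns=cols)
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    g = df[df["record_type"] == "gene"].set_index("id")[_GENE_COLS]
    for c in ("is_module_gene", "is_candidate_lnc", "crit_mantle", "crit_stage", "crit_damage"):
        g[c] = g[c].astype(str).str.lower() == "true"
    g.index.name = "gene_id"
    m = df[df["record_type"] == "module"].set_index("id")[_MODULE_COLS]
    m.index.name = "module_id"
    return TruthTable(genes=g, modules=m)


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_run(result: SimulationResult, outdir) -> None:
    """Write a full simulated run directory (GFF3 + FASTA + TSVs)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for sp, genome in result.genomes.genomes.items():
        write_gff3(genome.annotation(), os.path.join(outdir, f"{sp}.gff3"))
        write_fasta(genome.transcripts, os.path.join(outdir, f"{sp}.transcripts.fna"))
        if genome.proteins:
            write_fasta(genome.proteins, os.path.join(outdir, f"{sp}.proteins.faa"))
    for name, panel in result.panels.items():
        write_counts(
            panel,
            os.path.join(outdir, f"{name}.counts.tsv"),
            os.path.join(outdir, f"{name}.samples.tsv"),
        )
    write_truth(result.truth, os.path.join(outdir, "truth.tsv"))
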