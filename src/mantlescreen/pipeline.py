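"""End-to-end orchestration: simulate -> dge -> screen -> cismap -> synteny.

``run_all`` executes the full screening workflow on a simulated dataset
with planted truth and writes every stage's tables into a run directory;
each output TSV carries a provenance header (tool version, config hash,
seed) and a rerun with the same config and seed is byte-identical.
External (non-simulated) data enters through the per-stage functions or
CLI subcommands, which read the standard formats directly.
"""

from __future__ import annotations

import hashlib
import io
import os
import sys
from dataclasses import asdict, dataclass, field, replace

import pandas as pd
import yaml

from . import __version__
from .cismap import module_report, modules_table, pair_within_window
from .dge import classify_panel, de_table, fpkm
from .formats import FormatError
from .screen import (
    asym_stage_fraction_table,
    combine_candidacy,
    damage_response,
    mantle_fraction_table,
    verify_lncrna,
)
from .synteny import (
    SyntenyParams,
    all_vs_all_hits,
    anchors_table,
    block_links,
    blocks_table,
    call_anchors,
    chain_collinear,
    conserved_table,
    find_conserved_modules,
)
from .synthio import SimConfig, TruthTable, simulate, write_run

__all__ = ["RunConfig", "RunResult", "run_all", "report", "evaluate_run"]


@dataclass
class RunConfig:
    """All thresholds of the pipeline in one place (no hidden constants)."""

    seed: int = 0
    outdir: str = "run"
    # DE
    alpha: float = 0.05
    lfc_min: float = 1.0
    floor: float = 1.0
    # screening
    tau_mantle: float = 0.7
    tau_stage: float = 0.7
    candidacy_rule: str = "intersection"
    orf_max: int = 100
    # cis pairing
    window: int = 100_000
    flank: int = 50_000
    distance_mode: str = "edge"
    # synteny
    synteny: SyntenyParams = field(default_factory=SyntenyParams)
    id_min: float = 50.0
    len_min: int = 200
    # simulation
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = (
        "simulate", "dge", "screen", "cismap", "synteny", "report",
    )

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("tau_mantle", 0.0, 1.0),
            ("tau_stage", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise FormatError(f"{name} must lie strictly in ({lo}, {hi})")
        if self.window <= 0 or self.lfc_min < 0:
            raise FormatError("window must be > 0 and lfc_min >= 0")
        # the seed drives every stage through the simulation config
        self.sim = replace(self.sim, seed=self.seed)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "synteny" in d and isinstance(d["synteny"], dict):
            d["synteny"] = SyntenyParams(**d["synteny"])
        if "sim" in d and isinstance(d["sim"], dict):
            for key in ("nb_mean_log_range",):
                if key in d["sim"] and isinstance(d["sim"][key], list):
                    d["sim"][key] = tuple(d["sim"][key])
            for key, val in list(d["sim"].items()):
                if isinstance(val, list):
                    d["sim"][key] = tuple(val)
            d["sim"] = SimConfig(**d["sim"])
        if "stages" in d and isinstance(d["stages"], list):
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output paths excluded), so
        identical analyses give identical provenance headers wherever the
        run directory lives."""
        d = asdict(self)
        d.pop("outdir", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    simulation: object | None = None
    de: pd.DataFrame | None = None
    candidates: pd.DataFrame | None = None
    venn: dict | None = None
    modules: list | None = None
    conserved: pd.DataFrame | None = None
    blocks: dict | None = None


def _write_tsv(df: pd.DataFrame, path, cfg: RunConfig, index: bool) -> None:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"# mantlescreen {__version__}; config={cfg.config_hash()}; "
            f"seed={cfg.seed}\n"
        )
        fh.write(buf.getvalue())


def _log(msg: str, logfh=None) -> None:
    print(msg, file=sys.stderr)
    if logfh is not None:
        logfh.write(msg + "\n")


def run_all(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the enabled stages in order on a simulated dataset.

    With ``write=False`` no files are produced (useful for repeated
    evaluation runs); otherwise every table lands under ``cfg.outdir``.
    """
    result = RunResult(config=cfg)
    stages = set(cfg.stages)
    logfh = None
    if write:
        os.makedirs(cfg.outdir, exist_ok=True)
        with open(os.path.join(cfg.outdir, "config.yaml"), "w", newline="\n") as fh:
            fh.write(cfg.to_yaml())
        logfh = open(os.path.join(cfg.outdir, "run.log"), "w", newline="\n")
    try:
        if "simulate" not in stages:
            _log("no simulate stage enabled: nothing further to run "
                 "(use the per-stage commands for external data)", logfh)
            return result
        _log(f"[simulate] seed={cfg.seed}", logfh)
        sim = simulate(cfg.sim)
        result.simulation = sim
        src = sim.genomes.genomes[sim.genomes.source]
        if write:
            write_run(sim, os.path.join(cfg.outdir, "sim"))

        if "dge" not in stages:
            return result
        _log("[dge] flat vs round mantle", logfh)
        records = classify_panel(
            sim.panels["mantle"], floor=cfg.floor, alpha=cfg.alpha,
            lfc_min=cfg.lfc_min,
        )
        de = de_table(records)
        biotype = {g.gene_id: g.biotype for g in src.annotation()}
        de["biotype"] = [biotype[g] for g in de.index]
        result.de = de
        if write:
            _write_tsv(de, os.path.join(cfg.outdir, "de.tsv"), cfg, index=True)

        sig = de[de["bias_class"] != "ns"]
        de_lnc = sig[sig["biotype"] == "lncRNA"].index.tolist()
        de_coding = sig[sig["biotype"] == "coding"].index.tolist()
        _log(f"[dge] {len(sig)} DE genes ({len(de_lnc)} lncRNA, "
             f"{len(de_coding)} coding)", logfh)

        if "screen" in stages:
            _log("[screen] candidacy criteria", logfh)
            lengths = src.gene_lengths()
            tissue_fpkm = fpkm(sim.panels["tissue"], lengths)
            stage_fpkm = fpkm(sim.panels["stage"], lengths)
            mfrac = mantle_fraction_table(tissue_fpkm, tau=cfg.tau_mantle)
            sfrac = asym_stage_fraction_table(
                stage_fpkm, asym_stages=cfg.sim.asym_stages, tau=cfg.tau_stage
            )
            _, responsive = damage_response(
                sim.panels["damage"], alpha=cfg.alpha, lfc_min=cfg.lfc_min
            )
            verified = [
                g for g in de_lnc
                if verify_lncrna(g, src.transcripts[g], orf_max=cfg.orf_max).verdict
            ]
            criteria = pd.DataFrame(
                {
                    "mantle_fraction": mfrac.loc[verified, "fraction"],
                    "crit_mantle": mfrac.loc[verified, "passes"],
                    "asym_stage_fraction": sfrac.loc[verified, "fraction"],
                    "crit_stage": sfrac.loc[verified, "passes"],
                    "crit_damage": responsive.loc[verified],
                }
            )
            cands, venn = combine_candidacy(criteria, rule=cfg.candidacy_rule)
            cand_df = pd.DataFrame(
                {
                    "gene_id": [c.gene_id for c in cands],
                    "mantle_fraction": [c.mantle_fraction for c in cands],
                    "asym_stage_fraction": [c.asym_stage_fraction for c in cands],
                    "crit_mantle": ["mantle" in c.criteria_set for c in cands],
                    "crit_stage": ["stage" in c.criteria_set for c in cands],
                    "crit_damage": ["damage" in c.criteria_set for c in cands],
                    "is_candidate": [c.is_candidate for c in cands],
                }
            ).set_index("gene_id")
            result.candidates = cand_df
            result.venn = venn
            if write:
                _write_tsv(
                    cand_df, os.path.join(cfg.outdir, "candidates.tsv"), cfg, True
                )
                venn_df = pd.DataFrame(
                    {"region": list(venn), "count": list(venn.values())}
                )
                _write_tsv(venn_df, os.path.join(cfg.outdir, "venn.tsv"), cfg, False)
            _log(f"[screen] {int(cand_df['is_candidate'].sum())} candidate "
                 f"lncRNAs of {len(cand_df)} screened", logfh)

        if "cismap" not in stages:
            return result
        _log(f"[cismap] window={cfg.window} bp", logfh)
        gene_by_id = {g.gene_id: g for g in src.annotation()}
        modules = pair_within_window(
            [gene_by_id[g] for g in de_lnc],
            [gene_by_id[g] for g in de_coding],
            window=cfg.window,
            mode=cfg.distance_mode,
        )
        result.modules = modules
        if write:
            _write_tsv(
                modules_table(modules),
                os.path.join(cfg.outdir, "modules.tsv"), cfg, False,
            )
            rep = module_report(
                modules, src.annotation(),
                de_status=dict(de["bias_class"]),
                flank=cfg.flank,
                bed_path=os.path.join(cfg.outdir, "modules.bed"),
            )
            _write_tsv(
                rep, os.path.join(cfg.outdir, "module_report.tsv"), cfg, False
            )
        _log(f"[cismap] {len(modules)} cis modules", logfh)

        if "synteny" not in stages:
            return result
        conserved_frames = []
        result.blocks = {}
        targets = [s for s in sim.genomes.genomes if s != sim.genomes.source]
        for sp in targets:
            tgt = sim.genomes.genomes[sp]
            _log(f"[synteny] {sim.genomes.source} vs {sp}", logfh)
            hits = all_vs_all_hits(src.proteins, tgt.proteins)
            anchors = call_anchors(
                hits, src.annotation(), tgt.annotation(), cfg.synteny
            )
            blocks = chain_collinear(anchors, cfg.synteny)
            result.blocks[sp] = blocks
            conserved = find_conserved_modules(
                modules, blocks, sp, tgt.annotation(), tgt.transcripts,
                src.transcripts, anchors=anchors, window=cfg.window,
                id_min=cfg.id_min, len_min=cfg.len_min, orf_max=cfg.orf_max,
            )
            conserved_frames.append(conserved_table(conserved))
            if write:
                _write_tsv(
                    anchors_table(anchors),
                    os.path.join(cfg.outdir, f"anchors_{sp}.tsv"), cfg, False,
                )
                _write_tsv(
                    blocks_table(blocks),
                    os.path.join(cfg.outdir, f"blocks_{sp}.tsv"), cfg, False,
                )
                _write_tsv(
                    block_links(blocks),
                    os.path.join(cfg.outdir, f"links_{sp}.tsv"), cfg, False,
                )
            _log(f"[synteny] {len(anchors)} anchors, {len(blocks)} blocks", logfh)
        conserved_df = (
            pd.concat(conserved_frames, ignore_index=True)
            if conserved_frames
            else pd.DataFrame()
        )
        result.conserved = conserved_df
        if write:
            _write_tsv(
                conserved_df, os.path.join(cfg.outdir, "conserved.tsv"), cfg, False
            )
        n_cons = int((conserved_df["status"] == "conserved").sum()) if len(conserved_df) else 0
        _log(f"[synteny] {n_cons} conserved module calls", logfh)

        if "report" in stages and write:
            text = report(cfg.outdir)
            with open(os.path.join(cfg.outdir, "summary.txt"), "w", newline="\n") as fh:
                fh.write(text)
        return result
    finally:
        if logfh is not None:
            logfh.close()


def report(run_dir: str) -> str:
    """Human-readable summary of a run directory's stage outputs."""
    lines = [f"mantlescreen {__version__} run summary", ""]

    def load(name: str, **kw):
        path = os.path.join(run_dir, name)
        if not os.path.exists(path):
            lines.append(f"[{name}] missing -- section skipped")
            return None
        return pd.read_csv(path, sep="\t", comment="#", **kw)

    de = load("de.tsv")
    if de is not None:
        lines.append("Valve-bias classes (flat vs round mantle):")
        counts = de["bias_class"].value_counts()
        for cls in ("flat_specific", "flat_biased", "round_specific",
                    "round_biased", "ns"):
            lines.append(f"  {cls:16s} {int(counts.get(cls, 0))}")
        lines.append("")
    venn = load("venn.tsv")
    if venn is not None:
        lines.append("Candidate-lncRNA criteria Venn (exclusive regions):")
        for _, r in venn.iterrows():
            lines.append(f"  {r['region']:22s} {int(r['count'])}")
        lines.append("")
    cands = load("candidates.tsv")
    if cands is not None:
        n = int(cands["is_candidate"].sum())
        lines.append(f"Candidate lncRNAs: {n} of {len(cands)} screened")
        lines.append("")
    mods = load("modules.tsv")
    if mods is not None:
        n_mod = mods["module"].nunique() if len(mods) else 0
        lines.append(f"cis modules: {n_mod} (lncRNA-partner pairs: {len(mods)})")
        lines.append("")
    cons = load("conserved.tsv")
    if cons is not None and len(cons):
        lines.append("Module conservation calls:")
        tab = cons.groupby(["target_species", "status"]).size()
        for (sp, status), cnt in tab.items():
            lines.append(f"  {sp:8s} {status:22s} {int(cnt)}")
        lines.append("")
    return "\n".join(lines) + "\n"


def evaluate_run(result: RunResult, truth: TruthTable) -> dict:
    """Score a run against the planted truth.

    Returns DE sensitivity/FDR over planted valve-biased genes, candidate
    recovery, and conserved-module sensitivity plus false-conserved count.
    """
    out: dict = {}
    if result.de is not None:
        de = result.de
        truth_bias = truth.genes["bias_class"].reindex(de.index).fillna("ns")
        true_pos = truth_bias != "ns"
        called = de["bias_class"] != "ns"
        tp = int((true_pos & called).sum())
        fp = int((~true_pos & called).sum())
        out["de_sensitivity"] = tp / max(int(true_pos.sum()), 1)
        out["de_fdr"] = fp / max(tp + fp, 1)
        out["de_called"] = int(called.sum())
    if result.candidates is not None:
        cand = result.candidates
        truth_cand = truth.genes.index[truth.genes["is_candidate_lnc"]]
        reported = set(cand.index[cand["is_candidate"]])
        out["candidate_sensitivity"] = (
            len(reported & set(truth_cand)) / max(len(truth_cand), 1)
        )
        out["candidate_false"] = len(reported - set(truth_cand))
    if result.conserved is not None and len(result.conserved):
        truth_pairs = set()
        for _, r in truth.modules.iterrows():
            for sp in str(r["conserved_in"]).split(";"):
                if sp:
                    truth_pairs.add((r["lnc_source"], sp))
        cons = result.conserved
        reported_pairs = {
            (r["lncRNA"], r["target_species"])
            for _, r in cons[cons["status"] == "conserved"].iterrows()
        }
        hit = len(reported_pairs & truth_pairs)
        out["conserved_truth_pairs"] = len(truth_pairs)
        out["conserved_recovered"] = hit
        out["conserved_sensitivity"] = hit / max(len(truth_pairs), 1)
        out["conserved_false"] = len(reported_pairs - truth_pairs)
    elif result.conserved is not None:
        out["conserved_truth_pairs"] = 0
        out["conserved_recovered"] = 0
        out["conserved_sensitivity"] = float("nan")
        out["conserved_false"] = 0
    return out
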