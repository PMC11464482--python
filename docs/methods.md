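# Methods

This note documents the models, parameter choices and numerical decisions
behind `mantlescreen`, in the spirit of a statistical methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression (dge)

Counts are modelled as negative binomial with variance `μ + αμ²`.
Normalization uses median-of-ratios size factors: `factor_s = median_g
(count_gs / geomean_g)` over genes with all-positive counts; if no such
gene exists the computation refuses rather than silently switching to a
pseudo-reference.

The two-group test is a Wald test on the log₂ fold change of normalized
group means (pseudo-count 0.5). The gene-wise dispersion is the method-of-
moments estimate `α̂_g = max(0, (s² − μ)/μ²)` from the pooled within-group
variance, shrunk toward the across-gene mean with weight 0.5. This
moderation matters: at n = 3 per group the raw moment estimate is
extremely noisy, and the shrinkage trades a small bias for a large
variance reduction. The Wald standard error comes from the delta method
under the NB variance model; p-values use the standard normal reference.
A t reference with n₁+n₂−2 degrees of freedom was considered and
rejected: at 3 vs 3 it destroys power (no p can fall below ≈ 8e−3, so
BH across thousands of genes can never call anything) while making the
null distribution *less* uniform, not more. The residual cost of the
normal reference is a mildly anti-conservative raw p at n = 3 (null
fraction p < 0.05 around 0.07); BH adjustment keeps the realized
false-discovery proportion near the nominal target, which the acceptance
checks measure directly.

Degenerate inputs: a gene with zero counts everywhere gets p = 1 and
log2fc = 0. Groups with fewer than 2 replicates are errors.

Bias classes partition tested genes: `ns` unless `padj < α` (0.05) and
`|log2fc| ≥ lfc_min` (1); the side is flat when log2fc > 0 (flat is
always the reference orientation, matching the flat-valve/right-valve
assignment); `*_specific` when the opposite valve's normalized mean falls
below `floor` (1 normalized count), `*_biased` otherwise. All three
thresholds are surfaced in `RunConfig`; the defaults are conventional DEG
practice.

FPKM is `count · 10⁹ / (length · library_size)` with the annotated gene
span as length (the simulated genes are intronless).

## Candidate lncRNA screening (screen)

Non-coding verification requires length > 200 nt, longest ATG→stop ORF
(both strands, three frames, stop required in-sequence) below 100 codons,
and no protein-domain hit. The 100-codon ORF ceiling and the domain-hit
veto are standard operational criteria; both are configurable.

The mantle criterion is the mantle's share of the sum of *per-tissue mean*
FPKM (> 0.7). Each tissue contributes its mean once, so unequal replicate
counts cannot tilt the denominator; a gene silent in every tissue has an
undefined fraction and fails with a flag. The stage criterion is the same
construction over larval stages, with the post-metamorphosis stages
(pediveliger, spat, juvenile — the stages spanning the symmetric-to-
asymmetric shell transition) as numerator; the stage-to-group mapping is
user configuration. The damage criterion runs the NB Wald test damaged vs
control separately per timepoint (BH across genes within a timepoint) and
fires when any timepoint is significant at the DE thresholds; timepoints
lacking two replicates of either arm are skipped with a warning.

Candidacy defaults to the intersection of all three criteria; `union` and
`threshold` modes exist. The seven-region Venn partition is reported so
single- and double-criterion genes remain visible.

Motif enrichment tests gapped patterns of fixed width 8 with the first and
last residue anchored, at least 3 anchored residues in total and `X`
wildcards elsewhere (the `LGXXGXXG` family). Patterns are enumerated from
the windows actually present in the data, a protein counts once however
often it matches, and patterns seen in fewer than 2 proteins overall are
not tested — the tested family is therefore "patterns observed in these
proteins", which is what BH corrects across. Significance is a two-sided
Fisher exact test; an exhaustive-hypergeometric oracle check covers all
margins up to 20 in the test suite.

## Cis-module detection (cismap)

Distance is the gap between closest gene-span edges (0 when spans
overlap), the weakest reading of "within 100 kb up- or downstream"; a
TSS-to-TSS mode is provided. The boundary is inclusive: a gap of exactly
100,000 bp pairs, 100,001 does not. Strand is recorded but never filters
a pair, and a coding gene may belong to several modules. Signed distance
is negative when the coding gene lies 5′ of the lncRNA on the + axis.

## Collinearity and conservation (synteny)

Anchors are reciprocal best hits: best = maximum bitscore, ties broken by
identity then lexicographic subject id; hits must clear e < 1e−5. When
no precomputed tabular hits are supplied, internal alignments are used:
Smith–Waterman, BLOSUM62, affine gaps (open 11, extend 1, NCBI
convention), with a shared-5-mer prefilter (≥ 2 distinct exact 5-mers)
so only plausible pairs are aligned — the same seed-and-extend shortcut
fast aligners use. The e-value proxy is the ungapped Karlin–Altschul
formula `K·m·n·e^(−λS)` with K = 0.041, λ = 0.267; identities for
reported hits come from the global edit distance, which is exact for the
substitution-only divergence of close orthologues. Real aligner output,
when supplied, is used verbatim.

Chaining is over gene ranks (0-based order per chromosome). Adding an
anchor to a chain contributes k = 50 and pays 1 per skipped rank on
either genome; per-step gaps are capped at m = 20 on both sides and
chains need s = 5 anchors to be reported. These parameter *semantics*
(s = minimum anchors, k = per-anchor score, m = maximum rank gap) are a
declared reading of the classical collinearity-chaining parameter set;
the original tool's exact scoring is not reproduced. Maximum-score chains
are found by O(n²) dynamic programming per chromosome pair and
orientation; disjoint blocks are extracted greedily, best score first,
with deterministic tie-breaks. A brute-force enumeration oracle verifies
score and membership on all small instances in the tests.

A module is conserved in a target genome when (1) a partner coding gene
has an anchor inside a collinear block, and (2) some lncRNA-annotated
locus within the pairing window of that orthologue aligns to the source
lncRNA (blastn-like scoring: match +2, mismatch −3, gap open 5 extend 2)
at ≥ 50 % identity over ≥ 200 aligned columns and itself passes the
non-coding checks. Failures carry reason codes (`no_anchor`,
`not_in_block`, `no_lncRNA_orthologue`). The 50 %/200 nt thresholds are
explicit stand-ins — no published cutoff exists for lncRNA orthologue
calls — and are configurable.

## Damage-repair statistics (repairstats)

Holes within one animal-valve are pseudo-replicates: ratios are averaged
per animal first, and treatment summaries are computed over animals (the
independent unit). Per-hole ratios are clipped to [0, 1] (overgrowth
counts as closed); "covered" defaults to full closure. The z-test is the
pooled two-proportion form; it refuses when the pooled proportion is 0 or
1. Student's t is pooled-variance by default (Welch by flag) with exact
handling of the zero-variance degenerate cases. The Pearson correlation
requires n ≥ 3 pairs and non-zero variance. A note on the assay's
published z statistic: the printed value is not reproducible from any
printed sample size with a standard two-proportion or two-mean z formula,
so the package implements the standard pooled test and the worked example
uses covered-hole counts (43/54 vs 7/54 → z ≈ 6.95) as its oracle.

## Synthetic data (synthio)

The generator defines the study conditions the acceptance checks run
under; its defaults are fixed and not tuned per run.

**Genomes.** An ancestral genome of 5 chromosomes × 400 genes (10 %
lncRNA) is laid out with exponential intergenic gaps (mean 8 kb), coding
genes 0.5–3 kb, lncRNAs 0.4–1.5 kb. Each derived species applies
alternating inversions (10–50 genes) and translocations (5–20 genes) —
2 rearrangements by default — then loses 5 % of genes at random.
Orthologous proteins (random 100–400 aa) diverge by i.i.d. substitutions
at 10 % of sites, so orthologues share ≈ 90 % identity and are trivially
RBH-detectable while random pairs are not. Coding and planted-lncRNA
transcripts diverge at 10 % likewise. Background lncRNA transcripts are
redrawn independently per species: lncRNA sequence conservation is the
exception in real genomes, and complete turnover makes the truth table's
negative conservation labels exact by construction instead of
probabilistic. lncRNA transcripts carry stop-codon cassettes every 120 nt
covering all six frames, so they verifiably stay non-coding even after
divergence.

**Modules.** Each planted module inserts a new lncRNA gene 2–20 kb from
a coding anchor gene (second partner included when it stays within the
50 kb module span, which is kept below the 100 kb pairing window).
Planting sites require an intact, contiguous, collinear 15-gene
neighbourhood in every species the module is conserved in, and sites are
≥ 40 gene positions apart — every planted conserved module is therefore
detectable by construction, and misses measure pipeline loss, not
generator artefacts. Conserved modules copy the lncRNA (10 % diverged)
next to the anchor's orthologue in the chosen targets; species-specific
modules exist only in the source.

**Expression.** Gene means are log-uniform on [10, 1000]; module genes
redraw from [50, 1000] (candidate biomineralization genes are abundant
mantle transcripts). One global dispersion α = 0.1; per-sample library
factors are log-normal(0, 0.2) to exercise normalization. Background
valve bias: 5 % of genes flat-biased and 2 % round-biased at log₂FC 2
(split symmetrically across valves); module genes are flat-specific at
log₂FC 4 with means in the abundant range — the side-specific, abundant
profile of shell-matrix genes. Planted candidates put ≥ 80 % of tissue
expression in mantle (others at mean/16), ≥ 80 % of stage expression
post-metamorphosis (symmetric stages at mean/12), and a 4-fold damage
induction at days 3 and 7 of the 0/1/3/7/14/21-day course. Six decoy
lncRNAs (two per criterion) satisfy exactly one criterion each, so the
Venn regions and the intersection rule are genuinely exercised. Panels:
3 replicates per valve (mantle), 5 tissues × 3, 6 stages × 3, and
6 timepoints × {control, damaged} × 3.

**What the generator does not emulate.** Real read alignment and counting
(counts are drawn directly), intron structure and codon usage, paralogy
and gene families (orthology is one-to-one by construction), dispersion
trends over mean (α is global), correlated samples, and partial lncRNA
conservation (background lncRNAs share no ancestry across species, so
borderline 40–60 % identity orthologues never occur). Passing tests
therefore demonstrate the screening logic under its stated noise model,
not performance on real libraries — in particular the conservation
search is easier here than in real genomes, where lncRNA orthology is
genuinely ambiguous.

**Determinism.** All randomness flows from one integer seed through
separate spawned streams for genomes, planting and expression; identical
config + seed reproduces byte-identical run directories (the provenance
hash covers the scientific parameters, not output paths).

## Problem sizes

The acceptance checks use the full default conditions: 20 seeded
end-to-end runs (3 species × 2,012 genes each) for module recovery;
8 × 2,000-gene null panels and 5 planted datasets for DE calibration;
200 random instances of ≤ 12 anchors against the exhaustive chaining
oracle; the complete margin grid ≤ 20 for the Fisher/hypergeometric
check. These sizes were chosen so the whole suite completes in well under
half an hour on a single core while keeping every binomial error bar
small relative to the thresholds being asserted.

## Known limitations

- The NB Wald test is slightly anti-conservative in raw p at n = 3; BH
  keeps realized FDR near nominal, but single-gene p-values near the
  threshold should not be over-read.
- `run_all` orchestrates simulated runs; external datasets enter through
  the per-stage functions and CLI subcommands rather than the end-to-end
  runner.
- The motif scan tests observed patterns of one fixed width with
  first/last anchoring; it is a screening device, not a substitute for a
  dedicated fuzzy-motif discovery tool.
- Conservation calls depend on annotated lncRNA loci in the target
  genome; unannotated orthologous loci are invisible to the search.
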