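"""Shared genomic types and I/O for the standard formats the pipeline touches.

Coordinate conventions: gene models are stored 1-based inclusive (GFF3
convention); BED output is 0-based half-open. Gene *rank* is the 0-based
order index of a gene along its chromosome, assigned by ascending start
(ties broken by end, then gene id); collinearity chaining operates on ranks,
not base pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GeneModel",
    "SampleMeta",
    "ExpressionPanel",
    "HitRecord",
    "FormatError",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_tabular_hits",
    "write_tabular_hits",
    "assign_ranks",
]

BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
}

VALID_VALVES = {"flat", "round", "none"}
VALID_CONDITIONS = {"control", "damaged", "none"}


class FormatError(ValueError):
    """Raised for malformed input files or invariant violations."""


@dataclass(frozen=True)
class GeneModel:
    """A located gene: 1-based inclusive span plus biotype and rank."""

    gene_id: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # inclusive
    strand: str  # '+' or '-'
    biotype: str  # 'coding' or 'lncRNA'
    rank: int = -1  # 0-based order index along the chromosome
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in {"coding", "lncRNA"}:
            raise FormatError(f"gene {self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata for an expression panel."""

    sample_id: str
    species: str = "unknown"
    valve: str = "none"  # flat | round | none
    tissue: str = "none"
    stage: str = "none"
    timepoint: int | None = None  # days, for damage-repair time courses
    condition: str = "none"  # control | damaged | none
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.valve not in VALID_VALVES:
            raise FormatError(f"sample {self.sample_id}: bad valve {self.valve!r}")
        if self.condition not in VALID_CONDITIONS:
            raise FormatError(
                f"sample {self.sample_id}: bad condition {self.condition!r}"
            )


class ExpressionPanel:
    """A genes x samples matrix of raw counts or FPKM with sample metadata.

    Thin wrapper around a pandas DataFrame (rows = genes, columns =
    sample ids) keeping sample metadata aligned with the columns.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleMeta],
        unit: str = "counts",
    ) -> None:
        if unit not in {"counts", "FPKM"}:
            raise FormatError(f"bad unit {unit!r}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in metadata")
        if list(values.columns) != ids:
            raise FormatError("sample metadata does not match matrix columns")
        arr = values.to_numpy()
        if (arr < 0).any():
            raise FormatError("negative expression values")
        if unit == "counts" and not (arr == arr.astype(int)).all():
            raise FormatError("counts must be integers")
        self.values = values
        self.samples = list(samples)
        self.unit = unit

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionPanel":
        keep = set(sample_ids)
        metas = [s for s in self.samples if s.sample_id in keep]
        ids = [s.sample_id for s in metas]
        return ExpressionPanel(self.values[ids], metas, unit=self.unit)

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all given metadata field values.

        A criterion value may be a scalar or a collection of admissible
        values, e.g. ``select(valve="flat")`` or ``select(tissue={"gill",
        "muscle"})``.
        """
        out = []
        for s in self.samples:
            ok = True
            for key, want in criteria.items():
                have = getattr(s, key)
                if isinstance(want, (set, frozenset, list, tuple)):
                    ok = have in want
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(s.sample_id)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionPanel({len(self.genes)} genes x "
            f"{len(self.samples)} samples, unit={self.unit})"
        )


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein (or nucleotide) hit, blast-tabular style."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}/{self.subject_id}: evalue < 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: identity outside [0,100]"
            )


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Assign per-chromosome 0-based ranks by (start, end, gene_id).

    Returns a new list sorted by (chrom, start, end, gene_id).
    """
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    out: list[GeneModel] = []
    counter: dict[str, int] = {}
    for g in ordered:
        r = counter.get(g.chrom, 0)
        counter[g.chrom] = r + 1
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                strand=g.strand,
                biotype=g.biotype,
                rank=r,
                product=g.product,
            )
        )
    return out


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed attribute {part!r}")
        key, _, val = part.partition("=")
        attrs[key.strip()] = val.strip()
    return attrs


def read_gff3(path, biotype_key: str = "gene_biotype") -> list[GeneModel]:
    """Parse gene features from a GFF3 file into ranked GeneModels.

    Only ``gene`` features are consumed (mRNA/exon children are ignored).
    Biotype is read from ``biotype_key`` in column 9 and mapped through
    {protein_coding -> coding, lncRNA -> lncRNA}; unknown biotypes are
    rejected. Ranks are assigned per chromosome by ascending start.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gff3_attributes(attr_s)
            if "ID" not in attrs:
                raise FormatError(f"{path}: line {lineno}: gene feature lacks ID")
            gid = attrs["ID"]
            if gid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            raw_bt = attrs.get(biotype_key)
            if raw_bt is None:
                raise FormatError(
                    f"{path}: line {lineno}: gene {gid!r} lacks attribute "
                    f"{biotype_key!r}"
                )
            if raw_bt not in BIOTYPE_MAP:
                raise FormatError(
                    f"{path}: line {lineno}: unknown biotype {raw_bt!r} for {gid!r}"
                )
            try:
                genes.append(
                    GeneModel(
                        gene_id=gid,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        biotype=BIOTYPE_MAP[raw_bt],
                        product=attrs.get("product"),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return assign_ranks(genes)


def write_gff3(genes: Sequence[GeneModel], path, biotype_key: str = "gene_biotype") -> None:
    """Write gene features as GFF3 (inverse of read_gff3 for gene lines)."""
    inverse_bt = {"coding": "protein_coding", "lncRNA": "lncRNA"}
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            attrs = f"ID={g.gene_id};{biotype_key}={inverse_bt[g.biotype]}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.chrom}\tmantlescreen\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_bed(features: Sequence, path) -> None:
    """Write BED6 (0-based half-open): bedStart = start - 1, bedEnd = end.

    Accepts any objects carrying chrom/start/end (GeneModel or module
    spans); name is taken from ``gene_id`` or ``name``, strand from
    ``strand`` if present.
    """
    with open(path, "w", newline="\n") as fh:
        for f in features:
            name = getattr(f, "gene_id", None) or getattr(f, "name", ".")
            strand = getattr(f, "strand", ".")
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{name}\t0\t{strand}\n"
            )


def read_counts(counts_path, meta_path, unit: str = "counts") -> ExpressionPanel:
    """Read a genes x samples TSV plus a sample-metadata TSV into a panel.

    The metadata table must contain every sample column of the count
    matrix, keyed by ``sample_id``.
    """
    mat = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in mat.columns:
        if not pd.api.types.is_numeric_dtype(mat[col]):
            raise FormatError(f"{counts_path}: non-numeric values in column {col!r}")
    if (mat.to_numpy() < 0).any():
        raise FormatError(f"{counts_path}: negative counts")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise FormatError(f"{meta_path}: missing sample_id column")
    meta = meta.set_index("sample_id", drop=False)
    samples = []
    for sid in mat.columns:
        if sid not in meta.index:
            raise FormatError(f"sample {sid!r} in counts missing from metadata")
        row = meta.loc[sid]
        tp = row.get("timepoint")
        timepoint = None if tp is None or pd.isna(tp) else int(tp)
        samples.append(
            SampleMeta(
                sample_id=sid,
                species=str(row.get("species", "unknown")),
                valve=str(row.get("valve", "none")),
                tissue=str(row.get("tissue", "none")),
                stage=str(row.get("stage", "none")),
                timepoint=timepoint,
                condition=str(row.get("condition", "none")),
                replicate=int(row.get("replicate", 1)),
            )
        )
    return ExpressionPanel(mat, samples, unit=unit)


def write_counts(panel: ExpressionPanel, counts_path, meta_path) -> None:
    """Write a panel back to counts + metadata TSVs (lossless round trip)."""
    mat = panel.values.copy()
    if panel.unit == "counts":
        mat = mat.astype(int)
    with open(counts_path, "w", newline="\n") as fh:
        mat.to_csv(fh, sep="\t", index_label="gene_id")
    rows = []
    for s in panel.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "valve": s.valve,
                "tissue": s.tissue,
                "stage": s.stage,
                "timepoint": "" if s.timepoint is None else s.timepoint,
                "condition": s.condition,
                "replicate": s.replicate,
            }
        )
    with open(meta_path, "w", newline="\n") as fh:
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_tabular_hits(path) -> list[HitRecord]:
    """Parse a 12-column blast-tabular (outfmt 6 dialect) hit file.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore. No filtering is applied.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Sequence[HitRecord], path) -> None:
    """Write hits in the 12-column tabular dialect (unused fields zeroed)."""
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t0\t0\t0\t0\t{h.evalue:.3g}\t"
                f"{h.bitscore:.1f}\n"
            )
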