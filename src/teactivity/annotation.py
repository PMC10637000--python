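"""Genome annotation handling: TE integrants, gene models, promoters and windows.

All coordinates are 0-based, half-open throughout the package. BED input is
taken verbatim; GTF and RepeatMasker ``.out`` coordinates (1-based, inclusive)
are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "TEIntegrant",
    "GeneModel",
    "read_te_bed",
    "write_te_bed",
    "read_bed_intervals",
    "read_repeatmasker_out",
    "merge_fragments",
    "build_promoters",
    "build_windows",
    "build_gene_models",
    "read_gene_table",
    "write_gene_table",
    "union_intervals",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        """Integer center coordinate, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of overlap on the same chromosome (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TEIntegrant:
    """A single annotated TE copy (possibly a fragment before merging)."""

    interval: GenomicInterval
    subfamily: str
    instance_id: str

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily label must be non-empty")


@dataclass
class GeneModel:
    """A protein-coding gene reduced to what the susceptibility model needs.

    ``promoters`` are clusters of TSS spaced < 1 kb, padded by 500 bp on each
    side and stored as a disjoint union. ``exon_union`` is the disjoint union
    of exons across all transcripts.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: list[int]
    promoters: list[GenomicInterval] = field(default_factory=list)
    exon_union: list[GenomicInterval] = field(default_factory=list)

    @property
    def exon_length(self) -> int:
        """Total exon-union length, used as the gene length for TPM."""
        return sum(iv.length for iv in self.exon_union)

    def cis_windows(self, flank: int = 50_000) -> list[GenomicInterval]:
        """Hard-threshold cis-regulatory windows: promoters ± ``flank``."""
        return build_windows(self.promoters, flank)


# ---------------------------------------------------------------------------
# interval arithmetic


def union_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Disjoint union of intervals; abutting or overlapping intervals merge."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur = ivs[0]
    for iv in ivs[1:]:
        if iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end, cur.strand)
        else:
            out.append(cur)
            cur = iv
    out.append(cur)
    return out


def merge_fragments(
    tes: Iterable[TEIntegrant], max_gap: int = 100
) -> list[TEIntegrant]:
    """Re-fuse fragmented integrants of one subfamily and strand.

    Within each (chromosome, strand, subfamily) group, intervals whose gap
    ``next.start - prev.end`` is strictly less than ``max_gap`` are chained
    into one integrant spanning the whole run. Idempotent and insensitive to
    input order; output sorted by (chrom, start).
    """
    groups: dict[tuple[str, str, str], list[TEIntegrant]] = {}
    for te in tes:
        key = (te.interval.chrom, te.interval.strand, te.subfamily)
        groups.setdefault(key, []).append(te)

    merged: list[TEIntegrant] = []
    for (chrom, strand, subfam), members in groups.items():
        members.sort(key=lambda t: (t.interval.start, t.interval.end))
        run = [members[0]]
        for te in members[1:]:
            prev_end = max(t.interval.end for t in run)
            if te.interval.start - prev_end < max_gap:
                run.append(te)
            else:
                merged.append(_fuse(run, chrom, strand, subfam))
                run = [te]
        merged.append(_fuse(run, chrom, strand, subfam))
    merged.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return merged


def _fuse(run: list[TEIntegrant], chrom: str, strand: str, subfam: str) -> TEIntegrant:
    if len(run) == 1:
        return run[0]
    start = min(t.interval.start for t in run)
    end = max(t.interval.end for t in run)
    instance = ",".join(t.instance_id for t in run)
    return TEIntegrant(GenomicInterval(chrom, start, end, strand), subfam, instance)


def build_promoters(
    tss: Sequence[int],
    chrom: str,
    cluster_gap: int = 1000,
    pad: int = 500,
) -> list[GenomicInterval]:
    """Cluster TSS spaced < ``cluster_gap`` and pad each cluster by ``pad``.

    Single-linkage chaining with a strict inequality; each cluster becomes
    ``[min_tss - pad, max_tss + pad)`` clipped at zero, and overlapping or
    abutting padded clusters are stored as their union.
    """
    if not tss:
        raise ValueError("at least one TSS is required")
    positions = sorted(tss)
    clusters: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] < cluster_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    padded = [
        GenomicInterval(chrom, max(c[0] - pad, 0), c[-1] + pad) for c in clusters
    ]
    return union_intervals(padded)


def build_windows(
    promoters: Sequence[GenomicInterval], flank: int = 50_000
) -> list[GenomicInterval]:
    """Extend each promoter by ``flank`` on both sides; union; clip at 0."""
    if not promoters:
        raise ValueError("at least one promoter is required")
    extended = [
        GenomicInterval(p.chrom, max(p.start - flank, 0), p.end + flank)
        for p in promoters
    ]
    return union_intervals(extended)


# ---------------------------------------------------------------------------
# readers / writers


def read_te_bed(path: str | Path) -> list[TEIntegrant]:
    """Read TE integrants from BED6.

    Column 4 holds the subfamily label, optionally ``subfamily|instance_id``.
    Coordinates are taken verbatim (BED is already 0-based half-open).
    """
    tes: list[TEIntegrant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if "|" in name:
                subfam, instance = name.split("|", 1)
            else:
                subfam, instance = name, f"{name}:{chrom}:{start_s}"
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            tes.append(TEIntegrant(iv, subfam, instance))
    return tes


def write_te_bed(tes: Iterable[TEIntegrant], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            name = f"{te.subfamily}|{te.instance_id}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (BED3+; e.g. functional ranges or TADs)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_repeatmasker_out(path: str | Path) -> list[TEIntegrant]:
    """Read a RepeatMasker ``.out`` table.

    The standard layout has two header lines and a blank line; coordinates are
    1-based inclusive and strand ``C`` denotes the minus strand. Both are
    converted on read. The repeat-name column provides the subfamily.
    """
    tes: list[TEIntegrant] = []
    with open(path) as fh:
        lines = fh.readlines()
    body = [
        (i + 1, ln)
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().lower().startswith(("sw", "score"))
    ]
    if not body:
        return []
    for lineno, line in body:
        fields = line.split()
        if len(fields) < 10:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker record")
        try:
            chrom = fields[4]
            begin, end = int(fields[5]), int(fields[6])
            strand = "-" if fields[8] in {"C", "-"} else "+"
            name = fields[9]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: unparsable record") from exc
        try:
            iv = GenomicInterval(chrom, begin - 1, end, strand)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        tes.append(TEIntegrant(iv, name, f"{name}:{chrom}:{begin - 1}"))
    return tes


def build_gene_models(gtf_path: str | Path) -> list[GeneModel]:
    """Build gene models from a GTF with gene/transcript/exon features.

    TSS are strand-aware transcript starts. When the GTF carries gene
    biotypes, genes that are not protein-coding are dropped; otherwise all
    genes are kept with a warning. Genes with no transcript are skipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    has_biotype = False
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["gene_id"][0]
        biotype = gene.attributes.get("gene_biotype") or gene.attributes.get(
            "gene_type"
        )
        if biotype is not None:
            has_biotype = True
            if biotype[0] != "protein_coding":
                continue
        strand = gene.strand
        if strand not in {"+", "-"}:
            warnings.warn(f"gene {gene_id}: unknown strand, treating as '+'")
            strand = "+"
        transcripts = list(
            db.children(gene, featuretype=("transcript", "mRNA"), order_by="start")
        )
        if not transcripts:
            warnings.warn(f"gene {gene_id}: no transcript, skipped")
            continue
        tss = sorted(
            {(t.start - 1) if strand == "+" else t.end for t in transcripts}
        )
        exons = [
            GenomicInterval(gene.seqid, e.start - 1, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=strand,
                tss=tss,
                promoters=build_promoters(tss, gene.seqid),
                exon_union=union_intervals(exons),
            )
        )
    if models and not has_biotype:
        warnings.warn("GTF carries no gene biotypes; keeping all genes")
    return models


_GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exons"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the flat TSV alternative to GTF.

    Columns: gene_id, chrom, strand, tss (comma-separated positions), exons
    (comma-separated ``start-end`` pairs, 0-based half-open).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_TABLE_COLUMNS:
            raise ValueError(f"{path}: expected columns {_GENE_TABLE_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            gene_id, chrom, strand, tss_s, exons_s = fields
            tss = sorted(int(x) for x in tss_s.split(","))
            exons = []
            for pair in exons_s.split(","):
                s, e = pair.split("-")
                exons.append(GenomicInterval(chrom, int(s), int(e)))
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    promoters=build_promoters(tss, chrom),
                    exon_union=union_intervals(exons),
                )
            )
    return models


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            tss_s = ",".join(str(t) for t in g.tss)
            exons_s = ",".join(f"{iv.start}-{iv.end}" for iv in g.exon_union)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{tss_s}\t{exons_s}\n")
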