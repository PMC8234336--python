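"""Gene models, GFF3/FASTA I/O, and gene-structure / chromosome statistics.

Coordinates are 1-based inclusive in GFF3 (as the format requires) and
0-based half-open everywhere inside the package; conversion happens only at
the file boundary so interval arithmetic stays off-by-one-proof.

One mRNA per gene is assumed; when an annotation carries several, the mRNA
with the longest CDS is taken as the primary model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Segment = tuple[int, int]  # 0-based half-open


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene (single primary mRNA)."""

    gene_id: str
    chromosome: str
    strand: str  # '+' or '-'
    start: int  # 0-based
    end: int  # half-open
    exons: tuple[Segment, ...]  # genomic order, UTR included
    cds_segments: tuple[Segment, ...]
    utr5_segments: tuple[Segment, ...] = ()
    utr3_segments: tuple[Segment, ...] = ()
    cds: str = ""
    protein: str = ""
    gene_rank: int = -1  # ordinal by start among genes on this chromosome

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        if self.cds and len(self.cds) % 3:
            raise AnnotationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return max(0, len(self.exons) - 1)

    @property
    def has_utr(self) -> bool:
        return bool(self.utr5_segments or self.utr3_segments)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class Genome:
    """A set of gene models keyed by id, with chromosome lengths."""

    genes: dict[str, GeneModel]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, genes in by_chrom.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for rank, g in enumerate(genes):
                self.genes[g.gene_id] = replace(g, gene_rank=rank)

    def __len__(self) -> int:
        return len(self.genes)

    def chromosomes(self) -> list[str]:
        return sorted(
            {g.chromosome for g in self.genes.values()}, key=natural_key
        )

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes.values() if g.chromosome == chromosome),
            key=lambda g: g.gene_rank,
        )


def natural_key(label: str):
    """Sort chr2 before chr10."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", label)
    )


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O


def write_genome(genome: Genome, gff3_path, protein_path, cds_path) -> None:
    """Serialize to GFF3 (1-based inclusive) plus protein and CDS FASTA."""
    lines = ["##gff-version 3"]
    for chrom in genome.chromosomes():
        length = genome.chromosome_lengths.get(chrom)
        if length:
            lines.append(f"##sequence-region {chrom} 1 {length}")
    for chrom in genome.chromosomes():
        for g in genome.genes_on(chrom):
            gid, mid = g.gene_id, f"{g.gene_id}.mRNA1"

            def row(ftype, s, e, attrs, g=g):
                return "\t".join(
                    [g.chromosome, "abcsurvey", ftype, str(s + 1), str(e),
                     ".", g.strand, ".", attrs]
                )

            lines.append(row("gene", g.start, g.end, f"ID={gid}"))
            lines.append(row("mRNA", g.start, g.end, f"ID={mid};Parent={gid}"))
            for s, e in sorted(g.exons):
                lines.append(row("exon", s, e, f"Parent={mid}"))
            phase_left = 0
            cds_segments = sorted(g.cds_segments, reverse=(g.strand == "-"))
            for s, e in cds_segments:
                r = row("CDS", s, e, f"Parent={mid}")
                parts = r.split("\t")
                parts[7] = str(phase_left)
                lines.append("\t".join(parts))
                phase_left = (3 - ((e - s) - phase_left) % 3) % 3
            for s, e in sorted(g.utr5_segments):
                lines.append(row("five_prime_UTR", s, e, f"Parent={mid}"))
            for s, e in sorted(g.utr3_segments):
                lines.append(row("three_prime_UTR", s, e, f"Parent={mid}"))
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    def records(attr):
        for chrom in genome.chromosomes():
            for g in genome.genes_on(chrom):
                seq = getattr(g, attr)
                if seq:
                    yield SeqRecord(Seq(seq), id=g.gene_id, description="")

    SeqIO.write(records("protein"), protein_path, "fasta")
    SeqIO.write(records("cds"), cds_path, "fasta")


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_genome(gff3_path, protein_path=None, cds_path=None) -> Genome:
    """Parse a GFF3 annotation, cross-referencing protein and CDS FASTA.

    Raises AnnotationError when an mRNA's sequences are missing or when the
    CDS and protein lengths disagree (a terminal stop codon is allowed).
    """
    proteins = _read_fasta(protein_path) if protein_path else {}
    cds_seqs = _read_fasta(cds_path) if cds_path else {}
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    chrom_lengths: dict[str, int] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                chrom_lengths[chrom] = int(end)
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue

        def cds_len(m):
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        mrna = max(mrnas, key=cds_len)
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        )
        cds_segments = tuple(
            sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        )
        utr5 = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="five_prime_UTR")
            )
        )
        utr3 = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="three_prime_UTR")
            )
        )
        gid = gene.id
        cds = cds_seqs.get(gid, "")
        protein = proteins.get(gid, "")
        if cds_seqs and not cds:
            raise AnnotationError(f"no CDS sequence for gene {gid}")
        if proteins and not protein:
            raise AnnotationError(f"no protein sequence for gene {gid}")
        if cds and protein:
            n_codons = len(cds) // 3
            if n_codons - 1 != len(protein) and n_codons != len(protein):
                raise AnnotationError(
                    f"{gid}: CDS codons ({n_codons}) inconsistent with protein "
                    f"length ({len(protein)})"
                )
        genes[gid] = GeneModel(
            gene_id=gid,
            chromosome=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=exons,
            cds_segments=cds_segments,
            utr5_segments=utr5,
            utr3_segments=utr3,
            cds=cds,
            protein=protein,
        )
    return Genome(genes, chrom_lengths)


# ---------------------------------------------------------------------------
# Statistics


def structure_stats(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-gene exon/intron counts and UTR presence."""
    rows = [
        {
            "gene_id": g.gene_id,
            "exon_count": g.exon_count,
            "intron_count": g.intron_count,
            "has_utr": g.has_utr,
        }
        for g in genes
    ]
    return pd.DataFrame(rows)


def structure_summary(stats: pd.DataFrame) -> dict:
    n = len(stats)
    if n == 0:
        return {"n_genes": 0}
    return {
        "n_genes": n,
        "exon_min": int(stats["exon_count"].min()),
        "exon_max": int(stats["exon_count"].max()),
        "n_single_exon": int((stats["exon_count"] == 1).sum()),
        "n_with_utr": int(stats["has_utr"].sum()),
        "utr_fraction_pct": round(100.0 * stats["has_utr"].sum() / n, 2),
    }


def chromosome_distribution(
    genome: Genome, terminal_fraction: float = 0.25
) -> pd.DataFrame:
    """Per-chromosome gene counts, percentage shares, and terminal-region share.

    A gene is "terminal" when its midpoint lies within ``terminal_fraction``
    of either chromosome end (requires a known chromosome length).
    """
    if not 0 < terminal_fraction <= 0.5:
        raise ValueError("terminal_fraction must be in (0, 0.5]")
    total = len(genome)
    rows = []
    for chrom in genome.chromosomes():
        genes = genome.genes_on(chrom)
        length = genome.chromosome_lengths.get(chrom)
        n_terminal = None
        if length:
            cut = terminal_fraction * length
            n_terminal = sum(
                1 for g in genes if g.midpoint < cut or g.midpoint > length - cut
            )
        rows.append(
            {
                "chromosome": chrom,
                "n_genes": len(genes),
                "share_pct": round(100.0 * len(genes) / total, 1) if total else 0.0,
                "n_terminal": n_terminal,
            }
        )
    return pd.DataFrame(rows)


def terminal_share_pct(distribution: pd.DataFrame) -> float:
    known = distribution.dropna(subset=["n_terminal"])
    total = known["n_genes"].sum()
    if total == 0:
        return 0.0
    return round(100.0 * known["n_terminal"].sum() / total, 1)
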