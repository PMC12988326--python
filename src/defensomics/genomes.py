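"""Shared containers: annotated genomes, genes, and defense-call tables.

An :class:`AnnotatedGenome` is an ordered collection of protein-coding genes
on one or more linear contigs, with 1-based inclusive nucleotide coordinates
and the translated protein sequence attached to each gene. It is the unit on
which homology assignment and RM neighborhood analysis operate.

Defense-system occurrences (from external tools or the internal RM caller)
are exchanged as tidy tables with one row per called system; see
:func:`calls_to_frame`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: column order of a defense-call table
CALL_COLUMNS = ["genome_id", "system_name", "subtype", "gene_ids", "source"]

CALL_SOURCES = {"padloc", "defensefinder", "rebase_rm", "crisprcastyper"}


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene on a contig.

    ``index`` is the 0-based rank of the gene on its contig in coordinate
    order; it is the distance unit of the neighborhood rules. Coordinates
    are 1-based inclusive on the contig.
    """

    gene_id: str
    contig: str
    index: int
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )


@dataclass
class AnnotatedGenome:
    """Ordered gene records per contig for one genome."""

    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError(f"genome {self.genome_id}: duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise LookupError(
                f"gene {gene_id!r} not found in genome {self.genome_id}"
            ) from None

    def contigs(self) -> list[str]:
        return sorted({g.contig for g in self.genes})

    def genes_on(self, contig: str) -> list[Gene]:
        """Genes on one contig in coordinate order."""
        return [g for g in self.genes if g.contig == contig]

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | os.PathLike) -> None:
        """Write one protein record per gene (id = the gene_id)."""
        records = [
            SeqRecord(Seq(g.protein), id=g.gene_id, description="")
            for g in self.genes
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_gff3(self, path: str | os.PathLike) -> None:
        """Write CDS features, 1-based inclusive, ID attribute = gene_id."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id}"
                fh.write(
                    "\t".join(
                        [
                            g.contig,
                            "defensomics",
                            "CDS",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_files(
        cls, genome_id: str, fasta_path: str | os.PathLike, gff3_path: str | os.PathLike
    ) -> "AnnotatedGenome":
        """Load a genome from a protein FASTA plus matching GFF3.

        FASTA record ids must equal GFF3 CDS ``ID`` attributes.
        """
        import gffutils

        proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        db = gffutils.create_db(
            str(gff3_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        per_contig: dict[str, list] = {}
        for feat in db.features_of_type("CDS"):
            gid = feat.attributes["ID"][0]
            if gid not in proteins:
                raise ValueError(f"GFF3 gene {gid!r} has no FASTA record")
            per_contig.setdefault(feat.seqid, []).append(
                (feat.start, feat.end, feat.strand, gid)
            )
        genes = []
        for contig, rows in per_contig.items():
            rows.sort()
            for idx, (start, end, strand, gid) in enumerate(rows):
                genes.append(
                    Gene(
                        gene_id=gid,
                        contig=contig,
                        index=idx,
                        start=start,
                        end=end,
                        strand=strand or "+",
                        protein=proteins[gid],
                    )
                )
        return cls(genome_id=genome_id, genes=genes)


@dataclass(frozen=True)
class DefenseCall:
    """One detected defense-system occurrence in one genome."""

    genome_id: str
    system_name: str
    gene_ids: tuple[str, ...] = ()
    subtype: str | None = None
    source: str = "padloc"

    def __post_init__(self) -> None:
        if not self.system_name:
            raise ValueError("system_name must be non-empty")
        if self.source not in CALL_SOURCES:
            raise ValueError(f"unknown call source {self.source!r}")


def calls_to_frame(calls: Iterable[DefenseCall]) -> pd.DataFrame:
    """Tabulate calls (gene ids semicolon-joined); stable row order."""
    rows = [
        {
            "genome_id": c.genome_id,
            "system_name": c.system_name,
            "subtype": c.subtype if c.subtype is not None else "",
            "gene_ids": ";".join(c.gene_ids),
            "source": c.source,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> list[DefenseCall]:
    calls = []
    for _, row in frame.iterrows():
        gene_ids = tuple(g for g in str(row.get("gene_ids", "") or "").split(";") if g)
        subtype = row.get("subtype", "")
        calls.append(
            DefenseCall(
                genome_id=row["genome_id"],
                system_name=row["system_name"],
                gene_ids=gene_ids,
                subtype=subtype if subtype not in ("", None) else None,
                source=row.get("source", "padloc"),
            )
        )
    return calls


def read_call_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a defense-call CSV (Padloc-like dialect)."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in ("genome_id", "system_name") if c not in frame.columns]
    if missing:
        raise ValueError(f"call table {path} missing columns: {missing}")
    for col in CALL_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    return frame[CALL_COLUMNS]


def write_call_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the genome-metadata TSV (genome_id, domain, phylum, size_mb,
    completeness, ogt_c)."""
    meta = pd.read_csv(path, sep="\t")
    required = {"genome_id", "domain", "phylum", "size_mb", "completeness"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)
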