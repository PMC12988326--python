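"""Best-hit homology assignment against the RM reference catalogue.

Query proteins are matched to catalogue entries either from an external
tabular search output (12-column BLAST-tab / MMseqs2 convention) or from
internally computed global alignments. Hits survive only above a sequence
identity of 0.65 with both-sided coverage of at least 0.8; among survivors
each query takes its single best match (lowest e-value, then highest score,
then lexicographically smallest reference id).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genomes import AnnotatedGenome
from .synthetic import ReferenceEntry

MIN_IDENTITY = 0.65
MIN_COVERAGE = 0.8

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class Hit:
    """One query-to-reference match with alignment statistics."""

    query_id: str
    ref_id: str
    identity: float
    query_coverage: float
    target_coverage: float
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        for name in ("identity", "query_coverage", "target_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class Assignment:
    """Best-hit functional assignment of one query protein."""

    query_id: str
    ref_id: str
    rm_type: str
    role: str
    identity: float = float("nan")
    coverage: float = float("nan")


def make_aligner() -> Align.PairwiseAligner:
    """Global affine-gap protein aligner (BLOSUM62, open 11, extend 1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_stats(alignment, qlen: int, tlen: int) -> tuple[float, float, float]:
    """Identity over columns between the first and last aligned pair, and
    per-sequence coverage of that span."""
    q_blocks, t_blocks = alignment.aligned
    if len(q_blocks) == 0:
        return 0.0, 0.0, 0.0
    matches = 0
    pair_columns = 0
    query, target = alignment.sequences
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for i in range(qe - qs):
            pair_columns += 1
            if query[qs + i] == target[ts + i]:
                matches += 1
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    # columns between first and last aligned pair: residue pairs plus
    # internal gap columns on either side
    columns = q_span + t_span - pair_columns
    identity = matches / columns if columns else 0.0
    return identity, q_span / qlen, t_span / tlen


def align_identity(query: str, target: str, aligner: Align.PairwiseAligner | None = None) -> Hit:
    """Globally align two proteins and report identity and coverages.

    Identity is matches divided by alignment columns excluding terminal
    gaps; coverage is the aligned span over each sequence's length.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_aligner()
    alignment = aligner.align(query, target)[0]
    identity, qcov, tcov = _alignment_stats(alignment, len(query), len(target))
    return Hit(
        query_id="query", ref_id="target",
        identity=identity, query_coverage=qcov, target_coverage=tcov,
        score=float(alignment.score),
    )


def search_genome(
    genome: AnnotatedGenome,
    refdb: Sequence[ReferenceEntry],
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = 0.0,
) -> list[Hit]:
    """Align every gene against the catalogue; keep one hit per gene.

    A score-only pass ranks the references, then a single traceback on the
    top-scoring reference yields the identity and coverage statistics (the
    downstream filter sees the same best hit it would with all pairs
    traced).
    """
    aligner = aligner or make_aligner()
    hits: list[Hit] = []
    for gene in genome.genes:
        best_ref = None
        best_score = -np.inf
        for ref in refdb:
            s = aligner.score(gene.protein, ref.sequence)
            if s > best_score or (s == best_score and best_ref is not None and ref.ref_id < best_ref.ref_id):
                best_score = s
                best_ref = ref
        if best_ref is None or best_score < min_score:
            continue
        alignment = aligner.align(gene.protein, best_ref.sequence)[0]
        identity, qcov, tcov = _alignment_stats(
            alignment, len(gene.protein), len(best_ref.sequence)
        )
        hits.append(
            Hit(
                query_id=gene.gene_id, ref_id=best_ref.ref_id,
                identity=identity, query_coverage=qcov, target_coverage=tcov,
                score=float(best_score),
            )
        )
    return hits


# --------------------------------------------------------------- tabular I/O

def parse_hit_table(
    path: str | os.PathLike,
    length_map: Mapping[str, int] | None = None,
) -> list[Hit]:
    """Read a 12(+2)-column BLAST-tab/MMseqs2 TSV into hits.

    ``pident`` (0-100) is rescaled to a 0-1 identity. Coverage needs
    sequence lengths: either optional 13th/14th columns (``qlen``,
    ``slen``) or a ``length_map`` from sequence id to length. Malformed
    rows are rejected with their (1-based) row number.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    n_cols = frame.shape[1]
    if n_cols not in (12, 13, 14):
        raise ValueError(
            f"{path}: expected 12 (or +qlen/slen) columns, found {n_cols}"
        )
    names = BLAST_COLUMNS + ["qlen", "slen"][: n_cols - 12]
    frame.columns = names
    hits = []
    required = [c for c in BLAST_COLUMNS if c != "mismatch"]
    for i, row in frame.iterrows():
        rownum = i + 1
        if any(pd.isna(row[c]) for c in required):
            raise ValueError(f"{path}: malformed row {rownum}: missing fields")
        try:
            pident = float(row["pident"])
            qstart, qend = int(row["qstart"]), int(row["qend"])
            sstart, send = int(row["sstart"]), int(row["send"])
            evalue = float(row["evalue"])
            bitscore = float(row["bitscore"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row {rownum}: {exc}") from None

        def _length(col: str, seq_id: str) -> int:
            if col in frame.columns and not pd.isna(row[col]):
                return int(row[col])
            if length_map is not None and seq_id in length_map:
                return int(length_map[seq_id])
            raise ValueError(
                f"{path}: row {rownum}: no {col} column and no length for "
                f"{seq_id!r}; coverage cannot be computed"
            )

        qlen = _length("qlen", row["qseqid"])
        slen = _length("slen", row["sseqid"])
        hits.append(
            Hit(
                query_id=row["qseqid"], ref_id=row["sseqid"],
                identity=pident / 100.0,
                query_coverage=(abs(qend - qstart) + 1) / qlen,
                target_coverage=(abs(send - sstart) + 1) / slen,
                score=bitscore, evalue=evalue,
            )
        )
    return hits


def write_hit_table(hits: Iterable[Hit], path: str | os.PathLike,
                    lengths: Mapping[str, int] | None = None) -> None:
    """Write hits in the 14-column convention (with qlen/slen when known).

    Alignment start/end positions are reconstructed from the coverages as a
    span from position 1 (internal hits carry no block structure).
    """
    rows = []
    for h in hits:
        qlen = (lengths or {}).get(h.query_id, 0)
        slen = (lengths or {}).get(h.ref_id, 0)
        qspan = int(round(h.query_coverage * qlen)) if qlen else 0
        sspan = int(round(h.target_coverage * slen)) if slen else 0
        rows.append(
            [
                h.query_id, h.ref_id, round(h.identity * 100.0, 3),
                max(qspan, sspan), 0, 0,
                1, max(qspan, 1), 1, max(sspan, 1),
                h.evalue if h.evalue is not None else 0.0, h.score,
                qlen, slen,
            ]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------- assignment

def best_hit_assign(
    hits: Iterable[Hit],
    refdb: Sequence[ReferenceEntry] | Mapping[str, ReferenceEntry],
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
) -> list[Assignment]:
    """Filter hits and assign each query its single best reference.

    A hit survives when identity >= ``min_identity`` and BOTH query and
    target coverage >= ``min_coverage`` (the both-sided coverage mode).
    Among survivors per query the lowest e-value wins; absent e-values rank
    after present ones and fall back to the highest score; remaining ties
    break by higher score, then smallest ref_id.
    """
    if isinstance(refdb, Mapping):
        by_id = dict(refdb)
    else:
        by_id = {e.ref_id: e for e in refdb}
    survivors: dict[str, list[Hit]] = {}
    for hit in hits:
        if hit.identity < min_identity:
            continue
        if min(hit.query_coverage, hit.target_coverage) < min_coverage:
            continue
        if hit.ref_id not in by_id:
            raise LookupError(f"hit references unknown catalogue entry {hit.ref_id!r}")
        survivors.setdefault(hit.query_id, []).append(hit)

    assignments = []
    for query_id in sorted(survivors):
        best = min(
            survivors[query_id],
            key=lambda h: (
                h.evalue if h.evalue is not None else np.inf,
                -h.score,
                h.ref_id,
            ),
        )
        ref = by_id[best.ref_id]
        assignments.append(
            Assignment(
                query_id=query_id, ref_id=ref.ref_id,
                rm_type=ref.rm_type, role=ref.role,
                identity=best.identity,
                coverage=min(best.query_coverage, best.target_coverage),
            )
        )
    return assignments


def assignments_to_frame(assignments: Iterable[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id, "ref_id": a.ref_id,
                "rm_type": a.rm_type, "role": a.role,
                "identity": a.identity, "coverage": a.coverage,
            }
            for a in assignments
        ],
        columns=["query_id", "ref_id", "rm_type", "role", "identity", "coverage"],
    )
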