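"""RM system calling from assignments and gene neighborhoods.

Candidate RM components (best-hit assignments against the catalogue) are
first purged of proteins that external tools placed in non-RM systems.
Every remaining restriction nuclease (role R) or single-gene module (Types
IV and IIG) anchors a neighborhood of five genes upstream and five genes
downstream; the neighborhood is classified by per-type architecture rules:

* Type I   — anchor is a type I R with type I M **and** S in the window
* Type II  — type II R with a type II M
* Type III — type III R with a type III M
* Type IV  — a type IV module alone
* Type IIG — a type IIG module alone

Anchors are processed left-to-right along each contig and greedily consume
their components (nearest eligible gene, ties upstream), so calls are
disjoint and deterministic. Contigs are linear; windows truncate at ends.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomes import AnnotatedGenome, Gene
from .homology import Assignment

WINDOW = 5

#: tool system names treated as RM during conflict filtering and merging;
#: editable because tool dialects differ
DEFAULT_RM_NAME_PREFIXES = ("RM", "restriction")

#: non-system annotation rows: DNA modification proteins (frequently RM
#: methyltransferases) and VSPR entries; never evidence of non-RM system
#: membership
NONCANONICAL = {"DMS", "VSPR"}

ANCHOR_ROLES = {"R", "module"}


def is_rm_system_name(name: str, prefixes: Sequence[str] = DEFAULT_RM_NAME_PREFIXES) -> bool:
    low = str(name).lower()
    return any(low.startswith(p.lower()) for p in prefixes)


@dataclass(frozen=True)
class Neighborhood:
    """Genes within the ±window of one anchor nuclease."""

    genome_id: str
    contig: str
    anchor_gene_index: int
    members: tuple[Gene, ...]
    roles: Mapping[str, Assignment]  # gene_id -> assignment (assigned genes only)

    @property
    def anchor(self) -> Gene:
        for g in self.members:
            if g.index == self.anchor_gene_index:
                return g
        raise LookupError("anchor not among members")


@dataclass(frozen=True)
class RMSystemCall:
    """One called RM system occurrence."""

    genome_id: str
    rm_type: str
    component_gene_ids: tuple[str, ...]
    anchor_gene_id: str


def filter_conflicts(
    assignments: Iterable[Assignment],
    external_calls: pd.DataFrame | None,
    rm_name_prefixes: Sequence[str] = DEFAULT_RM_NAME_PREFIXES,
) -> list[Assignment]:
    """Drop assignments claimed by external non-RM system calls.

    A protein listed among the gene ids of any external call whose system
    name is not an RM name is removed from the candidate pool; membership
    in external RM calls does not disqualify, and DMS/VSPR rows are ignored
    (they label individual modification proteins or non-defense entries,
    not membership in a competing system).
    """
    assignments = list(assignments)
    if external_calls is None or len(external_calls) == 0:
        return assignments
    claimed: set[str] = set()
    for _, row in external_calls.iterrows():
        name = str(row["system_name"])
        if name.upper() in NONCANONICAL:
            continue
        if is_rm_system_name(name, rm_name_prefixes):
            continue
        for gid in str(row.get("gene_ids", "") or "").split(";"):
            if gid:
                claimed.add(gid)
    return [a for a in assignments if a.query_id not in claimed]


def extract_neighborhood(
    genome: AnnotatedGenome,
    anchor_gene_id: str,
    assignments: Mapping[str, Assignment] | None = None,
    window: int = WINDOW,
) -> Neighborhood:
    """Up to ``2*window + 1`` genes around the anchor by rank on its contig,
    truncated at contig ends."""
    anchor = genome.get(anchor_gene_id)
    contig_genes = genome.genes_on(anchor.contig)
    rank = next(i for i, g in enumerate(contig_genes) if g.gene_id == anchor_gene_id)
    members = tuple(contig_genes[max(rank - window, 0): rank + window + 1])
    roles = {
        g.gene_id: assignments[g.gene_id]
        for g in members
        if assignments and g.gene_id in assignments
    }
    return Neighborhood(
        genome_id=genome.genome_id,
        contig=anchor.contig,
        anchor_gene_index=anchor.index,
        members=members,
        roles=roles,
    )


def classify_rm(neighborhood: Neighborhood) -> str | None:
    """Apply the per-type architecture rule to one neighborhood.

    Components count only when their assigned rm_type matches the
    anchor's; a neighborhood that fails its anchor's rule yields ``None``.
    """
    anchor = neighborhood.anchor
    assignment = neighborhood.roles.get(anchor.gene_id)
    if assignment is None or assignment.role not in ANCHOR_ROLES:
        raise ValueError(
            f"anchor {anchor.gene_id} must be an assigned restriction "
            f"nuclease (role R) or module"
        )
    rm_type = assignment.rm_type
    if assignment.role == "module":
        return rm_type if rm_type in ("IV", "IIG") else None
    present_roles = {
        a.role
        for gid, a in neighborhood.roles.items()
        if gid != anchor.gene_id and a.rm_type == rm_type
    }
    if rm_type == "I" and {"M", "S"} <= present_roles:
        return "I"
    if rm_type in ("II", "III") and "M" in present_roles:
        return rm_type
    return None


def _nearest(
    neighborhood: Neighborhood,
    rm_type: str,
    role: str,
    available: set[str],
) -> Gene | None:
    """Nearest eligible gene to the anchor; ties go upstream."""
    anchor_idx = neighborhood.anchor_gene_index
    best = None
    best_key = None
    for g in neighborhood.members:
        a = neighborhood.roles.get(g.gene_id)
        if a is None or g.gene_id not in available:
            continue
        if a.rm_type != rm_type or a.role != role:
            continue
        key = (abs(g.index - anchor_idx), g.index)  # ties -> upstream (lower index)
        if best_key is None or key < best_key:
            best, best_key = g, key
    return best


def call_rm_systems(
    genome: AnnotatedGenome,
    assignments: Iterable[Assignment],
    external_calls: pd.DataFrame | None = None,
    window: int = WINDOW,
    rm_name_prefixes: Sequence[str] = DEFAULT_RM_NAME_PREFIXES,
) -> list[RMSystemCall]:
    """Full per-genome RM pipeline: conflict filter, anchor scan, classify.

    Anchors are visited left-to-right by contig and coordinate; a
    successful classification consumes the anchor and its components, which
    then cannot serve later anchors.
    """
    kept = filter_conflicts(assignments, external_calls, rm_name_prefixes)
    by_gene = {a.query_id: a for a in kept if a.query_id in genome}
    anchors = [
        g for g in genome.genes
        if g.gene_id in by_gene and by_gene[g.gene_id].role in ANCHOR_ROLES
    ]
    consumed: set[str] = set()
    calls: list[RMSystemCall] = []
    for anchor in anchors:
        if anchor.gene_id in consumed:
            continue
        available_assignments = {
            gid: a for gid, a in by_gene.items() if gid not in consumed
        }
        nb = extract_neighborhood(genome, anchor.gene_id, available_assignments, window)
        rm_type = classify_rm(nb)
        if rm_type is None:
            continue
        assignment = by_gene[anchor.gene_id]
        components = [anchor.gene_id]
        if assignment.role == "R":
            available = {gid for gid in available_assignments if gid != anchor.gene_id}
            needed = ["M", "S"] if rm_type == "I" else ["M"]
            ok = True
            for role in needed:
                gene = _nearest(nb, rm_type, role, available)
                if gene is None:
                    ok = False
                    break
                components.append(gene.gene_id)
                available.discard(gene.gene_id)
            if not ok:
                continue
        order = {g.gene_id: g.index for g in genome.genes}
        components.sort(key=lambda gid: order[gid])
        calls.append(
            RMSystemCall(
                genome_id=genome.genome_id,
                rm_type=rm_type,
                component_gene_ids=tuple(components),
                anchor_gene_id=anchor.gene_id,
            )
        )
        consumed.update(components)
    return calls


# ----------------------------------------------------------------- tabular

def rm_calls_to_frame(calls: Iterable[RMSystemCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "rm_type": c.rm_type,
                "anchor_gene_id": c.anchor_gene_id,
                "component_gene_ids": ";".join(c.component_gene_ids),
            }
            for c in calls
        ],
        columns=["genome_id", "rm_type", "anchor_gene_id", "component_gene_ids"],
    )


def write_rm_calls(calls: Iterable[RMSystemCall], path: str | os.PathLike) -> None:
    rm_calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def summarize_rm_types(calls: Iterable[RMSystemCall]) -> pd.DataFrame:
    """Per-genome counts of calls by RM type."""
    frame = rm_calls_to_frame(calls)
    if frame.empty:
        return pd.DataFrame(columns=["genome_id", "I", "II", "III", "IV", "IIG"])
    counts = (
        frame.groupby(["genome_id", "rm_type"]).size().unstack(fill_value=0)
    )
    for t in ("I", "II", "III", "IV", "IIG"):
        if t not in counts.columns:
            counts[t] = 0
    return counts[["I", "II", "III", "IV", "IIG"]].reset_index()
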