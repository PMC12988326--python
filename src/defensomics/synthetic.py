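"""Synthetic cohorts with recorded ground truth.

Two levels of simulation back the pipeline's validation:

* **Sequence level** — genomes with planted RM operons of each type
  (components copied from a reference catalogue and mutated to a controlled
  amino-acid identity) plus random decoy genes, so the homology and
  neighborhood stages can be scored against a known plan. Emulated
  tool-output tables include DMS/VSPR decoy rows and a deliberately weak RM
  channel so the merge policy is exercised.

* **Cohort level** — per-genome metadata (domain, phylum, genome size,
  completeness, optimal growth temperature) together with defense-system
  counts drawn from a negative-binomial regression model and per-system
  presence drawn from logistic models, with every generating coefficient
  recorded in the :class:`SimulationPlan`.

All randomness flows from a single master seed; each genome gets its own
stream derived from ``(master seed, genome index)`` so cohorts reproduce
under any generation order.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit

from .genomes import AnnotatedGenome, DefenseCall, Gene, calls_to_frame

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: valid (rm_type, role) combinations: Type I systems have R, M and S
#: subunits; II and III have R and M; IV and IIG are single modules.
VALID_COMBOS: tuple[tuple[str, str], ...] = (
    ("I", "R"), ("I", "M"), ("I", "S"),
    ("II", "R"), ("II", "M"),
    ("III", "R"), ("III", "M"),
    ("IV", "module"),
    ("IIG", "module"),
)

RM_TYPES = ("I", "II", "III", "IV", "IIG")

#: components required by each RM type (anchor role first)
TYPE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "I": ("R", "M", "S"),
    "II": ("R", "M"),
    "III": ("R", "M"),
    "IV": ("module",),
    "IIG": ("module",),
}


@dataclass(frozen=True)
class ReferenceEntry:
    """One catalogue protein: a REBASE-style RM component."""

    ref_id: str
    rm_type: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if (self.rm_type, self.role) not in VALID_COMBOS:
            raise ValueError(
                f"invalid (rm_type, role) = ({self.rm_type}, {self.role})"
            )
        if not self.sequence or set(self.sequence) - set(AMINO_ACIDS.tolist()):
            raise ValueError(f"reference {self.ref_id}: invalid sequence")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=max(int(length), 30)))


def generate_reference_db(
    n_per_role: int, mean_len: int = 150, seed: int = 0
) -> list[ReferenceEntry]:
    """Build a reference catalogue covering every valid (rm_type, role).

    Lengths are Poisson-scattered around ``mean_len`` (floor 30 residues);
    sequences are uniform over the 20-letter alphabet. Deterministic given
    the seed.
    """
    if n_per_role < 1:
        raise ValueError("n_per_role must be >= 1")
    if mean_len < 30:
        raise ValueError("mean_len must be >= 30")
    rng = np.random.default_rng(seed)
    entries = []
    for rm_type, role in VALID_COMBOS:
        for i in range(n_per_role):
            length = max(30, int(rng.poisson(mean_len)))
            entries.append(
                ReferenceEntry(
                    ref_id=f"{rm_type}-{role}-{i}",
                    rm_type=rm_type,
                    role=role,
                    sequence=_random_protein(rng, length),
                )
            )
    return entries


def write_reference_fasta(entries: Iterable[ReferenceEntry], path: str | os.PathLike) -> None:
    """Headers follow the ``ref_id|rm_type|role`` convention."""
    records = [
        SeqRecord(Seq(e.sequence), id=f"{e.ref_id}|{e.rm_type}|{e.role}", description="")
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | os.PathLike) -> list[ReferenceEntry]:
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(f"reference header {rec.id!r} not 'ref_id|rm_type|role'")
        entries.append(ReferenceEntry(parts[0], parts[1], parts[2], str(rec.seq)))
    return entries


def mutate_to_identity(sequence: str, target_identity: float, seed: int = 0) -> str:
    """Return a copy with exactly ``round(len * (1 - target))`` substitutions.

    Each mutated position receives a different residue, so positional
    identity to the input equals the target up to rounding (within 1/len).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity == 1.0:
        return sequence
    rng = np.random.default_rng(seed)
    n = len(sequence)
    n_mut = int(round(n * (1.0 - target_identity)))
    positions = rng.choice(n, size=n_mut, replace=False)
    seq = list(sequence)
    for pos in positions:
        alternatives = AMINO_ACIDS[AMINO_ACIDS != seq[pos]]
        seq[pos] = str(rng.choice(alternatives))
    return "".join(seq)


# --------------------------------------------------------------------------
# sequence-level simulation
# --------------------------------------------------------------------------

@dataclass
class PlantedSystem:
    """Ground-truth record of one planted system.

    For RM systems ``components`` holds the role labels (anchor role first);
    for non-RM systems it holds one entry per gene, each either ``None``
    (random sequence) or a ``(rm_type, role)`` trap spec whose gene is a
    mutated copy of a catalogue entry — planted to exercise the conflict
    filter.
    """

    system_name: str
    rm_type: str | None = None
    components: tuple = ()
    contig: str = "c1"
    identity: float = 0.75
    gene_indices: tuple[int, ...] = ()
    gene_ids: tuple[str, ...] = ()
    anchor_gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.rm_type is not None:
            if self.rm_type not in TYPE_COMPONENTS:
                raise ValueError(f"unknown rm_type {self.rm_type!r}")
            if not self.components:
                self.components = TYPE_COMPONENTS[self.rm_type]
            for role in self.components:
                if (self.rm_type, role) not in VALID_COMBOS:
                    raise ValueError(
                        f"invalid component {role!r} for type {self.rm_type}"
                    )
        elif not self.components:
            self.components = (None, None)


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic genome."""

    genome_id: str
    planted: list[PlantedSystem] = field(default_factory=list)
    n_decoys: int = 12
    decoy_len_mean: int = 150
    intersperse: int = 0  # decoy genes inserted inside each operon (<= 2)
    window: int = 5


def _refs_by_combo(refdb: Sequence[ReferenceEntry]) -> dict[tuple[str, str], list[ReferenceEntry]]:
    by_combo: dict[tuple[str, str], list[ReferenceEntry]] = {}
    for entry in refdb:
        by_combo.setdefault((entry.rm_type, entry.role), []).append(entry)
    return by_combo


def generate_genome(
    spec: GenomeSpec, refdb: Sequence[ReferenceEntry], seed: int = 0
) -> AnnotatedGenome:
    """Lay out planted operons and decoy genes on linear contigs.

    Operon components are kept within a window the downstream ±``window``
    neighborhood rule can recover (an operon whose block would exceed
    ``2*window + 1`` genes is an error). Operon blocks are separated by at
    least ``window + 1`` decoy genes so neighborhoods of distinct systems
    never overlap. Ground truth (gene indices, ids, anchor) is written back
    into ``spec.planted``.
    """
    rng = np.random.default_rng(seed)
    by_combo = _refs_by_combo(refdb)
    if spec.intersperse > 2:
        raise ValueError("at most 2 interspersed decoys per operon")

    # build per-operon gene blocks: list of (protein, planted_ref, role)
    blocks: list[list[tuple[str, PlantedSystem | None, str | None]]] = []
    for system in spec.planted:
        block: list[tuple[str, PlantedSystem | None, str | None]] = []
        for comp in system.components:
            if system.rm_type is not None:
                combo = (system.rm_type, comp)
            elif comp is not None:
                combo = tuple(comp)
            else:
                combo = None
            if combo is not None:
                candidates = by_combo.get(combo)
                if not candidates:
                    raise ValueError(f"reference catalogue has no entry for {combo}")
                ref = candidates[int(rng.integers(len(candidates)))]
                protein = mutate_to_identity(
                    ref.sequence, system.identity, seed=int(rng.integers(2**31))
                )
            else:
                protein = _random_protein(rng, rng.poisson(spec.decoy_len_mean))
            role = comp if system.rm_type is not None else None
            block.append((protein, system, role))
        # intersperse decoys at random internal junctions
        for _ in range(spec.intersperse):
            if len(block) < 2:
                break
            pos = int(rng.integers(1, len(block)))
            block.insert(
                pos, (_random_protein(rng, rng.poisson(spec.decoy_len_mean)), None, None)
            )
        if len(block) > 2 * spec.window + 1:
            raise ValueError(
                f"operon {system.system_name} spans {len(block)} genes, "
                f"larger than the ±{spec.window} window"
            )
        blocks.append(block)

    separator = spec.window + 1
    n_sep_decoys = separator * max(len(blocks) - 1, 0)
    n_free = max(spec.n_decoys - n_sep_decoys, 2)
    n_lead = int(rng.integers(0, n_free + 1))
    n_trail = n_free - n_lead

    def decoy() -> tuple[str, None, None]:
        return (_random_protein(rng, rng.poisson(spec.decoy_len_mean)), None, None)

    layout: list[tuple[str, PlantedSystem | None, str | None]] = []
    layout.extend(decoy() for _ in range(n_lead))
    for i, block in enumerate(blocks):
        if i > 0:
            layout.extend(decoy() for _ in range(separator))
        layout.extend(block)
    layout.extend(decoy() for _ in range(n_trail))
    if not layout:
        layout = [decoy()]

    genes: list[Gene] = []
    placed: dict[int, list[tuple[int, str, str | None]]] = {}
    pos = 1
    contig = spec.planted[0].contig if spec.planted else "c1"
    for idx, (protein, system, role) in enumerate(layout):
        start = pos
        end = start + 3 * len(protein) + 2
        gene_id = f"{spec.genome_id}|{contig}|{idx}"
        genes.append(
            Gene(
                gene_id=gene_id, contig=contig, index=idx,
                start=start, end=end, strand="+", protein=protein,
            )
        )
        pos = end + int(rng.integers(20, 200))
        if system is not None:
            placed.setdefault(id(system), []).append((idx, gene_id, role))

    for system in spec.planted:
        records = placed.get(id(system), [])
        system.gene_indices = tuple(idx for idx, _, _ in records)
        system.gene_ids = tuple(gid for _, gid, _ in records)
        if system.rm_type is not None:
            anchor_role = "module" if system.rm_type in ("IV", "IIG") else "R"
            for idx, gid, role in records:
                if role == anchor_role:
                    system.anchor_gene_id = gid
                    break
    return AnnotatedGenome(genome_id=spec.genome_id, genes=genes)


def apply_incompleteness(
    genome: AnnotatedGenome, completeness: float, seed: int = 0
) -> AnnotatedGenome:
    """Retain each gene independently with probability ``completeness``.

    Models MAG incompleteness as uniform gene dropout; survivor coordinates
    and ids are unchanged.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if completeness == 1.0:
        return AnnotatedGenome(genome_id=genome.genome_id, genes=list(genome.genes))
    rng = np.random.default_rng(seed)
    keep = rng.random(len(genome.genes)) < completeness
    genes = [g for g, k in zip(genome.genes, keep) if k]
    return AnnotatedGenome(genome_id=genome.genome_id, genes=genes)


def emit_tool_calls(
    genome: AnnotatedGenome,
    planted: Sequence[PlantedSystem],
    seed: int = 0,
    n_dms: int = 1,
    n_vspr: int = 1,
    rm_report_fraction: float = 0.5,
) -> pd.DataFrame:
    """Emulate an external defense-caller table for one genome.

    One row per planted non-RM system, plus DMS/VSPR decoy rows (which the
    canonical filter must discard) and a weak RM channel: each planted RM
    system is reported with probability ``rm_report_fraction`` under the
    name ``RM_type_<T>`` so the REBASE-replacement merge policy is
    exercised.
    """
    rng = np.random.default_rng(seed)
    calls: list[DefenseCall] = []
    surviving = {g.gene_id for g in genome.genes}
    for system in planted:
        gene_ids = tuple(g for g in system.gene_ids if g in surviving)
        if system.rm_type is None:
            calls.append(
                DefenseCall(
                    genome_id=genome.genome_id,
                    system_name=system.system_name,
                    gene_ids=gene_ids,
                    source="padloc",
                )
            )
        elif rng.random() < rm_report_fraction and gene_ids:
            calls.append(
                DefenseCall(
                    genome_id=genome.genome_id,
                    system_name=f"RM_type_{system.rm_type}",
                    gene_ids=gene_ids,
                    source="padloc",
                )
            )
    decoy_pool = [g.gene_id for g in genome.genes]
    for name, count in (("DMS", n_dms), ("VSPR", n_vspr)):
        for _ in range(count):
            gid = ()
            if decoy_pool:
                gid = (decoy_pool[int(rng.integers(len(decoy_pool)))],)
            calls.append(
                DefenseCall(
                    genome_id=genome.genome_id, system_name=name,
                    gene_ids=gid, source="padloc",
                )
            )
    return calls_to_frame(calls)


# --------------------------------------------------------------------------
# cohort-level simulation
# --------------------------------------------------------------------------

@dataclass
class CountModel:
    """Negative-binomial regression truth for total defense counts.

    ``mu = exp(intercept + beta_ogt * OGT_c + beta_log_size * log(size_mb)
    + phylum offset)``; counts ~ NB(mu, theta) with Var = mu + mu²/theta.
    """

    intercept: float = 1.0
    beta_ogt: float = float(np.log(1.357) / 10.0)  # +35.7% per 10 °C
    beta_log_size: float = 1.0
    phylum_offsets: dict[str, float] = field(default_factory=dict)
    theta: float = 2.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("dispersion theta must be > 0")

    def mu(self, ogt_c: float, size_mb: float, phylum: str) -> float:
        eta = (
            self.intercept
            + self.beta_ogt * ogt_c
            + self.beta_log_size * np.log(size_mb)
            + self.phylum_offsets.get(phylum, 0.0)
        )
        return float(np.exp(eta))


@dataclass
class PresenceModel:
    """Logistic truth for one system's presence/absence.

    ``logit(p) = intercept + beta_completeness * completeness
    + beta_domain * [domain == Bacteria]``.
    """

    intercept: float = -1.0
    beta_completeness: float = 2.0
    beta_domain: float = 0.5

    def prob(self, completeness: float, domain: str) -> float:
        eta = (
            self.intercept
            + self.beta_completeness * completeness
            + self.beta_domain * (domain == "Bacteria")
        )
        return float(expit(eta))


#: systems emulated by default — the prevalent families the survey models
DEFAULT_SYSTEMS = (
    "RM", "CRISPR-Cas", "CBASS", "viperin", "SoFic", "AbiE", "DndABCDE", "argonaute",
)


def _default_presence_models() -> dict[str, PresenceModel]:
    # intercepts spread so prevalences span rare to common
    base = {
        "RM": 0.8, "CRISPR-Cas": 0.1, "CBASS": -1.2, "viperin": -2.0,
        "SoFic": -1.5, "AbiE": -1.0, "DndABCDE": -2.2, "argonaute": -1.8,
    }
    return {
        name: PresenceModel(intercept=b0 - 2.0, beta_completeness=2.0, beta_domain=0.5)
        for name, b0 in base.items()
    }


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the survey's setting: archaeal genomes smaller
    (≈1.8 Mb vs ≈3.8 Mb), less complete on average, and spanning
    mesophilic-to-hyperthermophilic growth temperatures, with defense
    counts following the count model and per-system presence following
    the logistic models.
    """

    phyla: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "Archaea": {"Phylum_A1": 120, "Phylum_A2": 120, "Phylum_A3": 60},
            "Bacteria": {"Phylum_B1": 150, "Phylum_B2": 150},
        }
    )
    count_model: CountModel = field(default_factory=CountModel)
    presence_models: dict[str, PresenceModel] = field(
        default_factory=_default_presence_models
    )
    # completeness ~ Beta(a, b) rescaled to (0.5, 1]; archaea lower on average
    completeness_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Archaea": (5.0, 2.0), "Bacteria": (8.0, 1.5)}
    )
    # log-normal genome sizes (median Mb, sigma of log)
    size_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"Archaea": (1.8, 0.35), "Bacteria": (3.8, 0.35)}
    )
    # OGT mixture per domain: (weight, mean, sd) triples
    ogt_mixture: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: {
            "Archaea": ((0.55, 37.0, 8.0), (0.3, 65.0, 8.0), (0.15, 85.0, 5.0)),
            "Bacteria": ((0.9, 34.0, 7.0), (0.1, 60.0, 8.0)),
        }
    )


@dataclass
class SimulationPlan:
    """Everything the generator planted, for recovery scoring.

    ``planted_systems`` (sequence-level cohorts) maps genome_id to the
    planted-system records; the model fields (cohort-level) record the
    generating coefficients.
    """

    seed: int
    n_genomes_per_domain: dict[str, int] = field(default_factory=dict)
    phylum_labels: dict[str, int] = field(default_factory=dict)
    planted_systems: dict[str, list[PlantedSystem]] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)
    ogt_celsius: dict[str, float] = field(default_factory=dict)
    genome_size_mb: dict[str, float] = field(default_factory=dict)
    count_model: CountModel | None = None
    presence_models: dict[str, PresenceModel] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=encode, indent=1)

    def expected_rm_calls(self, genome_id: str) -> list[tuple[str, str]]:
        """(rm_type, anchor_gene_id) for each planted RM system."""
        return [
            (s.rm_type, s.anchor_gene_id)
            for s in self.planted_systems.get(genome_id, [])
            if s.rm_type is not None
        ]


def _genome_rng(master_seed: int, genome_index: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), int(genome_index)])


def generate_rm_cohort(
    n_genomes: int,
    refdb: Sequence[ReferenceEntry],
    seed: int = 0,
    identity: float = 0.75,
    completeness: float = 1.0,
    n_decoys: int = 12,
    max_systems: int = 2,
    include_types: Sequence[str] = RM_TYPES,
    non_rm_systems: Sequence[str] = ("CBASS", "viperin"),
    p_non_rm: float = 0.3,
    intersperse: int = 0,
    drop_type_i_s: bool = False,
) -> tuple[dict[str, AnnotatedGenome], SimulationPlan, pd.DataFrame, pd.DataFrame]:
    """Sequence-level cohort with planted RM operons.

    RM types cycle through ``include_types`` so every type appears; each
    genome carries 1..``max_systems`` RM systems plus, with probability
    ``p_non_rm``, one non-RM system. ``drop_type_i_s`` omits the specificity
    subunit from every Type I operon (an ablation for the S-dependence of
    the Type I rule). Genomes alternate between the two domains with two
    phyla each and carry drawn size/OGT metadata, so the aggregated cohort
    is a valid substrate for the downstream statistics.

    Returns ``(genomes, plan, tool_calls, metadata)``.
    """
    plan = SimulationPlan(seed=seed)
    genomes: dict[str, AnnotatedGenome] = {}
    call_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    default_cfg = CohortConfig()
    type_cycle = 0
    for g in range(n_genomes):
        rng = _genome_rng(seed, g)
        genome_id = f"G{g:04d}"
        domain = "Archaea" if g % 2 == 0 else "Bacteria"
        phylum = f"Phylum_{domain[0]}{1 + (g // 2) % 2}"
        planted: list[PlantedSystem] = []
        k = int(rng.integers(1, max_systems + 1))
        for _ in range(k):
            rm_type = include_types[type_cycle % len(include_types)]
            type_cycle += 1
            components = TYPE_COMPONENTS[rm_type]
            if drop_type_i_s and rm_type == "I":
                components = tuple(r for r in components if r != "S")
                planted.append(
                    PlantedSystem(
                        system_name="RM_I_noS", rm_type="I",
                        components=components, identity=identity,
                    )
                )
            else:
                planted.append(
                    PlantedSystem(
                        system_name=f"RM_{rm_type}", rm_type=rm_type,
                        identity=identity,
                    )
                )
        if non_rm_systems and rng.random() < p_non_rm:
            name = non_rm_systems[int(rng.integers(len(non_rm_systems)))]
            planted.append(PlantedSystem(system_name=name))
        spec = GenomeSpec(
            genome_id=genome_id, planted=planted,
            n_decoys=n_decoys, intersperse=intersperse,
        )
        genome = generate_genome(spec, refdb, seed=int(rng.integers(2**31)))
        if completeness < 1.0:
            genome = apply_incompleteness(
                genome, completeness, seed=int(rng.integers(2**31))
            )
        genomes[genome_id] = genome
        plan.planted_systems[genome_id] = planted
        plan.completeness[genome_id] = completeness
        median, sigma = default_cfg.size_lognormal[domain]
        size_mb = float(np.exp(rng.normal(np.log(median), sigma)))
        ogt = max(_sample_mixture(rng, default_cfg.ogt_mixture[domain]), 2.0)
        plan.genome_size_mb[genome_id] = size_mb
        plan.ogt_celsius[genome_id] = ogt
        plan.n_genomes_per_domain[domain] = plan.n_genomes_per_domain.get(domain, 0) + 1
        plan.phylum_labels[phylum] = plan.phylum_labels.get(phylum, 0) + 1
        meta_rows.append(
            {
                "genome_id": genome_id, "domain": domain, "phylum": phylum,
                "size_mb": size_mb, "completeness": completeness, "ogt_c": ogt,
            }
        )
        call_frames.append(
            emit_tool_calls(genome, planted, seed=int(rng.integers(2**31)))
        )
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else calls_to_frame([])
    )
    metadata = pd.DataFrame(
        meta_rows,
        columns=["genome_id", "domain", "phylum", "size_mb", "completeness", "ogt_c"],
    )
    return genomes, plan, calls, metadata


def _sample_mixture(
    rng: np.random.Generator, mixture: tuple[tuple[float, float, float], ...]
) -> float:
    weights = np.array([w for w, _, _ in mixture])
    weights = weights / weights.sum()
    i = int(rng.choice(len(mixture), p=weights))
    _, mean, sd = mixture[i]
    return float(rng.normal(mean, sd))


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, SimulationPlan]:
    """Cohort-level simulation: metadata plus counts and presence.

    ``total_systems`` is drawn from the negative-binomial count model;
    per-system presence columns are drawn from the logistic presence
    models (these are the two substrates of the abundance and prevalence
    analyses, sampled from their respective marginal models).
    """
    config = config or CohortConfig()
    if config.count_model.theta <= 0:
        raise ValueError("dispersion theta must be > 0")
    plan = SimulationPlan(
        seed=seed,
        count_model=config.count_model,
        presence_models=dict(config.presence_models),
    )
    rows = []
    g = 0
    systems = list(config.presence_models)
    for domain, phyla in config.phyla.items():
        plan.n_genomes_per_domain[domain] = sum(phyla.values())
        for phylum, n in phyla.items():
            plan.phylum_labels[phylum] = n
            for _ in range(n):
                rng = _genome_rng(seed, g)
                genome_id = f"S{g:05d}"
                a, b = config.completeness_beta[domain]
                completeness = 0.5 + 0.5 * float(rng.beta(a, b))
                median, sigma = config.size_lognormal[domain]
                size_mb = float(np.exp(rng.normal(np.log(median), sigma)))
                ogt = max(_sample_mixture(rng, config.ogt_mixture[domain]), 2.0)
                mu = config.count_model.mu(ogt, size_mb, phylum)
                theta = config.count_model.theta
                total = int(rng.negative_binomial(theta, theta / (theta + mu)))
                row = {
                    "genome_id": genome_id, "domain": domain, "phylum": phylum,
                    "size_mb": size_mb, "completeness": completeness,
                    "ogt_c": ogt, "total_systems": total,
                }
                distinct = 0
                for name in systems:
                    p = config.presence_models[name].prob(completeness, domain)
                    present = int(rng.random() < p)
                    row[name] = present
                    distinct += present
                row["distinct_types"] = distinct
                plan.completeness[genome_id] = completeness
                plan.ogt_celsius[genome_id] = ogt
                plan.genome_size_mb[genome_id] = size_mb
                rows.append(row)
                g += 1
    cohort = pd.DataFrame(rows)
    return cohort, plan
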