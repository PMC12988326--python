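"""Defensome aggregation: merge, filter, and summarize call tables.

The defensome of a genome is the union of its called defense systems.
External tool tables are first purged of non-defense rows (DNA modification
systems, "DMS", and "VSPR" entries); for genomes routed through the
REBASE-based RM caller the tool's own RM rows are replaced by the internal
calls. The resulting per-genome system counts feed all prevalence and
abundance statistics.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genomes import CALL_COLUMNS, calls_to_frame
from .rm_detection import (
    DEFAULT_RM_NAME_PREFIXES,
    NONCANONICAL,
    RMSystemCall,
    is_rm_system_name,
)

#: systems excluded when asking which genomes are "defenseless beyond the
#: near-universal core" (RM and CRISPR-Cas)
DEFAULT_CORE_EXCLUDE = ("RM", "CRISPR-Cas")

METADATA_COLUMNS = ["genome_id", "domain", "phylum", "size_mb", "completeness", "ogt_c"]


def filter_noncanonical(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop DMS and VSPR rows (case-insensitive); preserve order."""
    if calls.empty:
        return calls.copy()
    mask = ~calls["system_name"].str.upper().isin(NONCANONICAL)
    return calls[mask].reset_index(drop=True)


def merge_defensome(
    tool_calls: pd.DataFrame,
    rm_calls: Iterable[RMSystemCall] | pd.DataFrame,
    rebase_genomes: Iterable[str] | None = None,
    rm_name_prefixes: Sequence[str] = DEFAULT_RM_NAME_PREFIXES,
) -> pd.DataFrame:
    """Replace tool RM rows by internal RM calls for selected genomes.

    ``rebase_genomes`` is the set of genomes routed through the REBASE-based
    caller (default: every genome with at least one internal RM call or
    listed in the internal table). Tool RM rows for those genomes are
    dropped; internal calls are appended as ``RM`` rows with source
    ``rebase_rm``. Non-RM tool rows pass through untouched.
    """
    if isinstance(rm_calls, pd.DataFrame):
        rm_frame = rm_calls
    else:
        from .rm_detection import rm_calls_to_frame

        rm_frame = rm_calls_to_frame(rm_calls)
    if rebase_genomes is None:
        rebase = set(rm_frame["genome_id"]) if not rm_frame.empty else set()
    else:
        rebase = set(rebase_genomes)

    if tool_calls.empty:
        kept = tool_calls.copy()
    else:
        is_rm = tool_calls["system_name"].map(
            lambda s: is_rm_system_name(s, rm_name_prefixes)
        )
        drop = is_rm & tool_calls["genome_id"].isin(rebase)
        kept = tool_calls[~drop]

    rm_rows = pd.DataFrame(
        [
            {
                "genome_id": row["genome_id"],
                "system_name": "RM",
                "subtype": f"RM_type_{row['rm_type']}",
                "gene_ids": row["component_gene_ids"],
                "source": "rebase_rm",
            }
            for _, row in rm_frame.iterrows()
            if row["genome_id"] in rebase
        ],
        columns=CALL_COLUMNS,
    )
    parts = [f for f in (kept, rm_rows) if not f.empty]
    if not parts:
        return calls_to_frame([])
    return pd.concat(parts, ignore_index=True)


def summarize_cohort(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-genome system counts, totals, and distinct-type counts.

    Every genome in the metadata appears (zeros when it has no calls);
    calls naming a genome absent from the metadata are an error.
    """
    meta = metadata.set_index("genome_id", drop=False)
    if meta.index.has_duplicates:
        raise ValueError("duplicate genome_id in metadata")
    if not calls.empty:
        unknown = set(calls["genome_id"]) - set(meta.index)
        if unknown:
            raise LookupError(f"calls reference unknown genomes: {sorted(unknown)[:5]}")
        counts = (
            calls.groupby(["genome_id", "system_name"]).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(index=pd.Index([], name="genome_id"))
    counts = counts.reindex(meta.index, fill_value=0).astype(int)
    cohort = meta.reset_index(drop=True).copy()
    system_cols = sorted(counts.columns)
    for col in system_cols:
        cohort[col] = counts[col].to_numpy()
    cohort["total_systems"] = counts.sum(axis=1).to_numpy() if system_cols else 0
    cohort["distinct_types"] = (
        (counts > 0).sum(axis=1).to_numpy() if system_cols else 0
    )
    cohort.attrs["system_columns"] = system_cols
    return cohort


def system_columns(cohort: pd.DataFrame) -> list[str]:
    """System count columns of a cohort table (everything that is neither
    metadata nor a derived total)."""
    if "system_columns" in cohort.attrs:
        return list(cohort.attrs["system_columns"])
    skip = set(METADATA_COLUMNS) | {"total_systems", "distinct_types"}
    return [c for c in cohort.columns if c not in skip]


def prevalence_by(cohort: pd.DataFrame, group: str = "domain") -> pd.DataFrame:
    """Fraction of genomes encoding each system (count > 0), per group."""
    cols = system_columns(cohort)
    return cohort.groupby(group)[cols].agg(lambda s: float((s > 0).mean()))


def core_defensome(
    cohort: pd.DataFrame, k: int = 20
) -> tuple[dict[str, list[str]], list[str]]:
    """Top-``k`` most prevalent systems per domain and their union.

    Ranking: prevalence (fraction of genomes with the system), ties broken
    by higher total occurrence count, then by name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    domains = sorted(cohort["domain"].unique())
    if len(domains) < 2:
        raise ValueError("core defensome needs both domains present")
    cols = system_columns(cohort)
    top: dict[str, list[str]] = {}
    for domain in domains:
        sub = cohort[cohort["domain"] == domain]
        prev = (sub[cols] > 0).mean()
        total = sub[cols].sum()
        ranked = sorted(cols, key=lambda s: (-prev[s], -total[s], s))
        top[domain] = ranked[: min(k, len(cols))]
    union = sorted(set().union(*top.values()))
    return top, union


def defenseless_fraction(
    cohort: pd.DataFrame,
    exclude: Sequence[str] = DEFAULT_CORE_EXCLUDE,
    rm_name_prefixes: Sequence[str] = DEFAULT_RM_NAME_PREFIXES,
) -> pd.DataFrame:
    """Fraction of genomes with no systems beyond the excluded core.

    A genome counts when every system it encodes is in ``exclude`` (RM
    names match by prefix) — including genomes with no calls at all.
    Reported per domain and per phylum.
    """
    if cohort.empty:
        return pd.DataFrame(columns=["level", "group", "fraction", "n"])
    cols = system_columns(cohort)
    excluded_names = {e.lower() for e in exclude}

    def is_excluded(name: str) -> bool:
        return name.lower() in excluded_names or is_rm_system_name(
            name, rm_name_prefixes
        )

    beyond = [c for c in cols if not is_excluded(c)]
    defenseless = (cohort[beyond] == 0).all(axis=1) if beyond else pd.Series(
        True, index=cohort.index
    )
    rows = []
    for level in ("domain", "phylum"):
        for group, sub in cohort.groupby(level):
            rows.append(
                {
                    "level": level,
                    "group": group,
                    "fraction": float(defenseless[sub.index].mean()),
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def normalize_per_mb(cohort: pd.DataFrame) -> pd.Series:
    """Defense-system density: total systems per megabase of genome."""
    size = cohort["size_mb"].to_numpy(dtype=float)
    if np.any(size <= 0):
        raise ValueError("size_mb must be positive")
    return pd.Series(
        cohort["total_systems"].to_numpy(dtype=float) / size,
        index=cohort.index,
        name="systems_per_mb",
    )
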