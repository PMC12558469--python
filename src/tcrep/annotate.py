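"""Match cluster CDR3s against local antigen-specificity snapshot tables.

Reference snapshots are user-supplied TSVs with four columns — ``cdr3_aa``,
``antigen``, ``category`` (microbial / autoimmune / cancer / other) and
``source_db`` — typically local exports of public TCR-specificity databases.
Matching is case-normalized exact amino-acid identity (no V-gene
conditioning, no partial matches). A cluster is flagged *convergent* when at
least two distinct member sequences map to the same antigen label: structurally
similar receptors with a shared reported specificity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cluster import ClusterSet
from .io import STANDARD_AA

logger = logging.getLogger(__name__)

CATEGORIES = ("microbial", "autoimmune", "cancer", "other")


@dataclass(frozen=True)
class SpecificityRecord:
    cdr3_aa: str
    antigen: str
    category: str
    source_db: str

    def __post_init__(self) -> None:
        if not set(self.cdr3_aa) <= STANDARD_AA:
            raise ValueError(f"non-standard residues in reference CDR3 {self.cdr3_aa!r}")
        if not self.source_db:
            raise ValueError("source_db must be non-empty")


def read_reference(path: str | Path) -> list[SpecificityRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("cdr3_aa", "antigen", "category", "source_db")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing reference column {col!r}")
    return [
        SpecificityRecord(
            cdr3_aa=r.cdr3_aa.strip().upper(),
            antigen=r.antigen.strip(),
            category=r.category.strip() or "other",
            source_db=r.source_db.strip(),
        )
        for r in df.itertuples()
    ]


@dataclass
class ClusterAnnotation:
    cluster_id: int | None  # None for singleton clonotypes
    matches: pd.DataFrame  # member, antigen, category, source_db
    convergent: bool


def match_specificity(
    cluster_set: ClusterSet, reference: list[SpecificityRecord]
) -> tuple[pd.DataFrame, dict]:
    """Exact-match cluster members (and singletons) against the reference.

    Returns a long annotation table and a nested cluster → member → antigen
    mapping suitable for circle-packing visualization.
    """
    if not reference:
        logger.warning("empty specificity reference; no annotations produced")
        return (
            pd.DataFrame(columns=["cluster_id", "member", "antigen", "category", "source_db", "convergent"]),
            {"clusters": [], "singletons": []},
        )
    by_seq: dict[str, list[SpecificityRecord]] = {}
    for rec in reference:
        by_seq.setdefault(rec.cdr3_aa, []).append(rec)

    rows = []
    nested: dict = {"clusters": [], "singletons": []}
    for c in cluster_set.clusters:
        hits = {m: by_seq[m.upper()] for m in sorted(c.members) if m.upper() in by_seq}
        if not hits:
            continue
        antigen_members: dict[str, set[str]] = {}
        node = {"cluster_id": c.cluster_id, "motif": c.motif, "members": []}
        for member, recs in hits.items():
            for rec in recs:
                rows.append(
                    {
                        "cluster_id": c.cluster_id,
                        "member": member,
                        "antigen": rec.antigen,
                        "category": rec.category,
                        "source_db": rec.source_db,
                    }
                )
                antigen_members.setdefault(rec.antigen, set()).add(member)
            node["members"].append(
                {"cdr3_aa": member, "antigens": sorted({r.antigen for r in recs})}
            )
        convergent = any(len(ms) >= 2 for ms in antigen_members.values())
        node["convergent"] = convergent
        nested["clusters"].append(node)
        for row in rows:
            if row["cluster_id"] == c.cluster_id:
                row["convergent"] = convergent
    for s in cluster_set.singletons:
        if s.upper() in by_seq:
            for rec in by_seq[s.upper()]:
                rows.append(
                    {
                        "cluster_id": None,
                        "member": s,
                        "antigen": rec.antigen,
                        "category": rec.category,
                        "source_db": rec.source_db,
                        "convergent": False,
                    }
                )
            nested["singletons"].append(
                {"cdr3_aa": s, "antigens": sorted({r.antigen for r in by_seq[s.upper()]})}
            )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "member", "antigen", "category", "source_db", "convergent"]
    )
    return table, nested


def write_annotation(table: pd.DataFrame, nested: dict, prefix: str | Path) -> None:
    prefix = Path(prefix)
    table.to_csv(str(prefix) + ".tsv", sep="\t", index=False)
    Path(str(prefix) + ".json").write_text(json.dumps(nested, indent=1))
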