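"""Reading, validation, filtering and aggregation of TCRβ rearrangement tables.

Two on-disk dialects are supported for rearrangement-level input: ImmunoSEQ-style
exports (``aminoAcid``/``count (templates/reads)``/``frame_type`` or the
snake_case variant used by later kit versions) and AIRR Rearrangement TSV
(``junction_aa``/``duplicate_count``/``productive``). Both are parsed into the
same in-memory :class:`Repertoire` container: one record per CDR3β amino-acid
clonotype with a template count.

Downstream analysis operates on *productive* clonotypes only: in-frame CDR3β
amino-acid sequences over the 20 standard residues, with no early stop codon
(``*``) and no ambiguity markers (``X`` or the non-standard letters B, J, O, U,
Z). :func:`filter_productive` applies exactly that rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GROUPS = ("healthy", "MGUS", "SMM", "MM")
DISEASE_GROUPS = ("MGUS", "SMM", "MM")
SOURCES = ("PBMC", "whole_blood")
KIT_VERSIONS = ("v3", "v4")


class RepertoireFormatError(ValueError):
    """A rearrangement or metadata file violates the expected format."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One CDR3β amino-acid clonotype with its template (molecule) count."""

    cdr3_aa: str
    count: int
    productive: bool = True
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if int(self.count) < 1:
            raise ValueError(f"count must be >= 1, got {self.count} for {self.cdr3_aa}")


@dataclass
class Repertoire:
    """One sample's clonotype table (CDR3β amino acid → template count)."""

    sample_id: str
    records: list[ClonotypeRecord] = field(default_factory=list)

    @property
    def total_templates(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def n_clonotypes(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        """cdr3_aa → count mapping (later duplicates summed)."""
        out: dict[str, int] = {}
        for r in self.records:
            out[r.cdr3_aa] = out.get(r.cdr3_aa, 0) + r.count
        return out

    @classmethod
    def from_counts(
        cls, sample_id: str, counts: dict[str, int], productive: bool = True
    ) -> "Repertoire":
        recs = [
            ClonotypeRecord(cdr3_aa=s, count=int(c), productive=productive)
            for s, c in counts.items()
        ]
        return cls(sample_id=sample_id, records=recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "cdr3_aa": [r.cdr3_aa for r in self.records],
                "count": [r.count for r in self.records],
                "productive": [r.productive for r in self.records],
                "v_call": [r.v_call for r in self.records],
                "j_call": [r.j_call for r in self.records],
            }
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical/technical annotations."""

    sample_id: str
    group: str
    age: float
    timepoint: str = "baseline"
    source: str | None = None
    kit_version: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RepertoireFormatError(
                f"unknown group label {self.group!r} for sample {self.sample_id}; "
                f"expected one of {GROUPS}"
            )
        if self.age < 0:
            raise RepertoireFormatError(f"negative age for sample {self.sample_id}")


# ---------------------------------------------------------------------------
# rearrangement-table dialects

_IMMUNOSEQ_AA = ("aminoAcid", "amino_acid")
_IMMUNOSEQ_COUNT = ("count (templates/reads)", "templates", "count")
_IMMUNOSEQ_FRAME = ("frame_type", "frameType", "sequenceStatus")
_IMMUNOSEQ_V = ("vGeneName", "v_gene", "v_resolved")
_IMMUNOSEQ_J = ("jGeneName", "j_gene", "j_resolved")


def _pick_column(columns: Sequence[str], candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in columns:
            return c
    raise RepertoireFormatError(
        f"missing mandatory {what} column; expected one of {list(candidates)}, "
        f"found {list(columns)}"
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    # pandas handles .gz transparently via the compression inference
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_count(raw: str, line_no: int, path: str | Path) -> int:
    try:
        value = int(float(raw)) if raw.strip() else 0
        if float(raw) != value:
            raise ValueError
    except ValueError:
        raise RepertoireFormatError(
            f"{path}: non-integer count {raw!r} at line {line_no}"
        ) from None
    if value < 1:
        raise RepertoireFormatError(
            f"{path}: count must be a positive integer, got {raw!r} at line {line_no}"
        )
    return value


def read_immunoseq(path: str | Path, sample_id: str | None = None) -> Repertoire:
    """Read an ImmunoSEQ-style rearrangement TSV into a :class:`Repertoire`.

    Accepts either the camelCase (``aminoAcid``, ``count (templates/reads)``)
    or snake_case (``amino_acid``, ``templates``) header style; ``frame_type``
    equal to ``"In"`` marks productive rearrangements. No filtering is applied
    here — every row becomes a record.
    """
    path = Path(path)
    df = _read_table(path)
    aa_col = _pick_column(df.columns, _IMMUNOSEQ_AA, "amino-acid")
    count_col = _pick_column(df.columns, _IMMUNOSEQ_COUNT, "count")
    frame_col = _pick_column(df.columns, _IMMUNOSEQ_FRAME, "frame")
    v_col = next((c for c in _IMMUNOSEQ_V if c in df.columns), None)
    j_col = next((c for c in _IMMUNOSEQ_J if c in df.columns), None)

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        d = dict(zip(df.columns, row))
        cdr3 = d[aa_col].strip().upper()
        if not cdr3:
            raise RepertoireFormatError(f"{path}: empty CDR3 at line {line_no}")
        count = _parse_count(d[count_col], line_no, path)
        records.append(
            ClonotypeRecord(
                cdr3_aa=cdr3,
                count=count,
                productive=d[frame_col].strip() == "In",
                v_call=(d[v_col].strip() or None) if v_col else None,
                j_call=(d[j_col].strip() or None) if j_col else None,
            )
        )
    if not records:
        logger.warning("%s: no rearrangement rows after header", path)
    return Repertoire(sample_id=sample_id or _stem(path), records=records)


_TRUE = {"T", "TRUE", "1", "YES", "Y"}
_FALSE = {"F", "FALSE", "0", "NO", "N", ""}


def read_airr(path: str | Path, sample_id: str | None = None) -> Repertoire:
    """Read an AIRR Rearrangement TSV (junction_aa / duplicate_count / productive).

    Count fallback order when ``duplicate_count`` is absent or empty:
    ``consensus_count``, else 1 with a warning (AIRR makes counts optional).
    """
    path = Path(path)
    df = _read_table(path)
    aa_col = _pick_column(df.columns, ("junction_aa",), "junction_aa")
    prod_col = _pick_column(df.columns, ("productive",), "productive")
    count_col = next(
        (c for c in ("duplicate_count", "consensus_count") if c in df.columns), None
    )
    if count_col is None:
        logger.warning(
            "%s: neither duplicate_count nor consensus_count present; counts set to 1",
            path,
        )
    elif count_col == "consensus_count":
        logger.warning("%s: duplicate_count absent, falling back to consensus_count", path)
    v_col = "v_call" if "v_call" in df.columns else None
    j_col = "j_call" if "j_call" in df.columns else None

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        d = dict(zip(df.columns, row))
        cdr3 = d[aa_col].strip().upper()
        if not cdr3:
            raise RepertoireFormatError(f"{path}: empty junction_aa at line {line_no}")
        if count_col is None or not d[count_col].strip():
            count = 1
        else:
            count = _parse_count(d[count_col], line_no, path)
        prod_raw = d[prod_col].strip().upper()
        if prod_raw in _TRUE:
            productive = True
        elif prod_raw in _FALSE:
            productive = False
        else:
            raise RepertoireFormatError(
                f"{path}: unrecognized productive flag {prod_raw!r} at line {line_no}"
            )
        records.append(
            ClonotypeRecord(
                cdr3_aa=cdr3,
                count=count,
                productive=productive,
                v_call=(d[v_col].strip() or None) if v_col else None,
                j_call=(d[j_col].strip() or None) if j_col else None,
            )
        )
    if not records:
        logger.warning("%s: empty repertoire (no rows after header)", path)
    return Repertoire(sample_id=sample_id or _stem(path), records=records)


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".tsv", ".txt", ".csv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


# ---------------------------------------------------------------------------
# filtering / aggregation

def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep in-frame clonotypes over the 20 standard residues only.

    Drops records flagged non-productive and any CDR3 containing a stop (``*``),
    ambiguity marker (``X``), or non-standard letter (B, J, O, U, Z): the
    physicochemical scales downstream are undefined for them.
    """
    kept = [
        r
        for r in rep.records
        if r.productive and set(r.cdr3_aa) <= STANDARD_AA
    ]
    if not kept and rep.records:
        logger.warning("%s: no productive clonotypes after filtering", rep.sample_id)
    return Repertoire(sample_id=rep.sample_id, records=kept)


def aggregate_by_cdr3aa(rep: Repertoire) -> Repertoire:
    """Merge records sharing a CDR3 amino-acid sequence; counts are summed.

    V/J calls are retained only when unanimous among merged records; the
    productive flag survives only if all merged records carry it.
    """
    by_seq: dict[str, list[ClonotypeRecord]] = {}
    order: list[str] = []
    for r in rep.records:
        if r.cdr3_aa not in by_seq:
            by_seq[r.cdr3_aa] = []
            order.append(r.cdr3_aa)
        by_seq[r.cdr3_aa].append(r)
    merged = []
    for seq in order:
        group = by_seq[seq]
        v_calls = {g.v_call for g in group}
        j_calls = {g.j_call for g in group}
        merged.append(
            ClonotypeRecord(
                cdr3_aa=seq,
                count=sum(g.count for g in group),
                productive=all(g.productive for g in group),
                v_call=v_calls.pop() if len(v_calls) == 1 else None,
                j_call=j_calls.pop() if len(j_calls) == 1 else None,
            )
        )
    return Repertoire(sample_id=rep.sample_id, records=merged)


# ---------------------------------------------------------------------------
# canonical repertoire TSV (long format, any number of samples per file)

_CANONICAL_COLS = ["sample_id", "cdr3_aa", "count", "productive", "v_call", "j_call"]


def write_repertoires(reps: Iterable[Repertoire], path: str | Path) -> None:
    """Write repertoires to the canonical long-format TSV (gzip if ``.gz``)."""
    frames = [r.to_frame() for r in reps]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_CANONICAL_COLS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_repertoires(path: str | Path) -> list[Repertoire]:
    """Read the canonical long-format TSV back into per-sample repertoires."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cdr3_aa": str})
    reps: dict[str, Repertoire] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid not in reps:
            reps[sid] = Repertoire(sample_id=sid)
            order.append(sid)
        v = getattr(row, "v_call", None)
        j = getattr(row, "j_call", None)
        reps[sid].records.append(
            ClonotypeRecord(
                cdr3_aa=str(row.cdr3_aa),
                count=int(row.count),
                productive=bool(getattr(row, "productive", True)),
                v_call=None if pd.isna(v) else str(v),
                j_call=None if pd.isna(j) else str(j),
            )
        )
    return [reps[s] for s in order]


# ---------------------------------------------------------------------------
# sample metadata

_META_REQUIRED = ("sample_id", "group", "age")


def read_metadata(
    path: str | Path, drop_young_healthy: bool = False
) -> list[SampleMetadata]:
    """Read and validate the sample metadata table (CSV or TSV).

    With ``drop_young_healthy=True``, healthy donors younger than 40 years are
    excluded (age ≥ 40 kept) — the age-confounding mitigation applied before
    all group comparisons.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in _META_REQUIRED:
        if col not in df.columns:
            raise RepertoireFormatError(f"{path}: missing mandatory column {col!r}")
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in seen:
            raise RepertoireFormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            age = float(row["age"])
        except ValueError:
            raise RepertoireFormatError(
                f"{path}: non-numeric age {row['age']!r} for sample {sid}"
            ) from None
        meta = SampleMetadata(
            sample_id=sid,
            group=row["group"].strip(),
            age=age,
            timepoint=row.get("timepoint", "baseline").strip() or "baseline",
            source=(row.get("source", "") or "").strip() or None,
            kit_version=(row.get("kit_version", "") or "").strip() or None,
        )
        out.append(meta)
    if drop_young_healthy:
        n_before = len(out)
        out = [m for m in out if not (m.group == "healthy" and m.age < 40)]
        dropped = n_before - len(out)
        if dropped:
            logger.info("%s: dropped %d healthy donors under 40 years", path, dropped)
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    ms = list(metadata)
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in ms],
            "group": [m.group for m in ms],
            "age": [m.age for m in ms],
            "timepoint": [m.timepoint for m in ms],
            "source": [m.source or "" for m in ms],
            "kit_version": [m.kit_version or "" for m in ms],
        }
    )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)
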