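"""Physicochemical descriptors of CDR3β amino-acid sequences.

Nine per-sequence descriptors, computed over the 20-standard-residue alphabet:

* ``length`` — residue count;
* ``gravy`` — grand average of hydropathy (mean Kyte–Doolittle value);
* ``bulk`` — mean Zimmerman bulkiness;
* ``polarity`` — mean Grantham polarity;
* ``aliphatic`` — Ikai's aliphatic index, ``X_Ala + 2.9·X_Val + 3.9·(X_Ile +
  X_Leu)`` with X in mole percent;
* ``charge`` — Henderson–Hasselbalch net side-chain charge at pH 7.4 (free
  termini excluded: the CDR3 is an internal peptide fragment) using the EMBOSS
  side-chain pK set;
* ``basic`` / ``acidic`` / ``aromatic`` — fractions of positions that are
  {R, H, K}, {D, E} and {H, F, W, Y} respectively.

Residue scales ship as versioned data files (``data/aa_scales.tsv``:
Kyte & Doolittle 1982 hydropathy; Zimmerman, Eliezer & Simha 1968 bulkiness;
Grantham 1974 polarity. ``data/pk_sidechain.tsv``: EMBOSS side-chain pK
values) so alternative tables are pluggable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cluster import ClusterSet
from .diversity import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

BASIC_RESIDUES = frozenset("RHK")
ACIDIC_RESIDUES = frozenset("DE")
AROMATIC_RESIDUES = frozenset("HFWY")
_ALIPHATIC_WEIGHTS = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}

PROPERTY_NAMES = (
    "length",
    "gravy",
    "bulk",
    "aliphatic",
    "polarity",
    "charge",
    "basic",
    "acidic",
    "aromatic",
)


@dataclass(frozen=True)
class PropertyScales:
    """Per-residue value tables driving the descriptors."""

    hydropathy: dict[str, float]
    bulkiness: dict[str, float]
    polarity: dict[str, float]
    pk_basic: dict[str, float]
    pk_acidic: dict[str, float]
    ph: float = 7.4


def load_scales(ph: float = 7.4) -> PropertyScales:
    """Load the shipped residue scales (Kyte–Doolittle / Zimmerman / Grantham /
    EMBOSS pK)."""
    pkg = resources.files("tcrep") / "data"
    aa = pd.read_csv(str(pkg / "aa_scales.tsv"), sep="\t").set_index("residue")
    pk = pd.read_csv(str(pkg / "pk_sidechain.tsv"), sep="\t")
    return PropertyScales(
        hydropathy=aa["hydropathy"].to_dict(),
        bulkiness=aa["bulkiness"].to_dict(),
        polarity=aa["polarity"].to_dict(),
        pk_basic={r.residue: r.pk for r in pk.itertuples() if r.kind == "basic"},
        pk_acidic={r.residue: r.pk for r in pk.itertuples() if r.kind == "acidic"},
        ph=ph,
    )


_DEFAULT_SCALES: PropertyScales | None = None


def default_scales() -> PropertyScales:
    global _DEFAULT_SCALES
    if _DEFAULT_SCALES is None:
        _DEFAULT_SCALES = load_scales()
    return _DEFAULT_SCALES


@dataclass(frozen=True)
class PhysicalProperties:
    length: int
    gravy: float
    bulk: float
    aliphatic: float
    polarity: float
    charge: float
    basic: float
    acidic: float
    aromatic: float

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in PROPERTY_NAMES})


def net_charge(seq: str, scales: PropertyScales | None = None) -> float:
    """Henderson–Hasselbalch net side-chain charge at the configured pH."""
    scales = scales or default_scales()
    ph = scales.ph
    charge = 0.0
    for r in seq:
        if r in scales.pk_basic:
            charge += 1.0 / (1.0 + 10.0 ** (ph - scales.pk_basic[r]))
        elif r in scales.pk_acidic:
            charge -= 1.0 / (1.0 + 10.0 ** (scales.pk_acidic[r] - ph))
    return charge


def physical_properties(
    seq: str, scales: PropertyScales | None = None
) -> PhysicalProperties:
    """Compute the nine descriptors for one standard-alphabet sequence."""
    scales = scales or default_scales()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(scales.hydropathy)
    if bad:
        raise ValueError(
            f"non-standard residues {sorted(bad)} in {seq!r}; filter upstream"
        )
    n = len(seq)
    counts = {r: seq.count(r) for r in set(seq)}
    gravy = sum(scales.hydropathy[r] for r in seq) / n
    bulk = sum(scales.bulkiness[r] for r in seq) / n
    polarity = sum(scales.polarity[r] for r in seq) / n
    aliphatic = sum(
        _ALIPHATIC_WEIGHTS[r] * 100.0 * counts.get(r, 0) / n for r in _ALIPHATIC_WEIGHTS
    )
    basic = sum(counts.get(r, 0) for r in BASIC_RESIDUES) / n
    acidic = sum(counts.get(r, 0) for r in ACIDIC_RESIDUES) / n
    aromatic = sum(counts.get(r, 0) for r in AROMATIC_RESIDUES) / n
    return PhysicalProperties(
        length=n,
        gravy=gravy,
        bulk=bulk,
        aliphatic=aliphatic,
        polarity=polarity,
        charge=net_charge(seq, scales),
        basic=basic,
        acidic=acidic,
        aromatic=aromatic,
    )


def sequence_property_frame(
    sequences, scales: PropertyScales | None = None
) -> pd.DataFrame:
    scales = scales or default_scales()
    rows = {s: physical_properties(s, scales).as_series() for s in sequences}
    return pd.DataFrame(rows).T.rename_axis("cdr3_aa")


# ---------------------------------------------------------------------------
# cluster-level summaries

def cluster_property_summary(
    cluster_set: ClusterSet, scales: PropertyScales | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unweighted per-cluster mean of member properties + per-property z-scores.

    z-normalization is across clusters (each property column standardized to
    mean 0, sd 1); a zero-variance property gets z = 0 with a warning. Returns
    ``(means, zscores)`` indexed by cluster_id.
    """
    scales = scales or default_scales()
    means = {}
    for c in cluster_set.clusters:
        seq_props = sequence_property_frame(sorted(c.members), scales)
        means[c.cluster_id] = seq_props.mean(axis=0)
    means_df = pd.DataFrame(means).T.rename_axis("cluster_id")
    z = means_df.copy()
    for col in z.columns:
        sd = z[col].std(ddof=0)
        if sd == 0 or np.isnan(sd):
            logger.warning("property %r has zero variance across clusters; z := 0", col)
            z[col] = 0.0
        else:
            z[col] = (z[col] - z[col].mean()) / sd
    return means_df, z


def compare_property_distributions(
    summary: pd.DataFrame, directions: pd.Series
) -> pd.DataFrame:
    """Per-property Wilcoxon rank-sum between healthy- and disease-enriched clusters.

    ``summary`` is the per-cluster property means frame; ``directions`` maps
    cluster_id → "healthy_enriched" / "disease_enriched".
    """
    directions = directions.reindex(summary.index).dropna()
    rows = []
    for prop in PROPERTY_NAMES:
        xs = summary.loc[directions[directions == "healthy_enriched"].index, prop]
        ys = summary.loc[directions[directions == "disease_enriched"].index, prop]
        if len(xs) < 2 or len(ys) < 2:
            logger.warning(
                "property %s: a direction class has < 2 clusters; skipped", prop
            )
            rows.append({"property": prop, "statistic": np.nan, "p": np.nan})
            continue
        stat, p = wilcoxon_rank_sum(xs.to_numpy(), ys.to_numpy())
        rows.append({"property": prop, "statistic": stat, "p": p})
    return pd.DataFrame(rows).set_index("property")
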