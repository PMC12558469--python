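"""Differential cluster prevalence and group exclusivity.

Each cluster's prevalence — the number of samples carrying at least one member
sequence — is compared between healthy donors and patients (MGUS + SMM + MM
pooled) with a two-sided Fisher exact test on the 2×2 presence table.
Candidate clusters are selected at a nominal α (default 0.001) on the training
split only; Benjamini–Hochberg q-values are reported alongside. Group
exclusivity (the share of clusters whose carriers all belong to one diagnosis
group) is calibrated against a permutation null in which sample labels are
shuffled with group sizes preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterMatrix

logger = logging.getLogger(__name__)

DIRECTION_DISEASE = "disease_enriched"
DIRECTION_HEALTHY = "healthy_enriched"


@dataclass(frozen=True)
class ContingencyTable:
    """Sample-level 2×2 presence table.

    ``a``: diseased samples carrying the cluster, ``b``: diseased without,
    ``c``: healthy carrying, ``d``: healthy without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass(frozen=True)
class DAResult:
    cluster_id: int
    table: ContingencyTable
    p: float
    q: float
    direction: str
    selected: bool


@dataclass(frozen=True)
class ExclusivityResult:
    group: str
    observed_pct: float
    null_mean_pct: float
    p_upper: float  # observed at least as large as null
    p_lower: float  # observed at least as small as null


# ---------------------------------------------------------------------------
# Fisher exact test (probability-mass rule, log-space)

_TIE_TOL = 1e-12


@lru_cache(maxsize=65536)
def _log_support(N: int, K: int, n1: int) -> tuple[int, np.ndarray]:
    """Hypergeometric log-pmf over the full support for fixed margins.

    Cached because every cluster tested against the same sample split shares
    the same group sizes, so margins repeat heavily.
    """
    lo = max(0, K - (N - n1))
    hi = min(n1, K)
    support = np.arange(lo, hi + 1)
    return lo, stats.hypergeom.logpmf(support, N, K, n1)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (relative tie
    tolerance 1e-12), in log space for numerical stability at large margins.
    A zero margin admits only one table: p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n1 = a + b  # diseased
    n2 = c + d  # healthy
    k_total = a + c  # samples with the cluster
    N = n1 + n2
    if n1 == 0 or n2 == 0 or k_total == 0 or k_total == N:
        return 1.0
    lo, logpmf = _log_support(N, k_total, n1)
    log_obs = logpmf[a - lo]
    mask = logpmf <= log_obs + _TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logpmf[mask]))))


def prevalence_tables(
    matrix: ClusterMatrix, labels: pd.Series
) -> dict[int, ContingencyTable]:
    """Per-cluster presence tables for a healthy/diseased binary labelling.

    ``labels`` maps sample_id → "healthy" or "diseased" and defines which
    samples participate (restrict to the training split before calling to keep
    the test split out of selection). Clusters absent from every participating
    sample are dropped.
    """
    lab = labels.reindex(matrix.abundance.index).dropna()
    classes = set(lab.unique())
    if classes != {"healthy", "diseased"}:
        raise ValueError(
            f"labels must contain both 'healthy' and 'diseased', got {sorted(classes)}"
        )
    presence = (matrix.abundance.loc[lab.index] > 0).to_numpy()
    is_dis = (lab == "diseased").to_numpy()
    n_dis = int(is_dis.sum())
    n_healthy = int((~is_dis).sum())
    with_dis = presence[is_dis].sum(axis=0)
    with_healthy = presence[~is_dis].sum(axis=0)
    out: dict[int, ContingencyTable] = {}
    for j, cid in enumerate(matrix.abundance.columns):
        a = int(with_dis[j])
        c = int(with_healthy[j])
        if a + c == 0:
            continue
        out[int(cid)] = ContingencyTable(a=a, b=n_dis - a, c=c, d=n_healthy - c)
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    matrix: ClusterMatrix, labels: pd.Series, alpha: float = 0.001
) -> list[DAResult]:
    """Fisher tests + BH-FDR + nominal selection for every carried cluster."""
    tables = prevalence_tables(matrix, labels)
    cluster_ids = sorted(tables)
    pvals = np.array([fisher_exact(tables[cid]) for cid in cluster_ids])
    qvals = bh_fdr(pvals)
    results = []
    for cid, p, q in zip(cluster_ids, pvals, qvals):
        t = tables[cid]
        rate_dis = t.a / (t.a + t.b) if (t.a + t.b) else 0.0
        rate_healthy = t.c / (t.c + t.d) if (t.c + t.d) else 0.0
        direction = DIRECTION_DISEASE if rate_dis >= rate_healthy else DIRECTION_HEALTHY
        results.append(
            DAResult(
                cluster_id=cid,
                table=t,
                p=float(p),
                q=float(q),
                direction=direction,
                selected=bool(p < alpha),
            )
        )
    return results


def select_candidates(results: list[DAResult]) -> list[int]:
    """Cluster ids selected at the nominal threshold (training split only)."""
    return [r.cluster_id for r in results if r.selected]


def da_frame(results: list[DAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
            "selected": [r.selected for r in results],
        }
    )


# ---------------------------------------------------------------------------
# exclusivity and its permutation null

def _exclusive_counts(presence: np.ndarray, group_onehot: np.ndarray) -> np.ndarray:
    """Per-group counts of clusters whose carriers all lie in that group.

    ``presence``: samples × clusters boolean; ``group_onehot``: groups × samples.
    """
    per_group = group_onehot.astype(float) @ presence  # groups × clusters carrier counts
    total = presence.sum(axis=0)
    return ((per_group == total) & (per_group > 0)).sum(axis=1)


def exclusivity(presence: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Observed percentage of clusters exclusive to each group.

    A cluster is exclusive to group g iff every sample carrying it belongs to
    g; the percentage is over all clusters carried by at least one sample.
    """
    groups = groups.reindex(presence.index)
    levels = sorted(groups.unique())
    onehot = np.stack([(groups == g).to_numpy() for g in levels])
    P = presence.to_numpy()
    carried = P.sum(axis=0) > 0
    P = P[:, carried]
    counts = _exclusive_counts(P, onehot)
    denom = max(1, P.shape[1])
    return pd.Series(100.0 * counts / denom, index=levels, name="exclusive_pct")


def permutation_exclusivity_test(
    presence: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[ExclusivityResult]:
    """Empirical calibration of group exclusivity under label shuffling.

    Labels are permuted over samples ``n_permutations`` times with group sizes
    preserved; empirical p-values use the add-one convention
    ``(1 + #extreme) / (B + 1)`` and both tails are reported.
    """
    groups = groups.reindex(presence.index)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    onehot = np.stack([(groups == g).to_numpy() for g in levels])
    P = presence.to_numpy()
    P = P[:, P.sum(axis=0) > 0]
    n_clusters = max(1, P.shape[1])
    observed = 100.0 * _exclusive_counts(P, onehot) / n_clusters

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(levels)))
    n_samples = P.shape[0]
    for b in range(n_permutations):
        perm = rng.permutation(n_samples)
        null[b] = 100.0 * _exclusive_counts(P, onehot[:, perm]) / n_clusters

    results = []
    for gi, g in enumerate(levels):
        ge = int((null[:, gi] >= observed[gi] - 1e-12).sum())
        le = int((null[:, gi] <= observed[gi] + 1e-12).sum())
        results.append(
            ExclusivityResult(
                group=g,
                observed_pct=float(observed[gi]),
                null_mean_pct=float(null[:, gi].mean()),
                p_upper=(1 + ge) / (n_permutations + 1),
                p_lower=(1 + le) / (n_permutations + 1),
            )
        )
    return results
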