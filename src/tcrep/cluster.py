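"""CDR3β similarity clustering: Hamming-1 graph + Markov clustering (MCL).

Sequences from all baseline samples are pooled and connected whenever two
equal-length CDR3s differ at exactly one position. All such pairs are found by
deletion-key hashing: each sequence is indexed under every string obtained by
masking one position, and sequences sharing a key are verified pairs. Connected
components of the resulting graph are refined by Markov clustering — repeated
expansion (matrix powering of a column-stochastic random-walk matrix) and
inflation (entrywise powering + renormalization) until convergence, with
attractor rows defining the final partition. Clusters of fewer than two
members are excluded from the sample × cluster matrix but retained as
singletons for annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Repertoire
from .diversity import gini

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCLParams:
    """Markov-clustering hyperparameters (reference-tool defaults)."""

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")


@dataclass(frozen=True)
class Cluster:
    """A set of equal-length CDR3s connected through Hamming-1 similarity."""

    cluster_id: int
    members: frozenset[str]
    motif: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    singletons: list[str] = field(default_factory=list)

    def member_to_cluster(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clusters:
            for m in c.members:
                out[m] = c.cluster_id
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for m in sorted(c.members):
                rows.append({"cluster_id": c.cluster_id, "member": m, "motif": c.motif})
        return pd.DataFrame(rows, columns=["cluster_id", "member", "motif"])


@dataclass
class ClusterMatrix:
    """Samples × clusters abundance (summed clone fraction of member CDR3s)."""

    abundance: pd.DataFrame  # index: sample_id, columns: cluster_id, float

    @property
    def presence(self) -> pd.DataFrame:
        return self.abundance > 0

    def clusters_per_sample(self) -> pd.Series:
        return self.presence.sum(axis=1)


# ---------------------------------------------------------------------------
# Hamming-1 graph via deletion keys

def hamming_edges(sequences: Sequence[str]) -> list[tuple[int, int]]:
    """All unordered index pairs of equal-length sequences at Hamming distance 1.

    Deletion-key hashing: for each sequence of length L, L keys are formed by
    masking one position; two distinct sequences share a key iff they differ at
    exactly that position. Pairs are verified before being reported.
    """
    seqs = list(sequences)
    if len(set(seqs)) != len(seqs):
        raise ValueError("sequences must be unique")
    by_length: dict[int, list[int]] = {}
    for idx, s in enumerate(seqs):
        by_length.setdefault(len(s), []).append(idx)
    edges: set[tuple[int, int]] = set()
    for L, idxs in by_length.items():
        # one length group at a time keeps the key table small
        for pos in range(L):
            buckets: dict[str, list[int]] = {}
            for idx in idxs:
                s = seqs[idx]
                buckets.setdefault(s[:pos] + s[pos + 1 :], []).append(idx)
            for bucket in buckets.values():
                if len(bucket) < 2:
                    continue
                for i in range(len(bucket)):
                    a = bucket[i]
                    for j in range(i + 1, len(bucket)):
                        b = bucket[j]
                        pair = (a, b) if a < b else (b, a)
                        if pair not in edges and _hamming1(seqs[a], seqs[b]):
                            edges.add(pair)
    return sorted(edges)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


# ---------------------------------------------------------------------------
# Markov clustering

def mcl(
    n_nodes: int, edges: Iterable[tuple[int, int]], params: MCLParams | None = None
) -> list[set[int]]:
    """Partition a graph by Markov clustering, component by component.

    Self-loops are added internally; disconnected components can never merge,
    so MCL runs independently (and densely) within each connected component.
    Returns a partition covering every node; isolated nodes come back as
    singleton clusters.
    """
    params = params or MCLParams()
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adjacency: dict[int, set[int]] = {}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    components: dict[int, list[int]] = {}
    for node in range(n_nodes):
        components.setdefault(find(node), []).append(node)

    partition: list[set[int]] = []
    for nodes in components.values():
        if len(nodes) <= 2:
            partition.append(set(nodes))
            continue
        local = {node: i for i, node in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for node in nodes:
            for nb in adjacency.get(node, ()):
                A[local[node], local[nb]] = 1.0
        for block in _mcl_dense(A, params):
            partition.append({nodes[i] for i in block})
    return partition


def _mcl_dense(A: np.ndarray, params: MCLParams) -> list[set[int]]:
    """Run MCL on a dense adjacency matrix of one connected component."""
    n = A.shape[0]
    M = A + np.eye(n)  # self-loops
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iterations):
        last = M
        M = np.linalg.matrix_power(M, params.expansion)
        M = M ** params.inflation
        M[M < params.prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - last)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations on a component of size %d; "
            "returning current partition",
            params.max_iterations,
            n,
        )
    # attractors: nodes with mass on their own diagonal; cluster = the columns
    # each attractor row supports, merging attractor rows that share columns
    attractors = np.where(np.diag(M) > 1e-9)[0]
    assigned = np.full(n, -1, dtype=int)
    cluster_ids: dict[int, int] = {}
    clusters: list[set[int]] = []
    for a in attractors:
        cols = set(np.where(M[a] > 1e-9)[0].tolist()) | {int(a)}
        hit = {assigned[c] for c in cols if assigned[c] >= 0}
        if hit:
            tgt = min(hit)
            for other in sorted(hit - {tgt}, reverse=True):
                clusters[tgt] |= clusters[other]
                for node in clusters[other]:
                    assigned[node] = tgt
                clusters[other] = set()
            clusters[tgt] |= cols
        else:
            tgt = len(clusters)
            clusters.append(set(cols))
        for c in cols:
            assigned[c] = tgt
        cluster_ids[int(a)] = tgt
    out = [c for c in clusters if c]
    for node in range(n):
        if assigned[node] < 0:  # numerically orphaned node
            out.append({node})
    return out


# ---------------------------------------------------------------------------
# pooled clustering across a cohort

def consensus_motif(members: Iterable[str]) -> str:
    """Position-wise consensus with '.' wildcards at variable positions."""
    ms = sorted(members)
    motif = []
    for chars in zip(*ms):
        motif.append(chars[0] if len(set(chars)) == 1 else ".")
    return "".join(motif)


def coarse_partition(
    sequences: list[str], max_group_size: int, seed: int = 0
) -> list[list[str]]:
    """Coarse pre-partition for very large pools: by length, then k-means.

    Length groups larger than ``max_group_size`` are split by k-means on the
    per-sequence physicochemical vectors. This bounds the working-set size of
    the exact stage but CAN split true clusters across groups — it is an
    opt-in scalability trade, not the default path.
    """
    from sklearn.cluster import KMeans

    from .properties import sequence_property_frame

    by_length: dict[int, list[str]] = {}
    for s in sequences:
        by_length.setdefault(len(s), []).append(s)
    groups: list[list[str]] = []
    for L in sorted(by_length):
        block = sorted(by_length[L])
        if len(block) <= max_group_size:
            groups.append(block)
            continue
        k = -(-len(block) // max_group_size)  # ceil
        feats = sequence_property_frame(block).to_numpy()
        labels = KMeans(n_clusters=k, n_init=3, random_state=seed).fit_predict(feats)
        for g in range(k):
            members = [s for s, lab in zip(block, labels) if lab == g]
            if members:
                groups.append(members)
    return groups


def cluster_pooled(
    repertoires: list[Repertoire],
    params: MCLParams | None = None,
    min_cluster_size: int = 2,
    coarse_max_group: int | None = None,
) -> ClusterSet:
    """Pool unique CDR3s across samples and cluster them.

    The cluster universe is shared across the cohort (clusters are later
    projected back onto each sample), which is what per-sample cluster counts
    and cross-group exclusivity require. ``coarse_max_group`` enables the
    coarse pre-partition (see :func:`coarse_partition`) for pools too large
    for the exact path; it may split true clusters and is off by default.
    """
    pool = sorted({r.cdr3_aa for rep in repertoires for r in rep.records})
    if not pool:
        raise ValueError("empty sequence pool: no clonotypes to cluster")
    if coarse_max_group is not None:
        pos = {s: i for i, s in enumerate(pool)}
        partition = []
        for group in coarse_partition(pool, coarse_max_group):
            sub_edges = hamming_edges(group)
            for block in mcl(len(group), sub_edges, params):
                partition.append({pos[group[i]] for i in block})
    else:
        edges = hamming_edges(pool)
        partition = mcl(len(pool), edges, params)
    clusters: list[Cluster] = []
    singletons: list[str] = []
    blocks = sorted(
        (sorted(pool[i] for i in block) for block in partition),
        key=lambda b: b[0],
    )
    cid = 0
    for block in blocks:
        if len(block) >= min_cluster_size:
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    members=frozenset(block),
                    motif=consensus_motif(block),
                )
            )
            cid += 1
        else:
            singletons.extend(block)
    return ClusterSet(clusters=clusters, singletons=sorted(singletons))


def build_cluster_matrix(
    cluster_set: ClusterSet, repertoires: list[Repertoire]
) -> ClusterMatrix:
    """Project clusters onto samples: summed clone fraction of member CDR3s."""
    lookup = cluster_set.member_to_cluster()
    n_clusters = len(cluster_set.clusters)
    sample_ids = [rep.sample_id for rep in repertoires]
    data = np.zeros((len(repertoires), n_clusters))
    for i, rep in enumerate(repertoires):
        total = rep.total_templates
        if total == 0:
            continue
        for r in rep.records:
            cid = lookup.get(r.cdr3_aa)
            if cid is not None:
                data[i, cid] += r.count / total
    abundance = pd.DataFrame(
        data, index=pd.Index(sample_ids, name="sample_id"),
        columns=[c.cluster_id for c in cluster_set.clusters],
    )
    return ClusterMatrix(abundance=abundance)


def cluster_gini_per_sample(matrix: ClusterMatrix) -> pd.Series:
    """Gini of each sample's nonzero cluster abundances (NaN if none)."""
    out = {}
    for sid, row in matrix.abundance.iterrows():
        nz = row[row > 0].to_numpy()
        if nz.size == 0:
            logger.warning("sample %s carries no clusters; Gini undefined", sid)
            out[sid] = float("nan")
        else:
            out[sid] = gini(nz)
    return pd.Series(out, name="cluster_gini")


# ---------------------------------------------------------------------------
# persistence

def write_cluster_set(cluster_set: ClusterSet, path: str | Path) -> None:
    cluster_set.to_frame().to_csv(path, sep="\t", index=False)


def write_cluster_matrix(matrix: ClusterMatrix, prefix: str | Path) -> None:
    """MatrixMarket sparse abundance + row/column label files."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(matrix.abundance.to_numpy()))
    Path(str(prefix) + ".rows.txt").write_text(
        "\n".join(map(str, matrix.abundance.index)) + "\n"
    )
    Path(str(prefix) + ".cols.txt").write_text(
        "\n".join(map(str, matrix.abundance.columns)) + "\n"
    )


def read_cluster_set(path: str | Path) -> ClusterSet:
    df = pd.read_csv(path, sep="\t", dtype={"member": str, "motif": str})
    clusters = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        clusters.append(
            Cluster(
                cluster_id=int(cid),
                members=frozenset(grp["member"]),
                motif=str(grp["motif"].iloc[0]),
            )
        )
    return ClusterSet(clusters=clusters)
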