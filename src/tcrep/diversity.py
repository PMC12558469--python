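"""Depth normalization and clonality estimation.

Sequencing depth varies by orders of magnitude between samples, so clonality is
compared after downsampling every repertoire to a common template total — an
exact multivariate-hypergeometric draw of templates without replacement (no
probabilistic refit of the abundance model). Clonality itself is the Gini
coefficient of the clone-count distribution: 0 for a perfectly even repertoire,
values approaching 1 when a few clonotypes dominate.

Group comparisons use Wilcoxon rank-sum tests; because clonality rises with
age and patient groups skew older, an ordinary-least-squares model of Gini on
age plus diagnosis indicators (healthy as reference) provides the age-adjusted
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io import Repertoire, ClonotypeRecord

logger = logging.getLogger(__name__)


class DownsampleError(ValueError):
    """Requested downsampling target exceeds a sample's template total."""


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample clonality summary."""

    sample_id: str
    n_unique: int
    gini_raw: float
    gini_downsampled: float


# ---------------------------------------------------------------------------

def downsample(rep: Repertoire, target: int, seed: int) -> Repertoire:
    """Draw exactly ``target`` templates without replacement from a repertoire.

    The draw is multivariate hypergeometric over the expanded template pool;
    clonotypes are reduced to their sampled counts and zero-count clonotypes
    dropped. The output total always equals ``target``.
    """
    total = rep.total_templates
    if target > total:
        raise DownsampleError(
            f"sample {rep.sample_id}: target {target} exceeds total templates {total}"
        )
    if target == total:
        return Repertoire(sample_id=rep.sample_id, records=list(rep.records))
    rng = np.random.default_rng(seed)
    counts = np.array([r.count for r in rep.records], dtype=np.int64)
    sampled = rng.multivariate_hypergeometric(counts, target)
    records = [
        ClonotypeRecord(
            cdr3_aa=r.cdr3_aa,
            count=int(c),
            productive=r.productive,
            v_call=r.v_call,
            j_call=r.j_call,
        )
        for r, c in zip(rep.records, sampled)
        if c > 0
    ]
    return Repertoire(sample_id=rep.sample_id, records=records)


def gini(counts) -> float:
    """Gini coefficient of a positive count vector (population form).

    Sorted form ``sum_i (2i - n - 1) x_(i) / (n * sum(x))`` with 1-based ranks
    over ascending-sorted values; algebraically equal to the pairwise mean
    absolute difference divided by twice the mean, with no small-sample
    correction. Scale-invariant; 0 iff all counts are equal.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(x <= 0):
        raise ValueError("counts must be strictly positive (drop zeros upstream)")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum((2.0 * i - n - 1.0) * xs) / (n * xs.sum()))


# ---------------------------------------------------------------------------
# rank tests

def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when ``n_x + n_y <= 20`` and there are no ties, otherwise
    the normal approximation with tie-corrected variance and continuity
    correction. Returns the Mann–Whitney U statistic of ``x`` and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    exact = (x.size + y.size <= 20) and not _has_ties(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(1.0, res.pvalue))


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences (zeros dropped).

    Exact null distribution for n ≤ 15 non-zero differences, otherwise the
    normal approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    exact = d.size <= 15 and not _has_ties(np.abs(d))
    if exact:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.statistic), float(min(1.0, res.pvalue))


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("spearman: zero rank variance; correlation undefined")
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# age-adjusted group model

@dataclass(frozen=True)
class GroupAgeModel:
    """OLS fit of clonality on age + diagnosis-group contrasts."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    rsquared: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "stderr": self.bse, "p": self.pvalues}
        )


def fit_group_age_model(gini_values, age, group, reference: str = "healthy") -> GroupAgeModel:
    """OLS of Gini on age plus group indicators (``reference`` as baseline).

    Raises on a rank-deficient design, naming the collinear columns.
    """
    g = np.asarray(gini_values, dtype=float)
    age = np.asarray(age, dtype=float)
    group = pd.Series(list(group), dtype="object")
    levels = [reference] + sorted(set(group) - {reference})
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    X = pd.DataFrame({"intercept": np.ones(len(g)), "age": age})
    for lev in levels[1:]:
        X[f"group[{lev}]"] = (group == lev).astype(float).to_numpy()
    if len(g) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        cols: list[str] = []
        for c in X.columns:
            cols.append(c)
            if np.linalg.matrix_rank(X[cols].to_numpy()) < len(cols):
                bad.append(c)
                cols.pop()
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(g, X).fit()
    return GroupAgeModel(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        nobs=int(fit.nobs),
        rsquared=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# cohort-level driver

def diversity_table(
    repertoires: list[Repertoire], target: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample clonality before and after common-depth downsampling.

    ``target`` defaults to the cohort minimum template total (the deepest
    normalization every sample can support). One seeded draw per sample.
    """
    totals = {r.sample_id: r.total_templates for r in repertoires}
    if target is None:
        target = min(totals.values())
    rows = []
    for i, rep in enumerate(repertoires):
        counts = np.array([r.count for r in rep.records], dtype=float)
        down = downsample(rep, target, seed=seed + i)
        down_counts = np.array([r.count for r in down.records], dtype=float)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "total_templates": totals[rep.sample_id],
                "n_unique": down.n_clonotypes,
                "gini_raw": gini(counts),
                "gini_downsampled": gini(down_counts),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def group_comparisons(div: pd.DataFrame, groups: pd.Series, column: str = "gini_downsampled") -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of clonality between groups."""
    levels = sorted(groups.unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            xa = div.loc[groups[groups == a].index, column].to_numpy()
            xb = div.loc[groups[groups == b].index, column].to_numpy()
            stat, p = wilcoxon_rank_sum(xa, xb)
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
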