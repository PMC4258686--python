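"""Enterotype clustering: PAM on a distance matrix with CH/SI model selection.

The partitioning-around-medoids (PAM) implementation is the classical
Kaufman–Rousseeuw BUILD + SWAP algorithm operating directly on a
precomputed distance matrix, with deterministic lowest-index tie-breaking,
so results are reproducible without a random seed.

The number of clusters is chosen by maximizing a medoid-based
Calinski–Harabasz pseudo F-statistic over a scanned k range; the mean
silhouette width qualifies the quality of the chosen partition (using the
Kaufman–Rousseeuw support bands) but never overrides the CH choice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .distances import DistanceMatrix
from .io_core import AbundanceTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ("Bacteroides", "Prevotella")


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    """Index of the nearest medoid per sample (ties -> lowest medoid index)."""
    med = sorted(medoids)
    return np.argmin(D[:, med], axis=1), med


def _cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, sorted(medoids)].min(axis=1).sum())


def pam_cluster(dm: DistanceMatrix, k: int) -> tuple[list[int], np.ndarray, float]:
    """Partition around medoids: greedy BUILD then exhaustive SWAP.

    Returns ``(medoid_indices, assignments, total_cost)`` where assignments
    are cluster indices 0..k-1 ordered by ascending medoid sample index and
    total_cost is the summed distance of every sample to its medoid.
    Deterministic: all ties break toward the lowest sample index.
    """
    n = dm.n
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    D = dm.D

    # BUILD: seed with the sample minimizing total distance, then greedily
    # add the point yielding the largest cost reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: apply the best strictly improving (medoid, non-medoid) exchange
    # until none exists.
    current = _cost(D, medoids)
    improved = True
    while improved:
        improved = False
        best = (current, None, None)
        medoid_set = set(medoids)
        for m in sorted(medoid_set):
            others = [x for x in medoids if x != m]
            for h in range(n):
                if h in medoid_set:
                    continue
                c = _cost(D, others + [h])
                if c < best[0] - 1e-12:
                    best = (c, m, h)
        if best[1] is not None:
            medoids = [x for x in medoids if x != best[1]] + [best[2]]
            current = best[0]
            improved = True

    assignments, med = _assign(D, medoids)
    # medoids must sit in their own cluster even under distance ties
    for ci, m in enumerate(med):
        assignments[m] = ci
    return med, assignments, _cost(D, medoids)


def pam_exhaustive(dm: DistanceMatrix, k: int) -> tuple[list[int], float]:
    """Globally optimal medoid set by brute-force search (small n only)."""
    n = dm.n
    best_cost, best_set = np.inf, None
    for combo in itertools.combinations(range(n), k):
        c = _cost(dm.D, list(combo))
        if c < best_cost - 1e-12:
            best_cost, best_set = c, list(combo)
    return best_set, float(best_cost)


# ---------------------------------------------------------------------------
# cluster-quality indices
# ---------------------------------------------------------------------------


def _cluster_medoid(D: np.ndarray, members: np.ndarray) -> int:
    """Member minimizing total distance to the other members (ties -> lowest index)."""
    sub = D[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def ch_index(dm: DistanceMatrix, assignments: np.ndarray) -> float:
    """Medoid-based Calinski–Harabasz pseudo F-statistic on a distance matrix.

    W sums squared distances of samples to their cluster medoid; B sums, per
    cluster, the size-weighted squared distance of the cluster medoid to the
    overall medoid (the sample minimizing total distance to all samples).
    CH = [B/(k-1)] / [W/(n-k)].  A zero within-cluster dispersion returns
    +inf.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    k, n = len(labels), dm.n
    if k < 2:
        raise ValidationError("CH undefined for one cluster")
    D = dm.D
    overall = int(np.argmin(D.sum(axis=1)))
    W = 0.0
    B = 0.0
    for lab in labels:
        members = np.flatnonzero(assignments == lab)
        med = _cluster_medoid(D, members)
        W += float((D[members, med] ** 2).sum())
        B += len(members) * float(D[med, overall] ** 2)
    if W == 0.0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


SUPPORT_BANDS = (
    (0.25, "no support"),
    (0.50, "weak support"),
    (0.75, "reasonable support"),
    (np.inf, "strong support"),
)


def support_category(si: float) -> str:
    """Kaufman–Rousseeuw interpretation band for a mean silhouette width."""
    for upper, name in SUPPORT_BANDS:
        if si <= upper:
            return name
    return "strong support"  # pragma: no cover


def silhouette_index(dm: DistanceMatrix, assignments: np.ndarray) -> tuple[float, np.ndarray, str]:
    """Mean silhouette width, per-sample widths, and the support category.

    Uses the standard s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the
    mean distance to the sample's own cluster (excluding itself); singleton
    clusters score 0.
    """
    assignments = np.asarray(assignments)
    if len(np.unique(assignments)) < 2:
        raise ValidationError("silhouette undefined for one cluster")
    widths = silhouette_samples(dm.D, assignments, metric="precomputed")
    si = float(widths.mean())
    return si, widths, support_category(si)


# ---------------------------------------------------------------------------
# model selection and labeling
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    """Outcome of the k scan on one distance metric."""

    metric: str
    sample_ids: list[str]
    records: list[dict] = field(default_factory=list)  # per-k: k, medoids, assignments, ch, si
    selected_k: int = 0
    labels: pd.Series | None = None  # canonical enterotype labels, 1-based
    silhouette_widths: pd.Series | None = None
    support: str = ""

    @property
    def assignments(self) -> np.ndarray:
        return self.labels.to_numpy()

    def record_for(self, k: int) -> dict:
        for rec in self.records:
            if rec["k"] == k:
                return rec
        raise KeyError(k)

    def medoid_ids(self) -> list[str]:
        return [self.sample_ids[m] for m in self.record_for(self.selected_k)["medoids"]]

    def assignment_frame(self) -> pd.DataFrame:
        if self.labels is None:
            return pd.DataFrame(columns=["sample_id", "enterotype", "cluster", "silhouette_width"])
        rec = self.record_for(self.selected_k)
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "enterotype": self.labels.to_numpy(),
                "cluster": rec["assignments"],
                "silhouette_width": self.silhouette_widths.to_numpy(),
            }
        )

    def scan_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"k": r["k"], "ch": r["ch"], "si": r["si"]} for r in self.records]
        )


def select_k(dm: DistanceMatrix, k_min: int = 2, k_max: int | None = None) -> ClusteringResult:
    """Run PAM over a range of k and select the CH-maximizing cluster number.

    Ties in CH break toward the smaller k (parsimony).  The silhouette
    support category of the chosen partition is recorded alongside but never
    overrides the CH choice.
    """
    n = dm.n
    if k_max is None:
        k_max = min(10, n - 1)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValidationError(f"need 2 <= k_min <= k_max <= n-1; got [{k_min}, {k_max}], n={n}")
    result = ClusteringResult(metric=dm.metric, sample_ids=list(dm.sample_ids))
    for k in range(k_min, k_max + 1):
        medoids, assignments, cost = pam_cluster(dm, k)
        ch = ch_index(dm, assignments)
        si, widths, _ = silhouette_index(dm, assignments)
        result.records.append(
            {"k": k, "medoids": medoids, "assignments": assignments, "cost": cost,
             "ch": ch, "si": si, "widths": widths}
        )
    ch_values = [r["ch"] for r in result.records]
    best = int(np.argmax(ch_values))  # argmax returns the first (smallest k) on ties
    rec = result.records[best]
    result.selected_k = rec["k"]
    # provisional 1-based labels ordered by medoid index; label_enterotypes refines
    result.labels = pd.Series(rec["assignments"] + 1, index=result.sample_ids, name="enterotype")
    result.silhouette_widths = pd.Series(rec["widths"], index=result.sample_ids, name="silhouette_width")
    result.support = support_category(rec["si"])
    return result


def label_enterotypes(
    result: ClusteringResult,
    table: AbundanceTable,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> ClusteringResult:
    """Canonicalize cluster labels by marker-genus dominance.

    The cluster with the highest mean abundance of ``markers[0]`` (default
    *Bacteroides*) becomes enterotype 1, the highest-mean cluster for
    ``markers[1]`` (*Prevotella*) becomes 2, and so on in marker priority
    order; remaining clusters are labeled by decreasing size.  When no
    marker is present in the feature list, labels fall back to size order
    with a warning.
    """
    rec = result.record_for(result.selected_k)
    raw = rec["assignments"]
    clusters = list(np.unique(raw))
    df = table.data.loc[result.sample_ids]
    mapping: dict[int, int] = {}
    next_label = 1
    usable = [m for m in markers if m in df.columns]
    if not usable and markers:
        logger.warning("label_enterotypes: markers %s absent; labeling by cluster size", markers)
    for marker in usable:
        candidates = [c for c in clusters if c not in mapping]
        if not candidates:
            break
        means = {c: df.loc[raw == c, marker].mean() for c in candidates}
        winner = max(candidates, key=lambda c: (means[c], -c))
        mapping[winner] = next_label
        next_label += 1
    remaining = [c for c in clusters if c not in mapping]
    remaining.sort(key=lambda c: (-(raw == c).sum(), c))
    for c in remaining:
        mapping[c] = next_label
        next_label += 1
    result.labels = pd.Series(
        [mapping[c] for c in raw], index=result.sample_ids, name="enterotype"
    )
    return result


def cross_metric_agreement(a: pd.Series, b: pd.Series) -> tuple[bool, float]:
    """Best label-permutation agreement between two partitions of one sample set.

    Returns ``(exact_match, agreement_fraction)`` where agreement is
    maximized over all relabelings of ``b``.
    """
    if set(a.index) != set(b.index):
        raise ValidationError("partitions cover different sample sets")
    b = b.loc[a.index]
    labels_b = sorted(b.unique())
    best = 0.0
    for perm in itertools.permutations(sorted(set(a.unique()) | set(labels_b))):
        relabel = dict(zip(sorted(set(a.unique()) | set(labels_b)), perm))
        agree = float(np.mean(a.to_numpy() == np.array([relabel[x] for x in b])))
        best = max(best, agree)
    return bool(best == 1.0), best


@dataclass
class CrossTab:
    """Counts and percent-of-total for functional cluster x enterotype."""

    counts: pd.DataFrame  # rows: functional clusters (+Total), cols: enterotypes (+Total)
    percent: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.counts.index)
        for col in self.counts.columns:
            out[(str(col), "N")] = self.counts[col]
            out[(str(col), "%")] = self.percent[col].round(1)
        out.columns = pd.MultiIndex.from_tuples(out.columns)
        return out


def crosstab_enterotype_function(genus_labels: pd.Series, kegg_labels: pd.Series) -> CrossTab:
    """Cross-tabulate enterotypes against functional clusters with totals."""
    if set(genus_labels.index) != set(kegg_labels.index):
        raise ValidationError("label series cover different sample sets")
    kegg_labels = kegg_labels.loc[genus_labels.index]
    counts = pd.crosstab(
        kegg_labels.rename("functional_cluster"),
        genus_labels.rename("enterotype"),
        margins=True,
        margins_name="Total",
    )
    total = len(genus_labels)
    percent = counts / total * 100.0
    return CrossTab(counts=counts, percent=percent)
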