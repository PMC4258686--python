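"""Twin concordance, longitudinal persistency and permutation tests.

Concordance is scored per paired observation — an (MZ pair, time point) at
which both co-twins were sampled — as the fraction in which both co-twins
share the enterotype.  Persistency is scored per longitudinally sampled
subject as the fraction keeping its enterotype across the two time points.

Community similarity by relationship is probed by classifying every
unordered sample pair into exactly one of four sets (same subject over
time, co-twins at the same time, co-twins across times, unrelated
individuals) and comparing mean distances between sets with a two-sample
permutation test on the pooled distance values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io_core import TwinDesign, ValidationError, round_half_up


@dataclass
class PairedObservation:
    """Both co-twins of one MZ pair observed at one time point."""

    pair_id: str
    time_point: int
    sample_a: str
    sample_b: str
    enterotype_a: int
    enterotype_b: int

    @property
    def concordant(self) -> bool:
        return self.enterotype_a == self.enterotype_b


@dataclass
class RelationshipDistances:
    """Pairwise distances grouped by the relationship of the two samples."""

    self_over_time: np.ndarray
    twin_same_time: np.ndarray
    twin_diff_time: np.ndarray
    unrelated: np.ndarray

    def sizes(self) -> dict[str, int]:
        return {
            "self_over_time": len(self.self_over_time),
            "twin_same_time": len(self.twin_same_time),
            "twin_diff_time": len(self.twin_diff_time),
            "unrelated": len(self.unrelated),
        }


def paired_observations(design: TwinDesign, labels: pd.Series) -> list[PairedObservation]:
    """Build the (pair, time) observations at which both co-twins are sampled."""
    t = design.table.merge(
        labels.rename("enterotype"), left_on="sample_id", right_index=True, how="left"
    )
    if t["enterotype"].isna().any():
        missing = t.loc[t["enterotype"].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples without an enterotype label: {missing}")
    obs = []
    for (pair, tp), grp in t.groupby(["pair_id", "time_point"]):
        if grp["subject_id"].nunique() != 2:
            continue
        grp = grp.sort_values("subject_id")
        a, b = grp.iloc[0], grp.iloc[1]
        obs.append(
            PairedObservation(
                pair_id=str(pair),
                time_point=int(tp),
                sample_a=str(a["sample_id"]),
                sample_b=str(b["sample_id"]),
                enterotype_a=int(a["enterotype"]),
                enterotype_b=int(b["enterotype"]),
            )
        )
    obs.sort(key=lambda o: (o.pair_id, o.time_point))
    return obs


def concordance_rate(obs: list[PairedObservation]) -> tuple[int, int, float]:
    """(n_concordant, n_total, percent) over paired observations."""
    if not obs:
        raise ValidationError("no paired observations")
    n_conc = sum(o.concordant for o in obs)
    n_total = len(obs)
    return n_conc, n_total, round_half_up(100.0 * n_conc / n_total, 1)


def concordance_table(obs: list[PairedObservation]) -> pd.DataFrame:
    """Concordant/discordant paired-observation counts per enterotype."""
    rows = []
    enterotypes = sorted({o.enterotype_a for o in obs} | {o.enterotype_b for o in obs})
    n_total = len(obs)
    for e in enterotypes:
        n = sum(1 for o in obs if o.concordant and o.enterotype_a == e)
        rows.append({"enterotype": str(e), "concordant_n": n, "discordant_n": 0})
    n_disc = sum(1 for o in obs if not o.concordant)
    rows.append({"enterotype": "discordant", "concordant_n": 0, "discordant_n": n_disc})
    df = pd.DataFrame(rows).set_index("enterotype")
    df["total_n"] = df["concordant_n"] + df["discordant_n"]
    for col in ("concordant_n", "discordant_n", "total_n"):
        df[col.replace("_n", "_pct")] = (100.0 * df[col] / n_total).round(1)
    return df


def persistency_rate(
    design: TwinDesign, labels: pd.Series
) -> tuple[int, int, float, pd.DataFrame]:
    """Fraction of twice-sampled subjects keeping their enterotype.

    Returns ``(n_stable, n_longitudinal, percent, transition_counts)`` where
    transition_counts is the enterotype(t1) x enterotype(t2) table.
    """
    t = design.table.merge(
        labels.rename("enterotype"), left_on="sample_id", right_index=True, how="left"
    )
    if t["enterotype"].isna().any():
        missing = t.loc[t["enterotype"].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples without an enterotype label: {missing}")
    wide = t.pivot(index="subject_id", columns="time_point", values="enterotype")
    if 1 not in wide.columns or 2 not in wide.columns:
        raise ValidationError("no subjects sampled at both time points")
    both = wide.dropna(subset=[1, 2])
    if both.empty:
        raise ValidationError("no subjects sampled at both time points")
    e1, e2 = both[1].astype(int), both[2].astype(int)
    n_stable = int((e1 == e2).sum())
    n_long = len(both)
    transitions = pd.crosstab(e1.rename("t1"), e2.rename("t2"))
    labels_all = sorted(set(transitions.index) | set(transitions.columns))
    transitions = transitions.reindex(index=labels_all, columns=labels_all, fill_value=0)
    return n_stable, n_long, round_half_up(100.0 * n_stable / n_long, 1), transitions


def _design_arrays(dm: DistanceMatrix, design: TwinDesign) -> tuple[np.ndarray, ...]:
    t = design.table.set_index("sample_id")
    missing = [s for s in dm.sample_ids if s not in t.index]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    t = t.loc[dm.sample_ids]
    return (
        t["subject_id"].to_numpy(),
        t["pair_id"].to_numpy(),
        t["time_point"].to_numpy(),
    )


def _bucket_distances(
    D: np.ndarray, subj: np.ndarray, pair: np.ndarray, tp: np.ndarray
) -> RelationshipDistances:
    iu = np.triu_indices(len(subj), 1)
    d = D[iu]
    same_subj = (subj[:, None] == subj[None, :])[iu]
    same_pair = (pair[:, None] == pair[None, :])[iu]
    same_tp = (tp[:, None] == tp[None, :])[iu]
    return RelationshipDistances(
        self_over_time=d[same_subj],
        twin_same_time=d[~same_subj & same_pair & same_tp],
        twin_diff_time=d[~same_subj & same_pair & ~same_tp],
        unrelated=d[~same_pair],
    )


def relationship_distance_sets(dm: DistanceMatrix, design: TwinDesign) -> RelationshipDistances:
    """Classify every unordered sample pair by relationship and collect distances.

    Pairs sharing a subject go to ``self_over_time``; pairs sharing an MZ
    pair (but not a subject) split by time point into ``twin_same_time`` /
    ``twin_diff_time``; all cross-pair pairs are ``unrelated``.
    """
    subj, pair, tp = _design_arrays(dm, design)
    return _bucket_distances(dm.D, subj, pair, tp)


def permutation_test(
    x,
    y,
    n_perm: int = 10_000,
    alternative: str = "less",
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sample permutation test on the difference of means.

    The statistic is mean(x) - mean(y); the null is built by randomly
    re-splitting the pooled values into sets of the original sizes.  The
    add-one estimator p = (1 + #extreme) / (1 + n_perm) never returns 0.
    Returns ``(statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both distance sets must be non-empty")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if alternative not in ("less", "greater", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx, ntot = len(x), len(pooled)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    sum_x = perms[:, :nx].sum(axis=1)
    null = sum_x / nx - (pooled.sum() - sum_x) / (ntot - nx)
    if alternative == "less":
        extreme = np.sum(null <= observed + 1e-12)
    elif alternative == "greater":
        extreme = np.sum(null >= observed - 1e-12)
    else:
        extreme = np.sum(np.abs(null) >= abs(observed) - 1e-12)
    return observed, float((1 + extreme) / (1 + n_perm))


def subject_permutation_test(
    dm: DistanceMatrix,
    design: TwinDesign,
    sets: tuple[str, str] = ("twin_same_time", "unrelated"),
    n_perm: int = 1_000,
    alternative: str = "less",
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test that permutes design labels rather than distances.

    The naive :func:`permutation_test` treats every distance value as
    exchangeable, ignoring that distances sharing a sample are dependent.
    This variant instead permutes the assignment of (subject, pair, time)
    design rows to samples, rebuilds the relationship sets each round, and
    compares the mean-distance difference between the two named sets.
    Returns ``(statistic, p)`` with the add-one estimator.
    """
    valid = ("self_over_time", "twin_same_time", "twin_diff_time", "unrelated")
    if any(s not in valid for s in sets) or len(sets) != 2:
        raise ValidationError(f"sets must be two of {valid}, got {sets}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if alternative not in ("less", "greater", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    subj, pair, tp = _design_arrays(dm, design)
    rng = np.random.default_rng(seed)

    def stat(s, p, t) -> float:
        buckets = _bucket_distances(dm.D, s, p, t)
        a = getattr(buckets, sets[0])
        b = getattr(buckets, sets[1])
        if len(a) == 0 or len(b) == 0:
            raise ValidationError(f"empty relationship set among {sets}")
        return float(a.mean() - b.mean())

    observed = stat(subj, pair, tp)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(subj))
        null = stat(subj[perm], pair[perm], tp[perm])
        if alternative == "less":
            extreme += null <= observed + 1e-12
        elif alternative == "greater":
            extreme += null >= observed - 1e-12
        else:
            extreme += abs(null) >= abs(observed) - 1e-12
    return observed, float((1 + extreme) / (1 + n_perm))
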