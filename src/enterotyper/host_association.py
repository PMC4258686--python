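"""Enterotype-host associations: traits, diet, nutrient patterns.

Traits, food-group intakes and energy-adjusted nutrient intakes are each
compared between the two enterotypes with the Wilcoxon rank-sum test and
Benjamini-Hochberg correction applied within the variable family.  Nutrient
intakes are energy-adjusted by the residual method (standardized residuals
of an ordinary least-squares fit of each nutrient on total energy intake),
then optionally clustered hierarchically (Euclidean distance, average
linkage) and tested against the enterotype split with Fisher's exact test.
Enterotype-discordant co-twins are compared with the Wilcoxon signed-rank
test on within-pair differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from ._ranktests import rank_sum_p, signed_rank_p
from .io_core import MetadataTable, ValidationError
from .twin_longitudinal import PairedObservation

logger = logging.getLogger(__name__)

FAMILIES = ("trait", "food", "nutrient")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _family_cols(metadata: MetadataTable, family: str) -> list[str]:
    if family == "trait":
        return metadata.trait_cols
    if family == "food":
        return metadata.food_cols
    if family == "nutrient":
        return metadata.nutrient_cols
    raise ValidationError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _rank_sum_frame(values: pd.DataFrame, labels: pd.Series, family: str) -> pd.DataFrame:
    """Rank-sum test per column of ``values`` between the two label groups."""
    labels = labels.loc[labels.index.intersection(values.index)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly two enterotypes, got {groups}")
    rows = []
    for var in values.columns:
        col = values[var].reindex(labels.index).dropna()
        g1 = col[labels.loc[col.index] == groups[0]]
        g2 = col[labels.loc[col.index] == groups[1]]
        if len(g1) < 2 or len(g2) < 2:
            logger.warning("%s %r skipped: group sizes %d vs %d", family, var, len(g1), len(g2))
            continue
        p = rank_sum_p(g1.to_numpy(), g2.to_numpy())
        med1, med2 = g1.median(), g2.median()
        if med1 == med2:
            higher = 0
        else:
            higher = groups[0] if med1 > med2 else groups[1]
        rows.append(
            {
                "variable": var,
                "family": family,
                "n": len(g1) + len(g2),
                "statistic": float(
                    sp_stats.mannwhitneyu(g1, g2, alternative="two-sided").statistic
                ),
                "p": p,
                "higher_in": higher,
            }
        )
    df = pd.DataFrame(rows, columns=["variable", "family", "n", "statistic", "p", "higher_in"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df


def wilcoxon_association(
    metadata: MetadataTable, labels: pd.Series, family: str
) -> pd.DataFrame:
    """Per-variable two-sided rank-sum association with BH within the family.

    For the nutrient family, raw intakes are first energy-adjusted via
    :func:`energy_adjust`.  Variables with fewer than two non-missing values
    in either enterotype are skipped with a log entry.
    """
    if family == "nutrient":
        values = energy_adjust(metadata)
    else:
        cols = _family_cols(metadata, family)
        values = metadata.data[cols]
    return _rank_sum_frame(values, labels, family)


def energy_adjust(metadata: MetadataTable) -> pd.DataFrame:
    """Energy-adjusted nutrient intakes by the residual method.

    Each nutrient is regressed (OLS with intercept) on total energy intake
    over complete cases; the residuals are standardized to mean 0, sd 1
    (sample sd).  A zero-variance residual column is returned as all zeros
    with a warning.
    """
    if metadata.energy_col is None or not metadata.nutrient_cols:
        raise ValidationError("metadata lacks an energy column or nutrient block")
    cols = [metadata.energy_col] + metadata.nutrient_cols
    complete = metadata.data[cols].dropna()
    if len(complete) < 3:
        raise ValidationError(f"need >= 3 complete cases, got {len(complete)}")
    energy = complete[metadata.energy_col].to_numpy()
    X = np.column_stack([np.ones_like(energy), energy])
    out = {}
    for nutrient in metadata.nutrient_cols:
        y = complete[nutrient].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            logger.warning("energy_adjust: zero-variance residuals for %r", nutrient)
            out[nutrient] = np.zeros_like(resid)
        else:
            out[nutrient] = (resid - resid.mean()) / sd
    return pd.DataFrame(out, index=complete.index)


def nutrient_cluster(
    residuals: pd.DataFrame,
    n_groups: int = 2,
    subset: list[str] | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """UPGMA clustering of samples on (a subset of) nutrient residuals.

    Returns ``(group_labels, linkage_matrix)`` with 1-based group labels and
    the SciPy average-linkage merge table on Euclidean distances.
    """
    if subset is not None:
        missing = [s for s in subset if s not in residuals.columns]
        if missing:
            raise ValidationError(f"subset nutrients absent: {missing}")
        residuals = residuals[subset]
    if len(residuals) < n_groups:
        raise ValidationError(f"need >= {n_groups} samples, got {len(residuals)}")
    Z = hierarchy.linkage(residuals.to_numpy(), method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return pd.Series(labels, index=residuals.index, name="diet_group"), Z


def fisher_association(groups: pd.Series, enterotypes: pd.Series) -> tuple[float, float, pd.DataFrame]:
    """Two-sided Fisher exact test on the 2x2 group x enterotype table.

    Uses the probability-mass rule (sum over tables no more probable than
    the observed one).  Returns ``(odds_ratio, p, table)``.
    """
    shared = groups.index.intersection(enterotypes.index)
    table = pd.crosstab(groups.loc[shared], enterotypes.loc[shared])
    if table.shape != (2, 2):
        raise ValidationError(f"need a 2x2 table, got shape {table.shape}")
    odds, p = sp_stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return float(odds), float(p), table


def discordant_twin_test(
    metadata: MetadataTable,
    obs: list[PairedObservation],
    families: tuple[str, ...] = FAMILIES,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Signed-rank tests on within-pair differences of discordant co-twins.

    For each variable the difference is taken as (enterotype-2 twin minus
    enterotype-1 twin) per discordant paired observation; zero differences
    are dropped.  BH is applied within family and significance is flagged
    at the given FDR.
    """
    discordant = [o for o in obs if not o.concordant]
    if len(discordant) < 2:
        raise ValidationError("need >= 2 discordant paired observations")
    rows = []
    for family in families:
        cols = _family_cols(metadata, family)
        if family == "nutrient" and cols:
            values = energy_adjust(metadata)
        else:
            values = metadata.data[cols] if cols else pd.DataFrame(index=metadata.data.index)
        for var in values.columns:
            diffs = []
            for o in discordant:
                hi = o.sample_a if o.enterotype_a > o.enterotype_b else o.sample_b
                lo = o.sample_b if o.enterotype_a > o.enterotype_b else o.sample_a
                if hi in values.index and lo in values.index:
                    d = values.loc[hi, var] - values.loc[lo, var]
                    if pd.notna(d):
                        diffs.append(float(d))
            if len(diffs) < 2:
                logger.warning("discordant test: %r skipped (n=%d)", var, len(diffs))
                continue
            if all(d == 0 for d in diffs):
                logger.warning("discordant test: %r all-zero differences", var)
                p, n_used = 1.0, 0
            else:
                p, n_used = signed_rank_p(diffs)
            rows.append(
                {
                    "variable": var,
                    "family": family,
                    "n_pairs": len(diffs),
                    "n_nonzero": n_used,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows, columns=["variable", "family", "n_pairs", "n_nonzero", "p"])
    if len(df):
        adj = np.empty(len(df))
        for family in df["family"].unique():
            mask = (df["family"] == family).to_numpy()
            adj[mask] = bh_adjust(df.loc[mask, "p"].to_numpy())
        df["p_adj"] = adj
        df["significant"] = df["p_adj"] < fdr
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
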