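"""Tabular I/O for the enterotyping pipeline.

Three table kinds flow through the pipeline:

* relative-abundance tables (samples x features, genus- or KEGG-level),
* a twin design table mapping samples to subjects, MZ pairs and time points,
* a host metadata table carrying clinical traits, food-group intakes and
  nutrient intakes.

All on-disk formats are plain TSV with a header row; lines starting with
``#`` are ignored, except a leading ``#``-prefixed header (the MetaPhlAn
merged-table convention), which is used as the header after stripping the
marker.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("genus", "kegg_pathway", "kegg_module")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (conventional reporting, not banker's)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ValidationError(ValueError):
    """Raised when a table violates its structural contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x features non-negative abundance matrix.

    ``data`` is indexed by sample id with one column per feature (genus name
    or KEGG pathway/module id). Values may be raw relative abundances on any
    scale; :func:`enterotyper.distances.normalize_profiles` rescales each row
    to sum to one.
    """

    data: pd.DataFrame
    level: str = "genus"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance at sample {self.data.index[bad[0]]!r}, "
                f"feature {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[bad[0]]!r}, "
                f"feature {self.data.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), level=self.level)


@dataclass
class TwinDesign:
    """Maps each sample to its subject, MZ twin pair and sampling time point.

    Each subject may be sampled at time points 1 and 2; every pair id covers
    exactly two subjects (monozygotic co-twins).
    """

    table: pd.DataFrame  # columns: sample_id, subject_id, pair_id, time_point

    REQUIRED = ("sample_id", "subject_id", "pair_id", "time_point")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in design")
        dup = t.duplicated(subset=["subject_id", "time_point"])
        if dup.any():
            rows = t.loc[dup, ["subject_id", "time_point"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (subject, time_point) rows: {rows}")
        bad_tp = set(t["time_point"]) - {1, 2}
        if bad_tp:
            raise ValidationError(f"time_point must be 1 or 2, got {sorted(bad_tp)}")
        sizes = t.groupby("pair_id")["subject_id"].nunique()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValidationError(
                f"each pair must have exactly 2 subjects; offending pairs: {dict(bad)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.table["pair_id"].unique().tolist())

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()

    def longitudinal_subjects(self) -> list[str]:
        """Subjects sampled at both time points."""
        counts = self.table.groupby("subject_id")["time_point"].nunique()
        return sorted(counts[counts == 2].index.tolist())

    def summary(self) -> dict:
        both_times = self.longitudinal_subjects()
        pair_tp = self.table.groupby(["pair_id", "time_point"])["subject_id"].nunique()
        paired_obs = int((pair_tp == 2).sum())
        return {
            "n_samples": len(self.table),
            "n_subjects": self.table["subject_id"].nunique(),
            "n_pairs": self.n_pairs,
            "n_longitudinal_subjects": len(both_times),
            "n_paired_observations": paired_obs,
        }


@dataclass
class MetadataTable:
    """Host metadata: clinical traits, food-group intakes and nutrient intakes.

    Column families are tracked explicitly so downstream multiple-testing
    correction can be applied within family.  Missing values stay as NaN and
    are never imputed; analyses use complete cases and log the n used.
    """

    data: pd.DataFrame  # indexed by sample_id
    trait_cols: list[str] = field(default_factory=list)
    food_cols: list[str] = field(default_factory=list)
    nutrient_cols: list[str] = field(default_factory=list)
    energy_col: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        for fam, cols in (("food", self.food_cols), ("nutrient", self.nutrient_cols)):
            if not cols:
                continue
            block = self.data[cols].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if (block < 0).any():
                    raise ValidationError(f"negative value in {fam} block")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def complete_cases(self, cols: Sequence[str]) -> pd.DataFrame:
        sub = self.data[list(cols)].dropna()
        dropped = len(self.data) - len(sub)
        if dropped:
            logger.info("metadata: using %d complete cases (%d dropped)", len(sub), dropped)
        return sub


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV keeping a '#'-prefixed first header line, skipping other '#' lines."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    kept: list[str] = []
    header_seen = False
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#"):
            if not header_seen and "\t" in line:
                kept.append(line.lstrip("#"))
                header_seen = True
            continue
        header_seen = True
        kept.append(line)
    if not kept:
        raise ValidationError(f"{path}: empty table")
    return pd.read_csv(io.StringIO("\n".join(kept)), sep="\t", index_col=0)


def _looks_like_clade(label: str) -> bool:
    return "|" in label or "__" in label


def read_abundance_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    level: str = "genus",
    orientation: str | None = None,
) -> AbundanceTable:
    """Read an abundance table, returning it oriented samples x features.

    Parameters
    ----------
    dialect:
        ``plain_tsv`` — numeric matrix with a header row; orientation is
        auto-detected (clade-like row labels imply features-as-rows, a
        ``sample_id``/``#SampleID`` index header implies samples-as-rows)
        unless ``orientation`` overrides it.
        ``metaphlan_merged`` — MetaPhlAn merged table (features as rows,
        clade strings like ``k__...|g__Bacteroides``); only genus-level rows
        are retained and clade prefixes are stripped to the bare genus name.
    orientation:
        ``"samples"`` or ``"features"`` — what the on-disk *rows* are.
    """
    df = _read_tsv(path)
    if dialect == "metaphlan_merged":
        mask = [
            "g__" in str(ix) and not any(r in str(ix).split("g__")[-1] for r in ("s__", "t__"))
            for ix in df.index
        ]
        df = df.loc[mask]
        df.index = [str(ix).split("g__")[-1].strip("|") for ix in df.index]
        df = df.T  # -> samples x genera
    elif dialect == "plain_tsv":
        if orientation is None:
            index_name = (df.index.name or "").lstrip("#").lower()
            if index_name in ("sampleid", "sample_id", "sample"):
                orientation = "samples"
            elif any(_looks_like_clade(str(ix)) for ix in df.index):
                orientation = "features"
            else:
                orientation = "samples"
        if orientation == "features":
            df = df.T
        elif orientation != "samples":
            raise ValidationError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric abundance body ({exc})") from exc
    return AbundanceTable(df, level=level)


def read_twin_design(path: str | Path) -> TwinDesign:
    df = _read_tsv(path).reset_index()
    df["time_point"] = df["time_point"].astype(int)
    for col in ("sample_id", "subject_id", "pair_id"):
        df[col] = df[col].astype(str)
    design = TwinDesign(df[list(TwinDesign.REQUIRED)])
    logger.info("design: %s", design.summary())
    return design


def read_metadata(
    path: str | Path,
    trait_cols: Sequence[str] | None = None,
    food_cols: Sequence[str] | None = None,
    nutrient_cols: Sequence[str] | None = None,
    energy_col: str | None = None,
) -> MetadataTable:
    """Read a metadata table indexed by sample id.

    When the column families are not given explicitly they are inferred from
    the naming convention the simulator writes: ``food_*`` columns form the
    food block, ``nutrient_*`` the nutrient block, ``energy`` the energy
    column, everything else a clinical trait.
    """
    df = _read_tsv(path)
    df.index = df.index.map(str)
    if trait_cols is None and food_cols is None and nutrient_cols is None:
        food_cols = [c for c in df.columns if c.startswith("food_")]
        nutrient_cols = [c for c in df.columns if c.startswith("nutrient_")]
        if energy_col is None and "energy" in df.columns:
            energy_col = "energy"
        special = set(food_cols) | set(nutrient_cols) | ({energy_col} if energy_col else set())
        trait_cols = [c for c in df.columns if c not in special]
    return MetadataTable(
        df,
        trait_cols=list(trait_cols or []),
        food_cols=list(food_cols or []),
        nutrient_cols=list(nutrient_cols or []),
        energy_col=energy_col,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_twin_design(design: TwinDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_assignments(result, path: str | Path) -> None:
    """Write a ClusteringResult's final assignment as TSV.

    Columns: sample_id, enterotype (canonical label), cluster (raw PAM
    cluster index) and per-sample silhouette width.  Round-trips losslessly
    through :func:`read_assignments`.
    """
    df = result.assignment_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_assignments(path: str | Path) -> pd.Series:
    """Read enterotype labels keyed by sample id from an assignment TSV."""
    df = _read_tsv(path).reset_index()
    df["sample_id"] = df["sample_id"].astype(str)
    return df.set_index("sample_id")["enterotype"].astype(int)


# ---------------------------------------------------------------------------
# joint consistency
# ---------------------------------------------------------------------------


def align_samples(
    abundance: AbundanceTable,
    design: TwinDesign,
    metadata: MetadataTable | None = None,
) -> list[str]:
    """Intersect the sample sets of the joined tables, logging dropped ids.

    Returns the shared sample ids in the abundance table's order.
    """
    sets = [set(abundance.sample_ids), set(design.sample_ids)]
    if metadata is not None:
        sets.append(set(metadata.sample_ids))
    shared = set.intersection(*sets)
    for name, ids in (
        ("abundance", abundance.sample_ids),
        ("design", design.sample_ids),
        ("metadata", metadata.sample_ids if metadata is not None else None),
    ):
        if ids is None:
            continue
        dropped = sorted(set(ids) - shared)
        if dropped:
            logger.warning("align: dropping %d %s-only samples: %s", len(dropped), name, dropped)
    return [s for s in abundance.sample_ids if s in shared]
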