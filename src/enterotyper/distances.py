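"""Inter-sample community distances and principal coordinate analysis.

Three beta-diversity metrics are supported on relative-abundance profiles:

* ``js`` — Jensen–Shannon distance, the square root of the Jensen–Shannon
  divergence computed in log base 2 so distances are bounded by 1 (sqrt-JSD
  is a true metric);
* ``bc`` — Bray–Curtis dissimilarity;
* ``eu`` — Euclidean distance on the relative abundances.

JS requires strictly positive profiles, so :func:`normalize_profiles` adds a
small pseudocount before renormalizing each sample to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import rel_entr

from .io_core import AbundanceTable, ValidationError

METRICS = ("js", "bc", "eu")


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise distance matrix with sample labels."""

    sample_ids: list[str]
    D: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.isfinite(self.D).all():
            raise ValidationError("non-finite distances")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(self.D)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        if (self.D < -1e-12).any():
            raise ValidationError("negative distances")
        # enforce exact structural invariants after numeric tolerance checks
        self.D = (self.D + self.D.T) / 2.0
        np.fill_diagonal(self.D, 0.0)
        self.D = np.clip(self.D, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids)

    def loc(self, a: str, b: str) -> float:
        ia = self.sample_ids.index(a)
        ib = self.sample_ids.index(b)
        return float(self.D[ia, ib])


def normalize_profiles(table: AbundanceTable, pseudocount: float = 1e-6) -> AbundanceTable:
    """Add a pseudocount to every entry and renormalize each sample to sum 1.

    With ``pseudocount > 0`` the output is strictly positive, as the JS
    distance requires.  Raises if any sample row is all zero.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    values = table.values
    row_sums = values.sum(axis=1)
    if pseudocount == 0 and (row_sums == 0).any():
        bad = table.sample_ids[int(np.argmax(row_sums == 0))]
        raise ValidationError(f"all-zero abundance row for sample {bad!r}")
    shifted = values + pseudocount
    normalized = shifted / shifted.sum(axis=1, keepdims=True)
    df = pd.DataFrame(normalized, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, level=table.level)


def _js_distance_matrix(X: np.ndarray, base: float) -> np.ndarray:
    """All-pairs sqrt Jensen-Shannon divergence, vectorized over pairs."""
    n = X.shape[0]
    D = np.zeros((n, n))
    log_base = np.log(base)
    for i in range(n):
        p = X[i]
        Q = X[i + 1 :]
        if len(Q) == 0:
            continue
        M = (p + Q) / 2.0
        jsd = 0.5 * rel_entr(p, M).sum(axis=1) + 0.5 * rel_entr(Q, M).sum(axis=1)
        jsd = np.clip(jsd / log_base, 0.0, None)
        D[i, i + 1 :] = np.sqrt(jsd)
    return D + D.T


def pairwise_distance(table: AbundanceTable, metric: str = "js", base: float = 2.0) -> DistanceMatrix:
    """Compute all pairwise distances between the samples of an abundance table.

    For ``js`` the profiles must be strictly positive (apply
    :func:`normalize_profiles` with a pseudocount first); divergences are
    computed in log base ``base`` (default 2, bounding the distance by 1).
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    X = table.values
    if not np.isfinite(X).all():
        raise ValidationError("non-finite abundances")
    if metric == "js":
        if (X <= 0).any():
            raise ValidationError(
                "js distance requires strictly positive profiles; "
                "apply normalize_profiles with a pseudocount"
            )
        D = _js_distance_matrix(X, base=base)
    elif metric == "bc":
        D = squareform(pdist(X, metric="braycurtis"))
    else:
        D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(table.sample_ids, D, metric)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns the top
    ``n_axes`` coordinate columns scaled by the square roots of the
    non-negative eigenvalues.  Negative eigenvalues (possible for
    non-Euclidean metrics such as js and bc) are clamped to zero; their total
    magnitude is returned so the distortion can be reported.

    Returns ``(coordinates, eigenvalues, negative_eigenvalue_mass)``.
    """
    n = dm.n
    if not 1 <= n_axes <= n - 1:
        raise ValidationError(f"n_axes must be in [1, {n - 1}], got {n_axes}")
    A = -0.5 * dm.D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    eigvals_clamped = np.clip(eigvals, 0.0, None)
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals_clamped[:n_axes])
    frame = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    return frame, eigvals_clamped[:n_axes], neg_mass


# ---------------------------------------------------------------------------
# distance matrix I/O
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = dm.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_distance_matrix(path: str | Path, metric: str = "js") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), metric)


def write_phylip_lower(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a lower-triangle PHYLIP-style distance matrix."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{dm.n}\n")
        for i, sid in enumerate(dm.sample_ids):
            row = "\t".join(f"{dm.D[i, j]:.12g}" for j in range(i))
            fh.write(f"{sid}\t{row}\n" if row else f"{sid}\n")
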