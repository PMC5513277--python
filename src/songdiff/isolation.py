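"""Population-level distance matrices and Mantel / partial Mantel tests.

Song differentiation between populations is related to three
candidate drivers: geographic distance (great-circle km between
population coordinates), the number of dispersal barriers separating a
pair of populations along the mountain chain, and genetic
differentiation (a pairwise F_ST matrix supplied as input — it is
never estimated here).  Song distances come in two families computed
separately: spectral (Euclidean distance between population centroids
in retained principal-component space) and syntax (Euclidean distance
over mean SVI and mean versatility-category proportions).

Association between distance matrices is tested with the Mantel
permutation test (one-tailed positive by default, matching the
isolation-by-distance hypothesis) and its partial variant controlling
for a third matrix via residuals.  For small numbers of populations
the permutation null is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDistanceMatrix",
    "MantelResult",
    "UndefinedCorrelationError",
    "haversine_km",
    "geographic_distances",
    "barrier_distances",
    "spectral_distance_matrix",
    "syntax_distance_matrix",
    "mantel",
    "partial_mantel",
    "read_square_matrix",
]

EARTH_RADIUS_KM = 6371.0088


class UndefinedCorrelationError(ValueError):
    """A distance matrix is constant; the Mantel r is undefined."""


@dataclass
class LabeledDistanceMatrix:
    """Symmetric population × population distance with fixed label order."""

    labels: list[str]
    values: np.ndarray
    kind: str  # geographic_km, barrier_count, fst, song_spectral, song_syntax

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, labels: list[str]) -> "LabeledDistanceMatrix":
        """Reorder to a given label order (all labels must be present)."""
        idx = [self.labels.index(l) for l in labels]
        return LabeledDistanceMatrix(
            labels=list(labels), values=self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="population_id")


def read_square_matrix(path: str | Path, kind: str = "fst") -> LabeledDistanceMatrix:
    """Read a labeled square TSV or PHYLIP-style square matrix.

    Labeled TSV: header row of labels, first column of labels.
    PHYLIP style: first line the count n, then n lines of
    ``label v1 ... vn`` (whitespace-separated).
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0].split()
    if len(first) == 1 and first[0].isdigit():
        rows = path.read_text().strip().splitlines()
        n = int(rows[0].strip())
        labels, vals = [], []
        for line in rows[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            vals.append([float(x) for x in parts[1 : n + 1]])
        return LabeledDistanceMatrix(labels, np.array(vals), kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LabeledDistanceMatrix(
        labels=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        kind=kind,
    )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two lat/lon points, km."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distances(coords: pd.DataFrame) -> LabeledDistanceMatrix:
    """Pairwise great-circle distances from a table with columns
    ``population_id``, ``lat``, ``lon`` (decimal degrees)."""
    labels = [str(x) for x in coords["population_id"]]
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return LabeledDistanceMatrix(labels, D, "geographic_km")


def barrier_distances(
    zones: dict[str, int], binary: bool = False
) -> LabeledDistanceMatrix:
    """Barriers separating each pair of populations.

    Populations are assigned ordinal *zones* along the mountain chain,
    with exactly one barrier between consecutive zones; the entry for a
    pair is the number of barriers between their zones (``binary=True``
    collapses this to presence/absence of any barrier).
    """
    labels = list(zones)
    z = np.array([int(zones[l]) for l in labels])
    D = np.abs(z[:, None] - z[None, :]).astype(float)
    if binary:
        D = (D > 0).astype(float)
    return LabeledDistanceMatrix(labels, D, "barrier_count")


def spectral_distance_matrix(
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    pop_col: str = "population_id",
) -> LabeledDistanceMatrix:
    """Euclidean distance between population centroids in PC space."""
    if score_cols is None:
        score_cols = [c for c in scores.columns if c.startswith("PRIN")]
    counts = scores.groupby(pop_col).size()
    empty = counts[counts == 0]
    cent = scores.groupby(pop_col)[score_cols].mean()
    labels = [str(x) for x in cent.index]
    X = cent.to_numpy(dtype=float)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return LabeledDistanceMatrix(labels, D, "song_spectral")


def syntax_distance_matrix(summary: pd.DataFrame) -> LabeledDistanceMatrix:
    """Euclidean distance over per-population syntax means.

    ``summary`` is the long-format bootstrap summary (population,
    metric, mean, ...); the distance uses mean SVI plus the four mean
    category proportions.
    """
    wide = summary.pivot(index="population_id", columns="metric", values="mean")
    cols = ["svi", "prop_new", "prop_mod", "prop_old", "prop_same"]
    X = wide[cols].to_numpy(dtype=float)
    labels = [str(x) for x in wide.index]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    return LabeledDistanceMatrix(labels, D, "song_syntax")


@dataclass
class MantelResult:
    r: float
    pvalue: float
    permutations: int
    tail: str
    exhaustive: bool
    partial: bool = False
    control_kind: str | None = None


def _check_aligned(*mats: LabeledDistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError(
                "distance matrices are not label-aligned; call .align() first"
            )


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("constant distance matrix")
    return float((xc @ yc) / denom)


def _tail_count(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    eps = 1e-12
    if tail == "greater":
        return int(np.sum(r_perm >= r_obs - eps))
    if tail == "less":
        return int(np.sum(r_perm <= r_obs + eps))
    if tail == "two-sided":
        return int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))
    raise ValueError(f"unknown tail {tail!r}")


def _permuted_triangles(
    values: np.ndarray, perms: "list[tuple[int, ...]] | np.ndarray"
) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    out = np.empty((len(perms), len(iu[0])))
    for i, p in enumerate(perms):
        p = np.asarray(p)
        out[i] = values[np.ix_(p, p)][iu]
    return out


def _corr_rows(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of T with y (rows non-constant)."""
    Tc = T - T.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Tc**2).sum(axis=1) * (yc @ yc))
    return (Tc @ yc) / denom


def mantel(
    a: LabeledDistanceMatrix,
    b: LabeledDistanceMatrix,
    permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of association between two distance
    matrices.

    r is the Pearson correlation of the upper triangles.  The null is
    generated by jointly permuting rows and columns of ``b``.  When n!
    does not exceed ``permutations`` the null is enumerated over all
    n! relabelings and p is the exact fraction with r* at least as
    extreme (the identity included); otherwise ``permutations`` random
    relabelings are drawn and the add-one correction
    p = (1 + extreme) / (1 + permutations) is applied.
    """
    _check_aligned(a, b)
    n = a.n
    if n < 4:
        raise ValueError("need at least 4 populations for a Mantel test")
    xa, xb = a.condensed(), b.condensed()
    r_obs = _corr(xa, xb)
    n_fact = math.factorial(n)
    exhaustive = n_fact <= permutations
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        r_perm = _corr_rows(_permuted_triangles(b.values, perms), xa)
        p = _tail_count(r_perm, r_obs, tail) / n_fact
        n_used = n_fact
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(permutations)]
        r_perm = _corr_rows(_permuted_triangles(b.values, perms), xa)
        p = (1 + _tail_count(r_perm, r_obs, tail)) / (1 + permutations)
        n_used = permutations
    return MantelResult(
        r=r_obs, pvalue=float(p), permutations=n_used, tail=tail, exhaustive=exhaustive
    )


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    a: LabeledDistanceMatrix,
    b: LabeledDistanceMatrix,
    control: LabeledDistanceMatrix,
    permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel test of a ~ b controlling for a third matrix.

    r is the correlation of the residuals of a's and b's upper
    triangles after regressing each on the control's.  The null
    permutes a's rows/columns jointly, recomputing a's residuals on
    the control each time.
    """
    _check_aligned(a, b, control)
    n = a.n
    if n < 4:
        raise ValueError("need at least 4 populations for a partial Mantel test")
    xc = control.condensed()
    if np.allclose(xc, xc[0]):
        logger.warning("control matrix constant; partial Mantel reduces to Mantel")
        return mantel(a, b, permutations, seed, tail)
    xa, xb = a.condensed(), b.condensed()
    res_b = _residuals(xb, xc)
    r_obs = _corr(_residuals(xa, xc), res_b)
    n_fact = math.factorial(n)
    exhaustive = n_fact <= permutations
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        n_used = n_fact
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(permutations)]
        n_used = permutations
    tri = _permuted_triangles(a.values, perms)
    # residual of each permuted row on the control triangle, vectorized
    Xc = np.column_stack([np.ones_like(xc), xc])
    beta = np.linalg.lstsq(Xc, tri.T, rcond=None)[0]
    res_tri = tri - (Xc @ beta).T
    r_perm = _corr_rows(res_tri, res_b)
    if exhaustive:
        p = _tail_count(r_perm, r_obs, tail) / n_fact
    else:
        p = (1 + _tail_count(r_perm, r_obs, tail)) / (1 + permutations)
    return MantelResult(
        r=r_obs,
        pvalue=float(p),
        permutations=n_used,
        tail=tail,
        exhaustive=exhaustive,
        partial=True,
        control_kind=control.kind,
    )
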