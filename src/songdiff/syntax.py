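"""Song-type identity, bout versatility and the Song Variety Index.

Two syntax traits are computed from fixed-length bouts of consecutive
songs (default 11, the minimum available per individual in the study
design this pipeline targets):

* the **Song Variety Index (SVI)** — distinct song types divided by
  bout length, so SVI ranges from 1/n (one type repeated) to 1 (all
  distinct);
* **versatility in song organization** — each song in the bout is
  classed as ``new`` (novel type), ``mod`` (novel type that reuses a
  block of at least two note classes copied from an earlier song in
  the bout), ``old`` (a type already sung earlier but not immediately
  before) or ``same`` (an immediate repeat).

Song-type identity was originally a trained visual judgement; here it
is operationalized as an explicit rule so it can be reproduced: notes
are binned into classes on log duration × log bandwidth with a
relative tolerance (default 20%), absolute frequency position is
ignored (a transposed song is the same type), and maximal runs of two
or more consecutive identical classes — trills — are collapsed to a
single run marker, so trill elongation or shortening does not create a
new type.  Adding or removing a (non-trill) note does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import Song

__all__ = [
    "CATEGORIES",
    "DEFAULT_BOUT_SIZE",
    "DEFAULT_NOTE_TOLERANCE",
    "Signature",
    "BoutClassification",
    "SongTypeLibrary",
    "note_class",
    "song_signature",
    "signature_pairs",
    "select_bout",
    "classify_bout",
    "classify_signatures",
    "svi_of_signatures",
    "build_library",
    "bootstrap_ci",
    "bootstrap_summary",
    "svi_spectral_correlation",
    "UndefinedCorrelationError",
]

CATEGORIES = ("new", "mod", "old", "same")
DEFAULT_BOUT_SIZE = 11
DEFAULT_NOTE_TOLERANCE = 0.20

#: a signature element: (note class, is_trill_run)
Signature = tuple[tuple[tuple[int, int], bool], ...]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance input)."""


def note_class(
    duration: float, bandwidth: float, tolerance: float = DEFAULT_NOTE_TOLERANCE
) -> tuple[int, int]:
    """Bin a note into a (duration, bandwidth) class.

    Bins are uniform on the log scale with width ``log(1 + tolerance)``
    so two notes in one bin differ by at most ~`tolerance` relatively.
    Frequency *position* is deliberately absent: transposition must not
    change a note's class.
    """
    w = math.log1p(tolerance)
    return (int(round(math.log(duration) / w)), int(round(math.log(bandwidth) / w)))


def _collapse_runs(
    classes: Sequence[tuple[int, int]],
) -> Signature:
    out: list[tuple[tuple[int, int], bool]] = []
    i = 0
    while i < len(classes):
        j = i
        while j + 1 < len(classes) and classes[j + 1] == classes[i]:
            j += 1
        out.append((classes[i], j > i))  # run of >=2 -> trill marker
        i = j + 1
    return tuple(out)


def song_signature(
    song: Song, tolerance: float = DEFAULT_NOTE_TOLERANCE
) -> Signature:
    """Trill-collapsed, transposition-invariant note-composition signature."""
    classes = [note_class(n.duration, n.bandwidth, tolerance) for n in song.notes]
    return _collapse_runs(classes)


def signature_pairs(sig: Signature) -> set[tuple[tuple[int, int], tuple[int, int]]]:
    """Ordered consecutive note-class pairs of a collapsed signature.

    A shared pair is exactly a shared contiguous two-class block, the
    evidence required to call a novel song "mod" rather than "new".
    """
    cls = [c for c, _ in sig]
    return {(cls[i], cls[i + 1]) for i in range(len(cls) - 1)}


def select_bout(
    songs: Sequence[Song],
    n: int = DEFAULT_BOUT_SIZE,
    start: str | int = "first",
    rng: np.random.Generator | None = None,
) -> list[Song]:
    """Take ``n`` consecutive songs from one individual's ordered songs.

    ``start`` may be ``"first"`` (default), ``"random"`` (requires
    ``rng``; used by the random-start robustness diagnostic) or an
    explicit 0-based offset.  Raises ``ValueError`` when fewer than
    ``n`` songs are available — callers exclude such individuals.
    """
    if len(songs) < n:
        raise ValueError(
            f"individual has {len(songs)} songs; {n} consecutive songs required"
        )
    if start == "first":
        off = 0
    elif start == "random":
        if rng is None:
            raise ValueError("start='random' requires an rng")
        off = int(rng.integers(0, len(songs) - n + 1))
    else:
        off = int(start)
        if off < 0 or off + n > len(songs):
            raise ValueError(f"start offset {off} out of range")
    return list(songs[off : off + n])


@dataclass
class BoutClassification:
    """Versatility classification of one individual's bout."""

    individual_id: str
    population_id: str
    song_ids: list[str]
    signatures: list[Signature]
    categories: list[str]
    svi: float

    @property
    def n(self) -> int:
        return len(self.categories)

    def category_proportions(self) -> dict[str, float]:
        return {c: self.categories.count(c) / self.n for c in CATEGORIES}


def classify_signatures(signatures: Sequence[Signature]) -> tuple[list[str], float]:
    """Classify each song of a bout by signature and compute the SVI.

    Rules, applied in order for song *i* (the first song is ``new`` by
    convention):

    * ``same`` — signature equals the immediately preceding song's;
    * ``old``  — signature equals an earlier, non-adjacent song's;
    * ``mod``  — novel signature sharing a contiguous note-class block
      of length ≥ 2 with any earlier song in the bout;
    * ``new``  — otherwise.

    SVI = number of distinct signatures / bout length.
    """
    cats: list[str] = []
    seen_pairs: set = set()
    for i, sig in enumerate(signatures):
        if i == 0:
            cats.append("new")
        elif sig == signatures[i - 1]:
            cats.append("same")
        elif sig in signatures[:i]:
            cats.append("old")
        elif signature_pairs(sig) & seen_pairs:
            cats.append("mod")
        else:
            cats.append("new")
        seen_pairs |= signature_pairs(sig)
    svi = len(set(signatures)) / len(signatures)
    return cats, svi


def svi_of_signatures(signatures: Sequence[Signature]) -> float:
    return len(set(signatures)) / len(signatures)


def classify_bout(
    bout: Sequence[Song], tolerance: float = DEFAULT_NOTE_TOLERANCE
) -> BoutClassification:
    """Signature, category and SVI computation for one bout of songs."""
    sigs = [song_signature(s, tolerance) for s in bout]
    cats, svi = classify_signatures(sigs)
    return BoutClassification(
        individual_id=bout[0].individual_id,
        population_id=bout[0].population_id,
        song_ids=[s.song_id for s in bout],
        signatures=sigs,
        categories=cats,
        svi=svi,
    )


@dataclass
class SongTypeLibrary:
    """Equivalence classes of songs under the type-matching rules."""

    types: dict[str, Signature]  # type_id -> exemplar signature
    members: dict[str, list[tuple[str, str]]]  # type_id -> (individual, song)

    @property
    def n_types(self) -> int:
        return len(self.types)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, sig in self.types.items():
            rows.append(
                {
                    "type_id": tid,
                    "signature": _signature_str(sig),
                    "n_members": len(self.members[tid]),
                    "members": ";".join(
                        f"{ind}:{sid}" for ind, sid in self.members[tid]
                    ),
                }
            )
        return pd.DataFrame(rows)


def _signature_str(sig: Signature) -> str:
    return "|".join(
        f"{c[0]},{c[1]}{'*' if trill else ''}" for c, trill in sig
    )


def build_library(
    bouts: Sequence[BoutClassification],
) -> tuple[SongTypeLibrary, pd.DataFrame]:
    """Cluster bout signatures into a cross-population song-type library.

    Returns the library and an individual × individual sharing matrix
    whose off-diagonal entries count song types sung by both
    individuals (the diagonal holds each individual's repertoire size).
    """
    types: dict[str, Signature] = {}
    members: dict[str, list[tuple[str, str]]] = {}
    index: dict[Signature, str] = {}
    for b in bouts:
        for sid, sig in zip(b.song_ids, b.signatures):
            tid = index.get(sig)
            if tid is None:
                tid = f"T{len(index):04d}"
                index[sig] = tid
                types[tid] = sig
                members[tid] = []
            members[tid].append((b.individual_id, sid))
    inds = sorted({b.individual_id for b in bouts})
    share = pd.DataFrame(0, index=inds, columns=inds, dtype=int)
    for tid, mem in members.items():
        who = sorted({ind for ind, _ in mem})
        for a in who:
            for b_ in who:
                share.loc[a, b_] += 1
    return SongTypeLibrary(types=types, members=members), share


def bootstrap_ci(
    values: np.ndarray,
    b: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling the given units."""
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, values.size, size=(b, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def bootstrap_summary(
    bouts: Sequence[BoutClassification],
    b: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-population mean and bootstrap CI of SVI and the category
    proportions, resampling individuals within a population.

    Individuals are the unit of replication (each contributes one SVI
    and one set of proportions).  Populations with a single individual
    get a point estimate with ``ci_available = False``.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    per_ind = pd.DataFrame(
        [
            {
                "individual_id": x.individual_id,
                "population_id": x.population_id,
                "svi": x.svi,
                **{f"prop_{c}": x.category_proportions()[c] for c in CATEGORIES},
            }
            for x in bouts
        ]
    )
    metrics = ["svi"] + [f"prop_{c}" for c in CATEGORIES]
    for pop, grp in per_ind.groupby("population_id", sort=True):
        for m in metrics:
            vals = grp[m].to_numpy()
            row = {
                "population_id": pop,
                "metric": m,
                "n_individuals": len(vals),
                "mean": float(vals.mean()),
                "ci_available": len(vals) >= 2,
                "ci_level": level,
            }
            if len(vals) >= 2:
                row["ci_low"], row["ci_high"] = bootstrap_ci(vals, b, level, rng)
            else:
                row["ci_low"] = row["ci_high"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def svi_spectral_correlation(per_individual: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-individual SVI with mean song
    bandwidth and mean delivery rate.

    ``per_individual`` needs columns ``svi``, ``song_bandwidth`` and
    ``delivery_rate`` (one row per individual).  Returns r, df = n − 2
    and the two-sided p from the t transform for each pairing.
    """
    if len(per_individual) < 3:
        raise ValueError("need at least 3 individuals for a correlation")
    rows = []
    for col in ("song_bandwidth", "delivery_rate"):
        x = per_individual[col].to_numpy(dtype=float)
        y = per_individual["svi"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise UndefinedCorrelationError(
                f"zero variance in {col!r} or 'svi'"
            )
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"pair": f"svi~{col}", "r": float(r), "df": len(x) - 2, "p": float(p)}
        )
    return pd.DataFrame(rows)
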