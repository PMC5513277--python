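"""Song-level spectral features and complex-vocal-mechanism (CVM) signals.

Fourteen song-level variables are derived from the per-note times and
frequencies: means and SDs of note length, high frequency, low
frequency and note bandwidth; whole-song bandwidth and duration; note
count and delivery rate; and two CVM indicators.  The CVM indicators
count, per song, (i) internote intervals shorter than 2 ms — below the
minimum duration of a minibreath, the inhalation normally taken
between notes — and (ii) temporal overlaps between consecutive notes.
Either signal implies a complex vocal mechanism (two-voice use of both
syrinx sides, or nonlinear dynamics of one side; the two cannot be
told apart from annotations alone).  Both counts are scaled by the
number of notes in the song so that populations with longer songs are
not biased upward.

A companion per-pair table records the frequency shift between
consecutive notes (high frequency of a note minus low frequency of the
note before it), classed by whether the internote interval is below or
at/above the 2 ms threshold; a two-sample Kolmogorov–Smirnov test
compares the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import Song

__all__ = [
    "CVM_THRESHOLD_S",
    "FEATURE_NAMES",
    "SongFeatureVector",
    "DegenerateSongError",
    "InsufficientDataError",
    "internote_intervals",
    "cvm_counts",
    "extract_features",
    "features_table",
    "frequency_shifts",
    "shifts_table",
    "ks_compare_shifts",
]

#: default internote-interval threshold separating CVM-indicative pairs
#: (2 ms, stored in seconds to keep one unit system throughout)
CVM_THRESHOLD_S = 0.002

#: the 14 song-level spectral variables, in canonical column order
FEATURE_NAMES = (
    "mean_note_length",
    "sd_note_length",
    "mean_high_freq",
    "sd_high_freq",
    "mean_low_freq",
    "sd_low_freq",
    "mean_note_bandwidth",
    "sd_note_bandwidth",
    "song_bandwidth",
    "song_duration",
    "n_notes",
    "delivery_rate",
    "cvm_short_interval_rate",
    "cvm_overlap_rate",
)


class DegenerateSongError(ValueError):
    """Song duration is not positive; features are undefined."""


class InsufficientDataError(ValueError):
    """A statistical comparison has an empty class."""


@dataclass(frozen=True)
class SongFeatureVector:
    """The 14 spectral variables for one song, plus its labels.

    Times are seconds, frequencies Hz, delivery rate notes/second, and
    the two CVM rates are per-song counts divided by the note count.
    SDs over a single note are defined as 0 so one-note songs remain
    usable.
    """

    song_id: str
    individual_id: str
    population_id: str
    mean_note_length: float
    sd_note_length: float
    mean_high_freq: float
    sd_high_freq: float
    mean_low_freq: float
    sd_low_freq: float
    mean_note_bandwidth: float
    sd_note_bandwidth: float
    song_bandwidth: float
    song_duration: float
    n_notes: float
    delivery_rate: float
    cvm_short_interval_rate: float
    cvm_overlap_rate: float

    def as_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _sd(x: np.ndarray) -> float:
    # sample SD; a single observation has SD 0 by convention
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def internote_intervals(song: Song) -> np.ndarray:
    """Silence between consecutive notes: start(i+1) − end(i), seconds.

    Negative values mean the notes overlap in time.  A one-note song
    yields an empty array.
    """
    starts = np.array([n.start_time for n in song.notes])
    ends = np.array([n.end_time for n in song.notes])
    return starts[1:] - ends[:-1]


def cvm_counts(
    song: Song, threshold_s: float = CVM_THRESHOLD_S
) -> tuple[int, int]:
    """Count CVM-indicative consecutive-note pairs in a song.

    Returns ``(short_interval_count, overlap_count)`` where a *short
    interval* is a non-negative internote interval strictly below the
    threshold and an *overlap* is a strictly negative interval.  Each
    pair contributes to exactly one counter.
    """
    iv = internote_intervals(song)
    short = int(np.sum((iv >= 0) & (iv < threshold_s)))
    overlap = int(np.sum(iv < 0))
    return short, overlap


def extract_features(
    song: Song, cvm_threshold_s: float = CVM_THRESHOLD_S
) -> SongFeatureVector:
    """Derive the 14 song-level spectral variables from a song's notes."""
    durs = np.array([n.duration for n in song.notes])
    highs = np.array([n.high_freq for n in song.notes])
    lows = np.array([n.low_freq for n in song.notes])
    bws = highs - lows
    song_duration = song.end_time - song.start_time
    if song_duration <= 0:
        raise DegenerateSongError(
            f"song {song.song_id!r} has non-positive duration {song_duration}"
        )
    n = song.n_notes
    short, overlap = cvm_counts(song, cvm_threshold_s)
    return SongFeatureVector(
        song_id=song.song_id,
        individual_id=song.individual_id,
        population_id=song.population_id,
        mean_note_length=float(durs.mean()),
        sd_note_length=_sd(durs),
        mean_high_freq=float(highs.mean()),
        sd_high_freq=_sd(highs),
        mean_low_freq=float(lows.mean()),
        sd_low_freq=_sd(lows),
        mean_note_bandwidth=float(bws.mean()),
        sd_note_bandwidth=_sd(bws),
        song_bandwidth=float(highs.max() - lows.min()),
        song_duration=float(song_duration),
        n_notes=float(n),
        delivery_rate=float(n / song_duration),
        cvm_short_interval_rate=short / n,
        cvm_overlap_rate=overlap / n,
    )


def features_table(
    songs: Iterable[Song], cvm_threshold_s: float = CVM_THRESHOLD_S
) -> pd.DataFrame:
    """Feature vectors for many songs as one data frame (one row/song)."""
    rows = [extract_features(s, cvm_threshold_s).as_dict() for s in songs]
    return pd.DataFrame(rows)


def frequency_shifts(
    song: Song, cvm_threshold_s: float = CVM_THRESHOLD_S
) -> pd.DataFrame:
    """Per consecutive-note-pair frequency shifts with interval class.

    The shift for pair *i* is ``high_freq(note i) − low_freq(note i−1)``
    (Hz); the class is ``below_2ms`` when the internote interval used by
    the CVM counters is `< cvm_threshold_s` (including overlaps) and
    ``at_or_above_2ms`` otherwise (the boundary value falls in the
    upper class).
    """
    iv = internote_intervals(song)
    highs = np.array([n.high_freq for n in song.notes])
    lows = np.array([n.low_freq for n in song.notes])
    shift = highs[1:] - lows[:-1]
    cls = np.where(iv < cvm_threshold_s, "below_2ms", "at_or_above_2ms")
    return pd.DataFrame(
        {
            "song_id": song.song_id,
            "individual_id": song.individual_id,
            "population_id": song.population_id,
            "pair_index": np.arange(1, song.n_notes),
            "interval": iv,
            "shift": shift,
            "interval_class": cls,
        }
    )


def shifts_table(
    songs: Iterable[Song], cvm_threshold_s: float = CVM_THRESHOLD_S
) -> pd.DataFrame:
    """Pool per-song frequency-shift tables across a dataset."""
    parts = [frequency_shifts(s, cvm_threshold_s) for s in songs]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=[
                "song_id",
                "individual_id",
                "population_id",
                "pair_index",
                "interval",
                "shift",
                "interval_class",
            ]
        )
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    n_below: int
    n_at_or_above: int


def ks_compare_shifts(table: pd.DataFrame) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test of frequency shifts between
    the below-threshold and at/above-threshold interval classes.

    D is the supremum of the absolute ECDF difference; the p-value uses
    the asymptotic two-sample KS distribution.
    """
    below = table.loc[table["interval_class"] == "below_2ms", "shift"].to_numpy()
    above = table.loc[
        table["interval_class"] == "at_or_above_2ms", "shift"
    ].to_numpy()
    if below.size == 0 or above.size == 0:
        raise InsufficientDataError(
            "both interval classes must be non-empty for the KS comparison "
            f"(got {below.size} below, {above.size} at/above)"
        )
    res = stats.ks_2samp(below, above, method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_below=int(below.size),
        n_at_or_above=int(above.size),
    )
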