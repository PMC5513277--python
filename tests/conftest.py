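import numpy as np
import pandas as pd
import pytest

from songdiff import analyze_dataset, annotations, simulate
from songdiff.annotations import NoteRecord, Song


def make_song(
    spans,
    song_id="s1",
    individual_id="i1",
    population_id="p1",
):
    """Build a Song from (start, end, low, high) tuples (already ordered)."""
    notes = tuple(
        NoteRecord(
            population_id=population_id,
            individual_id=individual_id,
            song_id=song_id,
            start_time=float(a),
            end_time=float(b),
            low_freq=float(lo),
            high_freq=float(hi),
            note_index=i,
        )
        for i, (a, b, lo, hi) in enumerate(spans)
    )
    return Song(
        song_id=song_id,
        individual_id=individual_id,
        population_id=population_id,
        notes=notes,
    )


@pytest.fixture(scope="session")
def study_dataset():
    """The study-shaped default simulation: 6 populations, 38 individuals."""
    return simulate.simulate_dataset(simulate.default_config(123))


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """Full analysis of the study-shaped dataset (ordination skipped for
    speed; it has its own dedicated small test)."""
    return analyze_dataset(
        study_dataset.notes,
        study_dataset.metadata,
        fst=study_dataset.fst,
        seed=7,
        nmds_restarts=0,
        permutations=999,
    )


def small_config(seed=0, cvm=None, turnover=None):
    """A 4-population miniature of the study design for fast tests."""
    cfg = simulate.default_config(seed)
    cfg.populations = [p for p in cfg.populations if p.population_id in
                       ("BRAH", "OOTY", "GRHL", "PEP")]
    for p in cfg.populations:
        p.n_individuals = 2
        p.songs_mean, p.songs_sd, p.songs_range = 12.0, 1.0, (11, 14)
        if cvm is not None:
            p.cvm_prob = cvm
        if turnover is not None:
            p.repertoire_turnover = turnover
    return cfg


@pytest.fixture()
def small_dataset():
    return simulate.simulate_dataset(small_config(5))
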