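"""Hierarchical synthetic song-annotation generator.

Recordings behind the study design this pipeline targets are not
publicly deposited, so every stage is exercised on synthetic data with
the same hierarchical statistical structure: populations hold
individuals, individuals hold ordered songs, songs hold notes.  The
generator plants known parameters at every level so that downstream
estimates can be scored against ground truth:

* **spectral level** — per-population Gaussian note lengths and
  bandwidths (truncated positive), a transposition window for absolute
  frequency, and a target delivery rate realized through the internote
  gap distribution;
* **CVM level** — with probability ``cvm_prob`` a consecutive-note gap
  is drawn from the complex-vocal-mechanism window [−10 ms, 2 ms)
  (uniform), otherwise from a positive window centred to meet the
  delivery-rate target;
* **syntax level** — each individual owns a unique repertoire of song
  types (no cross-individual sharing, matching the empirical
  observation the study design reports) and sings them through a
  4-state categorical chain (new / mod / old / same) whose novelty
  mass is ``repertoire_turnover``, giving a planted Song Variety
  Index; "mod" types retain a copied block of ≥ 2 note classes from a
  parent type, matching the bout classifier's rule by construction;
* **landscape level** — populations carry coordinates and ordinal
  barrier zones; a synthetic pairwise F_ST matrix is fabricated as a
  monotone function of barrier count and geographic distance plus
  noise (F_ST is an *input* to the analysis, never estimated).

The default configuration is study-shaped: six populations in three
song clusters (simple north, complex centre, intermediate south)
separated by three barriers, 38 individuals, 11–30 songs each.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import NoteRecord, notes_to_frame
from .isolation import LabeledDistanceMatrix, geographic_distances
from .syntax import DEFAULT_NOTE_TOLERANCE, note_class

__all__ = [
    "PopulationParams",
    "SimulationConfig",
    "SimulatedDataset",
    "ConfigError",
    "config_from_json",
    "default_config",
    "simulate_dataset",
    "simulate_type_chain",
    "expected_svi",
    "recover_parameters",
    "write_dataset",
]


class ConfigError(ValueError):
    """Simulation parameters are inconsistent or infeasible."""


@dataclass
class PopulationParams:
    """Generative parameters for one population.

    Times in seconds, frequencies in Hz, delivery rate in notes/s.
    ``repertoire_turnover`` is the probability that a bout position
    introduces a novel song type (split 70/30 between "new" and "mod");
    the complement is split evenly between "same" and "old".
    """

    population_id: str
    n_individuals: int
    note_length_mean: float
    note_length_sd: float
    note_bandwidth_mean: float
    note_bandwidth_sd: float
    base_freq_range: tuple[float, float]
    delivery_rate: float
    cvm_prob: float
    repertoire_turnover: float
    lat: float
    lon: float
    barrier_zone: int
    song_cluster: str
    #: share of novelty events that are brand-new (vs modified) and of
    #: repeat events that are immediate repeats (vs recalls); clusters
    #: differ in versatility composition, not just in turnover
    new_frac: float = 0.7
    same_frac: float = 0.5
    notes_per_song: tuple[int, int] = (4, 8)
    trill_prob: float = 0.3
    trill_length: tuple[int, int] = (2, 5)
    songs_mean: float = 22.0
    songs_sd: float = 7.0
    songs_range: tuple[int, int] = (11, 30)

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError(f"{self.population_id}: n_individuals must be >= 1")
        for name in ("cvm_prob", "repertoire_turnover", "trill_prob",
                     "new_frac", "same_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{self.population_id}: {name}={v} not in [0, 1]")
        for name in ("base_freq_range", "notes_per_song", "trill_length", "songs_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{self.population_id}: {name} range unordered")
        if self.note_length_mean <= 0 or self.note_bandwidth_mean <= 0:
            raise ConfigError(f"{self.population_id}: non-positive note parameters")
        if self.mean_gap() <= 0.011:
            raise ConfigError(
                f"{self.population_id}: delivery rate {self.delivery_rate}/s "
                f"is incompatible with mean note length {self.note_length_mean}s "
                "(no room for positive internote gaps)"
            )

    def mean_gap(self) -> float:
        return 1.0 / self.delivery_rate - self.note_length_mean

    def gap_window(self) -> tuple[float, float]:
        """Uniform window for non-CVM gaps, centred on the mean gap."""
        return (0.010, 2 * self.mean_gap() - 0.010)


@dataclass
class SimulationConfig:
    populations: list[PopulationParams]
    seed: int
    note_tolerance: float = DEFAULT_NOTE_TOLERANCE
    fst_alpha: float = 0.06  # F_ST per barrier
    fst_beta: float = 0.00015  # F_ST per km
    fst_noise_sd: float = 0.01

    def validate(self) -> None:
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ConfigError("population ids must be unique")
        for p in self.populations:
            p.validate()


def config_from_json(path: str | Path, seed: int | None = None) -> SimulationConfig:
    """Load a simulation config from JSON.

    The document mirrors :class:`SimulationConfig`: top-level scalar
    fields plus a ``populations`` list of :class:`PopulationParams`
    field mappings (list-valued fields stand in for tuples).  A
    ``seed`` argument overrides the file's seed.
    """
    doc = json.loads(Path(path).read_text())
    pops = []
    for entry in doc["populations"]:
        kwargs = dict(entry)
        for key in ("base_freq_range", "notes_per_song", "trill_length", "songs_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        pops.append(PopulationParams(**kwargs))
    cfg = SimulationConfig(
        populations=pops,
        seed=int(doc.get("seed", 0)),
        note_tolerance=float(doc.get("note_tolerance", DEFAULT_NOTE_TOLERANCE)),
        fst_alpha=float(doc.get("fst_alpha", 0.06)),
        fst_beta=float(doc.get("fst_beta", 0.00015)),
        fst_noise_sd=float(doc.get("fst_noise_sd", 0.01)),
    )
    if seed is not None:
        cfg.seed = seed
    return cfg


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-shaped default: six populations on a ~600 km
    north-south chain, three barriers, three song clusters, 38
    individuals.

    The simple northern cluster sings long narrow-band notes slowly
    with rare CVMs and low turnover; the complex central cluster the
    opposite; the southern population is intermediate.  Turnover is
    constant within a barrier zone except for a small north-cluster
    step, so syntax distances track barrier counts, while the spectral
    gradient plus cluster structure makes spectral distances track
    geography.
    """

    # versatility composition per cluster: the simple cluster sings mostly
    # brand-new novelty and immediate repeats; the complex cluster modifies
    # songs often and recalls rather than repeats; intermediate in between
    SPLITS = {
        "simple": (0.80, 0.65),
        "complex": (0.55, 0.35),
        "intermediate": (0.65, 0.50),
    }

    def pop(pid, n, nl, nlsd, bw, bwsd, fr, rate, cvm, turn, lat, lon, zone, cluster, nps):
        new_frac, same_frac = SPLITS[cluster]
        return PopulationParams(
            population_id=pid,
            n_individuals=n,
            note_length_mean=nl,
            note_length_sd=nlsd,
            note_bandwidth_mean=bw,
            note_bandwidth_sd=bwsd,
            base_freq_range=fr,
            delivery_rate=rate,
            cvm_prob=cvm,
            repertoire_turnover=turn,
            new_frac=new_frac,
            same_frac=same_frac,
            lat=lat,
            lon=lon,
            barrier_zone=zone,
            song_cluster=cluster,
            notes_per_song=nps,
        )

    pops = [
        # northern simple cluster (zones 0 and 1, split by a river barrier)
        pop("BRAH", 2, 0.26, 0.05, 700, 160, (1800, 2600), 1.8, 0.02, 0.50,
            13.30, 75.50, 0, "simple", (3, 6)),
        pop("OOTY", 10, 0.23, 0.05, 850, 180, (1800, 2700), 2.1, 0.06, 0.56,
            11.55, 76.55, 1, "simple", (3, 6)),
        # central complex cluster (zone 2, beyond the deepest gap)
        pop("GRHL", 7, 0.085, 0.020, 2600, 450, (1500, 4200), 5.5, 0.26, 0.84,
            10.45, 76.90, 2, "complex", (5, 9)),
        pop("KODI", 7, 0.095, 0.022, 2450, 430, (1500, 4200), 5.1, 0.08, 0.84,
            10.30, 77.50, 2, "complex", (5, 9)),
        pop("HWS", 6, 0.080, 0.018, 2750, 470, (1500, 4200), 5.8, 0.30, 0.84,
            10.10, 77.10, 2, "complex", (5, 9)),
        # southern intermediate population (zone 3, beyond the second gap)
        pop("PEP", 6, 0.150, 0.030, 1600, 320, (1700, 3500), 3.5, 0.14, 0.70,
            8.60, 77.20, 3, "intermediate", (4, 8)),
    ]
    return SimulationConfig(populations=pops, seed=seed)


# ------------------------------------------------------------- syntax chain


def _draw_category(u: float, turnover: float, new_frac: float, same_frac: float) -> str:
    t = turnover
    if u < new_frac * t:
        return "new"
    if u < t:
        return "mod"
    if u < t + same_frac * (1 - t):
        return "same"
    return "old"


def simulate_type_chain(
    turnover: float,
    n_songs: int,
    rng: np.random.Generator,
    new_frac: float = 0.7,
    same_frac: float = 0.5,
) -> tuple[list[str], list[int], dict[int, int]]:
    """Run the 4-state song-organization chain over a song sequence.

    Returns (categories, abstract type index per song, parent of each
    "mod" type).  Fallbacks: "old" with no earlier non-adjacent type
    becomes "same"; the first song is always "new".  The SVI implied by
    the chain depends only on ``turnover`` (both "new" and "mod" add a
    distinct type); the split parameters shape the versatility
    composition.
    """
    cats = ["new"]
    types = [0]
    parents: dict[int, int] = {}
    next_id = 1
    for i in range(1, n_songs):
        cat = _draw_category(float(rng.random()), turnover, new_frac, same_frac)
        if cat == "old":
            candidates = sorted(set(types) - {types[-1]})
            if not candidates:
                cat = "same"
        if cat == "new":
            types.append(next_id)
            next_id += 1
        elif cat == "mod":
            parent = int(rng.choice(sorted(set(types))))
            parents[next_id] = parent
            types.append(next_id)
            next_id += 1
        elif cat == "same":
            types.append(types[-1])
        else:  # old
            types.append(int(rng.choice(candidates)))
        cats.append(cat)
    return cats, types, parents


def expected_svi(
    turnover: float,
    bout_size: int = 11,
    reps: int = 3000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo expectation of the SVI implied by the chain."""
    rng = np.random.default_rng(0) if rng is None else rng
    vals = np.empty(reps)
    for r in range(reps):
        _, types, _ = simulate_type_chain(turnover, bout_size, rng)
        vals[r] = len(set(types)) / bout_size
    return float(vals.mean())


# ---------------------------------------------------------- type realization


class _TypeFactory:
    """Builds an individual's song types with the guarantees the bout
    classifier relies on: globally unique signatures, no adjacent
    duplicate classes, and — within an individual — no shared ordered
    class pair between independently created ("new") types, so a new
    type is never mistaken for a modification."""

    def __init__(
        self,
        params: PopulationParams,
        tolerance: float,
        rng: np.random.Generator,
        global_signatures: set,
    ):
        self.p = params
        self.tol = tolerance
        self.rng = rng
        self.global_signatures = global_signatures
        self.used_pairs: set = set()
        self.types: list[dict] = []  # {"classes": [...], "trill_pos": int|None}

    def _draw_class(self) -> tuple[tuple[int, int], float, float, float]:
        p = self.p
        dur = max(0.02, float(self.rng.normal(p.note_length_mean, p.note_length_sd)))
        bw = max(100.0, float(self.rng.normal(p.note_bandwidth_mean, p.note_bandwidth_sd)))
        off = float(self.rng.uniform(0, 600))
        return note_class(dur, bw, self.tol), dur, bw, off

    def _signature(self, classes: list[dict], trill_pos: int | None):
        return tuple(
            (c["cls"], i == trill_pos) for i, c in enumerate(classes)
        )

    def _finish(self, classes, trill_pos, pairs) -> int:
        sig = self._signature(classes, trill_pos)
        if sig in self.global_signatures:
            return -1
        self.global_signatures.add(sig)
        self.used_pairs |= pairs
        self.types.append({"classes": classes, "trill_pos": trill_pos})
        return len(self.types) - 1

    def new_type(self) -> int:
        p = self.p
        for _ in range(100):  # whole-type retries
            length = int(self.rng.integers(p.notes_per_song[0], p.notes_per_song[1] + 1))
            classes: list[dict] = []
            pairs: set = set()
            ok = True
            for _k in range(length):
                placed = False
                for _try in range(60):
                    cls, dur, bw, off = self._draw_class()
                    if classes and cls == classes[-1]["cls"]:
                        continue
                    if classes:
                        pair = (classes[-1]["cls"], cls)
                        if pair in self.used_pairs or pair in pairs:
                            continue
                        pairs.add(pair)
                    classes.append({"cls": cls, "dur": dur, "bw": bw, "off": off})
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                # class space locally saturated: relax the pair constraint
                # for this type rather than loop forever
                while len(classes) < length:
                    cls, dur, bw, off = self._draw_class()
                    if classes and cls == classes[-1]["cls"]:
                        continue
                    if classes:
                        pairs.add((classes[-1]["cls"], cls))
                    classes.append({"cls": cls, "dur": dur, "bw": bw, "off": off})
            trill_pos = (
                int(self.rng.integers(0, len(classes)))
                if self.rng.random() < p.trill_prob
                else None
            )
            tid = self._finish(classes, trill_pos, pairs)
            if tid >= 0:
                return tid
        raise ConfigError(
            f"{p.population_id}: could not create a unique song type; "
            "note-class space too narrow for the requested repertoire"
        )

    def mod_type(self, parent_idx: int) -> int:
        """Novel type retaining a contiguous >=2-class block of a parent."""
        p = self.p
        parent = self.types[parent_idx]
        pc = parent["classes"]
        for _ in range(100):
            if len(pc) >= 2:
                blen = int(self.rng.integers(2, len(pc) + 1))
                bstart = int(self.rng.integers(0, len(pc) - blen + 1))
                block = [dict(c) for c in pc[bstart : bstart + blen]]
            else:
                block = [dict(pc[0])]
            n_new = int(self.rng.integers(1, 4))
            classes = [dict(c) for c in block]
            pairs: set = set()
            append_front = bool(self.rng.random() < 0.5)
            ok = True
            for _k in range(n_new):
                placed = False
                for _try in range(60):
                    cls, dur, bw, off = self._draw_class()
                    anchor = classes[0]["cls"] if append_front else classes[-1]["cls"]
                    if cls == anchor:
                        continue
                    pair = (cls, anchor) if append_front else (anchor, cls)
                    if pair in self.used_pairs or pair in pairs:
                        continue
                    pairs.add(pair)
                    if append_front:
                        classes.insert(0, {"cls": cls, "dur": dur, "bw": bw, "off": off})
                    else:
                        classes.append({"cls": cls, "dur": dur, "bw": bw, "off": off})
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                continue
            trill_pos = parent["trill_pos"]
            if trill_pos is not None:
                # keep the parent's trill only if it sits inside the block
                if bstart <= trill_pos < bstart + blen:
                    trill_pos = trill_pos - bstart + (n_new if append_front else 0)
                else:
                    trill_pos = None
            tid = self._finish(classes, trill_pos, pairs)
            if tid >= 0:
                return tid
        # fall back to a brand-new type (still "novel", block not retained)
        return self.new_type()


# ------------------------------------------------------------- main entry


@dataclass
class SimulatedDataset:
    notes: pd.DataFrame  # canonical note columns
    metadata: pd.DataFrame  # population_id, lat, lon, barrier_zone, song_cluster
    fst: LabeledDistanceMatrix
    ledger: dict


def _truncated_count(rng, mean, sd, lo, hi) -> int:
    return int(round(float(np.clip(rng.normal(mean, sd), lo, hi))))


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedDataset:
    """Generate a full synthetic dataset plus its ground-truth ledger.

    The same (config, seed) always yields the identical dataset; the
    master seed fans out to one child stream per individual plus one
    for the F_ST noise.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    notes: list[NoteRecord] = []
    global_signatures: set = set()
    ledger_individuals: dict = {}
    n_total_individuals = sum(p.n_individuals for p in config.populations)
    children = ss.spawn(n_total_individuals + 1)
    child_iter = iter(children[:-1])
    fst_rng = np.random.default_rng(children[-1])

    for p in config.populations:
        for j in range(p.n_individuals):
            rng = np.random.default_rng(next(child_iter))
            ind_id = f"{p.population_id}_i{j:02d}"
            n_songs = _truncated_count(
                rng, p.songs_mean, p.songs_sd, p.songs_range[0], p.songs_range[1]
            )
            cats, type_seq, parents = simulate_type_chain(
                p.repertoire_turnover, n_songs, rng, p.new_frac, p.same_frac
            )
            factory = _TypeFactory(p, config.note_tolerance, rng, global_signatures)
            concrete: dict[int, int] = {}  # abstract chain id -> factory index
            songs_ledger = []
            cursor = 0.0
            glo, ghi = p.gap_window()
            for k, (cat, tid) in enumerate(zip(cats, type_seq)):
                if tid not in concrete:
                    if tid in parents:
                        concrete[tid] = factory.mod_type(concrete[parents[tid]])
                    else:
                        concrete[tid] = factory.new_type()
                t = factory.types[concrete[tid]]
                song_id = f"{ind_id}_s{k:03d}"
                base_low = float(rng.uniform(*p.base_freq_range))
                rendered: list[tuple[float, float, float]] = []  # dur, low, high
                for i, c in enumerate(t["classes"]):
                    reps = 1
                    if i == t["trill_pos"]:
                        reps = int(
                            rng.integers(p.trill_length[0], p.trill_length[1] + 1)
                        )
                    low = base_low + c["off"]
                    for _ in range(reps):
                        rendered.append((c["dur"], low, low + c["bw"]))
                start = cursor
                for i, (dur, low, high) in enumerate(rendered):
                    end = start + dur
                    notes.append(
                        NoteRecord(
                            population_id=p.population_id,
                            individual_id=ind_id,
                            song_id=song_id,
                            start_time=round(start, 6),
                            end_time=round(end, 6),
                            low_freq=round(low, 2),
                            high_freq=round(high, 2),
                        )
                    )
                    if i < len(rendered) - 1:
                        if rng.random() < p.cvm_prob:
                            gap = float(rng.uniform(-0.010, 0.002))
                        else:
                            gap = float(rng.uniform(glo, ghi))
                        start = end + gap
                song_end = max(n.end_time for n in notes[-len(rendered) :])
                cursor = song_end + float(rng.uniform(2.0, 6.0))
                songs_ledger.append(
                    {
                        "song_id": song_id,
                        "category": cat,
                        "type_id": f"{ind_id}_t{concrete[tid]:03d}",
                        "n_notes": len(rendered),
                    }
                )
            ledger_individuals[ind_id] = {
                "population_id": p.population_id,
                "n_songs": n_songs,
                "songs": songs_ledger,
            }

    metadata = pd.DataFrame(
        [
            {
                "population_id": p.population_id,
                "lat": p.lat,
                "lon": p.lon,
                "barrier_zone": p.barrier_zone,
                "song_cluster": p.song_cluster,
                "n_individuals": p.n_individuals,
            }
            for p in config.populations
        ]
    )
    geo = geographic_distances(metadata)
    zones = {p.population_id: p.barrier_zone for p in config.populations}
    labels = geo.labels
    n = len(labels)
    F = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            barriers = abs(zones[labels[i]] - zones[labels[j]])
            val = (
                config.fst_alpha * barriers
                + config.fst_beta * geo.values[i, j]
                + float(fst_rng.normal(0, config.fst_noise_sd))
            )
            F[i, j] = F[j, i] = float(np.clip(val, 0.0, 0.5))
    fst = LabeledDistanceMatrix(labels, F, "fst")

    ledger = {
        "seed": seed,
        "note_tolerance": config.note_tolerance,
        "populations": {
            p.population_id: {
                k: v for k, v in asdict(p).items() if k != "population_id"
            }
            for p in config.populations
        },
        "individuals": ledger_individuals,
    }
    return SimulatedDataset(
        notes=notes_to_frame(notes), metadata=metadata, fst=fst, ledger=ledger
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write notes TSV, population metadata TSV, F_ST TSV and the
    ground-truth ledger (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.notes.to_csv(outdir / "notes.tsv", sep="\t", index=False)
    ds.metadata.to_csv(outdir / "populations.tsv", sep="\t", index=False)
    ds.fst.write(outdir / "fst.tsv")
    (outdir / "ledger.json").write_text(json.dumps(ds.ledger, indent=1))


# ------------------------------------------------------------ recovery


def recover_parameters(
    ds: SimulatedDataset,
    bout_size: int = 11,
    tolerance: float | None = None,
    seed: int = 0,
    svi_reps: int = 2000,
) -> dict:
    """Score the pipeline's estimates against the generator's truth.

    Checks, per population: the mean extracted CVM rate against
    cvm_prob·(n−1)/n within two standard errors, and the mean measured
    SVI against the chain-implied Monte-Carlo expectation.  Globally:
    between-cluster DFA confusion and the planted Mantel contrasts
    (spectral ↔ geographic distance, syntax ↔ barrier count).
    """
    from . import pipeline

    tolerance = ds.ledger["note_tolerance"] if tolerance is None else tolerance
    res = pipeline.analyze_dataset(
        ds.notes,
        ds.metadata,
        fst=ds.fst,
        bout_size=bout_size,
        note_tolerance=tolerance,
        seed=seed,
        nmds_restarts=0,
    )
    report: dict = {"per_population": {}, "checks": {}}
    feats = res["features"]
    feats = feats.assign(
        cvm_rate=feats["cvm_short_interval_rate"] + feats["cvm_overlap_rate"]
    )
    pops = ds.ledger["populations"]
    rng = np.random.default_rng(seed)
    cvm_ok, svi_ok = [], []
    for pid, truth in pops.items():
        sub = feats[feats["population_id"] == pid]
        exp_rate = float(
            (truth["cvm_prob"] * (sub["n_notes"] - 1) / sub["n_notes"]).mean()
        )
        obs = sub["cvm_rate"].to_numpy()
        se = obs.std(ddof=1) / math.sqrt(len(obs)) if len(obs) > 1 else 0.0
        ok = abs(obs.mean() - exp_rate) <= 2 * se + 1e-9
        cvm_ok.append(ok)
        svis = res["bouts_frame"]
        sub_svi = svis[svis["population_id"] == pid]["svi"].to_numpy()
        exp_svi = expected_svi(
            truth["repertoire_turnover"], bout_size, svi_reps, rng
        )
        mc_sd = 0.12  # per-bout SVI spread; dominates for small populations
        se_svi = mc_sd / math.sqrt(max(len(sub_svi), 1))
        ok_svi = abs(sub_svi.mean() - exp_svi) <= 3 * se_svi
        svi_ok.append(ok_svi)
        report["per_population"][pid] = {
            "cvm_rate_observed": float(obs.mean()),
            "cvm_rate_expected": exp_rate,
            "cvm_pass": bool(ok),
            "svi_observed": float(sub_svi.mean()),
            "svi_expected": exp_svi,
            "svi_pass": bool(ok_svi),
        }
    clusters = {
        pid: truth["song_cluster"] for pid, truth in pops.items()
    }
    conf = res["dfa"].confusion
    total = conf.to_numpy().sum()
    between = sum(
        conf.loc[a, b]
        for a in conf.index
        for b in conf.columns
        if clusters[a] != clusters[b]
    )
    between_rate = float(between / total)
    mant = res["mantel_table"]

    def _r(song, driver):
        row = mant[(mant["song"] == song) & (mant["driver"] == driver) & (~mant["partial"])]
        return float(row["r"].iloc[0])

    report["checks"] = {
        "dfa_between_cluster_confusion": between_rate,
        "dfa_between_cluster_pass": between_rate <= 0.05,
        "mantel_spectral_distance_r": _r("spectral", "geographic_km"),
        "mantel_spectral_barrier_r": _r("spectral", "barrier_count"),
        "mantel_syntax_barrier_r": _r("syntax", "barrier_count"),
        "mantel_syntax_distance_r": _r("syntax", "geographic_km"),
        "syntax_tracks_barriers_pass": _r("syntax", "barrier_count")
        > _r("spectral", "barrier_count"),
        "sharing_offdiagonal_total": int(res["sharing_offdiagonal"]),
        "no_sharing_pass": int(res["sharing_offdiagonal"]) == 0,
        "cvm_all_pass": all(cvm_ok),
        "svi_all_pass": all(svi_ok),
    }
    return report
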