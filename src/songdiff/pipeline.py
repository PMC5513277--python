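"""End-to-end orchestration: ingest → features → syntax → stats → isolation.

``analyze_dataset`` is the library entry point: it takes a canonical
notes table plus population metadata (and optionally a pairwise F_ST
matrix) and returns every stage's results in one dictionary.
``run_pipeline`` wraps it with file I/O and writes a report bundle.

All stochastic steps (bootstrap, NMDS restarts, Mantel permutations)
are seeded from one master seed via a spawned seed sequence, so the
whole run is reproducible and stages can be re-run in isolation with
their recorded child seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations, features, isolation, multivariate, syntax
from .features import CVM_THRESHOLD_S
from .syntax import DEFAULT_BOUT_SIZE, DEFAULT_NOTE_TOLERANCE

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "analyze_dataset", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run, with study-matching defaults:
    2 ms CVM threshold, 11-song bouts, eigenvalue > 1 retention and
    1,000 bootstrap replications."""

    notes_path: str | None = None
    metadata_path: str | None = None
    fst_path: str | None = None
    out_dir: str = "songdiff_out"
    seed: int = 0
    bout_size: int = DEFAULT_BOUT_SIZE
    cvm_threshold_s: float = CVM_THRESHOLD_S
    note_tolerance: float = DEFAULT_NOTE_TOLERANCE
    eigenvalue_cutoff: float = 1.0
    bootstrap_reps: int = 1000
    permutations: int = 9999
    mantel_tail: str = "greater"
    nmds_restarts: int = 20
    strict_io: bool = True


def analyze_dataset(
    notes_frame: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    fst: isolation.LabeledDistanceMatrix | None = None,
    bout_size: int = DEFAULT_BOUT_SIZE,
    cvm_threshold_s: float = CVM_THRESHOLD_S,
    note_tolerance: float = DEFAULT_NOTE_TOLERANCE,
    eigenvalue_cutoff: float = 1.0,
    bootstrap_reps: int = 1000,
    permutations: int = 9999,
    mantel_tail: str = "greater",
    nmds_restarts: int = 20,
    seed: int = 0,
) -> dict:
    """Run the full analysis battery on an in-memory dataset.

    ``metadata`` needs columns ``population_id``, ``lat``, ``lon`` and
    ``barrier_zone`` for the isolation stage; without it that stage is
    skipped.  ``nmds_restarts=0`` skips the ordination.
    """
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("bootstrap", "nmds", "mantel"), ss.spawn(3)
        )
    }
    out: dict = {"seed": seed}

    # ---- ingest
    records = annotations.frame_to_notes(notes_frame)
    songs = annotations.assemble_songs(records)
    manifest = annotations.summarize_dataset(songs)
    out["manifest"] = manifest

    # ---- spectral features
    feats = features.features_table(songs, cvm_threshold_s)
    out["features"] = feats
    shifts = features.shifts_table(songs, cvm_threshold_s)
    out["shifts"] = shifts
    try:
        out["ks_shift"] = features.ks_compare_shifts(shifts)
    except features.InsufficientDataError as exc:
        logger.warning("KS shift comparison skipped: %s", exc)
        out["ks_shift"] = None

    # ---- syntax
    by_ind: dict[str, list] = {}
    for s in songs:
        by_ind.setdefault(s.individual_id, []).append(s)
    bouts, excluded = [], []
    for ind, ss_songs in by_ind.items():
        if len(ss_songs) < bout_size:
            excluded.append(ind)
            continue
        bout = syntax.select_bout(ss_songs, n=bout_size, start="first")
        bouts.append(syntax.classify_bout(bout, note_tolerance))
    if excluded:
        logger.warning(
            "%d individuals excluded from syntax stage (<%d songs): %s",
            len(excluded), bout_size, excluded,
        )
    out["bouts"] = bouts
    out["excluded_individuals"] = excluded
    out["n_songs_syntax"] = sum(b.n for b in bouts)
    bouts_frame = pd.DataFrame(
        [
            {
                "individual_id": b.individual_id,
                "population_id": b.population_id,
                "svi": b.svi,
                **{f"prop_{c}": b.category_proportions()[c] for c in syntax.CATEGORIES},
            }
            for b in bouts
        ]
    )
    out["bouts_frame"] = bouts_frame
    library, sharing = syntax.build_library(bouts)
    out["library"] = library
    out["sharing"] = sharing
    off = sharing.to_numpy().copy()
    np.fill_diagonal(off, 0)
    out["sharing_offdiagonal"] = int(off.sum())
    out["syntax_summary"] = syntax.bootstrap_summary(
        bouts, bootstrap_reps, 0.95, seeds["bootstrap"]
    )
    # SVI vs spectral correlates, per individual (means over analyzed bouts)
    analyzed = {b.individual_id: set(b.song_ids) for b in bouts}
    rows = []
    for b in bouts:
        sub = feats[feats["song_id"].isin(analyzed[b.individual_id])]
        rows.append(
            {
                "individual_id": b.individual_id,
                "svi": b.svi,
                "song_bandwidth": float(sub["song_bandwidth"].mean()),
                "delivery_rate": float(sub["delivery_rate"].mean()),
            }
        )
    per_ind = pd.DataFrame(rows)
    try:
        out["svi_correlations"] = syntax.svi_spectral_correlation(per_ind)
    except (ValueError, syntax.UndefinedCorrelationError) as exc:
        logger.warning("SVI correlation skipped: %s", exc)
        out["svi_correlations"] = None

    # ---- multivariate battery
    pca = multivariate.pca_reduce(feats, eigenvalue_cutoff, list(features.FEATURE_NAMES))
    out["pca"] = pca
    out["manova"] = multivariate.nested_manova(pca.scores)
    out["anova"] = multivariate.nested_anova_per_pc(pca.scores)
    out["dfa"] = multivariate.discriminant_analysis(pca.scores)
    if nmds_restarts > 0:
        out["nmds"] = multivariate.nmds(
            feats,
            feature_names=list(features.FEATURE_NAMES),
            restarts=nmds_restarts,
            seed=seeds["nmds"],
        )
    else:
        out["nmds"] = None
    out["kw_cvm_short"] = multivariate.kruskal_dunn(
        feats["cvm_short_interval_rate"].to_numpy(),
        feats["population_id"].to_numpy(),
    )
    out["kw_cvm_overlap"] = multivariate.kruskal_dunn(
        feats["cvm_overlap_rate"].to_numpy(),
        feats["population_id"].to_numpy(),
    )

    # ---- isolation
    out["mantel_table"] = None
    if metadata is not None:
        geo = isolation.geographic_distances(metadata)
        zones = dict(
            zip(metadata["population_id"].astype(str), metadata["barrier_zone"])
        )
        barrier = isolation.barrier_distances(zones)
        spectral = isolation.spectral_distance_matrix(pca.scores)
        syntax_d = (
            isolation.syntax_distance_matrix(out["syntax_summary"])
            if len(bouts_frame) and bouts_frame["population_id"].nunique() >= 4
            else None
        )
        labels = [l for l in geo.labels if l in spectral.labels]
        aligned = {
            "geographic_km": geo.align(labels),
            "barrier_count": barrier.align(labels),
            "song_spectral": spectral.align(labels),
        }
        if syntax_d is not None:
            labels_s = [l for l in labels if l in syntax_d.labels]
        if fst is not None:
            aligned["fst"] = fst.align(labels)
        rows = []
        rng = seeds["mantel"]

        def _add(song_kind, song_m, driver_kind, control=None):
            try:
                if control is None:
                    r = isolation.mantel(
                        song_m, aligned[driver_kind], permutations, rng, mantel_tail
                    )
                else:
                    r = isolation.partial_mantel(
                        song_m,
                        aligned[driver_kind],
                        aligned[control],
                        permutations,
                        rng,
                        mantel_tail,
                    )
                rows.append(
                    {
                        "song": song_kind,
                        "driver": driver_kind,
                        "partial": control is not None,
                        "control": control,
                        "r": r.r,
                        "p": r.pvalue,
                        "permutations": r.permutations,
                        "exhaustive": r.exhaustive,
                    }
                )
            except (isolation.UndefinedCorrelationError, ValueError) as exc:
                logger.warning(
                    "Mantel %s~%s skipped: %s", song_kind, driver_kind, exc
                )

        song_mats = {"spectral": aligned["song_spectral"]}
        if syntax_d is not None:
            song_mats["syntax"] = syntax_d.align(labels_s)
        for kind, mat in song_mats.items():
            drivers = ["geographic_km", "barrier_count"]
            if fst is not None:
                drivers.append("fst")
            for d in drivers:
                _add(kind, mat, d)
            if fst is not None:
                _add(kind, mat, "fst", control="geographic_km")
                _add(kind, mat, "fst", control="barrier_count")
        out["mantel_table"] = pd.DataFrame(rows)
        if fst is None:
            logger.warning(
                "no F_ST matrix supplied: isolation stage limited to "
                "geographic-distance and barrier tests"
            )
    return out


def _write_report(res: dict, cfg: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    res["features"].to_csv(outdir / "features.tsv", sep="\t", index=False)
    res["shifts"].to_csv(outdir / "shifts.tsv", sep="\t", index=False)
    res["bouts_frame"].to_csv(outdir / "bout_classification.tsv", sep="\t", index=False)
    res["library"].to_frame().to_csv(outdir / "song_type_library.tsv", sep="\t", index=False)
    res["sharing"].to_csv(outdir / "sharing_matrix.tsv", sep="\t", index_label="individual_id")
    res["syntax_summary"].to_csv(outdir / "syntax_summary.tsv", sep="\t", index=False)
    pca = res["pca"]
    pca.loadings_frame().to_csv(outdir / "pca_loadings.tsv", sep="\t", index_label="variable")
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
    res["anova"].to_csv(outdir / "nested_anova.tsv", sep="\t", index=False)
    res["dfa"].confusion.to_csv(outdir / "dfa_confusion.tsv", sep="\t", index_label="population_id")
    res["dfa"].canonical_scores.to_csv(outdir / "canonical_scores.tsv", sep="\t", index=False)
    res["kw_cvm_short"].dunn.to_csv(outdir / "dunn_cvm_short.tsv", sep="\t", index=False)
    if res["mantel_table"] is not None:
        res["mantel_table"].to_csv(outdir / "mantel_tests.tsv", sep="\t", index=False)
    if res["svi_correlations"] is not None:
        res["svi_correlations"].to_csv(outdir / "svi_correlations.tsv", sep="\t", index=False)

    manifest = res["manifest"]
    report = {
        "seed": res["seed"],
        "config": dataclasses.asdict(cfg),
        "manifest": manifest.describe(),
        "n_songs_syntax": res["n_songs_syntax"],
        "excluded_individuals": res["excluded_individuals"],
        "pca": {
            "retained": pca.k,
            "retained_variance_fraction": pca.retained_variance,
            "eigenvalues": [float(x) for x in pca.eigenvalues[: pca.k]],
        },
        "manova": [dataclasses.asdict(m) for m in res["manova"]],
        "dfa": {
            "canonical_correlations": [
                float(x) for x in res["dfa"].canonical_correlations
            ],
            "variance_explained": [float(x) for x in res["dfa"].variance_explained],
            "correct_rate": res["dfa"].correct_rate,
        },
        "nmds_stress": None if res["nmds"] is None else res["nmds"].stress,
        "kw_cvm_short": {
            "chi2": res["kw_cvm_short"].statistic,
            "df": res["kw_cvm_short"].df,
            "p": res["kw_cvm_short"].pvalue,
        },
        "kw_cvm_overlap": {
            "chi2": res["kw_cvm_overlap"].statistic,
            "df": res["kw_cvm_overlap"].df,
            "p": res["kw_cvm_overlap"].pvalue,
        },
        "ks_shift": None
        if res["ks_shift"] is None
        else {"D": res["ks_shift"].statistic, "p": res["ks_shift"].pvalue},
        "library_size": res["library"].n_types,
        "sharing_offdiagonal": res["sharing_offdiagonal"],
        "mantel": None
        if res["mantel_table"] is None
        else res["mantel_table"].to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based pipeline run: read inputs, analyze, write the bundle.

    Returns the summary report dictionary (also written as
    ``report.json`` in the output directory).
    """
    if cfg.notes_path is None:
        raise ValueError("RunConfig.notes_path is required")
    records = annotations.read_selection_table(
        cfg.notes_path, label_map={}, strict=cfg.strict_io
    )
    notes_frame = annotations.notes_to_frame(records)
    metadata = (
        pd.read_csv(cfg.metadata_path, sep="\t") if cfg.metadata_path else None
    )
    fst = (
        isolation.read_square_matrix(cfg.fst_path, "fst") if cfg.fst_path else None
    )
    res = analyze_dataset(
        notes_frame,
        metadata,
        fst,
        bout_size=cfg.bout_size,
        cvm_threshold_s=cfg.cvm_threshold_s,
        note_tolerance=cfg.note_tolerance,
        eigenvalue_cutoff=cfg.eigenvalue_cutoff,
        bootstrap_reps=cfg.bootstrap_reps,
        permutations=cfg.permutations,
        mantel_tail=cfg.mantel_tail,
        nmds_restarts=cfg.nmds_restarts,
        seed=cfg.seed,
    )
    return _write_report(res, cfg, Path(cfg.out_dir))
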