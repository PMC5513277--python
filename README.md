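# songdiff

Geographic variation in birdsong for populations isolated at different
spatial and temporal scales — for bioacousticians and evolutionary
biologists working with note-level song annotations rather than raw
audio.

The package targets the analysis design of a sky-island songbird
complex: several populations on isolated mountaintops, some separated
by ancient valley barriers, others only by recent deforestation.  From
tab-separated selection tables (one row per *note*, with start/end
time in seconds and low/high frequency in Hz, plus song / individual /
population labels) it derives:

* **14 song-level spectral variables** — mean and SD of note length,
  high frequency, low frequency and note bandwidth; song bandwidth and
  duration; note count; delivery rate; and two **complex-vocal-
  mechanism (CVM)** rates: counts of internote intervals < 2 ms
  (shorter than a minibreath) and of temporal overlaps between
  consecutive notes, each scaled by the song's note count.  Either
  signal implies two-voice syrinx use or nonlinear phenomena.
* **Syntax complexity** from fixed-length bouts of N = 11 consecutive
  songs: the Song Variety Index `SVI = (distinct song types) / N`, and
  the versatility classification of each song as *new*, *mod* (novel
  but copying a block of ≥ 2 note classes from an earlier song), *old*
  (recalled) or *same* (immediate repeat); a cross-population song-type
  library with an individual × individual sharing matrix; percentile
  bootstrap CIs (1,000 replications) over individuals.
* **Population differentiation**: correlation-matrix PCA (eigenvalue
  > 1 retention), nested MANOVA/ANOVA (songs in individuals in
  populations; Wilks' Λ with Rao's F), canonical discriminant analysis
  with resubstitution classification, non-metric MDS, and
  Kruskal–Wallis with Dunn–Bonferroni follow-up for the CVM rates.
* **Isolation analysis**: population-level distance matrices
  (great-circle km, ordered barrier counts, pairwise F_ST read from a
  file — never estimated, and Euclidean song distances for spectral and
  syntax traits separately) compared with one-tailed Mantel and
  partial Mantel permutation tests (exhaustive enumeration for small
  n, add-one-corrected random permutations otherwise).

Because the recordings behind this design are not publicly deposited,
the package ships a hierarchical simulator (`songdiff.simulate`) that
generates study-shaped datasets — 6 populations in 3 song clusters
separated by 3 barriers, 38 individuals, 11–30 songs each — with every
generating parameter recorded in a ground-truth ledger, so the whole
pipeline is validated by parameter recovery.

## Worked example

```bash
songdiff simulate --seed 1 --out data/
songdiff run --notes data/notes.tsv --metadata data/populations.tsv \
             --fst-matrix data/fst.tsv --out results/ --seed 1 \
             --nmds-restarts 2
```

or equivalently in Python:

```python
import songdiff as sd

ds = sd.simulate.simulate_dataset(sd.simulate.default_config(1))
res = sd.analyze_dataset(ds.notes, ds.metadata, fst=ds.fst, seed=1,
                         nmds_restarts=2, permutations=999)
print(res["manifest"].describe())
print(res["n_songs_syntax"], res["dfa"].correct_rate)
print(res["ks_shift"])
```

prints (seed 1):

```
814 songs from 38 individuals across 6 populations (5436 notes); songs per individual 21.4 ± 6.0 (range 11-30)
418 0.6965601965601965
KSResult(statistic=0.21227948492679616, pvalue=1.806134748777291e-25, n_below=755, n_at_or_above=3867)
```

Reading: the syntax stage analyzed exactly 11 × 38 = 418 songs; the
discriminant model classified 69.7 % of songs to the correct
population (confusion concentrated inside the three song clusters);
and frequency shifts between consecutive notes differ in distribution
when the internote interval is below 2 ms (KS D = 0.21), the signature
of complex-vocal-mechanism use.  The report bundle in `results/`
contains per-stage TSVs (features, bout classifications, song-type
library, sharing matrix, PCA/DFA/NMDS outputs, Mantel table) and a
`report.json` summary.

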