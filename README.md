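# mpnoise

How robust is the matrix profile to noisy data?

The matrix profile (MP) of a time series *X* of length *n*, for a window
length *m*, is the array of length *n* − *m* + 1 whose entry *i* is the
z-normalised Euclidean distance from the subsequence starting at *i* to its
nearest neighbour elsewhere in the series. Its minima locate **motifs**
(repeated patterns), its maximum locates the **discord** (the most anomalous
subsequence), and it does this exactly, with the window length as the only
parameter. That makes it a workhorse for unsupervised pattern and anomaly
mining in behavioural and sensor streams — keystroke dynamics, wearable
accelerometry on livestock, city traffic counts — where labels don't exist
and pre-filtering noise risks deleting the very anomalies being sought.

But such streams are noisy, and the MP has no built-in noise tolerance.
`mpnoise` measures what noise actually does to it. The package

1. computes exact matrix profiles (STOMP-style O(n²) pass, validated
   against a brute-force oracle);
2. corrupts a series with two additive noise schemes — **duplicated
   anomalies** (a random 5% of values repeated *k* = 2…6 times) and
   **irrelevant features** (insertion of *p* = 1–50% extra draws from
   Unif[min X, max X]) — with full provenance of what went where;
3. compares the before/after profiles, which differ in length, by aligning
   them with FastDTW (radius 30, |aᵢ − bⱼ| local cost) and reporting the
   normalised dissimilarity

   D = Σ<sub>path</sub> |aᵢ − bⱼ| / (N · y₁),

   where *N* is the original series length and *y₁* the original profile's
   maximum — 0 for identical profiles, growing with disruption;
4. runs the full ten-condition study per series and emits table-shaped CSV
   and fully seeded JSON reports, plus synthetic generators that emulate the
   three case-study data families so everything is testable without any
   downloads.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from mpnoise import (GeneratorSpec, MPConfig, NoiseSpec, DTWParams,
                     gen_traffic_like, compute_matrix_profile, mp_summary,
                     locate_motif_discord, inject, mp_dissimilarity)

# 30 days of hourly traffic-like counts, with one sensor-fault day planted
series = gen_traffic_like(GeneratorSpec(family="traffic", n=720, seed=3,
                                        anomalous_days=(12,)))
mp = compute_matrix_profile(series, MPConfig(window=24))
s = mp_summary(mp)
motif, discord = locate_motif_discord(mp)
print(f"clean MP: length={len(mp)}  mean={s.mean:.3f}  max={s.max:.3f}  min={s.min:.3f}")
print(f"motif pair at {motif}, discord at {discord}")

result = inject(series, NoiseSpec("duplicated_anomaly", factor=6, seed=1))
noisy_mp = compute_matrix_profile(result.corrupted, MPConfig(window=24))
d = mp_dissimilarity(mp, noisy_mp, DTWParams(radius=30))
print(f"duplicated x6: n {series.n} -> {result.corrupted.n}, "
      f"sum|diff|={d.sum_abs_diffs:.1f}, normalised={d.normalised:.3f}")
```

prints

```
clean MP: length=697  mean=0.576  max=5.712  min=0.250
motif pair at (429, 45), discord at 289
duplicated x6: n 720 -> 900, sum|diff|=186.5, normalised=0.045
```

The discord lands at hour 289 — inside the planted anomalous day, which
starts at hour 288. Duplicating a random 5% of values six times adds
exactly 25% more data (720 → 900); aligning the corrupted profile against
the clean one accumulates 186.5 of absolute matched difference, i.e. a
normalised dissimilarity of 0.045 — a small perturbation, consistent with
the study's finding that the MP tolerates modest duplication noise.

The same pipeline is scriptable from a shell:

```bash
mpnoise generate --family traffic --n 3600 --seed 7 --out series.csv
mpnoise inject --input series.csv --noise irrelevant:p=0.05 --seed 7 --out masked.csv
mpnoise study --input series.csv --window 24 --dtw-radius 30 --seed 11 --out results/
```

## The analysis

Numbered drivers under `analysis/` rerun the whole study on synthetic
stand-ins for the three case-study datasets and write their tables under
`results/`:

| driver | what it does | output |
|---|---|---|
| `01_generate_series.py` | generate the three series | `series_overview.csv` |
| `02_clean_profiles.py` | clean MPs, motifs/discords | `clean_profile_summary.csv` |
| `03_noise_study.py` | ten noise conditions per series | `tables/`, `normalised_dissimilarities.csv` |
| `04_trends.py` | 20-seed trend check on traffic | `trend_summary.csv` |

Run them in order from the repository root (`python analysis/01_generate_series.py`
…). The headline results on the bundled runs: the median normalised
dissimilarity rises monotonically with both the duplication factor and the
irrelevant-feature proportion; inserting 5% irrelevant values disrupts the
profile far more than duplicating 5% of values twice (0.825 vs 0.127 on
traffic-like data), because duplicates form a pattern the profile can match
while uniform insertions match nothing; and the shortest series is hit
hardest.

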