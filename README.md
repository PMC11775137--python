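# sedarange

Temporal richness / range-size analysis for multi-lake sedimentary-DNA
(sedaDNA) plant community records.

Palaeoecologists reconstructing vegetation from lake-sediment
metabarcoding face a recurring question: as climate shifted from
glacial to interglacial, did taxa with large geographic ranges
accompany high richness (as facilitation-dominated communities would
suggest) or oppose it (as competition would)? `sedarange` implements
the full analysis chain for answering that from long-format read-count
tables over several lakes and 1000-year time-slices:

- **rarefaction** of every lake-slice sample to a common depth
  (5000 reads, 100 iterations) by hypergeometric subsampling;
- **range sizes** per taxon and slice by AOO (number of occupied
  lakes) and EOO (area of 200 km equal-area grid cells overlapping the
  convex hull of occupied lakes, under a Lambert azimuthal equal-area
  projection);
- **moving-window regression** of richness *S* on mean range size *R̄*
  in 5-slice (5000-year) windows: OLS with posterior slope simulation,
  Spearman's R, and sign classification (positive if R > 0.2, negative
  if R < −0.2);
- **heterogeneity** as multiple-site Jaccard turnover across lakes,
  β_JTU = 2Σmin(b_ij,b_ji) / [(ΣS_i − S_T) + 2Σmin(b_ij,b_ji)];
- **interaction GLMs**: logistic regressions of the per-window
  relationship sign on cushion-plant and tree read share (%), the
  stress-gradient proxies;
- a **positive co-occurrence network** of plant families (Spearman
  r > 0.6, BH-adjusted p < 0.05 after a 10-read / 5-slice filter) with
  exact modularity-optimal community detection;
- a **synthetic community generator** that reproduces the statistical
  structure the analysis assumes — a glacial regime where occupancy
  rises with richness and cushion plants dominate, a Holocene regime
  with the opposite coupling and tree dominance — so the whole
  pipeline is testable without sequencing data.

See `docs/methods.md` for the statistical details and the generator's
assumptions and limitations.

## Worked example

```python
import sedarange as sr

table, lakes, traits, truth = sr.generate_dataset(sr.SimParams(rng_seed=1))
cfg = sr.RunConfig(rng_seed=1)

rs = sr.rarefy_dataset(table, cfg)                      # 100 × 210 samples × 5000 reads
summaries = sr.slice_range_summaries(rs, lakes, cfg)    # per (iteration, slice)
results = sr.analyze_windows(summaries, cfg)

for res in results[:3] + results[-3:]:
    print(f"{res.label:>8}  n={res.n}  slope={res.slope:+7.2f}  "
          f"R={res.spearman_r:+.3f}  {res.sign_class}")
```

prints

```
   5–1ka  n=500  slope=  -8.54  R=-0.990  negative
   6–2ka  n=500  slope=  -8.19  R=-0.987  negative
   7–3ka  n=500  slope=  -8.17  R=-0.987  negative
 28–24ka  n=500  slope=  +9.39  R=+0.945  positive
 29–25ka  n=500  slope=  +9.74  R=+0.978  positive
 30–26ka  n=500  slope=  +8.22  R=+0.973  positive
```

Each window pools 500 (iteration, slice) points — 5 slices × 100
rarefaction iterations. Young (Holocene) windows show a negative
richness/range relationship, old (glacial) windows a positive one, and
the sign flips at the ~11 ka regime boundary built into the generator —
the qualitative pattern the analysis is designed to detect. The
`examples/` directory has one short script per capability (simulation,
rarefaction and range metrics, window regression, turnover, interaction
GLMs, network), each printing the numbers it computes with a note on
what they mean.

A thin CLI mirrors the stages for shell use:

```sh
sedarange run --seed 1 --outdir results/      # simulate → ... → network
sedarange report results/
```

Stages communicate through tidy CSVs in the output directory, and a
`manifest.json` records config, digests and versions; re-running with
the same seed reproduces bit-identical outputs.

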