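# swathbench

Multi-laboratory benchmarking analysis for SWATH-MS (data-independent
acquisition proteomics with peptide-centric scoring), as a reusable,
tested Python pipeline.

## The problem

Whether a mass-spectrometry acquisition method produces *reproducible*
results can only be settled by inter-laboratory studies: identical samples,
many sites, one central analysis. The benchmark this package implements
spikes 30 stable isotope-labeled standard (SIS) peptides — five groups of
six, serially diluted threefold from group starts of 1 fmol to 10 pmol,
covering 0.012–10,000 fmol on column — into a constant HEK293-style
background digest, acquired at 11 sites on a fixed schedule (5 samples/day,
S4 in triplicate, on days 1, 3, 5; 21 runs per site). The analysis then
asks: is the same set of proteins detected everywhere? how large are the
intra-day, inter-day and inter-site CVs? what LLOQ, linearity and dynamic
range does each site achieve? and do quantitative profiles cluster by
acquisition site?

`swathbench` provides every stage:

- **study_design** — dilution groups, nominal concentrations,
  per-site acquisition schedules;
- **synthetic data** — a generator emitting scored peak-group tables with
  1:1 decoys, SIS dilution responses with MS1 counterparts, site offsets,
  peptide×site effects, nested lognormal noise, signal saturation and a
  detection floor, with full ground truth;
- **error control** — semi-supervised combination of sub-scores into a
  discriminant (d-score), Storey/decoy q-values in the global and
  experiment-wide contexts, and the consecutive 1% FDR filter
  (global peptide-query ∧ global protein ∧ run-wise peptide-query):

  q(s) = min over t ≤ s of [ π̂0 · m · p(t) / #{targets ≥ t} ],  p(t) = #{decoys ≥ t}/#decoys

- **quantification** — protein abundance as the top-5 fragment areas of the
  top-3 peak groups, and median-equalization normalization transferable to
  the SIS areas;
- **dilution metrics** — 1/x-weighted response-curve fits, LLOQ by the
  bioanalytical rules (CV < 20%, S/N > 20, accuracy 80–120%), dynamic range
  log10(top/LLOQ), averaged per-group curves, step fold changes,
  percent-detected curves for MS2 vs MS1;
- **reproducibility** — CV = 100·sd/mean at intra-day / inter-day /
  inter-site levels, pairwise detection repeatability |A∩B|/|A∪B|,
  completeness;
- **similarity** — pairwise-complete Pearson correlation of normalized
  log2 protein abundances and hierarchical clustering (Euclidean,
  complete linkage) with Newick export.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
from swathbench import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_sites=3, n_proteins=200, seed=7, dropout=1)
report = run_pipeline(cfg, mode="synthetic", out_dir="out")
print(report.summary_text())
```

prints (abridged):

```
[detection]
  n_proteins_global: 191
  median_proteins_per_run: 185
  site_by_site_protein_counts: {'site01': 189, 'site02': 193, 'site03': 196}
  aggregated_per_site_protein_counts: {'site01': 191, 'site02': 190, 'site03': 191}
[quantification]
  n_proteins_quantified: 191
  n_complete_proteins: 181
[dilution]
  median_lloq_fmol_ms2: 1.235
  fold_3x: 2.927
  fold_9x: 8.617
  fold_27x: 25.39
[reproducibility]
  cv: {'sis_intra-day': {'median': 4.10, ...}, 'sis_inter-site': {'median': 31.4, ...},
       'sis_inter-site_norm': {'median': 23.3, ...}, ...}
  repeatability_study_wide_protein: 97.35
[similarity]
  median_all: 0.9923
  median_within_site: 0.9951
  median_between_site: 0.9915
```

Reading the numbers: of 200 simulated background proteins, 191 pass the
consecutive 1% FDR filter and the cumulative detection curve is flat after
a handful of runs (the global filter caps accumulation of false
identifications); the aggregated analysis gives each site a near-identical
protein count while the site-by-site analysis varies more. The adjacent
dilution-step fold change of 2.93 reflects the threefold design with mild
compression from saturation and the detection floor. Intra-day SIS CVs
recover the generator's 5% injection noise; inter-site CV drops from 31%
to 23% when the background-derived median normalization is transferred to
the SIS areas; and within-site correlations exceed between-site ones, the
signature of peptide×site effects that makes runs cluster by laboratory.

The same stages are available from a shell:

```sh
swathbench simulate --seed 7 --sites 11 --dropout 2 --out-dir out   # 229 run tables
swathbench detect   --seed 7 --in-peakgroups out/peakgroups.tsv --out-dir out
swathbench report   --seed 7 --out-dir out                          # full pipeline
```

In `real` mode the same pipeline reads peak-group and SIS area tables in
the documented TSV dialect (see `swathbench.io`), e.g. exported from an
OpenSWATH/MultiQuant analysis of the deposited study data.

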