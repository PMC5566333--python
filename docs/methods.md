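# Methods

`swathbench` re-implements, as a reusable and tested pipeline, the analysis
used to benchmark SWATH-MS (data-independent acquisition with
peptide-centric scoring) across multiple mass-spectrometry laboratories: a
dilution series of 30 stable isotope-labeled standard (SIS) peptides spiked
into a constant HEK293-style background proteome, acquired at many sites on
a fixed schedule, and analysed centrally for detection consistency,
quantitative reproducibility, sensitivity, linearity, and cross-site
similarity. This note documents the models, the synthetic-data generator
that stands in for the deposited raw study, the numerical choices, and the
limits of what the bundled tests demonstrate.

## Study design

Thirty SIS peptides are partitioned into five groups (A–E) of six. Each
group starts from a different top amount in sample S5 — by default 1, 10,
100, 1,000 and 10,000 fmol on column — and is serially diluted threefold
four times (S4 → S1), giving 25 nominal concentrations spanning
0.012–10,000 fmol (six orders overall, though no single peptide covers
them). The original study prints only the endpoint starts ("1 fmol to 10
pmol"); decade spacing for the intermediate groups reproduces both
endpoints and the overall span and is configurable. Every site acquires
S1–S5 once per day on days 1, 3 and 5, with S4 in technical triplicate: 7
injections/day, 21/site, 231 planned runs for 11 sites (the deposited study
retained 229 after two acquisition failures; the generator's `dropout`
parameter emulates this). Acquisition order within a day is S1→S5 ascending
with the S4 replicates consecutive — the published order lives in a
supplementary table we do not depend on, so this is a configurable
convention.

## Synthetic study generator

The generator emits scored peak-group tables (the input format of the
error-control stage), a MultiQuant-style SIS area table, and a ground-truth
table that the analysis stages never read.

**Background proteome.** `n_proteins` present proteins with log10
abundances uniform over `span_orders` (default 4.5) decades of
fmol-equivalent amounts, plus `absent_fraction` (default 0.5) library-only
proteins that are absent from the sample — mimicking a spectral library
that is a superset of the detectable proteome, which is what makes false
discovery control a non-trivial problem. Peptides per protein are
1 + Poisson(mean − 1) with mean 8 (matching the ~8 proteotypic peptides
per protein a deep library yields); ~15% of peptides are queried at a
second charge state; all peptides are proteotypic. Each query carries a
lognormal response factor and six relative fragment intensities
(Dirichlet, sorted).

**Signal model.** For a query carrying amount *a* in a run:

    area = gain · (soft_sat(a) · exp(ε) + n_floor · exp(η))
    soft_sat(a) = a / (1 + a / saturation_level)
    gain = site_offset · response_factor · site_peptide_effect · day_effect

with ε the injection-level lognormal noise (σ from `cv_intraday`, default
5%), η the interference noise (σ = 0.5), per-peptide day effects (σ from
`cv_interday`, default 7% — the day-level component on top of injection
noise), per-site global response offsets (log-uniform in 0.5–2× by
default), and lognormal peptide-by-site interaction effects (σ = 0.30).
The interaction term is essential: a purely global site offset is removed
exactly by median normalization and is invisible to log-scale Pearson
correlation, so it cannot reproduce the observed clustering of runs by
acquisition site. σ = 0.30 was calibrated so that site-wise clustering,
within-site > between-site correlation, and normalized inter-site CVs in
the 15–30% range all hold at once; it is a calibration choice, not ground
truth.

**Detection floor and S/N.** Each site has a detection floor in amount
space (default 0.1 fmol-equivalent). The noise-floor amount is defined as
`detection_floor / sn_at_floor` with `sn_at_floor = 20`, i.e. the floor is
*the amount at which the synthetic signal-to-noise ratio crosses 20* — the
same S/N criterion the bioanalytical LLOQ rules apply. This choice makes
the injected floor recoverable by the LLOQ procedure to within one
threefold dilution step, which is the parameter-recovery check the test
suite runs. The per-record floor is jittered lognormally (σ = 0.25). MS1
signals use the same model with a floor `ms1_interference_scale` (default
10) times higher and a 3× higher gain: MS1 precursors are brighter but
drown in interference near the limit, reproducing the ~one-order
sensitivity advantage of MS2 extraction.

**Saturation.** `saturation_level` defaults to 30,000 fmol-equivalent, so
the 10,000 fmol top point is visibly compressed (~25%), the mean adjacent
dilution-step fold change falls just below the design value of 3, and
removing the top point improves the linear fit — the qualitative behaviour
reported for the real instruments. Stronger saturation distorts the
1/x-weighted calibration line enough to push LLOQs of the high groups
upward, which the real data does not show.

**Targets, noise candidates and decoys.** A query above its floor emits a
true peak group whose sub-scores (4 of them) are shifted from the standard
normal null proportionally to log10(amount/floor), loaded unevenly across
sub-scores so the discriminant has something to learn. Below-floor and
absent-protein queries emit a noise-only candidate with probability
`p_noise` (default 0.5) — modelling a peptide-centric engine that reports
its best-scoring candidate signal whether or not the peptide is present —
and are otherwise missing from the run table. Decoys are generated
identically to noise candidates, one candidate decoy per library query at
`decoy_ratio` 1:1, so the decoy score distribution matches the target null
exactly and decoy-based error estimates are calibrated by construction.
Ground truth records presence per (run, query); empirical false discovery
proportions count discovered queries of absent proteins as false.

**Seeding.** A single master seed; every run, site effect and background
draw uses an independent substream derived from the seed and a CRC of the
entity's identifier, so outputs are byte-identical across calls and
insensitive to generation order.

## Error control

Sub-scores are combined by semi-supervised linear discriminant analysis:
seed on a designated sub-score (default the first), take targets passing an
inner q ≤ 0.15 cut against all decoys, fit an LDA, rescore, iterate
(default 5 iterations — unstated upstream; converges on separable data).
Weights can be learned on a subsample (the reference analysis used
≈ 1/number-of-samples) keyed by a stable hash of record identity so results
are invariant to row order; d-scores are standardised against the decoy
distribution.

q-values use decoy-ECDF p-values, Storey's π0 at fixed λ = 0.4, and the
step-up minimum. No smoothing is added to the decoy tail count, so a
target scoring above every decoy has q = 0 exactly. Two contexts are
computed: *global* (one q per unit, from its best-scoring instance across
all runs, targets and decoys reduced alike) and *experiment-wide* (one q
per unit per run, all records pooled). Protein-level scores are the
maximum d-score over the protein's queries — the simplest defensible
estimator; the upstream tools do not publish their formula — with decoy
proteins inheriting their decoy queries. Ties are broken by unit id.

Detection applies the consecutive filters: a peptide query is detected in
run *r* iff its global q and its protein's global q are ≤ α (default 1%)
*and* its run-wise q in *r* is ≤ α; a protein is detected where any of its
queries is. A consequence worth noting: the per-run detected sets of the
final matrix are subsets of the global-context set by construction, but
the raw run-wise q-value table alone is not — a unit seen in a single run
competes globally against best-of-N decoy maxima and can pass run-wise yet
fail globally.

## Quantification and normalization

Protein abundance per run: rank the protein's detected peak groups by
total fragment area, keep the top three (all if fewer), sum each one's top
five fragment areas (all if fewer), and add. The ranking statistic is the
summed fragment area ("most intense" is otherwise ambiguous); ranking by
apex fragment is available. Missing cells stay missing; nothing is imputed
here.

Normalization equalizes per-run medians of peak-group areas on the linear
scale, computed on detected, non-decoy background peak groups only (decoys
and spike-ins excluded so the invariant-background assumption holds). The
reference is the median of per-run medians, so coefficients are symmetric
around 1. The same per-run coefficients are applied to the SIS area table,
transferring the background-derived correction to the spike-in
quantification.

## Dilution metrics

Response curves are fit by weighted least squares of mean area against
nominal amount with 1/x weights (standard bioanalytical practice,
down-weighting the saturated top end); R² is the weighted coefficient of
determination. The LLOQ search walks from the lowest concentration up:
refit on retained points, test the lowest for replicate CV < 20%, mean
S/N > 20, and back-calculated accuracy within 80–120% (the accuracy uses
the fit including the evaluated point; leave-one-out is a flag); drop it
on failure and repeat; undetermined if no point passes or fewer than two
points remain. Retained points above the LLOQ that fail criteria are
flagged, not removed — the reference analysis removed only manually
confirmed interferences. Dynamic range is log10(top point / LLOQ).
Averaged response curves are per-group means of peptide mean areas (the
alternative — pooling all 30 peptides — would mix concentration grids).
Fold changes between points 1, 2 and 3 dilution steps apart are aggregated
by geometric mean, ratios being multiplicative. The percent-detected curve
counts a peptide at concentration *c* iff *c* ≥ its LLOQ, giving the
rising detection curves whose MS2-over-MS1 separation summarises the
sensitivity advantage.

## Reproducibility and similarity

CV is 100·sd/mean (sample sd). SIS CVs use the S4 sample: intra-day over
the three same-day replicates (per peptide × site × day), inter-day over
the nine S4 injections of a site's week, inter-site over all S4 injections
study-wide. Protein CVs use proteins detected in strictly more than 80% of
runs (the ">80%" boundary is strict). Reports carry the full per-unit
distribution; the headline is median ± sd of that distribution, with
per-site medians also available. Repeatability between two runs is
100·|A∩B|/|A∪B| over detected units; pairs with both sets empty are
excluded from medians and counted separately.

Pairwise run similarity is the Pearson correlation of normalized log2
protein abundances over each pair's common proteins (pairwise-complete,
minimum 3 shared proteins). Clustering is agglomerative with Euclidean
distance and complete linkage — the default behaviour of the R dist/hclust
routines this analysis is conventionally run with — on the complete-case
protein subset (median imputation is an option; which protein set the
original clustering used is not stated). Runs are processed in sorted id
order so merges are deterministic. The dendrogram serialises to Newick
with branch lengths from merge heights.

## Problem sizes used by the tests

The bundled checks run the full pipeline at reduced scale, chosen as the
smallest sizes at which the statistical claims are stable: FDR calibration
on ten replicate 3-site studies of 500 present proteins (mean realized FDP
at global q ≤ 0.01 stays below 0.02); floor recovery on ten replicate
single-site SIS studies; similarity structure on the full 11-site layout
with 150 proteins and 5 peptides/protein. Cluster purity by site is robust
at the 11-site layout (0.84–1.0 across seeds) but not at 3 sites, where
single outlier runs dominate complete-linkage merges.

## Known limitations

- The generator works at the level of scored peak groups: no spectra,
  chromatograms, retention-time drift, or fragment-level interference, and
  no cross-run alignment (the benchmarked workflow deliberately used none).
- Decoy generation is an idealised 1:1 null; real decoys inherit library
  imperfections the simulation does not model, so real-data calibration
  can be worse than the synthetic check shows.
- The background is biologically static across samples; only technical
  variation is simulated, so the tests say nothing about missingness or
  batch effects of biological origin.
- Site effects are purely multiplicative (global offset + peptide×site
  lognormal); drifts within a week are available (`drift_per_day`) but off
  by default.
- Headline values of the original study (e.g. 4,984 proteins at 1% FDR,
  median inter-site CV 47.3% → 21.3% after normalization, median Pearson
  0.940) derive from the 229 deposited runs and are reproducible only from
  the deposited tables, which this package reads in "real" mode but does
  not bundle.
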