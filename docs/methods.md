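# Methods

`cexqtl` implements bulk-segregant X-QTL mapping for obligate-outcrossing
worm crosses: a forward simulator of multigenerational segregant pools and
the pooled-sequencing statistics used to map QTLs from them. This note
documents the models, the defaults and why they hold, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## Population model

A cross between two inbred parents (allele A = parent 1, reference-like;
allele B = parent 2) founds an F1 population that is propagated through
non-overlapping generations without selfing. The biology encoded:

* **Meiosis.** Each chromosome independently undergoes at most one
  crossover per meiosis, with probability `p_xo = 0.5` — the effective
  rate of half a recombination per chromosome characteristic of
  C. elegans bivalents. The crossover position is drawn uniformly in
  genetic-map units (cM) and converted to bp through a piecewise-linear
  map, so crossovers concentrate where the map is steep (chromosome arms
  in the arm-biased fixture genome). One of the two reciprocal products is
  transmitted with equal probability.
* **Sex.** X/0 determination: males are hemizygous for the X; a sperm is
  X-bearing with probability 1/2 and determines offspring sex, so males
  inherit their X from the mother.
* **Mating.** Every female mates exactly once; her mate is drawn with
  replacement from the males with probability proportional to his fitness
  weight (uniform in the absence of fitness loci). Each mated female
  leaves a fixed number of progeny (default 10).
* **Regulation.** Offspring surviving drive lethality are pooled and
  down-sampled uniformly without replacement to the population cap
  (default 50,000). Defaults — 1,000 F1 founders, cap 50,000, 10 progeny
  per female — are the standard design for this kind of experiment.

Two representations implement the same meiosis rule. `Haplotype` /
`Individual` store exact breakpoint segments (at most one new breakpoint
per meiosis keeps the lists short) and expose the tiling invariant; the
`Population` engine stores parental origin at the marker grid as dense
int8 arrays, so a generation of a 50,000-individual population is a
handful of vectorised numpy operations. The marker-dense engine is the
package's own design choice for population-scale work: per-meiosis Python
loops do not scale to the hundreds of thousands of zygotes per generation
that the standard design produces. A unit test pins the two paths against
each other draw-for-draw, and the engine only ever needs genotypes at
markers, which is also all the downstream statistics consume.

A consequence of the one-directional founding cross (A females x B males)
worth knowing: the neutral expectation on autosomes is exactly 0.5, but on
the X it is 1/3 B, because F1 males carry only the maternal (A) X. Neutral
conservation checks therefore average over autosomal markers; X markers
equilibrate near 1/3 and their deviations should be read against that
baseline.

## Selection models

* **Toxin-antidote drive.** A sperm-delivered toxin with a zygotically
  expressed antidote, both linked at one autosomal locus: a zygote is at
  risk iff its father carries at least one element allele, and it dies
  with probability `s` (the penetrance) iff it inherits zero element
  copies. The maternal genotype never triggers lethality. Het x het
  crosses with `s = 1` therefore lose exactly the quarter of zygotes that
  inherit no element.
* **Fitness loci.** Per-genotype male mating weights, multiplied across
  loci. Only male participation is weighted by default; the hemizygous X
  maps dose 0/1 onto the homozygote weight classes. Whether several loci
  share one underlying factor or act independently is left open by the
  experimental evidence; the implementation exposes independent per-locus
  weights, which subsumes the shared-factor reading when the user scales
  them jointly.
* **Truncation selection.** Each individual's phenotype is `S = g + d`
  with `g` the 0/1/2 causal genotype and `d ~ Normal(0, sigma^2)`. The
  default `sigma^2 = Vl (1 - Ve) / Ve` (with `Vl = Var(g)`) is the
  variance-consistent form: it makes `Var(g)/Var(S) = Ve` exactly, for
  any causal-allele frequency. The alternative `as-printed` form
  `sigma^2 = (1 - Ve)/(Ve Vl)` is retained behind a flag; the two agree
  only at `Vl = 1`, and the variance-consistent form is the default
  because `Ve` is defined as the fraction of variance the locus explains.
  The top `truncation` fraction (default 5%) by `S` is the selected pool;
  the control is an independent uniform subset, by default of the same
  size (its size is a free design choice; equal sizes balance the two
  pools' sampling noise). Boundary ties are broken uniformly at random
  under the run's seed.
* **Sequencing.** Pooled reads are Binomial(C, pool allele frequency) per
  marker per pool at fixed depth C (default 100x), independent across
  markers — no read-level error model.

## Scan statistics

For counts n1/n3 (A/B, high pool) and n2/n4 (A/B, low pool), with baseline
allele-A frequency `q = n2/(n2+n4)` estimated from the control pool
(absorbing segregation distortion shared by both pools) and coverage C
(default: mean of the two pools' depths; `min` and `control` conventions
selectable):

    N = (1 - q)(n2 - n1) + q(n3 - n4)
    G = N^2 / (2 C q (1 - q))

The squared-numerator form is the default: a signed linear N/(2Cq(1-q))
can be negative, which neither a chi-square-type statistic nor a
log-normal null admits; under equal pool depths the squared form reduces
to (n2 - n1)^2 / (2Cq(1-q)), a 1-df chi-square-like quantity. The linear
form is available as `variant="as-printed-linear"` for fidelity, and
non-positive values are excluded before the log-normal fit.

Markers with a monomorphic or empty control pool (q outside (0,1)) are
excluded, not clamped — the statistic divides by q(1-q) — and the
exclusion count is logged.

Raw G is smoothed along the genetic map with a tri-cube kernel,
`(1 - D^3)^3` for normalized distance `D = |cM_j - cM_s| / 12.5` within a
+-12.5 cM window (W = 25 cM), weights normalised to sum to one. The null
distribution of smoothed G' is fitted robustly as log-normal using the
median and the normal-consistent MAD (x1.4826) of log G'; robust location
and scale tolerate the minority of true-signal markers, so the fit pools
all chromosomes without masking peaks. p-values are upper-tail
probabilities of that log-normal. The fit refuses fewer than 100 positive
G' values or a zero MAD.

Peaks are contiguous runs of markers below `alpha` (default 1e-5, a CLI
parameter; no effective-test correction is applied because the scan
reports raw p-values), summarised by the run's minimum-p marker (leftmost
on ties).

**Confidence intervals by simulation.** The whole experiment is
re-simulated with the causal variant planted at the observed peak and an
effect size drawn uniformly per iteration from a configured range (default
15-25% of variance): propagate, truncation-select, sequence, scan, record
the top-G' marker position on the peak's chromosome; the 95% CI is the
central nearest-rank interval of the recorded positions (for 1..1000 the
interval is [26, 975]). The default iteration count is 1300. Restricting
the recorded top marker to the peak chromosome keeps the interval
well-defined in iterations where another chromosome wins by noise.

## Selection-coefficient estimation

The drive's observable is a per-generation deviation trajectory: the
maximum, over markers in a window (default: the element's whole
chromosome — the search region is not otherwise constrained), of the
allele-frequency deviation toward the element-bearing parent. Candidate
penetrances on a 20-value grid spanning [0, 1] are each simulated (default
50 replicates x 10,000 worms x 20 generations); the estimate is the grid
value minimising the summed *absolute* difference between the mean
simulated and observed trajectories across shared generations. Absolute
rather than signed differences: a signed sum lets over- and under-shoot
cancel, making the objective non-identifiable. No interpolation between
grid values is attempted. Replicates that go extinct are dropped and
logged; more than 20% dropped is an error. The max-over-markers statistic
carries a small positive drift bias at `s = 0` that shrinks with
population size; it affects observed and simulated trajectories alike, so
the matching is unbiased to first order.

## eQTL mapping

Probes observed in fewer than 2/3 of samples are removed (a probe exactly
at the boundary is kept); expression and genotype rows are scaled to mean
0, variance 1 (population variance, over non-missing entries). Each probe
is Pearson-correlated with every marker — pairwise-complete with a
per-pair n when values are missing — and converted to
`LOD = -n ln(1 - R^2) / (2 ln 10)`. The genome-wide cutoff comes from
permuting the expression matrix's sample labels (genotype LD structure is
preserved) 100 times: `FDR(t)` is the mean permuted count of probes whose
best LOD reaches `t` divided by the observed count, evaluated on a 0.1-LOD
grid (configurable), and the cutoff is the smallest `t` with
`FDR(t) <= 0.05`. With no observed discoveries the result is flagged as
no-signal rather than given an arbitrary cutoff.

## Synthetic data

The fixture genome has 6 chromosomes of 17 Mb (one flagged X), 50 cM each,
with 45 of the 50 cM on the outer thirds — emulating the strongly
arm-concentrated recombination of C. elegans — and markers placed
uniformly in bp (2,000 by default). What it deliberately omits: real
marker ascertainment, variable per-site coverage, reference bias,
structural variants, mutation, selfing escape, and overlapping
generations. Passing tests therefore demonstrate correctness of the
simulation and inference machinery under the stated model, not robustness
to the artefacts of real pooled sequencing.

Experiment scales used by the test suite were sized for a single CPU:
neutral calibration at 1,000 individuals, drive fits at 10 replicates x
2,000 worms x 15 generations, detection-power runs at the full 50,000-
individual pool with a 3,000-marker grid, CI coverage at 4,000-individual
pools with 200 iterations.

## Resolution limits

Two distinct notions of "detection" behave very differently at these
scales. Significance — a genome-wide-significant peak on the correct
chromosome arm — is reached essentially always for a locus explaining 5%
of variance in a 50,000-pool design at 100x. Sub-cM *localization* of the
smoothed-statistic argmax is another matter: the 12.5-cM tri-cube window
flattens the G' profile into a plateau whose realised tilt is dominated by
per-marker coverage noise, so the argmax wanders by roughly +-2 cM at
desk-scale marker densities (hundreds to a few thousand markers). At very sparse grids (tens of markers per
chromosome) a second, systematic artifact appears: next to a gap in the
map, a marker's window can consist almost entirely of high-G neighbours,
so the normalised kernel average peaks beside the gap rather than at the
causal locus — kernel smoothing needs marker spacing well below the
12.5-cM window half-width to behave. The stochastic scatter
shrinks as marker density grows, because independent coverage
noise averages out within the window — at the ~10^5-SNV densities of real
experiments the top-variant spread tightens to sub-cM, which is exactly
what the simulation-based CI machinery quantifies. Users mapping at
moderate marker density should read peak positions with the
simulation-based CI, not as point estimates.
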