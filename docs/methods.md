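# Methods

## The neutral community model

The core question the package addresses is how much of the structure of a
set of gut microbial communities can be explained without invoking host
selection — by passive dispersal and ecological drift alone. Sloan's
neutral community model treats each local community (one animal's gut) as
a fixed pool of `N` individuals undergoing continual birth–death turnover.
When an individual dies, its slot is filled by an immigrant from a shared
source pool with probability `m`, or by the offspring of a local
individual otherwise. For a taxon whose relative abundance in the source
pool is `p`, the stationary distribution of its local relative abundance
`x` is well approximated by

    x ~ Beta(N m p,  N m (1 − p))

so the probability of *detecting* the taxon in a community — its expected
occurrence frequency across hosts — is the exceedance of that beta above
the detection limit `d`:

    f(p) = 1 − I_d(N m p, N m (1 − p))

with `I_d` the regularized incomplete beta function. The package fits `m`
by least squares on the per-OTU (mean relative abundance, observed
occurrence frequency) pairs and reports a generalized
`R² = 1 − SSE/SST`. `Nm` is the dispersal estimate; both `m` and `Nm` are
reported and labelled, since the two are often conflated in the
literature.

Key numerical choices:

- **N and d.** The model's `N` is taken as the arithmetic mean read depth
  and `d = 1/N` by default; both are configurable. Reads are not
  individuals, so the simulator decouples sequencing depth from the
  ecological community size — the fit only sees depths.
- **Optimization.** One-dimensional bounded least squares on
  `m ∈ (1e-6, 1]`, multi-started from {0.001, 0.01, 0.1, 0.5} plus a
  full-range pass with best-SSE selection, converged to `xatol = 1e-10`.
  The multi-start guards against the flat-SSE plateau the objective can
  develop at very small `m`.
- **Confidence interval on m.** Asymptotic standard error of the
  one-parameter nonlinear fit: `SE² = (SSE/(k−1)) / (JᵀJ)` with `J` the
  central-difference sensitivity of the predictions to `m`; the ±1.96·SE
  interval is truncated to (0, 1].
- **Prediction bands and partition.** Per-OTU 95% bands are Wilson score
  intervals around the neutral prediction with the number of communities
  as denominator. The Wilson form was chosen over the normal approximation
  because the study design has only 7–12 communities per treatment, where
  normal intervals under-cover badly. OTUs are labelled `above`, `neutral`
  or `below` the band.
- **R² is not clipped.** It may be negative when the neutral curve fits
  worse than a flat mean; reporting it as-is keeps poor fits visible.
- **Detection rule.** Default is "count ≥ 1 read"; a `rel_gt_d` rule
  (relative abundance strictly above `d`) is available. At depth ≈ N the
  two nearly coincide.

## The neutral simulator

Two modes with the same stationary target:

- **beta_multinomial** draws each community's composition from
  Dirichlet(`N m p`) — whose marginals are exactly the beta above — and
  then samples reads multinomially. This is the fast stationary shortcut
  used for fixtures. Tiny concentration parameters (rare taxa) are handled
  through the gamma representation, which degrades gracefully to exact
  zeros instead of failing.
- **moran** runs the mechanism itself: per event one uniformly chosen
  resident dies and is replaced by a source-pool draw with probability `m`
  or by the offspring of a uniformly chosen *surviving* resident. One
  generation is `N` events. Communities start as multinomial draws from
  the source and burn in for 200 generations by default — several times
  the ~`N/m`-event relaxation scale at the parameter ranges used here —
  which keeps desk-scale runtime while the acceptance checks confirm
  stationarity against the beta marginals (KS < 0.03 at N = 1000,
  m = 0.05 over 2000 communities). The update loop is vectorized across
  communities.

The simulator's configuration permits `m` only in (0, 1]; pure-drift
behaviour (fixation) is exercised with a vanishingly small rate rather
than exactly zero, which is indistinguishable over any finite run.

**Study fixture.** `make_study_fixture` emulates the design the analysis
chain is meant for: 29 gut communities from one shared 300-OTU log-series
source, split Control 10 / N-limitation 7 / P-limitation 12 with
immigration rates 0.017 / 0.038 / 0.023 and depth 1000 reads. The
log-series source (θ = 0.999) reflects the few-dominant-families shape of
real gut communities; a Dirichlet option exists for flatter pools. The
1000-read depth is a stand-in — no depth statistics were available for
the libraries the design mimics — and the absolute fitted values at other
depths will differ through `N` and `d`.

What the fixture does *not* emulate: taxonomic structure tied to real
lineages, chimeras and sequencing error (the OTU table is taken as
already clustered and denoised), overdispersion beyond neutral sampling,
and any selection. Passing tests on it demonstrate correct inference
*under the neutral model's own assumptions* — parameter recovery,
ordering recovery, calibration — not that real gut data are neutral.

## Read quality control

Filters for merged 341F/787R amplicon contigs, applied in a fixed order
with first-failing-rule attribution so reports are reproducible:
length within [135, 152] bp; mean Phred ≥ 25; no run of more than 3
consecutive low-quality bases; every base ≥ Q3; at least 75% of bases
high-quality; zero ambiguous bases. Two knobs deserve comment:

- The threshold defining a "low-quality base" for the run rule and the
  75% rule is not pinned down by the filter set's usual statement; the
  package defaults it to Q < 25, mirroring the mean-quality cutoff, and
  exposes it as `lowq_run_threshold` — one documented knob instead of a
  hidden constant.
- The 75% rule is read as a *total fraction* of high-quality bases. The
  alternative reading — a single contiguous high-quality block covering
  75% of the read — is stricter; if needed it can be emulated by
  tightening `max_lowq_run`.

Primer trimming matches the forward primer as a prefix and the reverse
complement of the reverse primer as a suffix, with IUPAC degeneracy codes
matching their base sets and a configurable mismatch allowance
(default 0). Input is Sanger Phred+33 only; scores above Q60 in the first
records trigger a Phred+64 warning. Chimera removal, pair merging and
demultiplexing are out of scope (established external tools).

## Differential abundance (LEfSe convention)

Per-sample counts are scaled to one million; each feature is screened
with a tie-corrected Kruskal–Wallis test (α = 0.05; constant features get
p = 1); significant features enter a bootstrapped two-class linear
discriminant: per bootstrap (30 by default) a class-balanced two-thirds
subsample is drawn, a Fisher discriminant direction is computed with the
within-class scatter ridge-regularised (ε = 1e-6 · trace/k, configurable),
and the per-feature raw effect is `0.5·(|coefficient| + |class-mean
difference|)`; the final score is `log10(1 + mean raw effect)`. This
follows the published convention of the LEfSe tool; bit-exact agreement
with that program is explicitly not promised — its internal effect
formula has undocumented details — and the subclass (Wilcoxon) stage is
omitted because the target design has no subclasses. With a taxonomy map
attached, clades from domain to genus can be expanded as summed features
and scored independently, with no multiplicity correction (the tool's
convention; noted, not endorsed).

## Grazing and stoichiometry calculators

Clearance `F = ln(Ct′/Ct) · V/(n·t)` compares end-point prey
concentrations in a grazer-free control bottle (Ct′) and the experimental
bottle (Ct); ingestion `I = F · [C]`. `F` is computed in the unit of `V`
(mL) and converted explicitly, defaulting to µL·ind⁻¹·d⁻¹ for reporting.
`[C]`, the prey concentration "averaged over the incubation", defaults to
the Frost-style logarithmic mean `(C₀ − C_t)/ln(C₀/C_t)` — exact when
prey decline exponentially under constant clearance — with the arithmetic
mean available. Negative clearance (prey net growth in the experimental
bottle) is returned with a warning rather than clamped, since truncation
would bias treatment means. Molar ratios use atomic masses C 12.011,
N 14.007, P 30.974 g/mol; relative expression is the standard
2^−ΔΔCt; polyphosphate fluorescence is normalised per mg protein. The
calculators are per-observation and agnostic about whether a renewal
design implies t = 1 d per daily interval or a cumulative incubation.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is deterministic
under it. The validation suite uses: 300-OTU / 29-sample tables with 20
replicates per immigration rate for recovery; 50 replicate study fixtures
for ordering; 2000 communities of 1000 individuals for the
moran-vs-beta comparison; 10⁶ Monte-Carlo draws per point for the
prediction check; 1000 reads for the QC oracle; 2000 features for screen
calibration; 2000 binomial draws for interval coverage. These sizes give
stable pass/fail behaviour across seeds at the tolerances stated in the
tests.

## Known limitations

- The fit assumes one shared source pool and a common `N` across
  communities; heterogeneous depths enter only through their mean.
- OTU-level observations are treated as independent in the least squares
  and in the per-feature screens; compositional coupling is ignored, as
  is standard for this model.
- The LDA effect size is a convention, not a calibrated statistic; its
  scores rank features but their absolute values depend on the scaling
  and ridge choices.
- The beta approximation degrades for taxa whose expected count `N·p` is
  below ~1; the moran comparison therefore targets the abundant taxa,
  where the approximation is meaningful at the discretisation `1/N`.
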