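# gutneutral

Quantitative toolkit for asking how much of a zooplankton gut microbiome's
structure is explained by neutral processes — passive dispersal from the
ambient water plus ecological drift — rather than host selection, and for
the supporting measurements such studies make along the way.

Built for microbial ecologists analysing 16S amplicon OTU tables from
replicated host communities (e.g. *Daphnia* guts under different diets),
it provides:

- **Neutral community model fitting** (`gutneutral.ncm`): Sloan's model
  predicts a taxon's occurrence frequency across hosts from its mean
  relative abundance `p`, the community size `N` and the immigration rate
  `m`, via the beta exceedance
  `f(p) = 1 − I_d(Nmp, Nm(1−p))` at detection limit `d`. The package
  estimates `m` (and `Nm`) by least squares, reports a generalized `R²`,
  95% Wilson prediction bands, and partitions taxa into
  above/within/below the neutral expectation.
- **Neutral assembly simulation** (`gutneutral.neutral_sim`): both the
  stationary Dirichlet-multinomial shortcut and individual-based Moran
  dynamics, plus fixture generators (a 29-community study-design table,
  FASTQ read sets with recorded truth, two-class tables with spiked
  fold changes).
- **Amplicon read QC** (`gutneutral.amplicon_qc`): the 135–152 bp /
  mean-Q25 / low-quality-run / Q3-floor / 75%-high-quality / zero-N
  filter set with IUPAC-aware 341F/787R primer trimming and per-rule
  rejection reports.
- **Differential abundance** (`gutneutral.diffabund`): LEfSe-convention
  Kruskal–Wallis screen plus bootstrapped LDA effect sizes on a
  per-million scale, reported in log10 units.
- **Ecological calculators** (`gutneutral.eco_calc`): clearance
  `F = ln(Ct′/Ct)·V/(nt)` and ingestion `I = F·[C]` rates, molar C:N:P
  ratios, 2^−ΔΔCt relative expression, and polyphosphate fluorescence per
  mg protein.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Simulate the 29-gut study design (three diet groups with immigration
rates 0.017 / 0.038 / 0.023 sharing one log-series source pool) and fit
the neutral model per group:

```python
from gutneutral import make_study_fixture
from gutneutral.ncm import fit_ncm_per_group

table = make_study_fixture(seed=1)
for label, fit in fit_ncm_per_group(table).items():
    print(f"{label:8s} m={fit.m:.4f}  Nm={fit.Nm:.1f}  R2={fit.r_squared:.3f}")
```

```
Control  m=0.0198  Nm=19.8  R2=0.677
N_lim    m=0.0548  Nm=54.8  R2=0.522
P_lim    m=0.0256  Nm=25.6  R2=0.664
```

Each fitted `m` is the per-replacement probability that a vacated slot in
a gut community is filled from the ambient pool rather than by local
reproduction; `Nm` is the corresponding dispersal estimate and `R²` the
fraction of occurrence-frequency variation the neutral curve explains.
Even with only 7–12 communities per group, the fitted rates recover the
simulation's ordering (N-limited > P-limited > Control) — the signature
of diet-enhanced immigration the model is used to detect.

The same chain is available from the shell:

```sh
gutneutral demo --seed 7 --out-dir demo_out
gutneutral simulate --m 0.038 --n-samples 7 --depth 1000 --otus 300 --seed 42 --out sim.tsv
gutneutral fit-ncm --table sim.tsv --out fit.json --plot fit.svg
gutneutral qc --in reads.fastq --out kept.fastq --report report.json
gutneutral graze --table grazing.tsv --out rates.tsv
```

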