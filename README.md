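# glycoce

Quantification of IgG-Fc N-glycosylation from capillary electrophoresis with
laser-induced fluorescence (CE-LIF), and the cohort statistics used to study
IgG hypogalactosylation in inflammatory arthritis.

## The problem

The fragment-crystallizable (Fc) region of IgG carries complex biantennary
N-glycans whose terminal galactosylation modulates antibody effector
function.  In rheumatoid arthritis (RA) the proportion of agalactosylated
glycoforms is elevated — *IgG hypogalactosylation* — and tracks inflammatory
activity, whereas in axial spondyloarthritis (axSpA) and healthy controls
(HC) it is not.  The standard readout is built from APTS-labeled Fc N-glycans
separated by CE-LIF: peak positions are expressed in **glucose units (GU)**
against a dextran hydrolysate ladder (degree of polymerization = GU), peak
areas are normalized to the total, and galactosylation traits are sums over
structures in modified Oxford nomenclature (F = core fucose, A*x* =
antennary GlcNAc, B = bisecting GlcNAc, [3]/[6]G1 = arm-specific galactose,
S*x* = sialic acids):

```
G0 = A2 + A2B + FA2 + FA2B
G1 = A2[3]G1 + A2B[3]G1 + FA2[6]G1 + FA2[3]G1 + FA2B[6]G1 + FA2B[3]G1
   + A2[3]G1S1 + FA2[6]G1S1 + A2B[3]G1S1 + FA2[3]G1S1
G0/G1 ratio = G0 / G1          G0% = 100 · G0
```

This package implements the full chain as a testable pipeline:

* `glycoce.reference` — Oxford-name grammar, trait classification, and the
  22-peak / 29-structure assignment table (comigrating structures resolved
  by their dominant member);
* `glycoce.egram` — peak detection and integration, migration-time
  normalization to the APTS-maltose internal standard, monotone
  piecewise-linear GU calibration through the ladder, annotation against the
  reference table, relative intensities;
* `glycoce.traits` — trait vectors (G0, G1, G2, G0/G1, G0%, fucosylation,
  bisecting, sialylation) per sample and per cohort;
* `glycoce.stats` — Mann-Whitney U, Kruskal-Wallis + Dunn post hoc,
  age/sex(/CRP)-adjusted regression, disease-activity slope heterogeneity
  across serostatus strata (robust Wald interaction test), age/CRP/duration
  stratification, treatment contrasts, transcript fold changes, and
  Bonferroni correction for the 12-hypothesis secondary family;
* `glycoce.synth` — synthetic cohorts calibrated to the published baseline
  characteristics (RA n = 178, axSpA n = 126, HC n = 119) and a CE-LIF trace
  renderer, providing ground truth for every stage.

## Worked example

Simulate a healthy-control trace and quantify it:

```python
from glycoce import compose_profile, render_electropherogram, process_sample

areas = compose_profile(target_ratio=1.10, target_g0_percent=38.0)
sample, ladder = render_electropherogram(areas, seed=4, target_min_snr=60)
result = process_sample(sample, ladder)
print(f"G0/G1 ratio: {result.traits.g0_g1_ratio:.4f}  G0%: {result.traits.g0_percent:.2f}")
```

prints

```
G0/G1 ratio: 1.1040  G0%: 38.08
```

i.e. the pipeline (detection → maltose normalization → GU calibration →
annotation → relative areas → traits) recovers the composed targets within
0.5%.  The same run from the shell:

```
glyco simulate --preset table1 --seed 3 --out out/        # 3-cohort study table
glyco process  --egram trace.tsv --min-snr 5 --out out/   # one sample
glyco stats    --cohort out/cohort.csv --analysis groups  # KW + Dunn + MW
```

On a simulated study table, the group analysis reproduces the qualitative
findings: RA well above HC and axSpA (Dunn p ≈ 1e-19 at these sample
sizes), HC and axSpA indistinguishable, and sulfasalazine-treated RA showing
lower hypogalactosylation in the age/sex/CRP-adjusted model.

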