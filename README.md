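# insptools

Stereochemistry, subsite modelling, kinetics and quantification tools for
inositol phosphate kinases, built around the enzymology of *Arabidopsis*
ITPK4 (an inositol tris/tetrakisphosphate kinase with an unusual
enantiospecificity, a low K<sub>M</sub> for ATP and an N-terminal
HAD-like domain).

## Who this is for

Researchers working on plant inositol phosphate metabolism who need to:

* reason combinatorially about *myo*-inositol phosphate isomers — parse
  and format 1D names such as `Ins(1,4,6)P3`, take enantiomers under the
  C2/C5 mirror map (1↔3, 4↔6), detect meso species, and enumerate all
  isomers at a phosphorylation level;
* apply the hydroxy-kinase / phosphotransfer-to-ADP reaction map (ATP +
  InsP<sub>n</sub> ⇌ ADP + InsP<sub>n+1</sub>), including the measured
  AtITPK4 substrate table shipped as a machine-readable fixture;
* build stereochemically valid substrate poses on an idealized chair ring
  (obverse/reverse face rule, 180° C2–C5 flips, Kabsch superposition) and
  read off the A–F specificity subsite occupancy that rationalizes which
  enantiomer of a substrate pair the enzyme prefers;
* fit initial-rate data to the Michaelis–Menten or substrate-inhibition
  rate law, *v* = V<sub>max</sub>·S / (K<sub>M</sub> + S·(1 + S/K<sub>i</sub>)),
  with deterministic initialization and positive-parameter constraints;
* quantify inositol phosphates from chromatographic traces
  (baseline correction, peak detection, integration, calibration against
  an InsP6 standard, per-gram amounts, Welch tests across genotypes);
* scan protein sequences for HAD-superfamily signature motifs (I–IV) and
  classify HAD cap types (C0/C1/C2).

Every pipeline stage has a seeded synthetic-data generator
(`insptools.synth`) that emits a truth sidecar, so closed-loop recovery
can be scored end to end.

## Worked example

Fit the substrate-inhibition rate law to one noisy synthetic saturation
dataset generated at the AtITPK4 reference parameters (K<sub>M</sub> 52 µM,
V<sub>max</sub> 8.64 nmol·min⁻¹·mg⁻¹, K<sub>i</sub> 3.3 mM, 5%
proportional noise):

```python
from insptools.synth import gen_kinetic_dataset
from insptools.kinetics import ITPK4_ATP_KINETICS, KineticModel

df = gen_kinetic_dataset(ITPK4_ATP_KINETICS, noise_cv=0.05, seed=42)
res = KineticModel.from_dataframe(df, model="si").fit()
print(res.summary())
```

```
Kinetic fit results
===================
rate law:            substrate-inhibition
observations:        9
residual SSQ:        0.461436

 param     estimate      std err                units
  Vmax        7.977        0.356      nmol min-1 mg-1
    KM        43.64         5.99                   uM
    Ki         3896          624                   uM

optimum S = sqrt(KM*Ki) = 412.3 uM; Ki = 3.9 mM
```

A single 9-point replicate recovers the generating parameters to within
roughly their standard errors; medians over many seeded replicates
converge on the generating values (see the acceptance script below).

The subsite model explains why Ins(1,4,6)P3 is the preferred enantiomer:
posed for 3-kinase action (reverse face toward the γ-phosphate), its
4-phosphate occupies subsite B, the pocket whose occupancy tracks
substrate quality:

```python
from insptools import parse_name, occupancy_report
rep = occupancy_report(parse_name("Ins(1,4,6)P3"), 3)
print(rep["face"], rep["mapping"], rep["occupancy"]["B"], rep["favourability"])
```

```
reverse {'A': 3, 'B': 4, 'C': 5, 'D': 6, 'E': 1, 'F': 2} phosphate favourable
```

The mirror substrate Ins(3,4,6)P3, posed for 1-kinase action, instead
puts the poorly solvated axial 2-hydroxyl in subsite B and is flagged
unfavourable.

A command-line interface mirrors the library
(`insptools isomers --n 5 --report meso,pairs`, `insptools react ...`,
`insptools subsites ...`, `insptools fit-kinetics data.csv --model si`,
`insptools simulate panel --seed 1 --out dir/`,
`insptools scan-motifs seqs.fasta`).

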