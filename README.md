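# cinnaprint

**¹H-NMR fingerprinting, absolute quantification and safety screening for
cinnamon species authentication.**

Commercial "cinnamon" may come from several *Cinnamomum* species —
*C. verum* ("true" Ceylon cinnamon), *C. cassia* and *C. burmannii* —
that differ sharply in their content of bioactive molecules, most
importantly coumarin, a hepatotoxin with a regulatory tolerable daily
intake (TDI) of 0.1 mg per kg body weight per day. `cinnaprint` is a
library plus CLI for labs that authenticate such products by proton NMR:

* **simulate** 400 MHz 1-D spectra (32 K points, Lorentzian lines,
  solvent residuals, calibration reference) with known metabolite content;
* **fingerprint** spectra by rectangular bucketing over 1–12 ppm at
  0.01 ppm, solvent-region exclusion, and per-spectrum 0/1–100 integer
  normalization;
* **cluster** fingerprints hierarchically (Euclidean + Ward) and score
  species purity of the dendrogram;
* **quantify** 16 catalogued metabolites in mg per g of product by the
  external-reference qNMR ratio
  `C_met = (A_met/A_ref)·(n_ref/n_met)·C_ref`, in triplicate with
  mean ± SD reporting and signal-to-noise based ND flags;
* **classify** species by PCA ordination and nearest-centroid assignment
  in autoscaled metabolite space, with diagnostic concentration ratios;
* **screen** coumarin content against the TDI: the daily grams of product
  reaching the limit are `0.1 · bodyweight / c` for content `c` mg/g.

A 48-sample × 16-metabolite reference concentration table (mean ± SD,
with not-detected entries) and the metabolite signal catalogue are bundled;
see `docs/methods.md` for the underlying models and design choices.

## Worked example

Simulate the triplicate measurement of a high-coumarin cassia sample,
quantify it, and ask how much of the product a 60 kg consumer could eat
per day before hitting the coumarin TDI:

```python
import cinnaprint as cp
from cinnaprint.quantify import quantify_sample
from cinnaprint.safety import tdi_max_daily_grams

truth = cp.GroundTruth("Cin_cass_20", "C. cassia",
                       {"Coumarin": 9.2, "Cinnamaldehyde": 0.35,
                        "Methoxy cinnamaldehyde": 28.97})
reps = [cp.simulate_spectrum(truth, cp.SimulationParams(noise_sd=0.01, seed=s))
        for s in (1, 2, 3)]
result = quantify_sample(reps)
for name in ("Coumarin", "Cinnamaldehyde", "Methoxy cinnamaldehyde"):
    print(f"{name:24s} {result.mean[name]:6.2f} +/- {result.sd[name]:.2f} mg/g")
limit = tdi_max_daily_grams(result.mean["Coumarin"], body_weight_kg=60.0)
print(f"max daily intake at 60 kg: {limit:.3f} g of product")
```

```
Coumarin                   9.20 +/- 0.00 mg/g
Cinnamaldehyde             0.35 +/- 0.00 mg/g
Methoxy cinnamaldehyde    28.97 +/- 0.00 mg/g
max daily intake at 60 kg: 0.652 g of product
```

The quantifier recovers the generating concentrations exactly (to the
reported precision) because analyte and reference integrals share the same
window width, and flags that two thirds of a gram per day of this product
already exhausts a 60 kg adult's coumarin allowance.

The same screen over the bundled reference table, from the shell:

```sh
$ cinnaprint safety src/cinnaprint/data/reference_concentrations.csv
2 sample(s) exceed the TDI at 1.0 g/day, 60.0 kg
Cin_cass_20	coumarin 9.2 mg/g	max 0.6522 g/day
Cin_cass_12	coumarin 6.94 mg/g	max 0.8646 g/day
```

`cinnaprint all --out run --seed 42` runs the whole pipeline
(simulate → fingerprint → cluster → quantify → classify → safety) and
writes spectra, fingerprints, a Newick dendrogram, quantification and
ordination CSVs, species calls, the TDI report and a manifest; identical
config and seed give byte-identical outputs.

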