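# mbaq

Median-based absolute protein quantification (MBAQ) for label-free LC-MS/MS,
built around a fully unlabeled generic internal standard — a chimeric protein
that digests into equimolar artificial tryptic peptides.

## The problem

Label-free proteomics measures extracted-ion-chromatogram (XIC) peak areas,
which are only proportional to molar amount through an unknown, peptide-specific
ionization efficiency. Targeted methods fix this with isotope-labeled standards,
but cover few proteins; intensity heuristics (Top3/Hi-3, iBAQ) cover the
proteome but are biased by the best-ionizing peptides. MBAQ sits between the
two: the peak areas of an equimolar peptide mixture cluster around a median
that is largely independent of sequence, so that single median converts any
peak area into moles.

## The method

Given a run with a codigested standard chimera and a reference protein of
known amount *A*<sub>ref</sub> (e.g. 1 pmol BSA):

1. **Standard amount** from native/scrambled reference-peptide pairs:
   *A*<sub>std</sub> = *A*<sub>ref</sub> · median<sub>pairs</sub>(area<sub>scrambled</sub> / area<sub>native</sub>)
2. **Single-point calibrant**: *m* = median of the detected standard-peptide
   areas (zeros excluded); **response factor** *f* = *A*<sub>std</sub> / *m*
   (mol per area unit).
3. **Peptide molar estimates**: *â*<sub>p</sub> = area<sub>p</sub> · *f* for
   every detected analyte peptide.
4. **BestN protein amounts**: from the Top3 pool of a protein's estimates,
   take the size-2 or size-3 subset with the lowest coefficient of variation
   (CV, sample SD/mean); the protein amount is its arithmetic mean, flagged
   `qc_pass` when CV < 20 %. Two-peptide proteins use the pair directly;
   single-peptide proteins are excluded.
5. **QC statistics**: NMA (normalized median abundance) — the standard's
   median area over the reference-derived expectation, unity for an unbiased
   calibrant — and the near-median fraction (peptides within ±20 % of the
   median).

The package also contains the designer for such standards (tryptic digestion,
proteotypic filtering, constrained sequence scrambling with monoisotopic-mass
and hydropathy checks, uniqueness against proteome FASTAs), a bootstrap
analysis of how many peptides a stable median needs, and a synthetic-data
generator with known ground truth.

## Worked example

```python
from mbaq import (simulate_dataset, calibrate_all_runs, quantify_run,
                  truth_recovery_report)

table, spec, truth = simulate_dataset(seed=1)   # 200 proteins x 5 peptides x 3 runs
cals = calibrate_all_runs(table, spec)
cal = cals["run1"]
print(f"standard amount: {cal.standard_amount/1e-15:.0f} fmol")
print(f"median XIC area: {cal.median_area:.1f}")
print(f"NMA: {cal.nma:.2f}   near-median fraction: {cal.nm_fraction:.2f}")

quants = [q for run, c in cals.items() for q in quantify_run(table, spec, c)[0]]
rep = truth_recovery_report(quants, truth)
print(f"quantified {rep['n']} proteins over {len(cals)} runs; "
      f"median error vs truth: {rep['median_percent_error']:.1f}%")
```

prints

```
standard amount: 302 fmol
median XIC area: 271.4
NMA: 0.89   near-median fraction: 0.37
quantified 200 proteins over 3 runs; median error vs truth: 21.8%
```

The simulated standard was loaded at 300 fmol, and the scrambled/native
reference pairs recover 302 fmol; the 43 equimolar standard peptides spread
about 10-fold, with 37 % of areas within ±20 % of the median in this run; the
BestN amounts of 200 proteins spanning 3 orders of magnitude are recovered
with a median error of 21.8 %.

The same pipeline is available from the shell:

```
mbaq simulate --n-proteins 200 --seed 1 --out sim/
mbaq quantify --table sim/peptides.csv --standard sim/standard.yaml --out quant/
mbaq bootstrap --table sim/peptides.csv --standard sim/standard.yaml --out boot/
mbaq design --peptides peps.txt --proteome-db proteome.fasta --out design/
```

Designing a scrambled standard peptide:

```python
from mbaq import scramble_peptide
r = scramble_peptide("HLVDEPQNLIK", seed=1)
print(r.product_seq, r.events, f"{r.mono_mass_delta:+.4f} Da")
# HLVDPENNLIK [('swap', 5, 6), ('substitute', 7, 'Q', 'N')] -14.0157 Da
```

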