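# Methods

## Model

MBAQ treats a digested standard chimera as an equimolar peptide mixture whose
XIC peak areas, despite a roughly 10-fold spread in ionization efficiency,
cluster around a median. That median area corresponds to the (known) molar
amount of the chimera and becomes a single-point calibrant: any codetected
peptide's molar estimate is its area times the response factor
f = A_std / median_area.

The standard's own amount is not assumed; it is measured in-run against a
reference protein of known amount through native/scrambled peptide pairs:
A_std = A_ref · median over pairs of (area_scrambled / area_native). The pair
members are near-identical sequences (one conservative scramble apart), so
their efficiencies cancel in the ratio.

Two QC statistics summarize calibrant quality:

* **NMA** (normalized median abundance) = median standard area / (A_std ·
  k_ref) with k_ref = median over pairs of (area_native / A_ref). NMA is 1
  exactly when the standard peptides' median response equals the
  reference-derived response; it is the package's reconstruction of a
  statistic that is usually described only verbally, chosen so the no-bias
  point is exactly 1. A reversed-sequence standard, whose peptides ionize at
  roughly 0.45× their sources, yields NMA 0.45 under this definition — the
  reported linearity is exact because NMA is a ratio of medians.
* **Near-median fraction**: share of standard areas within ±20 % (relative)
  of their median. The 20 % band mirrors the CV acceptance threshold used
  throughout; both are configurable.

The calibrant median and NMA are computed over the standard's *near-median*
peptides, excluding the scrambled reference peptides: the reference pairs
determine the amount, the NM peptides the median. Zero areas mean "not
detected in this aligned run" and are excluded before every median; a warning
is issued when fewer than 30 standard peptides are detected, where the
bootstrap analysis shows the median's spread has not yet plateaued.

Calibration is per-run by default. The pooled mode treats runs as technical
replicates of one digest: one amount from all (run, pair) ratios jointly and
one median from all detected standard areas jointly, hence one shared
response factor. Pooling is the appropriate choice when the runs genuinely
remeasure the same sample, and it is what the recovery and dilution analyses
in the acceptance script use.

## Protein quantification

BestN: the protein's Top3 pool (three largest molar estimates, ties broken
lexicographically by sequence for cross-platform determinism) is searched
exhaustively over all size-2 and size-3 subsets; the subset with the smallest
sample CV (n−1 denominator, chosen for small-n correctness) wins, ties broken
deterministically by the sorted peptide tuple. The protein amount is the
subset's arithmetic mean. Proteins with exactly two peptides use the pair
(qc_pass records whether its CV clears the threshold); one-peptide proteins
are excluded and reported in a separate table rather than silently dropped.
Peptides shared between proteins are excluded by default and flagged. An
optional mean/median concordance filter (|mean − median|/median < 15 %) is
available but off by default, since the CV-based selection is the primary
algorithm. TopN/Hi-3 (mean of the Top3) is provided as the comparator.

Derived metrics: percent error = 100·|est − ref|/ref; copies per cell =
amount · N_A / cells; dilution concordance = per-protein amount ratios
against an expected ratio, with per-protein accuracy
100·(1 − |ratio − expected|/expected) summarized by the mean (and median).
Amounts are aggregated per protein by the median over runs before ratios are
formed.

## Bootstrap median stability

To ask how many equimolar peptides a stable median needs, k areas are drawn
without replacement (subset selection; a with-replacement mode exists behind
a flag) and their median recorded over n_iter = 100 iterations, for k from 3
to 120. The spread metric is the CV of the iteration medians — the plotted
spread is never named in descriptions of this experiment, and the CV makes
profiles comparable across pools. At k = pool size every draw is the full
set, so the spread is exactly 0. The recommended minimum is the smallest k
whose spread is below a threshold and changes by < 10 % (relative) over the
next two larger profiled k — a reconstruction of "reaching a plateau"; if no
k qualifies the largest is returned with a warning. Monte-Carlo jitter of the
spread estimate is ≈ spread/√(2·n_iter), so monotonicity checks in the tests
use a log-spaced k grid and 200–300 iterations, where successive decrements
dominate the jitter; the plateau search uses the dense unit grid.

## Standard design

In-silico trypsin cleaves after K/R except before P (the conventional rule).
Proteotypic candidates are fully tryptic peptides with no missed cleavage,
length 7–25 (standard practice bounds), no Cys or Met (oxidation/alkylation
artifacts), and no acidic N-terminal residue.

Scrambling makes a peptide distinct from all natural sequences while
preserving length, C-terminal K/R, net charge and hydropathy. The rule set:
at most one swap of two non-terminal residues plus at most two conservative
substitutions, drawn from S↔T, D↔E, N↔Q, F↔Y and aliphatic pairs of similar
hydropathy (|ΔKD| ≤ 2.5 on the Kyte–Doolittle scale, which allows G↔A, A↔V,
A↔L, V↔L, V↔I, L↔I and forbids G↔{V,L,I} and A↔I). The bound of one swap and
two substitutions is what the canonical reference pairs themselves require:
three of the four published BSA pairs are two edits, while
LGEYFGQNALIVR/LGDYGFNNALIVR differs at four positions and minimally
decomposes into one swap plus two substitutions. A valid scramble must change
the monoisotopic mass (so the product is MS-distinguishable from its source);
L↔I alone is mass-neutral and therefore never chosen as the mass-shifting
substitution, though it is accepted in validation when another edit shifts
the mass. Generation applies one swap and one mass-shifting substitution,
preferring middle-third positions and, among those, the substitution with
the smallest hydropathy change; retention time is not predicted — the mean
Kyte–Doolittle shift is reported as a proxy and warned about above |Δ| > 0.5.
Uniqueness is checked as substring occurrence in supplied proteome FASTAs
(any tryptic peptide of a database protein is necessarily a substring, so
the substring scan subsumes the tryptic-equality check; matches still report
which kind they are).

## Synthetic data

The generator emulates the statistical structure of a real standard digest:

* **Ionization efficiency** per peptide: with probability p a near-median
  draw, uniform on [0.8, 1.2]; otherwise a log-uniform tail on
  [10^-1/2, 10^1/2] excluding the band — a 10-fold total spread. p is solved
  from the two components' in-band retention rates so that the *realized*
  near-median fraction after replicate noise matches the 0.45 target
  (reported real standards cluster 42–48 % of peptides near the median).
  Standard-peptide efficiencies are normalized to median exactly 1, making
  the noise-free calibrant bias-free by construction.
* **Replicate noise**: multiplicative lognormal, σ = 0.1, keeping technical
  CVs in the single-digit-percent range typical of aligned label-free data.
* **Reference pairs**: the five native BSA proteotypic peptides (the four
  canonical published pairs plus LVNELTEFAK) scrambled by the package's own
  designer. Pair response ratios are constructed symmetrically around 1
  within [0.97, 1.03], the pair's two areas share their replicate noise with
  only a bounded ±2 % ratio jitter (paired co-eluting peptides co-vary; real
  native/scrambled pairs differ by < 5 %), and reference-peptide
  efficiencies are near-median draws normalized to median 1 (they are
  hand-picked, well-ionizing peptides).
* **Analytes**: 200 proteins by default, amounts log-uniform over 3 orders
  of magnitude (1 fmol–1 pmol), 5 peptides each with mixture efficiencies,
  3 technical runs; the standard is loaded at 300 fmol against a 1 pmol
  reference. A dilution factor scales analyte amounts only, and the noise
  stream is derived from (seed, dilution) so a dilution twin shares its
  ground truth but is an independent measurement. An optional per-protein
  efficiency outlier (inject_outlier_fold) reproduces the scenario where the
  most abundant peptide biases Top3/Hi-3 but is excluded by BestN.

What the generator does **not** model: chromatographic alignment errors,
interference/coelution, digestion kinetics and miscleavage, charge-state
splitting, intensity-dependent (heteroscedastic) noise, or missingness
beyond area = 0 dropout. Passing recovery tests therefore demonstrates the
estimator's behavior under the stated response model, not performance on any
particular instrument.

## Numerical choices and edge cases

Duplicate (run, protein, peptide) rows are summed on input (charge states
and modified forms collapse to the peptide level) with a logged warning;
modification annotations in brackets/parentheses are stripped and sequences
compared case-insensitively. Medians are used for all cross-pair and
cross-run aggregation, consistent with the method's robustness philosophy.
All molar quantities are SI mol internally; files use fmol. Empty inputs,
non-canonical residues, negative areas, zero-mean CVs and k > pool bootstraps
raise typed errors rather than propagating NaNs.

## Problem sizes

Default analyses run 200 proteins × 5 peptides × 3 runs; the recovery
acceptance repeats this over 50 seeds and the bootstrap profiles use a
230-peptide pool at 100–300 iterations per k. Everything completes in well
under a minute per analysis on one CPU.

## Known limitations

The standard-amount estimate rests on as few as five reference pairs, so its
sampling error (a few percent per run) is the dominant systematic across a
run; pooled calibration mitigates it. NMA inherits that error plus the
median-area spread, so single-run NMA values of 0.85–1.15 are within
expectation at σ = 0.1. The designer's substitution table is an explicit,
configurable choice: the complete table used for published standards is not
public, and the adopted KD-distance rule is the smallest principled set
consistent with the known examples.
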