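# pdselex

Simulation and analysis of **library-vs-library in vitro selection** of
RNA–protein pairs (PD-SELEX: phage display coupled with SELEX), for
researchers engineering orthogonal RNA–RNA-binding-protein (RBP) modules for
synthetic biology.

In a PD-SELEX campaign, a randomized RNA pool (a hairpin library with an
N20 loop, up to 4^20 ≈ 1.1 × 10^12 species) and a phage-displayed protein
pool (an L7Ae-like scaffold with 8 NNK-randomized surface residues,
theoretical diversity 20^8 = 2.56 × 10^10) are co-enriched as complexes
through a two-step affinity purification: phage are immobilized on beads
and capture their RNA ligands (step 1), then RNA–phage complexes are pulled
down via a fixed 3′ docking sequence on the RNA (step 2). Both pools are
amplified and re-selected over several rounds of increasing stringency, and
the surviving sequences are read out by NGS. The package provides:

- **`pdselex.simulate`** — a stochastic campaign simulator (equilibrium
  capture against the abundance-weighted partner mixture, avidity and urea
  stringency as apparent-K_D adjustments, binomial thinning, multinomial
  bottlenecks, lognormal amplification bias, barcoded FASTQ reads with
  substitution errors), with an exact expectation mode for analytic checks.
- **`pdselex.enrichment`** — the NGS analysis: demultiplexing,
  variable-region extraction, count tables, round-to-round enrichment
  factors EF = abundance_after / abundance_before, the monotonic EF ≥ 1
  filter, top-N ranking, copy-number diversity profiles, IUPAC
  consensus-motif fractions, positional residue preferences.
- **`pdselex.deconvolution`** — re-selection of a focused RNA library
  against individual candidate proteins, motif-subset box statistics, and
  cognate / depleted / neutral calls with orthogonal-pair proposals.
- **`pdselex.kinetics`** — a statsmodels-style `LangmuirModel` /
  `KineticFitResults` pair implementing the 1:1 Langmuir SPR model

  R(t) = R_max · C·k_on/(C·k_on + k_off) · (1 − e^−(C·k_on + k_off)·t)
  (association),  R(t) = R(t₀)·e^−k_off(t−t₀) (dissociation),

  fitted globally across a concentration series with K_D = k_off/k_on,
  double referencing, no-binding calls, replicate aggregation, and
  selectivity / orthogonality matrices.
- **`pdselex.library`** — NNK degenerate-codon statistics, diversity
  arithmetic, and IUPAC motif matching shared by all stages.

## Worked example: fitting SPR kinetics

Simulate a five-concentration sensorgram series at the rate constants of a
picomolar RNA–RBP pair (k_on = 2.00 × 10^7 M⁻¹s⁻¹, k_off = 1.36 × 10^−4
s⁻¹, so K_D = 6.8 pM), add 1 RU of noise, and fit globally:

```python
import numpy as np
from pdselex import LangmuirModel, LangmuirParams, simulate_sensorgrams, selectivity

rng = np.random.default_rng(0)
true = LangmuirParams(k_on=2.00e7, k_off=1.36e-4, r_max=100.0)
concs = np.geomspace(0.3, 30, 5) * true.k_d
sgs = simulate_sensorgrams(true, concs, t_assoc=200, t_diss=1500, dt=2,
                           noise_sd=1.0, rng=rng)
fit = LangmuirModel(sgs).fit()
print(fit.summary())
print(f"selectivity over LS12: {selectivity(2.75e-8, fit.k_d):g}-fold")
```

prints

```
1:1 Langmuir global fit
  curves: 5   RSS: 4249   converged: True   no binding: False
  parameter             estimate       std err
  k_on [1/(M s)]       1.981e+07     1.451e+05
  k_off [1/s]          0.0001338     1.439e-06
  R_max [RU]               100.5        0.5333
  K_D [M]              6.754e-12             -
selectivity over LS12: 4070-fold
```

The fitted rates recover the generating values within about 1% despite the
noise, the derived K_D is their exact quotient, and dividing an off-target
K_D (27.5 nM) by the fitted cognate K_D gives the fold selectivity.
`fit.plot()` overlays the data and fitted curves.

## Command line

Four entry points wrap the same machinery on files:

```bash
pdselex simulate  --out sim/ --seed 5 --n-rna 2000 --n-protein 50 --rounds 3
pdselex analyze   --rounds sim/rna_round0.fastq --rounds sim/rna_round1.fastq \
                  --rounds sim/rna_round2.fastq --rounds sim/rna_round3.fastq \
                  --motif UUGUGASGC --out analysis/
pdselex deconvolve --pre pre.tsv --post LS4.tsv --post LS12.tsv \
                  --motif UUGUGASGC --motif UCCAUGACGC --out dc/
pdselex spr-fit   --input sensorgrams.csv --out fit/
```

Every run writes a `manifest.json` recording inputs, parameters, the seed
and output checksums; the same seed reproduces outputs byte for byte.

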