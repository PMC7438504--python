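# cavekit

Analysis toolkit for bacteriophage directed-evolution experiments that couple
chemical mutagenesis with thermal selection. It provides:

- **kinetics** — nth-order (fractional-order) thermal-degradation model
  `dN/dt = -k(T) N^n` with Arrhenius coupling
  `k(T) = k_ref exp(-(Ea/R)(1/T - 1/T_ref))`; global bounded trust-region
  least-squares fitting of `(n, k_ref, Ea)` to log-transformed
  multi-temperature titer time-courses; closed-form half-lives and analytic
  propagation of initial-titer uncertainty into the half-life.
- **titer** — serial-dilution spot-test titer estimation via zero-intercept
  linear regression (slope = Σxy/Σx²) and percent-survival ratios for heat
  and pH challenge assays.
- **mutation_analysis** — VCF-based enrichment analysis across evolution
  rounds: background normalization against wild-type controls, gene mutation
  indices (sum of frequencies strictly above 0.01 within a gene), regional
  fractions over structural/regulatory/non-coding categories, per-variant
  trajectories, cross-series/cross-species comparisons via homolog maps,
  codon- and strand-aware variant classification, amino-acid substitution
  properties (Kyte–Doolittle hydropathy, Zamyatnin volumes), and
  homopolymer-run length shifts.
- **synthetic_data** — a lineage-census simulator of the full evolution
  cycle (EMS-biased mutagenesis → amplification → thermal selection →
  amplification) plus synthetic sequencing, degradation-course, and
  spot-test data, all with known ground truth and full seed determinism.

The nth-order integral form and the closed-form half-life are the unique
solutions consistent with the published derivative of half-life with respect
to initial titer; that consistency is itself verified in the test suite.

## Test

```bash
python -m pytest -q tests/
```

The suite (~2 minutes) includes unit tests per module, hypothesis property
tests, and `tests/test_acceptance.py` with one test per acceptance
criterion (analytic-vs-ODE equivalence, finite-difference checks of the
uncertainty formula, parameter recovery, estimator bias, brute-force index
oracles, 20-seed end-to-end evolution properties, VCF round trips).

## CLI

All commands write a JSON result to stdout and a run manifest (config,
input checksums, seed, outputs) to `--outdir`.

```bash
# simulate a full campaign (reference FASTA, GFF3, per-round VCFs, truth TSVs)
cave simulate --config examples/cave.toml --seed 1 --outdir sim/

# fit degradation kinetics and compute half-lives
cave simulate-decay --model model.json --seed 7 --out courses.tsv
cave fit-kinetics --input courses.tsv --tref-c 62 --out fit.json
cave half-life --fit fit.json --n0 1e8 --sigma-n0 2e7 --temp-c 60,62,64

# titers and survival ratios from spot-test TSVs
cave titer --input spots.tsv --plated-volume-ml 0.01
cave survival --treated treated.tsv --control control.tsv

# mutation enrichment from VCFs
cave mut-index --vcf sim/round_12.vcf --wt sim/wildtype.vcf \
    --gff sim/genes.gff3 --threshold 0.01 --out indices.tsv
cave trajectory --vcfs sim/round_01.vcf,sim/round_06.vcf,sim/round_12.vcf \
    --wt sim/wildtype.vcf --out traj.tsv
cave compare --a seriesA.tsv --b seriesB.tsv --homologs map.tsv
cave classify --vcf sim/round_12.vcf --gff sim/genes.gff3 --fasta sim/reference.fasta
```

File formats: time-course TSV (`temperature_c`, `time_min`,
`titer_pfu_ml`, `replicate`), spot-test TSV (`dilution_fraction`, `count`,
`replicate`), VCF v4.x with `AF` in INFO (AD/DP fallback), GFF3 with a
`functional_category` attribute or 4+ column BED, homolog map as 2-column
TSV.

## Notes

- Temperatures are Kelvin internally; CLI/config accept Celsius.
- For `n ≠ 1` the rate constant's numeric value depends on the titer unit;
  fits normalize titers to 1e8 PFU/mL per internal unit (recorded on the
  fit result) so `k_ref` is well-scaled and reproducible.
- Through-origin R² is uncentered (`1 − Σe²/Σy²`) and not comparable with
  centered R².
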