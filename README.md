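# admixmate

Simulation and inference of **ancestry-related assortative mating (AM)**
and **sex bias (SB)** in three-way admixed populations (sub-Saharan
African, Native American, European), with optional two-pulse migration
(**GFR**, gene-flow rate). The pipeline:

1. **Mating model** — couple mating probabilities from a bivariate normal
   kernel on the male−female ancestry-proportion difference. The kernel
   mean encodes SB, the (co)variances encode AM through
   `sigma^2 = 3^(3 − 7·AM)`. Sign convention: `d = a_male − a_female`, so
   positive SB means the male carries more of that ancestry.
2. **Forward simulator** — non-overlapping generations, constant even
   population size, exact half/half sex ratio, Poisson crossovers on a
   genetic map (cM), 22 autosomes + X (females two recombining X copies,
   males one X transmitted intact to daughters). Local ancestry is
   tracked as run-length-encoded tracts; the generation loop runs on a
   packed array representation with a numba kernel.
3. **Tract-length profile** — 22 log-spaced length windows (breakpoints
   `2^((k+1)/2)/10` cM, i.e. 0.2 … 204.8 cM, √2 spacing) × 3 ancestries ×
   {autosomes, X}; population mean with female-only X; normalisation
   variants (`divided_by_total`, `no_shortest`); bootstrap.
4. **Inference** — branched fully-connected regression network
   (512/256/128/64 shared ReLU trunk, dropout 0.2, one
   32-unit-ReLU/dropout/sigmoid branch per parameter; 251,141 trainable
   weights for the one-pulse spec). Adam + MSE, 40 epochs, batch 64,
   0.8/0.2 train/test split with 0.2 validation split; ensembles give a
   mean and 95 % CI per parameter. Implemented directly in NumPy — no
   deep-learning framework required.
5. **Model comparison** — independent-Poisson composite likelihood of an
   observed profile against simulated references; CLR (two pulses vs one
   pulse) per ancestry × chromosome class with bootstrap CIs; generalized
   variance for estimator concordance.
6. **Synthetic data** — founding-proportion presets for ACB, ASW, CLM,
   MXL, PEL, PUR; toy and human-scale genetic maps; training-set
   generation; emulated window-grid local-ancestry calls with
   configurable miscall rates.

## CLI

All subcommands write a `manifest.json` recording inputs, seeds and
version; outputs are never overwritten without `--force`.

```bash
# one forward simulation -> segments BED + per-generation proportions
admixmate simulate --config config.yaml --seed 1 --out runs/sim

# population profile from segments BED or an ancestry-grid TSV
admixmate profile --segments runs/sim/segments.bed \
    --sex-map runs/sim/sexes.tsv --out runs/prof

# synthetic fixtures (+ optional training set)
admixmate fixtures --config config.yaml --seed 1 --n-sims 2000 --out runs/fix

# train an ensemble, then predict with 95% CIs
admixmate train --dataset runs/fix/training_set.npz --k 10 --seed 2 --out runs/ens
admixmate predict --ensemble runs/ens \
    --profile runs/prof/profile_normalized.tsv --out runs/pred

# composite likelihood ratio: two pulses vs one pulse
admixmate compare --counts runs/prof/per_individual_counts.npy \
    --config config.yaml --seed 3 --out runs/clr
```

Example `config.yaml`:

```yaml
scenario:
  preset: PEL            # or founding_proportions: [0.032, 0.754, 0.214]
  population_size: 1000
  generations: 19
  migration_model: one_pulse   # or two_pulses (pulse_generation: 10)
  map: desk                    # desk | human | path to a HapMap-style map
params:
  am: [0.3, 0.7, 0.3]
  sb1: 0.0
  sb2: -0.1
  # gfr: [0.1, 0.5, 0.1]       # two_pulses only
prior:
  am_range: [0, 1]
  sb_range: [-1, 1]
  gfr_range: [0, 1]
```

## File formats (plain text)

- **Ancestry grid TSV**: `sample hap chrom sex window_cm calls`, with
  `calls` a space-separated vector of per-window codes (1/2/3) on a fixed
  genetic grid (default 0.1 cM). A column-map-configurable adapter reads
  RFMix-/Gnomix-style window×haplotype matrices.
- **Segments BED**: `sample hap chrom start_cm end_cm ancestry`,
  half-open cM intervals that must tile each haplotype.
- **Genetic map**: HapMap-style `chrom position rate map` text.
- **Profiles**: long-format TSV (`bin, bin_label, ancestry, chrom_class,
  value`).

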