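# polarcall

Trisomic-baseline copy-number analysis for preimplantation genetic testing
for aneuploidy (PGT-A) on **pooled polar bodies**.

The pooled first and second polar bodies of a euploid oocyte contain three
chromatids of every chromosome — two from the first polar body, one from
the second — so standard diploid-genome tooling miscalls them. `polarcall`
implements the two analysis arms such screening needs, both anchored at a
3-chromatid euploid state, plus the machinery to compare them:

* **Sequencing caller** for low-pass single-cell WGS after whole-genome
  amplification (WGA): MAPQ ≥ 5 filtering, fixed 100-kb bin counting with
  0.9985/0.1 quantile blacklisting from a merged euploid reference,
  variable-width ~1-Mb binning (equal reference reads per bin), GC
  correction, and a **zero-inflated negative-binomial HMM** over somy
  states 0–4 with tied emissions — an *s*-somy bin emits
  NB(mean = *s*·μ, var = *s*·σ²) — whose baseline is re-anchored so the
  modal decoded state is 3-somy. Segments < 10 Mb are absorbed; each
  chromosome is called by the somy covering the most bp.
* **aCGH classifier** using the trisomic expectations
  log2(4/3) = 0.42 (gain) and log2(2/3) = −0.58 (loss), with thresholds at
  the state midpoints log2(3.5/3) = 0.22 and log2(2.5/3) = −0.26; autosomes
  require both control channels beyond threshold, X uses the female
  control only. Includes the DLR-spread QC metric.
* **Concordance analysis** cross-tabulating the two methods' calls at
  sample or chromosome level, with per-class statistics and gain/loss
  tallies.
* **Seeded simulator** of karyotypes, WGA-like read sets (GC bias,
  lognormal bin-scale amplification noise, over-dispersion, dropout) and
  aCGH probe profiles calibrated to a target DLR spread, with exact ground
  truth — so the whole pipeline is testable at desk scale.

See `docs/methods.md` for the model, its assumptions, and all numerical
choices.

## Worked example

Simulate a polar-body pool with a chromosome 16 chromatid loss (plus its
matching aCGH profile), a merged euploid reference, and analyse:

```sh
polarcall simulate --genome toy --n-reads 1000000 --loss chr16 --seed 11 \
    --reads-out sample.tsv --probes-out probes.tsv
polarcall simulate --genome toy --n-reads 2000000 --seed 99 \
    --reads-out reference.tsv
polarcall call sample.tsv reference.tsv --genome toy --seed 11 \
    --sample-id PB011 --out ont.json --bed segments.bed
polarcall acgh probes.tsv --sample-id PB011 --out acgh.json
polarcall concordance acgh.json --against ont.json --level sample \
    --out concordance.json
```

The sequencing report (`ont.json`) classifies the sample as aneuploid with
exactly one affected chromosome and no baseline-anchoring problem:

```
"classification": {"baseline_flag": false, "highly_complex": false,
                   "n_aneuploid_chromosomes": 1, "n_no_call": 0,
                   "verdict": "aneuploid"}
```

and its only non-euploid chromosome call is `chr16: loss (modal somy 2)` —
the fitted per-chromatid unit mean is μ ≈ 2966 counts/bin, so chr16's bins
sit near 2μ while the rest of the genome sits near 3μ. The aCGH report
agrees: chr16 means of −0.61/−0.57 (male/female channel) fall below the
−0.26 loss threshold, the profile's DLR spread is 0.57, and the
sample-level concordance table reports `"overall": 1.0`.

`--genome` accepts `toy` (GRCh38 scaled 1:30, for fast runs), `grch38`
(full chromosome lengths), or a FASTA/length-table path. All pipeline
parameters (`--min-mapq`, `--bin-size`, `--expected-baseline`,
`--min-segment`, `--reads`, `--seed`, …) default to the standard workflow
values and can also be given as a YAML config. Exit codes: 0 success,
2 input error, 3 analysis error, 4 baseline-anchoring failure (report
still written). Single polar bodies can be analysed by setting
`--expected-baseline` to the appropriate chromatid count.

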