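# reefmito

Small-scale population structure of reef-building corals from whole
mitochondrial genomes.

Broadcast-spawning corals such as tabletop *Acropora* are usually assumed to
disperse larvae over tens to hundreds of kilometres, so population-genetic
structure between patch reefs 1–10 km apart is rarely looked for. Because
every base of the mitochondrial genome is completely linked, an ~18.5 kb
mitogenome behaves as a single locus with an effective mutation rate
thousands of times that of one SNP: colonies with *identical* mitogenomes
share a recent maternal ancestor. `reefmito` turns that observation into a
testable pipeline for surveys of a few hundred colonies across tens of
reefs nested in regions:

1. **Haplogroups** — cluster colonies whose genomes are identical at every
   jointly called site (pairwise deletion over N/gap), then fold colonies a
   single base from a group's consensus into that group.
2. **Hierarchical AMOVA** — partition squared inter-colony distances
   (δ² = number of differing sites d<sub>ij</sub>) across regions / reefs /
   colonies and report the fixation indices
   Φ<sub>RT</sub> = σ²<sub>a</sub>/σ²<sub>T</sub>,
   Φ<sub>PR</sub> = σ²<sub>b</sub>/(σ²<sub>b</sub>+σ²<sub>c</sub>),
   Φ<sub>ST</sub> = (σ²<sub>a</sub>+σ²<sub>b</sub>)/σ²<sub>T</sub>
   with permutation p-values.
3. **Co-occurrence test** — the count of same-reef, same-haplogroup colony
   pairs, Σ<sub>g,r</sub> C(k<sub>gr</sub>, 2), against a constrained
   permutation null that shuffles colonies among reef slots while fixing
   reef sizes and the group-size spectrum. Excess co-location of closely
   related genomes on the same reef is the signature of local larval
   retention.
4. **Isolation by distance** — OLS regressions of between-reef nucleotide
   distance and haplogroup sharing on great-circle distance and heat-exposure
   difference.
5. **Rate arithmetic** — divergence times and mutation wait times from a
   pairwise divergence rate (percent per Myr).
6. **Synthetic surveys** — a reef-metapopulation generator with a tunable
   natal-reef retention probability ρ and full ground truth, so every stage
   is testable without field data.

## Worked example

Simulate a survey at the default scale (7 regions, 39 reefs, ~280 colonies,
18,482-base genomes, retention ρ = 0.2) and run the co-occurrence test and
AMOVA:

```sh
reefmito simulate --out demo --seed 4
reefmito cooccur --alignment demo/alignment.fasta --metadata demo/metadata.csv \
    --b-reps 1000 --seed 4 --out demo/co
reefmito amova   --alignment demo/alignment.fasta --metadata demo/metadata.csv \
    --b-reps 499 --seed 4 --out demo/am
```

prints

```
wrote 277 colonies x 18482 bases to demo
observed 153 same-reef pairs (null mean 100.8); results in demo/co
PhiST=0.08493181317771947; results in demo/am
```

`demo/co/cooccurrence.json` holds the four headline tests; the haplogroup-mode
pair count is

```json
{"observed": 153, "null_mean": 100.846, "null_sd": 8.786, "p": 0.000999, "B": 1000}
```

153 same-reef same-haplogroup pairs were observed where random dispersal
predicts 100.8 ± 8.8 — colonies with identical genomes sit on the same reef
far more often than chance, exactly the excess the retention parameter was
set to produce (no null replicate out of 1000 reached the observed count, so
p = 1/1001). The AMOVA table (`demo/am/amova.tsv`) attributes 0% of variance
to regions (Φ<sub>RT</sub> = −0.0004, p = 0.43) and 8.5% to reefs within
regions (Φ<sub>PR</sub> = 0.085, p = 0.002): retention structures reefs, not
regions. Rate utilities need no data:

```sh
reefmito rates     # {"mutation_wait_years": 53642.3, "divergence_time_myr": 2.0}
```

i.e. at 0.1%/Myr an 18,642-base mitogenome waits ~54,000 years between
mutations, and clades 0.2% apart split ~2 Myr ago.

The same functionality is importable (`reefmito.simulate`,
`reefmito.assign_haplogroups`, `reefmito.permutation_null`,
`reefmito.amova`, ...); `reefmito run-all` chains every stage and writes a
seed-stamped manifest.

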