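# raptorsig

Comparative-genomics signatures of predatory and nocturnal lifestyles in bird
genomes, as a reusable, tested Python pipeline. The package is aimed at
comparative genomicists who want the *bespoke* computations of a raptor-style
genome comparison — the steps that sit between standard external tools — as
auditable, seed-deterministic code exercised end-to-end on synthetic data
with planted ground truth.

Five analysis stages are implemented, each behind a library module, a CLI
subcommand, and a numbered analysis driver:

| Stage | Statistic | Module |
|---|---|---|
| Conserved-region scan | per-window Fisher depletion test vs. the rest of the genome; BH q < 10⁻⁴; middle 10-kb core of each significant 100-kb window reported as an HCR | `raptorsig.hcr` |
| OR repertoire | intact / partial / pseudogene classification (start + stop + > 215 aa; 90-bp flank rescue; frameshift/premature-stop lesions) and clade diversity as mean column Shannon entropy (nats, columns with > 20% gaps excluded) | `raptorsig.orrep` |
| Selection | Nei–Gojobori counting dN/dS: ω = dN/dS with dₓ = −¾ ln(1 − 4pₓ/3), plus two-sided Mann–Whitney U gene-set acceleration tests (exact for n ≤ 8) | `raptorsig.codon` |
| GC3 bias | GC3 = G+C fraction at third codon positions; two-step z-normalization into a gene-set × species matrix | `raptorsig.codon` |
| Genome metrics | heterozygous SNVs per callable (depth > 5) bp; 0.5× / 0.25× (sex-linked) / 2× abnormal-depth gene filter | `raptorsig.variants` |

A sixth module, `raptorsig.simulate`, generates every input the pipeline
consumes — difference tracks with planted conserved windows, OR-like genes
with planted lesions, codon pairs evolved at a chosen ω, protein alignments
with planted group-specific residues, and depth/heterozygosity sets at
planted rates — so every stage is scored against known truth without any
downloads.

## Worked example

Simulate a 20-Mb same-order genome comparison (background difference rate
5 × 10⁻³ per bp, five windows planted at 5% of background) and scan it:

```bash
raptorsig simulate hcr --seed 1 --out sim
raptorsig hcr --diffs sim/differences.tsv --lengths sim/scaffold_lengths.tsv --out scan
# -> 5 significant windows, 5 HCR cores
```

or run the numbered driver, which also scores the calls against the planted
truth:

```bash
$ python analysis/01_scan_conserved_regions.py
windows scanned: 200; planted conserved windows: 5
recovered 5/5 planted windows, 0 background windows called
  HCR core sim1:2045000-2055000 (window q = 4.649e-168)
  HCR core sim1:5745000-5755000 (window q = 1.055e-165)
  ...
```

Each planted window carries ~25 differences against a genome-wide expectation
of ~500 per 100 kb, so its depletion q-value is astronomically small, while
no background window crosses q < 10⁻⁴; the reported cores are the exactly
centered middle 10 kb of each significant window. The other drivers behave
the same way, for example:

```bash
$ python analysis/03_estimate_dnds_selection.py
omega_true=0.0: omega_hat=0.0000 (seed 1)
omega_true=1.0: omega_hat=1.0926 (seed 1)
...
gene-set acceleration: U=225.0, two-sided Mann-Whitney p=3.392e-06 (significant at 0.05)
```

— the counting estimator recovers ω = 1 within [0.9, 1.1] on 5,000-codon
neutral simulations and ω = 0 exactly under strict purifying selection, and
the Mann–Whitney comparison flags the gene set simulated at elevated ω
(0.6 vs. a 0.2 background), the same design used to detect accelerated
sensory-system genes in nocturnal lineages.

All drivers write their tables under `results/`. The full CLI:

```
raptorsig simulate {hcr,or,dnds,specific-sites,depth-het} --seed N --out DIR
raptorsig hcr --window-size 100000 --core-size 10000 --q-threshold 1e-4 --sided {less,two}
raptorsig or-classify --min-aa 215 --flank 90
raptorsig or-diversity --gap-threshold 0.20
raptorsig dnds --a A.fasta --b B.fasta
raptorsig gc3 --cds SPECIES=cds.fasta --sets sets.tsv
raptorsig specific-sites --targets id1,id2 [--strict-gaps]
raptorsig het-rate --min-depth 5
raptorsig depth-filter --sex-scaffolds file
```

Every subcommand accepts `--config yaml` (precedence: CLI flag > config file
> built-in default) and emits a `resolved_config.yaml` recording the values
used and their provenance; outputs are written atomically, and reruns with
the same resolved configuration are byte-identical.

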