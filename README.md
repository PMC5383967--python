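# pancscan

Promoter-antisense non-coding RNA (pancRNA) analysis for strand-specific
RNA-seq, built around a cross-species, cross-tissue comparison.

Many mammalian promoters are bidirectional: besides the mRNA, they
produce a non-coding transcript from the opposite strand within the
2 kb immediately upstream of the transcription start site (TSS).  When
that promoter-associated ncRNA's expression tracks the mRNA across
tissues, the gene is called *pancRNA-partnered*; such genes tend to be
tissue-specific, carry C-/G-skewed promoter motifs and CpG islands, and
their pancRNA repertoires diverge strongly between species even where
mRNA tissue programs are conserved.  `pancscan` implements the full
analysis chain behind those observations, plus a planted-truth
synthetic data generator that makes every step testable.

## What it computes

* **Promoters** — per-gene upstream windows (`[TSS-2000, TSS)` on the
  gene strand), filtered so that no CLEAN promoter overlaps another
  gene or promoter or sits closer than 500 bp to another promoter;
  genes whose promoter contains part of another gene are flagged
  CONTAMINATED, unusable ones EXCLUDED.
* **Counts** — strand-aware unique-read counting of mRNA (sense over
  the gene) and pancRNA (antisense over the CLEAN promoter), with
  ambiguous reads discarded and a strandedness QC.
* **Normalization** — TMM (trimmed mean of M-values) wrapped in a
  DEG-elimination loop (DEGES): estimate factors, flag putative DE
  genes by fold-change rank, re-estimate on the rest.
* **Pairing** — Pearson r between mRNA and pancRNA tissue means:
  r > 0.7 partnered, r < 0.4 (or no antisense signal) lacking.
* **Tissue specificity** — tau = sum(1 - x_i/x_max)/(N-1), compared
  between gene classes with the Steel-Dwass all-pairs rank test.
* **Motifs and conservation** — matchPWM-style 70%-relative-score
  scanning, 50-bp sliding-window motif frequency around TSSs,
  C-/G-motif co-occurrence, and per-gene phastCons-style score means
  over promoters and CDS.
* **Comparative** — one-to-one-ortholog expression matrices across
  species, Spearman correlation, UPGMA clustering on 1 - rho, and a
  nearest-neighbour segregation score quantifying whether samples
  cluster by species or by tissue.
* **Simulation** — a 5-species x 5-tissue negative-binomial generator
  with planted partnered pairs, species-specific pancRNA gains, skewed
  promoter motifs and ordered conservation tracks, emitting full truth
  tables.

See `docs/methods.md` for the model details and every numerical
convention.

## Worked example

Simulate a five-species dataset and run the whole pipeline:

```python
from pancscan import SimulationConfig, RunConfig, run_all

report = run_all(RunConfig(simulation=SimulationConfig(n_genes=500, seed=11),
                           out_dir="out"))
print(report["table1"][0])
print(report["segregation"])
print(report["recovery"])
```

prints (seed 11):

```
{'species': 'sp1', 'total': 490, 'n_pos': 75, 'n_neg': 0, 'pct_pos': 15.3, 'pct_neg': 0.0}
{'mrna': {'by_species': 0.0, 'by_tissue': 1.0}, 'panc': {'by_species': 0.08, 'by_tissue': 0.92}}
{'partnered_recovery': 1.0, 'null_partnered_rate': 0.0019277108433734939,
 'n_planted_partnered': 375, 'specific_planted': 30, 'specific_detected': 33,
 'specific_recovery': 1.0, 'specific_fdr': 0.09090909090909091}
```

Reading this: of 500 simulated genes per species, 490 kept a CLEAN
promoter; 15.3% of them were classified pancRNA-partnered (the planted
rate is 15%), and every planted partnered pair was recovered while
uncorrelated promoters were almost never misclassified.  All 30 planted
species-specific gains were found (three extra calls are
classification noise at this small gene count).  mRNA expression
profiles cluster perfectly by tissue; with the default 8% species-
private pancRNA share the pancRNA profiles still cluster mostly by
tissue — raise `frac_species_specific_of_partnered` and they flip to
clustering by species.

The same stages are scriptable from the shell:

```bash
pancscan simulate --seed 7 --out-dir sim/
pancscan promoters --gtf sim/sp1.gtf --out sp1.promoters.bed
pancscan normalize --counts sim/sp1.mrna.counts.tsv --out sp1.norm.tsv
pancscan run-all --seed 7 --out-dir out/
```

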