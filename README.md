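# toxannot

Venom-gland transcriptome toxin annotation — and an audit of how badly it
can go wrong.

Venomics studies routinely call a transcript a "toxin" because it has a
BLAST hit to a toxin database. That inference is fragile: gene families
recruited into venom retain non-toxin paralogues expressed in ordinary
tissues, assemblies fragment coding sequences, and the reference database
may come from a distantly related lineage. `toxannot` implements the full
annotation workflow for a two-tissue (venom gland vs. muscle) study and the
accuracy audit that quantifies each failure mode against a venom proteome
and, on synthetic benchmarks, against exact ground truth:

* **Sequence post-processing** — six-frame ORF extraction (≥ 40 aa,
  stop-to-stop, no start-codon requirement), signal-peptide gating,
  removal of identical translations, greedy CD-HIT-style identity
  clustering.
* **Homology annotation** — exact Smith–Waterman local alignment
  (BLOSUM62, affine gaps: a gap of length *g* costs 11 + (*g*−1)), with
  Karlin–Altschul statistics `E = K·m·n·e^(−λS)` (λ = 0.267, K = 0.041),
  best-hit family assignment at E ≤ 10⁻³ against three database tiers of
  decreasing relatedness (species / lineage / distant).
* **Comparative expression** — FPKM from fragment counts
  (`count·10⁹ / (length·library)`), the venom-gland filter
  (FPKM ≥ 100 and ≥ 10-fold over muscle), and Spearman correlation of
  proteomic detection with expression.
* **Family phylogenetics** — neighbor-joining on −ln(identity) distances,
  midpoint rooting, and a clade-evidence retention rule: a candidate is
  kept only if some leaf within patristic distance *d*max (default: the
  tree's median pairwise distance) is proteome-detected or passes the
  expression filter.
* **Evaluation** — Venn regions among annotation tiers, false-positive
  rates vs. the proteome, per-family diversity profiles, precision/recall
  vs. ground truth, and intraspecific overlap of mature peptides between
  two populations at 95 %/90 % identity.
* **Synthetic benchmarks** — a generator that simulates toxin families on
  birth–death trees (recruited clades evolve faster), venom-gland-biased
  expression, logistic proteome detection, contig fragmentation, signal
  peptides, database tiers and a second diverged population — with full
  ground truth, so every audit number is checkable.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from toxannot import SimulationConfig
from toxannot.pipeline import run_synthetic

result = run_synthetic(SimulationConfig(seed=1))
rep = result.report
for tier in ("distant", "lineage", "species"):
    print(tier, rep["false_positive_rates"][tier]["sp_positive"])
```

prints (seed 1):

```
distant 1.0
lineage 0.782608695652174
species 0.5454545454545454
```

i.e. every distant-tier ("ToxProt-like") putative toxin, 78 % of
lineage-tier and 55 % of species-tier calls are absent from the venom
proteome — the annotation databases' relatedness directly controls the
false-positive rate, because deep databases preferentially recruit the
slow-evolving non-toxin paralogues rather than the fast-evolving recruited
toxin clades. Applying the expression filter to the combined dataset lifts
ground-truth precision from 48.3 % to 100 % in this replicate while
retaining 100 % of the proteome-detected transcripts (see
`examples/05_audit_report.py`; the other examples walk through each stage
individually, printing stage counts, correlations and an annotated family
tree).

The same pipeline runs from the shell:

```
toxannot run-all --seed 1 --out run1
toxannot simulate --seed 1 --out bench          # dataset with ground truth
toxannot annotate --contigs c.fa --db db.fasta --out hits.tsv
```

`examples/run_config.yaml` documents every configuration key.

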