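# Methods

`toxannot` implements a toxin-annotation workflow for two-tissue venom
studies and audits its accuracy on synthetic benchmarks with known ground
truth. This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic results do and do not say
about real data.

## The annotation workflow

**ORF extraction.** Contigs are translated in all six frames; every maximal
stop-free stretch of ≥ 40 residues is a candidate CDS. No start codon is
required — secreted peptide precursors are routinely assembled without a
complete 5′ end, and requiring ATG would silently discard exactly the
fragments the audit needs to count. An ORF bounded by in-frame stops on both
sides is "complete"; one running into a contig end is a partial CDS. Codons
containing N translate to X. Coordinates are 0-based half-open on the
forward strand throughout.

**Homology search.** Queries are aligned with exact Smith–Waterman under
BLOSUM62 with affine gap *costs* (a gap of length *g* costs
11 + (*g*−1)·1 — the blastp default scheme). Using full dynamic programming
instead of a word-seeded heuristic is a deliberate choice: at benchmark
scale exactness is affordable, and the hit list can only be a superset of
what a seeded search would find, so false-positive rates are not understated
for lack of sensitivity. Significance uses the Karlin–Altschul form
E = K·m·n·e^(−λS) with the standard gapped BLOSUM62/11/1 constants
λ = 0.267, K = 0.041; *n* is the total residue count of the database tier
searched. Composition-based score adjustment is not implemented. Hits with
E ≤ 10⁻³ are kept, with no query-coverage requirement. Each query takes the
family of its best hit (highest bit score, ties broken by lower E-value then
lexicographic subject id). Alignment is delegated to Biopython's
`PairwiseAligner`; the test suite checks it against an independent
hand-written Gotoh DP on 10,000 random peptide pairs.

**Post-processing.** Annotated CDSs are gated on a signal peptide, then
identical translations are collapsed (keeping the lexicographically smallest
id). Stage counts (unique contigs / unique CDS / unique CDS with signal
peptide / unique full-length CDS) are reported per tier. A manual-curation
step is represented only as an optional id-exclusion list — it is a human
judgement, not an algorithm.

**Signal peptides.** The default ("truth") mode reads the generator's
labels: a CDS is positive iff its translation still begins with the true
signal peptide (a 5′-truncated CDS that lost it is negative, as a real
predictor would find). A heuristic mode is provided as a deliberately simple
stand-in for a neural-network predictor: within the first 30 residues it
requires a K/R in positions 1–5, a run of ≥ 8 residues with mean
Kyte–Doolittle hydropathy ≥ 1.6, and small residues (A/G/S/C/T) at the −3/−1
positions of the proposed cleavage site, taking the earliest admissible
cleavage point. The window length and hydropathy threshold are engineering
defaults; the heuristic is total (never raises) and pure.

**Identity and clustering.** Pairwise identity is counted over a global
BLOSUM62 alignment and divided by the shorter sequence's length (the CD-HIT
convention, so a perfect fragment scores 1.0). Because co-optimal global
alignments can differ in identity count, arguments are canonically ordered
before aligning, making identity exactly symmetric. Clustering is greedy and
incremental: sequences are visited longest-first (ties by id) and join the
first cluster whose representative they match at ≥ the threshold, else found
a new one. Whether the original tool used global or local identity at which
word size is not recoverable from its defaults; this explicit greedy global
scheme is the documented stand-in, and the intraspecific-overlap statistics
are defined in terms of it.

**Expression.** FPKM = count·10⁹/(length_bp·library_total), with library
totals taken as column sums of the counts table; an empty library yields 0
by convention. The comparative filter retains a transcript iff venom-gland
FPKM ≥ 100 and FPKM_vg/(FPKM_muscle + 0.01) ≥ 10. The 0.01-FPKM pseudocount
is this package's explicit convention for venom-gland-unique transcripts
(muscle FPKM 0), which must be able to pass the fold rule — they are among
the strongest toxin candidates. The study design has one library per tissue
and no replicates, so the filter is a deterministic threshold rule, not a
statistical test. Spearman correlations use average ranks and a two-tailed
p-value from the t approximation t = r·√((n−2)/(1−r²)); an exact
permutation p-value is available for n ≤ 9.

**Family trees and clade-evidence retention.** Distances between family
members are d = −ln(identity) clamped at 5.0 (zero identity clamps with a
warning). Trees are built by canonical neighbor-joining (Saitou–Nei Q
criterion) with two determinism conventions: ties in Q join the pair whose
smallest-leaf-label pair sorts first, and negative branch lengths are
clamped to zero with the deficit moved to the sibling edge. NJ is exact on
additive matrices, which the tests exploit. Trees are midpoint rooted
(scikit-bio; a two-leaf tree is balanced directly). NJ on log-identity
distances replaces maximum-likelihood inference deliberately: the
contribution being implemented is the *clade-evidence logic*, not the tree
estimator, and NJ is dependency-free, fast and exact on clean input.

The retention rule formalizes a practice that is usually qualitative
("keep isoforms in clades with venom evidence"): a leaf is retained iff its
patristic distance to the nearest *evidence leaf* — proteome-detected or
expression-filter-passing — is ≤ d_max. Evidence leaves are always
retained. d_max defaults to the median of all pairwise patristic distances
in the tree, so the radius adapts to family depth; it is an explicit free
parameter, monotone by construction (growing d_max never shrinks the
retained set). A tree with no evidence leaves retains nothing, with a
warning.

**Evaluation.** False-positive rate is |predicted ∖ proteome|/|predicted|,
computed on the signal-peptide-positive deduplicated sets (reported also
after expression filtering). Family-diversity deltas are reported both in
percentage points and as fold ratios, since both idioms are used when
discussing over-/under-estimation. On synthetic data, precision/recall/F1
against the true toxin set are the ground-truth twins of the
proteome-referenced rates. Intraspecific overlap pools two populations'
mature (signal-peptide-free) peptides, clusters at 95 % and 90 % identity,
and counts clusters containing members of both populations.

## The synthetic benchmark

The generator produces the statistical structure the audit depends on, not
sequence realism:

* **Families.** Yule (pure-birth) topologies with exponential branch
  lengths, rescaled so the mean root-to-leaf depth equals `subst_rate`
  (default 0.5 substitutions/site — within-family identities of roughly
  50–75 %, the range typical of diversified venom peptide families).
  Proteins evolve by a per-site Poisson number of replacement events, each
  drawn from a BLOSUM62-conditional distribution (P(b|a) ∝ p_b·2^(s_ab/2)),
  i.e. conservative, matrix-consistent substitution with back-substitution
  possible. Root length 90 aa, the scale of a secreted venom protein's
  mature region.
* **Toxin recruitment.** With probability 0.8 one mid-sized clade per
  family is flagged as recruited venom toxins; its branches run 3× faster
  (accelerated evolution after recruitment is one of the most consistent
  observations in venom molecular evolution) and its members carry a signal
  peptide. Half of the non-toxin paralogues are also secreted, with a
  different signal peptide — secreted housekeeping homologues are exactly
  the class that homology annotation mistakes for toxins.
* **Expression and detection.** Per-contig target FPKMs are log-normal:
  log₁₀FPKM ~ N(2.5, 0.7) for toxins in the venom gland, N(0.8, 0.7)
  otherwise and in muscle. Counts are allocated multinomially from each
  library (10⁶ fragments), with the remainder of the library assigned to an
  explicit background row (the unannotated transcriptome), so counts sum
  exactly to library size and FPKMs computed from counts sit on the
  intended scale. Secreted toxins are proteome-detected with probability
  logistic(−3 + 1.5·log₁₀(FPKM_vg+1)) — about 50 % at FPKM 100, 88 % at
  FPKM 1000; non-toxins are never detected. This yields a detection set
  biased toward abundant toxins, the bias the expression filter exploits.
* **Emission.** Proteins are back-translated (one codon per residue),
  wrapped in random UTRs with in-frame stops delimiting the CDS, and with
  probability `frag_prob` = 0.25 truncated 5′ or 3′ by 10–60 % of the CDS.
  A 5′ truncation loses the signal peptide; either truncation marks the CDS
  incomplete. The fragmentation rate is a free parameter describing
  assembly quality — no empirical estimate of it exists.
* **Database tiers.** The species tier is the set of proteome-detected
  sequences themselves. The lineage tier holds, per family, two
  related-species representatives at `db_divergence`/2 = 0.4 extra
  substitutions/site: one descending from the recruited clade's ancestor (a
  published true toxin) and one from the family root (a "putative toxin" —
  compiled lineage lists are over-inclusive). The distant tier holds
  root-descended representatives at `db_divergence` = 0.8 for 75 % of
  families, plus three decoy families with no transcriptome homologue.
  These anchors were placed against the measured E-value recruitment curve
  (significance at E ≤ 10⁻³ decays between ~1.3 and ~2.0 substitutions/site
  for 90-aa proteins), so the three tiers reach genuinely different parts of
  each family: the species tier recruits the toxin clade and little else;
  the lineage tier also reaches non-toxin clades; the distant tier reaches
  non-toxin clades *preferentially*, because the recruited clades' 3×
  acceleration pushes them beyond its horizon. The false-positive gradient
  across tiers is therefore a mechanistic consequence of the biology being
  modelled, not a tuned output.
* **Populations.** Each toxin's mature peptide is additionally evolved by
  0.25 substitutions/site to create a second population — subspecies-level
  divergence under accelerated toxin evolution, which places most
  cross-population identities below the 90 % clustering threshold.

Randomness: one seed drives everything; per-family and per-stage generators
are derived via `SeedSequence(seed, spawn_key)`, so identical configurations
give byte-identical FASTA/TSV outputs and partial regeneration is stable.

**What passing tests show — and don't.** The benchmark reproduces the
*direction* and *mechanism* of the audit's findings (tier-dependent false
positives, filtering gains, detection–expression correlation), not the
magnitudes of any real transcriptome. Real data add codon structure,
expression correlation between tissues, chimeric contigs, alternative
isoforms and database curation artifacts, none of which are modelled;
absolute rates measured here should not be quoted as expectations for real
studies.

## Metric definitions at benchmark scale

The replicate study (default: 50 seeds) summarizes each seed by: the
false-positive rate of each tier's signal-peptide-positive set; precision
with and without the expression filter; pooled retention of
proteome-detected ids by the filter; and the Spearman correlation between
detection and venom-gland FPKM. Two definitions are deliberate:

* The filtered-vs-unfiltered precision comparison is made per seed on the
  **combined** (union of the three tiers') predicted set. Single-tier
  filtered sets — the distant tier's especially — can be empty in a small
  benchmark, leaving per-tier precision undefined; the combined dataset is
  always well-populated. Per-tier means are still reported.
* Filter retention is pooled across seeds (total retained detected ids over
  total detected ids) rather than averaged per seed, since per-seed
  denominators are small (~10–20 detected ids).

## Numerical conventions and degenerate inputs

* Residues outside the BLOSUM62 alphabet are scored as X; empty sequences
  are errors, as are empty databases and non-positive lengths in E-values.
* An empty predicted set makes false-positive rate and precision undefined
  (error in the API; reported as null in the pipeline report).
* Zero-variance inputs to Spearman are undefined-result errors; the
  detection–expression table reports such cells as NaN rather than failing.
* The 3-taxon NJ star uses the closed-form branch lengths; 2-taxon input
  yields a single edge split evenly.
* Reports are JSON with sorted keys; identical runs are byte-identical.

## Known limitations

* The signal-peptide heuristic is far weaker than a trained predictor; the
  audit therefore defaults to truth-mode labels, and heuristic-mode results
  conflate annotation error with predictor error.
* The E-value constants are fixed (no length-dependent edge corrections),
  so absolute E-values for very short queries are approximate; the audit
  only relies on them through the 10⁻³ threshold.
* NJ on log-identity distances underestimates deep branch lengths relative
  to a proper substitution model; the clade-evidence rule depends only on
  relative patristic distances within a family, which is why this is
  acceptable here.
* Real-data mode (`inputs:` in the run configuration) runs the same
  pipeline with the heuristic signal-peptide predictor and leaves
  truth-dependent report sections empty; it is functional but exercised far
  less than the synthetic path.
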