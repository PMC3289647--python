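# Methods

## The analysis

The pipeline asks whether single-nucleotide variation in estrogen-receptor
(ER) DNA-binding sequences is associated with a dichotomous phenotype,
tested separately in four strata (two diseases × two sexes). It has five
stages; each is a library module and all intermediate artifacts are plain
text.

### Motif scan on a masked genome

Known SNP positions are represented as IUPAC ambiguity codes in the genome
FASTA (e.g. Y for a C/T SNP). The two ERE half-site cores, GGTCA and its
reverse complement TGACC, are scanned on the forward strand only; this
covers both orientations of the palindromic element without double-counting.
Match semantics: a window matches when, at every non-wildcard consensus
position, the residue's allele set *contains* the consensus base — i.e. the
binding site exists under at least one allele. A matching window is
*disrupting* when some masked position also admits a base different from the
consensus base there, so the alternate allele can break the site. These are
the minimal semantics under which a masked motif both "contains a SNP" and
can be "disrupted" by it.

Two consequences are worth noting. `N` is treated as full ambiguity for
matching but not recorded as a SNP (assembly gaps are not variants;
configurable). And for 5-bp half-sites, every ambiguous position inside a
match is necessarily disrupting — an allele set that contains the consensus
base and has size ≥ 2 must contain a non-consensus base. Non-disrupting
masked positions inside a hit can only occur in the wildcard spacer of the
optional full 13-bp pattern (`GGTCAnnnTGACC`), where they deliberately do
not qualify as disrupting.

### ChIP-region consensus

"Regions all three ChIP studies agree on" is implemented as the positional
three-way intersection of the per-study merged interval sets: a base is in
the consensus iff every study reports binding there. Intervals are half-open
and 0-based; book-ended intervals merge, since half-open adjacency means
contiguous coverage. An alternative whole-region mode (keep any source
region overlapping regions from both other sets) is provided because
"agreement" is not uniquely defined; the positional intersection is the
default as it is strand- and length-agnostic.

### Candidate panel and LD proxies

Candidates are (a) SNPs inside the consensus regions, regardless of motif
context, and (b) disrupting ERE SNPs supported by at least one ChIP study.
A SNP qualifying under both is counted once with the consensus-region
provenance primary. Candidates absent from the genotyped panel are replaced
by the genotyped SNP in highest LD, subject to r² ≥ 0.89 — the threshold is
inclusive, reconciling the two ways the cutoff is conventionally quoted
(strictly above 0.89 vs equal to 0.89); ties break by smaller base-pair
distance, then lexicographic rsid. One proxy per candidate (the best), and a
proxy may stand in for several candidates; candidates with no qualifying
proxy are dropped and logged.

### Genotype QC

Applied independently within each disease × sex stratum, in the
conventional GWAS order: (1) persons with missing-call rate > 0.1 (computed
on the candidate panel); (2) SNPs with missingness > 0.05; (3) SNPs with
minor-allele frequency < 0.01 over the stratum's cases plus controls;
(4) SNPs with Hardy–Weinberg exact p < 0.001 in controls only. The HWE test
is the standard two-sided conditional exact test: heterozygote counts
compatible with the observed allele totals are enumerated via the
probability recurrence, and the p-value sums all configurations whose
conditional probability does not exceed the observed one (no mid-p
adjustment, matching the era's default toolchain behaviour). Per-stratum QC
is what makes the four post-QC panels differ slightly in general.

### Association

For each surviving SNP, allele counts (two per individual, missing
genotypes excluded) form a 2×2 minor/major × case/control table. The minor
allele is designated by pooled case+control frequency < 0.5 within the
stratum; an exact tie goes to the lexicographically smaller allele. The
test is the two-tailed Fisher exact test under the probability-mass
convention (sum of hypergeometric probabilities ≤ that of the observed
table); the implementation delegates to `scipy.stats.fisher_exact`, which
uses this convention, and the test suite verifies it against full
enumeration in exact rational arithmetic for all margins up to 60. The
effect estimate is the allelic odds ratio ad/bc with the Woolf
interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), z = Φ⁻¹(0.975) ≈ 1.959964.
Zero cells raise by default; the Haldane–Anscombe +0.5 correction is
available and is applied automatically only inside the batch driver so a
degenerate post-QC table yields a flagged estimate rather than aborting a
run (the Fisher p needs no correction).

Multiple testing uses a single study-wide Bonferroni factor,
diseases × sexes × panel size, with the panel size taken as the *maximum*
post-QC panel across strata — one shared factor even when per-stratum
panels differ, which reproduces the conventional reporting (e.g.
2 × 2 × 225 = 900). Corrected values above 1 display as ">1"; full
precision is retained internally. Display rounding is half-up at 3
decimals, applied through a decimal pre-quantisation step so that binary
float representation noise (e.g. 0.1395 stored fractionally below the
decimal midpoint) cannot flip the printed digit.

## Synthetic data

The generator emulates the study's inputs with exact ground truth.

* **Layout.** Features occupy a slot grid: one feature per slot, slots
  250 bp apart, ChIP-locus slots ≥ 500 bp apart. Each ChIP locus has a
  200 bp core around its anchor; each covering study's interval extends the
  core independently by up to 120 bp per side. With these bounds, intervals
  from different loci can never touch, so the true three-way consensus of a
  triple locus is exactly [max starts, min ends] — computed arithmetically
  in the generator, independently of the interval-sweep implementation it
  validates.
* **Genome.** Background sequence is scrubbed of accidental GGTCA/TGACC
  copies before planting; planted sites and decoy masked positions are
  locally re-checked so that the scan's hit list equals the planted truth
  exactly. Disrupting sites carry one ambiguity code containing the
  consensus base plus one alternate; non-disrupting planted sites are exact
  motif copies (see the half-site consequence above).
* **Genotypes.** Controls draw two allele copies independently at the SNP's
  control minor-allele frequency p₀ ~ U(0.05, 0.5) (HWE). A causal SNP with
  odds ratio ψ shifts its target stratum's case frequency to
  p₁ = ψp₀ / (1 − p₀ + ψp₀), making the planted ψ the estimand of the
  allelic test. Causal SNPs are planted as common variants at a fixed
  control MAF of 0.35 (default ψ = 0.6 in the female-bipolar stratum),
  the frequency class of the association the design is powered for; this
  keeps the end-to-end demonstration a check of stage wiring rather than
  a power lottery at rare frequencies, while power and estimation spread
  are measured separately by the null and OR-recovery studies. HWE violators add +0.35 absolute heterozygosity in controls
  only (the filter tests controls); at control-arm sizes of ~500 this puts
  the exact-test p far below the 10⁻³ threshold. Missingness is the union
  of a per-person and a per-SNP Bernoulli mask (1% each by default); one
  planted high-missing SNP (rate 0.2) and one failed sample (rate 0.5)
  deterministically violate the 0.05 and 0.1 thresholds — the person rate
  is high because person missingness is judged on the ~25-SNP candidate
  panel, where a 0.2 rate would escape the threshold too often.
* **LD.** Every ungenotyped candidate gets exactly one genotyped partner,
  alternating between r² ∈ [0.90, 0.99] (proxied) and [0.30, 0.85]
  (dropped), plus threshold-straddling noise pairs.
* **Scale and determinism.** Defaults: 2 chromosomes × 100 kb, 300 SNPs,
  60 planted half-sites (half disrupting), 40 regions per ChIP set with 40%
  triple overlap, cohort sizes as in the studied design (bipolar 487/490
  female, 477/508 male; depression 1200/1076, 527/682) — a full generate +
  analyse cycle takes a few seconds. All stages draw from named
  `numpy.random.default_rng([seed, stage])` streams; identical
  configuration and seed give byte-identical files.

What the generator does **not** emulate: realistic LD structure (no
coalescent haplotypes — LD values are labels consumed by proxy selection,
not estimable from the genotypes), population stratification, genotyping
batch effects, X-chromosome dosage, or per-disease genotyping platforms
(both diseases share one genotyped SNP set). Passing tests therefore
demonstrate the correctness and calibration of the pipeline's inference
under its own assumptions, not robustness to confounding present in real
cohort data.

## Verification strategy

Every statistical primitive is checked against an independent oracle in the
test suite: Fisher p against exhaustive hypergeometric enumeration with
`fractions.Fraction`; the HWE recurrence against the direct factorial
formula; interval operations against per-base boolean arrays on 10 kb toy
chromosomes; the motif scanner against brute-force enumeration of every
ambiguity resolution on sequences ≤ 200 bp; FASTA parsing against
biopython. Calibration is checked by simulation at study scale: the
null rejection rate of the stratified test at α = 0.05 over 500 SNPs
(expected slightly below nominal — Fisher's test is conservative under
discreteness), median recovery of a planted OR of 0.68 over 200 replicates,
and an end-to-end run in which a disrupting SNP planted in a triple-overlap
region must surface as its stratum's top association.

`scripts/acceptance.py` re-derives the headline numbers at run time; the
published 2×2 tables it reconstructs from reported MAFs and cohort sizes
are exact for the rows whose printed MAFs are consistent with full cohort
denominators. One reported odds ratio (male-depression top SNP) is known to
differ in the third decimal from the value implied by full-cohort counts,
presumably through per-SNP missingness in the original data; only its
Bonferroni product, which depends on the printed raw p alone, is
recomputed.

## Known limitations

* The motif model is the two 5-bp half-site cores (full 13-bp palindrome
  available as an optional pattern); no position-weight-matrix scoring and
  no tethered (AP-1/SP-1) binding prediction.
* LD is consumed, never estimated; no imputation.
* The allelic test assumes autosomal biallelic SNPs; no covariate
  adjustment, genomic control or permutation-based multiplicity.
* Consensus-region counts from the original published region sets are not
  reproducible here because those datasets are external; the interval
  semantics are instead verified exhaustively on synthetic data.
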