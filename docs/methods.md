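# Methods

This note documents the statistical model, the algorithms, and the design
choices behind `snpldb`. The package analyses *bi-phenotypic* qualitative
traits — traits with exactly two observed categories, such as brown vs. gray
pubescence or purple vs. white flowers — in an inbred germplasm collection
structured into a domestication series: annual wild (WA) → farmers' landrace
(LR) → released cultivar (RC) populations, each subdivided into four
ecoregion subpopulations (I north … IV south).

## Data model

Accessions are selfing inbred lines and are treated as effectively
homozygous: each carries a single haplotype per locus, and all haplotype
bookkeeping counts accessions, not chromosomes. Genotypes are stored as
integer codes per accession × SNP cell (0 ref-homozygote, 1 alt-homozygote,
2 heterozygous, −1 missing); heterozygous calls survive I/O and are only
resolved at QC. Coordinates are 1-based and inclusive throughout (VCF/GFF3
convention); half-open arithmetic never crosses a module boundary.

## Quality control

A SNP is removed when its missing rate exceeds 20%, its heterozygous rate
(among called genotypes) exceeds 20%, or its minor allele frequency falls
below 1%; boundary values are retained. A heterozygous call contributes half
an allele to each side of the MAF count — whether it should is genuinely
ambiguous for inbred panels, and the ½ convention is the package's choice.

Residual missing genotypes are imputed by a k-nearest-accession window vote:
the most frequent non-missing code among the k = 10 accessions closest in
normalized Hamming distance over a 50-SNP flanking window, ties resolved to
the per-SNP major allele. This is a deliberately simple, deterministic
imputer; its accuracy is validated by mask-and-recover experiments
(≥ 95% of 5%-masked cells recovered under the default simulation) rather
than by comparison with phasing-based methods, and it is adequate because
downstream haplotype calling only needs within-block consistency.
Residual heterozygous calls are collapsed to the per-SNP major homozygote
first — a lossy step, justified by the single-haplotype bookkeeping above.

## SNPLDB assembly

Markers are haplotype blocks: maximal runs of SNPs in strong pairwise
linkage disequilibrium. D′ is computed from haploid accession counts
(p̂_AB − p̂_A p̂_B normalized by its bound), never by EM over diploid
genotypes — the panel is inbred, so accession counts *are* haplotype
counts. The partition is greedy left-to-right: a block absorbs the next SNP
while its D′ with **every** current member exceeds 0.70 and the block span
stays within 200 kb; an unlinkable SNP becomes a single-SNP marker. The
greedy rule and the span cap are this package's operationalization — only
the D′ > 0.70 criterion itself is fixed by the marker definition — and both
are configurable. Confidence-interval (Gabriel) and four-gamete block
definitions are deliberately out of scope.

Each accession's allele string over a block's member SNPs is its haplotype;
the distinct strings, ordered by descending frequency, are the marker's
alleles. Haplotypes rarer than 1% are merged into an *approximate
haplotype*: the frequent haplotype at minimal Hamming distance, the more
frequent one if tied, iterated until stable. If every haplotype is rare the
two most frequent are kept as targets. No cap is imposed on the number of
haplotypes per marker; the 2–14 range seen in real germplasm data is
emergent, not enforced.

## Association

**Single-locus scan.** Every marker is tested with a Pearson χ² on its
H × 2 haplotype-by-category count table (zero rows dropped, df = H − 1, no
continuity correction — H × 2 tables with H > 2 have no standard correction
and consistency across H matters more). Markers are ranked by −log₁₀ p and
the top K (default 10) reported; no multiple-testing correction is applied
to the ranking because selection is by rank, not by threshold. p-values are
floored at 1e−300 to keep −log₁₀ p finite.

**Multi-locus model.** A restricted two-stage ("RTM-GWAS-style") procedure:
markers passing a single-locus preselection (p ≤ 0.05 by default) enter a
forward–backward stepwise least-squares fit of the 0/1-coded trait on
haplotype indicator variables, with the most frequent haplotype as the
omitted reference. The linear (not logistic) coding follows the multi-locus
framework this mirrors; for variance bookkeeping on a binary trait it is
exact. Entry and stay use partial F tests **Bonferroni-corrected by the
number of markers supplied to the stage** (threshold p/m). This is a design
choice: without genome-wide control every preselected marker would enter
under the null, and the procedure's intent is a sparse model whose
false-entry rate stays near the nominal level; with it, a null trait over
100 markers yields an empty model in ≈ 95% of replicates. Rank-deficient
additions (duplicated or collinear markers) are skipped with a warning.
Each selected locus is credited its sequential (type-I) sum-of-squares
share of the total phenotypic sum of squares, in selection order — a
reproducible decomposition that sums to the model R².

**Manhattan plots** truncate extreme significance: p < 1e−50 is replaced by
a seeded random value log-uniform in [1e−55, 1e−50], so one saturated locus
does not flatten the panel.

## Candidate genes

Genes are candidates when they overlap the associated marker's interval
expanded by 100 kb (closed interval; a gene touching the boundary base is
included). Every SNP inside a candidate gene is χ²-tested against each
marker member SNP on 2 × 2 haploid allele tables, at a per-SNP level of
0.05; a gene SNP is significant when any pair reaches the level. The
pairwise all-against-all reading is the permissive default (the alternative —
testing against the marker's haplotype classes — is implemented as
`mode="haplotype"`, and Bonferroni correction across pairs is available).
The significant gene SNPs define the gene's alleles: each accession's
nucleotide string (REF/ALT letters) over those SNPs. Gene alleles are *not*
rare-collapsed, unlike SNPLDB haplotypes, because germplasm allele tables
report alleles down to single carrier accessions. The module ranks genes
only by strongest linkage p; deciding which gene is "the" candidate requires
functional annotation, which is user-supplied metadata.

## Evolutionary tracing

Frequencies are tabulated per haplotype × population, × subpopulation, and
× (population × phenotype). A haplotype observed in a later population but
never among the n earlier accessions is called **emerged** when the
binomial probability of missing it by sampling error, (1 − f)ⁿ with f its
observed frequency where it *is* found, falls below 1e−6. The exponent is
n, not 2n (one haplotype per inbred accession), and the observed later
frequency stands in for the unobservable ancestral frequency — the only
computable reading. When more than one earlier population lacks the
haplotype, n is their combined size. A haplotype present earlier and absent
from a population onward is **excluded**. Candidate wild sources are the WA
subpopulations carrying the haplotype, ordered by descending frequency with
southern ecoregions (IV, III, II, I) breaking ties — a reporting convention
encoding the southern origin of the domestication series, nothing more.
No F-statistics, admixture modelling, or formal phylogeography is involved;
the inference is frequency bookkeeping.

## Synthetic populations

The generator emulates the *structure* the analysis assumes, not any
fitted demographic model — no generative model for the real germplasm data
exists, and all simulator distributions are stand-ins:

* 12 subpopulations (3 populations × 4 ecoregions) with configurable sizes,
  defaulting to a representative 1,024-accession collection
  (182 WA / 396 LR / 446 RC);
* chromosomes made of discrete LD blocks (default 2 chromosomes × 12
  blocks); each accession draws one haplotype per block from its
  subpopulation's frequency vector — no recombination, mutation, or
  coalescent machinery;
* block haplotype pools are threshold-type ("generalized staircase") allele
  strings, so every within-block SNP pair shows at most three gametes and
  has D′ = 1: the strong-LD regime block markers are designed for. Neutral
  blocks carry 18–24 SNPs and 4–8 haplotypes with Dirichlet base
  frequencies perturbed per subpopulation (Balding–Nichols-style scaling,
  F = 0.05) for mild structure. Block sizes are chosen so the imputer's
  50-SNP window is dominated by within-block signal;
* the phenotype is Bernoulli in the per-haplotype, per-population
  penetrance of one designated causal block — incomplete penetrance is what
  produces the "one haplotype, two colors" pattern, and emergence/exclusion
  are expressed purely as zero entries in the frequency vectors;
* missing and heterozygous codes are injected uniformly at random (defaults
  2% and 1%) *after* phenotype assignment, so QC is exercised without
  distorting truth;
* two bundled causal presets mirror the published pubescence-colour
  (6 haplotypes, one absent from WA and emerging in LR) and flower-colour
  (5 haplotypes, two excluded from RC) loci, with frequencies and
  penetrances transcribed from the published tables.

What passing simulation tests does **not** show: robustness to LD decay
within and between blocks, to genotyping error correlated with allele
frequency, to population admixture, or to phenotype misclassification —
none of which the generator emulates. Haplotype calls made from
noise-injected data carry a few percent miscall rate (the causal presets
span only 4–5 SNPs, so the imputer has little within-block signal there);
exact zero-count inferences such as emergence are therefore demonstrated on
truth assignments and on the packaged fixture tables, where counts are exact.

## Problem sizes and determinism

The seeded validation experiments use n = 1,000 accessions with ~500 SNPs in
24 blocks (50 replicates for ranking and variance recovery, 50 null
replicates over 100 markers, 10 replicates for classification recovery) —
sizes at which every experiment's outcome is stable across seeds while the
whole suite runs in about a minute. All randomness flows through
`numpy.random.default_rng` seeded from configuration; re-running any stage
with the same config and seed is byte-identical, and the pipeline manifest
records a SHA-256 digest of every result file to make that checkable.

## Known limitations

* The block partition is order-dependent (greedy left-to-right); a SNP can
  be "stolen" by a left block even when it fits the right one better.
* The linear 0/1 trait coding gives exact variance bookkeeping but not a
  calibrated effect-size model; a logistic alternative is out of scope.
* The imputer is not a phasing method and degrades on blocks much smaller
  than its window.
* Tracing treats populations as a fixed series (WA → LR → RC) and cannot
  represent gene flow back into earlier populations.
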