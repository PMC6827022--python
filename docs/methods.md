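# Methods

## The segregation model

The data are a sites × samples matrix of diploid genotype call strings
over {A,C,G,T} ("NN" = missing) with each sample labelled as one of two
species, built as the union of per-sample VCF calls (a sample with no
record at a site is *unknown*, "NN", never assumed homozygous reference —
per-sample variant callers omit ref/ref records, and assuming them would
manufacture spurious perfect segregation). Indels are excluded: the
downstream assay is SNP-based.

A site is informative for species classification when each species'
**major genotype** (most frequent call among that species' samples, with
"NN" competing as a category and ties broken to the lexicographically
smallest string) is carried by exactly that species. Sites with a missing
major genotype or with identical majors in both species are removed before
testing; the removal log records the triggering rule per site.

For each remaining site the **chi-square goodness of fit** asks whether
the carrier frequency of a species' major genotype matches that species'
sample ratio. With species sample sizes N_a and N_b, N = N_a + N_b, M
non-missing calls at the site, and c carriers of the species-A major
genotype among them, the two-category table O = [c, M−c] is compared with
E = [M·N_a/N, M·N_b/N] by χ² = Σ(O−E)²/E with one degree of freedom and an
upper-tail p-value; the same construction applies to the species-B major
genotype, and the reported statistic is the symmetrized worst case
(max χ², min p). Missing calls are dropped and the expected counts are
rescaled by M so that E sums to the observed total. Statistics below
1e-12 are snapped to exactly zero (p = 1) to absorb floating-point noise.
No multiple-testing correction is applied; selection happens downstream
through the gene score.

A **key site** segregates perfectly: every non-missing species-A sample
carries the species-A major genotype, every non-missing species-B sample
the (distinct) species-B major genotype. Perfect segregation implies
χ² = 0 and p = 1 when missingness is balanced across species, but the
converse fails: exchanging one sample per species preserves the carrier
*count* at its expectation (p = 1) while breaking segregation. The strict
combinatorial predicate is therefore the default key-site rule; the
p-value-only rule is available as `key_rule="p1"` for comparison. Note
that with strongly unbalanced missingness (e.g. a whole species missing at
a site) a perfectly segregating site can have p < 1 under the
sample-ratio expectation; the predicate deliberately ignores p.

## Gene scoring and the tail threshold

Each tested site inside a gene contributes +1 if key, −1 otherwise:
score = n_key − n_nonkey. Sites are assigned by coordinate containment in
the GFF3 `gene` feature span (introns included; the feature type is
configurable). A site inside overlapping genes scores all of them, which
inflates summed counts across genes — documented because conservation
checks must count (site, gene) pairs, not sites.

The key-gene threshold is the smallest integer t whose upper tail holds at
most the target fraction (default 5%) of the score distribution's mass:
either the empirical fraction of scores strictly above t, or the integral
above t of a Gaussian kernel density estimate (Scott's bandwidth). The
empirical rule is deterministic and used in tests; the two agree within
one score unit on well-separated bimodal distributions. Key genes are
those *strictly above* t. All-equal score lists are rejected rather than
given an arbitrary threshold.

## CAPS design

Recognition motifs use the 15-symbol IUPAC alphabet; scanning reports
0-based top-strand cut positions for motif occurrences in both
orientations (forward occurrence at i cuts at i + offset; an occurrence of
the reverse-complemented motif at i cuts at the mirrored offset
i + |motif| − offset). For a palindromic motif both orientations see the
same occurrences and one forward cut is reported per occurrence —
double-strand overhangs are ignored throughout, since gel electrophoresis
resolves fragment lengths, not ends. Consequently cut *positions* are
mirror-symmetric under reverse complement for non-palindromic enzymes, and
fragment multisets are preserved for centrally cutting palindromes; for a
palindromic enzyme with an off-centre cut (BspHI, T^CATGA) the reported
single cut shifts within the overhang under reverse complement, which is
invisible on a gel at the resolution this predicts.

An enzyme *discriminates* at a site when the multiset of recognition
occurrences overlapping the site differs between the two alleles
substituted there; the discriminating allele is the one creating the extra
occurrence. The search window defaults to |motif| − 1 bp each side — the
minimal span in which a substitution can alter a match.

In-silico PCR is exact-match: the forward primer and the reverse primer's
reverse complement must each occur exactly once, facing each other on one
sequence; multiple bindings raise an ambiguity error rather than guessing.
Validation primers are taken verbatim from the reference (default 20 bp at
±300 bp around the site), so exactness suffices and keeps the design
deterministic. Digestion is linear and complete; fragments are reported in
descending length, fragments under 50 bp are flagged as hard to see on an
agarose gel but still listed. A marker is emitted only if the two alleles'
fragment lists differ.

## Sample structure

Genotypes are encoded per site as the count of non-reference alleles in
the call (0/1/2); this collapses distinct non-reference alleles into one
dosage scale, which is sufficient for separating two species and avoids
the column blow-up of one-hot encodings. "NN" is imputed with the site
mean; all-missing sites are dropped with a log entry. PCA is an SVD of
the column-centered (not variance-scaled) dosage matrix, with each
component's sign fixed so its largest-magnitude loading is positive —
scores are then invariant to sample order. Samples are clustered on the
PC scores by average-linkage agglomerative clustering with Euclidean
distance (both exposed as options); the output is the dendrogram leaf
order plus a per-sample score table for heatmap rendering.

## The synthetic-data generator

The generator emulates a consolidated two-species resequencing matrix:

- **Sample imbalance**: defaults of 38 vs 5 samples reflect the common
  situation where the invasive species is densely resequenced and the
  confounder species sparsely.
- **Diagnostic sites** (default 5% of sites) carry two distinct homozygous
  genotypes, one per species — the fixed-difference pattern of
  between-species haplotypes. Haploid males appear as homozygous diploids,
  as genotype callers emit them.
- **Sample-specific polymorphism**: all other sites draw each sample's
  genotype independently of species from {ref/ref, ref/alt, alt/alt} with
  probabilities 0.6/0.25/0.15, re-drawn if monomorphic; most of these are
  later removed by the identical-major filter, as in real data.
- **Missingness** (default 2%) sets calls to "NN"; **noise** (default 1%)
  then replaces calls with a different genotype from the site's clean
  alphabet — the simplest error model able to break perfect segregation.
- **CAPS implants** (default 3): chosen diagnostic sites whose species-A
  allele equals a concrete base of an assigned enzyme's recognition motif.
  The reference realizes the motif around the site so that exactly the
  species-A allele completes it; all other diagnostic sites are scrubbed
  so no listed enzyme's motif overlaps them under either allele, and no
  second enzyme discriminates at an implant. Implanted markers are
  therefore exactly the recoverable ones — ground truth for end-to-end
  precision and recall.
- **Geometry**: one scaffold (default 500 kb), sites at least 15 bp apart
  (keeps motif windows disjoint) and 350 bp from the ends (room for
  primers); gene models are non-overlapping intervals tiling the sequence.
  Positions, sequence, and every stochastic choice derive from one seed;
  identical parameters give byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium, allele
frequency spectra, coverage-dependent missingness, indels, multi-scaffold
references, or clustering of diagnostic sites within particular genes.
That last point matters for interpretation: with uniformly scattered
diagnostic sites, gene scores stay at or below zero and no key genes
emerge at the 5% tail — passing tests show the scoring arithmetic and
threshold rule are right, not that key genes exist under uniform
placement. Gene-level selection is exercised with constructed fixtures in
which key sites cluster.

## Problem sizes and numerical choices

Tests and the end-to-end validation run at desk scale: 38 + 5 samples,
5,000 sites, 5% diagnostic, clean calls for exact-recovery checks (the
paired noise/missingness invariant only holds exactly at zero noise), and
smaller 10–14-sample matrices for unit tests. The chi-square oracle test
enumerates every 2-category table with total ≤ 12 against the closed-form
df = 1 tail (erfc(√(x/2))) at 1e-10. Digestion conservation is checked on
10,000 random sequence/enzyme pairs. The bundled enzyme table holds
twelve common type-II enzymes and is user-replaceable (TSV: name,
recognition, cut offset).

## Known limitations

- The goodness-of-fit expectation uses total species sample sizes, so
  heavily species-biased missingness distorts p at sites that still
  segregate perfectly; the key-site predicate is immune, but reported
  p-values at such sites understate segregation.
- Exact-match PCR cannot model primer mismatch tolerance; markers designed
  on a diverged reference may fail in the other species even though the
  site segregates.
- Overlapping genes double-count sites by design; per-gene scores remain
  correct individually but are not additive across overlapping genes.
- The dosage encoding discards phase and treats all non-reference alleles
  alike; PCA separation claims are about species-level structure, not
  finer population structure.
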