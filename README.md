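# capskit

Species-diagnostic SNP discovery and CAPS marker design from multi-sample
genotype calls.

## The problem

Distinguishing closely related species — for example the invasive red
imported fire ant *Solenopsis invicta* from the tropical fire ant
*S. geminata* at a port of entry — by morphology requires trained experts.
A molecular assay is faster and more reliable: find genomic sites whose
genotypes segregate perfectly between the two species, and turn one of them
into a CAPS (cleaved amplified polymorphic sequences) marker — a PCR
product that a restriction enzyme cuts under one species' allele but not
the other, so the species is read directly from gel fragment sizes.

capskit implements that pipeline for anyone with whole-genome resequencing
data of two species groups:

1. **Consolidation** — merge per-sample VCFs into a sites × samples
   genotype matrix ("AA", "AT", …, "NN" for missing), taking the union of
   sites; absent calls become "NN".
2. **Key-site test** — per site, a chi-square goodness of fit: the major
   genotype of each species should be carried by samples at that species'
   sample ratio. With species sample sizes N_a, N_b (N = N_a + N_b) and M
   non-missing calls at a site, the carrier count c of a major genotype is
   compared against E = [M·N_a/N, M·N_b/N] via χ² = Σ(O−E)²/E, df = 1.
   Sites whose major genotype is missing, or identical in both species, are
   filtered first. *Key sites* segregate perfectly (every non-missing
   sample carries its species' major genotype; this implies χ² = 0, p = 1).
3. **Gene scoring** — each tested site inside a gene adds +1 (key site) or
   −1 (non-key) to the gene's score; *key genes* exceed a threshold chosen
   so the upper tail of the score distribution holds 5% of its mass.
4. **CAPS design** — for each key site, find restriction enzymes whose
   recognition site exists under exactly one allele, amplify the region in
   silico, and predict per-allele digestion fragment lengths.
5. **Sample structure** — dosage-encode the matrix, run PCA, and cluster
   PC scores to verify that samples group by species (PC1 separates them).

A synthetic-data module generates genotype matrices, reference sequences
and annotations with planted ground truth (diagnostic sites, implanted
CAPS sites), so the full pipeline runs and is validated offline.

## Worked example

Simulate a two-species cohort (38 + 5 samples, 5,000 polymorphic sites of
which 5% are species-diagnostic, clean calls), then run the pipeline:

```sh
capskit simulate --n-a 38 --n-b 5 --sites 5000 --frac-diagnostic 0.05 \
    --missing-rate 0 --noise-rate 0 --seed 11 --out demo
capskit consolidate --vcf demo/samples.vcf --labels demo/labels.tsv \
    --out demo/matrix.tsv
capskit test-sites --matrix demo/matrix.tsv --labels demo/labels.tsv \
    --out demo/sites.tsv
capskit design-caps --ref demo/reference.fa --sites demo/sites.tsv \
    --out demo/markers.tsv
capskit pca --matrix demo/matrix.tsv --labels demo/labels.tsv --components 7 \
    --scores-out demo/scores.tsv
```

which prints:

```
5000 sites x 43 samples -> demo/matrix.tsv
1397 sites tested, 250 key sites -> demo/sites.tsv
3 markers for 250 key sites -> demo/markers.tsv
explained variance: 6.1%, 2.7%, 2.6%, 2.6%, 2.6%, 2.6%, 2.6%
```

Of 5,000 polymorphic sites, 1,397 pass the candidate filter (the rest have
missing or species-identical major genotypes — mostly sample-specific
polymorphism) and exactly the 250 planted diagnostic sites come out as key
sites (χ² = 0, p = 1). The three markers are the three implanted CAPS
sites; `demo/markers.tsv` holds their predicted gel patterns, e.g.

```
seqid  pos   enzyme  allele  is_discriminating  n_fragments  fragments  amplicon_length
ctg1   640   BspHI   T       True               2            303,298    601
ctg1   640   BspHI   A       False              1            601        601
```

— a 601 bp amplicon that BspHI cuts into 303 + 298 bp when the species-A
allele T is present and leaves whole under the species-B allele A: the two
species give visibly different gels. PC1 of the dosage PCA (6.1% explained
variance) alone separates the two species.

Gene scoring works the same way from the CLI (`capskit score-genes --sites
demo/sites.tsv --gff demo/genes.gff3 --out demo/gene_scores.tsv`); note
that this simulation scatters diagnostic sites uniformly, so no gene
concentrates enough key sites to clear the 5% tail threshold — key genes
appear when key sites cluster, as they do in real species comparisons.

## Library use

Every CLI step is a thin wrapper over `capskit` functions
(`consolidate`, `test_all_sites`, `score_genes`, `determine_threshold`,
`design_caps`, `run_pca`, …); see `docs/methods.md` for the statistical
model, parameter choices, and limitations.
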