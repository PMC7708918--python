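# Methods

This note documents the models, conventions and numerical choices behind
`gik`, and what the synthetic-data generator does and does not emulate.

## Structural-variant triage and panel design

SV records are reduced to the five-class vocabulary DEL / INS / INV / ITX /
CTX. Modern SV callers emit translocations as breakend (BND) mate pairs;
mates are resolved through the ALT breakend notation or the `CHR2`/`POS2`
INFO keys and classified ITX when both ends share a chromosome, CTX
otherwise, with each pair counted once. Legacy `TRA`-style records are
classified the same way. Insertion length comes from `SVLEN`/`INSLEN`
(POS = END for insertions); deletion and inversion length is END − POS.
Translocations carry no fragment length, so their `length` is `None` —
length histograms and the 50–400 bp candidate filter only ever touch
DEL/INS. The candidate filter bounds are inclusive: "50–400 bp" is read
the conventional way.

**Panel spacing.** Given a per-chromosome candidate list and a quota
(default 10), the panel maximizes the minimum pairwise physical distance of
the chosen subset. Because feasibility of a minimum gap *d* is monotone in
*d* and checkable by a leftmost-first greedy sweep, a binary search over the
achievable gap values gives the *exact* optimum for points on a line, not a
heuristic; the greedy sweep at the optimal gap also realises the
smaller-coordinate tie rule. A quota of one selects the candidate nearest
the midpoint of the candidate span. Marker ids follow the
`C<chromosome:02d><serial:03d>` convention with serials assigned by
position rank among the chromosome's candidates, so a selected marker keeps
its candidate rank (serials can exceed the quota).

**Multiplex packing.** Each marker occupies the product-size interval
between its two expected PCR products. Markers are placed by
first-fit-decreasing span into (group, dye) channels; within one channel,
intervals padded by `size_gap` (default 20 bp, a typical capillary binning
safety margin) must be pairwise disjoint, groups hold at most
`max_group_size` (default 24) markers, and products must fall inside the
detectable range (default 50–500 bp). First-fit-decreasing is a standard
packing heuristic; the output is always validated against the packing
constraints, only the group count is heuristic.

## Genotype tables

Calls are unordered allele multisets of integer fragment sizes; a single
observed allele on a diploid expands to a homozygote because capillary
chromatograms show one peak. Polyploids store their observed (≤ 2-allele)
set flagged dosage-unknown: they participate in identity matching (a
tetraploid sport can share a fingerprint with its diploid progenitor) but
are excluded from Hardy–Weinberg, diversity and Fst computations, which
assume diploid genotype proportions.

Biallelic recoding maps, per marker, the larger observed fragment to the
insertion allele (I) and the smaller to the deletion allele (D), over a
caller-chosen accession set; markers with three or more observed alleles
are excluded and listed, single-allele markers retained but flagged
monomorphic. Interoperability exports (PLINK PED/MAP, STRUCTURE two-row,
GenAlEx-style CSV) use the dialects' missing conventions (`0 0`, `-9`, `0`).

## Identity signatures

The canonical string concatenates `marker=alleleA|alleleB` fields sorted by
marker id, missing encoded `?`; the digest is SHA-256 of that string.
Grouping is exact string equality. Missing cells are matched as ordinary
symbols: wildcard ("ignore missing") matching is not transitive and
therefore can only partition accessions arbitrarily, so it is surfaced as a
*possible duplicates report*, never as merged groups. Name classification
is conservative — NFKC case-folding and punctuation stripping only, with an
optional user alias map, because synonym adjudication in a real collection
needs curator knowledge. Precedence is replicate > synonym > homonym. A
sport lineage report calls an accession distinguishable when its signature
is unique within its lineage; the rest fall into shared subgroups.

## Diversity, differentiation and Hardy–Weinberg

Per locus: Na = observed allele count, Ne = 1/Σp², I = −Σp·ln p, Ho =
heterozygous fraction of typed individuals, He = 1 − Σp² (uncorrected;
the 2n/(2n−1) small-sample variant is exposed as `uHe`), F = (He − Ho)/He.
Population summaries are unweighted across-locus means; F is averaged as a
mean of per-locus ratios over loci where it is defined (the GenAlEx
convention — with polymorphic loci, mean-of-ratios and ratio-of-means can
differ noticeably). Both "all loci" and "polymorphic loci only" summary
modes are provided. For biallelic loci the identity Ne = 1/(1 − He) is
asserted algebraically on every evaluation.

**Fst.** The default estimator is Weir & Cockerham's (1984) θ: per locus
and per allele the among-population (a), among-individual-within-population
(b) and within-individual (c) variance components are computed from sample
sizes, allele frequencies and heterozygote frequencies, summed over alleles
and loci, and combined as θ = Σa / Σ(a+b+c). Loci untyped in either
population, or with mean sample size ≤ 1, are dropped; two populations
fixed for alternative alleles give θ = 1 exactly. Nei's Gst
((Ht − Hs)/Ht with unweighted Hs and mean-frequency Ht) is the secondary
estimator; it is downward-biased relative to θ in small samples, which is
why differentiation results always name their estimator.

**Differentiation test.** Per biallelic locus, a two-sided Fisher exact
test on the 2×2 population × allele count table (for biallelic loci the
Markov-chain exact test used by standard genepop-style software degenerates
to Fisher's test); across loci, Fisher's combining statistic −2Σln p
against χ² with 2L degrees of freedom. Monomorphic loci are skipped; with
no polymorphic locus the combined p is reported as undefined.

**Hardy–Weinberg.** The conditional exact test: given the observed allele
counts, heterozygote counts of matching parity follow the Levene/Haldane
distribution; the p-value sums the probabilities of all outcomes no more
probable than the observed one (ties included with a 1e-12 relative
tolerance; probabilities are computed in log space via `gammaln` and
normalised, and the sum is clamped to 1 against floating-point overshoot).
Monomorphic samples give p = 1.

**Genotype-frequency patterns.** The marker × (species-group,
genotype-class) frequency matrix is clustered by complete-linkage
agglomerative clustering on Euclidean distance (the defaults of the common
heatmap packages) and cut at k = 5. Cluster naming priority, applied in
order to centroid summaries: highest mean heterozygote frequency → IV
(heterozygote-excess pattern); then highest mean DD minus II → I
(deletion-skewed); then lowest mean DD → II (deletion-rare); remaining
clusters are III, V, … in first-appearance order. The summaries are
reported so users can match clusters to biological descriptions themselves.

## Parentage

Duo compatibility at a locus = the two multisets share an allele; trio
compatibility = the offspring's two alleles admit an assignment of one
allele to each parent. Loci with any missing call are uninformative.
Confidence C is the compatible fraction of informative loci; a hypothesis
is accepted iff C > 0.98 AND mismatches ≤ 1 (both knobs exposed). The
mismatch threshold is the only mutation/null-allele tolerance — the
procedure is exclusion-based by design; no allele-frequency likelihood/LOD
model is fitted (noted as a possible extension). Collection scans collapse
identity groups to one representative first, since clonal sports are
interchangeable as parents, and report the full member list per hit; hits
are ranked by (mismatches ascending, confidence descending, id). The scan
uses a vectorized allele-membership formulation of the same trio rule that
is exhaustively cross-checked against the scalar predicate in tests.

## Synthetic collections

The generator draws ancestral allele frequencies from a (configurable)
uniform distribution truncated to [0.05, 0.95], then per-species
frequencies from the Balding–Nichols Beta distribution
Beta(p(1−φ)/φ, (1−p)(1−φ)/φ), whose mean is p and variance φ·p(1−p), so φ
is the expected Fst against the ancestral pool — a one-parameter analytic
handle that the Weir–Cockerham estimator should (and, per the calibration
checks, does) recover. Within species, genotypes are Hardy–Weinberg;
offspring receive one uniformly chosen allele per parent per locus; clones
copy their founder and mutate each locus independently with probability μ
by replacing one allele with a different member of the marker's allele set
(novel fragment lengths are rare in capillary genotyping, so no new alleles
are created). Missingness is i.i.d. per cell. Name errors are planted from
disjoint source draws so the truth log is unambiguous.

Default conditions mirror the study scale this kit targets: 102 markers;
seven species with sample sizes (27, 42, 20, 30, 19, 22, 13) and
divergence φ spread over 0.02–0.13; eight two-offspring families; three
clonal sport lineages of 160, 60 and 60 members; missing rate 0.01; ten
planted synonym pairs, ten homonym pairs and four replicate pairs
(scaled-representative counts). The somatic rate μ = 0.005 per locus per
clone is a package choice — published collections report discriminability,
not mutation rates — set so that a clone has ≈ 40% probability of at least
one mutation across 102 loci, the scale at which a meaningful fraction of
sports becomes distinguishable.

What the generator does **not** emulate: parallel/recurrent somatic
mutation at hotspot loci and chimerism (real sport lineages share derived
genotypes much more than independent mutation predicts, so real
discriminability is lower than simulated at matched μ); linkage between
markers (treated as unlinked, matching the downstream analyses);
ascertainment bias of markers developed in one species (which depresses
diversity in distant relatives); genotyping error other than missingness.
Passing tests on simulated data therefore validate the estimators and the
bookkeeping, not field performance on any particular collection. Note also
that with exact-symbol matching, missing calls make otherwise identical
accessions distinct: fingerprinting analyses of the default collection
reflect its 1% missing rate, and clone-recall properties are checked at
missing rate 0.

## Problem sizes and determinism

Calibration checks use 100 loci × 100 diploids per population × 200
replicates for θ recovery, a 100-marker/50-family pedigree for the
parentage scan, exhaustive enumeration up to n = 10 for the exact HWE test,
and brute-force subset enumeration up to 20 candidates for panel spacing —
sizes at which the independent oracles are exact and fast. All simulation
flows from one seeded `numpy` Generator; equal seeds give byte-identical
collections, and the pipeline writes a MANIFEST of SHA-256 content digests
so re-runs can be verified file by file.

## Known limitations

* The real 1,251-accession genotype matrix cannot be redistributed, so the
  checks that reproduce its published counts require a user-supplied CSV
  export (see README).
* Triploid/tetraploid dosage is not modelled; polyploids carry observed
  allele sets only.
* The multiplex group count is first-fit-decreasing, not provably minimal.
* Exclusion-based parentage cannot rank multiple accepted hypotheses by
  genetic plausibility; a likelihood layer would be needed for that.
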