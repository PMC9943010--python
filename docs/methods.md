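# Methods

## Scope and data model

mlstkit analyses bacterial genome assemblies against MLST schemes. A scheme
is an ordered locus list; the four builtin definitions (P1, S2, S3, L1)
cover the schemes applied to *B. subtilis* — S1 shares P1's locus set (only
the concatenation order differs) and is therefore not instantiated
separately. S2 uses whole genes (`locus_mode=full_gene`, allele lengths may
vary); the others use fixed-length internal fragments, for which equal
allele length is enforced. Allele databases and ST profile tables are
bijections; novel entries always receive `max(existing)+1`, matching how
public registries extend numbering, and registration is idempotent.

Scheme databases are directories of per-locus allele FASTA files (headers
`<locus>_<number>`, PubMLST convention), a `profiles.tsv` table
(`ST<TAB>locus1...locusK`) and a `scheme.yaml` definition. Writing then
reloading a database is the identity; tests freeze this round-trip.

## Typing

Locus location is two-staged. Stage 1 searches every known allele verbatim
on both strands of every contig; a unique occurrence is returned with
identity 1.0. Stage 2 aligns each allele in infix mode (edlib, HW) against
each contig/strand and accepts the best span when identity over the full
allele length is at least `min_identity` (default 0.90 — within one species
housekeeping loci are highly conserved, so a lower bound would only admit
paralogs). Two or more non-overlapping qualifying spans are reported as
`ambiguous` rather than resolved arbitrarily; mutually overlapping hits
(e.g. the same span found forward and reverse) are resolved
deterministically by identity, then plus strand, then leftmost position.
Coordinates are 0-based half-open on the forward strand; extracted
sequences are reported in database orientation. Loci split across contig
boundaries are reported `missing`; no protein-level discovery is attempted.

Novel-allele policy: `extend` registers new alleles and STs by continuation
numbering (appropriate when curating one's own database, as was done for
S2/S3/L1); `strict` reports them without numbers and leaves the database
untouched (appropriate when comparing against a public registry, as for
P1). An ST can only be derived when every locus call carries a number, so
`st_status` is `undefined` whenever a call is missing, ambiguous, or novel
in strict mode; a strict-mode unseen profile is reported `novel` with
`st=None`. Hits containing ambiguous bases (N) can never be exact and are
never registered — allele databases stay strictly A/C/G/T.

The partition of strains into STs is invariant under input order (only the
labels of newly assigned numbers depend on it); typing is invariant under
contig-wise reverse complement. Both are property-tested.

## Diversity statistics

* Polymorphic sites: columns with ≥2 states among equal-length sequences.
* Typing efficiency: alleles per polymorphic site; undefined (not 0) for a
  monomorphic locus.
* Discriminatory power (Hunter–Gaston): D = 1 − Σ nⱼ(nⱼ−1)/(N(N−1)),
  computed over strains — each strain contributes its type's group size —
  because the index is defined as the probability that two randomly
  selected strains are distinguished. Requires N ≥ 2.
* dN/dS: Nei–Gojobori (1986) counting. Potential synonymous sites per codon
  are Σ over positions of (synonymous one-step changes)/3, with changes to
  stop codons counted as non-synonymous; S and N are averaged over the two
  sequences. Observed differences are resolved by averaging over all
  minimal substitution pathways, skipping pathways through stop codons
  (when every pathway is blocked, all pathways are used so Sd+Nd still
  equals the nucleotide difference count). Proportions are corrected with
  Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), reported undefined when p ≥ 3/4
  rather than clamped; an uncorrected mode exists for oracle tests. Per
  gene, dN and dS are means over all unordered strain pairs (duplicates
  included, matching common MEGA practice; a `distinct_only` flag switches
  to allele representatives since either convention is defensible), and the
  ratio is mean(dN)/mean(dS) — aggregating pairwise ratios would let
  division-by-zero pairs dominate. The implementation agrees with
  Biopython's NG86 routine to machine precision on random ORFs (test-only
  cross-check) and with a codon-pathway enumeration oracle over all 61×61
  sense-codon pairs.
* Scheme summaries are unweighted arithmetic means across loci; the ST
  count excludes strains with undefined ST. Nucleotide diversity beyond
  polymorphic-site counts is deliberately not computed (no agreed formula
  in this context).

## Clonal complexes and the goeBURST MST

Profile distance is the Hamming distance over loci. SLV/DLV counts come
from the all-pairs distance matrix; clonal complexes are connected
components (≥2 members) of the SLV graph and STs with no SLV partner are
singletons. The full MST is built by Kruskal over the complete distance
graph with edges ordered by: distance; then, descending, the endpoint SLV
counts (larger endpoint first, then the smaller), the endpoint DLV counts,
the endpoint frequencies (isolate counts); then ascending ST numbers. This
is the goeBURST tiebreak hierarchy; the comparator is frozen by tests that
enumerate all minimum spanning trees on small instances. Strains with
undefined ST are excluded from CC/MST with a warning (their distance is
undefined). The complete graph is connected so a single tree results; a
`max_level` cutoff drops edges above a given distance to produce the
display forest. Bootstrap founder confidence and graphical layout are out
of scope; the tree is exported as TSV and convertible to a networkx graph
for standard writers.

## Gene screening

References are FASTA, nucleotide or protein by alphabet. Nucleotide
screening short-circuits on an exact occurrence, otherwise takes the best
local alignment (match 2 / mismatch −3 / gap −5,−2) over all
contigs/strands; protein screening aligns against all six reading frames
(BLOSUM62, stop-free segments). Identity is identical positions over
aligned columns; coverage is the aligned fraction of the reference. A gene
is present iff identity ≥ 0.80 and coverage ≥ 0.70 — explicit stand-ins for
the annotation-server evidence the screen replaces, exposed as flags and
recorded in every report; presence is monotone in both thresholds. The
glutamate-from-histidine verdict follows the pathway chain literally
(hutH → hutU → hutI → hutG): any missing gene breaks it. Downstream
synthesis of glutamine/arginine/proline from glutamate is annotation, not
computation.

## Synthetic populations

The generator plants everything the pipeline later estimates. Per locus it
draws a random stop-free ancestral ORF and derives alleles by point
substitution at distinct sites; each substitution is synonymous with
probability `syn_bias`, placed by rejection sampling over codon positions,
and never creates a stop codon. `n_STs` distinct profiles are drawn from
the pools; every ST receives one strain and the remainder are assigned by
`st_frequencies` (uniform by default). Assemblies embed each planted allele
exactly once, on a random strand, between i.i.d. uniform flanks; a
post-check regenerates flanks that create a spurious exact occurrence of
any pool allele. The four hut genes are fixed-seed synthetic ~900 bp ORFs —
arbitrary coding sequences, not *B. subtilis* biology, since the screen is
tested on identity/coverage logic. Knockouts delete the gene body entirely
and are planted clonally (whole STs at a time), reflecting gene loss as a
lineage trait; `hutU` is always retained, matching the observed pattern in
the organism this emulates.

Defaults emulate the study population: 7 loci × 450 bp, 6 alleles per
locus, substitution rate 0.01/site, `syn_bias` 0.7 (housekeeping genes
under purifying selection, dN/dS ≪ 1), 39 strains in 31 STs, knockout
fraction 7/39, contigs split per strain. These sizes keep a full
simulate–type–screen cycle under ten seconds while preserving the study's
shape.

What passing tests on synthetic data do **not** show: real assemblies have
sequencing error, indels, paralogy, mobile elements, fragmented loci and
pseudogenes; the generator produces none of these (substitutions only,
single-copy loci, whole-gene deletions). Recovery results therefore
validate the logic — search, numbering, statistics, tree construction,
thresholds — not robustness to assembly artefacts.

## Determinism and outputs

All randomness flows through one numpy generator per run seed. Pipeline
outputs are TSV with fixed column order and a header comment carrying the
tool version, a hash of the scientific configuration (the output directory
is excluded from the hash) and the seed; a JSON manifest lists every file
with its SHA-256. Rerunning with the same seed and inputs is byte-identical,
which the tests assert.

## Known limitations

* No read-level simulation (assemblies only) and no handling of loci
  fragmented across contigs.
* dN/dS is counting-based; no maximum-likelihood codon models.
* The P1 fragment coordinates and the L1 numbering baseline of any
  particular public snapshot are inputs, not built-ins: typing against real
  registries requires supplying those databases as files.
* Screening thresholds are sequence-evidence stand-ins; they cannot
  distinguish a full deletion from a diverged pseudogene near the cutoff.
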