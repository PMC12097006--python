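# Methods

## Scope and model

`protfam` re-implements the decision layer of a family-guided
metagenomic discovery pipeline as a library with a thin CLI. The
external tools in such a pipeline (quality control, assembly, gene
calling, HMMER, DIAMOND, Kraken2/Bracken, Bowtie2-style mappers,
COMEBin/MetaBinner-style binners, Phobius) are treated as format
contracts: the package parses their standard text outputs and makes the
downstream decisions. This keeps every decision deterministic,
auditable and testable against planted inputs.

## Family knowledge base

A Swiss-Prot flat-file record contributes: the first AC accession, the
DE full names (recommended then alternative, in order; short names only
behind a flag, since which DE subfields count as "names" is a
convention choice), the OS organism, the SQ length, the Pfam DR
cross-references (the trailing match count expands to one accession per
domain, so a protein's *profile set* is a true multiset), and the
family from the similarity comment. Section notes ("In the C-terminal
section", "In the central section", "In the N-terminal section") are
appended to the family name as a qualifier, so section-specific
memberships form distinct families with distinct codes.

Per family the KB stores: member accessions, mean and median member
length, name frequencies (counted once per DE occurrence by default; a
flag switches to once per protein), and **all** profile sets tied at the
maximum member frequency. Empty profile sets never participate in the
maximum; a family of profile-less proteins simply has no representative
set. Tied sets are ordered by their canonical serialized form
(`acc:freq` pairs, accessions sorted) so KB builds are reproducible.
Family codes are consecutive integers in order of first appearance —
they are artifact-local identifiers, resolvable by name as well.

## Database construction

The name threshold is a percentage of the maximum name frequency:
`keep name n iff f(n) ≥ (t/100)·max f`, compared inclusively, so `t=0`
keeps everything and `t=100` keeps exactly the argmax names. Name
matching against FASTA descriptions is case-insensitive substring
matching; a name carrying leading/trailing spaces (the abbreviation
convention) matches only at token boundaries, with the description
virtually padded so boundary tokens still match. Matching uses the
description only (text after the first whitespace), not the sequence
identifier. FASTA filtering chunks the input, filters chunks
independently (optionally in parallel) and concatenates in chunk order,
so output bytes are independent of the worker count.

Profile-database extraction copies the HMMER3 text blocks whose
accessions appear in the union of the selected families'
maximum-frequency sets, each block once, in database order; accessions
missing from the HMM database are warned about and returned in a
missing list rather than failing the build.

Header taxa: nr-style headers yield every `[...]` group across
`\x01`-separated sub-headers; UniRef-style headers yield the `Tax=`
field. Dialect auto-detection is by the `UniRef` identifier prefix.

## Seek mode

Type 1 = proteins with ≥ 1 profile hit. Type 2 = profile-negative
proteins with ≥ 1 alignment hit at E ≤ cutoff; the comparison is
inclusive and the default cutoff is 1e-70. Type 3 is the disjoint
union. Domain tables are parsed with the per-domain independent E-value
by default; a flag switches to the full-sequence column, since which
column a given screening setup thresholds is a local convention.

Gene geometry assumes `contig_start_end_strand` headers with 1-based
inclusive coordinates. Start/stop presence is evaluated on the oriented
nucleotide gene (reverse complement for minus strand) against the
translation-table-11 codon sets {ATG, GTG, TTG} / {TAA, TAG, TGA},
both configurable. Distances to the contig ends are `start − 1` and
`contig length − end`.

Best-hit selection orders by (E-value asc, bitscore desc, subject id
asc); the total order makes family prediction deterministic under ties.
The predicted family's mean length gives the signed difference
`protein length − mean`. Motif search supports literal residues plus an
`X` wildcard only — overlapping matches are all reported, 1-based — to
keep matches auditable without regex semantics.

## Read-classification route

Threshold tokens: a token containing a dot is a relative percent
applied to `100·fraction`; an all-digit token is an absolute read
count; `gut`/`non-gut` select automatic thresholds. Filtering keeps
records meeting the threshold (inclusive), **never renormalizes** the
surviving fractions (pruned species' reads are not reassigned), and
applies at species rank only.

The Shannon index is `H = −Σ pᵢ ln pᵢ` over fractions renormalized to
sum 1. The published gut/non-gut calibration mapping H to a concrete
threshold is not reproduced here; the mapping is a pluggable policy and
the shipped default is a clearly labelled non-canonical linear
stand-in, so automatic kinds are exercisable but real analyses should
inject their own calibration.

Contig assignment counts one vote per primary alignment whose read is
classified at species rank (reads classified below species are lifted
to their species ancestor through the taxdump; reads at genus or above
contribute nothing) and whose species survived filtering. A unique
argmax assigns the species; a tie or an empty tally leaves the contig
unassigned and excluded from binning. Bins are one-per-species and
inherit the species' estimated reads and fraction. Re-estimation
defaults surfaced in configuration: read length 100, minimum 10 reads.

## Binning route

Contigs participate only above 1000 nt (strict inequality). A protein
needs ≥ 1 profile-database hit (the gate) and ≥ 1 filtered-database
hit; it then inherits every organism on its best hit's header, each
with weight 1 (per-organism weighting of multi-organism headers is not
specified anywhere authoritative, so counting is uniform). Organisms
resolve to taxids by exact scientific-name match, then synonyms;
unresolved names are kept as string taxa counted by identity. Bin taxa
are all taxa tied at the maximum frequency over the bin's proteins; a
bin with no taxon-bearing protein gets no annotation. Quantification
counts primary alignments to the bin's contigs over the total
preprocessed reads.

The post-filter discards any bin with more than one taxon at the target
rank, groups survivors by taxon, and sums relative abundances across a
taxon's bins ("merging" them); taxa at other ranks pass through with
their rank labels.

## Evaluation

Presence/absence metrics use the standard formulas with 0 conventions
for empty denominators. Accuracy needs true negatives, hence an
explicit evaluation universe; without one it falls back to the Jaccard
index (documented, and reported as such). The L1 norm renormalizes each
profile to sum 1, treats missing species as 0 and ranges over [0, 2].
Name-keyed matching lowercases, collapses whitespace and strips
`str.`/`substr.` suffixes; taxid matching is preferred when available.
The best-combination analysis takes, per sample, the maximum
(TP/sensitivity/precision/accuracy/F1/Jaccard) or minimum (FP/FN/L1)
score and credits every tied combination.

## Synthetic worlds

The generator plants a community of `n_species` (default 10) species in
a toy taxonomy (root → Bacteria → genus → species, plus strain children
under the first two species to exercise rank lifting), with
`n_contigs_per_species` (3) contigs of 1.4–2.2 kb and
`reads_per_contig` (20) mapped 100 nt reads, giving known relative
abundances; GC bias knobs shift base composition only. Two genes are
planted per contig with recorded start/stop-codon flags; internal stop
codons are excluded by construction. Protein families follow a fixed
blueprint (including a section-qualified family); seek roles partition
the predicted proteins into profile-positive, below-cutoff,
boundary-exact (1e-70), above-cutoff and negative classes. All outputs
are byte-reproducible from (seed, parameters).

`corrupt` adds: false species (round(rate·n_species), each on unmapped
reads and below 1% relative abundance, with the bound recorded),
misclassified reads (reassigned to another true species; abundance
records follow the classifier's view), and spurious profile hits. All
noise events are logged in the manifest.

What the generator does **not** emulate: sequencing error models,
quality scores, assembly artifacts, chimeric contigs, homology between
planted families, or realistic E-value distributions. Passing tests
therefore demonstrate the correctness of the decision logic under its
stated contracts, not classifier or assembler performance on real data.

## Pipeline orchestration

Stages run in a fixed order (four validation stubs for the externally
produced raw data, then import, screening, taxonomy, quantification,
annotation); the read-classification and binning routes are mutually
exclusive within a run. Every stage writes a JSON artifact, so a run
can start at any stored boundary; starting past a missing artifact is
an error naming it. Stage timing is recorded per stage with the total
as their sum, and stages imported from a previous run are marked
"reused". The annotation TSV has a stable column order, leaves
taxonomy columns blank for unassigned proteins, and merging a later run
into an existing file unions columns per protein, preserves the row
count, and fails loudly on conflicting non-blank values.

## Problem sizes and verification

The test suite and the acceptance script run entirely on generated
worlds: 10 species × 3 contigs × 20 reads (600 reads, 60 genes), random
oracle sweeps of 200–1000 cases per property, chosen as the smallest
sizes at which every decision path (ties, boundaries, gates, empty
cases) is exercised. Oracles are independent re-implementations
(exhaustive enumeration for family sets, linear scans for thresholds,
argmax-with-tie checks for votes, direct summation for H and L1).

## Known limitations

- The automatic Shannon-based threshold ships with a placeholder
  mapping; published calibrations must be injected by the caller.
- Accuracy without an explicit universe is the Jaccard fallback.
- The Swiss-Prot parser covers the fields the KB needs (ID, AC, DE,
  OS, DR Pfam, CC similarity, SQ), not the full flat-file feature set.
- Motif patterns are literal + wildcard only.
- Name-string taxa (unresolvable organisms) compare by exact string
  identity, so spelling variants count separately.
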