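# Methods

## The model

A provirus integrates with two identical long terminal repeats (LTRs) and a
short (4–6 bp) target-site duplication. After integration each LTR
accumulates neutral substitutions independently, so the expected pairwise
divergence of the two LTRs of one element after time *t* is 2·R·t, with R
the neutral substitution rate per site per year. `ervatlas` inverts this
clock: the Kimura two-parameter (K2P) distance

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

is computed from the transition (P) and transversion (Q) difference
proportions of the globally aligned LTR pair, and the insertion age is

    T = (D / R) / 2        [years; reported in Myr, 2 decimals]

with R = 2.2e-9 substitutions/site/year by default — the average mammalian
neutral rate, a configuration key (`dating_rate`) that can be set per run.
K2P corrects for multiple hits and distinguishes the two substitution
classes; it assumes equal base frequencies, no rate variation across sites,
no gene conversion between LTRs and no CpG hypermutation. None of these are
corrected for; with a borrowed host-averaged rate the ages are order-of-
magnitude estimates, which is why saturated pairs (log arguments ≤ 0) are
flagged and excluded rather than truncated. The LTR–LTR alignment is global
(end-to-end) because both boundaries are structurally defined; columns
containing a gap or N are removed before counting (complete deletion).

## The simulator and what passing tests show

The synthetic-genome module is the forward process of that model and the
ground truth for every stage. Background DNA is i.i.d. with configurable GC
(default 0.42, a typical mammalian average). Provirus templates are
LTR (default 600 bp; 387 bp for the beta-like lineage, the short-LTR case) +
PBS (18-mer reverse complement of a labeled tRNA 3' end) + three ORF
cassettes (GAG 520 aa, POL 650 aa, ENV 430 aa — sizes chosen so the
tree-candidate length filters GAG > 500 / POL > 600 / ENV > 400 aa pass on
intact elements) + a 15-nt pure-purine PPT + the second LTR copy. The ORF
cassettes carry the full motif set at recorded positions so motif recall is
measurable. Substitutions follow K2P with kappa = 2.0 (a typical
transition:transversion rate ratio; the K2P estimator needs one free ratio
and the simulator states it in its parameters): per-site event counts are
Poisson(R·t) — identical in distribution to summing per-site exponential
waiting times — and events are applied sequentially, so multiple hits and
back-mutations arise naturally; the dating estimator is therefore tested
against a true multiple-hit process, not against its own inverse.

Planting states: *intact* (LTRs aged independently, internal region aged
once), *degraded* (additionally one premature stop mid-ORF in each gene),
*solo* (a single aged LTR between the TSD copies — the LTR–LTR
recombination scar), *nested* (a LINE-1-like cassette, ~3 kb body with
poly-A tail and no terminal repeats, interposed between ENV and the
3'-junction spacer). Two host-side conventions keep truth well defined:

* **TSD copies and single-genome flanks are not aged.** The clock of
  interest is the element's; host divergence enters only in the
  species-pair simulation, where whole descendant genomes are mutated
  independently after the split.
* **Integration sites are unambiguous.** A site where chance context
  matches would create a flanking duplication longer than the planted TSD
  at a nearby boundary shift has no unique integration boundary (a real
  phenomenon); the simulator slides to the nearest unambiguous site so the
  planted TSD is a fact, not a convention.

What the simulator does **not** emulate: indels, rearrangements,
recombination other than the solo-LTR deletion, selection, CpG effects,
insertion-site preference, and assembly artifacts (gaps, N runs beyond
input sanitization). Passing tests therefore demonstrate correctness of the
algorithms under the stated substitution model — not robustness to
real-assembly pathologies such as segmental duplications or tandem repeats,
which a real-genome analysis must assess separately.

## Search kernels

`local_align` is optimal Smith–Waterman (affine gaps) via Biopython's
`PairwiseAligner`; `seeded_search` is the heuristic layer: exact k-mers
(k = 11) for nucleotide search, one fixed spaced seed of weight 21 over 28
columns (third codon positions of the first seven codons wildcarded) for
the discontiguous-megablast dialect, and BLOSUM62 neighborhood words
(k = 3, word-pair score ≥ 13) for protein-vs-six-frame-translation search.
Seeds are chained per diagonal (two-hit rule), extended ungapped with
X-drop, merged on a diagonal when closer than 30 bp, and joined across
nearby diagonals over short gaps. Hits short enough (≤ 3000 query units)
are re-scored with `local_align`, so their reported score and identity are
exactly those of the optimal local alignment of the reported ranges; very
long hits (orthology flanks) keep their chained statistics. E-values use
E = K·m·n·exp(-λ·S) with shipped (K, λ) approximations per scoring scheme
(BLOSUM62 11/1; nucleotide +2/-3, gaps 5/2). The behavioural contracts
throughout are identity/coverage/E *thresholds*, not E-value agreement with
any particular external BLAST build. N is a wildcard that never matches
anything, including N, and never counts as an identity.

Identity is counted over aligned non-gap columns; coverage over the full
query length — the conventions the published thresholds are written
against.

## Structural calling

Paired LTRs are direct repeats found by seeded self-comparison constrained
to the geometry window (length 100–7000 bp, start separation
1000–15000 bp, similarity ≥ 0.85). Extension endpoints maximize the
ungapped score, i.e. boundaries sit at maximal exact-match ends; because
chance context matches can over- or under-shoot the integration site by a
few bases, boundaries are then refined by searching a ±(4–7) bp shift
window for an exact flanking 4–6 bp duplication, preferring the longest
duplication and then the smallest move. Overlapping candidate pairs are
resolved by (similarity, LTR length, leftmost). The reported similarity is
the Smith–Waterman identity of the two reported LTR sequences.

PBS: the reverse complement of each library tRNA 3' 18-mer is sought within
20 bp downstream of the 5' LTR with ≤ 2 mismatches (fewest mismatches, then
closest wins). The shipped tRNA library is synthetic (labeled stand-ins
including decoys); real tRNA sets are user-suppliable. PPT: the longest
window with ≥ 90% purines, length ≥ 10, starting and ending on a purine and
ending within 20 bp of the 3' LTR (ties go to the tract closest to the
LTR). TSD, PBS and PPT are annotations; full-length status requires only
paired LTRs plus an internal region.

## Lineages, consensus, solo LTRs

Copies are chained hits with > 4 kb aligned length at ≥ 80% identity.
Clustering is single-linkage at > 90% pairwise global identity (the
pairwise rule gates clustering; identity to the consensus is also computed
and reported). Identity for these large nucleotide comparisons is
edit-distance based (edlib), 1 − edits/alignment-length. The consensus is a
star alignment to the longest member with per-column majority vote, ties to
the earliest copy, columns gapped in more than half the rows dropped;
characters inserted relative to the reference are not represented as
consensus columns. On indel-free simulated copies the star MSA is exact;
for heavily indel-divergent real families an external MSA tool would be
preferable. Solo LTRs follow the three-part rule (qualifying LTR hit; no
partner forming a valid pair, i.e. same strand with start distance in the
pairing window; no internal-region remnant within 15,000 bp on either
side — the same 15 kb figure as the maximal pairing distance). Names follow
`ERV-<Genus>.<letter><n>-<host>`: letters rank lineages within a genus by
descending copy number (ties by leftmost copy), copies numbered in genomic
order, `SoloLTR-` prefix for solo lineages, letters extending a…z, aa, ab…
beyond 26. Genus labels come from probe provenance (which probe family
seeded the lineage); phylogenetic inference is out of scope.

## Motifs and the envelope call

ORFs are called in all six frames, running from the first AUG of a
stop-delimited segment (configurable) through the stop, strictly longer
than 180 nt counting the stop codon. Motif patterns are degenerate regular
expressions; all (including overlapping) occurrences are reported, matches
never span a stop, and CX₆C is suppressed at anchors where CX₆CC matches.
The envelope call is gamma-type iff CX₆CC is present, beta-type iff CX₆C
without CX₆CC, otherwise indeterminate; immunosuppressive-domain scoring is
optional (no canonical ISD consensus is bundled — a user-supplied reference
peptide can be scored alongside), so the default call rests on the cysteine
motif alone.

## Orthology

For each candidate pair, the insertion regions and up to 30,000 bp of flank
per side (clipped at contig ends; achieved lengths recorded) are compared
with the discontiguous dialect. Alignments shorter than 500 bp or weaker
than E = 1e-5 are discarded; the verdict is *ortholog* iff insertion
identity ≥ 85% and the union of retained flank alignments covers ≥ 50% of
the achieved flank length. Coverage is computed jointly over both flanks on
genome A's coordinates (A is the query by convention — one defensible
reading of a coverage rule that could also be applied per flank).
`survey_orthologs` keeps the best partner per element (highest flank
coverage, then insertion identity) after a cheap insertion-identity
prefilter.

## Numerical and reporting choices

All internal coordinates are 0-based half-open; emitted GFF3/TSV/BED use
their standard 1-based/0-based conventions. Ages are reported to 2 decimals
in Myr. All randomness descends from one master seed through labeled
streams; a rerun with the same configuration and seed is byte-identical
(verified as a contract). Desk-scale problem sizes — a ~620 kb demo genome
with 22 planted elements for structure/solo tests, 70 kb-per-contig
species pairs with 5 shared + 4 private elements for orthology, 50
replicates per age for clock recovery — are chosen so the full suite and
the acceptance script each complete in minutes on one CPU while leaving
every rate estimable from double-digit counts.

## Known limitations

No indel handling in the dating alignment beyond gap-column deletion; no
gene-conversion detection (which biases paired-LTR ages downward in real
data); solo-LTR classification assumes elements are not nested within
15 kb of unrelated copies; the E-value constants are approximations; the
screen's sensitivity guarantee is empirical (tested at 85% identity), not
exhaustive; and none of the bundled thresholds have been re-validated
against real pangolin-scale assemblies, which are outside desk scale.
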