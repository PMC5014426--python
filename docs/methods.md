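# Methods

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted at the I/O boundary. Sequences are uppercase DNA over
`{A,C,G,T,N}`; `U` maps to `T` on input. `N` bases never match a nickase
motif, never count as TSD matches, and are excluded from mismatch,
insertion and deletion counts, so assembly gaps cannot inflate variant
densities.

## Structural detectors

Every detector is a bounded exhaustive search, so each has a natural
brute-force oracle that the test suite compares against on short inputs.

* **TIR** — longest terminal inverted repeat with at most `max_mismatch`
  mismatches; a flag records whether the termini conform to the canonical
  `TG...CA` recognised by integrases/transposases.
* **TSD** — longest word that ends the upstream flank (allowing a shift of
  up to `offset_tol` bases away from the junction; default 1, motivated by
  naturally occurring one-base offsets such as `ATTTTT`/`ATTTT`) and
  begins the downstream flank. Ties break to longer length, then smaller
  offset. Bounds: `min_len` 4, `max_len` 12, exact match by default.
* **LTR pair** — local affine alignment of the first versus last
  `max_ltr` bp (match +2 / mismatch −3 / open −6 / extend −2); reported
  when the aligned spans are ≥ `min_ltr` bp at identity ≥ 0.90, equal in
  length within 2 bp, ordered and non-overlapping. The aligned spans are
  the LTR boundaries — the maximal extension at the identity floor.
* **PBS** — minus-strand reverse transcription is primed by a tRNA
  annealed just downstream of the 5′ LTR, so the PBS is the reverse
  complement of a tRNA 3′ terminus. The detector scans windows starting
  within `search_window` (20) bp of the LTR against every supplied tRNA
  end; best = longest, then closest. Watson–Crick pairing by default; a
  `allow_gu` flag admits G:U-equivalent pairs (off, since no published
  pairing rule covers the imperfect "patches" seen in real elements).
* **PPT** — longest A/G run ending within `search_window` bp of the 3′
  LTR, minimum 8 by default (the worked case is a 13-purine run ending
  flush at the LTR).
* **ORF layout** — maximal stop-to-stop reading frames on the forward
  strand (elements are oriented by LTR/TIR polarity first), selected into
  a non-overlapping chain of maximal total coding length by weighted
  interval scheduling; spacer stop counts are read in the upstream ORF's
  frame. Stop-to-stop (rather than ATG-anchored) ORFs are used because
  decayed elements often lose initiator codons before losing coding
  signal.
* **RNAP3 association** — with a ~10-nt pre-tRNA leader and a 5-bp TSD,
  start-targeted integration places element sequence 15–17 bp upstream of
  the mature tRNA start; the window is configurable. Precedence:
  start-targeted > internal > adjacent (≤100 bp) > unassociated. The
  classifier is strand-symmetric by construction (mirror coordinates give
  mirror calls).
* **Solo-LTR clustering** — single-linkage at edit-distance identity
  ≥ 0.80 over the longer sequence; per-family consensus by majority rule
  over a star alignment onto the family medoid. Star consensus (not a full
  MSA) is adequate at intra-family divergences of a few percent.
* **Census** — `blastn` hits of each family reference (dust off, no soft
  masking, identity ≥ 80%), merged per family when overlapping, then
  classified: full-length at ≥ 0.92 of the reference length (a fraction,
  not a fixed bp, so one rule serves families of very different sizes),
  partial above 1 kb, fragment between 30 bp and 1 kb; shorter hits are
  noise and discarded.

## iLoci and flanks

Overlapping *and abutting* features merge into one feature iLocus (the
member list is preserved); gaps become intergenic iLoci; the partition
tiles each chromosome exactly, and input feature order never changes the
output. TE features participate in the partition. The flank resolver
returns the nearest `k` (default 2) iLoci per side that do not overlap the
TE interval; a shortfall near chromosome ends and the use of a
neighbouring TE locus as a flank are both flagged rather than forbidden.

## Alignment and variant densities

`align_pair` is a glocal affine-gap alignment (match +1, mismatch −2, gap
open −6, gap extend −1, a length-L gap costing `open + L·extend`):
both sequences are fully consumed but terminal gaps are free on both
sides, so a locus embedded in a longer partner aligns without overhang
penalty, and terminal overhangs are reported as unaligned rather than as
indels. Alignments are computed in a canonical orientation and mirrored,
making `align_pair(a, b)` and `align_pair(b, a)` exact transposes (I and
D swap). Above a 50-kb cap, unique shared 21-mers are chained (longest
colinear chain) and the gaps between anchors aligned exactly.

Reciprocal mapping prescreens candidate partners by shared 15-mers (top 3
candidates, ≥ max(3, 5%) shared), aligns each candidate pair once, and
emits a reciprocal pair when each locus is the other's best valid hit —
valid meaning identity ≥ 0.80 and coverage ≥ 0.80 *on the better-covered
side*. The coverage rule is deliberate: a strain-specific TE insertion
splits an intergenic locus into fragments whose counterpart is one intact
locus in the other strain; requiring both-side coverage would orphan
exactly the loci the flanking analysis needs. Loci without a reciprocal
partner but with a valid best hit are additionally paired non-reciprocally
(flagged) so their densities remain available; they still count as
orphans, and only reciprocal pairs anchor allelism calls. Best-hit ties
break by longer alignment, then lexicographic id, making the mapping
deterministic and order-invariant.

Variant densities are counts per kb of the locus on the side being
profiled (strain-A length for A-keyed densities, strain-B length for
B-keyed ones); insertions are bases present in A and absent in B, and
vice versa for deletions — bases, not events, following the "nucleotides
present in one and not the other" convention; event counts are available
from the alignment operations.

## Allelism, naive sites and the group test

A TE is **allelic** when the partner-strain region delimited by the
reciprocal partners of its nearest flanking iLoci contains a same-family
element of any class (a solo LTR at a full-length element's position
still counts — inter-LTR recombination changes the class, not the
locus). Flanks without reciprocal partners resolve to non-allelic; if
both sides are unresolved a warning is attached.

The **naive site** excises the element, the offset filler and one TSD
copy, keeping `window` (default 300) bp per flank; by construction this
restores the pre-insertion locus exactly on simulated data. The **empty
site** search aligns the naive junction as an infix of each partner
chromosome (edit-distance semiglobal via edlib); "found" requires the
whole naive sequence contiguous at identity ≥ 0.90, which an
element-bearing allele cannot satisfy because the element interrupts the
junction.

Flank records average M, I and D (unweighted) over the 1–4 flank iLoci
with available densities. Allelic elements enter the pooled record set
once (from the strain-A side); non-allelic elements enter from whichever
strain carries them. The group comparison is a two-sided label-permutation
test on the difference of group means with the (count+1)/(n_perm+1)
convention (default 10,000 permutations, seeded; a Mann–Whitney rank-sum
p is reported alongside as a cross-check). The three metrics are tested
separately. Families are pooled for the headline test; per-family mode is
available. Verdicts: H1 is *excluded* when any naive site is found empty;
H2 is *supported* when non-allelic mean M exceeds allelic mean M at
p < 0.05, otherwise the data are labelled H3-consistent.

## The synthetic study system

The generator emulates a haploid parent/progeny pair from a cross:

* **Ancestor** — uniform random sequence at GC 0.49 with non-overlapping
  genes (density 0.25/kb, lengths ~N(1300, 300) clipped to 0.4–3 kb) and
  tDNAs (0.025/kb, 75 bp), on 2 chromosomes of 150 kb. These sizes are
  the package's study scale — large enough for ~190 iLoci and 20 planted
  elements per run while keeping a 20-seed end-to-end experiment cheap;
  rates and densities follow genome-scale observations in food-yeast
  strain pairs (intergenic ~2.4 mismatches/kb, genic ~1.2/kb).
* **Strain B divergence** — substitutions and indels (geometric lengths,
  mean 2 bp, capped at 50) applied to strain B relative to the ancestor,
  so configured rates equal expected A-vs-B densities directly; genic and
  intergenic rates differ. **Parent-2 blocks** (alternating exponential
  renewal, mean 20 kb, fraction 0.30, stationary start; at least one
  block is guaranteed when the fraction is positive) multiply both rates
  by 3.
* **Elements** — templates specify the full anatomy; the default
  full-length family is 3 kb (scaled to the chromosomes), and a preset
  reproduces the published 5,973-bp element exactly (244-bp LTRs,
  TGTAAG/CTTACA termini, 14-nt PBS two bases downstream of the 5′ LTR,
  13-purine PPT, 324-bp GAG–POL spacer with four stops). Copies of one
  family are identical at planting (recent insertions); element bodies
  are excluded from the mutation process, so planted anatomy stays exact
  — detector robustness to intra-element divergence is tested directly
  instead. Element interiors are built so that no accidental ORF, PBS
  extension or TIR extension can arise: pads carry stop codons in all
  three frames, and junction bases are chosen to be non-pairing.
* **Placement** — ancestral (allelic) elements are planted before the
  strain split and confined to parent-1 (non-block) sequence: under the
  chromosomal-inheritance scenario, elements shared by both strains ride
  the less divergent parental background, which is what makes allelic
  flank densities sit near the genome-wide base rate. Lineage-B elements
  are confined to parent-2 blocks (H2 geometry) or placed uniformly (H3
  geometry); an RNAP3-targeted rule plants 15–17 bp upstream of a tDNA
  start. Target sites are re-drawn until the planted TSD round-trips
  through the detector, so truth labels are exact. Insertion positions
  are tracked: features, block intervals and previously planted elements
  all shift consistently as insertions accumulate.
* **Determinism** — one `numpy.random.default_rng(seed)` drives
  everything; identical config + seed give byte-identical FASTA, GFF3 and
  truth JSON.

What the generator does **not** emulate: sequencing or assembly error,
rearrangements beyond optional explicit events, element decay
(substitution within element bodies), segregation of more than two
parental haplotypes, and tRNA gene sequence realism. Passing tests
therefore demonstrate that the pipeline recovers inheritance structure
from assembly-level divergence patterns, not that it is robust to
assembly artefacts.

## The virtual digest

The Nt.BspQI motif (`GCTCTTC`) is scanned on both strands (a nickase cuts
one strand, so strand is reported per site; overlapping occurrences are
all kept). Tandem-period detection folds the strand-merged inter-site
interval sequence at every candidate period (sum of k consecutive
intervals, smallest k first), accepting a period when all intervals match
their k-shifted counterparts within 5% and at least 3 unit repeats are
covered; a minimum inter-site distance parameter (default 0) can collapse
near-adjacent opposite-strand nicks, which appear as a single label on a
physical map.

## Problem sizes used by the tests

Detector–oracle suites run 150–1,000 random draws per detector on inputs
up to 2 kb; alignment is checked against an independent Gotoh dynamic
program on pairs up to 300 bp; the end-to-end inheritance experiment runs
20 seeds of the default 2 × 150 kb conditions with 2,000 permutations per
test, asserting a non-allelic/allelic mismatch-density ratio ≥ 2 with
p < 0.05 in at least 18 of 20 seeds, genic < intergenic baseline density
in at least 19, and ≥ 95% correct allelism labels.

## Known limitations

* The census depends on an external `blastn` binary; a missing executable
  raises a clear error rather than falling back to a slower search.
* Glocal end-gap freedom can trim a terminal mismatch into unaligned
  overhang, so mismatches in the outermost one or two bases of a locus
  may go uncounted.
* Empty-site identity uses edit distance over the naive sequence, which
  slightly undercounts identity for indel-rich sites.
* Solo-LTR consensus ignores insertions relative to the medoid; at high
  intra-family divergence a profile-based consensus would be better.
* The permutation test treats per-element flank means as exchangeable
  units; elements sharing a flank iLocus are not fully independent, which
  is mildly anticonservative at very high element density.
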