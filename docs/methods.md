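# Methods

This note records the models, rules and numerical choices behind
`famscan`, and what the synthetic-data tests do and do not demonstrate.

## Domain grammar

WRKY domain calling is a two-part grammar match rather than a profile-HMM
search. This keeps the operation fully in-repo, deterministic, and exactly
testable against planted ground truth; the cost is that there is no
statistical score — a sequence either satisfies the grammar or it does not.

* **Heptapeptide rule.** A 7-mer hits iff residues 1/4/5 are W/Y/G and the
  Hamming distance to WRKYGQK is ≤ 2 (`max_mismatch`, configurable). This
  is the smallest rule that admits every variant heptapeptide observed in
  surveyed *B. napus* domains (WRKYGKK, WRKYGRK, WKKYGQK, WKKYGQR,
  WKNYGQK, WMKYGQK, WRKYGHK) while excluding anchor-broken 7-mers. `X`
  never matches any position.
* **Zinc-finger rule.** C2H2 = `C X{4,5} C X{22,23} H X H`;
  C2–HC = `C X{7} C X{23} H X C`. Spacer alternatives are tried smallest
  first; when both finger types match at the same start, C2H2 wins — it is
  the majority type (groups I and II) — and the preference is documented
  here rather than hidden.
* **Pairing.** Greedy left-to-right: each heptapeptide takes the nearest
  downstream finger starting within the linker window (default 50 aa after
  the heptapeptide, bounding the domain near its canonical ~60 aa size;
  `max_span` 80 aa caps the total). A finger is never shared between
  domains. An unpaired heptapeptide or finger yields no domain, which is
  what rejects the decoy classes.
* **Classification.** ≥2 domains → I; one C2H2 → II; one C2–HC → III;
  none → unclassified. Genes with more than two domains stay in group I
  (conservative generalization of the two-domain rule); the summary
  records the per-gene maximum so the `two_domain = domains − genes`
  identity is only asserted when it is valid.

## Alignment and subgroups

Percent identity, not alignment score, drives every downstream rule, so
the aligner is a plain Needleman–Wunsch with +1/−1 match/mismatch and
linear −2 gaps (configurable; substitution matrices are an extension
point). The traceback preference (diagonal > gap-in-first > gap-in-second)
is fixed so identity is deterministic among co-optimal alignments; tests
check the score against an independent aligner and the reported alignment
against its own reported score.

Subgroups IIa–e are assigned by nearest reference domain under p-distance
(1 − identity/100). The support threshold defaults to 0.7: genes whose
nearest reference is farther are left unclassified, the analogue of family
members dropped from a phylogeny for lack of support. The bundled
reference set is **synthetic** — one domain per label generated from the
package's own per-subgroup templates — because the assignment *logic*, not
a curated reference collection, is what the package tests; users supply
their own labeled FASTA (`>id|IIa`) for real analyses. Neighbor joining is
delegated to scikit-bio; negative branch-length estimates are clamped to
zero and counted on the tree object.

## Duplication rules

* Duplicate: global-alignment identity strictly greater than 85% (protein
  sequences; the threshold is the conventional cutoff for calling
  duplicates in family surveys and is configurable).
* Tandem: a duplicate pair on one chromosome with no other family member
  between the genes and an inter-gene gap ≤ 100 kb. Both knobs are
  configurable; the definition makes "tandem" mean literal neighbors.
* Ortholog: reciprocal best hit across sub-genomes (chromosome-name
  prefix A/C by default, mapping configurable), requiring identity above
  the duplicate threshold; ties break by gene-id order. RBH is one-to-one
  by construction; many-to-one orthology (a real feature of polyploid
  genomes) is out of scope for the pair list.
* Segmental block: duplicate pairs bucketed by chromosome pair, sorted by
  first-chromosome position, chained greedily while inter-anchor gaps on
  both chromosomes stay ≤ 2 Mb and second-chromosome positions stay
  strictly monotonic (either direction, so inverted blocks chain); chains
  of ≥ 3 pairs survive. Greedy sweep instead of DP chaining: blocks in a
  gene-family survey contain a handful of anchors, and the sweep is
  deterministic and easy to check by hand.

## Coordinates and QTL overlap

All coordinates are 1-based inclusive internally (GFF3 convention); BED
I/O converts at the file boundary. A gene resides in a QTL when spans
share ≥ 1 bp on the same chromosome; strict containment is an option
(`--contained`). Strand is ignored — QTL intervals are strandless. Span
strings in QTL tables tolerate hyphen, en/em-dash and tilde separators.
Intersection runs on interval trees; the test oracle is an independent
nested-loop scan.

## qPCR model

Livak 2^−ΔΔCt with amplification efficiency fixed at 2.0 (perfect
doubling; efficiency correction is an extension hook). Technical
replicates are averaged in Cq space within each biological replicate;
ΔΔCt and folds are computed per biological replicate and summarized as
mean ± SD in fold space. This pooling order is standard Livak practice.
The method is invariant to any constant plate offset, which the suite
asserts as a property. Thresholds: fold ≥ 2 up, ≤ 0.5 down, ≥ 20 highly
up, applied exactly at the boundary; a gene highly up-regulated under
every profiled condition is multi-stress responsive. Tandem-pair profile
similarity is Pearson r on log2 folds concatenated across conditions,
concordant at r ≥ 0.8 (no standard metric exists for "similar profiles";
the threshold is configurable and raw r is always reported).

## Synthetic-data generator

The generator is the package's ground-truth instrument, so its design
follows one principle: planted labels must satisfy the detectors'
definitions by construction.

* **Templates.** Each group/subgroup label has a fixed canonical domain:
  heptapeptide + 10-aa linker + minimal-spacing finger, with label-keyed
  spacers so templates of different subgroups are mutually distant
  (p ≈ 0.6–0.7) while instances of one label start identical. Spacers and
  flanks draw only from residues that cannot complete a grammar element
  (no W, C or H), so decoys and flanks never create spurious hits, and
  grammar-critical residues are excluded from every mutation mask.
* **Genome layout.** Defaults: 3 chromosomes of 40 Mb per sub-genome;
  25 primary A-genes (I:6, IIa:2, IIb:3, IIc:4, IId:3, IIe:3, III:4);
  regular intergenic spacing uniform in 2.2–3.2 Mb, giving the ~2.7 Mb
  mean spacing typical of a WRKY complement on a *Brassica*-sized
  chromosome. The C sub-genome is built by copying a fraction (default
  0.8) of A-genes at 5% divergence onto the matching C chromosome —
  mirroring the allopolyploid A/C structure — so planted ortholog pairs
  sit near 95% identity, safely above the 85% duplicate threshold, while
  unrelated genes (identical domains, independent random flanks) fall far
  below it.
* **Planted structures.** Tandem clusters (default two clusters of 2 at
  identity targets 95%/92%) are consecutive group-III genes with 5–30 kb
  internal gaps — well under the 100 kb tandem rule; manifest identity is
  recomputed from the realized sequences. Segmental blocks (default one
  3-pair block within the A sub-genome) use 0.2–0.6 Mb internal gaps,
  below the 2 Mb chaining gap, while the regular spacing floor (2.2 Mb)
  keeps scattered ortholog anchors from chaining — the detector and the
  generator agree on what a block is. A cross-sub-genome block, if
  configured, also contributes its pairs to the manifest ortholog list,
  since reciprocal-best-hit detection necessarily reports them.
* **Variants and noise.** A fraction (default 0.15) of planted domains
  receive a variant heptapeptide, drawn with WRKYGKK weighted at 0.6
  (Q→K substitutions dominate observed divergence). Optional spacer
  mutation (default 0) perturbs non-grammar residues per gene for
  subgroup-recovery experiments. Cq tables place the reference gene at
  Cq 20 and the control target at Cq 25, shift the treated target by the
  planted log2 fold, and add per-technical-replicate Gaussian noise
  (default SD 0.15 Cq; 3×3 replication). Six planted expression genes
  include three at peak fold ≈ 24 under all three stresses (the
  multi-stress truth), one condition-specific up, one down, one flat.
* **What passing does not show.** The generator plants exact grammar
  instances, substitution-only divergence (no indels, no gene loss), and
  clean replicate structure. Perfect recovery therefore demonstrates the
  detectors implement their definitions, not that the grammar thresholds
  or the 85% rule are optimal for real proteomes with degenerate domains,
  fragmented gene models or assembly-induced indels; unclassified-gene
  handling on real data should be inspected, not assumed.

## Degenerate inputs and determinism

Empty sequences give empty hit lists (alignment of an empty sequence is an
error); absent stages skip cleanly in the pipeline; overlapping QTLs are
never merged; repeated QTL names are disambiguated with `#k` suffixes.
Identical seed + config reproduces every output file byte for byte; the
scan → classify → detect pipeline itself is fully deterministic. Summary
percentages are formatted round-half-up to two decimals, and the summary
re-asserts its internal arithmetic (group sums, density = count/Mb,
anchored + unanchored = total, percentage recomputation) at emit time.

## Problem sizes

The default synthetic survey (61 proteins, ~65 domains, ~25 high-identity
pairs) and the bundled tables (31 QTL intervals, 57 evidence records) are
sized so the whole suite and the acceptance script each complete in well
under a minute on one CPU; all detectors are exercised at full coverage at
these sizes, and every detector scales linearly or quadratically in ways
the oracle-equivalence tests (≤ 50-gene instances) already cover.
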