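# Methods

This note documents the models, rules and numerical choices behind
`erfscan`, in the spirit of the methods documentation of established
scientific Python packages: what each stage assumes, which parameters
matter, and what the synthetic fixtures can and cannot demonstrate.

## Family and subfamily classification

The AP2/ERF superfamily is defined by the ~60-residue AP2 DNA-binding
domain. Classification is purely architectural and runs in a fixed decision
order over a protein's domain hits:

1. no AP2 domain → *rejected* (not a superfamily member);
2. curated soloist id (or ≥ 50 % global identity to the soloist reference,
   via `assign_soloist_by_reference`) → *soloist*;
3. AP2 + B3 → *RAV*;
4. ≥ 2 AP2 domains, or membership in a curated override set → *AP2*;
5. otherwise (single AP2 domain) → *ERF* family.

Domain hits are inputs (the shape of an hmmscan domain table); no profile
HMM search is performed here. The override set stands in for the
phylogeny-based rescue of single-domain AP2-family members; an optional
helper (`derive_ap2_overrides`) proposes overrides for genes whose three
nearest tree leaves are majority-AP2.

BLAST-style candidate retention uses strict inequalities: bit score > 200
and E-value < 0.001. A hit at exactly 200 bits is dropped.

### Diagnostic residues

The ERF-vs-DREB split reads two residues through a global alignment onto a
reference AP2-domain frame: Ala-33 and Asp-43 call ERF; Val-21 and Glu-26
call DREB. Published numbering of these positions varies with the alignment
frame (the classical literature uses 14/19), so the positions and residues
are configurable (`DiagnosticResidues`; `config.DIAGNOSTICS_CLASSICAL`
provides the 14/19 frame). Calls require both residues of a rule to match;
one-of-each or gapped positions return `unresolved` rather than a silent
guess, and alignments covering < 50 % of the reference frame raise an error.

### Alignments

Every pairwise alignment in the package (similarity, diagnostics, distance
matrices) is a global Needleman–Wunsch alignment under BLOSUM62 with gap
open 10 and gap extend 0.5 — standard protein defaults. Percent similarity
is 100 × identities / alignment length (gap columns included); the distance
used for phylogeny is 1 − identical/aligned-columns (gap columns excluded).
Because co-optimal alignments exist, sequence pairs are ordered canonically
before aligning so both measures are exactly symmetric.

## Motif scanning

Patterns are ordered residue-sets with repeat ranges; `X` means any of the
20 standard amino acids, and a literal `X` in input is rejected. EAR
matches (`[LF]DLN[LP]`) are reported non-overlapping leftmost-first; the
zinc-finger pattern (`C x2 C x4 C x2..4 C`) reports one match per start
position, shortest Cys stretch first. The published motif tables are
consensus strings, so a Hamming-distance scanner (`scan_consensus`)
replaces de-novo motif discovery; MEME ambiguity letters (Z, J) in printed
consensus strings are compared literally.

## Gene structure

Intron count is #exons − 1 of the single annotated isoform,
strand-independent; when a GFF3 gene carries several mRNAs the isoform with
the longest summed exon span is used (the jujube annotation has one model
per locus, so this is a tie-break that rarely fires). Coordinates are
1-based inclusive end-to-end, so `gene_length_bp = end − start + 1` matches
the published per-gene lengths directly. The packaged roster was
transcribed from the published summary table and is validated in the test
suite against its printed aggregate facts (family counts 5/17/57/39/1,
length range 402–6536 bp, residue range 133–889, intron histograms).

## Duplication typing

Homolog pairing ignores pairs below 50 % similarity; cross-genome
co-orthologs additionally require reciprocal best hits. This replaces
Markov-cluster-based ortholog grouping with an explicit threshold rule —
the downstream duplication logic only consumes pair lists, so the simpler
pairing is fully transparent and testable.

A qualifying pair (similarity strictly > 40 %) is **tandem** when both
genes share a seq region with at most 4 annotated loci strictly between
them, and **segmental** otherwise. Consequences of this reading: similarity
exactly 40.0 is not a duplication; 4 intervening loci is tandem; 5 is
segmental (the published wording leaves spacing 5 unassigned — we assign it
to segmental as the complement of the tandem rule); different regions are
never tandem. The intervening-locus count is over *all* annotated loci,
which is why `GeneOrderMap` must cover the whole annotation, not only
superfamily members.

## Neighbor joining

Standard Q-criterion NJ with deterministic tie-breaking (smallest index
pair), terminating in a trifurcating root over the last three nodes.
Negative branch lengths — possible on non-additive inputs — are clamped to
zero and the summed deficit recorded on the root
(`negative_length_deficit`). On additive matrices the algorithm provably
recovers the generating tree; the tests verify this against random additive
trees (n ≤ 12), a least-squares quartet-topology oracle, and the reference
implementation in scikit-bio. Distances are pairwise (not MSA-based), which
removes the external aligner dependency while keeping the NJ stage exact
and testable; for closely related domain sequences the pairwise and
MSA-column distances are close, but they are not identical in general.

## Expression

* RPKM = count / (kb of exon model × millions of mapped reads).
* The expression gate takes tissue means over replicates; mean RPKM
  strictly below 1.0 is "no expression" (exactly 1.0 is expressed). Fruit
  expression uses the mean RPKM per ripening stage.
* Row z-scores use the population standard deviation (configurable
  convention; constant rows raise an error naming the gene).
* Clustering: average linkage over all inter-cluster pairs with Pearson
  distance d = 1 − r. Dendrogram nodes are reported as similarities
  1 − merge-distance, i.e. on the correlation scale in [−1, 1] — matching
  the convention in which published clade-separation values like −0.4492
  are correlations. Clades are connected components after removing merges
  with similarity ≤ the cut.
* qPCR relative expression is 2^−(Cq_target − Cq_reference), averaged over
  the three biological replicates downstream.
* The ethylene response test is a two-sided **Welch** t-test (the unequal-
  variance form is the safer default when only "t-test" is specified) at
  α = 0.05, with ≥ 2 replicates per group required. Degenerate zero-variance
  groups are defined to give p = 1 on equal means and p = 0 otherwise.

## Ripening direction rule

"Up/downregulated with ripening" needs a numeric operationalization. Over
stage means (YF, WM, BR, HR, FR) with fold f = 2:

* up: mean(HR, FR) ≥ f × mean(YF, WM) and FR > WM;
* down: mean(YF, WM) ≥ f × mean(HR, FR) and FR < WM;
* otherwise none.

The endpoint condition (FR vs WM, ripening onset) keeps transient
mid-ripening peaks from being called directional; the rule is symmetric,
scale-invariant, and configurable (`fold`, stage groupings). Verdicts then
follow the screen's invariants: activator = up/up; repressor = down/down
with an EAR motif; everything else is reported as `other` with the
combination recorded (down/down genes without EAR are flagged, not
dropped).

## Synthetic fixtures

All fixtures are generated by seeded `numpy` generators; identical
(name, seed, parameters) yield byte-identical outputs, and the seed is
recorded in every output header. Noise parameters default to 0 — the
deterministic mode used for acceptance runs; under declared noise, recovery
rates are reported by the tests, never asserted.

* **Proteome** — backgrounds are drawn from an alphabet without Cys and Asp
  so random background cannot form EAR or zinc-finger motifs by accident;
  domain blocks are copied from bundled *synthetic* reference blocks
  (composed for this package, not database sequences) with seeded point
  mutations that avoid the diagnostic positions, and every output is
  re-verified with the scanners before release.
* **F-dup** — 18 paralog pairs with planted spacings (0–4 intervening loci
  for the five tandem pairs, including the boundary; 5+ or cross-region for
  the 13 segmental pairs) and similarities planted above 40 % via
  controlled mutation counts on 120-residue proteins.
* **F-expr119** — the packaged 119-gene roster crossed with three tissues;
  85 genes have at least one tissue mean ≥ 1.0 (71.4 %), exactly two
  (ZjDREB12, ZjDREB17) are fruit-specific, and expressed genes follow four
  clade profiles whose members are exact scalings of each other, so
  within-clade correlation is exactly 1 and a similarity cut of 0.99
  separates the planted clades in noise-free mode.
* **F-ripen** — 44 genes with planted trajectories (15 up, 23 down, 6
  flat), ethylene Cq tables built from a 4-fold shift with fixed replicate
  offsets (±0.05 Cq) so the Welch test yields exactly 6 up and 16 down, and
  EAR flags placed so the screen returns exactly 2 activators (ZjERF54,
  ZjDREB39) and 2 repressors (ZjERF25, ZjERF36).

Because these counts are planted by construction, fixture runs demonstrate
that the rule engines implement their stated decision rules exactly — they
say nothing about how the rules would perform on real transcriptomes, where
replicate noise, partial domains and ambiguous architectures occur. That
caveat is the reason the generators also expose noise parameters and the
tests keep rule-boundary cases (bit score 200, similarity 40.0, spacing 4
vs 5, RPKM 0.99 vs 1.0) explicit.

## Problem sizes

Default test and acceptance runs use the bundled 119-gene roster, 15-protein
synthetic proteomes, 18 duplication pairs and 44 ripening genes — the sizes
of the study's own tables — and complete in a few seconds on one CPU.

## Known limitations

* No profile-HMM search, MSA construction, bootstrap support, read mapping
  or counting: domain hits and count/RPKM matrices are inputs.
* The duplication rule depends on annotation completeness through the
  intervening-locus count; a sparser gene-order map inflates tandem calls.
* Published clade similarity values from the source transcriptome cannot be
  reproduced without that transcriptome; they anchor interpretation only.
* Graphics (karyotype, heatmap, tree figures) are out of scope.
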