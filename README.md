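# erfscan

Genome-wide identification and screening toolkit for the plant **AP2/ERF
transcription-factor superfamily**, built around the analysis of the Chinese
jujube (*Ziziphus jujuba* Mill.) superfamily and its role in ethylene-related
fruit ripening. It is aimed at plant genomicists who have a proteome, gene
models, domain-hit tables and expression matrices in hand and want a tested,
reproducible implementation of the standard family-survey workflow.

## What it computes

Given domain hits (hmmscan-style tables are inputs, never produced here), the
pipeline applies the superfamily's architecture rules:

* **Family calls** — AP2 + B3 domain → *RAV*; ≥ 2 AP2 domains (or a curated
  phylogeny-based override) → *AP2*; a curated/soloist-reference match →
  *soloist*; a single AP2 domain → *ERF* family.
* **Subfamily calls** — the ERF family splits into *ERF* vs *DREB* by
  diagnostic residues read through a global alignment onto a reference AP2
  domain frame (Ala-33/Asp-43 for ERF, Val-21/Glu-26 for DREB; the classical
  14/19 frame is available in `erfscan.config`).
* **Motif scans** — the EAR repression core `(L/F)DLN(L/P)` and the putative
  zinc finger `C-x2-C-x4-C-x2..4-C`, plus Hamming-budget scanning of printed
  MEME consensus strings.
* **Gene structure** — intron counts (#exons − 1) and per-family summaries
  of gene length, residue count and intron histograms.
* **Duplication typing** — pairs above 40 % global-alignment similarity are
  *tandem* when separated by ≤ 4 annotated loci on one linkage group, else
  *segmental*; pairing uses a 50 % similarity floor plus reciprocal best hit.
* **Phylogeny** — neighbor joining over pairwise alignment distances
  (d = 1 − fraction identical, gaps excluded), newick output, and a
  k-nearest-leaf helper for rescuing single-domain AP2 members.
* **Expression** — RPKM, the "expressed" gate at mean RPKM ≥ 1.0,
  z-scoring, average-linkage clustering with Pearson distance d = 1 − r
  (dendrogram nodes reported as similarities 1 − d), 2^−ΔCt qPCR
  quantification, and Welch t-tests for ethylene response (α = 0.05).
* **Screening** — a gene upregulated with ripening **and** induced by
  ethylene is a candidate *activator*; downregulated on both axes **and**
  EAR-positive is a candidate *repressor*.

A seeded `synthetic_data` module generates every fixture the tests need —
proteomes with implanted domains/motifs, duplication layouts, tissue
expression matrices and ripening/ethylene profiles — so nothing is ever
downloaded. The summary roster of the 119 jujube superfamily genes and the
ERF/DREB consensus-motif table ship as packaged TSVs.

## Worked example

Generate the ripening fixture, quantify the qPCR table, and run the screen:

```sh
erfscan simulate F-ripen --seed 1 --out-dir demo/fx
erfscan qpcr demo/fx/qpcr_cq.tsv --out demo/qpcr.tsv
# derive per-gene ethylene directions (control vs treated Welch t-test),
# then intersect with ripening trajectories and EAR flags:
erfscan screen demo/fx/stage_means.tsv demo/ethylene.tsv \
    demo/fx/ear_flags.tsv --out demo/verdicts.tsv
```

which logs

```
screen: 2 activators, 2 repressors among 44 genes
```

and writes per-gene verdicts such as

```
gene_id   ripening  ethylene  has_ear  verdict
ZjDREB39  up        up        False    activator
ZjERF25   down      down      True     repressor
ZjERF36   down      down      True     repressor
ZjERF54   up        up        False    activator
ZjAP2.14  down      down      False    other    # down/down but no EAR motif
```

Of the 44 fruit-expressed genes, 15 are called ripening-upregulated and 23
downregulated; 6 are ethylene-induced and 16 suppressed. The two up/up genes
are the candidate ripening activators and the two EAR-bearing down/down
genes the candidate repressors. `erfscan summarize --out summary.tsv`
likewise reproduces the roster statistics (119 genes, lengths 402–6536 bp,
133–889 residues).

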