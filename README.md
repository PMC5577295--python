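# barcodegap

Evaluate how well a short DNA barcode (such as nuclear ribosomal ITS2)
separates closely related species in one genus. The package is aimed at
molecular taxonomists and herbal-product authentication labs that hold an
aligned matrix of barcode sequences with species labels and want to know:
is there a barcoding gap, can queries be assigned to the right species, do
species come out monophyletic on distance trees, and are there diagnostic
nucleotide positions for the species of commercial interest?

## What it computes

All pairwise distances use the Kimura 2-parameter model under pairwise
deletion. For sequences with transition proportion *P* and transversion
proportion *Q* over *n* comparable sites,

```
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
```

with the entry marked undefined (never imputed, never truncated) when a
logarithm argument is non-positive or no sites overlap.

On top of the distance matrix the package provides:

* **Divergence summary** — the six standard parameters: mean interspecific
  distance, theta' (mean between-species distance averaged over species
  pairs), minimum interspecific distance; mean intraspecific distance,
  theta (mean within-species distance averaged over species with >= 2
  representatives), and coalescent depth (maximum intraspecific distance).
* **Barcoding-gap distributions** — binned intra- vs inter-specific
  distance histograms with an overlap flag, plus a Wilcoxon two-sample
  rank test (exact by enumeration for small samples, tie- and
  continuity-corrected normal approximation otherwise) and a pooled-median
  test (Fisher exact or chi-square).
* **Species identification** — best-hit (aligned-column identity, a BLAST
  surrogate on a fixed alignment) and nearest-distance rules, each with
  the three-way outcome CORRECT / AMBIGUOUS / INCORRECT, tabulated per
  species.
* **Tree tests** — Saitou–Nei neighbor joining and UPGMA with column
  bootstrap supports and a per-species monophyly report (rooted clade or
  unrooted bipartition test).
* **Diagnostic SNPs** — single alignment columns, or minimal multi-site
  combinations, at which a target species is fixed for states no other
  sequence can carry.
* **Haplotype collapsing** — identical sequences grouped into haplotypes,
  globally or per species.
* **Synthetic genus generator** — a seeded K2P sequence-evolution
  simulator (star radiation, few haplotypes per species, dominant-first
  sampling, optional cross-species haplotype sharing) so every stage is
  testable without real data.

## Worked example

Simulate a 47-species genus at realistic divergence magnitudes and analyse
it (every subcommand also works on your own aligned FASTA + tab-separated
`id  species  population` sample map):

```sh
barcodegap simulate --out-dir demo --seed 7 --n-species 47 --sharing-prob 0.1
barcodegap divergence --fasta demo/alignment.fasta --samplemap demo/samples.tsv \
    --out demo/divergence.tsv
barcodegap identify --fasta demo/alignment.fasta --samplemap demo/samples.tsv \
    --out demo/id.tsv --method nearest_distance
```

prints

```
wrote 193 sequences (47 species) to demo
wilcoxon W=1.71184e+08 p=2.33e-157 (normal_approximation); median p=3.8e-63 (chi_square)
inter 0.029135768856215126 intra 0.008012027260630106 min_inter 0.0 overlap=True
species: 28 correct (59.6%), 6 incorrect, 13 ambiguous
```

Reading the output: interspecific divergence (~0.029) is significantly
larger than intraspecific variation (~0.008) by both rank tests, but the
minimum interspecific distance is 0 — two species share an identical
haplotype — so the distance distributions overlap and only 28 of 47
species are identified unambiguously by their nearest neighbour. The full
six-parameter table lands in `demo/divergence.tsv`; `barcodegap run`
chains every stage (haplotypes, distances, divergence, identification,
NJ/UPGMA + bootstrap + monophyly, SNP diagnostics) into one output
directory with a machine-readable `summary.json`.

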