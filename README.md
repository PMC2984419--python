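# codereassign

Detection and phylogenetic analysis of **TAR→Gln stop-codon
reassignment** in green algal nuclear genomes.

Several ulvophycean green algae — the Dasycladales, Cladophorales,
Trentepohliales and the genus *Blastophysa* — use a non-canonical
nuclear genetic code in which the stop codons TAG and TAA ("TAR") encode
glutamine, leaving TGA as the sole terminator.  Their relatives
(Bryopsidales, *Ignatius*, Ulvales–Ulotrichales, and the rest of the
green plants) use the standard code, so the reassigned taxa are
*paraphyletic* on the reference phylogeny: explaining the distribution
requires either a single origin with a reversal, three independent
gains, or a stepwise acquisition.  This package provides the tools to
establish and interpret such a distribution, for molecular
evolutionists working with multi-gene coding alignments:

* **Code inference** — screen alignments for TAG/TAA at codon columns
  where a standard-code reference panel conservedly encodes glutamine,
  corroborated by 3′ terminal stop-codon usage; verdicts are
  `STANDARD`, `TAR_GLN` or `AMBIGUOUS` with pooled evidence counts.
* **Codon usage** — per-taxon frequencies of CAG/CAA/TAG/TAA (glutamine
  under the reassigned code), the input to ancestral mapping.
* **Ancestral reconstruction** — equal-cost (Fitch) and irreversible
  (Camin–Sokal) parsimony with *exact* enumeration of all
  maximum-parsimony labelings, partitioning changes into gains and
  losses; Brownian-motion maximum likelihood for continuous usage
  frequencies (the GLS solution x̂ minimising Σ (Δx)²/t on the tree,
  with σ² per trait and standard errors).
* **Likelihood engine** — per-site log-likelihoods on fixed topologies
  under partitioned GTR+Γ (Felsenstein pruning, 8 equal-probability
  rate categories by default), branch-length optimisation, per-site
  rate scores, and slow-site stripping (keep the 75% slowest sites).
* **Topology tests** — multiscale RELL bootstrap with the
  approximately-unbiased (AU) fit bp(r) = 1 − Φ(d√r + c/√r),
  p = 1 − Φ(d − c), plus KH and SH companions.
* **Synthetic data** — seeded generators for every input above, with
  complete ground-truth logs.

## Worked example

Simulate a multi-gene dataset on the shipped 11-lineage reference
topology, infer each taxon's code, and count scenario events:

```sh
codereassign simulate --seed 5 --outdir sim/
codereassign infer-code --aln sim/gene1.fasta --aln sim/gene2.fasta \
    --aln sim/gene3.fasta --aln sim/gene4.fasta --aln sim/gene5.fasta \
    --aln sim/gene6.fasta --aln sim/gene7.fasta --aln sim/gene8.fasta \
    --refs sim/refs.txt --stops sim/terminal_stops.tsv --out assignments.tsv
```

`assignments.tsv` (excerpt):

```
taxon            verdict   n_TAR  n_CAR  stops_observed
Trentepohliales  TAR_GLN   26     38     TGA,TGA,TGA,TGA,TGA,TGA,TGA,TGA
Dasycladales     TAR_GLN   19     45     TGA,TGA,TGA,TGA,TGA,TGA,TGA,TGA
Bryopsidales     STANDARD  0      64     TAA,TAA,TAG,TAG,TAG,TGA,TGA,TGA
```

`n_TAR` counts TAG/TAA codons at conserved glutamine columns (64 were
screened per taxon across the 8 genes): the reassigned lineages show
many internal "stops" at glutamine positions and terminate only with
TGA, while Bryopsidales shows none and uses all three stop codons.

```sh
codereassign scenarios --tree sim/tree.nwk --assignments assignments.tsv \
    --mode fitch --out events_fitch.tsv
# min changes: 2; MP labelings: 1; gains: 1; losses: 1
codereassign scenarios --tree sim/tree.nwk --assignments assignments.tsv \
    --mode irreversible --out events_gains.tsv
# min changes: 3; MP labelings: 1; gains: 3; losses: 0
```

Under equal costs the unique optimal history is a single origin of the
non-canonical code on the stem of the five-lineage clade plus a reversal
on the Bryopsidales stem (2 changes); forbidding reversals instead
requires 3 independent gains, on the stems of Trentepohliales,
Dasycladales and Cladophorales+*Blastophysa* (`events_gains.tsv` lists
exactly those three clades).  The tension between these two counts is
what motivates a stepwise-acquisition reading.

The library API mirrors the CLI (`codereassign.code_inference.infer_codes`,
`codereassign.trait_reconstruction.fitch_parsimony`, …); see
`docs/methods.md` for the models, defaults and their rationale.

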