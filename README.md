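# lmerbin

Unsupervised taxonomic binning of metagenomic DNA fragments from their
l-mer (oligonucleotide) composition — no reference genomes, no marker
genes, no training data.

## The problem

Shotgun sequencing of an environmental sample yields DNA fragments from a
mixture of mostly unknown species. *Binning* groups those fragments by
their species of origin. Genomes carry a compositional signature: the
frequencies of short substrings (l-mers, by default tetranucleotides) are
stable within a genome and differ between taxa, so fragments can be
clustered on composition alone.

## The method

1. **Features.** Each fragment of length *L* is scanned with a sliding
   window, giving *L − l + 1* l-mer counts (497 tetramers in 500 bp).
   An l-mer and its reverse complement are collapsed into one canonical
   class so both strands give identical vectors; for *l* = 4 this yields
   N(4) = (4⁴ + 4²)/2 = 136 classes. Counts are divided by the window
   total, giving a normalised frequency vector *f* with Σᵢ fᵢ = 1.

2. **Distance.** For two vectors *a*, *b* the absolute component
   differences Dᵢ = |aᵢ − bᵢ| are sorted ascending and only those whose
   relative rank lies in a band (default 60 %–80 %) are summed:

   d(a, b) = Σ Dᵢ,  i/m ∈ (0.6, 0.8]

   The bottom 60 % of ranks are near-tied, statistically unstable
   components with little species signal ("interspecies noise"); the top
   20 % are dominated by atypical genome regions such as promoters or
   horizontally transferred segments ("intraspecies noise"). The band
   keeps 27 of the 136 components (~20 % of the dimension). With band
   [0, 1) the distance is Manhattan; with only the top rank it is the
   classical Chebychev distance.

3. **Clustering.** k-means with this distance for assignment and
   arithmetic-mean centre updates (Forgy initialisation from k data
   rows), restarted from several seeds; the restart with the smallest
   within-cluster distance sum wins.

A first-order-Markov community simulator generates labelled synthetic
communities (species divergence, fragment length, abundance ratio and
substitution error rate are all configurable) so the whole pipeline is
testable without downloads, and an evaluation module scores clusterings
against true labels via optimal one-to-one cluster–species matching.

## Worked example

```python
import lmerbin as lb

# two-species community: 2000 + 2000 fragments of 2000 bp, 2% errors
config = lb.default_two_species_community(seed=1)
fragments, _ = lb.build_community(config)

model = lb.CompositionBinning.from_fragments(fragments, l=4)
result = model.fit(k=2, restarts=10, seed=0)
print(result.summary())
print("accuracy:", result.score({f.id: f.label for f in fragments}))
```

```
Composition Binning Results
==============================================
No. fragments:              4000
Feature dimension N(l):     136
Clusters (k):               2
Distance band:              0.60-0.80
Restarts:                   10
Base seed:                  0
Winning seed:               0
Iterations (winner):        3
Converged:                  True
Objective:                  186.624758
----------------------------------------------
cluster       size
0             2000
1             2000
==============================================
accuracy: 100.0
```

The objective is the summed band distance of every fragment to its
cluster centre; the accuracy is the percentage of fragments on the
diagonal after optimally matching clusters to species — here both
species are recovered perfectly despite the 2 % substitution errors.

The same pipeline from the shell:

```bash
lmerbin simulate --seed 1 -o community/
lmerbin bin -i community/fragments.fasta -k 2 --seed 0 -o run/
lmerbin evaluate --assignments run/assignments.tsv --labels community/labels.tsv
```

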