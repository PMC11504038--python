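# nlrevo

Tools for studying the diversity and evolution of plant **NLR**
(nucleotide-binding leucine-rich repeat) resistance-gene families, built
around the kind of multi-genome survey done for crop species such as citrus:
hundreds to thousands of NLR genes are identified across a set of related
genomes, classified by domain architecture, and the mechanisms that shaped
their copy-number differences — gene duplication, horizontal gene transfer
(HGT) and recombination — are quantified from gene trees and alignments.

`nlrevo` provides the downstream analysis as a tested library plus a small
CLI. The heavy external steps (HMMER/BLAST searches, alignment, tree
inference, PAML, RDP) stay outside: their tabular outputs are this package's
inputs. A built-in gene-family simulator generates species-labelled gene
trees, domain states and recombinant alignments with known ground truth, so
every rule can be validated without any downloads.

## What it computes

- **Identification & classification** (`nlr_identify`): merge HMM and BLAST
  candidate sets; filter candidates by phylogenetic placement (kept iff the
  smallest clade joining a candidate to a reference contains plant R-protein
  references only); drop alternative-splicing isoforms (longest per locus);
  classify each NB-ARC protein by its N-terminal domain into
  **TNL** (TIR), **RNL** (RPW8), **CNL** (Rx_N, the four-helix bundle
  annotated in place of the classical CC motif) or plain **NL**.
- **Event calling** (`tree_events`): on a rooted gene tree with species
  labels, a *duplication* is a maximal single-species clade of ≥ 2 genes
  (scored per internal node or per clade); an *HGT* is called when one
  species' genes nest inside another's — each of the next `context_depth`
  enclosing clades must add genes of one single other species (the donor).
  Donor×recipient matrices summarize directed transfer counts.
- **Recombination** (`recombination`): a pairwise **MaxChi** scan — the
  maximum 2×2 chi-square contrasting match/mismatch counts left vs right of
  a sliding point along polymorphic sites, with a site-order permutation
  p-value — plus the consensus rule used with RDP-style method batteries:
  an event is significant iff ≥ 4 of the 7 methods report p < 10⁻⁶.
- **Selection** (`selection`): the M7-vs-M8 likelihood-ratio test
  (χ², df = 2, upper tail `exp(−stat/2)`) with BEB-site counts; a group is
  positively selected iff the LRT is significant and ≥ 1 site passes the
  posterior cutoff.
- **Summaries** (`summary`): per-species TNL/CNL/RNL/NL count tables and
  Pearson/Spearman correlations between per-species NLR counts and event
  frequencies.
- **Simulation** (`synthetic_data`): birth–death–transfer gene families
  along a dated species tree, two-state domain gain/loss from an NL root
  state, and alignments with one planted recombination breakpoint.

## Worked example

```python
from nlrevo import (SimulationConfig, simulate_gene_family,
                    call_duplications, call_hgt, hgt_matrix)

cfg = SimulationConfig(dup_rate=0.3, loss_rate=0.0, transfer_rate=0.1, seed=28)
truth = simulate_gene_family(cfg)
print(len(truth.species_map), "extant genes in", len(truth.species), "species")

dups = call_duplications(truth.gene_tree, mode="node_count")
hgts = call_hgt(truth.gene_tree, context_depth=2)
print(sum(d.n_events for d in dups), "duplication events,",
      len(hgts), "HGT events")
print(hgt_matrix(hgts, truth.species).to_numpy().sum(), "transfers in matrix")
```

prints

```
17 extant genes in 10 species
2 duplication events, 1 HGT events
1 transfers in matrix
```

i.e. this seeded family kept 17 gene copies, two of which arose by within-
species duplication, and one species' diversity is nested inside another's —
the called transfer, which matches the simulator's own event log. The same
analyses run from the shell via `nlrevo simulate`, `nlrevo events`,
`nlrevo classify`, `nlrevo recomb`, `nlrevo selection` and
`nlrevo summarize` (see `nlrevo --help`).

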