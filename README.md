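# biofilm-assembly

Community-assembly analysis for membrane-biofilm microbiomes.

Biofilms that grow on the membranes of membrane bioreactors (MBRs) foul
them, and fouling control depends on understanding *how* those biofilm
communities assemble from the surrounding activated sludge: are they
deterministically selected by the membrane environment, or shaped by
stochastic colonisation and drift — and does the answer change as the
biofilm ages? This package implements the statistical pipeline for that
question: rarefaction and diversity statistics, ordination, permutational
MANOVA, and a phylogenetic-bin-based null-model framework that partitions
community turnover into five ecological processes. It is aimed at
microbial ecologists working with OTU/ASV count tables, a rooted
phylogeny, and sample metadata from time-series biofilm experiments.

Because deposited amplicon data require an upstream clustering pipeline
that is out of scope here, the package ships a first-class synthetic-data
module that simulates metacommunities under each assembly regime with
known ground truth — every downstream stage is validated against it.

## The framework

Taxa are first divided into phylogenetically coherent **bins** (clades
with small internal cophenetic diameter, merged up to a minimum size).
For every pair of communities and every bin, two null models are scored:

- **βNRI** (β net relatedness index): the standardised effect size of the
  abundance-weighted between-community mean pairwise phylogenetic
  distance (βMPD) against a null that shuffles taxon identities among the
  bin's tips,

  βNRI = (βMPD_obs − mean βMPD_null) / sd βMPD_null.

- **RC** (modified Raup-Crick): the rank of the observed bin-level
  Bray-Curtis dissimilarity in a null ensemble that preserves each
  sample's bin richness and abundance while drawing taxa by occupancy and
  filling individuals by mean relative abundance, rescaled to [−1, 1].

Each pair-bin is then classified:

| condition | process |
|---|---|
| βNRI > +1.96 | heterogeneous selection (HeS) |
| βNRI < −1.96 | homogeneous selection (HoS) |
| else RC > +0.95 | dispersal limitation (DL) |
| else RC < −0.95 | homogenizing dispersal (HD) |
| otherwise | drift (DR) |

Per pair, bins are weighted by their mean relative abundance in the two
samples; per group (e.g. sampling day), pair fractions are averaged. The
five fractions always partition unity.

## Worked example

The numbered scripts under `analysis/` reproduce the full study-shaped
analysis on synthetic data (seed 1):

```sh
python analysis/01_simulate_study.py --seed 1   # DNA + cDNA datasets
python analysis/02_diversity_ordination.py --seed 1
python analysis/03_permanova.py --seed 1
python analysis/04_assembly_partition.py --seed 1
python analysis/05_scenario_recovery.py --seed 1
```

`04_assembly_partition.py` prints, for the DNA dataset:

```
== DNA: per-day process fractions (mean over within-day pairs)
       n_pairs    HeS    HoS     HD     DL     DR
group
1           45  0.000  0.646  0.354  0.000  0.000
10          45  0.000  0.599  0.401  0.000  0.000
20          45  0.000  0.883  0.000  0.000  0.117
30          36  0.054  0.022  0.000  0.924  0.000
DNA: homogeneous selection 65% at day 1 → 2% at day 30; drift + dispersal
limitation reach 92% by day 30
```

Read: among day-1 biofilm sample pairs, 65% of (abundance-weighted) bin
comparisons are classified as homogeneous selection — young biofilms are
deterministically filtered by the early-coloniser niche — while by day 30
the selection signal has collapsed and dispersal limitation plus drift
dominate turnover, the succession pattern the simulated study encodes.
Heterogeneous selection stays near zero throughout, as expected for
samples sharing one reactor environment. `03_permanova.py` shows the same
story in distance space: sampling day explains ~83% of Bray-Curtis
variance (p = 0.001), while membrane type, surface chemistry and permeate
flux are non-significant.

`05_scenario_recovery.py` validates the inference against ground truth —
each of the five simulated regimes is recovered as the modal process in
85–100% of 20 replicates.

Equivalent functionality is exposed as a CLI (`biofilm-assembly simulate |
rarefy | diversity | ordinate | permanova | assembly | all |
export-top-taxa`).

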