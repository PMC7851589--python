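# oriscan

Rearrangement-aware analysis of spatial substitution trends in bacterial
genomes.

## The problem

Bacterial replication starts at a single origin (*oriC*) and proceeds
bidirectionally, so a chromosome is naturally indexed by *distance from the
origin along a position's own replichore* rather than by raw GenBank
coordinates. Substitution rates have repeatedly been claimed to increase
with that distance — but bacterial genomes rearrange constantly, and a gene
sitting near the terminus today may have accumulated most of its
substitutions somewhere else. Testing a spatial trend honestly requires
knowing *where each substitution happened*, not where its descendants sit
now.

`oriscan` is a pipeline for comparative genomicists who have: per-replicon
multi-genome alignments partitioned into locally colinear blocks (LCBs,
e.g. from progressiveMauve), coding annotations per taxon, and a rooted
tree with branch lengths. It:

1. re-indexes each replicon around its origin with the bidirectional
   transform (circular and linear replicons, explicit or midpoint termini);
2. filters blocks to codon-consistent, gap-free gene segments
   (universal-block selection, gap-fraction trimming, codon-position
   agreement, 100-bp minimum, codon-complete trimming);
3. jointly reconstructs ancestral **nucleotides** (marginal ML under HKY,
   Felsenstein pruning) and ancestral **genomic positions** (block-level
   Fitch/Sankoff parsimony with a likelihood tie-break) at every internal
   node, and emits per-branch substitution events tagged with their
   ancestral position;
4. fits the spatial statistics: a per-site logistic regression
   `logit P(substitution) = β0 + β1·d`, windowed substitutions-per-10-kb
   densities with Tukey outlier flagging, windowed linear regressions at
   10–400 kb, an origin-shift permutation test (±100 kb in 10-kb steps),
   and a leave-one-taxon-out jackknife;
5. estimates per-segment dN, dS and ω = dN/dS by Nei–Gojobori counting with
   Jukes–Cantor correction, with the zero- and outlier-handling rules and
   length-weighted genome averages, plus selection-vs-distance regressions.

A synthetic-genome simulator (`oriscan.simulate`) generates desk-scale
genomes evolved along a tree with a configurable log-linear rate gradient
`rate(d) = μ·exp(g·d)`, block translocations and inversions, purifying
selection, and complete truth logs — so every stage of the pipeline is
validated by parameter recovery rather than by trust.

## Worked example

Simulate five taxa on a 100-kb circular replicon whose substitution rate
doubles across each replichore (`g = ln 2 / (L/2) ≈ 1.39e-5` per bp), with
rearrangements, then run the full analysis:

```python
import math
from oriscan.simulate import SimulationConfig, simulate
from oriscan.pipeline import run_full_analysis

L = 100_000
cfg = SimulationConfig(seed=42, n_taxa=5, length=L,
                       gradient=math.log(2) / (L / 2),
                       block_span=(5_000, 20_000))
res = simulate(cfg)
report = run_full_analysis(res.blocks, res.annotations, res.tree,
                           res.replicon, with_permutation=False)
print(report.counts)
print(report.logistic)
print(report.selection_summary)
```

prints (abridged):

```
{'blocks_read': 19, 'blocks_kept': 19, 'gap_trimmed_columns': 0,
 'segments': 105, 'coding_sites': 86492, 'events': 4415}
logistic beta1 = 1.202e-05  se = 1.053e-06  p = 3.4e-30  n = 86492
{'dS_bar': 0.0587, 'dN_bar': 0.0098, 'omega_bar': 0.1749,
 'n_records': 105, 'n_outliers': 5}
```

Reading this: 19 homologous blocks survived filtering into 105
codon-consistent gene segments covering 86,492 coding sites; 4,415
substitution events were reconstructed and mapped to ancestral coordinates.
The logistic slope per bp of origin distance comes back positive and close
to the simulated gradient (fitted 1.20e-5 vs true 1.39e-5 on the logit
scale), decisively significant — the pipeline recovers the gradient it was
shown, through the rearrangements. The genome-averaged dS̄ = 0.059 >
dN̄ = 0.010 (ω̄ ≈ 0.17) reflects the simulated purifying selection.

The same stages are scriptable from a shell:

```bash
oriscan simulate --config sim.yaml --seed 42 --out data/
oriscan run --config run.yaml          # full analysis + run_report.json
oriscan permute-origin --config run.yaml
oriscan jackknife --config run.yaml
oriscan selection --config run.yaml
```

where `run.yaml` names the replicon geometry (length, topology, origin,
terminus or `midpoint`), the input paths (XMFA blocks, annotation TSV/GFF3,
Newick tree), and any filter/analysis overrides. Outputs are plain TSVs
(site table, window densities, events, selection records, regressions) and
a JSON run report whose every number is recomputable from the TSVs.

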