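# ncnet

Differential ncRNA–mRNA coexpression network analysis.

`ncnet` builds condition-specific bipartite networks of negative
ncRNA–mRNA Pearson correlations from expression matrices, derives the
correlation cutoff analytically from the sample size, characterizes
network topology (combined betweenness×outdegree centrality, power-law
degree fits, six-descriptor summaries), compares the relapse / remission /
control networks edge by edge to extract a status-independent core and a
disease-specific network, runs Rank Products differential expression, and
selects candidate therapeutic ncRNAs by combining network centrality with
differential expression. A synthetic-cohort simulator with a planted,
power-law-sized regulatory structure and condition-specific rewiring makes
every stage testable without external data.

## Package layout

| module | what it does |
| --- | --- |
| `ncnet.simulate` | synthetic cohorts with planted edges, rewiring, DE shifts |
| `ncnet.preprocess` | intensity / detection filters, per-gene z-scoring |
| `ncnet.netbuild` | pairwise ncRNA×mRNA Pearson R, `critical_r` t-inversion cutoff, thresholding |
| `ncnet.topology` | centralities, degree/path distributions, power-law fit, descriptors, hubs, core subnetwork |
| `ncnet.diffnet` | 3-way Venn partitions, status-independent core, disease-specific network, descriptor PCA |
| `ncnet.rankprod` | Rank Products with permutation pfp, paired and unpaired designs |
| `ncnet.targets` | candidate selection and caution flags |
| `ncnet.pipeline` / `ncnet.cli` | orchestration, manifests, `ncnet` command line |

## Command line

```bash
# simulate a cohort
ncnet simulate --config sim.json --out cohort/

# build one network (condition: global|relapse|remission|control)
ncnet network --expression cohort/expression.tsv --samples cohort/samples.tsv \
      --condition relapse --alpha 0.01 --out relapse

# topology of a saved network
ncnet topology --network relapse.tsv --out topo/

# compare three condition networks
ncnet diffnet --relapse relapse.tsv --remission remission.tsv \
      --control control.tsv --out diff/

# Rank Products differential expression
ncnet rankprod --expression cohort/expression.tsv --samples cohort/samples.tsv \
      --comparison relapse_vs_remission --out rp_rel.tsv

# candidate selection
ncnet candidates --disease-net diff/disease_specific.tsv \
      --rankprod-relapse rp_rel.tsv --rankprod-remission rp_rem.tsv \
      --core-net diff/core_status_independent.tsv --out candidates.tsv

# or everything at once (simulated or loaded data)
ncnet run-all --simulate --seed 1 --out run/
```

Expression input is a tab-separated table (gene id, gene class, then one
column per sample) plus a sample sheet (sample id, condition, patient id);
networks are written as edge TSV (`source  interaction  target  r`) and
Cytoscape SIF.

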