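# geneconnectome

Network-based prioritization of disease-gene candidates by **biological
distance**, with the complete surrounding pipeline: building a weighted gene
network from pairwise interaction confidence scores, computing per-gene
connectomes, filtering whole-exome variant tables, and ranking candidate
gene lists against known core genes.

## Who this is for

Human geneticists with a high-throughput candidate list — typically the
genes left after filtering a patient's whole-exome sequencing (WES)
variants — and one or more *core genes* already known to drive the
phenotype. The working hypothesis is that causal genes of a phenotype are
functionally close to each other, so good candidates sit at a short
biological distance from the core genes in the protein-protein interaction
network.

## The model

Given an interaction table with confidence scores *s* ∈ (0, 1] (STRING-style
integer scores are normalized by 1000 at read time), each edge receives a
**direct biological distance**

> d = 1 / s   (default; d = 1 − s + ε is available for sensitivity analysis)

on an undirected, weighted graph over all genes. The biological distance
between any two genes *a*, *b* is the total weight of the minimal-weight
path, found by Dijkstra's algorithm, and the **route** is the gene sequence
realizing it. The **gene-specific connectome** of a core gene *c* is the
list of all other genes ordered by distance to *c*, annotated with:

- distance, rank (1..N, ties broken alphabetically),
- connectivity p-value p = rank / N (unreachable genes get p = 1),
- best reciprocal p-value BRP(a, b) = min(p_a(b), p_b(a)) — a symmetric
  measure compensating for hub and isolated genes,
- distance / median-distance and distance / mean-distance ratios,
- sphere (rank decile, 1–10), route, degrees of separation (route edge
  count), and full gene name from an alias table.

Candidate lists are ranked by distance, p-value or BRP — globally (each
candidate once, with its best core gene) or separated per core gene. The
WES variant filter keeps nonsynonymous variants with population frequency
< 1% in both databases and cohort frequency ≤ 0.6%.

## Worked example

The toy network has confidence scores A–B 0.9, B–C 0.5, A–C 0.25, C–D 0.8
and an isolated gene E. Under reciprocal inversion the two-hop route
A→B→C (1/0.9 + 1/0.5 = 3.1111) beats the direct A–C edge (1/0.25 = 4).

```python
from geneconnectome import InteractionRecord, build_network, build_connectome

records = [InteractionRecord(*t) for t in
           [("A", "B", 0.9), ("B", "C", 0.5), ("A", "C", 0.25), ("C", "D", 0.8)]]
net = build_network(records, include_nodes=["E"])
for r in build_connectome(net, "A").records:
    print(r.target, round(r.distance, 4), r.rank, r.p_value, "->".join(r.route))
```

prints

```
B 1.1111 1 0.25 A->B
C 3.1111 2 0.5 A->B->C
D 4.3611 3 0.75 A->B->C->D
E inf 4 1.0
```

i.e. B is the closest gene to A (rank 1, p = 1/4), D is reached through the
three-edge route A→B→C→D, and the disconnected E is ranked last with p = 1.

The same pipeline from the shell:

```sh
hgc synth network --seed 1 --out-prefix fx_        # synthetic benchmark data
hgc summary --network fx_edges.tsv
hgc filter-variants --in variants.tsv --out kept.tsv --genes-out genes.txt
hgc prioritize --network fx_edges.tsv --candidates genes.txt \
    --cores G0042 --metric distance --mode global --out ranked.tsv
```

Exit codes: 0 success, 1 usage error, 2 data error.

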