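# sctri

Decision-level integration of conflicting single-cell cluster annotations.

Single-cell experiments routinely produce several incompatible clusterings of
the same cells: different algorithms, different resolutions, different
modalities (RNA, ADT, ATAC), labels projected from reference atlases. `sctri`
does not average them or embed them jointly. It scores every cluster of every
annotation set with stability metrics — the **reassign** score (fraction of a
cluster's cells reclassified to their own centroid in a marker-PCA space),
**TF-IDF(n)** exclusivity (the strength of the nth-ranked exclusively
expressed feature) and the **SCCAF** score (cross-validated multinomial
logistic-regression recall) — and then treats each annotation set as a player
in a coalitional game. For each cell *i* with per-annotation score matrix
D ∈ R^(A×M), the importance of annotation *a* is its Shapley value

  Φ_a = Σ_{T ⊆ A∖{a}} |T|!(A−|T|−1)!/|A|! · (V(T∪{a}) − V(T)),

where a coalition's value credits players that top-rank the coalition per
metric within an additive tolerance (offset 0.01). The cell is assigned to
argmax_a Φ_a(i); winner clusters that retain < 25% of their originating
cluster or < 10 cells are pruned and their cells reassigned to the nearest
stable centroid. The package also reports per-cluster modality contributions
(rank-weighted membership of each modality in the top-20 markers) and
entropy-based agreement metrics (homogeneity, completeness, V-measure), and
ships a Splat-style group-structured count simulator used by the built-in
benchmarks.

## Worked example

Simulate five cell populations (3000 cells) and four deliberately conflicting
annotation sets — Broad merges groups c1+c2+c3, Median merges c2+c3, Fine
arbitrarily halves c5, Excessive halves c2 and c3 — so that no single input
matches the simulated truth, then triangulate:

```python
from sctri import RunConfig, evaluate, make_fixture, normalize_cptt, triangulate

matrix, annotations, truth = make_fixture("experiment1", seed=1, n_genes=2000)
result = triangulate(normalize_cptt(matrix), annotations, RunConfig(random_seed=1))

import pandas as pd
print(pd.Series(result.final_label).value_counts())
print(evaluate(truth.group_labels, result.final_label))
```

```
Broad@c5        715
Broad@c4        676
Excessive@c1    673
Fine@c2         503
Fine@c3         433
Name: count, dtype: int64
{'homogeneity': 1.0, 'completeness': 1.0, 'v_measure': 1.0,
 'n_clusters_pred': 5, 'n_clusters_truth': 5}
```

The engine recovered exactly the five simulated populations by mixing
clusters from different inputs: c1 from the over-clustered annotation
(where it was left intact), c4 and c5 from the broadest annotation, and the
subtly distinct c2 and c3 from the only annotation that kept them apart. The
`annotation@cluster` labels say which input each final cluster was borrowed
from, and the V-measure of 1.0 against the (withheld) truth means the
integrated partition is identical to it up to renaming.

The same thing from the shell:

```bash
sctri simulate --fixture experiment1 --seed 1 --outdir sim/
sctri triangulate --matrix sim/matrix.mtx --normalize cptt \
    --annotations sim/annotations.tsv --seed 1 --outdir run/
sctri evaluate --pred run/cell_results.tsv --truth sim/truth.tsv
```

`run/` then holds per-cell results (winner annotation, raw and final labels,
per-annotation importances), per-cluster results (size, winning fraction,
quality) and a JSON manifest with the configuration and seed.

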