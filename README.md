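# meshgat

Classification of breast tumors as **benign** or **malignant** from 3D
triangle meshes of the tumor region of interest (ROI), for researchers in
quantitative ultrasound image analysis. Instead of 2D texture features, the
pipeline characterizes each tumor by ten 3D mesh shape features, links
similar tumors into a sample-similarity graph, and classifies the graph's
nodes with a multi-head graph attention network (GAT).

## Pipeline

1. **ROI extraction** — a grayscale ultrasound image is masked with its
   binary ground-truth mask (bitwise AND), isolating the tumor.
2. **Mesh quality control** — each surface mesh is screened for structural
   damage. Holes are quantified as the percentage of *boundary edges* (edges
   belonging to exactly one triangle) among all undirected edges; meshes with
   more than 10% compromised structure are excluded.
3. **Feature extraction** — ten features per mesh:
   - *sphericity* S = π¹ᐟ³ (6V)²ᐟ³ / Sa (isoperimetric ratio, 1 for a sphere),
   - *anisotropy* A = (λ₁ − λ₃)/λ₁ of the whole-mesh covariance eigenvalues,
   - *eigen-entropy* E = mean over vertices of −Σᵢ λᵢ ln λᵢ (local k-NN
     covariance, normalized eigenvalues λ₁ ≥ λ₂ ≥ λ₃ ≥ 0, Σλᵢ = 1),
   - *curvature* C = mean over vertices of λ₃/(λ₁+λ₂+λ₃),
   - *volume* V = |Σ (1/6)(v₁ × v₂)·v₃| and *surface area*
     Sa = Σ ½|(v₂−v₁) × (v₃−v₁)| over triangles (v₁, v₂, v₃),
   - *farthest distance* (mesh diameter), *centroid distance* (mean distance
     from the area-weighted surface centroid to the vertices), and the
     min/max *bounding-box distances* (vertex-to-box-corner extremes).
4. **Feature assessment** — per-feature one-way ANOVA F-test and greedy MRMR
   (minimum redundancy, maximum relevance) ranking.
5. **Graph construction** — feature-table rows become nodes; an undirected
   edge joins two rows when the Spearman rank correlation across their ten
   feature values is ≥ 0.7.
6. **GAT classification** — per attention head, the score for neighbor j of
   node i is e<sub>ij</sub> = LeakyReLU(a·[W x<sub>i</sub> ‖ W x<sub>j</sub>]),
   normalized as α<sub>ij</sub> = softmax<sub>j∈N(i)</sub>(e<sub>ij</sub>),
   and the update is activation(Σ<sub>j</sub> α<sub>ij</sub> W x<sub>j</sub>).
   Training is transductive full-graph gradient descent with momentum;
   evaluation reports the confusion matrix and eleven derived metrics.

Because mesh generation from 2D images requires GPU-scale pretrained
models, the package ships a synthetic tumor-mesh generator: smooth, oval
benign-like surfaces versus larger, eccentric, spiculated malignant-like
surfaces, with a `separation` dial (0 = identical classes) and per-mesh
parameter jitter. All generated meshes are watertight by construction.

## Worked example

```python
from meshgat import (make_dataset, build_feature_table, build_graph,
                     graph_stats, train_gat, GATConfig, anova_f)
from meshgat.pipeline import PIPELINE_GAT_DEFAULTS

meshes = make_dataset(n_benign=60, n_malignant=30, separation=0.8, seed=42)
table = build_feature_table(meshes)
print(table.groupby("target")[["sphericity", "anisotropy", "curvature", "volume"]].mean().round(3))
#            sphericity  anisotropy  curvature  volume
# benign          0.983       0.198      0.009   3.102
# malignant       0.848       0.405      0.028   8.064

graph = build_graph(table, threshold=0.7, standardize=True)
print(graph_stats(graph).as_dict())
# {'n_nodes': 90, 'n_edges': 633, 'intra_benign': 554,
#  'intra_malignant': 79, 'inter_class': 0}

model, report = train_gat(table, graph, GATConfig(**{**PIPELINE_GAT_DEFAULTS, "seed": 42}))
print(report.test_accuracy, report.sensitivity, report.f1)
# 100.0 100.0 100.0
```

Benign meshes are rounder (higher sphericity), smoother (lower curvature and
anisotropy) and smaller (lower volume) than malignant ones; the standardized
Spearman graph is strongly class-assortative (no inter-class edges here), and
the GAT separates the held-out test nodes perfectly at this class separation.

The same stages are available from the shell:

```bash
meshgat simulate --n-benign 120 --n-malignant 60 --seed 7 --out meshes/ --labels labels.csv
meshgat qc --in meshes/ --threshold 10 --report qc.csv
meshgat features --meshes meshes/ --labels labels.csv --out features.csv
meshgat graph --features features.csv --threshold 0.7 --standardize --out edges.csv --stats stats.json
meshgat train --features features.csv --out model/
meshgat run-all --out run/ --seed 7      # everything, one command
```

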