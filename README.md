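# stscsr — spatial-domain identification by shared-factor tri-factorization

Spatial transcriptomics assays (10x Visium, Stereo-seq, osmFISH, …) measure
expression at spatially indexed spots; the first analysis step is usually to
segment the tissue into **spatial domains** — contiguous regions whose spots
share expression character, such as cortical layers. `stscsr` identifies
these domains by learning a spot–spot affinity graph that fuses expression
and spatial structure, then clustering that graph.

## The model

Given a preprocessed expression matrix X ∈ ℝ^{m×n} (m features, n spots) and
the adjacency W of a spatial K-nearest-neighbor network over the spots
(K = 5; edge weights inversely proportional to profile distance,
w_ij = ‖x_i − x_j‖⁻¹), the method minimizes

```
min  ‖X − Bₑ C Fₑ‖²_F + ‖W − Bₛ C Fₛ‖²_F            (joint tri-factorization)
   + α · Tr(Fₑ L Fₑᵀ)                                 (local preservation, L = D − W)
   + β · (‖Fₑ − Fₑ Z‖²_F + ‖Fₛ − Fₛ Z‖²_F) + γ‖Z‖₁   (sparse self-representation)
s.t. Bₑ, Bₛ, Fₑ, Fₛ ≥ 0,   C = Cᵀ,   Z = Zᵀ,  diag(Z) = 0.
```

The shared symmetric core **C** couples the expression and spatial views and
is interpretable as a similarity matrix among domain-level meta-structures;
the learned affinity **Z** expresses each spot as a sparse combination of
like spots and is handed to Leiden community detection to produce the domain
labels. Defaults α = 2, β = 1, γ = 50, rank k = 50, K = 5. Downstream, domain
markers are genes expressed in ≥ 80 % of a domain's spots with log2 fold
change ≥ 1.5 and one-vs-rest Wilcoxon rank-sum FDR ≤ 0.05; partitions are
scored against references with ARI and NMI.

See `docs/methods.md` for the optimization scheme (block-coordinate descent
with exact constrained block solvers and an ADMM affinity step), the scale
conventions, and known limitations.

## Worked example

Simulate a 10×10 lattice with three banded domains and run the full
pipeline from the shell:

```bash
st-scsr simulate --out sim --grid-rows 10 --grid-cols 10 --n-genes 80 --seed 3
st-scsr run --expr sim/expression.csv --coords sim/coords.csv \
            --n-domains 3 --k 8 --max-outer 8 --seed 3 --out out
st-scsr evaluate --pred out/domains.csv --truth sim/truth.csv
st-scsr markers --expr sim/expression.csv --coords sim/coords.csv \
                --labels out/domains.csv --out markers.csv
```

prints

```
wrote 100 spots × 80 genes to sim
3 domains for 100 spots -> out/domains.csv
ARI	1.0000
NMI	1.0000
18 marker calls pass thresholds -> markers.csv
```

The run recovered the three planted bands exactly (ARI/NMI = 1 against the
generator's truth labels), and the marker table flags the planted
domain-specific genes (e.g. `gene0000` in domain 0: expressed in 97.5 % of
its spots, log2 fold change 1.59, FDR 2×10⁻⁸). The same steps are available
in Python via `stscsr.simulate`, `stscsr.run_pipeline`,
`stscsr.rank_markers`, `stscsr.ari`/`stscsr.nmi`.

The library also reads 10x-style inputs directly
(`stscsr.read_visium(matrix.mtx, features.tsv, barcodes.tsv,
tissue_positions.csv)` — out-of-tissue spots are dropped), and
`--n-domains auto` selects the domain count by consensus-NMF stability.

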