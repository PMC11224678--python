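# regionvec

Genomic-region embeddings for single-cell chromatin accessibility data.

`regionvec` treats each cell of a binary accessibility matrix as a document
whose words are its accessible genomic regions (`chrom_start_end` tokens,
signal = any entry > 0). A skip-gram model with negative sampling is trained
over per-epoch shuffled documents (region co-occurrence has no inherent
order, so context is simulated by shuffling), producing an embedding vector
per region. Cell embeddings are the unweighted mean of the region vectors
accessible in each cell, and feed clustering, 2D visualization, and
reference-based annotation.

Because the model embeds *regions*, not cells, a pre-trained model can embed
unseen datasets without retraining: query regions are mapped onto the model's
region set by genomic overlap and pooled with the reference vectors
(E-projection), and can additionally be pushed through a 2D reducer fitted on
the reference cells, placing new cells in the reference coordinate frame
(EV-projection). A k-nearest-neighbour classifier over labelled reference
embeddings then annotates query cells.

## Layout

| module | role |
| --- | --- |
| `io_formats` | MTX + barcodes/BED sidecar reading, BED, model bundles (TSV vector tables + consensus BED + metadata), label tables |
| `corpus` | matrix → region-word documents; deterministic per-epoch shuffling |
| `sgns` | skip-gram negative-sampling trainer (numba fast path, pure-numpy reference path), window 5 / dim 100 / exponential lr decay defaults |
| `pooling` | mean-pooled cell embeddings; NaN sentinels for zero-coverage cells |
| `projection` | interval overlap mapping, document translation, E-/EV-projection, UMAP reducer |
| `cluster_metrics` | K-means / Ward HC / Louvain clustering; ARI, AMI, homogeneity, Gini, RAGI, subsampled-RAGI protocol |
| `annotation` | KNN annotation, class mapping, confusion/F1 evaluation |
| `synthetic` | planted-cell-type matrix generator, exact-count dropout, region jitter |
| `cli` | `regionvec` command with all subcommands |

## CLI

```bash
regionvec simulate --types 5 --cells-per-type 100 --regions 2000 --seed 1 --out-dir data/
regionvec train --mtx data/matrix.mtx --barcodes data/barcodes.tsv \
    --regions data/regions.bed --out-model model/ --epochs 100 --seed 1
regionvec embed --mtx data/matrix.mtx --barcodes data/barcodes.tsv \
    --regions data/regions.bed --model model/ --out emb.tsv
regionvec cluster --embeddings emb.tsv --method louvain --out labels.tsv
regionvec evaluate --labels labels.tsv --truth data/truth.tsv
regionvec project --mtx query.mtx --barcodes q_barcodes.tsv --regions q_regions.bed \
    --model model/ --mode e --out proj.tsv
regionvec annotate --model model/ --reference-embeddings emb.tsv \
    --reference-labels data/truth.tsv --mtx query.mtx --barcodes q_barcodes.tsv \
    --regions q_regions.bed --out ann.tsv
regionvec corrupt --mtx data/matrix.mtx --barcodes data/barcodes.tsv \
    --regions data/regions.bed --rate 0.8 --out-dir corrupted/
```

Every run writes a `*.manifest.json` next to its primary output recording
parameters, seeds and input checksums; replaying a manifest reproduces
outputs byte-for-byte (training is bit-deterministic single-threaded).

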