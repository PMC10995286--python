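# mirsea

miRNA set enrichment analysis over fused heterogeneous similarity networks.

High-throughput studies show that miRNAs act in sets rather than alone, so a
differentially expressed miRNA list is best interpreted by testing it against
curated miRNA sets (disease sets, functional sets). A plain over-representation
test on the raw list, however, misses miRNAs that are functionally tied to the
list but did not pass the differential-expression cut. `mirsea` addresses this
by first **expanding** the list over a miRNA–miRNA association network built
from multiple evidence sources, then testing the expanded list.

The pipeline:

1. **miRSN-DA** — miRNA similarity from shared disease associations. Diseases
   are compared on a MeSH-like DAG by decayed ancestor contributions
   (decay Δ = 0.5): each disease *d* assigns every ancestor *t* the value
   D_d(t) = Δ^(min hops from d to t), its semantic value is DV(d) = Σ_t D_d(t),
   and S(d_i, d_j) = Σ_{t∈T_i∩T_j} (D_i(t)+D_j(t)) / (DV_i+DV_j).
   Two miRNAs with disease sets D1, D2 score
   (Σ_{d∈D1} S(d, D2) + Σ_{d∈D2} S(d, D1)) / (|D1|+|D2|), where S(d, D) is the
   best match of d against D.
2. **miRSN-GOA** — miRNA similarity from GO annotations of target genes.
   Term IC is −ln(|G_x|/|G_root|) over descendant-closed gene sets; term–term
   similarity is min(1, (IC_LCA + IC_HCD)/(IC(x)+IC(y))); each miRNA's terms
   are weighted by the hypergeometric surprise w_x = −ln P(X ≥ k) of its
   target–term overlap, and profiles are compared by a best-match weighted
   normalized Euclidean aggregation, symmetrized.
3. **miRSN-PPI** — miRNA similarity as the reciprocal mean shortest-path
   distance between the two miRNAs' target genes on a protein–protein
   interaction network, capped at 1.
4. **Fusion** — the networks are averaged per pair over the networks covering
   both miRNAs; pairs covered by no network get 0.
5. **Expansion** — the fused network is thresholded at a similarity
   coefficient τ = 0.6, columns are normalized into a transition matrix W, and
   a random walk with restart r ← c·W·r + (1−c)·e (c = 0.85) is run from the
   user's list; the top 50 % of positive non-seed nodes join the list.
6. **Enrichment** — the expanded list is tested against a GMT knowledge base
   with the inclusive upper-tail hypergeometric test
   p = Σ_{i=m}^{min(n,M)} C(M,i)·C(N−M,n−i)/C(N,n), corrected by
   Benjamini–Hochberg FDR (significance at FDR < 0.05). Hit rate against a
   reference set is 100·m/M.

## Worked example

All inputs can be generated synthetically: the planted scenario hides a
20-miRNA module with high within-module similarity in two of the three
networks and hands you half the module as the input list.

```sh
mirsea simulate --n-mirnas 60 --module-size 20 --seed 7 --out-dir demo
mirsea fuse --matrix demo/mirsn_da.tsv --matrix demo/mirsn_goa.tsv \
            --out demo/fused.tsv --report demo/fusion.json
mirsea expand --network demo/fused.tsv --list demo/input_list.txt \
              --out-list demo/expanded.txt --out-scores demo/scores.tsv
mirsea enrich --list demo/expanded.txt --gmt demo/knowledge_base.gmt \
              --out demo/enrichment.tsv
```

prints

```
planted scenario written to demo
fused 2 networks -> 60 miRNAs -> demo/fused.tsv
expanded 10 seeds by 5 miRNAs -> 15 total -> demo/expanded.txt
25 sets tested, 1 significant -> demo/enrichment.tsv
```

and the top of `demo/enrichment.tsv` reads

```
set_name        category  set_size  overlap  p_value       fdr           significant
planted_module  Disease   20        15       2.914610e-10  7.286524e-09  true
decoy_13        Function  20        9        1.471821e-02  1.839776e-01  false
```

The walk recovered 5 unseeded module members (hit rate against the planted
set: 50 % before expansion, 75 % after), and the planted set dominates the
enrichment ranking while every decoy stays non-significant.

The same chain runs end-to-end from raw tables (association TSV, ontology
TSV, target TSV, GO edges/annotations, PPI edge list, GMT, miRNA list) with
`mirsea run-all --config config.yaml`; the config surfaces every parameter
(Δ, c, τ, keep fraction, FDR threshold) with the defaults above and the run
writes all matrices, the expanded list, the enrichment table and a
machine-readable manifest.

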