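# wavewire

Age-dependent transcriptome dynamics for two-genotype, six-time-point
expression studies: dynamic-gene calling, expression-wave clustering,
cross-genotype wave-flow networks, gene-signature synchronization and
transcriptomal hub detection — with a synthetic-data generator that plants
every structure the pipeline is supposed to find.

## The problem

Bulk expression profiles (log2 intensity scale, e.g. RMA-normalized
microarrays) of a stem-cell population are collected from two genotypes —
wild type (WT) and a constitutively signaling mutant (`Onc`) — at six ages
(0.6, 1, 2.5, 4, 6 and 12 months) in triplicate. The questions the pipeline
answers, stage by stage:

1. **Which features are age-regulated?** For each feature, the time-point
   replicate means `X̄ᵢ` (intensity scale) are tested with

   `χ² = Σᵢ (X̄ᵢ − X̄)² / X̄`,  `df = N − 1`,

   where `X̄` is the grand mean over the `N = 6` time points, combined with a
   peak-to-trough fold-change gate `FC = 2^(max X̄ᵢ − min X̄ᵢ) ≥ 2` on the log2
   means. A feature is *dynamic* when `p(χ²) < 0.01` **and** `FC ≥ 2`.
2. **What temporal shapes do they follow?** Dynamic features are standardized
   and soft-clustered with fuzzy c-means (fuzzifier `m = 1.25`, membership
   threshold 0.5) into *expression waves*, named by the position and sign of
   their peaks (`+1+2.5+6`, `-12`, …), strongest peak first.
3. **How do waves map between genotypes?** A directed flow network from WT
   waves to mutant waves, edge weight = shared dynamic transcripts, edge shown
   only when the weight reaches 10% of the WT wave size
   (`weight ≥ ceil(0.10·size)`). Each node carries its *specificity*: the
   fraction of members not dynamic in the other genotype.
4. **Are functional gene signatures synchronized?** Per signature and
   genotype, the distribution of pairwise Pearson correlations between member
   temporal profiles is typed: 1 (centered at 0), 2 (skewed positive,
   co-regulated), 3 (skewed negative), 4 (bimodal). ssGSEA enrichment
   profiles over time feed a signature-correlation matrix whose maximal
   all-pairs-significant cliques (p ≤ 0.05, n = 6) are the functional
   clusters; a two-sample KS test compares r distributions across genotypes.
5. **Which genes anchor each wave?** Per wave, an unsigned weighted network
   `a_ij = |cor(xᵢ, xⱼ)|^β` (soft power β from scale-free topology fit);
   whole-network connectivity `kᵢ = Σ_j a_ij`; *hubs* are the top decile of
   `k` inside each wave. Hub sets are compared across genotypes, overall and
   per age phase (very early 0.6 M / early 1 M / middle 2.5–4 M / late
   6–12 M).

The synthetic generator (`wavewire.simulate`) plants all of the above —
waves, a flow map, hub blocks, signature types — with a machine-readable
truth object, so every stage can be scored (sensitivity/specificity, adjusted
Rand index, flow-edge F1, hub recall, type accuracy).

## Worked example

The numbered scripts under `analysis/` run the study end to end on a planted
dataset (all outputs under `results/`):

```bash
python analysis/01_simulate.py --seed 17        # matrix, design, truth, GMT
python analysis/02_dynamics.py                  # chi-squared + FC calls
python analysis/03_waves.py --n-waves 6         # planted count is known here
python analysis/04_flow.py
python analysis/05_signatures.py
python analysis/06_hubs.py
python analysis/07_recovery.py                  # score against truth
```

which prints (abridged):

```
planted dynamic features: WT 900, Onc 1320; 12 flow edges; 9 signatures
Onc: 1349/2000 features dynamic (67.5%)
WT: 926/2000 features dynamic (46.3%)
WT: 6 waves (+6: 149, -2.5: 152, -12: 148, +1+6: 155, +0.6: 159, +2.5: 154)
12 wave nodes, 12 edges at sensitivity 10%
Onc: type counts {1: 3, 2: 4, 4: 2}; 3 multi-signature clusters
conserved hub fraction: 43.8% overall
     dynamic_sensitivity [  WT]  1.000
                wave_ari [ Onc]  0.936
            flow_edge_f1 [both]  1.000
              hub_recall [ Onc]  0.970
           type_accuracy [ Onc]  1.000
```

Reading: both planted 6-wave structures are recovered (ARI ≈ 0.93 at the
realistic noise level of 0.25 log2 units), the planted 12-edge flow map is
recovered exactly under the 10% rule, the planted hub blocks are found with
recall ≈ 0.96, and all scorable signatures are typed correctly. The mutant
has many more age-regulated features than WT — the planted analogue of a
genotype that rewires the age-dependent program.

Without `--n-waves`, step 3 chooses the wave count as the largest one whose
centroids stay pairwise non-overlapping (correlation < 0.85) — the behavior
to use on real data, where the true count is unknown.

`wavewire.pipeline.run_all(RunConfig(...))` runs the same stages from one
config (YAML-serializable) and writes a manifest with content hashes; reruns
with the same config are bit-identical.

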