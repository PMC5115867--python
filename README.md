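# edsnet

Cross-species co-expression module detection and whole-genome-duplication
retention analysis for herbivory-induced early defense signaling (EDS).

When a chewing herbivore attacks a plant, herbivore-associated elicitors
in its oral secretions trigger a rapid (≤ 30 min) early-defense-signaling
layer — kinases, transcription factors, hormone-metabolism genes —
upstream of the jasmonate (JA) burst that mobilizes downstream defenses.
Comparing elicitor-induced leaf transcriptomes across six closely related
*Nicotiana* species lets one detect the co-expression module carrying
that layer (its induction covaries with the JA burst), test whether the
module is preserved across species, and ask an evolutionary question:
are duplicate genes created by the Solanaceae whole-genome triplication
(WGT) preferentially retained in this signaling network?

`edsnet` implements that entire chain as a reusable library with a known
ground-truth synthetic data generator, so every stage can be validated
end to end without any sequencing data:

- **simulate** — six-species phylogeny with a labelled WGT stem branch;
  negative-binomial count experiments (2 treatments × 3 replicates per
  species) with species batch effects, a planted trait-coupled module
  and decoy modules; gene families evolved by branch-wise
  duplication/loss including the stem triplication; codon-pair
  alignments at controlled Ka/Ks.
- **expression** — TMM scaling factors, FPKM on effective library
  sizes, the FPKM > 5 in ≥ 3 samples filter, the exact conditional
  negative-binomial two-group test (|FC| > 1.5, BH-FDR < 0.05), and
  parametric empirical-Bayes batch adjustment.
- **coexpression** — unsigned weighted networks (|cor|^β), topological
  overlap, soft-power selection by scale-free fit, module detection on
  1 − TOM, eigengenes / kME / kIM / hubs, module–trait coupling, and
  permutation module-preservation Z-summary scores (preserved > 10, not
  preserved < 2).
- **phylogenomics** — similarity-hit filtering, Markov clustering into
  homolog groups, LCA gene-tree/species-tree reconciliation, duplication
  dating under the aBayes > 0.9 three-branch support rule, and
  WGT/lineage-duplication retention classes with disjoint WGT pair
  lists.
- **kaks** — Nei–Gojobori-style Ka/Ks with Jukes–Cantor correction, the
  Ks < 0.02 exclusion rule, and a Fisher exact test of ω < 1.
- **enrichment** — the retention odds ratio
  `(p1/(1−p1))/(p2/(1−p2))` with exact binomial p, the
  preferential-pair-retention χ² test, and upstream TE-insertion window
  enrichment.

## Worked example

The retention-enrichment statistics can be recomputed directly from the
published worked-example counts (14,642 leaf-expressed genes of which
9,691 from multiple-copy families and 6,181 WGT-retained; 1,140
module genes of which 906 multi-copy and 587 WGT-retained; 692 conserved
core genes of which 561 and 355):

```bash
$ eds table2
     gene_set   category  k_in_set  n_set  k_genome  n_genome  pct_in_set  pct_genome     odds  odds_2dp      p_value p_printed
 complete_eds multi_copy       906   1140      9691     14642        79.5        66.2 1.978047      1.97 3.232624e-23 < 2.2E-16
 complete_eds        wgt       587   1140      6181     14642        51.5        42.2 1.453034      1.45 1.804621e-10   1.8E-10
 complete_eds        nld        87   1140      1249     14642         7.6         8.5 0.885944      0.88 8.737385e-01     0.874
conserved_eds multi_copy       561    692      9691     14642        81.1        66.2 2.187842      2.18 2.717535e-18 < 2.2E-16
conserved_eds        wgt       355    692      6181     14642        51.3        42.2 1.441987      1.44 9.200930e-07   9.2E-07
conserved_eds        nld        65    692      1249     14642         9.4         8.5 1.111633      1.11 2.257323e-01     0.226
pair retention: 120 observed vs 10.7 expected both-member pairs (chi2 1240.9, p < 2.2E-16)
```

Reading it: 79.5 % of module genes come from multiple-copy families
versus 66.2 % genome-wide (odds 1.97), and 51.5 % trace their most
recent duplication to the Solanaceae WGT versus 42.2 % (odds 1.45,
binomial p ≈ 1.8e-10) — WGT duplicates are over-represented in the
module while lineage-specific duplicates are not.  Of 4,292 WGT-derived
duplicate pairs, 120 have *both* members in the module where
independent recruitment predicts ~10.7, rejecting independence at
p < 2.2e-16: duplicated signaling genes were retained in the network as
pairs.

The full synthetic pipeline — simulation, normalization, DE, network,
modules, preservation, reconciliation, Ka/Ks, retention report — runs
with one command and prints a JSON report:

```bash
eds run --seed 1 --outdir eds_out
```

At the default study conditions (seed 1) it detects 5 modules, recovers
the planted trait-coupled module exactly after the kME > 0.75 core
filter (Jaccard 1.0), ranks it first for trait coupling
(rank-test p ≈ 7e-4), scores its preservation in an independent
replicate at Z-summary ≈ 89, dates duplication branches with 100 %
accuracy on 2,556 simulated genes, and recovers median ω 0.194 from
pairs simulated at ω = 0.2.

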