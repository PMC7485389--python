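# comorbnet

Comorbidity-network analysis of hospital discharge records.

Two diseases are *comorbid* when they occur in the same patient record more
often than chance alone would allow. Given a long-format discharge table
(one ICD-10 diagnosis per row), `comorbnet` builds the undirected
comorbidity network whose nodes are disease codes and whose edges are
statistically significant co-occurrences, characterizes its topology per
decade age bracket, decomposes it into flow-based modules, and links the
modules to biology through shared-gene overlap and pathway
over-representation. It is aimed at clinical data scientists and network
epidemiologists studying multimorbidity — cardiovascular cohorts being the
motivating case, where hubs such as cardiac arrhythmias, heart failure,
chronic kidney disease and hypertension centralize hundreds of
comorbidities.

## Method

1. **Edges** — for each disease pair with prevalences $n_A$, $n_B$ and
   co-occurrence count $k$ in a cohort of $N$ records, the one-sided
   hypergeometric tail $P(X \ge k)$, $X \sim \mathrm{Hypergeom}(N, n_A,
   n_B)$, is corrected by Benjamini–Hochberg across all pairs that co-occur
   at least once; edges require $q < \alpha$ (default 0.05, strict).
2. **Topology** — density $2E/[N(N-1)]$, average degree $2E/N$, Freeman
   degree centralization $\sum_i (k_{max}-k_i)/[(n-1)(n-2)]$, mean local
   clustering; reported for the full cohort and each age bracket.
3. **Modules** — the two-level map equation
   $L(\mathsf{M}) = q_\curvearrowright H(\mathcal{Q}) + \sum_m
   p_m^\circlearrowright H(\mathcal{P}_m)$ is minimized by a greedy
   Infomap-style single-node-move search with seeded restarts; node flow is
   PageRank (damping 0.85, unrecorded teleportation) and each module is
   labeled by its highest-PageRank disease.
4. **Genes & pathways** — comorbid pairs inside a module are scored by the
   Jaccard index $JI_{A,B} = |A \cap B| / |A \cup B|$ of their annotated
   gene sets; shared-gene lists are tested for pathway over-representation
   (hypergeometric + BH against a GMT collection).

A synthetic-cohort generator (`comorbnet.synthetic_data`) plants comorbidity
modules, hubs, age-dependent prevalence and module-aligned gene pools so the
whole pipeline is testable without access to any hospital registry.

## Worked example

```sh
comorbnet simulate --seed 3 --out sim
comorbnet network  --records sim/records.tsv --out work
comorbnet modules  --records sim/records.tsv --seed 1 --out work
comorbnet overlap  --records sim/records.tsv --modules-table work/modules.tsv \
                   --annotations sim/annotations.tsv --out work
comorbnet enrich   --overlap-table work/overlap.tsv --gmt sim/pathways.gmt --out work
comorbnet report   --records sim/records.tsv --workdir work --out work/report.md
```

`comorbnet network` prints the whole-cohort topology row, e.g.

```json
{
 "nodes": 60,
 "links": 569,
 "density": 0.3214689265536723,
 "average_degree": 18.966666666666665,
 "centralization": 0.0005844535359438924,
 "avg_clustering": 0.9982456140350877
}
```

— all 60 planted diseases enter the network and nearly every within-module
pair (3 modules × C(20,2) = 570 candidates, 569 recovered here) survives
FDR, while independent-disease nulls yield essentially no edges.
`comorbnet modules` then reports `3 modules, codelength 4.3219 bits`: the
map equation recovers exactly the three planted modules, each labeled with
its hub code. The report lists
per-bracket top-20 hubs, module labels, and the highest-Jaccard gene-sharing
pairs with their enriched pathways.

The same functions are importable as a library (`comorbnet.network_from_records`,
`comorbnet.detect_modules`, …) for use on real discharge tables with columns
`record_id`, `age`, `sex`, `icd10`.

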