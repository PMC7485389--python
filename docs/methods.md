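# Methods

## Unit of analysis and record validation

The cohort unit is the discharge record ("case"), not the unique patient:
repeat admissions remain separate records, matching how specialized-hospital
registries report their populations. A record carries an integer age in
years, a sex in {female, male, unknown}, and a *set* of ICD-10 codes —
duplicates within one record collapse silently, and all codes on a record
are treated symmetrically (the registry distinguishes a principal diagnosis,
but co-occurrence is an unordered relation, so we do not).

Codes are validated syntactically against the dotted pattern
`letter + two digits (+ "." + one alphanumeric)`, with `X` accepted as the
registry's subcategory placeholder (e.g. `I10.X`). Exclusion is tallied by
reason (`incomplete`, `invalid_age`, `non_existing_code`) so that
`n_input = n_retained + Σ tallies` is auditable from the log. A record with
more than 6 distinct codes (principal + five main comorbidities in the
source system) triggers a warning, not an error: the cap describes the
upstream EHR procedure, not a schema guarantee.

Age brackets are the ten decade intervals [0,10], [11,20], …, [81,90] and
an open-ended [91,∞) that keeps the conventional "91-100" label; they
partition the age axis, and stratification is checked to be disjoint and
exhaustive.

## Edge inference

For a pair of diseases carried by $n_A$ and $n_B$ of $N$ records and
co-occurring in $k$, the null of random assortment gives
$k \sim \mathrm{Hypergeom}(N, n_A, n_B)$; the edge statistic is the
one-sided upper tail $P(X \ge k)$ (enrichment only — a *depletion* of
co-occurrence is not a comorbidity). Numerics go through the hypergeometric
survival function, which is log-space stable; an exhaustive subset-
enumeration oracle pins it down for all populations $N \le 12$.

Multiple-testing uses Benjamini–Hochberg. Two reproducibility choices are
deliberate and documented because they fix the family size $m$:

* only pairs with $k \ge 1$ are tested — never-co-occurring pairs would
  inflate $m$ with $p = 1$ entries;
* each network is its own FDR family: the full cohort and every age bracket
  are corrected independently, since each is reported as a standalone
  analysis.

Edges require $q < \alpha$ strictly (default $\alpha = 0.05$) and
$k \ge$ `min_k` (default 1; no co-occurrence floor). Nodes are
edge-incident codes only; a flag admits isolated prevalent codes. Edge
metadata (k, p, q) is stored but the graph is treated as unweighted for
topology and module detection.

## Topology

Density $2E/[N(N-1)]$, average degree $2E/N$, Freeman degree centralization
$\sum_i (k_{\max} - k_i) / [(n-1)(n-2)]$ (equivalently
$(n\,k_{\max} - 2E)/[(n-1)(n-2)]$ from aggregate counts), and the mean
local clustering coefficient with degree-<2 nodes contributing 0. Freeman
centralization is 1 exactly on a star and 0 on any regular graph, and from
the published whole-network counts (n = 1,473, E = 20,543, hub degree 707)
it reproduces the printed 0.462 — which is why it is the centralization
index adopted here. Degenerate sizes (n < 2 for density, n < 3 for
centralization) yield NaN fields rather than exceptions.

## Flow modules

Node flow is PageRank on the undirected graph: a walker follows a uniformly
random incident edge with probability $d$ (damping, default 0.85) and
teleports uniformly otherwise; the power iteration (via networkx) runs to an
L1 change below `tol` (default 1e-12) and is cross-checked against the dense
linear solve of $(I - dP^{\mathsf T})x = (1-d)/n$.

A partition $\mathsf{M}$ is scored by the two-level map equation

$$L(\mathsf{M}) = q_\curvearrowright H(\mathcal{Q})
  + \sum_m p_m^\circlearrowright H(\mathcal{P}_m),$$

the expected description length (bits) of the walk under one index codebook
for module switches and one codebook per module. Teleportation is
*unrecorded*: it shapes visit rates but is excluded from module exit flows,
so $q_m = d \sum_{i \in m} p_i \cdot \mathrm{out}_i / \deg_i$ counts only
edge-crossing walk flow. A one-module partition therefore scores exactly the
Shannon entropy of the visit rates, and two disconnected 3-cliques at
$d \to 1$ score $\log_2 3$ bits under the two-module partition — both serve
as exact anchors in the tests. The implementation maintains the equivalent
closed form $L = \mathrm{plogp}(Q) - 2\sum_m \mathrm{plogp}(q_m) +
\sum_m \mathrm{plogp}(q_m + F_m) - \sum_i \mathrm{plogp}(p_i)$ so that a
single-node move touches only the source and destination modules.

Search is greedy agglomeration: all-singletons start, sweeps over a
seed-shuffled node order moving each node to the neighboring module (or a
fresh singleton) with the largest codelength decrease, repeated until a
sweep makes no move, best of `n_restarts` (default 10) shuffled restarts.
The result is floored at the one-module codelength, module ids are
canonicalized by smallest member (making the output invariant to node
relabeling), and the whole procedure is deterministic given
(seed, n_restarts). Exhaustive partition search (restricted-growth-string
enumeration) verifies optimality on small graphs; a full multi-level
Infomap with submodule moves is out of scope at this problem size. Each
module is labeled by its member with the highest PageRank visit rate, ties
broken lexicographically.

## Gene overlap and enrichment

The disease→gene table is an input contract (a curated ClinVar-style
mapping is not mechanically reproducible); symbols are uppercased and rows
with invalid codes dropped with a tally. Jaccard similarity
$|A \cap B| / |A \cup B|$ is defined as 0 with a warning when both sets are
empty. Ranked overlap considers only *significant comorbidity edges within
a module* (not all member pairs), both endpoints annotated; ties break by
shared-gene count then code pair.

Over-representation reuses the same hypergeometric and BH primitives as
edge inference: overlap $k$ of an $n$-gene list with a $K$-gene pathway in
a $U$-gene universe. The universe defaults to the union of the GMT
collection's genes (overridable); list genes outside the universe are
dropped before testing and logged. Significance is $q < 0.05$.

## Synthetic cohorts

The generator emulates the statistical shape of the motivating registry
rather than its content: co-occurrence is induced by a latent module per
record — a record draws a hidden module, then samples its 2–6 distinct
codes with module diseases up-weighted — which matches the intuition that
patients accumulate diseases from a physiopathological cluster and gives a
single controllable lift. Defaults (chosen once as the study conditions):

| parameter | default | why |
|---|---|---|
| n_records | 5,000 | large enough for exact tests to resolve planted pairs, small enough for seconds-scale runs |
| n_diseases / n_modules | 60 / 3 | three letter-coded modules (Q/I/N: congenital-, ischemic-, renal-flavoured) of 20 diseases |
| within_module_cooccurrence_boost | 40 | odds multiplier; gives ≈95% of a record's codes from its latent module, separating planted pairs from chance by several null SDs; boost = 1 is the exact independence null |
| codes per record | 2–6 uniform | principal + up to five comorbidities |
| hub_per_module / hub_weight | on / 4× | one oversampled hub disease per module, emulating star-like bracket networks |
| age_profile | Gaussian bracket weights, peaks spread young→old | congenital module concentrated in 0-10, systemic modules in later decades |
| annotation_probability | 0.4 | matches the ~37–43% ClinVar coverage reported for real modules |
| genes_per_module_pool / background pool | 40 / 100 | annotated diseases sample 75% of their module pool + Poisson(3) background genes → within-module JI ≈ 0.5, between ≈ 0 |
| pathways | 1 aligned per module + 5 decoys | the aligned pathway equals the module pool, so a within-module shared-gene list should rank it first |

Everything is deterministic given `seed`; emitted files (records TSV,
annotation TSV, GMT, ground-truth JSON) are byte-identical across runs.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: ICD-10 ontology structure (no hierarchical code
relatedness), overlapping or nested disease modules, temporal ordering of
diagnoses, sex-specific effect sizes beyond sampling, coding error modes,
and the heavy-tailed prevalence of real registries. Recovery results on
synthetic cohorts demonstrate correctness of the machinery, not clinical
validity.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery analysis at 10 generator
seeds × 5,000 records and the null control at 20 seeds × 2,000 records,
sizes chosen so the whole suite completes in well under a minute while the
planted-vs-null separation is many standard deviations wide. Codelength
comparisons use a 1e-9-bit slack; greedy-move acceptance uses a 1e-12
threshold so exact ties never cycle. Published-table identity checks accept
|difference| ≤ 5e-4, i.e. agreement at 3-decimal rounding without assuming
a half-even vs half-up rounding convention (one printed average-degree
entry, 12.3125 → 12.313, is rounded half-up).

## Known limitations

Two-level (not hierarchical) map equation; unweighted walk dynamics (edge
significance does not modulate flow); greedy single-node moves can in
principle miss the optimum on adversarial graphs (mitigated by restarts and
the one-module floor); ICD-10 validation is syntactic only — no code-list
lookup; no gene-symbol synonym resolution; ORA results depend on the chosen
universe, as they do in any enrichment tool.
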