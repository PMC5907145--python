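# Methods

## Model

`metnetwalk` predicts unobserved disease–metabolite associations from a
bipartite annotation table under one assumption: metabolites annotated to
similar diseases are functionally related, so an unannotated metabolite
that sits close, in a similarity network, to a disease's known metabolites
is a plausible new association. The pipeline has four stages.

**Disease similarity.** A disease is represented as a non-negative weight
vector over the global (lexicographically sorted) metabolite ordering and
compared by cosine. The annotation weights themselves are pluggable:

- `binary` (default): w = 1 iff the metabolite is annotated to the
  disease. The cosine then reduces to |G₁∩G₂| / √(|G₁||G₂|) over the
  annotation sets, which is what the test oracles exploit.
- `idf`: membership × log(n_diseases / diseases-per-metabolite), so a
  metabolite annotated to every disease carries zero information. Vectors
  are left unnormalized; the cosine normalizes.

When a disease-ontology DAG is supplied, the cosine is scaled by
|G₁||G₂| / |G_MICA|². Annotations are first propagated child→ancestor
(true-path rule); the MICA of two diseases is their common ancestor
(ancestor sets include the term itself) with the smallest propagated
annotation set, ties broken lexicographically for determinism. Under
propagation, ancestor sets are supersets of their descendants' sets, so
the factor is ≤ 1 and clamping is a no-op; without propagation the factor
could exceed 1, so matrix entries are clipped to [0, 1] by default
(`clamp=False` disables this). Diseases missing from the DAG degrade to
factor 1 with a warning rather than erroring — ontology coverage is never
complete. The diagonal is forced to exactly 1, which the best-match stage
relies on when disease groups overlap.

**Metabolite similarity** is the best-match average over the two
metabolites' disease groups (see README for the formula). It is symmetric,
bounded in [0, 1] by construction when the disease matrix is, and equals 1
on the diagonal because every disease's best match in its own group is
itself. The implementation is vectorized (per-metabolite best-match
columns, then one matrix product) and is verified in the tests against a
literal double-loop evaluation.

**Network.** Off-diagonal pairs with similarity strictly greater than the
threshold (default 0.7) become weighted undirected edges; metabolites
incident to no edge are dropped and reported. Strict inequality is fixed
for determinism; the threshold is a parameter, so a ≥ convention is
reachable by nudging it. Edge lists are stored smaller-id-first.

**Random walk with restart.** The walk iterates
P_{t+1} = (1−γ)·A·P_t + γ·P₀ with A the *column*-normalized weighted
adjacency, P₀ uniform over the query disease's in-network metabolites,
and γ = 0.85. The iteration is a contraction with factor 1−γ, so it
converges geometrically from any start; we stop when the L1 step change
drops below the tolerance. Seeds are excluded from the ranked output by
default (they are the known associations); ties share the minimum
(competition) rank, secondarily ordered by id. A disease none of whose
metabolites survived the threshold yields an explicit "unreachable"
record instead of a ranking.

Row normalization (P = D⁻¹A) is kept alongside for the classical chain
quantities: the stationary distribution π ∝ weighted degree (satisfying
π·P_row = π) and the fundamental matrix. For the latter, both
(I − P + W)⁻¹ (`standard_plus`, the classical definition, rows summing
to 1) and (I − P − W)⁻¹ (`as_printed_minus`) are implemented; neither is
used by the prioritization itself.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `scheme` | `binary` | disease annotation weights (binary or idf) |
| `threshold` | 0.7 | minimum metabolite similarity for a network edge (unitless, [0,1)) |
| `gamma` | 0.85 | restart probability of the walk |
| `tolerance` | 1e-10 | L1 convergence bound of the walk iteration |
| `max_iter` | 1000 | iteration cap (far above the contraction bound ≈ 13 at γ=0.85) |

γ = 0.85 and threshold 0.7 are the values the method was published with;
the tolerance and cap are our choices — at γ = 0.85 the contraction bound
guarantees convergence to 1e-10 in ~13 iterations, so 1000 is effectively
"never stop early".

## Leave-one-out validation

Each pair (d, m) is withheld; the metabolite similarity matrix and
network are rebuilt from the remaining pairs; d's remaining in-network
metabolites seed a walk; m is the positive, and all network metabolites
not associated with d *in the full prior table* are the negatives.
Scores pooled across all folds give one rank-based (Mann–Whitney) AUC;
per-disease AUCs and the mean per-fold AUC are reported alongside, since
pooling vs. averaging is a reporting choice.

Two deliberate choices: (1) folds whose withheld metabolite leaves the
network, or whose disease keeps no in-network seed, are *recorded as
skipped* with a machine-readable reason, not silently dropped or scored
0 — at threshold 0.7 such folds are common and the denominator must be
transparent; (2) `fixed_dsim=True` computes disease similarity once from
the full table instead of per fold. Removing one pair perturbs exactly
one disease's weight vector, so the approximation is tight, and the mode
used is stamped into the result.

## Synthetic data

The generator emulates the structure of curated annotation sets: diseases
and metabolites are partitioned round-robin into k groups (deterministic
sizes, easy to reason about in tests); same-group pairs are associated
with probability p_in, cross-group pairs with p_out; entities left
isolated are patched with one within-group association so the
no-isolated-entity invariant holds without rejection sampling. Defaults
(40 diseases × 60 metabolites, 4 groups, p_in = 0.8, p_out = 0.02) give a
table of roughly 520 pairs whose planted structure a working pipeline
must recover: pooled LOOCV AUC ≈ 0.94 at seed 7.

The null calibration uses the same generator with a single group at
density 0.3. The density was chosen so that, at the default 0.7
threshold, well over 200 folds keep their withheld metabolite in the
network (the requirement is on fold count; AUC ≈ 0.5 is structural for a
structureless table). Measured: AUC 0.508–0.511 over ~700 scored folds.

What a green synthetic test does *not* establish: real annotation tables
have heavy-tailed degree distributions (one metabolite annotated to
hundreds of diseases, many diseases with a single metabolite),
correlated extraction noise from text mining, and ontology-structured
disease identity, none of which the block model reproduces. Absolute AUC
values on real data will differ; the tests establish correctness of the
machinery and directional behavior (structure ⇒ high AUC, no structure
⇒ 0.5).

A companion generator produces random rooted trees as stand-in
ontologies (each node attaches to a uniform existing node with spare
child capacity), used to exercise propagation and the MICA factor.

## Numerical choices

- Walk convergence: L1 norm; iterative fixed points are checked against
  a direct solve of (I − (1−γ)A)P = γP₀ to 1e-8 L∞ in the tests.
- Cosine matrices are symmetrized ((M + Mᵀ)/2) to kill round-off
  asymmetry before validation at 1e-9.
- AUC uses midranks (scipy `rankdata`), i.e. half credit for ties;
  scikit-learn's `roc_auc_score` is the independent cross-check in tests,
  never the implementation.
- Degenerate inputs: empty tables, isolated ids, zero-norm weight
  vectors, empty seed sets, thresholds ≥ 1 and non-monotone histogram
  bins are all rejected with specific errors; an all-below-threshold
  similarity matrix yields an empty network with a warning, not an
  exception.

## Known limitations

- The disease weight vectors are annotation-derived only; the original
  information-flow weights from gene functional networks are out of
  scope (the weight scheme is pluggable precisely so externally computed
  vectors or similarity matrices can be dropped in via
  `--disease-sim`).
- Full per-fold rebuild of disease similarity is O(folds × pipeline);
  fine at desk scale (hundreds of pairs), slow beyond ~10⁴ pairs —
  use `fixed_dsim`.
- The MICA interpretation (smallest propagated annotation set) is the
  standard reading of most-informative common ancestors; other
  information-content definitions (e.g. corpus frequency) are not
  implemented.
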