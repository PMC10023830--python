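# Methods

This note documents the models, estimators and design choices behind
`drugnets`, and what the synthetic data does and does not emulate.

## Networks and their construction

A DDI network is the simple undirected graph G = (V, E) whose nodes are
approved human drugs and whose edges are reported drug–drug interactions.
Interaction listings in release XML are mirrored in principle but not always
in practice, so construction applies **symmetric closure**: an undirected
edge {a, b} exists if either record lists the other.  A DTI network is
bipartite and directed drug→target; targets are deduplicated by identifier
across drugs and restricted to the configured organism ("Humans" by default,
case-insensitive).  In both kinds, entities with no surviving interaction
are omitted, so every node has degree ≥ 1.

The **approved-drug filter** keeps a record iff it carries the `approved`
group label and carries neither `withdrawn` nor `vet_approved`.  Many
approved drugs also carry an `investigational` co-label; the default
(`permissive`) policy keeps them, since an approved drug under further study
is still an approved drug, and excluding them shrinks the network well below
the sizes reported for real releases.  A `strict` policy that also excludes
any `investigational`/`experimental` co-label is available as a switch.

The **non-edge universe** of a network is every structurally permitted node
pair without an edge: all unordered drug pairs for DDI, all drug×target
pairs for DTI, on the *current* node set (drugs already excluded as isolated
are not candidates — the perturbation analysis below perturbs the known
network, whose node set is fixed).  The universe is never materialised:
membership, exact size, lazy enumeration and uniform without-replacement
sampling (integer pair-index rejection sampling, O(m) memory) are provided
instead.

## Metrics and centralities

Summary metrics follow the standard definitions: ⟨d⟩ = 2|E|/|V| (with in-,
out- and per-partition variants for directed/bipartite networks), average
clustering ⟨c⟩ (identically 0 for bipartite networks, which are
triangle-free), density r = 2|E|/(|V|(|V|−1)) using the total node count for
both network kinds, and average shortest-path length ⟨s⟩ and diameter φ.
Path metrics are computed by BFS on the **undirected view** over node pairs
of the **largest connected component**: distances between disconnected pairs
are undefined, and for a directed bipartite graph target→anything distances
would be trivially infinite.  Both are evaluated from one
`scipy.sparse.csgraph` distance matrix, so summaries of few-thousand-node
networks take well under a second.

Centralities (all on the undirected view):

* **degree** (plus in-/out-degree for DTI);
* **betweenness**, normalised by 2/(|V|(|V|−1)).  The default is Brandes'
  fractional count σ_jk(v)/σ_jk.  A `pair_indicator` variant is retained in
  which a pair (j,k) contributes 1 to every interior node lying on *some*
  shortest j–k path — a literal reading of the binary-σ definition.  The
  indicator dominates the fractional variant pointwise; both are tested
  against exhaustive path enumeration.
* **closeness** γ(v) = (Σ_{u∈C\{v}} s(v,u))⁻¹ scaled by (|C|−1)/(|V|−1),
  where C is v's component, so values are comparable across components of
  different sizes.  Note this is *not* the convention that multiplies by
  (|C|−1) first; the scaling used here preserves the raw
  inverse-distance-sum on connected graphs (P₃ centre → 0.5, K₄ node → 1/3).
* **eccentricity**: max BFS distance within the component.
* **eigenvector**: principal adjacency eigenvector per component, by power
  iteration on the shifted operator A + I (same eigenvectors as A;
  the shift suppresses the ±λ oscillation that raw power iteration exhibits
  on bipartite components).  L2-normalised, nonnegative; convergence when
  successive iterates differ by < 1e−10 in max-norm, error after 1000
  iterations.
* **PageRank** with damping 0.85 on the undirected view (each edge as two
  directed links); values sum to 1.

## Power-law fitting

Degree (and other centrality) distributions are fitted with the
Clauset–Shalizi–Newman procedure: the exponent α of P(x) ∝ x^−α is the MLE
on the tail x ≥ x_min, and x_min is chosen by scanning unique sample values
and minimising the Kolmogorov–Smirnov distance between the empirical tail
and the fitted model (ties broken toward smaller x_min; scans over more than
512 candidates are thinned by quantile).  Integer-valued samples use the
discrete (Hurwitz-zeta-normalised) likelihood, maximised numerically on
α ∈ (1, 20]; continuous samples use the closed form
α̂ = 1 + n/Σ ln(x_i/x_min).  Fits whose tail holds fewer than 10 points are
flagged, not rejected; all-equal samples raise a degenerate-sample error.

The widely quoted discrete approximation α̂ ≈ 1 + n/Σ ln(x_i/(x_min − 0.5))
is accurate only for x_min ≳ 6 (at x_min = 1 it deviates from the exact MLE
by ≈ 0.5); the test suite checks agreement in the regime where the
approximation is valid.

`loglog_slope` provides the naive alternative some robustness analyses
compare: the OLS slope of log₁₀(count/bin-width) against log₁₀(value) on a
log-binned histogram.  Width normalisation makes an exact power law give
slope ≈ −α and a flat *density* give slope 0.  The injection simulation uses
the MLE by default (`alpha_mode="mle"`), with `"loglog"` available.

A discrete power-law sampler (inverse-CDF on the explicitly normalised pmf,
truncated at 10⁶ where the residual mass is O(x_max^{1−α})) backs both the
synthetic generator and estimator-recovery tests.

## Benford first-digit testing

Benford's law P(f) = log₁₀(1 + 1/f), f ∈ {1..9}, is the distribution of
first significant digits of quantities spanning several orders of magnitude;
deviation of a centrality's first-digit distribution is used as a
data-quality signal.  Digits are extracted by power-of-ten scaling (never
string formatting).  Zero and non-finite values carry no significand and are
excluded (betweenness of leaves is commonly exactly 0); the exclusion count
is reported.  Three distances are reported: Pearson's χ² (used as a raw
distance — no p-value is attached), the 1-D Wasserstein on the ordered digit
support with unit ground distance (Σ|CDF_obs − CDF_Benford|), and the sum of
squared deviations of the proportion vectors.  All three are zero iff the
observed proportions equal Benford's exactly; because Benford proportions
are irrational, a finite sample matches only up to count rounding, and the
tests bound the distances by the corresponding rounding/sampling noise.  A
useful calibration: for an *exactly conformant* generator (e.g. a
log-uniform variable over an integer number of decades) the expected digit
Wasserstein is pure multinomial noise, ≈ 2.5/√n — about 0.025 at n = 10⁴ and
0.008 at n = 10⁵.  Conformance claims are therefore resolved at n = 10⁵.

## Robustness to unknown interactions

The injection simulation asks how stable centrality-based drug rankings are
if some currently unreported interactions turn out to be real.  For each
rate q in a grid (default 0.01..0.1) and each of R = 100 replicates:

1. sample m = round(q·|E_t∖E|) distinct non-edges uniformly (bipartite-
   respecting for DTI) and add them to G, giving G′;
2. compute the chosen centrality (degree or betweenness) on G and G′;
3. record the Kendall τ-b between the two rankings, and the fitted power-law
   exponent of the centrality distribution on G′.

Curves report per-q mean, variance and range of τ, mean/variance of α, and
the reference α at q = 0.  The τ-b variant corrects for ties, which are
pervasive in degree rankings; it is undefined when a ranking is constant, in
which case the replicate is excluded from the mean and counted (never
coerced to 0).  A τ-a variant (untied n(n−1)/2 normalisation, always defined
for n ≥ 2) is available.  Randomness is organised as per-(seed, q-index,
replicate) spawned substreams, so identical inputs give identical curves.

The rate convention is genuinely ambiguous in the field: relative to the
non-edge universe (|E_t∖E| ~ n²/2, the default here, consistent with an
"added edges ∝ n²" complexity budget) or relative to the known edge set
(m = round(q·|E|), available as `q_mode="edges"`).  The two differ by orders
of magnitude on sparse networks, and only the edges-relative mode leaves
τ ≳ 0.8 at q = 0.1 on sparse scale-free DTI networks; both are reported by
the acceptance script.  Betweenness-based runs are gated to networks below
2,000 nodes by default, reflecting the O(n·|E|) per-replicate cost on
densifying networks.

## Synthetic data

The generator produces study conditions shaped like real versioned releases:

* **DDI series**: version 1 realises a discrete power-law degree sequence
  (exponent 2.5 by default, truncated at n−1) via configuration-model stub
  pairing with self-loop/multi-edge rejection, then adjusts to the scheduled
  edge count; each later version adds edges by degree-proportional
  (preferential, +1 attractiveness) endpoint sampling until its scheduled
  density — edge supersets across versions, emulating monotone knowledge
  accretion.  An optional `removal_fraction` (default 0) deletes a random
  edge fraction between versions to emulate curation/filtering.  The default
  schedule (0.019, 0.06, 0.128) spans the sparse-to-dense trajectory
  observed across a decade of real releases; generated densities land within
  rounding (±0.5 edge) of schedule.
* **DTI**: drug out-degrees and target in-degrees are both drawn from the
  discrete power law and rescaled so each side sums to
  round(`dti_mean_degree`·n_drugs) (default mean 3.6, matching the real
  sparse regime), then joined by bipartite configuration-model pairing.
  A pure preferential-attachment process over a *fixed* target set was
  rejected: it yields Pólya-urn (geometric-tailed) in-degrees, not the
  power law with α ≈ 2.5–3.5 that real target degree distributions show.
* **XML fixtures**: networks are serialised in the DrugBank dialect read by
  the parser (drug ids, names, group labels, one-sided interaction listings
  — exercising symmetric closure — and human targets), deterministically
  ordered so identical seeds give byte-identical files, with a JSON manifest.
  Group labels are sampled per drug from configurable per-label
  probabilities (default: 88% approved, with small co-label fractions).

What the generator does **not** emulate: real per-version node counts,
interaction types/severities, target biology (every synthetic target is
"Humans"), the correlation between a drug's DDI and DTI degrees, and the
add-then-filter zigzag of real version histories (only the optional uniform
removal stands in for filtering).  Passing tests therefore demonstrate the
correctness and stability of the *methods* under realistic statistical
structure, not properties of any real database release.

Default problem sizes (hundreds to a thousand drugs in tests and the
acceptance script) were chosen so a full pipeline run completes in seconds
while keeping the fitted-exponent and density regimes representative;
published per-version node/link counts enter the analysis as printed inputs
to the metric identities rather than by re-deriving them from account-gated
downloads.

## Numerical choices and degenerate inputs

* Node ordering is lexicographic everywhere; all outputs are deterministic
  and diffable.  Evolution tables round to 6 significant digits.
* Randomness: one root seed per generator/simulation; substreams derived via
  `numpy` SeedSequence spawning with fixed keys.
* Empty networks are valid serialisation inputs; single-node components get
  closeness 0 and eccentricity 0; ⟨s⟩/φ are reported absent when no
  component has ≥ 2 nodes.
* Injection with m rounding to 0 returns the network unchanged (logged);
  m exceeding the universe is capped with a warning.
* Duplicate drug ids keep the first record; drugs listing themselves as
  interaction partners have the self-listing dropped; records without an id
  are skipped and counted.

## Known limitations

* The pair-indicator betweenness variant is O(n³)-ish and intended for
  small networks and cross-checks, not production runs.
* The x_min scan refits the exponent per perturbed replicate by default;
  a `fixed` mode reuses the reference x_min, and the two can disagree
  noticeably on heavily perturbed distributions.
* Closeness and eigenvector conventions differ across the literature; the
  conventions used here are stated above and in the docstrings, and should
  be checked before comparing against other tools' output.
* Real releases carry far richer schema (pathways, enzymes, transporters,
  SNP effects); the parser deliberately reads only ids, names, groups,
  interactions and targets.
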