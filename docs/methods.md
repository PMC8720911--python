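# Methods

## Data representation

A naming-task corpus is a list of `language speaker chip term` records.  The
stimulus grid has 8 chromatic rows (letters B–I, a lightness scale) by 40 hue
columns; hue is circular, so column 40 is adjacent to column 1, while rows do
not wrap.  The 10 achromatic chips (rows A/J and column 0) are excluded from
all analyses.  Each participant's responses are formatted as a *naming
matrix*: one row per distinct term, 320 columns in a fixed canonical chip
order (row-major over rows B–I and columns 1–40), every column summing to
exactly one.  Participants who did not name every chromatic chip are dropped
with a warning rather than imputed, because the feature transform requires a
total labeling.  Excluded languages are configuration, not code: surveys
typically omit a handful of languages for data-quality reasons, and the
identities belong to the data release, not the package.

## Neighbor-agreement features

The transform replaces term identities with partition structure.  For every
ordered pair of grid-adjacent chips (reference, neighbor) the feature is 1 if
the participant named both chips alike.  The adjacency scheme is
configurable (`NeighborScheme`):

- `kind` — von Neumann 4-neighborhood or Moore 8-neighborhood;
- `directed` — whether both orientations of each pair are stored;
- `hue_wraparound` — whether column 40 borders column 1.

The default is Moore-8, directed, with wraparound, giving
6 rows × 40 × 8 + 2 edge rows × 40 × 5 = **2,320** attributes — the standard
dimension for this representation.  The two descriptions in circulation for
this transform (4-neighborhood, unordered pairs vs. a 2,320-long vector)
are mutually inconsistent; only the ordered 8-neighborhood count reproduces
2,320, which is why that is the default while the alternatives remain
available (von Neumann undirected has 600 attributes, Moore undirected
1,160).  Directed vectors carry each unordered pair twice with equal values
(the same-name relation is symmetric), so the two variants are
information-equivalent; similarity measures are unaffected by the choice.

Pair order is deterministic: reference chips in canonical order, neighbors
in the fixed offset order N, S, E, W, NE, NW, SE, SW.  The transform depends
only on the partition, never on term strings (verified by property test),
and merging two of a participant's categories can only turn 0-entries into
1-entries.

## The mixture model

Observations are binary vectors $X_i \in \{0,1\}^D$.  The generative model:

- sticks $v_k \sim \mathrm{Beta}(1, \alpha)$ for $k < K$, $v_K = 1$;
  weights $\pi_k = v_k \prod_{l<k} (1 - v_l)$;
- emissions $\theta_{kd} \sim \mathrm{Beta}(\beta_1, \beta_2)$ i.i.d.;
- assignments $Z_i \sim \mathrm{Cat}(\pi)$; data
  $x_{id} \sim \mathrm{Bernoulli}(\theta_{Z_i d})$.

The truncation at $K$ realizes the Dirichlet process approximately; with
$K$ far above the number of occupied clusters the truncation is inert and
the occupied count $K^\*$ is data-driven.  Component indices are **not**
exchangeable under stick-breaking: the prior is size-biased in $k$
(earlier sticks expect more mass), so permuting component labels changes
the variational objective slightly and can steer coordinate ascent to a
different local optimum.  Observations, by contrast, are exchangeable, and
row-permutation equivariance is tested.  A finite symmetric-Dirichlet
approximation would make components exchangeable too; explicit
stick-breaking was chosen because it makes the ELBO of the truncated DP
well-defined without further approximation.

### Variational inference

Mean-field family $q(Z)\,q(v)\,q(\theta)$ with categorical $q(Z_i)$
(responsibilities $r_{ik}$), Beta $q(v_k)$ for $k<K$ (the last stick
degenerate at 1), and Beta $q(\theta_{kd})$.  One CAVI sweep:

1. $r_{ik} \propto \exp\big(\mathbb{E}[\log \pi_k] + \sum_d x_{id}\,
   \mathbb{E}[\log \theta_{kd}] + (1-x_{id})\,\mathbb{E}[\log(1-\theta_{kd})]\big)$,
   normalized per row by log-sum-exp;
2. $\gamma_{k1} = 1 + \sum_i r_{ik}$, $\gamma_{k2} = \alpha + \sum_i
   \sum_{j>k} r_{ij}$;
3. $a_{kd} = \beta_1 + \sum_i r_{ik} x_{id}$,
   $b_{kd} = \beta_2 + \sum_i r_{ik} (1 - x_{id})$;
4. ELBO evaluation (expected log-likelihood, assignment prior, stick prior,
   emission prior, and the three entropies).

Each step is an exact coordinate maximization, so the ELBO is
non-decreasing across sweeps; the implementation raises if a decrease
beyond round-off slack (1e-8, relative) is ever observed.  All expectations
use digamma/log-Beta special functions in log space: with $D \approx 2{,}320$
attributes, direct products underflow.

Convergence: relative ELBO change below `tol` (default 1e-6) or `max_iter`
(default 500) sweeps.  The fit runs `n_restarts` (default 5) seeded
restarts — restart seeds derive deterministically from the config seed — and
keeps the best-ELBO run.  Restarts matter: on well-separated data a single
run occasionally converges with two true clusters merged; five restarts
reliably escape such local optima.  Initialization draws each row's
responsibilities from a symmetric Dirichlet (concentration 1) and applies
one stick/emission update pass.  Argmax ties in hard assignment resolve to
the lower cluster index for determinism.

### Exact oracles

Two enumeration oracles validate the implementation on small instances:

- `crp_exact_log_evidence` — the untruncated DP marginal likelihood by
  summation over all set partitions (Chinese-restaurant prior times the
  closed-form Beta-Bernoulli block marginals); feasible for $N \le 8$.
- `truncated_exact_log_evidence` — the exact marginal of the $K$-truncated
  stick-breaking model by enumeration of all $K^N$ label assignments, with
  the stick prior integrated in closed form per assignment.  This, not the
  CRP evidence, is the quantity the truncated CAVI ELBO lower-bounds, and
  the test suite asserts that bound on random instances.

In the single-cluster conjugate case ($K=1$) the mean-field family contains
the exact posterior, so the converged ELBO must equal the closed-form
Beta-Bernoulli marginal to near machine precision; this is asserted at 1e-9.

### Hyperparameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| $\alpha$ | DP concentration | 1000 | selected operating point of the ELBO random search; the fit is insensitive to it over $10^0$–$10^4$ |
| $\beta_1=\beta_2$ | emission Beta shapes | 0.9 | search is restricted to $(0,1)$, where the Beta density favors near-deterministic attributes; 0.9 is the shipped operating point |
| $K$ | truncation | 100 | far above expected motif counts; occupied $K^\* < 100$ throughout |
| `tol` | relative ELBO tolerance | 1e-6 | desk-scale reproducibility |
| `n_restarts` | seeded restarts | 5 | escapes merged-cluster optima |

`random_search` draws $\alpha$ log-uniformly over $10^0$–$10^4$ (a range
containing the operating point) and $\beta$ uniformly on $(0,1)$, one fit
per trial, and ranks trials by ELBO; `beta_sensitivity_report` bins mean
ELBO by $\beta$ deciles and $\log_{10}\alpha$ deciles and reports Spearman
rank correlations.

## Post-cluster measures

- **Centroid (modal map)** — per chip, the group's most frequent term (ties
  to the lexicographically smallest token); for cross-language clusters,
  which share no vocabulary, the per-attribute majority bit of the cluster's
  feature rows (ties to 1), which minimizes total Hamming distance to the
  members.
- **Boundary heatmap** — per chip, the mean over participants and incident
  undirected pairs of the disagreement indicator; an 8 × 40 matrix in
  $[0,1]$.  The graded mean (rather than a binary any-neighbor-differs flag)
  distinguishes weak from sharp category boundaries.  Heatmaps merge
  linearly: a pooled group's heatmap is the participant-weighted mean of the
  subgroup heatmaps.
- **Schematic similarity (SS)** — the fraction of adjacency pairs on which
  two participants' partitions agree.  Identical schemes score 1; a
  single-term scheme against an all-singleton scheme scores 0.  $1-\mathrm{SS}$
  is a normalized Hamming distance, hence a metric.
- **Group error** — for one language's participants, the fraction of
  unordered pairs assigned to different clusters: 0 when the language
  clusters together, 1 when every participant is alone.  It is the unique
  simple pair statistic meeting both endpoints exactly.  A distance-weighted
  variant (each split pair scaled by $1-\mathrm{SS}$ of the two cluster
  centroids) is reported separately; its absolute scale is not comparable
  to the default.

SS and group error are reconstructions pinned to their published endpoint
behaviors; the originally published formulas are not public, so exact
numerical agreement with other software is not claimed.

## Synthetic corpora

`simulate` generates survey-format corpora from latent motifs so the whole
pipeline is testable without any download.  A motif is a nearest-seed
(Voronoi) partition of the grid under L1 distance with circular hue columns
(ties to the lowest seed index), which guarantees non-empty, grid-connected
categories.  A participant copies a motif and, per chip independently with
probability ε, takes the label of a uniformly chosen von Neumann neighbor —
noise that only perturbs category boundaries, preserving spatial coherence.
Defaults: 8 motifs of 6 categories, ε = 0.03, 20 languages × 25
participants (500 in total), uniform motif mixture per language (real
surveys show substantial within-language motif diversity).

What the generator emulates: complete per-participant labelings, contiguous
categories, boundary-localized disagreement, motif sharing across languages.
What it does not: variation in the *number* of terms across participants of
one motif, boundary placements differing by several chips, chip-level
response noise far from boundaries, or any perceptual (rather than
grid-topological) structure.  Consequently, within a recovered cluster the
overwhelming majority of feature columns are unanimous (all-0 or all-1).
This has a measurable consequence for hyperparameter sensitivity: the
Beta-Bernoulli marginal of a unanimous column strictly *decreases* in β
(spikier priors reward determinism), while only mixed columns reward larger
β, so on these synthetic corpora the ELBO *declines* with β (Spearman
correlation ≈ −0.87 over 40 search trials at every admissible ε; confirmed
against the closed-form marginal at the true partition, so it is not an
inference artifact).  On real survey data, where within-cluster
heterogeneity is much richer, higher β is favored — the basis of the shipped
β = 0.9 default.  Passing recovery tests on this generator therefore
demonstrate partition recovery under boundary noise, not the real-data
direction of β sensitivity.

## Problem sizes and runtime

Tests and the reproduction script run at desk scale: recovery uses 500
participants × 2,320 attributes at truncation 100 (about 1–2 s per fit);
exact-oracle checks use $N \le 6$, $D \le 4$, $K = 3$; the hyperparameter
search demonstration uses a 60-participant corpus at truncation 20.  These
sizes were chosen so the full validation suite completes in well under a
minute of compute per component while exercising every code path at the
full default feature dimension.

## Known limitations

- Batch CAVI only: no memoized/online variational inference, split-merge
  moves, or Gibbs sampling (beyond the small-N exact oracles).
- Hard assignments discard responsibility uncertainty; $K^\*$ counts argmax
  occupancy and can differ from effective-mass measures.
- The feature transform is purely grid-topological; perceptual chip
  distances (e.g., CIELAB) are out of scope.
- Term tokens are compared byte-exactly; no Unicode normalization or gloss
  translation.
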