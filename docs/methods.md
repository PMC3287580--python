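# Methods

## Model and assumptions

`svdtax` treats a species' proteome as a bag of overlapping amino-acid
trigrams. The counts of the 8000 possible trigrams over the 20-letter
alphabet form one column of the matrix *A* (8000 × n). The working
assumption is compositional: evolutionarily close species have similar
trigram spectra, so Euclidean distance in a rank-reduced SVD space of *A*
tracks lineage divergence. No alignment, no substitution model and no
molecular clock are involved; trees produced here are summaries of
compositional distance, not model-based phylogenies, and the package never
claims otherwise.

Counts are raw, not length-normalized, by default. Sequence length is an
informative signal for this method (missing gene families or short
proteomes visibly perturb clustering), and the reference behaviour this
package reproduces arises with raw counts. `decompose(..., normalize=True)`
provides per-column L1 normalization for users who want it.

The reduced representation is the latent-semantic-indexing embedding
*D_k* = Σ_k V_kᵀ. Two exact properties anchor the implementation and are
enforced by tests: at full numerical rank (singular values above
1e-10 · σ₁), distances between *D_k* columns equal distances between raw
columns of *A*; and every pairwise distance is non-decreasing in *k*, so
truncation only contracts the space.

## ASAP and the threshold grid

ASAP depends on the threshold *d* only through comparisons `value < d`, so
its behaviour is piecewise constant between consecutive distinct matrix
values. The grid of midpoints between consecutive unique values (plus 0 and
a point above the maximum) therefore enumerates *every* achievable
clustering — the profile is exhaustive, not a sample. Strict inequality
makes *d* = 0 produce n singletons, fixing the lower boundary law.

Pivot order: the published description of the clusterer is internally
inconsistent (random pivot in prose, first-column pivot in pseudo-code,
alphabetical-first in the tree-building section). The default is the first
remaining column of the distance matrix — deterministic, and alphabetical
when species are loaded in sorted order — with an optional seeded random
order for sensitivity checks.

## Choosing d for a target cluster count

Several disjoint intervals of *d* can realize the same cluster count with
different partitions. For each (k, c) the search keeps the realization
whose constant-count interval is *widest* (ties toward larger *d*): the
partition that tolerates the largest perturbation of *d* before changing.
The obvious alternative — the largest realizing *d* — systematically picks
the degenerate realization at the upper edge of a count's range, where a
pivot has half-swallowed a neighbouring group just below the next merge;
the widest-interval rule is what "stable" actually means for a step
function.

## The kdc search

- **EDRD** (Empirical Dimensional Range Division) = max(1, round(n/25))
  sets both grid steps; ranks run 3, 3+EDRD, … ≤ n (ranks 1–2 are
  degenerate projections) and target counts EDRD, 2·EDRD, … < n. For
  n = 76 this yields the canonical step of 3. A `dense` flag sweeps
  everything in 1..n.
- **Gate.** A configuration is valid only if the positive control group is
  exactly one cluster. Before any configuration is valid, Lcq is the useful
  progress statistic; after, it is misleading (it rewards partitions that
  bury the control in a large homogeneous cluster), so the final ranking
  uses the median per-cluster cLtlf.
- **Recursion.** If no configuration isolates the control, the best
  available one (maximal control-cluster cLtlf, then fewest singletons)
  donates its singleton species for removal, and the search repeats on the
  remainder, up to 3 extra depths. Control members are never removed, and
  the recursion aborts if fewer than |control| + 2 species would remain.
  Depth 3 is a termination guarantee; on data with genuine structure the
  search finishes at depth 0 or 1.
- **Finalize.** When a secondary control group is configured,
  configurations isolating it rank strictly above those that do not; the
  median cannot distinguish a clean fine partition from a coarse merge of
  valid groups (a merged pair of clades often scores a *higher* median),
  and a second, deeper control is precisely the information that breaks
  that degeneracy — it is how the 8-cluster/rank-9 configuration was
  selected over two higher-median candidates on the mitochondrial corpus.
  Within each stratum: descending median, then fewer singleton clusters,
  then smaller k, then more multi-member clusters. The full ranking table
  is always emitted so a user with a different target taxonomic depth can
  pick a row manually.

## Linnaean statistics

Shared levels = longest common lineage *prefix* over the 14 canonical
ranks; lineages are nested, so prefix semantics is the meaningful one.
Distinct species cap at 13 (shared genus) and singletons score 13 by
convention, the documented minimum cLtlf. The standard deviation is the
sample (n−1) form and the median of an even count is the mean of the two
central values — both verified by reproducing every printed statistic of
the reference tables to 2 decimals in the test suite. Lcq is undefined
(reported as NA/None) when σ = 0, e.g. all-singleton partitions.

## Synthetic data generator

`synthetic.simulate` emulates the structure of the corpus the method was
built for: one random root protein; per-clade ancestors by i.i.d. per-site
substitution with probability `between_clade_subst` (default 0.35); leaves
from their ancestor at `within_clade_subst` (default 0.02); optional
outlier species drawn as fresh random sequences (the negative-control
analogue). Substitutions are uniform over the 19 alternative residues —
the method reads only composition, so an empirical exchangeability matrix
would add nothing the statistics can see. Lineages: all clades share ranks
1–8 (as the core corpus shares 8 levels), clade members share ranks 1–10
(as the 10-species control class shares 10), ranks 11–14 are
species-specific; outliers split at rank 2. Clade 1 is the positive
control; clade 2 is the secondary control by default, mirroring the
two-control protocol of the reference analysis.

Defaults (4 clades × 5 species, length 2000) give a mean between-clade to
mean within-clade trigram-distance ratio of ≈2.7–2.9× across seeds —
enough for the reduced space to separate clades cleanly at small k. What
the generator does *not* emulate: indels, rate heterogeneity across sites,
gene content variation, compositional bias, unequal clade sizes and
unequal sequence lengths. Passing the recovery tests therefore shows the
machinery is correct and the search criteria behave as designed on
separable data; it does not certify performance on real proteomes, where
separation is weaker and length variation is a real confounder.

## Numerical choices

- Thin SVD via LAPACK (`scipy.linalg.svd`, `full_matrices=False`); the
  sign of singular vectors is unconstrained and all consumers use only
  distances, which are sign-invariant.
- Numerical rank: singular values above 1e-10 · σ₁.
- ASAP membership is strict (`< d`); Q-matrix ties in neighbor joining and
  pivot ties in ASAP break toward the lowest index, making every pipeline
  stage deterministic for fixed inputs.
- Neighbor joining clamps negative branch-length estimates to zero and
  shifts the deficit to the sister branch (the convention of the classic
  PHYLIP NEIGHBOR program, which this module replaces in-process; the
  PHYLIP square-matrix writer is kept so external cross-checks remain
  possible).
- k-means: Lloyd iterations from c distinct random columns, empty clusters
  re-seeded from the worst-fitted point, inertia asserted non-increasing
  per iteration (measured after the centroid update, where the guarantee
  holds even with re-seeding), tolerance 1e-6 on centroid shift.
- Ambiguous residues (B, J, O, U, X, Z), stops and gaps are removed and
  tallied per species rather than rejected, keeping the trigram space
  exactly 20³; the counts appear in run reports so the user can audit.

## Known limitations

- Composition-based distances conflate sequence length with divergence;
  the recursion's singleton-dropping exists precisely because incomplete
  proteomes strand species.
- The median criterion is degenerate between a clean partition and coarse
  merges of equally-deep groups without a secondary control; supply one
  when possible.
- Only the in-house threshold clusterer and a reference k-means are
  built in; external clusterers can be scored via assignment-TSV import
  but are not executed.
- Problem sizes: the test and acceptance runs use 12–20-species simulated
  datasets with protein length 300–2000 — small enough to sweep the full
  kdc grid in seconds while exercising every code path; the pipeline
  itself is O(n²) in species count past the one-off SVD and comfortably
  handles hundreds of species.
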