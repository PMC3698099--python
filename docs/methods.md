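# Methods

This note documents the models, conventions and numerical choices behind
`tcmchromatin`. The package re-implements, against synthetic data, a
materia-medica-wide analysis chain: quantifying traditional cold-hot and
yin-yang annotations of medicinals, testing their phylogenetic
autocorrelation, predicting each medicinal's modulation of 18 histone/DNA
modifications from chemical–protein interactions, clustering the
resulting profiles, and testing whether multi-medicinal formulas are
chromatin-directionally coherent.

## Annotation quantification

The cold-hot *nature* of a medicinal maps onto a seven-level integer
scale: cold (−3), mild cold (−2), cool (−1), neutral (0), mild warm (+1),
warm (+2), hot (+3). Each *flavor* token carries +1 for the yang flavors
(sweet, pungent, plain) and −1 for the yin flavors (sour, bitter, salty),
with every "mild" grade exactly half the full grade; a medicinal's flavor
score is the unrestricted sum over its tokens (so sweet + mild pungent =
1.5). The composite yin-yang score is nature + flavor. We deliberately do
not clamp the composite to the empirically observed [−4, 4] range of the
original data: additivity is the defining rule, and a three-flavor yang
medicinal may legitimately exceed 4. Missing annotations propagate as NA
and are removed listwise from any downstream statistic.

When a medicinal id appears on several catalog rows (different plant
parts), the annotations of the *first* occurrence are kept; the
constituent-chemical sets of all occurrences are unioned, a choice that
maximizes interaction recall where the merge rule for chemicals is
otherwise unspecified.

## Phylogenetic autocorrelation

Moran's I over the leaves of a phylogeny,

    I = (n / S0) · Σᵢⱼ wᵢⱼ (yᵢ−ȳ)(yⱼ−ȳ) / Σᵢ (yᵢ−ȳ)² ,

with wᵢⱼ = 1/dᵢⱼ the reciprocal cophenetic (path-length) distance and
S0 = Σ wᵢⱼ. The null expectation is E[I] = −1/(n−1). Two significance
routes are provided and cross-checked against each other:

- **analytic** (default): normal approximation with the
  randomization-assumption variance (the standard permutation-moment
  formula involving S0, S1, S2 and the trait kurtosis);
- **permutation**: label shuffling with
  p = (1 + #{|I* − E| ≥ |I − E|}) / (1 + n_perm), seeded.

The low-level API uses the raw 1/d weight matrix exactly as the formula
states. The pipeline front end defaults to **row-standardized** weights
(each row divided by its sum), the convention of the classical
tree-autocorrelation tooling in R's `ape`; a unit test reproduces
`ape::Moran.I` to 1e-10 in that mode. Row standardization also has
materially better power on deep trees because raw reciprocal distances
concentrate weight on a few closest pairs. Both conventions are exposed
(`row_standardize`).

Zero cophenetic distances (duplicate taxa) are a hard error directing the
user to deduplication rather than silently perturbed. Trees without
branch lengths get unit edges, so distances count edges; a tree can also
be built from root-to-species lineage strings (one edge per rank step,
polytomies allowed), in which case two species sharing a genus sit at
distance 2, and a k-rank chain below the deepest shared taxon contributes
k edges per side.

The normal approximation carries percent-level error at very small n
(observed ≈0.05 absolute against the exact 8!-relabeling tail mass at
n = 8); the permutation route is exact up to Monte-Carlo error and is the
reference at such sizes.

## Potency profiles and chromatin calls

A medicinal modifies attribute X if any of its constituent chemicals
interacts with an enzyme of the family catalysing X; its X *potency* is
the **count of chemical–protein interaction pairs** (two chemicals
hitting one enzyme are two pairs). Interactions whose direction the
source database leaves unspecified are tallied as inhibiting, following
the prevailing direction of chemical–protein interactions. The 18
attributes partition into 7 euchromatic, 10 heterochromatic and 1
ambivalent (ATP-dependent remodeling, which can act in either
direction).

Chromatin classification counts, by default, the *distinct attributes
touched*: n_het heterochromatic and n_eu euchromatic attributes with at
least one pair; net = n_het − n_eu labels the entity condensing (> 0),
unpacking (< 0) or poising (= 0 with at least one attribute touched,
including ATP-only entities). The ambivalent attribute contributes to
histone-modifying status but to neither side of the net. Two options
generalize this: `interaction_pairs` granularity weights by pair counts,
and `direction_aware` pushes an activating pair toward the attribute's
conformation and an inhibiting pair toward the opposite one. The
count-based default reproduces the arithmetic of the original analysis
(whose "co-inhibition of DNMT and HDAC" heterochromatinization reading is
itself direction-agnostic); the discrepancy is surfaced as an option, not
resolved.

Score–potency association uses Pearson correlation restricted to
histone-modifying medicinals with non-NA scores, two-sided P from the
exact t transform (n−2 df), screened per attribute at α = 0.05 with **no
multiple-testing correction** — an explicitly per-attribute screen, as in
the original analysis; the report flags this.

## Hierarchical clustering

Entities × 18 potency matrices are clustered agglomeratively under
Euclidean distance, complete linkage by default (average and single are
options), no scaling by default (z-scoring behind a flag). Ties at equal
merge distance break toward the smallest cluster index (leaves in input
order, then merge creation order), making trees bit-reproducible. The
implementation is a Lance–Williams update loop verified against a
brute-force re-agglomeration oracle for small instances and against
scipy's linkage heights on tie-free data. Dendrograms serialize to
Newick with branch length = parent merge height − child merge height.

## Formula synergy

A formula's profile is the attribute-wise sum of its member profiles; it
is histone-modifying iff any member is. For each chromatin chemistry
class (me/ph/ac/all) the normalized net heterochromatinization
f = (n_het − n_eu)/(n_het + n_eu) (0 when the class is untouched) is
compared between the formula and the mean over its histone-modifying
members: Δ = f(formula) − mean f(members), bounded in [−2, 2]. The
normalized fraction, rather than raw net counts, is used because a
formula pools far more pairs than any member; raw counts would conflate
synergy with size.

Controls are 199 random formulas of size N = the real formulas' median
size (rounded), drawn uniformly without replacement from the pool of
medicinals making up the histone-modifying real formulas, constrained to
reproduce the real formulas' median count of histone-modifying members.
Two matching mechanisms exist: whole-set redraw-until-match (bounded,
then error) and a stratified construction that fixes each control's
modifying-member count so the set median lands on the target; the default
tries the former briefly and falls back to the latter, which is the only
mechanism that can bridge a systematic gap between the pool's sampling
distribution and homophilous real formulas.

The report statistic is the two-sided rank-sum (Mann–Whitney) comparison
of |Δ| real vs control per class. The *synergy flag* uses the one-sided
("real |Δ| smaller") rank-sum P at α = 0.05: unlike "two-sided P < α and
direction", whose null firing rate is ≈ α/2, the one-sided rule fires at
exactly the nominal rate under the null while implying the direction.

## Synthetic data generator

The generator emulates the statistical structure of the study inputs; it
does not mimic real chemistry, enzyme identifiers or interaction-score
distributions.

- **Tree**: pure-birth (Yule) tree, rate 1, grown to n leaves with
  exponential waiting times.
- **Nature trait**: Brownian motion from root value 0 at rate σ_BM plus
  iid noise (sd `trait_noise_sd`), discretized into the seven nature
  tokens by equal-frequency bins, so token frequencies are balanced.
  With both rates zero every leaf stays at the root value and gets the
  same token. A configurable fraction of leaves is left NA.
- **Flavors**: 1–3 tokens per medicinal; each token is drawn from the
  yang set with probability sigmoid(coupling · standardized trait), so
  flavor polarity tracks the nature trait.
- **Chemistry**: 2–5 private chemicals per medicinal; 2–10 synthetic
  enzymes per attribute (protein-family redundancy). Chemicals are not
  shared between medicinals — real catalogs share constituents, which
  this generator does not emulate.
- **Interactions**: every chemical × enzyme pair enters independently at
  `base_interaction_rate`; a planted association (attribute, side,
  effect) adds pairs for that attribute at rate effect · |score|/3 on the
  stated side of the cold-hot scale. Actions are 20% activation / 50%
  inhibition / 30% unspecified — the unspecified share deliberately
  exercises the →inhibition rule.
- **Formulas**: sizes uniform on a configured range; the first member is
  uniform and each later member comes from the first member's chromatin
  class with probability `homophily_strength`, else uniformly.

Default study conditions (chosen once, at a scale a single CPU handles in
seconds per bundle): 200 medicinals, base rate 0.001 (≈36–44% of
medicinals histone-modifying, the materia-medica regime of the original
data), σ_BM = 1.0 with noise sd 0.25 and 10% NA (strong but not
saturated phylogenetic signal), one planted association (H3K9,
cold-enriched, effect 0.02; induces r ≈ −0.45 among modifying
medicinals), 50 formulas of sizes 4–10 with homophily 0.9. Under the
zero-signal variant (`null_config`: iid traits, no planted effects, no
homophily) Moran's I, the 18-attribute correlation screen and the
synergy flag all reject at the nominal 5% rate within binomial
tolerance; at the defaults each planted signal is recovered in well over
80% of seeded replicates. Passing these suites demonstrates internal
consistency and statistical calibration of the chain on data with known
truth — not that the original databases would yield the same biology.

All randomness flows from one master seed split per stage
(`numpy.random.SeedSequence`); identical config + seed give
byte-identical bundles, stage outputs and reports.

## Known limitations

- Potencies are presence/count-based: no binding affinity, dose,
  pharmacokinetics, or whether a chemical reaches the nucleus.
- Pearson correlation on sparse pair counts is mildly conservative
  (observed null rejection ≈0.04 at the default sparsity), which the
  calibration bands accommodate.
- The per-attribute α = 0.05 screen performs no multiplicity control by
  design.
- Enzyme membership in the bundled modification catalog is a synthetic
  set of representative human gene symbols; only the attribute →
  conformation mapping carries scientific content.
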