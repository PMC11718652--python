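# Methods

This note documents the models and procedures implemented in
`hybridscreen`, the parameters that matter, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## SMILES dialect and molecular graphs

The parser supports the organic subset (B, C, N, O, P, S, F, Cl, Br, I;
aromatic b, c, n, o, p, s), bracket atoms with formal charge and explicit
hydrogen counts, branches, ring closures (`1`–`9`, `%nn`), bond symbols
`- = # :` and dot-disconnection. Stereo markers and isotopes are accepted
and ignored: both fingerprints are stereo-agnostic, so retaining them
would add parser complexity without changing a single bit.

Implicit hydrogens follow default valences (B 3, C 4, N 3, O 2, P 3, S 2,
halogens 1), with P promotable to 5 and S to 4 or 6 when the explicit
bond-order sum requires it. Aromatic atoms are **not** kekulized; instead
the bond-order sum counts each aromatic bond as 1 and adds 1 for the
delocalized π system for aromatic B/C/N/P. Aromatic O and S contribute a
lone pair rather than a π bond, so they receive no increment — this is
what makes furan and thiophene perceive correctly (O/S with two ring
bonds, zero hydrogens). A bracket hydrogen count is authoritative:
`[nH]` has exactly one H and the valence rule is not applied on top of
it. Positive charge raises the valence of N/P; negative charge lowers it
for O/S anions. These rules reproduce standard hydrogen perception on
drug-like motifs (the test suite checks total H counts against RDKit over
a 60+ molecule corpus) without a full aromaticity/kekulization engine.

Aromaticity is taken from the input notation, as written in large vendor
libraries; an aromatic atom not lying on a cycle of aromatic bonds is a
parse error rather than a silent re-interpretation.

Ring membership is computed via bridge detection (a bond is in a ring iff
it is not a bridge); rings themselves come from a minimum cycle basis.
Aromatic-ring features use basis cycles of size 5–7 with all-aromatic
bonds.

## Morgan fingerprint

Round-0 atom identifiers hash the tuple (atomic number, heavy degree,
total H, formal charge, aromatic flag, ring flag) with the stable mix
`h = 17; h ← (31·h + c) mod 2³²`. Each subsequent round hashes
(previous identifier, sorted (bond order, neighbor identifier) pairs).
Identifiers from all rounds 0..radius are pooled, deduplicated by value,
and folded modulo the bit length. Degree-0 atoms contribute only round 0
(an isolated atom has no larger environment). Defaults are radius 2 and
2048 bits, the de-facto ECFP4 conventions. The explicit polynomial hash
makes bit patterns identical across platforms and sessions; environment
deduplication is by identifier value only (canonical-environment
deduplication as in full ECFP is out of scope and irrelevant at the
similarity-ranking level — the suite checks Spearman ρ > 0.7 against
RDKit's Morgan Tanimoto ranking).

## Pharmacophore fingerprint

Feature families (minimal rule set expressible without a SMARTS engine):

| family | rule |
| --- | --- |
| donor | N/O with ≥1 H and charge ≥ 0 |
| acceptor | N/O with charge ≤ 0, except aromatic N–H |
| aromatic | one feature per aromatic ring (full atom set) |
| hydrophobe | halogen, or non-aromatic C with only C neighbors |
| pos_ionizable | charge > 0, or aliphatic amine N (only C/H neighbors, no adjacent carbonyl) |
| neg_ionizable | charge < 0, or carboxylic-acid hydroxyl O |

Aromatic carbons are deliberately excluded from the hydrophobe rule: the
ring is already represented as one aromatic feature, and admitting its
carbons individually would drown every aromatic compound in
hydrophobe–hydrophobe pairs (benzene would carry 7 features instead
of 1).

Every unordered pair of distinct features (same-family pairs included)
sets one bit: index = pair-rank × 6 + distance-bin, with the 21 family
pairs ranked lexicographically and topological distance (minimum
bond-count between the two atom sets) binned as [0], [1], [2–3], [4–5],
[6–7], [8, ∞). 126 bits total, no hashing, hence no collisions and exact
decodability (bit → family pair + bin is a bijection, property-tested).
Feature pairs spanning disconnected components are skipped. The bin edges
are the usual coarse choice for 2D pharmacophore pairs: finer bins would
make the fingerprint hypersensitive to single-bond edits, coarser ones
would collapse ortho/meta/para distinctions.

## Similarity

Tanimoto, cosine and Euclidean metrics operate on on-bit sets; the values
are identical to the dense 0/1-vector definitions (oracle-tested on
random pairs) but cost O(|bits|) per comparison, which is what makes a
10⁶-compound profile tractable. Two all-zero fingerprints have Tanimoto
0: an empty pattern is treated as absence of evidence, matching common
toolkit behavior. Tanimoto ≤ cosine holds for all binary vectors and is
property-tested. The library profile keeps one row per parsed compound in
input order; parse failures are collected with their reasons and logged —
never silently dropped.

## K-Means and model selection

Lloyd's algorithm with Euclidean distance: assign to nearest centroid
(ties → lowest cluster index), recompute means, stop when the maximum
centroid displacement drops below `tol = 1e-6` or after `max_iter = 300`
rounds. Initial centroids are k distinct data points chosen uniformly at
random — the protocol's stated initialisation — with best-of-10 restarts
by WCSS as the default variance control. Greedy k-means++ seeding is
available behind `init="kmeans++"`; it is what the optimality checks use,
because plain random seeding needs far more restarts to reach the global
1-D optimum reliably (best-of-20 random seeding attains the exact DP
optimum on only ~90% of small random instances; greedy k-means++ raises
that above 95%). Empty clusters are repaired by reassigning the point
farthest from its centroid.

The exact 1-D solver (`dp_kmeans_1d`) sorts the values and runs dynamic
programming over contiguous segments with prefix-sum segment costs — an
independent optimality oracle, kept free of any Lloyd code.

WCSS curves reuse the best k-model's centroids plus the farthest point as
a warm start for k+1; adding a centroid cannot raise the objective and
Lloyd never increases it, so the curve is exactly monotone
non-increasing, which the elbow rule needs. The elbow is the interior k
maximizing perpendicular distance to the chord of the min-max-normalized
curve (ties → smaller k): a defensible formalization of "the bend", since
visual elbow-picking has no unique definition. The default scan range is
k = 1..20.

Silhouette: s = (b − a)/max(a, b) per point, singleton clusters score 0,
mean reported; exact up to 10⁵ points and estimated on a seeded
10,000-point subsample above that (the exact computation is O(n²)).
Equality with scikit-learn's implementation is asserted in the tests.

## Top-cluster rule and consensus

"The cluster with the highest range of similarity values" is formalized
as: maximal cluster minimum, ties broken by maximal maximum, then larger
count, then lowest id. On both published 20- and 17-cluster summary
tables shipped under `data/` this uniquely selects the reported clusters
(2197 members at 0.29–0.38; 1958 members at 0.27–0.40). The alternative
reading (maximal width max − min) would pick the same clusters on these
tables but is less robust: a single low outlier can inflate a cluster's
width without making it similar to the query. Consensus identity is by
library row identifier — both clusterings are views of one indexed
library, so no SMILES canonicalization is needed.

## Synthetic benchmark

The generator emulates the similarity structure the screen assumes: a
planted series of query analogs above a band of unrelated decoys. Analogs
decorate the built-in benzodiazepinone query (diazepam's SMILES — a
representative small-molecule kinase-era drug scaffold with two aromatic
rings, an amide and a halogen) with up to `depth` substituents drawn from
{methyl, hydroxyl, fluoro, amino, methoxy} at random positions carrying a
spare hydrogen. Decoys are sampled from a fixed pool of 36 chemically
valid drug-like scaffolds (chains, saturated rings, small
heteroaromatics), half of them decorated once. Defaults — 20 analogs,
200 decoys, depth 1, seed 7 — give Morgan Tanimoto 0.56–0.79 for analogs
vs ≤ 0.12 for decoys, and pharmacophore Tanimoto 0.42–1.0 vs ≤ 0.28.
Labels are kept outside the screen's input path, so recovery is measured
from similarity alone.

The benchmark screen fixes k = 2, matching the two populations the
generator plants (analog band vs decoy band); this isolates the funnel's
recovery behavior from model selection, which is exercised separately on
a three-component Gaussian mixture where the elbow rule must find k = 3.
With elbow-chosen k over the default 1–20 range the screen still yields a
pure analog top cluster, but at finer granularity it may retain only the
upper part of the analog band — a real property of elbow-picked
fine clusterings, not a defect of the funnel.

What the benchmark does **not** show: performance on a real vendor
library (10⁶ compounds with a continuous similarity spectrum rather than
a planted gap), fingerprint behavior on stereochemistry-dependent
series, or any downstream affinity prediction. Those downstream stages
(neural-network affinity scoring, docking, molecular dynamics) are out of
scope; the consensus set is exported as `.smi` for external tools.

## Problem sizes and determinism

All shipped computations run on one CPU in seconds: the benchmark screen
profiles 220 compounds and clusters 1-D vectors; the optimality battery
solves 100 instances with n ≤ 60, k ≤ 5; the mixture test clusters 900
points over k = 1..10. Every stochastic component (initial centroids,
restart streams, subsampling, instance generation) derives from an
explicit integer seed; configurations without a seed are rejected rather
than defaulted, so no run is silently irreproducible.
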