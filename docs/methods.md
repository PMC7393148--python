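# Methods

## Model

The package treats a network as a simple, undirected, unweighted, connected
graph and summarizes its topology by the census of its 2- and 3-node
graphlets: the edge G0, the 3-node path G1 and the triangle G2, with
automorphism orbits O0 (edge endpoint), O1 (path end), O2 (path center) and
O3 (triangle vertex). The per-node orbit touch counts follow exactly from
degrees and per-node triangle counts:

    O0_i = d_i
    O3_i = t_i
    O2_i = C(d_i, 2) − t_i          (pairs of non-adjacent neighbors)
    O1_i = Σ_{j∈N(i)} (d_j − 1) − 2 t_i

Triangles are found by neighbor-set intersection per edge, iterating from
the lower-degree endpoint, giving O(|V| d²) total work with d the maximum
degree. An independent O(N³) brute-force census (classify every 3-subset as
disconnected / path / triangle) is shipped as `brute_force_orbits` and the
test suite requires exact per-node agreement between the two on random and
canonical graphs; the closed forms are never trusted on their own.

The twelve dimensions are ratios of integer aggregates of these counts (see
README for the formulas), grouped as Global connectivity (ρ1–ρ3), Hubs
(ρ4–ρ5), Strings (ρ6–ρ7) and Triangles (ρ8–ρ12). Scaling by the network's
own max degree / max O2 (per network, never corpus-wide) keeps ρ2–ρ12 in
[0, 1]; ρ1 ∈ [−1/(N−1), 1) for a connected graph. Six unscaled variants are
reported alongside.

### Assumptions

* Input graphs are connected and simple. Directed, weighted or multi-edge
  inputs are degraded to simple undirected form with a warning; the metric
  carries no direction or weight information.
* N ≥ 3. With fewer nodes there are no 3-node graphlets and the metric is
  undefined; smaller inputs are rejected.
* Disconnected inputs are either rejected (`require` policy) or reduced to
  their largest component (ties broken by lexicographically smallest sorted
  label set, for determinism).

## Numerical choices

* **Exact rational arithmetic.** Every dimension except ρ5 is a ratio of
  integers and is computed as a `fractions.Fraction`; floats appear only at
  serialization. This removes accumulation error and lets tests assert
  exact equality against closed forms.
* **ρ5 (Spearman rank correlation of O1 vs O2)** is computed over *all*
  nodes with average ranks for ties (midranks), as Pearson correlation of
  the rank vectors. The result is a float (it involves a square root);
  correlations of exactly 0 or ±1 are kept exact. When either variable is
  constant the correlation is undefined: ρ′5 is set to 0 (so ρ5 = 0.5,
  "no association") and the dimension is flagged.
* **Degenerate denominators** get documented fills plus a flag, keeping
  vectors finite and PCA-ready while preserving the information that the
  value is conventional: ρ2 = 0 when no non-triangle node touches O1;
  ρ3 = 0 when there are no leaves; ρ4 = ρ6 = 0 when no node touches O2;
  ρ7 = 0 when there are no string middles; ρ8–ρ12 = 0 in triangle-free
  graphs.
* **ρ11 variant.** "Isolated triangle vertex" admits three readings that
  disagree on small complete graphs: a triangle vertex of degree exactly 2
  (default `degree2`), one with O2 = 1 (`eq23`), or one with O2 = 0
  (`no_o2`). The degree-2 reading is the only one under which ρ11 falls as
  triangles acquire outside connections, which is the quantity's stated
  meaning, so it is the default; the others are selectable via
  `MetricConfig.rho11_variant`.
* **Strings.** A string middle is a node with O2 = 1 and O3 = 0; a string
  is a connected component of the subgraph induced on middles, and n (the
  string count in ρ7) is the number of such components. A component that
  closes into a ring (every member's two neighbors both middles, as in a
  cycle graph taken whole) has no end nodes; it is counted as one string
  and a warning is logged, since the end-node picture does not cover it.

## Collection analysis

Fingerprints of a collection stack into a networks × 12 matrix
(`build_matrix`; degenerate fills applied upstream so there are no missing
entries). `run_pca` mean-centers by default — the dimensions are already
commensurable, mostly in [0, 1] — with z-scoring available by flag;
zero-variance columns are centered only and keep loading 0, preserving the
12-column layout. Components are sign-fixed (largest-|loading| entry
positive) so outputs are identical across runs and platforms. Kaiser-
normalized varimax rotation (tolerance 1e−8, ≤ 500 iterations) is optional;
rotated variance shares are re-attributed from the rotated scores, and the
orthogonality of the rotation preserves total explained variance to
machine precision. With k = 12 the scores-times-loadingsᵀ product
reconstructs the centered matrix to ~1e−14.

`group_summary` reports per-group median/min/max per dimension (the radar-
chart summary). `detect_outliers` flags networks whose score distance to
their group centroid exceeds a threshold times the median absolute
deviation of the group's distances. The default threshold is 10 MADs:
distances of same-class networks to their centroid routinely reach ~8 MADs
(the MAD of a distance cloud is small relative to its tail), while a
structurally foreign network lands one to two orders of magnitude out, so
10 keeps false positives rare without risking misses. A zero MAD (perfectly
tight group) falls back to flagging any nonzero distance.

## Synthetic data

The generator module stands in for a large real-network corpus at desk
scale. Canonical families (paths, cycles, stars, complete graphs, bowtie
chains) have exact closed-form fingerprints (`expected_ghust`, rational
arithmetic) and serve as the metric layer's oracle. Random families
(uniform random trees, Erdős–Rényi, Barabási–Albert, Watts–Strogatz, grid
lattices) are seeded and fully reproducible; ER connectivity is enforced by
resampling up to 100 times, then falling back to the largest component with
a log line.

`corpus` assembles labeled collections from three profiles chosen to echo
broad real-world classes, plus their union:

* `string_heavy` — uniform random trees of 40–80 nodes, or narrow 2–3-row
  grid meshes with 5–9 pendant chains of length 3–8 hanging off them, the
  way road and distribution networks string nodes along corridors. Chain
  middles dominate: ρ6 > 0.3 on every instance.
* `hub_sparse` — Barabási–Albert graphs, n = 60–120, m ∈ {1, 2}:
  hub-dominated, sparse, few or no triangles (m = 1 gives trees with hubs).
* `triangle_dense` — Watts–Strogatz rings (k ∈ {6, 8}, rewiring 0.05) or
  dense ER (n = 30–50, p = 0.3): clustered and triangle-rich.
* `mixed` — cycles through the three pure profiles, emulating a collection
  of unknown heterogeneous origin.

Sizes were chosen once as the smallest at which the class character is
unambiguous while whole-corpus analyses complete in seconds; problem sizes
used by the shipped tests and the acceptance script are 30 graphs per
profile (120-network corpus), a 500-graph range battery, and ~100-graph
oracle batteries.

What the synthetic corpus does *not* emulate: real degree-distribution
tails at scale, community structure, geographic embedding, and measurement
noise. Passing the collection-level tests therefore shows that the
pipeline separates classes whose generative mechanisms differ — the
qualitative claim — not that any particular real-world taxonomy would be
recovered. Note also that the `mixed` profile is by construction inseparable
from the pure profiles, so the 4-label silhouette of the corpus
(~0.25–0.28) understates the separation of the three well-defined classes
(~0.55–0.62 without it).

## Known limitations

* Orbit counting is pure Python; at O(|V| d²) it handles the desk-scale
  corpora here in seconds but would want a vectorized or compiled core for
  million-edge graphs.
* ρ5's value on graphs where O1 or O2 is nearly constant is dominated by
  tie handling; the flag only marks exactly constant input.
* The PCA standardization default (centering only) is a declared
  convention; z-scoring can change which dimensions dominate the loadings
  and should be chosen deliberately when dimensions with large raw spread
  (ρ1 on dense graphs) mix with near-constant ones.
* Outlier screening assumes groups are unimodal in score space; a group
  containing two legitimate sub-classes will flag neither or both.
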