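# Methods

## Model

Each residue is reduced to a single interaction site: the Cβ coordinate
(side-chain direction; default) or the Cα coordinate. An order-k interaction
(k = 2, 3, 4) is a set of k sites in which **every** pair lies within an
inclusive Euclidean window `[d_lo, d_hi]` — the mutual-contact (clique)
criterion. The geometric rationale is sphere packing: treating residues as
equal spheres, no more than four can touch mutually in 3-D, so enumeration
stops at quadruplets. Triplets are exactly the triangles and quadruplets
exactly the 4-cliques of the pairwise contact graph; every reported
quadruplet therefore contains four reported triplets and six reported pairs
(downward closure), which the test suite verifies.

No energetic weighting or statistical propensity is attached to the
interactions; the package computes the combinatorial objects only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `atom_type` | `CB` | representative atom; Cβ reflects side-chain packing, Cα the backbone trace |
| `d_lo`, `d_hi` | 1.0, 7.0 Å | inclusive window; 1–7 Å is the conventional range for residue-level contacts, and both bounds are user-settable (e.g. 0–8 Å for cross-chain surveys, 10 Å for permissive triplet screens) |
| `min_seq_sep` | 1 | minimum \|Δ sequence index\| for intra-chain pairs; 1 admits sequence neighbours (nothing in the contact definition excludes them), raise to 2–3 to suppress trivial backbone contacts; inter-chain pairs are always eligible |
| `gly_policy` | `fallback_to_ca` | glycine has no Cβ; it contributes its Cα (marked `CA-fallback`) rather than silently vanishing, `skip` drops it |
| `model_index` | 0 | NMR ensembles: first model by default, any model selectable |
| `include_hetero` | off | HETATM residues excluded (waters always); MSE is remapped to MET and treated as standard, since selenomethionine is a routine crystallographic substitution |

Window semantics are **inclusive on both ends**: a pair at exactly 7.00 Å is
a contact under `[1, 7]`. Open/closed conventions differ across tools; this
one is fixed here and tested. Distances are compared at full double
precision internally and printed to 2 decimals by default (`--precision`
overrides).

## Design choices

* **Residue identity** is author numbering plus insertion code, which is how
  users cite residues; sequential adjacency uses a separate 0-based
  `seq_index` per chain, so gapped or insertion-coded numbering cannot
  corrupt the sequence-separation rule.
* **Altlocs**: all alternate locations are retained at parse time; at site
  selection the highest-occupancy conformer wins, ties broken alphabetically
  by altloc id. Residues missing the representative atom (missing density)
  are skipped with a logged warning, not an error.
* **Spatial search**: candidate pairs come from a scipy `cKDTree`
  (`query_pairs` at `r = d_hi`), then the lower cutoff and sequence rule are
  applied. A k-d tree was preferred over a hand-rolled cell list: identical
  contract (exact equality with all-pairs search, which the suite asserts on
  seeded random structures), zero custom spatial code to maintain.
  Degenerate inputs (coincident points) hold no special cases — the tree
  handles them.
* **Clique enumeration** is ordered vertex extension in canonical rank
  (chain id, then `seq_index`): each edge is extended only by
  higher-ranked common neighbours, so every clique appears exactly once and
  output order is lexicographic — byte-stable across runs. At a 7 Å cutoff
  the graph is sparse and this is near edge-linear; generic clique
  algorithms would buy nothing.
* **Queries**: anchored queries restrict the search to common contact
  neighbours of the anchors, with a hard contract of equality to filtering
  the full enumeration (tested for every anchor count and order). Anchors
  are conjunctive — results contain *all* anchors. Typed queries filter the
  full enumeration; both `any_member` and `all_members` semantics are
  provided because either reading of "interactions of given residue types"
  is defensible; `any_member` is the default as the more useful screen.
* **Mixed-chain cliques** are labelled `inter-chain` if any member pair
  crosses chains.
* **Parsing** is delegated to Biopython's strict-mode PDB parser (malformed
  records are reported with their line number); the package adds the
  residue/site model and policies on top. mmCIF, symmetry expansion and
  hydrogens are out of scope.

## Synthetic generators and what green tests establish

The generators produce the stated test world, not realistic proteins:

* **ideal helix** — Cα on the canonical α-helix (radius 2.3 Å, rise 1.5 Å,
  100° twist per residue), Cβ 1.53 Å radially outward. Distances have closed
  forms, e.g. `d(i, i+k) = sqrt((2·2.3·sin(50°k))² + (1.5k)²)`: 3.83 Å for
  k = 1, 6.20 Å for k = 4 (inside a 7 Å window), 14.26 Å for k = 9 (outside).
* **polyhedra** — tetrahedron (edge 5 Å: the complete graph K4, counts
  6/4/1), square (5 Å sides, 7.07 Å diagonals: quadruplet correctly absent
  at `d_hi = 7`), octahedron.
* **random packing** — uniform points in a 30 Å box rejection-sampled to
  ≥ 3 Å pairwise separation (a crude excluded-volume stand-in, density
  comparable to a small protein's residue count in that volume), poly-ALA or
  a caller-supplied sequence, seeded and reproducible; rejection is bounded
  (10 000 retries per site) so infeasible specs fail deterministically.

The independent oracle restates the definition literally — test every
C(n, k) subset against the window — and the suite asserts *set equality*
(member keys and distances) between engine and oracle over 20 seeds at two
windows, n = 60. A green suite therefore establishes combinatorial and
geometric correctness on point sets, plus format round-trips and byte
determinism. It does **not** establish anything about real side-chain
chemistry, and the two checks pinned to published distances on real PDB
entries (1WYI, 1G5Q) require those coordinate files: with no network and no
local copy under `tests/data/`, they fail with a diagnostic rather than
silently passing. Synthetic multi-chain packings and cysteine-sprinkled
sequences stand in for the qualitative multi-chain/typed-query scenarios.

## Numerical notes and limitations

* All coordinates in Å; PDB fixed-width serialization rounds to 3 decimals,
  so round-trip tests use a 1–2 × 10⁻³ Å tolerance; in-memory comparisons
  use exact or 10⁻⁶ tolerances.
* The brute-force oracle is guarded to n ≤ 100 (C(100,4) ≈ 3.9 M subsets);
  it exists for tests only.
* Two-chain limits, assemblies, hydrogens, solvent accessibility, all-atom
  contact definitions, and order ≥ 5 are out of scope by design.
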