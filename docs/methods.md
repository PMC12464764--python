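# Methods

## Fingerprints and similarity

Structures are parsed with RDKit; a record whose SMILES does not parse is
rejected individually with a reason, never silently dropped. The
deduplication key is the canonical isomeric SMILES: stereoisomeric natural
products are distinct compounds, so stereo layers are kept. How a source
database treats tautomers or salt forms is outside the key's control — the
parsed structure is taken as-is.

Fingerprints are hashed circular substructures (Morgan) of **radius 2**
over **2048 bits**, binary occupancy, achiral atom invariants (a
`use_chirality` switch adds chirality flags). 2048 bits is the de-facto
standard length for hashed Morgan fingerprints; hash collisions are
accepted as inherent to the representation. Similarity is the Dice
coefficient on bit sets, defined as 0 for two empty sets (a valid molecule
always sets at least one bit, so this case is purely defensive).

## Network and clusters

An edge joins every pair with Dice **≥ 0.75** (inclusive). Clustering is
single linkage: connected components of the thresholded graph. Cluster ids
are assigned 1, 2, … by decreasing size, ties broken by the
lexicographically smallest member id — deterministic and documented, since
no canonical numbering convention exists for such networks; clusters should
be matched across tools by membership, not by index.

The all-pairs engine packs each fingerprint into 32 `uint64` words and
computes block-pairwise intersection popcounts with `numpy.bitwise_count`
(block size 512). This is exact — identical output to the naive double
loop, which the tests assert — and keeps the full-database case (~36k
compounds, ~6.6×10⁸ pairs) feasible on one workstation. Memory per block
pair is ~64 MB at the default block size.

## Cluster statistics

*Median edge count* is the median over a cluster's members of their
within-cluster degree, midpoint convention for even counts. Since
components contain all their incident edges, this is simply each member's
degree in the network. A complete family has median `size − 1`.

*Purity* is the fraction of members with a **known** kingdom that belong to
the most frequent kingdom (ties broken alphabetically for determinism);
members with kingdom `unknown` are excluded from the denominator, and a
cluster with no known-kingdom member has undefined purity and is excluded
from purity counts. A cluster counts as "pure microbial" when its dominant
kingdom is bacterial or fungal and purity ≥ 0.95 (inclusive). Input labels
are normalised onto {bacterium, fungus, other, unknown}; cyanobacteria map
to bacterium.

The dataset-level *median cluster size* is reported over clusters of two or
more members (the primary figure, matching the framing of clusters as
containing at least two compounds); the singleton-inclusive median is also
emitted, clearly labelled, since either convention is defensible.

## Rank profiles and boundary drops

A profile ranks all other compounds by descending similarity to one query
(ties broken by ascending compound id), truncated to `top_n` (default 500).
The *boundary drop* is (minimum score among same-cluster entries) −
(maximum score among outsiders); it is negative when an outsider outranks a
member, which the caller sees flagged rather than hidden. No numeric
definition of a "steep" drop is imposed — the raw quantity is reported.

## Temporal novelty

A compound of year *y* is a **contemporary singleton** when no compound of
a strictly earlier year reaches the cutoff; same-year compounds are not
compared to each other (an `include_same_year` flag enables the alternative
reading). A **current singleton** has no neighbour at all, which makes it
exactly a size-1 cluster; the cross-module identity is asserted in tests.
Records without a year are excluded from the per-year accounting and from
the prior-year comparison set (they cannot be placed in time) but remain in
the current-singleton comparison set, preserving the size-1-cluster
identity. Because every earlier-year neighbour is also an any-year
neighbour, current ⊆ contemporary per year, so contemporary percentages
dominate current ones — a structural invariant, tested over random
collections.

## Macrolactone census

A macrolactone is a simple cycle of exactly N atoms (default 16) containing
an ester `–O–C(=O)–` with both the sp³ oxygen and the carbonyl carbon in
the cycle; the carbonyl oxygen has degree 1 and is therefore necessarily
exocyclic. A smallest-set-of-smallest-rings treatment misses macrocycles
bridged by fused smaller rings, so detection enumerates simple cycles
directly: anchored at each ester O–C bond, a depth-first search looks for a
simple path of N atoms closing that bond. Depth is bounded by N, which
keeps the search cheap even on fused polycyclics; an exhaustive
`networkx.simple_cycles` oracle confirms agreement on all small fixture
molecules. A compound with several distinct matching rings counts once,
with multiplicity recorded. Matched compounds are grouped into classes by
re-running connected components over the matched subgraph; classes below
the minimum size (default 3) are reported as minor groups. The census is
purely structural — no attempt is made to decide whether a match is
PKS-derived.

## PKS combinatorics

The idealized assembly line adds two-carbon units, each ending in one of
**5** reduction states (keto, R-alcohol, S-alcohol, olefin, saturated). An
N-membered macrolactone uses N/2 units, one retained as the keto anchor for
macrolactonization, leaving N/2 − 1 variable units and `5^(N/2−1)` products
— 78,125 for N = 16. Arithmetic is exact Python integers; no floating-point
or logarithmic shortcut. The model deliberately ignores alternative starter
and extender units and tailoring reactions, so the count is a lower bound
on formal diversity.

## Synthetic collections

The generator emulates the one structural feature the pipeline measures:
similarity topology. A *family* is a scaffold plus members decorated with
small substituents (methyl, hydroxyl, chloro, fluoro, amino, methoxy,
acetyl; at most 2 per member by default); a *singleton* is a bare scaffold
from a distant part of the library. The packaged library holds 26
hand-written natural-product-like skeletons (17–37 heavy atoms: steroids,
macrolactones, alkaloids, terpenoids, glycosides, peptides…), not taken
from any database.

Scaffold size matters: below roughly 18 heavy atoms a single substituent
perturbs so large a fraction of a molecule's radius-2 environments that
decorated variants cannot stay at Dice ≥ 0.75, so no clique family exists
at that cutoff. The library was therefore curated empirically — every
skeleton supports 8-member families reliably and all scaffold pairs sit
below Dice 0.6.

Family assembly enumerates a candidate pool (every single-decoration
variant plus 400 sampled multi-decoration combinations), keeps candidates
similar to the scaffold, and grows a clique greedily, restarting with
reshuffled order up to 30 times; a candidate joins only if it reaches the
cutoff against *every* accepted member. Emitted families are thus cliques
at the cutoff. After assembling a dataset, a **separation certificate** is
checked over all pairs: intra-family Dice ≥ cutoff, everything else
< cutoff; violation raises an error rather than emitting a dataset with
wrong ground truth. This is what turns cluster recovery into an exact test.
Kingdoms are drawn per family (default mix 60% bacterial / 35% fungal / 5%
other, mirroring the microbial skew of public collections); years are
uniform over the configured range. Everything is deterministic per seed.

What the generator does **not** emulate: real molecular-weight, logP or
scaffold-frequency distributions; families that are chains rather than
cliques; near-cutoff borderline pairs. Passing tests therefore demonstrate
correctness of the machinery on well-separated topologies, not performance
claims about any real database.

## Problem sizes and numerical choices

The test suite and the acceptance script run on collections of ~30–200
synthetic compounds — large enough to exercise the blocked engine across
block boundaries and small enough to check it against naive O(n²) oracles
exactly. Scores are compared exactly (the engine and the naive loop perform
the same integer popcounts; the only float is one final division).
Percentages are reported to one decimal place. Degenerate inputs (empty
compound sets, singleton queries, all-unknown kingdoms, yearless records)
raise typed errors or are flagged explicitly rather than returning NaNs.

## Known limitations

- Single-linkage components chain: one borderline pair merges two families.
  This is inherent to the method, not a defect of the implementation.
- The macrolactone definition is structural only; matching counts for a
  real database depend on its curation (salt stripping, sugar handling)
  and may differ from counts obtained with additional biosynthetic filters.
- Tautomers and salt forms are not normalised; deduplication treats the
  parsed structure as-is.
- The purity statistic is descriptive; no statistical test is attached.
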