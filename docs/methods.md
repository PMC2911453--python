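# Methods

## Model and assumptions

The package plans immunoaffinity-MS experiments that use antibodies against
short terminal peptide sequences. Its model of the experiment makes four
idealising assumptions:

* the background proteome is fully known and is what the future sample will
  contain;
* the tryptic digest is complete — cleavage after every K/R not followed by
  P, no missed or mis-cleavages, no modelling of post-translational
  modifications or protein N-terminal methionine excision;
* an antibody binds exactly the peptides carrying its epitope at the
  declared terminus — no cross-reactivity, no sequence variants;
* two captured peptides are distinguishable in one spectrum iff their masses
  differ by at least Δ_min.

Under these assumptions epitope selection is exactly a minimum set cover on
the bipartite protein–epitope graph, and the multicoverage variants are the
natural generalisations described below.

## Masses

Peptide mass = Σ residue masses + H₂O. Monoisotopic residue masses (from
pyteomics) are the default because they match MALDI-TOF practice for peptides
of this size and reproduce the canonical near-isobaric example
(|m(AYEQLGYR) − m(HLEILGYR)| = 1.068 Da); an average-mass table is available
via `MassTable.average()`. Ambiguity codes X, B, Z, J carry no mass — any
peptide containing them is dropped by the unknown-positions filter.
Selenocysteine (U) and pyrrolysine (O) keep their standard masses but can be
declared unknown through the `unknown` argument of the table constructors.

## Filter parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `max_epitope_load` | 600 | combinations | loads above this make the antibody cluttered and insensitive; strict inequality (600 survives) |
| `delta_min` | 2.0 | Da | permissive end of the realistic 2–10 Da window for MALDI-TOF resolution |
| `min/max_peptide_len` | 8 / 30 | residues | rule-of-thumb detection range of the mass spectrometer; bounds inclusive |
| epitope lengths | {4, 5} | residues | short enough to be shared across proteins, long enough to be specific |

Ordering: the high-abundant-epitope filter evaluates |C^e| and must therefore
run before the weight filter (which flags members of C^e), which must run
before the length filter; the pipeline validates this before doing any work
and the load is always evaluated at the stage where the filter actually runs.
The unknown-positions, methionine and stoplist filters commute freely.

Weight-filter conventions (the physically-motivated readings where the
procedure leaves room):

* conflicts are symmetric and *both* near-isobaric peptides are marked
  undetectable — the overlapping peak is ambiguous for both;
* detection is by sorting each capture group by mass and scanning adjacent
  pairs, so chains of conflicts (a≈b≈c) knock out every member;
* identical peptide sequences occurring in several proteins are one
  molecular species: they produce one peak, never conflict with themselves,
  and each parent protein retains coverage;
* undetectable combinations stay in the dump files (`detectable=false`) for
  traceability but never enter the cover graph.

The stoplist filter bans an epitope *wherever* it occurs once any stoplisted
protein carries it, since the antibody cannot distinguish provenance.

## Graph construction and robinson removal

Target restriction happens after filtering against the full background, so
epitope loads and weight conflicts reflect the whole digest, not just the
target list. Epitopes supported by exactly one peptide species of exactly one
protein ("robinson" antibodies) are pruned before optimization — a broader
antibody covering the same protein always dominates them. Applied literally
this rule can orphan a protein whose only cover is a robinson epitope, so a
guard keeps (and logs) such epitopes; robinson candidates are processed in
deterministic lexicographic order so the guard's keep/remove decisions are
reproducible.

## Solvers

* **Greedy** picks, per iteration, the epitope covering the most
  still-uncovered proteins; ties are broken by larger new coverage, then
  lexicographically by (side, sequence). Guaranteed within H(n) of the
  optimum, n = largest capture size.
* **Greedy-MC** scores `s_cov·|new| + s_mcov·|recovered|` and only admits
  epitopes adding ≥ 1 new protein (hard exclusion), so it terminates with at
  most |P| epitopes. Default weights are regime-dependent: 100 : 1
  (innovation over redundancy) for graphs with more than 500 proteins, where
  many high-capacity epitopes overlap anyway, and 1 : 10 for smaller target
  lists, where redundancy must be actively rewarded. The 500-protein
  threshold is this package's operational cut between the two regimes, which
  are originally described only as "large" vs "small" datasets. With
  s_mcov = 0 the procedure reduces exactly to the plain greedy.
* **IP** minimises Σ s_a subject to Σ_{a∋i} s_a ≥ 1, s_a ∈ {0,1}.
* **IP-MC** raises the bound to 2 for every protein of degree ≥ 2 (degree-1
  proteins keep the single-cover constraint). This formulation is known to
  admit "elongation" pairs — one selected epitope a terminal extension of
  another (e.g. IER / EIER) — chosen only to satisfy the double-cover
  constraint; the package surfaces such pairs as a report warning rather
  than adding constraints the formulation does not define.
* **IP-MMC** maximises Σ S_i with binary linking variables S_i, constraints
  Σ_{a∋i} s_a ≥ 1 (full cover), Σ_{a∋i} s_a ≥ 1 + S_i (linking; S_i = 1
  forces double coverage) and Σ s_a ≤ cost_max (budget). The useful budget
  window is [minimum cover size, IP-MC optimum]: below the lower bound the
  program is infeasible (the bound is reported), at the upper bound every
  degree-≥2 protein is multicovered. The linking form Σ s_a ≥ 1 + S_i was
  chosen because it keeps the full-cover constraint separate and satisfies
  the verbal definition of the requirement.

All ILPs run on HiGHS through `scipy.optimize.milp` with binary variables, a
configurable time limit (default 300 s at desk scale; proteome-scale studies
historically allowed 12 h) and relative gap. `status` distinguishes proven
optima from time-limited feasible solutions. A brute-force subset enumerator
(guard: |A| ≤ 20) provides the independent exact oracle for all three ILP
variants in the tests — solver correctness is never asserted against the
solver itself.

Determinism: both greedy variants are bit-reproducible under the tie-break
rule; for ILPs the *objective* is reproducible while the selected set may
vary between solver versions, so tests assert objectives.

## Synthetic data

The generator emulates the three structural motifs that make the method
work or fail, planting them into random tryptic peptides (filler alphabet
excludes K/R/M/P and ambiguity codes so planted structure survives digestion
and filtering untouched):

* shared-terminus groups — several proteins yielding peptides with one
  common terminal epitope (what makes one antibody cover many proteins);
  member peptides get staggered lengths so their masses never collide;
* near-isobaric pairs — two peptides sharing a C-terminal epitope whose
  masses differ by ≈ 1.07 Da (two prefixes of equal length whose
  monoisotopic compositions differ by that amount), the weight filter's
  target;
* an overloaded epitope — a planted capture group exceeding the
  high-abundant-epitope threshold.

A JSON manifest of planted truths accompanies each proteome and is what the
tests assert against. The generator is a pure function of (spec, seed).

What it does **not** emulate: realistic amino-acid frequencies, protein
length distributions, peptide ionizability/flyability, homologous sequence
families, or shared peptides between paralogs. Passing tests therefore show
the pipeline and solvers are correct on the structures they claim to handle,
not that coverage scores on synthetic proteomes predict those on real ones —
real proteomes have far heavier terminal-sequence sharing, which is exactly
what makes the method economical there.

Random cover instances for solver tests are Erdős–Rényi bipartite graphs
repaired to guarantee feasibility (every protein gets at least one edge;
isolated epitopes are attached to one random protein so vertex counts match
the request).

## Numerical and scale choices

* Floating-point mass comparison uses strict `<` against Δ_min, matching the
  "almost the same weight" reading; the 1.068 Da pair is undetectable at
  Δ_min = 2.0 and survives at 1.0.
* ILP objective values are rounded to the nearest integer before reporting
  (they are sums of binaries; HiGHS returns them to ~1e-9).
* The acceptance script uses 100 random instances with |A| ≤ 13 and
  |P| ≤ 30 plus a 24-protein synthetic proteome — sizes at which the
  brute-force oracle is exact and the full five-solver comparison completes
  in seconds while still exercising non-trivial optima (greedy gaps,
  multicover forcing, budget sweeps).
* Degenerate inputs: empty combination sets flow through the pipeline and
  produce zero-count reports; a graph with an uncoverable protein yields an
  `infeasible` result naming the protein rather than an exception; empty
  selections score coverage 0 with every protein uncovered.

## Known limitations

* No modelling of missed cleavages — real digests are incomplete, so real
  capture groups are supersets of the modelled ones.
* Antibody specificity is binary; affinity differences and off-target
  binding are out of scope.
* The stoplist must be curated by hand; the package does not estimate
  protein abundance.
* IP-MC's elongation-pair artefact is reported, not prevented.
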