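# txpselect

Design tool for immunoaffinity mass spectrometry with terminal-epitope
("TXP") antibodies. Such antibodies recognise a short (3–5 residue) N- or
C-terminal sequence and therefore capture *every* tryptic peptide in a digest
sharing that terminus — so a single well-chosen antibody can enrich peptides
from dozens of proteins at once. The design question this package answers:
given a background proteome and a list of target proteins, **which minimal
set of terminal epitopes covers all targets**, and how can the selection be
biased toward redundant (multiple) coverage for robustness?

## Method

1. **Digest.** The proteome is digested in silico with trypsin: cleavage
   after every K or R not followed by P, complete digest (no missed
   cleavages). Peptide masses are monoisotopic by default.
2. **Combinations.** For each peptide, epitope length *l* ∈ {4, 5} and
   terminus *t* ∈ {n, c}, one peptide–antibody combination
   (protein, peptide, *t*, epitope) is enumerated. The combinations sharing
   an epitope *e* form its capture group C^e.
3. **Filters**, in order: unknown positions (peptides with X — mass not
   computable), methionine in the epitope (oxidation hampers binding),
   high-abundant epitope (|C^e| > 600 — a cluttered, insensitive antibody),
   weight (two peptides in one C^e within Δ_min = 2 Da are mutually
   indistinguishable in the spectrum: both marked undetectable), length
   (peptides outside 8–30 residues fall out of the detection range), and a
   stoplist banning epitopes carried by high-abundant proteins. Filters that
   score capture groups must precede filters that change them; the pipeline
   rejects misordered configurations.
4. **Cover graph.** A bipartite graph G = (P ∪ A, E) connects each target
   protein to every epitope with at least one detectable combination.
   "Robinson" epitopes — capturing a single peptide of a single protein —
   are pruned (unless they are a protein's only cover).
5. **Selection.** Five procedures:
   * `greedy` — classic greedy set cover, approximation ratio H(n);
   * `greedy-mc` — greedy with score s_cov·|new| + s_mcov·|re-covered|;
   * `ip` — exact minimum set cover as a binary linear program
     (min Σ s_a s.t. Σ_{a∋i} s_a ≥ 1 ∀i);
   * `ip-mc` — enforced multicover (≥ 2 for every protein of degree ≥ 2);
   * `ip-mmc` — maximize the number of multiply covered proteins within a
     full cover and an antibody budget cost_max
     (max Σ S_i s.t. Σ_{a∋i} s_a ≥ 1 + S_i, Σ s_a ≤ cost_max).

   ILPs are solved with HiGHS via `scipy.optimize.milp`; a brute-force
   enumerator provides an independent exact oracle for small instances.

The **coverage score** of a solution L is |L| / |P| — antibodies needed per
target protein; lower is better.

## Worked example

```sh
txpselect simulate --n-proteins 12 --seed 5 --group LGYR:c:4 \
    --near-isobaric-pairs 1 --out-fasta syn.fasta --out-manifest man.json
txpselect run --fasta syn.fasta --solver ip --max-epitope-load 50 -o outdir
txpselect report --summary outdir/summary.json
```

prints

```
wrote 12 synthetic proteins -> syn.fasta
ip: selected 8 epitopes for 12 proteins (coverage score 0.667)
method:            ip
status:            optimal
epitopes selected: 8
target proteins:   12
coverage score:    0.667 (66.7% antibodies/protein)
single covered:    11
multi covered:     1
```

The synthetic proteome plants four proteins sharing the C-terminal epitope
LGYR plus one near-isobaric peptide pair. The optimum needs only 8 epitopes
for 12 proteins because one LGYR antibody covers the whole planted group;
the near-isobaric pair was marked undetectable by the weight filter (its two
peptides differ by ~1.07 Da, below the 2 Da tolerance) and contributes no
coverage. `outdir/` also holds the filter-impact table, the graph edge list
and the per-epitope solution table.

The library mirrors the CLI one-to-one:

```python
import txpselect as t
records = t.read_fasta("proteome.fasta")
cset = t.enumerate_combinations(t.digest_proteome(records), {4, 5}, {"n", "c"})
filtered, report = t.run_pipeline(cset, t.FilterConfig())
graph = t.remove_robinson(t.build_graph(filtered, targets=my_targets))
result = t.ilp_cover(graph)
print(result.solution.coverage_score)
```

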