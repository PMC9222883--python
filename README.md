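# omegascan

Parallel selection-pressure analysis on protein-coding sequence alignments.

Natural selection on a protein leaves a signature in the ratio of
nonsynonymous to synonymous substitution rates, ω = dN/dS: ω < 1 indicates
purifying selection, ω ≈ 1 neutral evolution, and ω > 1 positive (adaptive)
selection. `omegascan` fits the standard battery of maximum-likelihood
codon substitution models to an in-frame codon alignment and a phylogeny,
runs the nested likelihood-ratio tests automatically, and compiles the
evidence per codon and per branch:

* **Site models** — M1a vs M2a and M7 vs M8 (df = 2 each): does a class of
  sites with ω > 1 improve the fit? Significant comparisons trigger naive
  and Bayes empirical-Bayes (NEB/BEB) posterior probabilities that each
  codon belongs to the positive-selection class.
* **Branch-site models** — model A and its ω₂ = 1 null (df = 1), run once
  per possible foreground branch: episodic positive selection at sites on a
  single lineage. Every branch of the tree is enumerated automatically as a
  `#1`-labelled tree copy.
* **Branch models** — foreground ω free vs fixed at 1 (df = 1), also per
  enumerated foreground branch: lineage-wide shifts in average ω.
* **FEL scan** — per-codon synonymous (α) and nonsynonymous (β) rates
  against an α = β null (df = 1): the one test that detects *negative*
  (purifying) selection site by site, alongside positive selection.

Model fits use a 61-sense-codon HKY-style rate matrix (transition bias κ,
F3x4 or equal codon frequencies), Felsenstein pruning with per-node
scaling, and bounded quasi-Newton optimization. Independent tasks (one per
model × foreground topology) run in parallel processes and persist results
atomically, so aborted runs resume where they stopped and the output is
byte-identical for any thread count.

A built-in simulator generates alignments under every implemented model,
which is how the statistical behaviour of the tests (type-I error, power,
parameter recovery) is validated without any external data.

## Worked example

Simulate a small dataset with a genuine positive-selection class and run
the full battery from the shell:

```python
from omegascan import SimulationSpec, balanced_tree, make_mixture, write_fixture_set

tree = balanced_tree(6, 0.5, seed=2)                    # 6 taxa, 9 branches
mix = make_mixture("M2a", kappa=2.0, q0=0.55, q1=0.65,  # ~16% of sites at omega 5
                   omega0=0.1, omega2=5.0)
write_fixture_set(SimulationSpec(tree=tree, mixture=mix, n_codons=60, seed=13),
                  "example", basename="sel")
```

```sh
cd example && omegascan -p 2 -t 1h
```

This writes `sel.run/summary.txt`, which for this seed begins:

```
# Selection analysis summary: sel
# significance threshold s = 0.05

## Test 1: site models
M1a/M2a: lnL_null=-974.791470 lnL_alt=-970.473540 stat=8.635860 df=2 p=0.0133274 SIGNIFICANT
M7/M8: lnL_null=-976.837613 lnL_alt=-970.543651 stat=12.587925 df=2 p=0.00184743 SIGNIFICANT
M8-BEB significant sites (posterior >= 0.95): 1(0.972), 6(0.962), 9(0.988), ...
```

Both comparisons reject their null: a positive-selection site class is
supported, and the empirical-Bayes lists name the codons driving it. The file continues with the NEB/BEB codon lists, and
`sel.run/codon_overview.tsv` maps every codon to its posteriors, FEL α/β
estimates and p-value, while `sel.run/highlighted.fasta` uppercases the
significant codons for downstream re-alignment. Run `omegascan -i` for
task-level status and `omegascan -c` to remove temporary task folders.

Real datasets are driven the same way by a ctl file naming the inputs
(`seqfile = ALIGNMENT.fasta`, `treefile = TREE.tre`), with the outgroup as
the first sequence, no stop codons, and gap columns removed codon-wise
(`omegascan` verifies and performs the codon-wise cleaning itself).

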