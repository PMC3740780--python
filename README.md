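# symevol

Comparative protein evolution and symbiont community analysis for
*Symbiodinium* clades A–D.

Reef-building corals depend on photosynthetic dinoflagellate endosymbionts
(*Symbiodinium*, "zooxanthellae"), and the deeply divergent subgeneric
lineages (clades A–D) differ functionally — clade D in particular tends to
confer elevated thermal tolerance on the coral holobiont.  A route to the
genetic basis of such differences is to compare rates of protein evolution
(dN/dS, ω) along the clade C and clade D lineages across thousands of
orthologous coding sequences assembled from field-collected, mixed-symbiont
transcriptome data.  `symevol` implements that analysis pipeline end to end
for desk-scale, fully synthetic data with known ground truth:

* **Community profiling** (`community_profile`): classify short reads
  (36–76 bp) against six clade-diagnostic marker references (ITS1, ITS2,
  cp23S × clades C/D), remove PCR duplicates, and estimate per-library
  clade-D proportions with length normalisation — the basis for deciding
  which libraries feed which clade's assembly (≥ 95% single-clade rule).
* **Contig joining** (`contig_joiner`): reference-guided meta-assembly —
  join contigs whose top hits (≥ 100 bp, ≥ 85% identity) land on the same
  reference transcript at overlapping or directly adjacent coordinates with
  ≥ 95% overlap identity.
* **Ortholog pipeline** (`ortholog_pipeline`): 6-frame ORF calling with the
  homology-or-≥200-aa retention rule, BLOSUM62 protein alignment,
  reciprocal-best-hit pairing, CD/BCD/ABCD group assembly, codon threading
  with gap/stop column removal, the tree-length filter cascade
  (≤ 2 × n_taxa substitutions per codon, 4 → 3 → 2 taxa), Kimura
  2-parameter divergences and substitution-rate extrapolation.
* **Codon model** (`codon_model`): the Goldman–Yang model with branch-class
  ω — `q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for single-step
  codon changes, normalised to one expected substitution per codon per unit
  branch length — with Felsenstein pruning likelihoods, bounded multi-start
  ML fitting, the one-ratio vs two-ratio branch test
  (`LRT = 2(lnL₁ − lnL₀) ~ χ²₁`), and ML pairwise dN/dS.
* **Corrections** (`stats_multiple_testing`): χ²₁ LRT p-values,
  Benjamini–Hochberg FDR, the sequential goodness-of-fit (SGoF) procedure
  with an exact binomial metatest, and hypergeometric GO-term enrichment.
* **Synthetic data** (`synthetic_data`): generators for every input —
  codon alignments evolved under known branch-specific ω, mixed-clade marker
  reads with error and PCR duplication, planted ortholog universes and
  joinable contig layouts — all deterministic under a seed.

See `docs/methods.md` for the model details, defaults and known limitations.

## Worked example

Simulate a 2,000-codon alignment on the fixed 4-taxon clade tree
((B,C),D,A) with an elevated foreground rate on the clade-D branch
(ω_D = 1.5 against ω_BG = 0.1), then test that branch:

```python
import symevol as se

tree  = se.clade_tree(foreground="D")
truth = se.CodonModelParams(2.0, {"background": 0.1, "foreground": 1.5},
                            se.equal_pi())
aln, _ = se.simulate_codon_alignment(tree, truth, 2000, seed=11)

res = se.branch_test(aln, se.clade_tree(), "D", restarts=1, seed=0,
                     pi=se.equal_pi())
print(f"omega_fg = {res.omega_fg:.3f}   omega_bg = {res.omega_bg:.3f}")
print(f"LRT = {res.lrt_stat:.2f}   p = {res.p_value:.3g}")
```

prints

```
omega_fg = 1.432   omega_bg = 0.097
LRT = 348.21   p = 1.04e-77
```

— both ω values are recovered near their true values and the two-ratio
model is overwhelmingly preferred, as it should be for a branch simulated
under positive selection.  Aggregating a mixed library's per-locus clade-D
proportions reproduces the published community-table arithmetic:

```python
prof = se.aggregate_profile("61_control",
                            {"ITS1": 0.439, "ITS2": 0.387, "cp23S": 0.587}, 521)
print(f"average = {prof.average:.3f}  sd = {prof.sd:.3f}")
# average = 0.471  sd = 0.104
se.assign_pools([prof])
# {'61_control': 'mixed'}
```

A command-line interface mirrors the library
(`symevol simulate|profile-community|join-contigs|build-orthologs|`
`branch-test|divergence|correct|enrich`, with `--config`, `--seed`,
`--log-level`, `--out-dir`).

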