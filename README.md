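# tcrrep

Analysis of T-cell receptor beta-chain (TCRβ) CDR3 repertoires from deep
sequencing, built for paired before/after-treatment comparisons of clonal
structure — the kind of question asked when testing whether a therapy
(e.g. a low-dose DNA-demethylating agent) broadens a patient's peripheral
T-cell repertoire.

The package covers the whole desk-side pipeline:

* **Germline reference handling** — TRBV/TRBD/TRBJ segments with validated
  CDR3 anchor annotations (the V region's second conserved cysteine, the J
  region's conserved phenylalanine of the FG-X-G motif).
* **CDR3 calling** — seed-and-extend V/J gene assignment on raw reads,
  extraction of the anchor-bounded junction (Cys codon through Phe codon,
  both included), productivity classification, and aggregation into
  clonotypes keyed by (V gene, J gene, CDR3 nucleotide sequence).
* **Repertoire metrics** — clonotype frequency distributions, inverse
  Simpson diversity `1/D_s = 1 / Σ p_i²`, Shannon entropy
  `H = −Σ p_i ln p_i`, top-N cumulative frequencies, clones above a strict
  frequency threshold, CDR3 length spectratypes, V×J usage matrices and the
  CD4/CD8-informative V-gene bias (V5-4 + V7-2 + V18) / V7-9.
* **Paired comparison** — clonotype turnover (shared/gained/lost), fold
  changes with a detection-limit floor for clones absent on one side,
  diversity deltas, usage shifts, and a Mann-Whitney rank-sum test (exact
  enumeration for small groups).
* **A V(D)J recombination simulator** — ground-truth repertoires with
  geometric junctional trimming and Poisson N-insertions, clonal abundance
  presets (`pre_like`, `post_like`) that reproduce a published pre/post
  clonality structure (top clone 15.4% with 9 clones above 1% vs top clone
  6.1% with 2 clones above 1%), and multinomial read emission with
  substitution errors — used throughout the test suite as an oracle.

## Worked example

Simulate a pre-treatment-like and a post-treatment-like library (scaled to
2,000 clonotypes / 50,000 reads), call the reads back, and compare:

```bash
tcrrep simulate --preset pre_like  --seed 7 --clones 2000 --depth 50000 --sample UPN1_pre  --out pre
tcrrep simulate --preset post_like --seed 8 --clones 2000 --depth 50000 --sample UPN1_post --out post
tcrrep compare --pre pre/clonotypes.tsv --post post/clonotypes.tsv --out cmp
```

`pre/summary.tsv` then contains (provenance header trimmed):

```
metric	value
n_unique_clonotypes	2000
inverse_simpson	38.3272163
shannon	6.41242416
exp_shannon	609.3691
max_clone_freq	0.1512
top10_cumulative_freq	0.30576
clones_above_0.01	9
clones_above_0.01_cumulative_freq	0.29598
```

The called pre-treatment library recovers the configured clonal skew: the
top clone holds 15.1% of productive reads (truth 15.4%), nine clones exceed
1%, and the top ten hold 30.6%. `cmp/deltas.tsv` quantifies the contrast
with the post-like library:

```
pre_inverse_simpson	38.3272163
post_inverse_simpson	197.872569
d_inverse_simpson	159.545353
pre_max_clone_freq	0.1512
post_max_clone_freq	0.06
```

Inverse Simpson diversity rises from ≈38 to ≈198 while the dominant clone
shrinks from 15.1% to 6.0% of reads — the signature of a repertoire that
has become markedly more even. All outputs are plain TSV with `#`-prefixed
provenance headers; reruns with the same seed are byte-identical.

The same stages are available as library functions
(`tcrrep.simulate_repertoire`, `tcrrep.build_clonotype_table`,
`tcrrep.summarize`, `tcrrep.compare_repertoires`, …) and the `call`
subcommand accepts any FASTQ/FASTA of rearranged TCRβ reads together with a
germline FASTA (`>TRBV7-9|V anchor=30` style headers, or a two-column
anchor TSV).

## Method notes

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, what the simulator does and does not emulate, numerical
conventions, and known limitations.
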