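# Methods

## The CDR3 junction and its anchors

The TCRβ CDR3 is defined as the nucleotide segment starting with the second
conserved cysteine codon near the 3′ end of the V region and ending with the
conserved phenylalanine codon of the J region, both anchor codons included.
"Second conserved cysteine" is operationalized as the 3′-most in-frame
TGT/TGC codon of the supplied V region (the IMGT 2nd-CYS convention); the J
anchor is the first in-frame TTT/TTC that begins the canonical FG-X-G motif,
falling back to the first in-frame Phe codon when the motif is incomplete.
Anchor annotations are supplied explicitly (FASTA `anchor=` tags or a TSV)
and verified by translation at load time; motif-based location is only a
fallback for unannotated references, because silently mislocating anchors in
truncated references is worse than demanding annotation. Coordinates are
0-based, half-open; `anchor_offset` addresses the first base of the codon.

A rearrangement is **productive** when its junction length is divisible by
3, its translation contains no stop, and the translation begins with C and
ends with F. Because the junction by construction starts at a Cys codon and
ends with a Phe codon, in-frame junctions without stops are productive;
frame shifts introduced by junctional editing make the remainder
unproductive, as in real repertoires.

## Clonotype identity and frequencies

A clonotype is a unique (V gene, J gene, CDR3 nucleotide sequence) triple.
Amino-acid-level grouping is offered as a view (the `junction_aa` column)
but is never the aggregation key, because nucleotide-distinct clones can
converge on one amino-acid sequence. D-segment assignment is deliberately
not attempted: the CDR3 definition spans V anchor to J anchor only, and D
identity is rarely unambiguous after trimming.

Frequencies are **read-weighted** fractions of assigned reads and by
default computed over productive clonotypes only (repertoire studies report
"% of all reads" over unique productive sequences); a flag includes
unproductive clones for diagnostics. Whether published diversity values
were computed on productive reads only is typically unstated; productive-only
is this package's documented default.

## Diversity and clonality statistics

* Inverse Simpson `1/D_s = 1/Σp_i²`: 1 for a monoclonal repertoire, equal
  to the clone count for a perfectly even one.
* Shannon entropy `H = −Σ p_i ln p_i` in natural-log units (no base is
  standard in the literature); `exp(H)` is also reported as a base-free
  effective clone number.
* Both are plug-in (maximum-likelihood) estimators with no small-sample
  correction — none is standard in the clinical repertoire literature this
  pipeline mirrors. A bias-corrected inverse Simpson
  (`Σ n_i(n_i−1)/(N(N−1))`) is available separately and off by default.
* "Clones above θ" uses a strict inequality (`p_i > θ`); a clone at exactly
  the threshold is excluded. This matters: the preset pre-treatment
  structure pins its 10th clone at exactly 1%.
* Spectratypes are read-weighted CDR3 nucleotide-length histograms
  (clone-weighted mode available, matching classic electrophoretic
  spectratyping); CDR3 length includes both anchor codons, so productive
  lengths are ≡ 0 mod 3 and concentrate in the 33–51 nt range.
* The CD4/CD8 marker bias is (fV5-4 + fV7-2 + fV18)/fV7-9 over V marginal
  usage, reflecting reported CD4- vs CD8-characteristic Vβ genes; a zero
  CD8-marker denominator yields a flagged undefined value rather than an
  exception.

## The simulator

The simulator is the package's ground-truth generator, standing in for
deposited patient libraries at desk scale.

**Clonal abundance.** Three models: `explicit` (fixed dominant frequencies,
residual split evenly), `expanded` (fixed dominant frequencies atop a
power-law tail, exponent configurable) and `even`. The named presets pin
the dominant frequencies to a published subject's printed clonality
structure:

* `pre_like`: (0.154, 0.028, 0.024, 0.021, 0.018, 0.016, 0.014, 0.012,
  0.011, 0.010) — nine clones strictly above 1% totalling 29.8%, top-10
  cumulative 30.8%;
* `post_like`: (0.061, 0.033) — two clones above 1% totalling 9.4%.

Both presets use a **flat tail** over the remaining clones. This is forced
by the printed post-treatment numbers, where top-2 and top-10 cumulative
frequencies are equal at printed precision (9.4%), so clones ranked 3–10
must contribute < 0.05% combined; any appreciable power-law exponent
violates that. Preset size is 30,000 clonotypes ("tens of thousands of
distinct rearrangements per sample"), putting individual tail clones near
3×10⁻⁵.

**Junctional editing.** Trimming at each of the four coding ends (V 3′, D
5′, D 3′, J 5′) is geometric with support {0, 1, …} and mean `trim_mean`
(default 2.0 nt), capped so the anchor codons always survive (the D may be
fully consumed). N-region lengths are Poisson with mean `insert_mean`
(default 2.5 nt) per junction, bases uniform. This is the standard minimal
junctional-diversity model; the defaults were calibrated a priori to the
toy reference's geometry (15 nt V contribution + 12/15 nt D + 18 nt J
contribution ≈ 46.5 nt before editing) so that productive CDR3 lengths
centre near 43 nt with ~90% of mass inside the reported 33–51 nt window.
Real junctional-edit statistics for the mirrored dataset are unpublished;
these means are calibration choices, not measurements.

**Reads.** Reads are full-length rearrangements (V prefix + junction + J
suffix) drawn multinomially from the true frequencies, with i.i.d. per-base
substitution errors at `error_rate` and constant Phred+33 qualities. The
presets default to error-free reads; tests characterizing error inflation
set the rate explicitly.

**What is not emulated:** PCR amplification bias and primer dropout,
paired-end read structure and merging, indel sequencing errors, UMI
deduplication, allele-level gene resolution, and thymic selection.
Consequently, passing tests demonstrate correctness of the *analysis* under
a clean multinomial sampling model — they do not certify caller accuracy
against platform-specific artifacts of real libraries.

## The caller

V and J genes are assigned by exact k-mer seeding (k = 12 for V, 8 for J)
with diagonal voting followed by ungapped rescoring; a candidate is
accepted only if its longest contiguous run of matching bases reaches 20
(V) or 12 (J), thresholds tuned on the simulator. Ties break to the
lexicographically smaller gene name, making calls deterministic. The anchor
position is projected from the germline annotation through the alignment
diagonal, so junction extraction is positional and works equally for
unproductive reads. Identical read sequences are called once and pooled.
No error-correction or near-identical junction merging is performed
(1-mismatch clustering is deliberately absent: it is not part of the
mirrored analysis, and sequencing-error clonotype inflation is instead
characterized via the simulator).

## Paired comparison

Turnover partitions the union of the two clonotype sets into shared, gained
and lost by key identity. Fold changes are `post_freq/pre_freq`; clones
absent on one side have the absent side floored at 1/assigned_reads of that
sample (the one-read detection limit) and are flagged censored. The
"highest expansion" clonotype is reported twice — as the argmax fold among
shared clones and separately among gained (censored) clones — because
published top-expansion tables include clones essentially absent before
therapy. No multiple-testing correction is applied to per-gene usage
shifts; they are descriptive deltas, with the Mann-Whitney test reserved
for small cross-sample group comparisons. The test enumerates the exact
permutation null of the U statistic (midranks, so ties are handled) for
combined n ≤ 12 and otherwise uses the normal approximation with tie and
continuity corrections.

## Numerical conventions

* Frequency vectors are validated to sum to 1 within 1e-8; `0·ln 0 := 0`.
* The abundance constructor skips renormalization when the constructed
  vector already sums to 1 within 1e-12, so pinned frequencies (e.g. the
  clone at exactly the 1% reporting threshold) are preserved bit-exactly.
* Clonotype tables sort by descending count, then key, making every output
  deterministic; file frequencies are printed at 9 decimals and checked on
  load against counts within 5e-10 (the rounding radius of 9 decimals).
* All randomness flows through seeded numpy generators; simulation and
  read emission use distinct child streams of the configured seed, and
  repeated runs are byte-identical.

## Scale choices

The test suite and acceptance script run the presets at their full 30,000
clonotypes but sample reads at 2×10⁵–10⁶ depth rather than the ~1.75
million reads per library of the mirrored study; caller-exactness checks
use 300-clonotype repertoires at depth 10⁴ across 20 seeds. These sizes
give the binomial confidence intervals used in the checks while keeping a
full run in minutes.

## Known limitations

* The toy reference has 6 V / 2 D / 3 J genes; it exercises every code path
  (including the four marker V genes) but not the combinatorial ambiguity
  of the full 50 V / 13 J human locus. Loading a complete human TRB
  reference is supported but not bundled (no allele resolution, no
  pseudogene classification, no database download).
* Read-level frequencies are used throughout; whether published
  frequencies were computed over reads or cDNA molecules is often
  unstated.
* Amino-acid CDR3s containing non-standard symbols (e.g. a "~" placeholder
  occasionally seen in published tables) are not representable: the
  productivity validator accepts only the 20 standard residues and the
  stop symbol.
* The rank-sum test's exact branch is quadratic in C(n, n_a) and
  intentionally capped at combined n = 12.
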