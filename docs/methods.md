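# Methods

## The model

A morphological character matrix is treated as the encoder of a noisy
communication channel: each OTU is a message, its row of character states
the transmitted codeword, and unscorable cells (missing `?`, inapplicable
`-`) the channel noise. All information measures are plug-in (maximum-
likelihood) Shannon estimates in bits over empirical token distributions;
no bias correction (Miller–Madow or similar) is applied, because the
package's purpose is the descriptive comparison of matrices, not unbiased
estimation, and corrections would break the exact worked-example identities
(a uniform binary character is exactly 1 bit). Where a tolerance matters in
tests we use the analytic plug-in bias `(k_a−1)(k_b−1)/(2T ln 2)` plus
asymptotic standard errors.

### Cells, alphabets, conventions

- A cell is a singleton state, a polymorphism (set of ≥2 states), missing,
  or a gap. A character's alphabet is the set of tokens *observed* in its
  column, not the file-level SYMBOLS declaration — entropies must reflect
  the states that actually occur.
- `0·log₂0 := 0` throughout, so constant characters yield exactly 0 bits.
- Gaps are treated as missing for all information computations; a
  `gap_is_state` / `--gap-is-state` switch instead treats `-` as one more
  state, for datasets where inapplicability is itself informative.
- Polymorphic cells contribute fractional weight `1/|states|` to each listed
  state — deterministic and unbiased, as opposed to random resolution.
- Characters are 0-based internally and 1-based in every output, except TNT
  `ccode` lines, which use TNT's native 0-based numbering.

### Missing data

Two policies are implemented. *Equal redistribution* (the default for
entropy and weighting): each observed state's whole-matrix frequency gains
`(missing fraction)/k`. This shrinks distributions toward uniform, so it
never lowers a character below its scored-only entropy ranking but does
raise low-coverage characters toward 1 bit — a deliberate property of the
rule, worth remembering when weighting heavily incomplete characters.
*Scored-only* renormalisation is kept as the reference policy.

For mutual information the default is **pairwise-complete-case**: the joint
distribution of a character pair uses only OTUs scored for both, with
marginals recomputed on that subset. This guarantees `I ≥ 0` and makes the
diagonal equal the subset entropy (which is why MI diagonals need not match
the per-character entropies when data are missing). The alternative
`redistributed` policy spreads the missing OTUs' mass uniformly over the
observed joint support before applying the MI formula. Pairs informed by
fewer than two OTUs report 0 bits, with `n_joint` exported so sparse pairs
can be masked downstream.

### Joint-entropy prefix curve

`H(first i characters)` is the entropy of the empirical distribution of
i-length token sequences across OTUs. By default every OTU stays in the
curve with `?`/`-`/`{..}` as distinct tokens; this keeps the curve
nondecreasing in i and capped by log₂(#OTUs), the source entropy bound.
The alternative `drop-otu` policy excludes OTUs incomplete within the
prefix, which can be non-monotone (the OTU set changes with i) but never
counts missingness as distinguishing information. Prefixes follow matrix
order by default; the registry of unique sequences is kept in order of
first appearance down the matrix, so the j-th unique sequence of the first
i characters is well defined.

### Channel capacity and saturation

For a character order (matrix order by default; entropy-descending and
seeded-random orders for sensitivity analysis) and each bandwidth
B = 1..n_char, S(B) and N(B) are the raw counts of scored and unscored
cells among the first B characters — no normalisation, since signal and
noise "power" here are cell counts on the same scale — and
`C(B) = B·log₂(1 + S(B)/N(B))`. A prefix with N(B)=0 is noiseless and
reported as infinite capacity; such prefixes are excluded from the argmax.
Saturation is the *smallest* B maximizing C (first attainment), reported
also as a percentage of n_char. `C(n_char)` is order-invariant; the
saturation point generally is not, which is why the order is an explicit,
logged parameter. The wideband limit `C → S·log₂e/n₀ ≈ 1.44·S/n₀` under
constant noise density `N = n₀B` is exposed as `fixed_signal_capacity`,
and the 3-fold repetition code (majority decoding success
`Σ_{i>r/2} C(r,i)pⁱ(1−p)^{r−i}`, 0.784 at p=0.7) as the channel-coding
demonstration.

### Tree fit: Fitch steps, CI, RI

Characters are unordered (nonadditive) with unit cost, matching default
parsimony settings. Step counts use the Fitch–Hartigan plurality recursion,
which is exact on arbitrary trees including polytomies: each internal node
keeps the states preferred by the most children and pays one step per
non-conforming child. Missing/gap tips carry the full observed state set,
polymorphic tips their listed set; counts are root-placement invariant
(verified by test). Per character, `m = (observed states among scored
tips) − 1` and `g = scored tips − count of the most frequent state` (the
star-tree step count); for both bounds polymorphic tips are resolved to the
globally most frequent of their listed states (fractional-weight global
frequencies, ties to the lexically smallest token), which keeps
`m ≤ s ≤ g` coherent with ambiguity-aware Fitch. Characters with `g = 0`
(constant, under-scored) contribute to no sum rather than erroring, since
consensus-tree evaluations hit them constantly. `CI = Σm/Σs` (1.0 when
`Σs = 0`) and `RI = (Σg−Σs)/(Σg−Σm)` (NaN when `Σg = Σm`, i.e. no character
could show homoplasy). Weighted variants multiply all three per-character
terms by a weight vector; they are off by default, matching the unweighted
convention for reported indices.

### Entropy weighting

Raw weight = entropy in bits of the (by default redistributed)
distribution. The `max100` scale maps the highest-entropy character to 100
with half-up rounding — TNT wants bounded integers and the choice of scale
does not affect relative weights — and zero-entropy characters are
deactivated (`ccode ]`) rather than given weight 0 silently. The scale and
redistribution policy are recorded in the script header.

## Synthetic data

The generator draws each character independently from a stated state
distribution; dependent pairs are made by copying a source column and
re-drawing each cell uniformly from the other states with flip probability
ε, giving uniform binary pairs the analytic MI `1 − H₂(ε)`; missingness is
applied last, completely at random (MCAR), with one seeded stream per call
so identical specs yield byte-identical matrices. The tree-based generator
emits one binary character per non-trivial internal edge (tips inside the
clade score 1), a homoplasy-free matrix with CI = RI = 1 on its tree.

What this emulates: controlled marginal distributions, controlled pairwise
redundancy, and uniform incompleteness. What it does not: phylogenetic
autocorrelation among characters (no Mk-style evolution along a tree
except in the clean-matrix construction), taphonomically biased
missingness (real noise concentrates in poorly preserved taxa and
postcranial characters), misidentification noise, and the strong
cranial-sampling bias of real matrices. Passing tests therefore establish
correctness of the estimators and algorithms under known truth, not that
real matrices satisfy MCAR or AWGN assumptions — the capacity analysis
inherits the AWGN simplification by design.

Problem sizes in the test suite (6-OTU enumeration oracles, 200 random
trees of ≤7 tips against exhaustive minimisation, 100 random matrices for
curve properties, n = 512–2000 for MI recovery, T = 1000–10000 for entropy
convergence) were chosen so each check is decisive at desk scale: the
enumeration oracles are exact, and the stochastic tolerances are derived
from the analytic bias and standard-error formulas above rather than tuned.

## Numerical choices and degenerate inputs

- Entropies/MI compare to 1e-12 absolute in exact tests; CSV output rounds
  to 4 decimals.
- All-missing characters: degenerate distribution, H = 0, weight 0, k = 0.
- Capacity of a fully scored matrix: every prefix noiseless, saturation
  defined as the full bandwidth (capacity grows without bound in B).
- `merge_otus` keeps the intersection of scored state sets when non-empty
  (the most restrictive consistent reading), unions under `strict=False`,
  and errors on disjoint singleton states under `strict=True`.
- `binarize` maps a k-state character to k one-vs-rest binary characters;
  missing stays missing in all derived characters, and polymorphisms score
  presence per listed state.

## Known limitations

- Plug-in estimates are biased upward for sparse pairs; use `n_joint` to
  mask them rather than trusting tiny-support MI values.
- The saturation point depends on character order; only the default matrix
  order is a reproducible convention, and cross-study comparisons of
  saturation fractions should state the order used.
- Step-matrix (ordered/additive) characters and NEXUS ASSUMPTIONS blocks
  are out of scope; all characters are treated as unordered.
- Tree search is out of scope: trees are always inputs, and the exported
  TNT weight scripts exist precisely to hand weights to an external search
  program.
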