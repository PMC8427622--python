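# morphinfo

Information-theoretic analysis of discrete morphological character matrices
for phylogenetics and paleontological systematics.

Morphological matrices encode each operational taxonomic unit (OTU) as a
sequence of discrete character states, and almost every fossil-based matrix
is riddled with unscorable cells. `morphinfo` treats such a matrix as a
communication channel and quantifies, in bits, how much classifying
information it actually carries:

- **Per-character entropy** `H = -Σᵢ pᵢ log₂ pᵢ`, the expected information
  from observing one character state. A character constant across OTUs
  carries 0 bits; a uniform binary character carries exactly 1.
- **Pairwise mutual information** `I(A,B) = H(A) + H(B) − H(A,B)`, the
  redundancy between two characters — the ability of one to stand in for the
  other when a specimen is incomplete.
- **Joint entropy of character prefixes** `H(A₁,…,Aᵢ)`, the entropy of the
  distribution of i-length state sequences across OTUs: how many characters
  are needed before every OTU is distinguished (the curve is capped by
  log₂ #OTUs).
- **Channel capacity** `C = B·log₂(1 + S/N)` under an additive-white-
  Gaussian-noise analogy, where bandwidth B is the number of characters,
  signal S the scored cells and noise N the unscored (missing `?` and
  inapplicable `-`) cells among the first B characters. The smallest B
  maximizing C is the matrix's *saturation point*: beyond it, adding
  characters adds more noise than signal.
- **Entropy weighting**: each character's entropy used directly as its
  parsimony weight (scaled to integers for TNT `ccode` scripts), plus
  Fitch-based consistency and retention indices (`CI = Σm/Σs`,
  `RI = (Σg−Σs)/(Σg−Σm)`) to evaluate trees against matrices.

Missing data can be handled by the *equal-redistribution* rule (a binary
character scored 0 in 20% of OTUs, 1 in 40% and missing in 40% is estimated
as p = (0.4, 0.6)) or by renormalising over scored OTUs only.

Input formats: NEXUS (`CHARACTERS`/`DATA` blocks, interleaved or not,
polymorphism `{..}`) and TNT `xread` (`[..]` polymorphism); trees in newick;
anatomical partitions as a TSV of 1-based ranges.

## Worked example

The demonstration matrix of 9 taxa and 3 binary characters (Tail, Feather,
Five digits) contains two identically scored taxa, 7 and 7.1. Merging them
leaves the 8 distinct binary triples exactly once:

```python
from morphinfo import (table2_fixture, merge_otus, entropy_profile,
                       mi_matrix, joint_entropy_prefix,
                       repetition_code_accuracy, fixed_signal_capacity)

m = merge_otus(table2_fixture(), ["7", "7.1"], merged_label="7")
print("H =", entropy_profile(m).H)
print(mi_matrix(m).mi)
curve = joint_entropy_prefix(m)
print("H_joint =", curve.H_joint,
      "| s_2,1 =", curve.sequence(2, 1), "| s_3,3 =", curve.sequence(3, 3))
print("repetition(0.7, 3) =", repetition_code_accuracy(0.7, 3))
print("wideband capacity  =", round(fixed_signal_capacity(1, 1, 1e6), 4))
```

prints

```
H = [1.0, 1.0, 1.0]
[[1. 0. 0.]
 [0. 1. 0.]
 [0. 0. 1.]]
H_joint = [1.0, 2.0, 3.0] | s_2,1 = 00 | s_3,3 = 010
repetition(0.7, 3) = 0.7839999999999999
wideband capacity  = 1.4427
```

Every character carries its maximal 1 bit, yet every character pair shares 0
bits — the matrix is a pure source code with no redundancy: 3 characters
distinguish 2³ = 8 OTUs, but losing any one character collapses OTU pairs.
A 3-fold repetition code over a 70%-reliable channel illustrates what
redundancy buys: majority decoding is right 78.4% of the time. And with
fixed signal power and constant noise density, capacity saturates at
`1.44·S/n₀` bits no matter how far bandwidth grows — the reason real
matrices show character saturation.

The same analyses run from the shell, writing CSV/JSON plus a reproducible
run manifest:

```sh
morphinfo entropy example.nex -o out      # entropy.csv
morphinfo mi example.nex -o out           # mi.csv (long form)
morphinfo joint example.nex -o out        # joint_entropy.csv
morphinfo capacity example.nex -o out     # capacity.csv, noise_*.csv, summary JSON
morphinfo weights example.nex -o out      # weights.csv + TNT ccode script
morphinfo treestats example.nex trees.nwk -o out   # per-character m/s/g, CI, RI
morphinfo simulate --n-otu 32 --n-char 50 --missingness 0.3 --seed 1 -o out
```

For the unmerged 9-taxon matrix, `morphinfo entropy` reports
`H = 0.9911` bits per character (the duplicated taxon skews each state
distribution to 5/9 vs 4/9), and `morphinfo capacity` reports
`saturation_fraction: 100.0` — a fully scored matrix never saturates early.

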