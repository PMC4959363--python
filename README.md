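# refselect

Reference sequence selection for planted (l, d) motif search.

Pattern-driven motif-search tools enumerate candidate motifs from `k` of the
`t` input sequences. Which `k` sequences they start from changes the number
of candidates dramatically — a pair of sequences sharing near-identical
l-mers blows the candidate space up, especially over the protein alphabet.
`refselect` picks a `k`-subset that generates few candidates:

1. **Count table** — the number of l-length strings within Hamming distance
   `d` of both members of an l-mer pair depends only on the pair's distance;
   it is tabulated exactly (arbitrary-precision integers) for distances
   `0..2d`.
2. **Pairwise stage** — for every sequence pair, the Hamming distances of all
   `(n-l+1)^2` window pairs are computed in `O(n^2)` total time with a
   match-count recurrence, folded into a distance histogram, and combined
   with the table into raw and distance-weighted candidate totals. The stage
   is worker-parallel with a deterministic reduction.
3. **Selection** — weighted totals are inverted into a similarity graph,
   clustered with Markov clustering (inflation 1.8), and each cluster is
   refined greedily into an exactly-`k` set; the highest-scoring set wins.
   An exhaustive enumerator over all `C(t, k)` subsets is available as an
   exact mode and test oracle.

The package also ships a planted (l, d) benchmark generator (at-most-d and
exact-d implant modes) and an evaluation metric comparing the first-`k`
sequences against the selected set.

## CLI

```sh
# select k reference sequences and prepose them in the output
refselect select --input data.fa --l 13 --d 4 --k 3 \
    --output reordered.fa --report report.json

# k can be derived from the quorum: k = t - q + h
refselect select --input data.fa --l 13 --d 4 --q 18 --h 2 \
    --output reordered.fa --report report.json

# exact candidate-count / probability table (two significant figures)
refselect table --l 13 --d 4 --alphabet dna

# generate a planted benchmark and the implant answer key
refselect generate --t 20 --n 600 --l 13 --d 4 --seed 7 \
    --output bench.fa --answer answer.json

# candidate totals for first-k vs selected-k and their ratio
refselect evaluate --input bench.fa --l 13 --d 4 --k 3
```

Input may be FASTA or one-sequence-per-line text (auto-detected); all
sequences must have equal length. The alphabet is auto-detected as DNA iff
every character is one of `ACGT`, protein otherwise. Ambiguity codes (`N`,
`X`, …) are rejected rather than silently substituted.

The `select` output contains all `t` input records with the `k` selected
sequences first (in ascending original index) and the rest in original
relative order, ready to feed to a pattern-driven motif-search tool that
takes the first `k` sequences as references. The JSON report records the
selection, cluster diagnostics, candidate totals for the selected and the
first-`k` sets, and their ratio.

## Python API

```python
import refselect as rs

ds = rs.generate_planted_dataset(t=20, n=600, l=13, d=4, seed=7)
params = rs.PMSParams(l=13, d=4, sigma=4)
matrix = rs.similarity_matrix(ds.data, params, workers=4)
chosen = rs.select_references(matrix, k=3)       # MCL + greedy refinement
exact = rs.exhaustive_select(matrix, k=3)        # exact mode (small t)
print(chosen.indices, chosen.total_count)
```

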