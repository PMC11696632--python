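# movestruct

A move-structure full-text index for pangenome matching queries, in Python.

Pangenome references — many near-identical genomes indexed together — are a
natural fit for run-length-compressed full-text indexes: the Burrows-Wheeler
Transform (BWT) of such a reference decomposes into `r` maximal
single-character runs with `r` far below the text length `n`, and `r` grows
with the amount of *distinct* sequence rather than total length. The move
structure turns that compression into a queryable index that is a single
table with one row per BWT run, storing the run character `c`, length `l`,
head offset `p`, the LF-mapping of the head `π = LF[p]`, and the run index
`ξ` containing `π`. An LF step — the primitive behind all BWT matching — is
then

```
j' = π_i + (j − p_i)          (arithmetic)
i' = fast-forward from ξ_i    (short sequential row scan)
```

which gives `O(r)` space and query loops that touch only a handful of table
rows per read character. The package implements the full query repertoire of
this index family:

- **index construction** from FASTA (forward + reverse complement, single
  terminal `$`), via suffix array, BWT and LCP array;
- **run splitting** with balancing parameter `d`, so every LF needs fewer
  than `2d` fast-forwards at the cost of at most `⌈r/(d−1)⌉` extra rows
  ("constant" mode);
- **thresholds** per run and character — placed at the minimum-LCP point
  between consecutive occurrences — deciding whether a mismatching cursor
  repositions up (`jup`) or down (`jdn`), with both a scanning and a
  stored-pointer repositioning engine;
- **pseudo-matching lengths (PMLs)**: the one-pass approximation of matching
  statistics that resets to zero at each mismatch, the standard
  read-classification signal for this index family;
- **backward-search count queries** via top/bottom interval pointers;
- a **round-robin batch loop** (default 16 reads in flight) whose results
  are provably identical to sequential processing;
- a **synthetic pangenome generator** (base genome + mutated copies, read
  sampler with errors) so everything is testable without downloads.

Every structure is validated against brute-force oracles: naive LF, exhaustive
matching statistics, sliding-window counting, and a plain-BWT PML reference
implementation that must agree byte-for-byte with both table modes.

## Worked example

```
$ movestruct simulate pangenome -o pan.fa --base-len 2000 --copies 4 --mut-rate 0.001 --seed 7
$ movestruct simulate reads -f pan.fa -o reads.fq -n 5 --read-len 60 --error-rate 0.05 --seed 8
$ movestruct build -f pan.fa -o pan.idx --mode constant -d 4
[INFO] movestruct: built constant-mode index: n=16001 r=3053 rows=3053 n/r=5.24
$ movestruct stats pan.idx
n       16001
r       3053
rows    3053
n_over_r        5.2411
mode    constant
d       4
...
```

`n=16001`: four 2 kb copies, both strands, plus the sentinel. `n/r = 5.24`
is the rough compression ratio — four near-identical copies pack into a table
of 3,053 rows (a single random 2 kb sequence alone would already need ~3,000
runs; the three extra copies are nearly free). At this size no run needed
splitting (`rows == r`).

```
$ movestruct query pml pan.idx reads.fq -o pmls.txt
[INFO] movestruct: 5 reads: 300 LF steps, 58 fast-forwards, 64 repositioning scans
$ head -2 pmls.txt
>read0_copy1_2455-
14 13 12 11 10 9 8 7 6 5 4 3 2 1 0 0 1 0 0 0 1 0 31 30 29 28 27 26 25 24 ...
```

One PML per read base, left-to-right. Descending stretches like
`14 13 ... 1` and `31 30 ...` are exact matches to the reference running up
to the next sequencing error, where the length resets to 0 — on-target reads
show long descents, off-target reads hover near zero, which is what makes
PMLs a classification signal.

Count queries report occurrence counts (here: a 20-mer drawn from one copy
occurs once per copy, and a random 20-mer not present counts 0):

```python
from movestruct import deserialize_index, read_fasta
idx = deserialize_index("pan.idx")
ref = read_fasta("pan.fa")
idx.count(ref[0][1][100:120])   # -> 4
idx.count("TACGTTTACGGATCAGGCAT") # -> 0
```

The same pipeline is available as a library (`MoveIndex.build(records,
mode="constant", d=4)` → `.pml()`, `.count()`, `.batch_pml()`), with the
lower-level pieces (`build_suffix_array`, `build_move_table`, `split_runs`,
`compute_thresholds`, ...) exposed for inspection and testing.

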