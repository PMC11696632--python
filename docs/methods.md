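# Methods

## The move structure

Let `T` be a text of length `n` over `{A,C,G,T}` terminated by a sentinel `$`
that occurs nowhere else and compares smaller than every base
(`$ < A < C < G < T`). Sorting all rotations of `T` gives the BWM; its last
column is the Burrows-Wheeler Transform `BWT(T)`, and because the sentinel is
unique, rotation order equals suffix order, so the BWT is computed here from a
suffix array. The *LF-mapping* sends a position in the last column to the
position of the same text character in the first column:
`LF[j] = C[BWT[j]] + rank(BWT[j], j)`. Iterating LF walks the text
right-to-left.

The BWT of a pangenome — many near-identical genome copies — is highly
*runny*: it decomposes into `r << n` maximal single-character runs. The move
structure stores one table row per run:

| field | meaning |
|-------|---------|
| `c`   | run character |
| `l`   | run length |
| `p`   | BWT offset of the run head |
| `pi`  | `LF[p]` |
| `xi`  | index of the run containing `pi` |

An LF step from offset `j` in run `i` is then pure table arithmetic,
`j' = pi[i] + (j − p[i])`, followed by a *fast-forward*: a sequential scan
from row `xi[i]` to the row whose interval `[p, p+l)` contains `j'`. All
query state lives in a `(run, offset)` cursor; the BWT string itself is never
materialised at query time.

`pi` and `xi` are stored explicitly per row. Collapsing them into a single
relative offset would shrink the table but obscure the logic; at the problem
sizes this package targets, clarity wins.

## Run splitting (constant mode)

On an unbalanced table a fast-forward may traverse many rows. Balancing with
parameter `d ≥ 2` (default 4) restores a worst-case guarantee: while any
run's image interval `[pi, pi+l)` strictly contains at least `2d` row heads,
that run is split at its `d`-th contained head (splitting both its BWT
interval and its image interval, which adds one new row head elsewhere); the
loop repeats until no run qualifies. A potential argument over per-run head
counts shows the procedure terminates after at most `ceil(r/(d−1))` splits,
and afterwards every LF needs fewer than `2d` fast-forwards. Both bounds are
*measured*, not assumed: `verify_balance` computes the exact worst-case
fast-forward count over all `n` offsets (the count is monotone within a run,
so the per-run maximum is taken at the run's last offset) and the tests
assert `max_ff < 2d` and `rows_added ≤ ceil(r/(d−1))` for `d ∈ {2,4,8}`.

Splitting runs before threshold computation; thresholds and repositioning
pointers are always computed on the final table.

## Thresholds and repositioning

When a query character `c` differs from the BWT character under the cursor,
the cursor must *reposition* to the nearest offset above (`jup`) or below
(`jdn`) that carries `c`. The informative choice is the side whose sorted
suffix shares the longer common prefix with the suffix at the current offset.
Between two consecutive occurrences `a < b` of `c`, the LCP of the up-side
candidate is `min lcp(a+1..j]` and of the down-side `min lcp(j+1..b]`; both
minima bracket the global minimum of `lcp(a+1..b]`, so a single *threshold*
per gap — placed at the **last** position achieving that minimum — encodes
the decision: offsets before the threshold go up, offsets at or after it go
down. Placing the threshold at the last minimum makes exact LCP ties resolve
upward, and the same tie rule is used in the plain-BWT reference
implementation, so all three query routes land on identical offsets (the
validation is nevertheless tie-agnostic: it only asserts the chosen side's
LCP is `≥` the alternative's).

Thresholds are stored as absolute BWT offsets clamped into each row's
interval `[p, p+l]`; the boundary values `p` and `p+l` encode "always down"
and "always up". They are computed from the explicit LCP array (Kasai), which
is affordable at these scales. A row of character `c'` contains no `c`, so
the whole row falls in one gap and inherits one clamped threshold per
character — `σ−1` useful thresholds per row.

Two repositioning engines share the threshold decision. Default mode scans
row-by-row to the nearest run of `c` (cost = rows traversed, recorded in the
`reposition_scans` counter). Constant mode stores, per row, the nearest run
above and below for every character (six useful pointers per row for DNA) and
dereferences exactly one. The landing offset inside the target run is the one
closest to the query row: its last offset when moving up, its first when
moving down — exactly `jup`/`jdn`.

## Queries

**Pseudo-matching lengths.** The cursor starts at BWT offset 0 (an arbitrary
but fixed start; any offset is valid, and the CLI exposes `--start-offset`)
and the read is consumed right-to-left with a running match length `ℓ`.
Case 1 (BWT character equals the read character): `ℓ += 1`, record, LF step.
Case 2 (mismatch): `ℓ` resets to 0, record 0, reposition, then LF step.
Characters outside `{A,C,G,T}` (or absent from the index) record 0, reset
`ℓ`, and leave the cursor in place. PMLs are emitted left-to-right in read
orientation. Each `PML[i]` is witnessed by a real exact match, so
`PML[i] ≤ MS[i]` (matching statistics) everywhere. Reads are never
reverse-complemented at query time: the index holds both strands.

**Backward search.** The count query maintains an inclusive `[top, bottom]`
interval of BWM rows prefixed by the current pattern suffix. Initialisation
is the F-column block of the last pattern character; each extension
repositions the top pointer *downward* and the bottom pointer *upward* to the
nearest in-range offsets carrying the next character (direction forced by the
pointer's role — no thresholds involved), then advances both by LF. The final
interval width is the occurrence count. Counts are validated against naive
sliding-window counting.

**Batching.** `batch_query` processes up to `B` reads (default 16) in one
round-robin loop, advancing each read by one character per turn and loading
the next read as slots free up. This is the scheduling structure that lets a
low-level implementation issue a memory prefetch for one read's next table
row while other reads are serviced; here only the schedule is implemented —
no prefetch intrinsics — and the contract is that results are identical to
sequential processing for every `B`, which the tests assert for
`B ∈ {1, 2, 16, 32}`.

## Synthetic data

`simulate_pangenome` emulates a pangenome as one uniform-random base sequence
plus mutated copies: per-base substitutions to a uniformly random different
base (default rate 0.001, typical of closely related bacterial strains), and
optional single-base indels (default 0). `sample_reads` draws fixed-length
reads uniformly from the records, from either strand, never spanning record
boundaries; with error rate 0 every read is an exact substring of the
two-strand index. `r_growth_experiment` builds indexes over nested copy sets
and tabulates `n`, `r`, `n/r` and distinct canonical 31-mers (lexicographic
minimum of k-mer and reverse complement).

What the generator does *not* emulate: real mutation spectra (transition
bias, structural variation), sequencing error profiles (e.g. nanopore
homopolymer errors), read-length distributions, and base-quality information.
Passing tests therefore demonstrate algorithmic correctness and the
qualitative compression behaviour of repetitive references, not
classification accuracy on real instrument data.

## Numerical and design choices

- **Offsets** are 0-based half-open throughout.
- **Suffix array** by numpy prefix doubling (`O(n log² n)`); LCP by Kasai.
  Construction is quadratic-free and exact; disk-based construction for
  gigabase inputs is out of scope.
- **Multi-record references** are concatenated with a single terminal
  sentinel and no per-record separators; matches spanning record boundaries
  are accepted as a documented approximation.
- **Non-ACGT reference characters**: policy `strip` (remove and warn,
  default) or `reject` (error naming record and offset).
- **Default study sizes** used by the test-suite and the acceptance script:
  50 random texts up to 5 kb for the exhaustive LF sweep; a 2 kb text with
  2,200 patterns for count validation; a 4-copy, 3 kb-per-copy pangenome with
  1,000 mixed 150 bp reads for the PML identity and dominance checks;
  20 texts up to 2 kb for the splitting bounds; 10 texts up to 1 kb for the
  exhaustive repositioning sweep; copies {1,2,4,8,16} of a 2 kb base at
  mutation rate 0.001 for the compression trend.
- **Index serialization** is a versioned JSON container with a magic string;
  loads of corrupt, truncated or version-mismatched files fail cleanly.
  Exact round-tripping (field-equal tables, byte-identical query output) is
  the format's contract.
- **Degenerate inputs**: empty reads yield empty PML vectors; empty patterns
  are rejected; queries against an index lacking thresholds raise a
  configuration error rather than returning wrong answers.

## Known limitations

- Pure-Python query loops: correctness-first, not throughput-competitive;
  cache behaviour, prefetching and latency measurements are out of scope.
- Single sentinel across records means a pattern can match across a record
  boundary; tools using per-record separators may disagree on such patterns.
- The balanced-splitting bound is established empirically on every build
  (`verify_balance`), not proven here.
- PMLs approximate matching statistics from below; they cannot recover
  maximal exact matches.
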