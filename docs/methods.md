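# Methods

## Model

A tandem repeat is modelled as a run of adjacent copies ("units") of a
motif `mt` of fixed length `j ∈ [1, 12]`. A unit is *exact* when it equals
the motif and *degenerate* when it differs by substitutions only — at most
`min(2, ⌊j·d/100⌋)` of them for a degeneration percentage `d ∈ [0, 35]`
(the floor is the only rounding consistent with the 35%-of-a-7-mer =
two-substitutions anchor point; indels inside a unit are not modelled).
Consecutive units may be separated by at most `ga ≥ 0` arbitrary "gap"
characters. A locus qualifies when it accumulates at least the configured
minimum number of units, counting exact and degenerate units alike.

Each reported locus is a 5-tuple ⟨sp, fp, mt, g, lt⟩ — 1-based closed
start/end, motif, total gap characters, unit count — satisfying the span
identity `fp − sp + 1 = lt·j + g` and the gap bound `g ≤ (lt−1)·ga`.

## Algorithm

Words are radix-encoded (`r = 4` DNA / `20` protein) so each motif is an
integer key; encoding is bijective per length and a window's key is
maintained as a rolling hash (one multiply–add per symbol). Per sequence
and motif length the scan is:

1. **Presence table** — one pass flags every occurring motif key.
2. **Degeneration buffer** — for each present key, the *present* keys
   within the substitution budget (Hamming ball, substitutions only).
   Restricting to present keys bounds per-window work by the neighbourhood
   count `C(j,1)(r−1) + C(j,2)(r−1)²`, independent of sequence length,
   giving the O(n) scan. (The quadratic closed form
   `(1/2)(r−1)²j² + (r−1)j` is exposed as
   `neighborhood_size_quadratic_bound`; it over-counts the two-substitution
   term by `j²` vs `j(j−1)` and is treated strictly as an upper bound.)
3. **Bucket scan** — one open bucket per motif key. A window at `p`
   extends the bucket of its own key when it starts past the bucket's end
   and the inter-unit gap `p − fp − 1` is within `ga`; beyond tolerance the
   bucket is emitted (if it reached the minimum unit count) or discarded,
   and a fresh one opens at `p`. The window then extends — but never
   closes or creates — the buckets of the present motifs it is a
   degenerate copy of: a locus exists only from an exact occurrence of its
   motif onward, and only an exact occurrence restarts it.
4. **Overlap resolution** — candidates from all motif lengths are pooled
   per sequence, sorted by start (longer first on ties), and swept once:
   each element is compared to the most recently kept element; if their
   overlap degree (shared length / shorter span × 100) exceeds the
   permitted percentage, the shorter is deleted. Ties keep the
   earlier-starting element, then the lexicographically smaller motif.

### Numerical / procedural choices

- **Gap arithmetic.** Adjacent units have `p − fp = 1`; the gap is
  therefore `p − fp − 1` and extension requires `0 ≤ gap ≤ ga`, so `ga = 0`
  admits exactly contiguous units. Windows starting at or before the
  bucket's end are ignored, which makes `lt` count non-overlapping units
  and keeps the span identity exact.
- **Coordinates** are 1-based fully closed throughout, including the
  output table.
- **Case and unknown symbols.** Input is uppercased (soft-masked FASTA is
  accepted). Symbols without a digit (N and IUPAC codes in DNA; X, B, Z,
  `*` in protein) make the covering windows non-encodable: those windows
  are skipped, never coerced, so a repeat cannot span an N.
- **Strand.** DNA repeats are searched on the given strand only; no
  reverse-complement canonicalization.
- **Determinism.** Buffers store sorted variant keys, output is sorted by
  (sequence, sp, fp, motif), and the overlap sweep is order-defined, so
  runs are byte-identical — including when motif lengths are scanned in
  parallel processes (`-j`).
- **Sparse tables.** Presence tables, buffers and bucket stores hold only
  occupied keys; protein 6-mers (20⁶ ≈ 6.4·10⁷ possible keys) never force
  dense allocation. The bucket store is a hash map with O(1)
  insert/replace, which meets the constant-time insert/delete contract the
  linear-time argument needs.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `min_motif`, `max_motif` | motif length range | 1, 6 | ≤ 12; 1–6 is the microsatellite convention |
| `min_repeats` | minimum units per locus | 5 | global, or one value per motif length |
| `max_gap` (`ga`) | gap characters allowed between units | 0 | 0 = contiguous units only |
| `degeneration_percent` (`d`) | substitution allowance | 0 | budget `min(2, ⌊j·d/100⌋)`; capped at 35 |
| `overlap_percent` | permitted overlap between kept loci | 0 | 0 = keep only the biggest of any overlapping pair |
| `run_mode` | `dna` or `protein` | `dna` | selects radix and digit map |

## Synthetic data and what passing tests show

`synthetic.generate_sequence` draws a uniform i.i.d. background over the
alphabet and writes in planted repeats (perfect, substituted and/or
gapped) with exact ground-truth loci. When given check parameters it vets
the draw with the brute-force finder and regenerates until the resolved
output equals the truth exactly, so recovery tests measure the scanner,
not background luck. The brute-force finder is deliberately a different
algorithm — substring occurrence dictionaries plus pairwise Hamming
comparisons, quadratic cost, no hashing — so its agreement with the
scanner is independent evidence.

Uniform backgrounds lack the compositional skew, mosaic structure and
indel-mutated repeats of real genomes; passing these tests shows the
detection rules are implemented exactly as specified, not that the model
captures every repeat biologists would annotate (in particular,
indel-degenerate microsatellites are outside the model).

Scenario tolerances are chosen so that a vetted background exists at all:
single-symbol motifs are tested gap-free (with `ga ≥ 1`, chance
single-base chains are near-certain in any random sequence), dinucleotide
scenarios use `ga ≤ 1`, and degenerate scenarios run gap-free with a
budget of one substitution per unit placed at unit-internal positions.
Test problem sizes: oracle equivalence on 200 random sequences of length
≤ 200 across motif lengths 1–6; 100 planted scenarios; linear-work ratio
checks at n = 10³, 10⁴, 10⁵.

## Known limitations

- **Locus shift under a two-substitution budget.** With `max_mm = 2` a
  chain anchored one position before a true repeat always ties its span
  (each shifted window differs by ≤ 1 flank symbol + ≤ 1 substitution),
  and the earlier-start tie rule then reports the shifted locus. Reported
  start positions of imperfect repeats are therefore exact up to the
  substitution budget; exact-locus recovery is only guaranteed for budgets
  0 and 1.
- **Overlap sweep is order-sensitive by design.** Comparing against the
  most recently kept element only means the kept set at 0% permitted
  overlap is *not* always a subset of the kept set at a larger percentage
  (deleting a middle element can expose a later one); the pairwise
  monotonicity does hold, and resolution is idempotent.
- **Degenerate units are symmetric, unweighted substitutions** — no
  substitution matrices, no transition/transversion weighting.
- **Compound repeats** (distinct adjacent repeats) are reported as
  separate loci or collapsed by the overlap rule, not annotated as a
  category.
- The statistics column is symbol composition only; no entropy or scoring.
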