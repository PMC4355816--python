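# tandemhash

Exhaustive detection of perfect and imperfect tandem repeats —
microsatellite/SSR-style motifs of length 1–12 — in DNA and protein
(multi)FASTA files, in a single linear pass per motif length.

Tandem repeats are adjacent copies of a short motif, exact (*perfect*) or
carrying a bounded number of substitutions per copy (*imperfect*). They are
workhorse molecular markers in population genetics, parasitology and
forensics, and low-complexity protein repeats (such as the PNAN block of the
circumsporozoite protein) are of direct biological interest. `tandemhash` is
for anyone who needs *every* qualifying repeat locus in a genome or
proteome — not a scored or probabilistic subset — with explicit, simple
parameters: motif length range, minimum copy number, gap tolerance between
copies, substitution (degeneration) percentage, and permitted overlap
between reported loci.

## Method

Every window `Q_p` of length `j = |Q|` is read as a number in a positional
system of radix `r` (4 for DNA, 20 for protein) via a symbol→digit map `m`
(DNA: A=0, C=1, G=2, T=3):

```
h(Q) = Σ_{i=0}^{|Q|−1} m(q_i) · r^(|Q|−1−i)
```

so e.g. h(ACTGC) = 0·4⁴ + 1·4³ + 3·4² + 2·4 + 1 = 121. The key `h(Q)`
indexes two sparse hash tables:

1. a **presence table** flagging every motif that occurs in the sequence,
   from which a **degeneration buffer** is built: for each present motif,
   the *present* motifs within its substitution budget
   `min(2, ⌊j·d/100⌋)` for degeneration percentage `d ≤ 35`;
2. a **repeat table** holding one growing locus (*single bucket*
   ⟨sp, fp, mt, g, lt⟩ = start, end, motif, gaps, copy number) per motif
   key. Each window extends the bucket of its own key and, through the
   buffer, the buckets of motifs it is a degenerate copy of; copies may be
   separated by at most `ga` gap characters. A locus that falls out of
   tolerance is reported if it reached the minimum copy number.

Because the buffer is restricted to present motifs, per-window work is
bounded by the neighbourhood size `C(j,1)(r−1) + C(j,2)(r−1)²` — a constant
in the sequence length — so the scan is O(n). Finally, loci from all motif
lengths are pooled per sequence and overlapping loci beyond the permitted
percentage are resolved by keeping the biggest (the overlap degree is the
shared length over the shorter locus).

## Worked example

```
$ cat example.fa
>chr_demo example with two microsatellites
TTGACACACACACACACAGGTCGATCAGCAGCAGTAGCAGGTTTACGT

$ tandemhash -q example.fa -o repeats.tsv -i 2 -y 6 -r 4 -g 0 -v 0 -d 35 -m n
tandemhash: 1 sequence(s) read from example.fa; motif lengths 2-6, mode dna
tandemhash: chr_demo: 2 repeat(s) kept
tandemhash: 7 candidate(s), 2 kept after overlap resolution -> repeats.tsv

$ cat repeats.tsv
# sequence_id	sequence_length	min_repeats_allowed	repetition_amount	start	end	gaps	statistics	repeat
chr_demo	48	4	4	3	18	0	A:50.00;C:43.75;G:6.25;T:0.00	GACACACACACACACA
chr_demo	48	4	5	26	40	0	A:33.33;C:26.67;G:33.33;T:6.67	CAGCAGCAGTAGCAG
```

Two loci survive overlap resolution. The first is the (AC)ₙ block reported
as four copies of the 4-mer `GACA` (at 35% degeneration a 4-mer may carry
one substitution, so the three `CACA` copies extend the `GACA` locus — and
spanning 16 bases it is bigger than the 2-mer reading, so it wins the
overlap sweep). The second is a CAG repeat whose fourth copy is the
one-substitution variant `TAG`; five copies, positions 26–40, no gaps. The
statistics column gives the base composition of each repeat region;
coordinates are 1-based and inclusive.

The flags mirror the method's parameters: `-i/-y` motif length range,
`-r` minimum copies (global, or one value per length: `-r 6,5,5,4,4`),
`-g` maximum gap characters between copies, `-v` permitted overlap
percentage, `-d` degeneration percentage, `-m n|p` nucleotide or protein
mode. `-j N` scans motif lengths in N parallel processes with
byte-identical output.

The same pipeline is available as a library:

```python
from tandemhash import RunParams, scan_all, resolve, kept_candidates

params = RunParams(min_motif=2, max_motif=6, min_repeats=4,
                   degeneration_percent=35)
hits = kept_candidates(resolve(scan_all([("chr_demo", seq)], params),
                               params.overlap_percent))
```

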