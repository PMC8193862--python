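# Methods

## Model and assumptions

`umidedup` treats a UMI-tagged FASTQ library as a mixture of read families:
each original molecule was tagged with one random barcode of fixed length
*k* and amplified into some number of duplicate reads, and sequencing adds
independent substitution errors to both the barcode and the insert. The
method is strictly **columnar**: all reads in a run share one total length,
positions are compared index-by-index, and indels are outside the model. It
is also **alignment-free** — families are defined by barcode identity and
Hamming proximity, never by mapping coordinates, which is what makes the
tool applicable to hypervariable targets (BCR/TCR repertoires) that have no
usable reference.

## Consensus criterion

At each column of a read family, base *b* is scored by
`(freq_pct(b) + meanQ(b)) / 2`, with frequency expressed as a percentage
(0–100) and quality as a raw Phred score (0–41). These two scales were
chosen deliberately so that the two terms have comparable magnitude: a base
seen in 75% of reads at mean Q30 scores 52.5, and neither term can swamp
the other. The averaging scale is the single most consequential numerical
choice in the package and is therefore isolated in one function
(`consensus.consensus_base`); switching to, say, both terms normalized to
[0, 1] is a one-line change there. Qualities are averaged on the Phred
scale, not the error-probability scale — the method's notion of "mean
quality" is the plain arithmetic mean of the integer scores.

Tie handling: a criterion tie goes to the base with the higher **mean**
quality (means are what step 1 computes; a max-single-read-quality reading
of the tie rule would be inconsistent with the rest of the procedure), and
a remaining exact tie goes to the alphabetically smallest base
(A < C < G < N < T), which makes the call deterministic. `N` is a fifth
base symbol with no special handling: it wins a column only by the same
criterion. The emitted quality is the winner's mean quality rounded half-up
and clipped to [0, 41].

The consensus is permutation-invariant, idempotent, and reduces to the
input read under unanimity; if one base strictly dominates every other in
both frequency and mean quality it always wins (the criterion is strictly
monotone in both arguments). These properties are asserted in the test
suite, alongside agreement with an independent brute-force scorer on
randomized groups.

## Data cleaning and merging

Groups with fewer than `countsCutoff` reads are dropped before any
correction; the cutoff is **inclusive** (a group with exactly `countsCutoff`
reads survives — the parameter is a minimum, and a minimum passes itself).
Reads removed this way are counted in the run statistics but not reported
individually.

Merging is greedy and seed-centric. The pool of cleaned groups is sorted by
descending read count with a lexicographic UMI tie-break (so results never
depend on input order); the head of the pool seeds a cluster and absorbs
every remaining group with `hamming(seed_umi, umi) <= UMIdistance` **and**
`hamming(seed_cons, cons) <= sequenceDistance` for the step-1 consensus of
R1 — and independently of R2, when paired. "Each mate independently" was
chosen over R1-only, R2-only, or summed distance because it is the
strictest reading and the only one that cannot merge two molecules whose
forward reads merely share a primer region. Sequence distances are measured
between step-1 **consensus** reads, one per group, not between raw reads
pairwise — the merge operates on the output of the first correction pass.

No chaining: a group farther than `UMIdistance` from the seed is never
absorbed, even if it is close to an absorbed member. With `UMIdistance = 0`
every cluster is a singleton and the final output equals the first-pass
consensus.

The final consensus of a cluster is recomputed over the **pooled raw
reads** of all its groups rather than by averaging the per-group
consensuses. Pooling weights every original read equally, so a 1,001-read
group dominates a 12-read neighbour exactly in proportion to its evidence;
averaging consensuses would give the two groups equal say. The cluster's
representative UMI is the seed's (max-count) UMI — this is the barcode
correction: all absorbed barcodes are reported as variants of it in the
summary table.

For dual-barcode libraries (UMI on both R1 and R2) the two k-mers are
concatenated into a single 2k molecular key; exact grouping and UMI
distances operate on the concatenation, treating the pair as one molecular
identifier.

## Parameters

| Parameter | Meaning | Default |
|---|---|---|
| `pairedData` | paired-end input | `False` |
| `UMIlocation` | `R1` or `R1andR2` | `R1` |
| `UMIlength` | barcode length k (nt) | 12 |
| `sequenceLength` | insert length n (bp) after barcode removal | 50 |
| `countsCutoff` | min reads per UMI kept by cleaning (inclusive) | 1 |
| `UMIdistance` | max Hamming distance for barcode merging | 1 |
| `sequenceDistance` | max Hamming distance between step-1 consensus reads | 3 |

Every read length is validated: a UMI-carrying read must be at least
`UMIlength + 1` long, and every insert (and, in paired runs, every mate)
must equal `sequenceLength` exactly — a mismatch is a hard error, never a
silent trim, because a columnar consensus over ragged reads would be
meaningless. Qualities are Sanger Phred+33 only, clipped to [0, 41];
gzip is detected by the `.gz` suffix.

## Synthetic libraries

The generator (`umidedup.simulate`) emulates exactly the structure the
method assumes: distinct, well-separated truth barcodes (rejection-sampled
to pairwise Hamming distance ≥ `min_umi_separation`, default 3, which makes
"one cluster per molecule" a guarantee under a merge distance of 1 rather
than a likelihood); a fixed or uniform-range duplicate count per molecule;
independent per-base substitution with separate UMI and insert rates, the
substitute drawn uniformly from the three alternatives; and a two-level
quality model — correct bases at `quality_high` (default Q37), substituted
bases at `quality_low` (default Q14). Default study conditions: 200
molecules, 12-nt UMIs, 50-bp inserts, 8–30 duplicates, UMI/insert error
rates 0.002/0.005 per base — a small but realistic targeted-amplicon run at
depths where the consensus has real work to do.

What the simulator does **not** model: indels (excluded by the columnar
method itself), PCR jackpot/efficiency bias, position-dependent or
continuous quality profiles, chimeras, and adapter read-through. Passing
the recovery tests therefore shows the pipeline inverts its own generative
model at realistic error rates; it does not certify behaviour under indel
errors or heavily skewed amplification.

## Numerical and I/O choices

- Deterministic ordering everywhere: groups sorted by (count desc, UMI
  lex), merge seeds chosen the same way, clusters emitted in creation
  order. Two runs on identical inputs are byte-identical.
- Quality rounding: half-up to the nearest integer (FASTQ needs integer
  scores), clipped to [0, 41].
- Degenerate inputs: empty groups, ragged lengths, malformed FASTQ
  records, unsynchronized mate files and inconsistent configurations
  (e.g. dual-location UMIs with single-end data) all fail fast with a
  diagnostic naming the offending record or setting.
- Output files: `<input root>_corrected.<ext>` per input FASTQ plus a
  single `summary_table.csv`, all in a user-named output directory. Output
  read IDs are synthesized (`umi=<UMI>;reads=<count>`) because a consensus
  has no single source read; the summary table is the traceability
  mechanism (per-read ID lists are not stored — they are unbounded).

## Problem sizes in the test suite

The acceptance checks run at desk scale by design: oracle comparisons use
1,000 random groups of ≤ 10 reads × ≤ 20 bp (consensus) and 500 instances
of ≤ 10 UMI groups (merging); parameter recovery uses five 200-molecule
libraries (~3,800 reads each); the worked merge example reconstructs a
four-barcode, 1,049-read cluster. These sizes exercise every code path —
the implementation itself streams records and handles arbitrarily many
reads per file.

## Known limitations

Same-length reads only; substitution errors only; single-sample batches
(all inputs must share one protocol and one read length); no cell-barcode
awareness; no probabilistic (posterior) base calling — the criterion is a
heuristic blend of frequency and quality, not a likelihood model.
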