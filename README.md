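# umidedup

Alignment-free deduplication and error correction of UMI-tagged FASTQ
libraries.

Library protocols that ligate a **unique molecular identifier** (UMI) — a
short random barcode, typically 8–16 nt — to each input molecule before PCR
make amplification duplicates recognizable: every read descending from one
molecule carries (almost) the same barcode. `umidedup` collapses each such
family into a single consensus read, correcting both the sequencing errors
inside the insert and the errors inside the barcode itself, without any
alignment to a reference. That makes it usable as a plain preprocessing
step for any downstream pipeline, including targets with no usable
reference such as B-/T-cell receptor repertoires.

## Method

The workflow has three steps:

1. **Per-UMI consensus.** Reads are grouped by their exact 5′ barcode
   (after a data-cleaning filter that drops UMI groups with fewer than
   `countsCutoff` reads). At each position of a group, every base *b* gets
   a score

   criterion(*b*) = ( freq%(*b*) + meanQ(*b*) ) / 2

   where freq%(*b*) is the percentage of reads showing *b* at that position
   and meanQ(*b*) the arithmetic mean of their Phred qualities. The base
   with the highest criterion is called; a tie goes to the base with the
   higher mean quality, a remaining tie to the alphabetically smallest
   base. The consensus quality is the winner's mean quality, rounded.
2. **UMI merging.** Sequencing errors in the barcode split one molecule
   across several UMI groups. The unassigned group with the most reads
   seeds a cluster and absorbs every group whose UMI is within
   `UMIdistance` (Hamming) of the seed's **and** whose step-1 consensus
   read(s) are within `sequenceDistance` of the seed's (both mates
   independently, for paired data). Absorbed groups leave the pool and the
   next-largest survivor seeds the next cluster — greedy and seed-centric,
   with no transitive chaining.
3. **Final consensus.** Each cluster's consensus is recomputed from the
   pooled raw reads of all its groups and written out — one FASTQ record
   per original molecule, UMI removed.

Three library layouts are supported: single-end with the UMI at the start
of R1; paired-end with the UMI on R1 only; and paired-end with independent
UMIs on R1 and R2 (concatenated into one molecular key).

## Worked example

Simulate a tiny library (4 molecules, 8-nt UMIs, 10-bp inserts, 6 PCR
duplicates each) and run the workflow on it:

```bash
umidedup simulate --n-molecules 4 --umi-length 8 --insert-length 10 \
    --duplicates 6 6 --seed 2 --out-dir demo_raw
umidedup run --UMIlength 8 --sequenceLength 10 --countsCutoff 3 \
    --UMIdistance 1 --sequenceDistance 3 \
    --input-dir demo_raw --output-dir demo_out
```

which prints

```
sim_R1: 24 reads, 4 UMIs -> 4 after cleaning -> 4 molecules
summary: demo_out/summary_table.csv
```

24 raw reads over 4 barcodes collapse to 4 consensus reads, one per
original molecule. `demo_out/sim_R1_corrected.fastq` starts

```
@umi=CGTGTATA;reads=6
CCTTCGATTA
+
FFFFFFFFFF
```

— the record identifier names the cluster's representative UMI and its
pooled read count, the sequence is the corrected insert with the barcode
removed, and the qualities are the per-position mean Phred scores
(`F` = Q37). `summary_table.csv` holds one row per output sequence with the
representative UMI, any absorbed UMIs, pooled counts, and the consensus
sequences with their mean qualities, so every output read can be traced
back to its input barcodes:

```
input_file_root,representative_umi,absorbed_umis,n_umis_merged,pooled_count,consensus_r1,mean_quality_r1,consensus_r2,mean_quality_r2
sim_R1,CGTGTATA,,1,6,CCTTCGATTA,37.0,,
```

All run parameters can also be given as a YAML/JSON file via
`umidedup run --config run.yaml`, with command-line flags taking
precedence.

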