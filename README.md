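# tandemasm

A tandem-repeat-aware de Bruijn graph assembler for short reads.

Conventional short-read assemblers restore tandem repeats by bridging them
with paired-end tags, so any array longer than the insert size collapses.
`tandemasm` instead uses the *relative frequency* of reads: k-mer counts are
normalized into per-genome copy numbers, repeat loops in the graph are
detected and balanced so every loop vertex reaches zero degree (in-weights
minus out-weights), and a weight-consuming traversal then spells each motif
the correct number of times — even for arrays far longer than both the read
length and the insert size, and even from single-end data.

## Pipeline

1. **graph_core** — k-mer counting (optionally both strands), weighted de
   Bruijn graph construction, and cleaning (low-weight edges, tips, bubbles).
2. **coverage_model** — the edge-weight statistics: expected weights, the
   Poisson rate diagnostic, the normalization factor `p = G/(N(L-k+1))` with
   half-up rounding `w' = floor(p*w + 0.5)`, the normal approximation of
   repeat-edge weights, and a required-coverage planner based on the standard
   normal quantile.
3. **repeat_resolver** — detection of valid repeat loops (one entry vertex
   with two in-edges, one exit with two out-edges, all others 1-in/1-out),
   branch weight equalization (rounded median) and loop balancing to zero
   degree.
4. **contig_builder** — traversal with the return-path ambiguity rule: a
   vertex with two edges on a side stays unambiguous when exactly one of them
   lies on a simple return path; loop edges are preferred while they retain
   weight, which restores the repeat count.
5. **simulator** — seeded reference generator (tandem arrays separated by
   random spacers, linear or circular) and paired-end read simulator
   (normal insert sizes, substitution and indel errors).
6. **evaluator** — exact-match tandem-array detection and scoring of
   assemblies against simulation ground truth.
7. **io_formats** — FASTA/FASTQ (plain or gzipped) readers/writers, config
   handling and the CLI.

## CLI

```sh
# simulate a reference with a 300-bp motif repeated 5x between 1000-bp spacers
tandemasm simulate-ref --array 300x5 --spacer 1000 --seed 1 \
    --out ref.fa --truth-out truth.tsv

# paired 100-bp reads at 150x with 1% substitution errors
tandemasm simulate-reads --ref ref.fa --coverage 150 --insert-mean 250 \
    --insert-std 25 --substitution-rate 0.01 --indels --seed 2 \
    --out1 r1.fastq --out2 r2.fastq

# assemble (unitig mode; pairing is never used)
tandemasm assemble --reads r1.fastq --reads2 r2.fastq --k 55 \
    --genome-size 3500 --out contigs.fa

# score the result against the simulation truth
tandemasm evaluate-repeats --contigs contigs.fa --truth truth.tsv --out report.tsv

# coverage needed to resolve an n-bp array of d-bp motifs at confidence q
tandemasm required-coverage --q 0.95 --k 55 --read-length 100 \
    --repeat-length 1500 --motif-length 300
```

All `assemble` flags can also be supplied through `--config FILE`
(`key = value` lines); explicit flags win. Pass `--genome-size` whenever the
genome length is known — the default estimate (distinct k-mer count) is
biased low on repeat-dense sequences, which weakens copy-number recovery.

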