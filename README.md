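# mirscore

Reliability scoring and false-positive profiling for miRNA microarray
expression data.

## The problem

miRNA microarrays report relative fluorescence intensities. After standard
normalization (e.g. RMA), values are comparable *within* a miRNA across
samples, but not *between* miRNAs: many probes show high intensity for miRNAs
that matched sequencing finds essentially absent. Real tissues express only a
few dozen miRNAs at high levels, so array rankings taken at face value are
full of false positives — a problem for anyone prioritizing candidates for
PCR validation or flagging low-confidence features before differential
expression analysis.

## The score

`mirscore` assigns each mature miRNA a reliability score in [0, 1] from three
signals:

- **m** — median expression across all samples,
- **N** — the integer suffix of its miRBase MIMAT accession
  (`MIMAT0000062` → 62). Accessions are chronological, and early-discovered
  miRNAs are overwhelmingly the genuinely, highly expressed ones,
- **c** — the Spearman correlation between the miRNA's expression and that of
  its precursor (hairpin) probe: co-varying mature and precursor signal is
  evidence of genuine biogenesis rather than cross-hybridization.

Each signal is scaled to the unit interval over the analyzed set,

    A = m / m_max,    B = 1 − N / N_max,    C = (c + 1) / 2,

and combined as

    score = w_A·A + w_B·B + w_C·C,    (w_A, w_B, w_C) = (0.5, 0.3, 0.2).

Median and Spearman (rather than mean and Pearson) make the score robust to
outliers. With too few samples for meaningful rank correlations (fewer than
5 by default), or no precursor probes at all, the correlation factor is
either held neutral (C = 0.5) or dropped with the remaining weights
renormalized (`missing_corr="drop-weight"`).

The default weights maximize *specificity*: the factor by which discordant
selections (scored-high on the array, unexpressed by sequencing) shrink
relative to selecting the same number of miRNAs by raw intensity.
`optimize_weights` reproduces that selection by exhaustive simplex-lattice
search against any sequencing reference profile.

The package also characterizes array false positives at the sequence level:
GC-content of probe sequences (GC-rich probes form more stable mismatched
duplexes) and mismatch-tolerant occurrence counting of each probe sequence in
a genome (Hamming distance, both strands, overlapping sites counted).

## Worked example

Every capability is a short script under `examples/`; all inputs are
generated by the built-in synthetic module (50 truly expressed + 150 planted
false-positive miRNAs over 30 samples by default), so nothing needs to be
downloaded. `python examples/02_validate_against_sequencing.py` prints:

```
42 miRNAs selected by score; 33 concordant with the sequencing reference, 9 discordant; same-size selection by raw median expression: 34 discordant (specificity ratio 3.78x)
scores: expressed group mean 0.81 (sd 0.08) vs 0.58 (sd 0.11), U=6798, two-sided p=2.8e-20
grid search (step 0.25): best weights (w_A, w_B, w_C) = (0.25, 0.25, 0.50), specificity ratio 13.00
```

Reading: of the 42 miRNAs with score > 0.75, 33 are confirmed expressed
(median RPM > 10) in the reference; picking the 42 brightest array features
instead would have admitted 34 unconfirmed miRNAs rather than 9 — a 3.78×
specificity gain. Reference-expressed miRNAs score far higher than the rest
(0.81 vs 0.58), and on this fixture the grid search pushes weight onto the
precursor-correlation component, which carries the cleanest signal by
construction.

The same pipeline is available from a shell:

```bash
mirscore simulate --out fixture --seed 0
mirscore score --mirna fixture/mirna_expression.tsv \
    --precursor fixture/precursor_expression.tsv \
    --aliases fixture/aliases.txt --mapping fixture/mapping.tsv \
    --out scores.tsv
mirscore validate --scores scores.tsv --reference fixture/reference.tsv
mirscore fp-profile --expression fixture/mirna_expression.tsv \
    --reference fixture/reference.tsv --fasta fixture/mature.fasta \
    --genome fixture/genome.fasta --out fp.tsv
```

Real inputs drop in the same way: a TSV/CSV expression table (rows =
miRNAs), miRBase `aliases.txt` plus a precursor→mature mapping (or a
miRBase-style GFF3), an optional mature FASTA, and a two-column
`name, median_rpm` reference profile.

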