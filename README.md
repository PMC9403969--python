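# rnascan

Windowed thermodynamic z-score scanning and consensus secondary-structure
prediction for RNA transcripts, with downstream analytics.

A fixed-size window (default 120 nt, step 1) slides along each transcript.
Per window the package computes the minimum free energy (MFE) of folding,
a thermodynamic z-score against composition-preserving shuffles
(mononucleotide or Altschul–Erickson dinucleotide; default 100
randomizations), an empirical p-value and the ensemble diversity.  Base
pairs recurring across low z-score windows are accumulated (Zsum),
normalized by window exposure (Znorm), and competition is resolved so
each nucleotide keeps at most one partner; maximal nested components with
at least one pair at or below a z-score cutoff are extracted as motifs.
Downstream tools aggregate per-transcript and per-region (5'UTR/CDS/3'UTR)
metrics, summarize expression classes, bin covariation power, and run ROC
comparisons of predicted structures (CT files) against DMS/SHAPE
reactivity profiles.

## CLI

```sh
# scan: per-window tables + wig tracks (z, dG, ED, per-nt z-average)
rnascan scan transcripts.fa --out-dir scan_out \
    --window 120 --step 1 --randomizations 100 --shuffle mono \
    --temperature 37 --seed 1 --backend auto

# fold: consensus pairing, final partners, motif GFF3/CT/dbn, arc track
rnascan fold transcripts.fa --scan-dir scan_out --out-dir fold_out \
    --extract-z -2 --competition 1 --znorm-denominator pair

# metrics: per-transcript aggregates, regional z-averages, expression groups
rnascan metrics transcripts.fa --scan-dir scan_out --out metrics.tsv \
    [--gene-groups groups.tsv]

# roc: ROC sweep of a CT structure against a reactivity profile
rnascan roc --ct motif.ct --reactivity probe.react --out roc.tsv [--ac-only]

# power: bin covariation power values [0,0.1), [0.1,0.25), >=0.25
rnascan power pairs.power
```

FASTA headers may be plain identifiers or pipe-delimited records with
`UTR5:a-b|CDS:c-d|UTR3:e-f` fields (1-based, inclusive); coordinates are
1-based throughout.

## Layout

- `src/rnascan/seqio.py` — transcript FASTA I/O, region spans, length filter
- `src/rnascan/shuffle.py` — mono-/dinucleotide shuffling, per-window RNG streams
- `src/rnascan/fold/` — folding backend contract, builtin folder, ViennaRNA adapter
- `src/rnascan/scan.py` — windowed scanning, z/p/ED, per-nt z-average, tables/wig
- `src/rnascan/consensus.py` — Zsum/Znorm, competition, classification, motifs, writers
- `src/rnascan/metrics.py` — transcript/regional/expression aggregation, power bins
- `src/rnascan/roc.py` — CT/reactivity readers, threshold sweep, AUC, top-fraction mask
- `src/rnascan/synth.py` — synthetic transcripts/reactivities with recorded ground truth
- `src/rnascan/pipeline.py`, `src/rnascan/cli.py` — end-to-end wiring and CLI
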