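# multiguide

A toolkit for designing CRISPR/Cas9 guide RNAs that work across many
species at once. Given orthologous coding sequences, it finds perfectly
conserved, PAM-adjacent protospacer windows, predicts per-species
functionality by exact target+PAM matching, ranks off-target risk against
paralogs by minimal mismatch count, and designs/interprets T7-endonuclease
genotyping assays in silico.

## Modules

| module | purpose |
| --- | --- |
| `multiguide.seq_core` | sequence model, IUPAC matching, reverse complement, motif scanning, FASTA I/O |
| `multiguide.msa` | progressive multiple alignment (k-mer distances → UPGMA → affine-gap profile merges), alignment I/O, column↔residue coordinate maps |
| `multiguide.conservation` | conserved-window detection and PAM-adjacent guide enumeration |
| `multiguide.prediction` | per-species exact-match classification, min-mismatch off-target scan, flank identity, prediction-table aggregation |
| `multiguide.insilico_validation` | in-silico PCR, Cas9 cut placement, T7 fragment sizes, frameshift fraction |
| `multiguide.synthetic_data` | seeded ortholog-family/paralog generators and packaged fixtures |
| `multiguide.cli` | `multiguide` command-line entry point and report rendering |

## CLI

```bash
# simulate a 6-species ortholog family with one planted conserved window
multiguide simulate --n-species 6 --length 900 --divergence 0.1 \
    --conserved 300:323:pam --seed 7 -o family.fasta

# align and design guides
multiguide align family.fasta -o family.aln.fasta
multiguide design family.fasta --out-tsv guides.tsv --out-fasta guides.fasta

# classify guides against per-species target sequences
multiguide predict guides.fasta family.fasta --out-tsv predictions.tsv \
    --out-json predictions.json

# off-target scan and in-silico genotyping
multiguide offtarget --guide GTGATGTCCCACAGCAGCTG paralogs.fasta
multiguide amplicon template.fasta --forward AGCAGTCAAAAACACCGTCC \
    --reverse GACACCTGGACAACTCATCGG --guide GTGATGTCCCACAGCAGCTG

# summarize a published-style Yes/No prediction table
multiguide report src/multiguide/data/table1.tsv
```

Defaults (guide length 20, PAM `NGG`, conserved-window minimum 20,
mismatch reporting threshold 10, cut offset 3) live in
`multiguide.cli.RunConfig`; a flat YAML config file can override them and
command-line flags win over both. Runs with identical inputs, config and
seed produce byte-identical outputs.

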