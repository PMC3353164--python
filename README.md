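# vamir

Small-RNA miRNA discovery and variant analysis for deep-sequenced plant
libraries, built around the wild Amur grape (*Vitis amurensis* Rupr.)
study system.

Deep sequencing of a small-RNA library yields tens of millions of short
reads.  Turning them into miRNA biology takes a fixed chain of steps, and
`vamir` implements each as a tested, importable module:

1. **Cleaning** (`vamir.sequence_io`) — adapter trimming, quality and
   length filtering (18–30 nt by default), poly-A removal, and collapsing
   into *unique tags* carrying *redundant* read counts.
2. **Annotation** (`vamir.annotate`) — exact both-strand genome mapping
   and partition of every tag into one category (miRNA, rRNA, tRNA,
   snRNA, snoRNA, repeat, siRNA, exon/intron sense/antisense, unann) with
   unique/redundant percentage tables.
3. **Conserved miRNAs** (`vamir.conserved`) — mismatch-tolerant matching
   against a known mature set (0–3 substitutions, ≤3 nt terminal slack),
   per-member and per-family abundance, cross-species family presence
   matrices, and 5′/3′ terminal divergence between ortholog matures.
4. **Variants** (`vamir.variants`) — miR-SNPs (same length, exactly one
   substitution) and miR-LDs (substitution-free terminal extensions or
   truncations) of each conserved miRNA relative to its wild type, plus
   classification of SNP sites against miRNA:target duplexes.
5. **Novel miRNAs** (`vamir.hairpin`) — genomic windows excised around
   unannotated tags are folded and adjudicated against hairpin criteria:
   fold energy under threshold, mature on a single arm of one stem-loop,
   few unpaired mature bases, compact miRNA:miRNA\* duplex, plausible
   precursor length; a sequenced miRNA\* (the duplex partner with 2-nt 3′
   overhangs) is recorded as supporting evidence.
6. **Targets** (`vamir.targets`) — exhaustive complementarity scanning
   with Allen-style penalties (mismatch 1.0, G:U wobble 0.5, bulge 1.0,
   doubled at miRNA positions 2–13), cutoff 4.0, and slicer cleavage-site
   mapping opposite miRNA nucleotide 10 (or 9).
7. **Synthetic data** (`vamir.simulate`) — a seeded generator planting
   hairpin precursors with log-normal expression, SNP/LD variant reads,
   miRNA\* reads, category-stratified background reads and shuffled decoy
   windows, with complete ground truth for closed-loop validation.

RNA secondary structure comes from a built-in stacking-weighted
base-pair-maximization engine (exact dynamic programming over nested
structures) or, via a plug-in contract, any external tool that emits
dot-bracket + MFE lines (e.g. `RNAfold`).

## Worked example

Reproduce the published category accounting of the Amur grape library
from its packaged count table, measure ortholog divergence, and scan a
transcript for a target site:

```python
from vamir import datasets
from vamir.annotate import summarize_category_counts
from vamir.conserved import terminal_divergence
from vamir.targets import scan_transcripts, predict_cleavage, format_duplex
from vamir._util import revcomp

counts = datasets.load_category_counts()
df = summarize_category_counts(counts.unique.to_dict(), counts.redundant.to_dict())
print(df.loc[["miRNA", "siRNA", "unann", "Total"]])

d = terminal_divergence("TTGACAGAAGAGAGGGAGCAC", "TGACAGAAGAGAGGGAGCAC")
print(f"miR156 divergence: d5={d.d5} d3={d.d3} subs={d.internal_substitutions}")

mir = "TGACAGAAGAGAGGGAGCACA"
tx = "G" * 100 + revcomp(mir) + "G" * 100
(hit,) = scan_transcripts(mir, "vam-miR156a", {"tx1": tx}, max_score=4.0)
print("site", hit.start, hit.end, "score", hit.score,
      "cleavage@10:", predict_cleavage(hit, 10).transcript_position)
print(format_duplex(hit.alignment))
```

prints

```
          unique_count  unique_percent  redundant_count  redundant_percent
category
miRNA             1426            0.02          1030053               5.45
siRNA           283866            4.21          2927927              15.49
unann          4815596           71.45          8865829              46.90
Total          6740185          100.00         18902700             100.00
miR156 divergence: d5=1 d3=0 subs=0
site 101 121 score 0.0 cleavage@10: 112
5' TGTGCTCCCTCTCTTCTGTCA 3'  (target)
   |||||||||||||||||||||
3' ACACGAGGGAGAGAAGACAGT 5'  (miRNA)
```

The miRNA class carries 5.45% of redundant reads but only 0.02% of
unique tags — the classic signature of a few highly expressed conserved
miRNAs.  The ortholog pair differs by a single 5′-terminal nucleotide
with an identical core, and the perfect target duplex predicts cleavage
at transcript position 112, the base pairing miRNA nucleotide 10.

A full run over simulated data:

```bash
vamir simulate --seed 7 --out-dir simdata/
vamir clean --in simdata/reads.fastq --adapter3 TCGTATGCCGTCTTCTGCTTG \
    --min-len 15 --out tags.fa
vamir annotate --tags tags.fa --genome simdata/genome.fa \
    --gff simdata/tracks.gff3 --out summary.tsv
```

or configure everything in YAML and use `vamir run --config pipeline.yaml`.

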