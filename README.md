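# rbs-enrich

Sequence analysis for randomized **ribosome-binding-site (RBS) selection
libraries** — the computational arm of an in vitro selection (e.g. ribosome
display in a reconstituted *E. coli* translation system) in which the 18
bases immediately upstream of the start codon are fully randomized
(4^18 ≈ 6.9×10^10 sequences) and enriched for fast translation initiation.

It is written for experimentalists and computational biologists who have
amplicon sequencing of such a pool and want to know *what sequence features
were selected*: canonical Shine-Dalgarno (SD) motifs, non-SD C-rich
signatures, base-pairing potential to the ribosome's rRNA, and secondary
structure.

## What it computes

1. **Read filtering** — the randomized region is located by exact match of
   its fixed 10-base flanks (`TGTTTAACTT` … `ATGGCGGACT`); reads are
   rejected for flank errors, wrong region length, or a codon-aligned
   in-frame ATG.
2. **SD analysis** — classification by containment of the SD motif set
   {AAGG, AGGA, GGAG, GAGG, AGGU}, positional motif profiles over
   positions −18…−1, base composition, cytosine histograms.
3. **rRNA complementarity scan** — for every length-k window (k = 4–8) of
   an rRNA, the number of library members containing its strict
   Watson-Crick reverse complement, with empirical p-values against two
   nulls:

   * **P.rand** — random virtual libraries, p = (1 + #{null ≥ obs})/(N + 1),
   * **P.perm** — per-read permuted libraries (composition held fixed),

   Bonferroni-corrected within each per-k window family and thresholded at
   0.01; neighbouring significant 7-mers are merged into groups (BED
   export).
4. **Exhaustive motif search** — incidence of all 4^k motifs with
   Benjamini-Hochberg **Q.rand / Q.perm** (FDR < 0.01), top-motif tables
   and cross-list comparison (a published human 5′-UTR top-20 ranking is
   bundled); an exact analytic null (automaton containment probability +
   binomial tail) is available in place of Monte-Carlo replicates.
5. **Co-occurrence** — for significant motifs,
   metric(m1, m2) = #{regions with non-overlapping m1 and m2} / #{regions
   with m2}.
6. **Structure scan** — each region embedded in a 70-base molecule, five
   30-base windows at 10-base offset, scored by a simplified
   stacking-energy folding model (pluggable external-folder hook), compared
   against a simulated random library.
7. **Synthetic data** — a generator for naive (uniform N18) and
   round-3-like selected libraries (~24% SD with position-biased planting,
   C-rich non-SD calibrated so 61% carry ≥9 cytosines), wrapped into reads
   with configurable errors and ground-truth identifiers.

See `docs/methods.md` for models, calibrations and limitations.

## Worked example

Simulate a selected pool, recover regions, and analyze:

```bash
rbs-enrich simulate --mode selected --n 2000 --seed 1 --out reads.fasta
rbs-enrich filter --in reads.fasta --out lib.fasta --report report.tsv
rbs-enrich sd --lib lib.fasta --out-prefix sd_
rbs-enrich motifs --lib lib.fasta --k 5 --method analytic --out-prefix m_
```

prints

```
wrote 2000 members (2000 unique) to reads.fasta
accepted 1930/2000 reads (1930 unique)
SD fraction 0.223 (430/1930)
k=5: 114 significant motifs (q<0.01)
```

70 reads were dropped because their regions contained an in-frame ATG by
chance; 22.3% of the accepted regions contain an SD motif (the generator
plants toward the 24% round-3 target; a few percent of members are SD by
chance in either class), and 114 five-base motifs are enriched at
FDR < 0.01 relative to a uniform N18 pool. The top of `m_k5.tsv` by
frequency is dominated by C-rich motifs, e.g.

```
CCCCC  0.194
GCCCC  0.130
CCCGC  0.129
```

i.e. 19.4% of members contain CCCCC — against a ~1.3% expectation under
uniform base usage. The full pipeline (`rbs-enrich run --reads … --rrna
16S.fasta --out outdir`) adds the rRNA scan, co-occurrence and structure
stages and writes a one-page `summary.txt`.

As a library:

```python
from rbsenrich import GeneratorConfig, generate_selected_library, partition_library
lib = generate_selected_library(GeneratorConfig(library_size=4863, seed=1))
sd, non_sd = partition_library(lib)
print(sd.total / lib.total)          # ~0.24
```

## Notes

* Everything is DNA internally (U↔T normalized); outputs can render RNA.
* All statistics are read-multiplicity-weighted by default; pass
  `--unique` to collapse duplicates.
* The rRNA sequence is a user input (FASTA); scans run identically on 16S,
  23S or 5S.
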