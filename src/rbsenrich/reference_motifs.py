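"""Bundled reference motif rankings for cross-list comparison.

Two published top-20 rankings of five-base motifs over the 18 bases
immediately upstream of the start codon: one from a ribosome-display
selection for fast translation in a reconstituted E. coli system, one from
human 5' UTRs (Transterm-derived).  Frequencies are the fraction of
sequences containing the motif.  The compare operation accepts any
user-supplied ranked list; these two ship as the canonical example.
"""

#: (motif, frequency), rank order; selected-for-fast-translation library.
SELECTED_TOP20 = (
    ("CCACC", 0.152),
    ("CCGCC", 0.144),
    ("CGCCC", 0.143),
    ("CCCAC", 0.140),
    ("CCCCC", 0.133),
    ("CACCC", 0.130),
    ("CCCGC", 0.129),
    ("CCCUC", 0.114),
    ("GCCCC", 0.111),
    ("CCUCC", 0.105),
    ("CCCCA", 0.096),
    ("CCCCG", 0.096),
    ("ACCCC", 0.095),
    ("CUCCC", 0.091),
    ("CCCCU", 0.084),
    ("GGAGG", 0.076),
    ("CACGC", 0.074),
    ("CACAC", 0.073),
    ("AGGAG", 0.072),
    ("CGCAC", 0.068),
)

#: (motif, frequency), rank order; human 5' UTRs, 18 bases prior to AUG.
HUMAN_TOP20 = (
    ("CCGCC", 0.079),
    ("GCCGC", 0.071),
    ("GCGGC", 0.067),
    ("CAGCC", 0.062),
    ("GCAGC", 0.061),
    ("GGCGG", 0.059),
    ("CCCAG", 0.058),
    ("CCAGC", 0.055),
    ("CGCCG", 0.053),
    ("CGGCG", 0.052),
    ("CCCGC", 0.050),
    ("CGGCC", 0.050),
    ("CCAGG", 0.049),
    ("CCACC", 0.048),
    ("CCGGC", 0.047),
    ("GCGCC", 0.047),
    ("GCCCC", 0.046),
    ("CUGCC", 0.046),
    ("CCCGG", 0.046),
    ("GGAGG", 0.044),
)
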