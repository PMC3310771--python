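# Methods

This note documents the models, statistical procedures and numerical
choices behind `rbsenrich`. It is written for users who need to know what
the numbers mean, not how the code is organized.

## The analysis in one paragraph

A ribosome-display selection enriches mRNAs whose 18-base randomized region
(the candidate ribosome binding site, RBS, immediately upstream of the AUG)
supports fast translation initiation. The computational arm of such an
experiment, implemented here, is: (i) recover the randomized region from
amplicon reads by exact matching of the fixed 10-base flanks
(`TGTTTAACTT` / `ATGGCGGACT`); (ii) classify regions as Shine-Dalgarno (SD)
or non-SD by substring containment of five four-base SD motifs; (iii) scan
rRNA sequences for windows whose strict Watson-Crick reverse complements
are overrepresented in the library, against Monte-Carlo nulls; (iv) search
all k-mers (k = 4-8) exhaustively for enrichment with FDR control;
(v) quantify co-occurrence between significant motifs; and (vi) profile
secondary-structure propensity of the library in sliding windows against a
simulated random library.

## Read filtering

Reads are rejected, in order, when (1) the upstream flank has no exact
occurrence (`rejected_no_locus`) or no downstream flank follows it
(`rejected_flank`); (2) the enclosed span is not exactly 18 unambiguous
bases (`rejected_length`; regions containing N fall here); (3) the region
contains a codon-aligned ATG that could act as an alternate start site
(`rejected_inframe_start`). The frame is anchored to the downstream start
codon: since 18 = 0 mod 3, region offsets 0, 3, ..., 15 are in frame. Flank
matching is exact over the stored flank bases and the first occurrence
wins; no fuzzy matching and no reverse-strand search, because amplicon
reads are sense-oriented by construction. Duplicate regions are retained as
multiplicities; all statistics count reads by default, with a
unique-sequences mode available, since selection pools are analyzed as
sampled (the observed pool, not its support).

Coordinates are 0-based half-open internally; reports render 1-based
positions, and RBS positions render as -18..-1 with -1 adjacent to the
start codon.

## SD classification

SD candidacy is defined purely by substring containment of the five core
motifs AAGG, AGGA, GGAG, GAGG, AGGT — no duplex thermodynamics. The
extended set (the ten four-base windows of the reverse complement of the
16S 3' tail 5'-GAUCACCUCCUUA-3') is used for positional profiling only,
not for the headline SD/non-SD split. Positional profiles count
occurrences per offset (a member with two occurrences contributes twice);
the overall classification counts members once.

## Null models and p-values

Two nulls are used throughout:

* **random-uniform** (P.rand / Q.rand): virtual libraries of n i.i.d.
  regions (base probability 0.25 each by default), n equal to the observed
  pool. Sensitive to base composition *and* order.
* **permuted** (P.perm / Q.perm): the observed library with each read's
  region independently shuffled. Per-read composition is preserved exactly,
  so only base *order* is tested.

One replicate library yields the full 4^k incidence vector, shared by every
motif/window of that k — replicates are never resampled per motif.
Empirical p-values use the add-one estimator p = (1 + #{null >= obs}) /
(N + 1), which can never return 0 and is stable under Bonferroni
correction. The default replicate count is 1,000 (desk scale); ~100,000
matches the original analysis scale and is reachable via `--replicates`.

An exact alternative to Monte-Carlo exists for the random null: the
probability that an i.i.d. sequence contains a motif is computed by dynamic
programming over the motif's KMP failure automaton (Aho-Corasick for motif
unions), and the null incidence is then Binomial(n, p), giving exact
upper-tail p-values (`method="analytic"`). This route is used wherever the
required resolution would demand >10^5 replicates — e.g. FDR at 0.01 over
4^5 motifs needs raw p below 10^-5 — and it doubles as the independent
oracle against which the Monte-Carlo engine is tested. There is no
analytic closed form for the permutation null, which is always empirical.

Multiple testing: the rRNA scan uses Bonferroni within the per-k window
family of one rRNA (m = |rRNA| - k + 1), threshold 0.01; the motif search
uses Benjamini-Hochberg q-values within each 4^k family, threshold 0.01.
"Incidence" always means members containing at least one occurrence,
multiplicity-weighted (an occurrence-count mode exists behind a flag).

## rRNA scan and grouping

Complementarity is strict Watson-Crick (A:U, C:G) — no G:U wobble, by
definition of the statistic; no wobble option is offered to avoid silent
semantic drift. Window indices are 1-based at the window's first rRNA base.
For k = 7, significant windows sharing six bases with at least one
significant neighbour (consecutive indices) are merged into groups reported
as 1-based inclusive intervals and exported as BED (0-based half-open) for
structure-viewer consumption. Isolated significant 7-mers are dropped from
the grouped output.

## Co-occurrence

For significant motifs m1, m2 (any k, mixed): metric =
#{members containing non-overlapping occurrences of m1 and m2} /
#{members containing m2}. The non-overlap requirement follows the bracketed
definition of the metric; occurrences may overlap other occurrences of the
same motif when searching, but the counted pair must occupy disjoint spans
(two disjoint occurrences when m1 = m2). Self-pairs are excluded from the
table; pairs with zero coincidence or an absent m2 are omitted.

## Secondary structure

Each region is embedded in a 70-base molecule: 26 bases upstream, the
region, 26 bases from the start codon on. The inner 10 bases of each
default flank are the fixed amplicon context; the outer 16 bases are
synthetic vector-style padding (clearly labelled in the source — the full
original vector context is not reproduced here). Five 30-base windows at
offset 10 tile the molecule exactly.

The folding score is a deliberately simple stacking-energy model: minimum
energy over nested pairings (Watson-Crick + G:U), where only stacked
adjacent pairs contribute, using a small embedded nearest-neighbour table
(Turner-style Watson-Crick values at 37 °C; a flat -0.5 kcal/mol for any
stack involving G:U), hairpin loops keep >= 3 unpaired bases, and isolated
pairs contribute 0. There are no multiloop, bulge, dangle or
partition-function terms. This supports the intended use — comparing the
*shape* of a library's dG distribution against a simulated random library —
but is not calibrated to any full thermodynamic folder; users wanting
absolute energies can pass any `sequence -> dG` callable via the `folder`
hook. dG is invariant under U/T rendering, always <= 0, and 0 for any
window admitting no stacked pair (hence all windows <= 6 bases). True
strand symmetry fold(x) = fold(revcomp(x)) holds exactly when G:U pairing
is disabled; with G:U enabled it can break because a G:U pair maps to an
unpairable A:C under complementation.

Default simulated-library size is 10,000 (350,000 matches the original
scale). Histogram bin width is 1 kcal/mol.

## Synthetic data generator

The generator emulates two study conditions:

* **naive**: i.i.d. uniform 18-mers (the N18 pool; 4^18 ≈ 6.9e10 possible
  sequences).
* **selected (round-3-like)**: a mixture targeting the end-state
  composition of the third selection round — 24% SD-classified members and
  76% non-SD members that are cytosine-rich, with 61% of non-SD members
  carrying >= 9 cytosines of 18.

Composition calibration is analytic, not tuned: the default non-SD
cytosine probability (~0.507) is the exact solution of
P(Binomial(18, p) >= 9) = 0.61, and the SD planting fraction f solves
f + (1 - f) q = sd_fraction, where q is the exact Aho-Corasick probability
that a C-rich background draw contains an SD motif by chance. This makes
the *observed* SD-classified fraction equal the requested one, and lets
sd_fraction = 0 degenerate gracefully to chance-level SD containment.
Planted SD motifs overwrite bases (region length is fixed); the planting
offset follows a discretized Gaussian (sigma = 2) centred at region offset
6 — position -12, where SD positional enrichment peaks — with zero mass
where the motif would overrun the region. Motif identity is uniform over
the five core motifs unless weights are given. Read errors: per-base
substitutions at `error_rate` over the whole read, and at most one
insertion-or-deletion inside the region at `length_error_rate`. Ground
truth (original region, indel, substitution counts in flanks/region) is
carried in read identifiers.

What the generator does *not* model: selection dynamics across rounds,
any joint dependence between SD position and surrounding bases, position-
dependent cytosine enrichment, 454 homopolymer error structure, or quality
scores beyond a constant placeholder. Passing tests therefore demonstrate
correct recovery of *planted, independence-structured* signal at realistic
sizes — not performance on real 454 chemistry.

## Problem sizes in tests

Unit and acceptance tests run at sizes chosen to keep the default suite
fast while leaving every statistical check non-vacuous: libraries of
500-5,000 members (4,863 — the analyzed round-3 pool size — for
composition checks), 60-base synthetic rRNAs, 4,000-5,500 Monte-Carlo
replicates where Bonferroni significance at alpha = 0.01 must be
attainable (minimum p = 1/(N+1), so N must exceed m/alpha), and analytic
nulls where q < 0.01 would require >10^5 replicates. The null-calibration
check runs ten fixed-seed scans of uniform libraries and requires zero
significant windows in all of them.

## Known limitations

* Flank matching has no error tolerance by design; one sequencing error in
  either flank discards the read, which understates recovery on noisy data.
* The analytic null assumes i.i.d. bases; for the permuted null only the
  Monte-Carlo route exists.
* The folding model's energies are not comparable to full thermodynamic
  folders in absolute terms.
* Cross-list motif comparison treats the bundled human ranking as a fixed
  reference table; recomputing it requires an external UTR database.
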