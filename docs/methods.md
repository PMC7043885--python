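# Methods

`asdscan` analyzes the role of Shine-Dalgarno (SD) / anti-Shine-Dalgarno
(ASD) base-pairing in bacterial translation initiation from ribosome
profiling data, and ships a generative model of such data so that every
stage can be validated offline. This note documents the models, the
defaults, and the choices made where a convention had to be fixed.

## SD:ASD duplex energy

The affinity between an mRNA window and an ASD tail is scored with a
contiguous-helix nearest-neighbor model: the ASD scan sequence is slid,
ungapped and antiparallel, across the window; within each alignment every
contiguous run of two or more complementary pairs (Watson-Crick, plus G:U
wobble unless disabled) is scored as

```
dG = dG_init + sum(stack dG37) + terminal penalties
```

and the minimum total over all alignments and runs is reported. Internal
loops and bulges are disallowed by construction. Runs of fewer than two
pairs score nothing, and any total >= 0 collapses to the no-duplex sentinel
dG = 0, so SD strength (defined as -dG) is non-negative.

Details fixed here:

* **Parameter table.** The packaged table (`data/rna_nn_dg37.tsv`) carries
  Turner-2004-style RNA/RNA dG37 stacking energies: the 16 Watson-Crick
  steps at their published precision (e.g. 5'GC/3'CG = -3.42 kcal/mol) and
  the 20 wobble-containing steps at 0.1 kcal/mol precision, with a duplex
  initiation penalty of +4.09 kcal/mol and a +0.45 kcal/mol penalty per
  terminal A:U or G:U pair. The table is pluggable: any file in the same
  TSV format can be loaded, and every energy-dependent test in this package
  is phrased against whatever table is loaded rather than against absolute
  literature values.
* **All sub-runs, not only maximal runs.** A G:U-rich run can contain a
  destabilizing (positive) internal stack, in which case a shorter helix is
  lower in energy than the maximal run containing it; the scan therefore
  enumerates every contiguous sub-run. This also makes the mismatch
  monotonicity property exact: disrupting a pair can only remove candidate
  helices, never improve the minimum.
* **Orientation convention.** Both inputs are 5'->3' RNA strings; the
  built-in scan sequences are C = ACCUCCU (wild-type tail ACCUCCUUA),
  S = AGGAGGU (CCUCC core inverted), O = AUGGGAU (core -> UGGGA) and
  A = AAAAAAU (core -> AAAAA). Under this convention the physically
  meaningful symmetry of the scorer is the strand-role swap
  `dg(x, y) == dg(y, x)`.
* **Window.** SD strength is computed on the -15..-6 window (inclusive,
  10 nt) upstream of the A of the start codon (A = offset 0), in transcript
  orientation; the offsets are configurable to support spacing analyses.
  Genes whose leaders do not cover the window are excluded with an error,
  never silently scored.
* **Ties** break toward lower dG, then smaller alignment offset, then
  longer helix.
* **Affinity classes.** dG > -1 kcal/mol counts as "no predicted affinity";
  the weakest class ("low", used as logo foreground) is dG >= 0, which under
  positive-total clipping is exactly the no-predicted-duplex set; "strong"
  requires an explicit user cutoff (typically a quantile of the genome-wide
  distribution) because no universal threshold exists.

## Coverage tracks

Footprint alignments are end-assigned to their 3'-most base and RNA-seq
alignments to their 5'-most base, strand-aware (the 3' end of a
minus-strand alignment is the interval's lowest coordinate), one count per
read, giving stranded single-nucleotide tracks. Raw reads can first be
collapsed by full-sequence identity (UMIs included) and trimmed of the
3' linker (constant CACTCGGGCACCAAGGAC preceded by a 6-nt UMI; one mismatch
tolerated by default) and a 5' UMI. The 5' UMI length is not standardized
and defaults to 4 nt; it is configurable and echoed to the run log. Read
alignment itself is out of scope: the package ingests BED6 records or
pre-made WIG tracks, with an optional interval blacklist for contaminant
loci (tRNA/rRNA and similar). Internally all coordinates are 0-based
half-open; WIG and GFF3 I/O convert to and from their 1-based conventions.
rpm (reads per million mapped) normalization stores the original
`total_mapped` so raw-count filters remain available.

## Ribosome occupancy and delta logRO

Per-gene occupancy RO = (mean footprint rpm over the CDS) / (mean RNA-seq
rpm over the CDS). The scored region is the full CDS by default
(`trim_codons` can exclude start/stop-proximal codons). Genes pass coverage
when both raw-count sums over the scored region reach the thresholds
(default 10 reads each; the threshold behind published gene counts is not
standardized, so it is configurable and logged). delta logRO between two
ribosome variants is log10 RO_ref - log10 RO_alt over genes passing in
both; it cancels every mRNA-intrinsic factor shared by the variants and is
correlated (Pearson) against SD strength. Note that RO has an arbitrary
global scale (it is a ratio of two separately normalized densities), so
only differences and correlations are interpretable; elongation-rate
contributions to footprint density are not modeled.

## Initiation scores and metagene profiles

For each AUG (annotated starts, plus every sense-strand AUG inside
annotated CDS regions in any frame, counted once under overlap), the
initiation score is

```
IS = mean(track, offsets +3..+21) / mean(track, offsets -50..+50)
```

with both windows inclusive (19 and 101 positions). The wide numerator
window captures the 3' ends of initiation-complex footprints of various
sizes. A site is scored only when its wide window holds strictly more than
10 raw reads; eligibility always uses raw counts even when the score is
computed on rpm (IS itself is unit-invariant). Window inclusivity and the
raw-count eligibility basis are conventions fixed and documented here.
Sites whose windows cross a replicon end are flagged and excluded. The
high-IS class uses log2 IS > 1.5. Metagene profiles normalize each site's
window vector to unit sum before averaging, so the profile itself sums
to 1 and deeply covered genes do not dominate.

## Sequence logos and SHAPE windows

Logos contrast a foreground set of AUG-context sequences (offsets -30..+10
around the A) against a background set, per offset and nucleotide, with a
one-sided binomial tail test: the null frequency is the background
frequency with a pseudocount of 1 per nucleotide, the upper tail is used
when the foreground frequency exceeds it (enrichment), the lower tail
otherwise. Letter height is -log10(p), signed by direction, and a
Bonferroni factor of 4 x window width is reported. Only single-nucleotide
columns are computed (no k-mer modes). SHAPE reactivity tracks (high
reactivity = unstructured RNA) are summarized per aligned site set as the
per-offset median and interquartile range over a -60..+60 window, with a
per-site structure score defined as the median reactivity over -25..+25;
missing reactivities are skipped, not imputed, and sites with under 80%
defined positions are excluded and counted.

## The synthetic-data generator

`simulate_transcriptome` builds a single-replicon genome of non-overlapping
AUG-start CDSs (default 500 genes of 100-300 codons, 25-nt 5' leaders,
80-nt spacers, random strands). Each gene's -15..-6 window is drawn from a
mixture: with probability 0.6 an SD-like core (GGAGG or AGGAGGU, carrying
0-3 random mutations) embedded in a random 10-mer, otherwise a plain
random 10-mer — spanning roughly 0 to -10 kcal/mol against the wild-type
ASD. True per-gene, per-variant occupancy follows

```
log10 RO = c + beta_v * strength_v + alpha * Arich - gamma * struct
           [- occl * strength_C for mutants] + N(0, sigma)
```

with defaults beta_C = 0.15 per kcal/mol and beta = 0 for the S/O/A
variants (the mutant ASDs behave as general loss-of-function, with
negligible affinity for natural leaders), alpha = 1.0 per unit A-fraction
(-15..-1), gamma = 0.8 per unit of a latent structure covariate,
sigma = 0.15, and occlusion off by default (0.05 per kcal/mol when
enabled, producing the negative mutant-RO vs wild-type-strength
correlation; both candidate explanations of that signature are thereby
simulable). mRNA abundances are log-normal (sigma = 1); libraries are
negative-binomial counts (dispersion 0.1) at 2e6 reads each, footprints
uniform over the CDS (3'-end assigned) and RNA-seq uniform over the
transcript (5'-end assigned).

Retapamulin-style trapping moves `trap_frac` (default 0.8) of each gene's
footprint mass into 3'-end offsets +12..+18 from the start-codon A
(consistent with the +3..+21 capture window being deliberately generous).
A fraction (default 0.1) of internal AUGs is marked "active" — for every
ribosome variant, matching the observation that the same internal sites
initiate regardless of ASD sequence — and receives a trapped peak of 40x
the host gene's per-nucleotide footprint background. Planted sites are
placed at least 70 nt downstream of the annotated start and at least 75 nt
apart, so that their -50..+50 scoring windows are not confounded by the
annotated trap peak or by one another; unplanted internal AUGs carry no
initiation signal. The SHAPE generator emits baseline reactivity 0.4 with
Gaussian noise (sd 0.1, clipped at 0) over each transcript plus a 60-nt
upstream flank, and adds +0.3 within +/-30 nt of annotated starts.

Everything is deterministic under the config seed (identical config + seed
gives byte-identical files), and library totals equal the drawn counts by
construction.

**What the generator does not emulate:** operons and shared UTRs, non-AUG
starts, codon-level elongation pauses, positional bias in library
construction, rRNA/tRNA contamination, or sequence-dependent SHAPE bias
(the real reactivity dip at the aligned AUG is a sequence artifact this
generator does not produce). Passing the simulation-based tests therefore
demonstrates that the estimators recover the planted structure under the
stated noise model, not that real libraries satisfy that model.

## Numerical and testing choices

* Duplex energies are summed stack-by-stack in window order, and the
  brute-force oracle used in tests does the same, so equality is exact in
  floating point.
* The RO scale constant (from density normalization) is removed by median
  centering before comparing estimated with true log RO.
* Metagene "background" at annotated starts is the +25..+50 elongation
  region (synthetic leaders carry no footprints, so an upstream background
  would be degenerate); for internal AUGs, whose windows lie wholly inside
  a CDS, the all-offset mean is used.
* Planted-site sensitivity is evaluated among sites scorable under the
  >10-read rule: unscorable sites have no IS by definition, and their
  number reflects sequencing depth rather than the detector.
* Simulation-based checks run at 500 genes and 2e6 reads per library
  (about 0.4 Mb of genome), the package's reference conditions; the
  sign-structure experiment repeats over 20 seeds.
* Degenerate inputs fail loudly: empty or non-RNA sequences, reversed
  windows, zero-variance correlation inputs, double rpm normalization,
  out-of-bounds alignments and truncated scoring windows all raise or flag
  rather than returning silent zeros.

## Known limitations

The exact nearest-neighbor table and end conventions of older SD-scanning
tools vary; absolute dG values here are comparable within a table, and all
claims are table-relative. IS and RO conflate initiation with downstream
elongation effects. The logo model treats positions independently and
offers no k-mer or weighted modes. WIG I/O supports the variableStep
dialect only.
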