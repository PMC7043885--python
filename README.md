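# asdscan

Genome-wide analysis of Shine-Dalgarno (SD) function in bacterial
translation initiation, built for ribosome-profiling experiments that
compare ribosome variants carrying altered anti-Shine-Dalgarno (ASD)
sequences — a canonical ASD (C) against mutants (S, O, A) that cannot pair
with natural SD motifs — optionally combined with retapamulin treatment,
which traps newly initiated ribosomes at start codons.

It is aimed at bacterial translation / ribosome-profiling groups and
provides, as a Python library and an `asdscan` command line:

* **SD:ASD hybridization energy** — a contiguous-helix (no loops, no
  bulges) nearest-neighbor RNA:RNA duplex scan of the −15..−6 window
  upstream of each start codon against any ASD scan sequence, with a
  pluggable ΔG37 stacking table; SD strength is −ΔG.
* **Coverage ingest** — UMI collapse, 3′-linker trimming, end-assigned
  (3′ footprints / 5′ RNA-seq) stranded single-nucleotide tracks, rpm
  normalization, variableStep WIG I/O.
* **Ribosome occupancy** — per-gene RO = footprint density / mRNA density;
  ΔlogRO = log₁₀RO_ref − log₁₀RO_alt between ribosome variants, which
  cancels shared mRNA features and isolates the SD:ASD pairing
  contribution; Pearson correlation against SD strength.
* **Initiation analysis** — enumeration of annotated and CDS-internal AUG
  sites, metagene profiles of unit-normalized windows, and the initiation
  score IS = mean(+3..+21) / mean(−50..+50) with the strict >10-read
  eligibility rule, for retapamulin-style libraries.
* **Context analysis** — one-sided binomial probability logos (enriched
  letters up, depleted letters down, height = −log₁₀p) contrasting
  start-site context sets, and windowed median/IQR SHAPE-reactivity
  profiles with a per-site structure score (median over ±25 nt).
* **A synthetic-data generator** with per-gene and per-site ground truth
  (SD ΔG, A-richness, structure covariate, true RO per variant, planted
  active internal AUGs), so the whole pipeline is testable without any
  external download. See `docs/methods.md` for the generative model.

## The core quantities

For a gene g and ribosome variant v:

```
strength(g)   = −min ΔG over alignments of the ASD scan sequence
                to the −15..−6 leader window        (kcal/mol)
RO_v(g)       = footprint density / RNA-seq density (rpm/rpm)
ΔlogRO(g)     = log10 RO_ref(g) − log10 RO_alt(g)
IS(site)      = mean reads at +3..+21 / mean reads at −50..+50
```

The headline analysis is the Pearson correlation of ΔlogRO (SD-competent
minus SD-blind variant) with SD strength, which is strongly positive when
SD:ASD pairing drives occupancy, and the demonstration that start-codon
selection (metagene peaks, IS) is independent of it.

## Worked example

Score the consensus SD motif against the wild-type ASD scan sequence,
then run a simulated two-variant experiment end to end:

```python
import asdscan as a
from asdscan.tracks import rpm_normalize

params = a.load_nn_params("default")
print(a.duplex_delta_g("GGAGG", a.ASD_VARIANTS["C"].asd_seq, params))
# DuplexScore(delta_g=-6.86, offset=-1, helix_len=5, paired_span=(0, 5))

cfg = a.SimConfig(n_genes=500, variants=("C", "A"), seed=1)
tx = a.simulate_transcriptome(cfg)

def records(variant):
    lib = a.simulate_libraries(cfg, tx, variant)
    return a.compute_ro(rpm_normalize(lib.fp_raw), rpm_normalize(lib.rna_raw),
                        tx.genes, fp_raw=lib.fp_raw, rna_raw=lib.rna_raw)

dlro = a.delta_log_ro(records("C"), records("A"))
r, p, n = a.correlate_sd(dlro, tx.gene_truth["strength_C"])
print(f"r={r:.3f} p={p:.3g} n={n}")
# r=0.919 p=3.59e-203 n=500
```

The consensus GGAGG:CCUCC helix scores −6.86 kcal/mol (5 base pairs;
initiation +4.09 plus four stacks). In the simulation, the per-gene
occupancy difference between the SD-competent (C) and SD-blind (A)
ribosomes correlates at r ≈ 0.92 with SD strength across 500 genes — the
coupling the generator planted (0.15 log₁₀ units per kcal/mol), recovered
through the full count-noise pipeline.

The same analyses are available from the shell:

```
asdscan simulate --seed 1 --outdir sim/
asdscan dg --fasta sim/genome.fa --gff sim/genes.gff3 --asd C --out dg.tsv
asdscan occupancy --fp sim/fp_C.wig --rna sim/rna_C.wig \
    --fasta sim/genome.fa --gff sim/genes.gff3 --out occ_C.tsv
asdscan run --config pipeline.yaml     # all stages from one YAML file
```

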