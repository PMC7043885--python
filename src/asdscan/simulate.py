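"""Synthetic transcriptomes and sequencing tracks with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a bacterial-style genome of non-overlapping AUG-start CDSs, each with an
  upstream -15..-6 window drawn from a mixture of random 10-mers and
  SD-like motifs spanning roughly 0..-10 kcal/mol against the wild-type ASD;
* per-gene true log10 ribosome occupancy composed of an SD-strength coupling
  (per ribosome variant), an upstream A-richness effect, a structure penalty,
  an optional occlusion term (mutant ribosomes excluded from strong-SD genes)
  and log-normal gene noise;
* footprint tracks (3'-end assigned, negative-binomial counts over the CDS)
  and RNA-seq tracks (5'-end assigned, uniform over the transcript), with
  retapamulin-style trapping that moves a fraction of each gene's footprints
  into a start-codon peak, and planted "active" internal AUGs that receive
  peaks for every ribosome variant;
* a SHAPE-like reactivity track with a reactivity bonus (less structure)
  around annotated starts.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import thermo
from .annotation import Gene, transcribe, write_fasta, write_gff3
from .initiation import StartSite, enumerate_aug_sites
from .tracks import CoverageTrack
from .wig import write_wig

__all__ = ["SimConfig", "Transcriptome", "SimLibraries",
           "simulate_transcriptome", "simulate_libraries", "simulate_shape"]

_DNA = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generative-model parameters; defaults are the package's reference
    simulation conditions."""

    n_genes: int = 500
    cds_codons: tuple[int, int] = (100, 300)  # min/max codons incl. start
    utr5_len: int = 25
    intergenic_len: int = 80
    replicon: str = "simchr"
    variants: tuple[str, ...] = ("C", "S", "O", "A")
    # SD sampler: mixture of random 10-mers and mutated SD cores
    p_sd: float = 0.6
    sd_mut_max: int = 3
    # occupancy model (log10 RO units)
    beta: dict = field(
        default_factory=lambda: {"C": 0.15, "S": 0.0, "O": 0.0, "A": 0.0}
    )
    alpha_arich: float = 1.0      # per unit A-fraction in -15..-1
    gamma_struct: float = 0.8     # per unit structure covariate
    occlusion: float = 0.0        # mutant-RO penalty per kcal/mol WT strength
    ro_intercept: float = 0.0
    sigma: float = 0.15           # per-gene, per-variant noise SD
    # mRNA abundance and libraries
    mrna_mu: float = 0.0
    mrna_sigma: float = 1.0       # log-normal (natural log) abundance spread
    depth: float = 2e6            # reads per library
    nb_dispersion: float = 0.1
    # retapamulin trapping
    trap_frac: float = 0.8
    start_peak_offsets: tuple[int, int] = (12, 18)  # 3'-end offsets from A
    frac_active_nonannotated: float = 0.1
    active_peak_multiplier: float = 40.0  # peak mass / gene per-nt background
    # SHAPE emulation
    shape_baseline: float = 0.4
    shape_noise: float = 0.1
    shape_start_bonus: float = 0.3
    shape_window: int = 30
    shape_flank: int = 60         # upstream flank with defined reactivity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sd", "trap_frac", "frac_active_nonannotated"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.utr5_len < 16:
            raise ValueError("utr5_len must cover the -15..-6 SD window")


@dataclass
class Transcriptome:
    config: SimConfig
    genome: dict[str, str]
    genes: list[Gene]
    gene_truth: pd.DataFrame       # indexed by gene_id
    site_truth: pd.DataFrame       # one row per non-annotated AUG
    sites: list[StartSite]

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_gff3(self.genes, os.path.join(outdir, "genes.gff3"))
        self.gene_truth.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
        self.site_truth.to_csv(
            os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False
        )


@dataclass
class SimLibraries:
    """Raw-count tracks for one (variant, retapamulin) library pair."""

    variant: str
    retapamulin: bool
    fp_raw: CoverageTrack
    rna_raw: CoverageTrack

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        tag = self.variant + ("_ret" if self.retapamulin else "")
        write_wig(self.fp_raw, os.path.join(outdir, f"fp_{tag}.wig"))
        write_wig(self.rna_raw, os.path.join(outdir, f"rna_{tag}.wig"))


def _sample_sd_window(rng: np.random.Generator, config: SimConfig) -> str:
    """One upstream 10-mer from the SD mixture (DNA alphabet)."""
    window = rng.choice(_DNA, size=10)
    if rng.random() < config.p_sd:
        core = list("GGAGG" if rng.random() < 0.5 else "AGGAGGT")
        n_mut = int(rng.integers(0, config.sd_mut_max + 1))
        for i in rng.choice(len(core), size=min(n_mut, len(core)), replace=False):
            core[i] = rng.choice(_DNA)
        pos = int(rng.integers(0, 10 - len(core) + 1))
        window[pos : pos + len(core)] = core
    return "".join(window)


def simulate_transcriptome(config: SimConfig) -> Transcriptome:
    """Random genome + annotation + per-gene/per-site ground truth."""
    rng = np.random.default_rng([config.seed, 1])
    params = thermo.load_nn_params("default")
    chunks: list[str] = []
    genes: list[Gene] = []
    rows = []
    cursor = 0
    utr5s: dict[str, str] = {}
    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        cds_len = 3 * n_codons
        body = "".join(rng.choice(_DNA, size=cds_len - 6))
        cds = "ATG" + body + "TAA"
        utr5 = list("".join(rng.choice(_DNA, size=config.utr5_len)))
        sd = _sample_sd_window(rng, config)
        # utr5 index j corresponds to offset j - utr5_len; SD window at -15..-6
        utr5[config.utr5_len - 15 : config.utr5_len - 5] = list(sd)
        utr5 = "".join(utr5)
        intergenic = "".join(rng.choice(_DNA, size=config.intergenic_len))
        cassette = intergenic + utr5 + cds
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            chunks.append(cassette)
            cds_start = cursor + config.intergenic_len + config.utr5_len
            cds_end = cds_start + cds_len
        else:
            chunks.append(_revcomp(cassette))
            cds_start = cursor
            cds_end = cursor + cds_len
        cursor += len(cassette)
        genes.append(Gene(gene_id, config.replicon, strand, cds_start, cds_end))
        utr5s[gene_id] = utr5

        upstream_rna = transcribe(utr5)
        a_rich = upstream_rna[-15:].count("A") / 15.0
        struct = float(np.clip(rng.normal(0.5, 0.2), 0.0, 1.0))
        mrna = float(rng.lognormal(config.mrna_mu, config.mrna_sigma))
        row = dict(gene_id=gene_id, strand=strand, cds_len=cds_len,
                   a_rich=a_rich, struct=struct, mrna=mrna)
        strength_c = thermo.sd_strength(
            upstream_rna, thermo.ASD_VARIANTS["C"], params
        )
        for v in config.variants:
            strength = (
                strength_c if v == "C"
                else thermo.sd_strength(upstream_rna, thermo.ASD_VARIANTS[v], params)
            )
            row[f"dg_{v}"] = -strength
            row[f"strength_{v}"] = strength
            noise = rng.normal(0.0, config.sigma)
            occl = 0.0 if v == "C" else -config.occlusion * strength_c
            row[f"log_ro_{v}"] = (
                config.ro_intercept
                + config.beta.get(v, 0.0) * strength
                + config.alpha_arich * a_rich
                - config.gamma_struct * struct
                + occl + noise
            )
        rows.append(row)
    chunks.append("".join(rng.choice(_DNA, size=config.intergenic_len)))
    genome = {config.replicon: "".join(chunks)}
    gene_truth = pd.DataFrame(rows).set_index("gene_id")

    sites, _ = enumerate_aug_sites(genome, genes)
    internal = [s for s in sites if not s.annotated]
    gene_by_id = {g.gene_id: g for g in genes}
    eligible_idx = []
    for j, s in enumerate(internal):
        host = gene_by_id[s.host_gene]
        off = (s.pos_A - host.start) if host.strand == "+" else (host.end - 1 - s.pos_A)
        # planted sites stay clear of the annotated start peak (which would
        # fall inside their scoring window) and of the CDS 3' end
        if 70 <= off <= host.length - 25:
            eligible_idx.append(j)
    n_active = int(round(config.frac_active_nonannotated * len(eligible_idx)))
    # greedy draw keeping planted sites >= 75 nt apart so their scoring
    # windows are mutually unconfounded
    active_set: set[int] = set()
    chosen_pos: dict[str, list[int]] = {}
    for j in rng.permutation(eligible_idx):
        s = internal[j]
        near = chosen_pos.get(s.host_gene, [])
        if all(abs(s.pos_A - p) >= 75 for p in near):
            active_set.add(int(j))
            chosen_pos.setdefault(s.host_gene, []).append(s.pos_A)
        if len(active_set) >= n_active:
            break
    site_truth = pd.DataFrame(
        [
            dict(replicon=s.replicon, strand=s.strand, pos_A=s.pos_A,
                 host_gene=s.host_gene, active=(j in active_set))
            for j, s in enumerate(internal)
        ]
    )
    return Transcriptome(config, genome, genes, gene_truth, site_truth, sites)


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _nb_draw(rng: np.random.Generator, expected: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``expected`` and var e + disp*e^2."""
    counts = np.zeros_like(expected)
    nz = expected > 0
    if dispersion <= 0:
        counts[nz] = rng.poisson(expected[nz])
        return counts
    r = 1.0 / dispersion
    p = r / (r + expected[nz])
    counts[nz] = rng.negative_binomial(r, p)
    return counts


def simulate_libraries(
    config: SimConfig,
    transcriptome: Transcriptome,
    variant: str,
    retapamulin: bool = False,
) -> SimLibraries:
    """Footprint + RNA-seq raw-count tracks for one ribosome variant."""
    vi = ("C", "S", "O", "A").index(variant) if variant in "CSOA" else 9
    rng = np.random.default_rng([config.seed, 2, vi, int(retapamulin)])
    lengths = {rep: len(seq) for rep, seq in transcriptome.genome.items()}
    fp_expected = CoverageTrack.zeros(lengths)
    rna_expected = CoverageTrack.zeros(lengths)
    truth = transcriptome.gene_truth
    active_sites = transcriptome.site_truth.query("active")
    active_by_gene: dict[str, list[tuple[str, int]]] = {}
    for row in active_sites.itertuples():
        active_by_gene.setdefault(row.host_gene, []).append(
            (row.strand, row.pos_A)
        )
    o_lo, o_hi = config.start_peak_offsets
    n_peak = o_hi - o_lo + 1
    for gene in transcriptome.genes:
        t = truth.loc[gene.gene_id]
        mass = t["mrna"] * 10.0 ** t[f"log_ro_{variant}"]
        fp = fp_expected.get(gene.replicon, gene.strand)
        per_nt = mass / gene.length
        if retapamulin:
            fp[gene.start : gene.end] += (1 - config.trap_frac) * per_nt
            _add_peak(fp, gene.start_codon_pos, gene.strand, (o_lo, o_hi),
                      config.trap_frac * mass / n_peak)
            for strand, pos_A in active_by_gene.get(gene.gene_id, []):
                _add_peak(fp_expected.get(gene.replicon, strand), pos_A,
                          strand, (o_lo, o_hi),
                          config.active_peak_multiplier * per_nt / n_peak)
        else:
            fp[gene.start : gene.end] += per_nt
        rna = rna_expected.get(gene.replicon, gene.strand)
        if gene.strand == "+":
            tr = (gene.start - config.utr5_len, gene.end)
        else:
            tr = (gene.start, gene.end + config.utr5_len)
        rna[tr[0] : tr[1]] += t["mrna"] / (tr[1] - tr[0])

    libs = {}
    for name, expected in (("fp", fp_expected), ("rna", rna_expected)):
        total = sum(v.sum() for v in expected.data.values())
        track = CoverageTrack.zeros(lengths)
        for key, vec in expected.data.items():
            track.data[key] = _nb_draw(
                rng, vec * (config.depth / total), config.nb_dispersion
            )
        track.total_mapped = float(
            sum(v.sum() for v in track.data.values())
        )
        libs[name] = track
    return SimLibraries(variant, retapamulin, libs["fp"], libs["rna"])


def _add_peak(vec: np.ndarray, pos_A: int, strand: str,
              offsets: tuple[int, int], mass_per_pos: float) -> None:
    step = 1 if strand == "+" else -1
    for off in range(offsets[0], offsets[1] + 1):
        pos = pos_A + step * off
        if 0 <= pos < len(vec):
            vec[pos] += mass_per_pos


def simulate_shape(config: SimConfig, transcriptome: Transcriptome) -> CoverageTrack:
    """SHAPE-like reactivity track: baseline noise on each transcript (plus an
    upstream flank), with ``shape_start_bonus`` added within +/-
    ``shape_window`` of annotated starts.  Untranscribed positions are NaN."""
    rng = np.random.default_rng([config.seed, 3])
    lengths = {rep: len(seq) for rep, seq in transcriptome.genome.items()}
    track = CoverageTrack.zeros(lengths)
    for key in list(track.data):
        track.data[key][:] = np.nan
    for gene in transcriptome.genes:
        vec = track.get(gene.replicon, gene.strand)
        flank = config.utr5_len + config.shape_flank
        if gene.strand == "+":
            lo, hi = max(0, gene.start - flank), gene.end
        else:
            lo, hi = gene.start, min(len(vec), gene.end + flank)
        vals = np.clip(
            config.shape_baseline + rng.normal(0, config.shape_noise, hi - lo),
            0.0, None,
        )
        vec[lo:hi] = vals
        pos_A = gene.start_codon_pos
        w_lo = max(lo, pos_A - config.shape_window)
        w_hi = min(hi, pos_A + config.shape_window + 1)
        vec[w_lo:w_hi] += config.shape_start_bonus
    return track
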