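"""Declarative end-to-end driver chaining the analysis stages.

A :class:`PipelineConfig` (typically loaded from YAML) names the inputs and
stage parameters; :func:`run_pipeline` executes the requested stages in
dependency order and writes TSV outputs, a copy of the config, and a run log
recording seeds, thresholds, and exclusion counts.  Defaults standing in for
unstated upstream choices (coverage thresholds, UMI length) are echoed to the
log at WARN level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__, annotation, context, initiation, occupancy, thermo
from .simulate import SimConfig, simulate_libraries, simulate_shape, \
    simulate_transcriptome
from .tracks import rpm_normalize
from .wig import read_wig, write_wig

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "asdscan_out"
    # inputs (omit genome/gff to simulate instead)
    genome_fasta: str | None = None
    gff: str | None = None
    fp_wig: dict[str, str] = field(default_factory=dict)   # variant -> path
    rna_wig: dict[str, str] = field(default_factory=dict)
    fp_ret_wig: dict[str, str] = field(default_factory=dict)
    reactivity_tsv: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # stage parameters
    variants: list[str] = field(default_factory=lambda: ["C", "A"])
    reference_variant: str = "C"
    sd_window: tuple[int, int] = (-15, -6)
    min_fp_reads: float = 10
    min_rna_reads: float = 10
    trim_codons: int = 0
    is_threshold: float = 1.5  # log2 IS cutoff for the high-IS class
    logo_offsets: tuple[int, int] = (-20, 10)
    seed: int = 0

    def validate(self) -> None:
        if self.sd_window[0] > self.sd_window[1]:
            raise ValueError(
                f"sd_window must be ordered low..high, got {self.sd_window}"
            )
        if self.logo_offsets[0] > self.logo_offsets[1]:
            raise ValueError(
                f"logo_offsets must be ordered, got {self.logo_offsets}"
            )
        if self.reference_variant not in self.variants:
            raise ValueError(
                f"reference variant {self.reference_variant!r} not in variants"
            )
        if not self.simulate and (self.genome_fasta is None or self.gff is None):
            raise ValueError("genome_fasta and gff are required unless simulating")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("sd_window", "logo_offsets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns {artifact name: path}."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.outdir, "run.log"))
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("asdscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, str] = {}
    try:
        log.info("asdscan %s, seed %d", __version__, config.seed)
        log.warning(
            "coverage thresholds default to min_fp_reads=%s min_rna_reads=%s",
            config.min_fp_reads, config.min_rna_reads,
        )
        with open(os.path.join(config.outdir, "config.yaml"), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh)
        outputs["config"] = os.path.join(config.outdir, "config.yaml")

        stage = "simulate" if config.simulate else "load inputs"
        try:
            if config.simulate:
                sim_cfg = SimConfig(seed=config.seed, **config.sim)
                tx = simulate_transcriptome(sim_cfg)
                tx.write(config.outdir)
                genome, genes = tx.genome, tx.genes
                tracks = {}
                for v in config.variants:
                    libs = simulate_libraries(sim_cfg, tx, v)
                    ret = simulate_libraries(sim_cfg, tx, v, retapamulin=True)
                    libs.write(config.outdir)
                    ret.write(config.outdir)
                    tracks[v] = dict(fp=libs.fp_raw, rna=libs.rna_raw,
                                     fp_ret=ret.fp_raw)
                reactivity = simulate_shape(sim_cfg, tx)
            else:
                genome = annotation.load_genome(config.genome_fasta)
                genes = annotation.load_genes(config.gff)
                lengths = {rep: len(s) for rep, s in genome.items()}
                tracks = {
                    v: dict(
                        fp=read_wig(config.fp_wig[v], lengths),
                        rna=read_wig(config.rna_wig[v], lengths),
                        fp_ret=(
                            read_wig(config.fp_ret_wig[v], lengths)
                            if v in config.fp_ret_wig else None
                        ),
                    )
                    for v in config.variants
                }
                reactivity = (
                    context.read_reactivity_tsv(config.reactivity_tsv, lengths)
                    if config.reactivity_tsv else None
                )

            stage = "dg"
            params = thermo.load_nn_params("default")
            dg_rows = []
            n_short = 0
            for gene in genes:
                upstream = annotation.transcribe(
                    annotation.upstream_sequence(genome, gene, 40)
                )
                row = {"gene_id": gene.gene_id}
                try:
                    for v in config.variants:
                        score = thermo.duplex_delta_g(
                            thermo.extract_window(upstream, config.sd_window),
                            thermo.ASD_VARIANTS[v].asd_seq, params,
                        )
                        row[f"dg_{v}"] = score.delta_g
                        row[f"strength_{v}"] = -score.delta_g
                        row[f"offset_{v}"] = score.offset
                        row[f"helix_len_{v}"] = score.helix_len
                except thermo.WindowError:
                    n_short += 1
                    log.info("gene %s too close to a boundary for the SD "
                             "window: excluded", gene.gene_id)
                    continue
                dg_rows.append(row)
            if n_short:
                log.warning("%d gene(s) excluded from dG scan", n_short)
            dg = pd.DataFrame(dg_rows).set_index("gene_id")
            dg.to_csv(os.path.join(config.outdir, "dg.tsv"), sep="\t")
            outputs["dg"] = os.path.join(config.outdir, "dg.tsv")

            stage = "occupancy"
            records = {}
            for v in config.variants:
                fp, rna = tracks[v]["fp"], tracks[v]["rna"]
                fp_rpm = fp if fp.normalized else rpm_normalize(fp)
                rna_rpm = rna if rna.normalized else rpm_normalize(rna)
                rec = occupancy.compute_ro(
                    fp_rpm, rna_rpm, genes,
                    min_fp_reads=config.min_fp_reads,
                    min_rna_reads=config.min_rna_reads,
                    fp_raw=None if fp.normalized else fp,
                    rna_raw=None if rna.normalized else rna,
                    trim_codons=config.trim_codons,
                )
                records[v] = rec
                path = os.path.join(config.outdir, f"occupancy_{v}.tsv")
                rec.to_csv(path, sep="\t")
                outputs[f"occupancy_{v}"] = path
                log.info("variant %s: %d/%d genes pass coverage",
                         v, int(rec.pass_coverage.sum()), len(rec))

            stage = "dlro/corr"
            ref = config.reference_variant
            corr_rows = []
            for v in config.variants:
                if v == ref:
                    continue
                dlro = occupancy.delta_log_ro(records[ref], records[v])
                path = os.path.join(config.outdir, f"dlro_{ref}_{v}.tsv")
                dlro.to_frame().to_csv(path, sep="\t")
                outputs[f"dlro_{ref}_{v}"] = path
                r, p, n = occupancy.correlate_sd(dlro, dg[f"strength_{ref}"])
                corr_rows.append(dict(pair=f"{ref}-{v}", statistic="delta_log_ro",
                                      r=r, p=p, n=n))
                log.info("corr(delta logRO %s-%s, SD strength): r=%.3f n=%d",
                         ref, v, r, n)
            for v in config.variants:
                r, p, n = occupancy.correlate_sd(
                    records[v]["log_ro"], dg[f"strength_{ref}"]
                )
                corr_rows.append(dict(pair=v, statistic="log_ro", r=r, p=p, n=n))
            pd.DataFrame(corr_rows).to_csv(
                os.path.join(config.outdir, "corr.tsv"), sep="\t", index=False
            )
            outputs["corr"] = os.path.join(config.outdir, "corr.tsv")

            stage = "initiation"
            sites, census = initiation.enumerate_aug_sites(genome, genes)
            log.info("AUG census: %s", census)
            for site in sites:
                if site.upstream_window is not None:
                    window = site.upstream_window[
                        30 + config.sd_window[0] : 30 + config.sd_window[1] + 1
                    ]
                    for v in config.variants:
                        site.dg_by_asd[v] = thermo.duplex_delta_g(
                            window, thermo.ASD_VARIANTS[v].asd_seq, params
                        ).delta_g
            for v in config.variants:
                ret = tracks[v].get("fp_ret")
                if ret is None:
                    continue
                ret_rpm = ret if ret.normalized else rpm_normalize(ret)
                raw = None if ret.normalized else ret
                initiation.score_sites(ret_rpm, sites, raw_track=raw)
                site_df = _sites_frame(sites)
                path = os.path.join(config.outdir, f"sites_{v}.tsv")
                site_df.to_csv(path, sep="\t", index=False)
                outputs[f"sites_{v}"] = path
                annotated = [s for s in sites if s.annotated and s.eligible]
                if annotated:
                    off, prof, n = initiation.metagene_profile(ret_rpm, annotated)
                    pd.DataFrame({"offset": off, "mean": prof}).assign(
                        n_sites=n
                    ).to_csv(
                        os.path.join(config.outdir, f"metagene_{v}.tsv"),
                        sep="\t", index=False,
                    )
                    outputs[f"metagene_{v}"] = os.path.join(
                        config.outdir, f"metagene_{v}.tsv"
                    )

            stage = "logo"
            fg = [s.upstream_window for s in sites
                  if s.annotated
                  and "low" in thermo.classify_affinity(
                      s.dg_by_asd.get(ref, -99.0))]
            bg = [s.upstream_window for s in sites if not s.annotated]
            if fg and bg:
                logo = context.logo_enrichment(fg, bg, config.logo_offsets)
                logo.to_csv(os.path.join(config.outdir, "logo.tsv"),
                            sep="\t", index=False)
                outputs["logo"] = os.path.join(config.outdir, "logo.tsv")
            else:
                log.warning("logo skipped: empty foreground or background")

            stage = "shape"
            if reactivity is not None:
                for label, annotated_flag in (("annotated", True),
                                              ("non_annotated", False)):
                    subset = [s for s in sites if s.annotated == annotated_flag]
                    prof = context.shape_window_profile(reactivity, subset)
                    pd.DataFrame(
                        dict(offset=prof.offsets, median=prof.median,
                             q25=prof.q25, q75=prof.q75)
                    ).to_csv(
                        os.path.join(config.outdir, f"shape_{label}.tsv"),
                        sep="\t", index=False,
                    )
                    outputs[f"shape_{label}"] = os.path.join(
                        config.outdir, f"shape_{label}.tsv"
                    )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        with open(os.path.join(config.outdir, "outputs.json"), "w") as fh:
            json.dump(outputs, fh, indent=2)
        return outputs
    finally:
        root.removeHandler(handler)
        handler.close()


def _sites_frame(sites) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = dict(replicon=s.replicon, strand=s.strand, pos_A=s.pos_A,
                   annotated=s.annotated, gene_id=s.gene_id,
                   host_gene=s.host_gene, window_reads=s.window_reads,
                   eligible=s.eligible, is_score=s.is_score,
                   log2_is=s.log2_is,
                   window_truncated=s.window_truncated)
        for v, dg in s.dg_by_asd.items():
            row[f"dg_{v}"] = dg
        rows.append(row)
    return pd.DataFrame(rows)
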