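"""Per-gene ribosome occupancy (RO) and between-variant occupancy shifts.

RO is the per-gene footprint density divided by the mRNA density, a proxy for
translational efficiency.  Comparing log10 RO between ribosome variants
(delta logRO) cancels every mRNA-intrinsic contribution shared by the
variants, isolating the effect of SD:ASD pairing, which is then correlated
against per-gene SD strength.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Gene
from .tracks import CoverageTrack

__all__ = ["gene_density", "compute_ro", "delta_log_ro", "correlate_sd"]

log = logging.getLogger(__name__)


def _scored_region(gene: Gene, trim_codons: int) -> tuple[int, int]:
    trim = 3 * trim_codons
    start, end = gene.start + trim, gene.end - trim
    if end - start < 30:  # at least 10 codons must remain
        raise ValueError(
            f"trimming {trim_codons} codons leaves fewer than 10 codons of "
            f"{gene.gene_id} ({gene.length} nt)"
        )
    return start, end


def gene_density(track: CoverageTrack, gene: Gene, trim_codons: int = 0) -> float:
    """Mean signal per nucleotide over the (optionally trimmed) CDS."""
    start, end = _scored_region(gene, trim_codons)
    return float(np.mean(track.values(gene.replicon, gene.strand, start, end)))


def compute_ro(
    fp_track: CoverageTrack,
    rna_track: CoverageTrack,
    genes: Sequence[Gene],
    min_fp_reads: float = 10,
    min_rna_reads: float = 10,
    fp_raw: CoverageTrack | None = None,
    rna_raw: CoverageTrack | None = None,
    trim_codons: int = 0,
) -> pd.DataFrame:
    """Per-gene occupancy records.

    ``fp_track``/``rna_track`` must be rpm-normalized; the coverage filter
    (raw footprint reads >= min_fp_reads and raw RNA reads >= min_rna_reads
    within the scored region) is evaluated on the raw-count tracks, which
    default to de-normalized copies of the rpm tracks.  RO and log10 RO are
    computed only for genes passing coverage.
    """
    for name, t in (("footprint", fp_track), ("RNA-seq", rna_track)):
        if not t.normalized:
            raise ValueError(f"{name} track must be rpm-normalized")
    if fp_raw is None:
        fp_raw = _denormalize(fp_track)
    if rna_raw is None:
        rna_raw = _denormalize(rna_track)
    rows = []
    for gene in genes:
        if gene.replicon not in fp_track.lengths:
            log.warning("gene %s on unknown replicon %s: skipped",
                        gene.gene_id, gene.replicon)
            continue
        start, end = _scored_region(gene, trim_codons)
        region = (gene.replicon, gene.strand, start, end)
        fp_reads = float(np.sum(fp_raw.values(*region)))
        rna_reads = float(np.sum(rna_raw.values(*region)))
        passed = fp_reads >= min_fp_reads and rna_reads >= min_rna_reads
        fp_density = gene_density(fp_track, gene, trim_codons)
        rna_density = gene_density(rna_track, gene, trim_codons)
        ro = log_ro = np.nan
        if passed and rna_density > 0 and fp_density > 0:
            ro = fp_density / rna_density
            log_ro = np.log10(ro)
        elif passed:
            passed = False  # zero density despite read threshold: unscorable
        rows.append(
            dict(gene_id=gene.gene_id, fp_density=fp_density,
                 rna_density=rna_density, fp_reads=fp_reads,
                 rna_reads=rna_reads, ro=ro, log_ro=log_ro,
                 pass_coverage=passed)
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _denormalize(track: CoverageTrack) -> CoverageTrack:
    out = track.copy()
    scale = track.total_mapped / 1e6
    for key in out.data:
        out.data[key] = out.data[key] * scale
    out.normalized = False
    return out


def delta_log_ro(
    records_ref: pd.DataFrame, records_alt: pd.DataFrame
) -> pd.Series:
    """Per-gene log10(RO_ref) - log10(RO_alt) over genes passing in both.

    Genes failing coverage in either record set are excluded; the exclusion
    count is attached as ``result.attrs["n_excluded"]``.
    """
    common = records_ref.index.intersection(records_alt.index)
    ok = (
        records_ref.loc[common, "pass_coverage"]
        & records_alt.loc[common, "pass_coverage"]
    )
    if len(common) == 0:
        raise ValueError("record sets share no genes")
    genes = common[ok]
    out = (
        records_ref.loc[genes, "log_ro"] - records_alt.loc[genes, "log_ro"]
    ).rename("delta_log_ro")
    out.attrs["n_excluded"] = int(len(common) - len(genes))
    return out


def correlate_sd(
    values: pd.Series | Mapping[str, float],
    strengths: pd.Series | Mapping[str, float],
) -> tuple[float, float, int]:
    """Pearson correlation of a per-gene statistic against SD strength.

    Genes missing either value are dropped; returns (r, p_value, n).
    """
    v = pd.Series(values).dropna()
    s = pd.Series(strengths).dropna()
    common = v.index.intersection(s.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(common)}")
    x, y = v.loc[common].to_numpy(float), s.loc[common].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(common)
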