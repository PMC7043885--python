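"""Sequence-context and mRNA-structure statistics around start sites.

``logo_enrichment`` contrasts a foreground set of AUG-context sequences
against a background set, one position and nucleotide at a time, with a
one-sided binomial tail test (background frequencies with a pseudocount of 1
per nucleotide); letter height is -log10(p), signed positive for enrichment
and negative for depletion, with a Bonferroni factor of 4 x window width
reported alongside.

``shape_window_profile`` summarizes per-nucleotide SHAPE reactivity (high =
unstructured RNA) around aligned sites as a per-offset median and
interquartile range, plus a per-site structure score: the median reactivity
over -25..+25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .initiation import StartSite, _window_positions
from .tracks import CoverageTrack

__all__ = ["logo_enrichment", "shape_window_profile", "ShapeProfile",
           "read_reactivity_tsv"]

BASES = ("A", "C", "G", "U")


def logo_enrichment(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    offsets: tuple[int, int] = (-20, 10),
    seq_offsets: tuple[int, int] = (-30, 10),
) -> pd.DataFrame:
    """Per-offset, per-nucleotide binomial enrichment of fg vs bg.

    All sequences are aligned on the A of AUG; ``seq_offsets`` states which
    inclusive offset range the strings span (so the A sits at index
    ``-seq_offsets[0]``).  Sequences too short for the requested offsets are
    excluded and counted in ``result.attrs["n_fg_excluded"]`` /
    ``["n_bg_excluded"]``.  Returns one row per (offset, base) with columns
    fg_count, fg_n, bg_freq, p_value, direction, height, p_bonferroni.
    """
    if offsets[0] < seq_offsets[0] or offsets[1] > seq_offsets[1]:
        raise ValueError(
            f"requested offsets {offsets} exceed the sequence span {seq_offsets}"
        )
    expected_len = seq_offsets[1] - seq_offsets[0] + 1

    def usable(seqs):
        kept, dropped = [], 0
        for s in seqs:
            if s is not None and len(s) == expected_len:
                kept.append(s.upper().replace("T", "U"))
            else:
                dropped += 1
        return kept, dropped

    fg, n_fg_dropped = usable(fg_seqs)
    bg, n_bg_dropped = usable(bg_seqs)
    if not fg:
        raise ValueError("no usable foreground sequences")
    if not bg:
        raise ValueError("no usable background sequences")
    span = np.arange(offsets[0], offsets[1] + 1)
    bonferroni = 4 * len(span)
    rows = []
    for offset in span:
        idx = offset - seq_offsets[0]
        fg_col = [s[idx] for s in fg]
        bg_col = [s[idx] for s in bg]
        fg_n = len(fg_col)
        bg_counts = {b: bg_col.count(b) for b in BASES}
        bg_total = sum(bg_counts.values()) + 4  # pseudocount 1 per nucleotide
        for base in BASES:
            k = fg_col.count(base)
            p0 = (bg_counts[base] + 1) / bg_total
            if k / fg_n > p0:
                direction = "enriched"
                p = float(stats.binom.sf(k - 1, fg_n, p0))  # P[X >= k]
            else:
                direction = "depleted"
                p = float(stats.binom.cdf(k, fg_n, p0))     # P[X <= k]
            p = min(max(p, np.nextafter(0, 1)), 1.0)
            height = -np.log10(p) * (1 if direction == "enriched" else -1)
            rows.append(
                dict(offset=int(offset), base=base, fg_count=k, fg_n=fg_n,
                     bg_freq=p0, p_value=p, direction=direction,
                     height=float(height),
                     p_bonferroni=min(1.0, p * bonferroni))
            )
    out = pd.DataFrame(rows)
    out.attrs["n_fg_excluded"] = n_fg_dropped
    out.attrs["n_bg_excluded"] = n_bg_dropped
    out.attrs["bonferroni_factor"] = bonferroni
    return out


@dataclass
class ShapeProfile:
    """Windowed reactivity summary across aligned sites."""

    offsets: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_sites: int
    n_excluded: int
    site_scores: dict[int, float]  # keyed by pos_A


def shape_window_profile(
    reactivity: CoverageTrack,
    sites: Sequence[StartSite],
    profile_window: tuple[int, int] = (-60, 60),
    score_window: tuple[int, int] = (-25, 25),
    min_coverage_frac: float = 0.8,
) -> ShapeProfile:
    """Median/IQR reactivity per offset across sites, plus per-site scores.

    Missing reactivities are NaN in the track and are skipped, not imputed;
    sites with fewer than ``min_coverage_frac`` defined positions in the
    profile window are excluded and counted.
    """
    offsets = np.arange(profile_window[0], profile_window[1] + 1)
    vectors = []
    scores: dict[int, float] = {}
    n_excluded = 0
    s_lo = score_window[0] - profile_window[0]
    s_hi = score_window[1] - profile_window[0] + 1
    for site in sites:
        pos = _window_positions(site, profile_window,
                                reactivity.lengths[site.replicon])
        if pos is None:
            n_excluded += 1
            continue
        vec = reactivity.get(site.replicon, site.strand)[pos]
        if np.mean(~np.isnan(vec)) < min_coverage_frac:
            n_excluded += 1
            continue
        vectors.append(vec)
        score_vec = vec[s_lo:s_hi]
        scores[site.pos_A] = (
            float(np.nanmedian(score_vec))
            if np.any(~np.isnan(score_vec)) else float("nan")
        )
    if not vectors:
        raise ValueError("no site passed the reactivity coverage filter")
    mat = np.vstack(vectors)
    return ShapeProfile(
        offsets=offsets,
        median=np.nanmedian(mat, axis=0),
        q25=np.nanpercentile(mat, 25, axis=0),
        q75=np.nanpercentile(mat, 75, axis=0),
        n_sites=len(vectors),
        n_excluded=n_excluded,
        site_scores=scores,
    )


def write_reactivity_tsv(track: CoverageTrack, path: str) -> None:
    """Write defined (non-NaN) reactivities as (replicon, strand, 1-based
    position, reactivity) rows."""
    with open(path, "w") as fh:
        fh.write("replicon\tstrand\tposition\treactivity\n")
        for (replicon, strand), vec in sorted(track.data.items()):
            (defined,) = np.nonzero(~np.isnan(vec))
            for i in defined:
                fh.write(f"{replicon}\t{strand}\t{i + 1}\t{float(vec[i])!r}\n")


def read_reactivity_tsv(path: str, lengths: Mapping[str, int]) -> CoverageTrack:
    """Read per-nucleotide reactivities (replicon, strand, 1-based position,
    reactivity); positions absent from the file are NaN (missing)."""
    track = CoverageTrack.zeros(dict(lengths))
    for key in track.data:
        track.data[key][:] = np.nan
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["replicon", "strand", "position", "reactivity"],
                     header=None)
    # tolerate a header row
    if df.iloc[0]["position"] == "position":
        df = df.iloc[1:]
    for row in df.itertuples():
        track.get(row.replicon, row.strand)[int(row.position) - 1] = float(
            row.reactivity
        )
    return track
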