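"""Start-site enumeration, initiation scores and metagene profiles.

Retapamulin traps newly initiated ribosomes at start codons while elongating
ribosomes run off, so footprint 3'-ends pile up just downstream of true
initiation sites.  The initiation score (IS) of an AUG is the mean signal at
offsets +3..+21 from the A (capturing footprints of various sizes) divided by
the mean over -50..+50; sites need more than 10 raw reads in the wide window
to be scored.  Metagene profiles average per-site window vectors after
normalizing each to unit sum.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation import Gene, region_sequence, transcribe
from .tracks import CoverageTrack

__all__ = [
    "StartSite",
    "enumerate_aug_sites",
    "initiation_score",
    "score_sites",
    "metagene_profile",
    "select_sites",
]

NUMERATOR_WINDOW = (3, 21)    # inclusive offsets from the A of AUG
DENOMINATOR_WINDOW = (-50, 50)
MIN_WINDOW_READS = 10         # eligibility: strictly more than this many reads
CONTEXT_WINDOW = (-30, 10)


@dataclass
class StartSite:
    """An AUG locus; ``pos_A`` is the 0-based genomic coordinate of the A."""

    replicon: str
    strand: str
    pos_A: int
    annotated: bool
    gene_id: str | None = None      # if annotated
    host_gene: str | None = None    # if internal to a CDS
    upstream_window: str | None = None  # context at offsets -30..+10 (RNA)
    context_truncated: bool = False
    window_truncated: bool = False
    dg_by_asd: dict[str, float] = field(default_factory=dict)
    window_reads: float = 0.0
    eligible: bool = False
    is_score: float | None = None
    log2_is: float | None = None

    def offset_to_genomic(self, offset: int) -> int:
        return self.pos_A + offset if self.strand == "+" else self.pos_A - offset


def _window_positions(
    site: StartSite, window: tuple[int, int], replicon_len: int
) -> np.ndarray | None:
    """Genomic positions for inclusive offsets, 5'->3'; None if truncated."""
    lo = site.offset_to_genomic(window[0])
    hi = site.offset_to_genomic(window[1])
    if not (0 <= lo < replicon_len and 0 <= hi < replicon_len):
        return None
    step = 1 if site.strand == "+" else -1
    return np.arange(lo, hi + step, step)


def enumerate_aug_sites(
    genome: dict[str, str],
    genes: Sequence[Gene],
    context_window: tuple[int, int] = CONTEXT_WINDOW,
) -> tuple[list[StartSite], dict[str, int]]:
    """Annotated and CDS-internal AUG sites, with -30..+5 sequence context.

    The annotated set contains genes whose annotated start codon is AUG
    (others are excluded and counted); the non-annotated set contains every
    other sense-strand AUG inside an annotated CDS, in any reading frame,
    counted once even when CDSs overlap.  Returns (sites, census).
    """
    sites: list[StartSite] = []
    seen: set[tuple[str, str, int]] = set()
    census = {"annotated": 0, "non_annotated": 0, "non_aug_start": 0}
    annotated_keys: set[tuple[str, str, int]] = set()
    for gene in genes:
        pos = gene.start_codon_pos
        codon = _codon_at(genome, gene.replicon, gene.strand, pos)
        if codon == "AUG":
            annotated_keys.add((gene.replicon, gene.strand, pos))
    for gene in genes:
        pos = gene.start_codon_pos
        key = (gene.replicon, gene.strand, pos)
        codon = _codon_at(genome, gene.replicon, gene.strand, pos)
        if codon != "AUG":
            census["non_aug_start"] += 1
        elif key not in seen:
            seen.add(key)
            census["annotated"] += 1
            sites.append(
                _make_site(genome, gene.replicon, gene.strand, pos,
                           annotated=True, gene_id=gene.gene_id,
                           context_window=context_window)
            )
        cds = region_sequence(genome, gene.replicon, gene.strand,
                              gene.start, gene.end)
        for m in re.finditer("ATG", cds):
            i = m.start()
            if gene.strand == "+":
                gpos = gene.start + i
            else:
                gpos = gene.end - 1 - i
            gkey = (gene.replicon, gene.strand, gpos)
            if gkey in annotated_keys or gkey in seen:
                continue
            seen.add(gkey)
            census["non_annotated"] += 1
            sites.append(
                _make_site(genome, gene.replicon, gene.strand, gpos,
                           annotated=False, host_gene=gene.gene_id,
                           context_window=context_window)
            )
    return sites, census


def _codon_at(genome, replicon, strand, pos_A) -> str | None:
    n = len(genome[replicon])
    if strand == "+":
        if pos_A + 3 > n:
            return None
        return transcribe(genome[replicon][pos_A : pos_A + 3])
    if pos_A - 2 < 0:
        return None
    return transcribe(region_sequence(genome, replicon, "-", pos_A - 2, pos_A + 1))


def _make_site(genome, replicon, strand, pos_A, annotated,
               context_window, gene_id=None, host_gene=None) -> StartSite:
    site = StartSite(replicon=replicon, strand=strand, pos_A=pos_A,
                     annotated=annotated, gene_id=gene_id, host_gene=host_gene)
    lo = site.offset_to_genomic(context_window[0])
    hi = site.offset_to_genomic(context_window[1])
    start, end = (lo, hi + 1) if strand == "+" else (hi, lo + 1)
    n = len(genome[replicon])
    if start < 0 or end > n:
        site.context_truncated = True
    else:
        site.upstream_window = transcribe(
            region_sequence(genome, replicon, strand, start, end)
        )
    return site


def initiation_score(
    track: CoverageTrack,
    site: StartSite,
    raw_track: CoverageTrack | None = None,
    numerator_window: tuple[int, int] = NUMERATOR_WINDOW,
    denominator_window: tuple[int, int] = DENOMINATOR_WINDOW,
    min_window_reads: float = MIN_WINDOW_READS,
) -> StartSite:
    """Score one site in place and return it.

    IS = mean(track over +3..+21) / mean(track over -50..+50); eligibility
    requires strictly more than ``min_window_reads`` raw reads in the wide
    window (evaluated on ``raw_track``, defaulting to ``track``).  Sites whose
    window crosses the replicon end are flagged ``window_truncated`` and left
    unscored.
    """
    raw = raw_track if raw_track is not None else track
    n = track.lengths[site.replicon]
    den_pos = _window_positions(site, denominator_window, n)
    num_pos = _window_positions(site, numerator_window, n)
    site.is_score = site.log2_is = None
    site.eligible = False
    if den_pos is None or num_pos is None:
        site.window_truncated = True
        return site
    vec_raw = raw.get(site.replicon, site.strand)
    site.window_reads = float(vec_raw[den_pos].sum())
    if not site.window_reads > min_window_reads:
        return site
    vec = track.get(site.replicon, site.strand)
    den_mean = float(vec[den_pos].mean())
    num_mean = float(vec[num_pos].mean())
    if den_mean <= 0:
        return site
    site.eligible = True
    site.is_score = num_mean / den_mean
    site.log2_is = math.log2(site.is_score) if site.is_score > 0 else -math.inf
    return site


def score_sites(track, sites: Iterable[StartSite], raw_track=None,
                **kwargs) -> list[StartSite]:
    return [initiation_score(track, s, raw_track=raw_track, **kwargs)
            for s in sites]


def metagene_profile(
    track: CoverageTrack,
    sites: Sequence[StartSite],
    window: tuple[int, int] = DENOMINATOR_WINDOW,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean of per-site unit-sum-normalized window vectors.

    Only sites marked eligible contribute; sites whose window sum is zero or
    whose window is truncated are excluded (and reflected in the returned
    count).  Returns (offsets, profile, n_sites); the profile sums to 1.
    """
    offsets = np.arange(window[0], window[1] + 1)
    total = np.zeros(len(offsets))
    n_used = 0
    for site in sites:
        if not site.eligible:
            continue
        pos = _window_positions(site, window, track.lengths[site.replicon])
        if pos is None:
            continue
        vec = track.get(site.replicon, site.strand)[pos]
        s = vec.sum()
        if s <= 0:
            continue
        total += vec / s
        n_used += 1
    if n_used == 0:
        raise ValueError("no eligible site contributed to the metagene profile")
    return offsets, total / n_used, n_used


def select_sites(
    sites: Sequence[StartSite],
    log2_is_gt: float | None = None,
    annotated: bool | None = None,
    affinity: tuple[Sequence[str], str, "object"] | None = None,
) -> tuple[list[StartSite], dict[str, int]]:
    """Deterministic site filter; returns (subset, census).

    ``affinity`` is ``(variant_names, label, scheme)``: a site passes when the
    classification of its dG against EVERY listed variant includes ``label``
    (e.g. ``(["S", "O", "A"], "none", scheme)`` for sites with no predicted
    affinity to any mutant ASD).
    """
    from .thermo import classify_affinity

    subset = []
    census = {"input": len(sites), "selected": 0, "missing_fields": 0}
    for site in sites:
        if annotated is not None and site.annotated != annotated:
            continue
        if log2_is_gt is not None:
            if site.log2_is is None:
                census["missing_fields"] += 1
                continue
            if not site.log2_is > log2_is_gt:
                continue
        if affinity is not None:
            variants, label, scheme = affinity
            if any(v not in site.dg_by_asd for v in variants):
                census["missing_fields"] += 1
                continue
            if not all(
                label in classify_affinity(site.dg_by_asd[v], scheme)
                for v in variants
            ):
                continue
        subset.append(site)
    census["selected"] = len(subset)
    return subset, census
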