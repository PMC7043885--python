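"""SD:ASD hybridization free energy under a contiguous-helix nearest-neighbor model.

The anti-Shine-Dalgarno (ASD) tail of 16S rRNA base-pairs with purine-rich
Shine-Dalgarno (SD) motifs upstream of bacterial start codons.  This module
scores that interaction: an ASD scan sequence is slid, ungapped and
antiparallel, along an mRNA window, and every contiguous run of complementary
base pairs (Watson-Crick, plus G:U wobble by default) is scored as

    dG = init_dg + sum(stack dG37 over adjacent pairs) + terminal penalties

with no internal loops or bulges allowed.  The minimum total over all
alignments and runs is the reported duplex energy; "SD strength" is its
negative, so stronger motifs score higher.  Runs of fewer than two pairs, and
totals >= 0, collapse to a no-duplex sentinel of 0 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NNParameterSet",
    "DuplexScore",
    "AsdVariant",
    "ASD_VARIANTS",
    "AffinityScheme",
    "load_nn_params",
    "duplex_delta_g",
    "sd_strength",
    "classify_affinity",
    "WindowError",
]

RNA_ALPHABET = frozenset("ACGU")
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})
_WC_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: The 16 Watson-Crick/Watson-Crick dinucleotide steps, keyed by the step on
#: the mRNA ("top") strand; the paired step is implied by complementarity.
WC_STEPS = tuple(a + b for a in "ACGU" for b in "ACGU")


class WindowError(ValueError):
    """Raised when a requested window cannot be extracted from a sequence."""


def _check_rna(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be a non-empty RNA string")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-RNA character(s): {sorted(bad)}")


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor duplex parameters (dG37, kcal/mol).

    ``stack_dg`` maps ``(top, bottom)`` -> stacking free energy, where ``top``
    is a 5'->3' dinucleotide step on the mRNA strand and ``bottom`` is the
    paired dinucleotide on the ASD strand read 3'->5', aligned base-for-base
    under ``top``.
    """

    stack_dg: Mapping[tuple[str, str], float]
    init_dg: float = 4.09
    terminal_au_dg: float = 0.45
    allow_gu: bool = True

    def __post_init__(self) -> None:
        missing = []
        for top in WC_STEPS:
            bottom = _WC_COMP[top[0]] + _WC_COMP[top[1]]
            if (top, bottom) not in self.stack_dg:
                missing.append(f"{top}/{bottom}")
        if self.allow_gu:
            for top, bottom in _iter_gu_steps():
                if (top, bottom) not in self.stack_dg:
                    missing.append(f"{top}/{bottom}")
        if missing:
            raise ValueError(
                "nearest-neighbor table is missing step(s): " + ", ".join(missing)
            )

    def stack(self, top: str, bottom: str) -> float:
        return self.stack_dg[(top, bottom)]


def _iter_gu_steps() -> Iterable[tuple[str, str]]:
    """All (top, bottom) steps in which at least one pair is a G:U wobble."""
    pairs = sorted(WC_PAIRS | GU_PAIRS)
    for t1, b1 in pairs:
        for t2, b2 in pairs:
            if (t1, b1) in GU_PAIRS or (t2, b2) in GU_PAIRS:
                yield (t1 + t2, b1 + b2)


@dataclass(frozen=True)
class DuplexScore:
    """Result of a duplex scan.

    ``delta_g`` is the total free energy in kcal/mol (0 is the no-duplex
    sentinel); ``offset`` is the index in the mRNA window aligned to the
    3'-most base of the ASD; ``paired_span`` is the 0-based half-open interval
    of paired mRNA positions.
    """

    delta_g: float
    offset: int = 0
    helix_len: int = 0
    paired_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if (self.helix_len == 0) != (self.delta_g == 0.0):
            raise ValueError("helix_len == 0 iff delta_g == 0")
        if self.paired_span[1] - self.paired_span[0] != self.helix_len:
            raise ValueError("paired_span length must equal helix_len")


NO_DUPLEX = DuplexScore(0.0)


@dataclass(frozen=True)
class AsdVariant:
    """An anti-SD scan sequence, written 5'->3'.

    Built-ins follow the canonical E. coli 16S rRNA 3' tail (ACCUCCUUA) whose
    7-mer scan sequence is ACCUCCU; mutants replace the CCUCC core.
    """

    name: str
    asd_seq: str
    full_tail: str | None = None

    def __post_init__(self) -> None:
        _check_rna(self.asd_seq, "asd_seq")


ASD_VARIANTS: dict[str, AsdVariant] = {
    # C: canonical ASD; S: CCUCC core inverted to GGAGG; O: core mutated to
    # UGGGA (orthogonal ribosome); A: core mutated to AAAAA.
    "C": AsdVariant("C", "ACCUCCU", full_tail="ACCUCCUUA"),
    "S": AsdVariant("S", "AGGAGGU"),
    "O": AsdVariant("O", "AUGGGAU"),
    "A": AsdVariant("A", "AAAAAAU"),
}


def load_nn_params(source: str = "default") -> NNParameterSet:
    """Load a nearest-neighbor table from a TSV file or the packaged default.

    The file holds one ``top<TAB>bottom<TAB>dG37`` row per step, ``#!`` pragma
    lines for ``init_dg``, ``terminal_au_dg`` and ``allow_gu``, and ``#``
    comments.  ``load_nn_params("default")`` returns the packaged
    Turner-2004-style RNA/RNA table.
    """
    if source == "default":
        ref = resources.files("asdscan.data") / "rna_nn_dg37.tsv"
        text = ref.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    stack: dict[tuple[str, str], float] = {}
    meta = {"init_dg": 4.09, "terminal_au_dg": 0.45, "allow_gu": True}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            try:
                key, value = line[2:].split()
                if key == "allow_gu":
                    meta[key] = value.lower() in ("true", "1", "yes")
                else:
                    meta[key] = float(value)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed pragma at line {lineno}: {raw!r}") from exc
            continue
        if line.startswith("#") or line.lower().startswith("top\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"malformed table row at line {lineno}: {raw!r}")
        top, bottom, dg = fields
        try:
            stack[(top, bottom)] = float(dg)
        except ValueError as exc:
            raise ValueError(f"malformed dG value at line {lineno}: {raw!r}") from exc
    return NNParameterSet(stack_dg=stack, **meta)


def write_nn_params(params: NNParameterSet, path: str) -> None:
    """Serialize a parameter set back to its TSV form (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("#! init_dg\t%r\n" % params.init_dg)
        fh.write("#! terminal_au_dg\t%r\n" % params.terminal_au_dg)
        fh.write("#! allow_gu\t%s\n" % ("true" if params.allow_gu else "false"))
        fh.write("top\tbottom\tdg37\n")
        for (top, bottom), dg in sorted(params.stack_dg.items()):
            fh.write(f"{top}\t{bottom}\t{dg!r}\n")


def _is_pair(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in WC_PAIRS:
        return True
    return allow_gu and (a, b) in GU_PAIRS


def duplex_delta_g(window: str, asd: str, params: NNParameterSet) -> DuplexScore:
    """Minimum-energy contiguous RNA:RNA duplex between ``window`` and ``asd``.

    Both sequences are 5'->3' RNA strings; the ASD is scanned antiparallel
    against the window at every ungapped offset.  Within each alignment, every
    contiguous run of >= 2 complementary pairs is scored; loops and bulges are
    disallowed by construction.  Ties on delta_g break toward smaller offset,
    then longer helix.  Returns the sentinel (delta_g 0, helix_len 0) when no
    run scores below zero.
    """
    _check_rna(window, "window")
    _check_rna(asd, "asd")
    asd_rev = asd[::-1]  # read 3'->5' so index k aligns with window index offset+k
    n, m = len(window), len(asd_rev)
    allow_gu = params.allow_gu
    best: tuple[float, int, int] | None = None  # (dg, offset, -helix_len)
    best_score: DuplexScore | None = None
    for offset in range(-(m - 1), n):
        k_lo = max(0, -offset)
        k_hi = min(m, n - offset)  # exclusive
        if k_hi - k_lo < 2:
            continue
        paired = [
            _is_pair(window[offset + k], asd_rev[k], allow_gu)
            for k in range(k_lo, k_hi)
        ]
        # every contiguous sub-run of >= 2 consecutive pairs
        run_start = None
        runs: list[tuple[int, int]] = []  # inclusive k-index bounds of maximal runs
        for idx, ok in enumerate(paired + [False]):
            if ok and run_start is None:
                run_start = idx
            elif not ok and run_start is not None:
                if idx - run_start >= 2:
                    runs.append((run_start, idx - 1))
                run_start = None
        for r0, r1 in runs:
            for s in range(r0, r1):
                for e in range(s + 1, r1 + 1):
                    dg = params.init_dg
                    i0 = offset + k_lo + s
                    i1 = offset + k_lo + e  # inclusive window bounds of the run
                    for i in range(i0, i1):  # sum stacks in window order
                        k = i - offset
                        dg += params.stack(
                            window[i : i + 2], asd_rev[k] + asd_rev[k + 1]
                        )
                    for i in (i0, i1):
                        pair = (window[i], asd_rev[i - offset])
                        if pair not in (("G", "C"), ("C", "G")):
                            dg += params.terminal_au_dg
                    if dg >= 0:
                        continue
                    helix = e - s + 1
                    key = (dg, offset, -helix)
                    if best is None or key < best:
                        best = key
                        best_score = DuplexScore(
                            delta_g=dg,
                            offset=offset,
                            helix_len=helix,
                            paired_span=(i0, i1 + 1),
                        )
    return best_score if best_score is not None else NO_DUPLEX


def extract_window(upstream: str, window_offsets: tuple[int, int] = (-15, -6)) -> str:
    """Slice the scan window out of an upstream sequence.

    ``upstream`` is the sense-strand RNA immediately 5' of the start codon,
    whose last base sits at offset -1 relative to the A of AUG (offset 0).
    Offsets are inclusive on both ends, so the default -15..-6 window is 10 nt.
    """
    off5, off3 = window_offsets
    if off5 > off3:
        raise ValueError(f"window offsets must be ordered: {window_offsets}")
    if off3 > -1:
        raise WindowError("window must lie strictly upstream of the start codon")
    if len(upstream) < -off5:
        raise WindowError(
            f"upstream sequence too short ({len(upstream)} nt) for window "
            f"{off5}..{off3}"
        )
    end = len(upstream) + off3 + 1
    return upstream[len(upstream) + off5 : end]


def sd_strength(
    gene_upstream: str,
    asd: AsdVariant | str,
    params: NNParameterSet,
    window_offsets: tuple[int, int] = (-15, -6),
) -> float:
    """SD strength (-dG, kcal/mol) of a gene's upstream window against an ASD.

    Raises :class:`WindowError` when the upstream sequence does not cover the
    requested offsets, so short-leadered genes are excluded rather than
    silently mis-scored.
    """
    seq = asd.asd_seq if isinstance(asd, AsdVariant) else asd
    window = extract_window(gene_upstream, window_offsets)
    return -duplex_delta_g(window, seq, params).delta_g or 0.0


@dataclass(frozen=True)
class AffinityScheme:
    """Thresholds for affinity class labels.

    A site is labelled ``none`` when dG > none_above, ``low`` when
    dG > low_above, and ``strong`` when dG <= strong_below (if set).  The
    default mirrors the conventions used for ribosome-variant grouping:
    dG > -1 has no predicted affinity; dG > 0 is the low-affinity logo
    foreground.  No fixed "strong" cutoff is defined by default; callers set
    one (typically a quantile of the genome-wide dG distribution).
    """

    none_above: float = -1.0
    low_above: float = 0.0
    strong_below: float | None = None

    def __post_init__(self) -> None:
        if self.low_above < self.none_above:
            raise ValueError(
                "affinity thresholds not monotone: low_above must be >= none_above"
            )
        if self.strong_below is not None and self.strong_below > self.none_above:
            raise ValueError(
                "affinity thresholds not monotone: strong_below must be <= none_above"
            )


def classify_affinity(
    delta_g: float, scheme: AffinityScheme | None = None
) -> frozenset[str]:
    """Set of affinity labels a duplex energy qualifies for.

    Labels are cumulative on the weak side (a dG of +0.5 is both ``none`` and
    ``low``), matching how gene sets are composed: "no affinity" sets use
    dG > -1, logo foregrounds the weakest class, and "strong" sets an explicit
    cutoff.  ``low`` is inclusive of its threshold because the duplex scanner
    collapses every non-negative total to the 0 sentinel: dG = 0 *is* the
    no-predicted-duplex class.
    """
    scheme = scheme or AffinityScheme()
    labels = set()
    if delta_g > scheme.none_above:
        labels.add("none")
    if delta_g >= scheme.low_above:
        labels.add("low")
    if scheme.strong_below is not None and delta_g <= scheme.strong_below:
        labels.add("strong")
    return frozenset(labels)
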