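"""variableStep WIG I/O for stranded coverage tracks.

One track section is written per (replicon, strand), with the strand encoded
in the track name as ``"<replicon>:<strand>"``.  Positions are 1-based in the
file and 0-based internally; zero positions are omitted, so write-then-read is
the identity on sparse tracks.  Only the variableStep dialect is supported.
"""

from __future__ import annotations

import re

import numpy as np

from .tracks import CoverageTrack, STRANDS

__all__ = ["read_wig", "write_wig"]

_NAME_RE = re.compile(r'name="([^"]+)"|name=(\S+)')


class WigParseError(ValueError):
    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def write_wig(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_mapped={track.total_mapped!r}\n")
        fh.write(f"# normalized={'true' if track.normalized else 'false'}\n")
        for replicon in sorted(track.lengths):
            for strand in STRANDS:
                key = (replicon, strand)
                if key not in track.data:
                    continue
                vec = track.data[key]
                fh.write(
                    f'track type=wiggle_0 name="{replicon}:{strand}"\n'
                )
                fh.write(f"variableStep chrom={replicon}\n")
                (nz,) = np.nonzero(vec)
                for i in nz:
                    fh.write(f"{i + 1} {float(vec[i])!r}\n")


def read_wig(path: str, lengths: dict[str, int]) -> CoverageTrack:
    """Parse a stranded variableStep WIG file into a coverage track.

    ``lengths`` supplies replicon lengths (WIG files do not carry them).
    """
    track = CoverageTrack.zeros(lengths)
    current: np.ndarray | None = None
    strand = "+"
    chrom: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("total_mapped="):
                    track.total_mapped = float(body.split("=", 1)[1])
                elif body.startswith("normalized="):
                    track.normalized = body.split("=", 1)[1] == "true"
                continue
            if line.startswith("track"):
                m = _NAME_RE.search(line)
                if not m:
                    raise WigParseError("track line without a name", lineno)
                name = m.group(1) or m.group(2)
                if ":" not in name or name.rsplit(":", 1)[1] not in STRANDS:
                    raise WigParseError(
                        f"track name {name!r} does not encode a strand "
                        '(expected "<replicon>:<+|->")',
                        lineno,
                    )
                strand = name.rsplit(":", 1)[1]
                current = None
                continue
            if line.startswith("fixedStep"):
                raise WigParseError(
                    "unsupported dialect: only variableStep is accepted", lineno
                )
            if line.startswith("variableStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                if "chrom" not in fields:
                    raise WigParseError("variableStep without chrom=", lineno)
                chrom = fields["chrom"]
                if chrom not in lengths:
                    raise WigParseError(f"unknown replicon {chrom!r}", lineno)
                current = track.get(chrom, strand)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise WigParseError(f"malformed data line {line!r}", lineno)
            if current is None:
                raise WigParseError(
                    "data line before any variableStep header", lineno
                )
            try:
                pos = int(parts[0])
                value = float(parts[1])
            except ValueError:
                raise WigParseError(f"malformed data line {line!r}", lineno)
            if not 1 <= pos <= lengths[chrom]:
                raise WigParseError(
                    f"position {pos} outside replicon {chrom!r}", lineno
                )
            current[pos - 1] = value
    return track
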