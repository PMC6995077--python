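"""Degenerate dyad-motif scanning with a variable-length spacer.

The default pattern is the p53 response-element dyad ``CWWG[N]{2,12}CWWG``
(W = A/T): two CWWG quarter-site arms separated by 2-12 unconstrained bases.
This dyad is its own reverse complement, so a single-strand (+) scan finds
every occurrence; a both-strand mode exists for non-palindromic patterns.

IUPAC codes in the *pattern* are expanded to base classes; N in the pattern
matches any of A/C/G/T but never an N in the *sequence* (guides are not
designed against unknown bases).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .io import GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

DEFAULT_PATTERN = "CWWG[N]{2,12}CWWG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """Dyad consensus: two IUPAC arms separated by an N-spacer of variable length."""

    left_arm: str
    right_arm: str
    spacer_min: int
    spacer_max: int

    def __post_init__(self):
        if not self.left_arm or not self.right_arm:
            raise ValueError("motif arms must be non-empty")
        for arm in (self.left_arm, self.right_arm):
            bad = set(arm) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in arm {arm!r}")
        if self.spacer_min < 0 or self.spacer_min > self.spacer_max:
            raise ValueError(
                f"need 0 <= spacer_min <= spacer_max, got "
                f"[{self.spacer_min}, {self.spacer_max}]"
            )

    def hit_length(self, spacer_len: int) -> int:
        return len(self.left_arm) + spacer_len + len(self.right_arm)

    def is_palindromic(self) -> bool:
        """True when revcomp(left+right) == left+right under IUPAC identity."""
        joined = self.left_arm + self.right_arm
        return revcomp(joined) == joined


@dataclass(frozen=True)
class MotifHit:
    """One dyad match: interval spans left-arm start to right-arm end."""

    interval: GenomicInterval
    spacer_len: int
    peak_id: str
    motif_id: str


_PATTERN_RE = re.compile(r"^([A-Z]+)\[N\]\{(\d+),(\d+)\}([A-Z]+)$")


def compile_pattern(pattern_string: str = DEFAULT_PATTERN) -> MotifPattern:
    """Parse ``ARM1[N]{a,b}ARM2`` into a :class:`MotifPattern`.

    >>> compile_pattern("CWWG[N]{2,12}CWWG")
    MotifPattern(left_arm='CWWG', right_arm='CWWG', spacer_min=2, spacer_max=12)
    """
    m = _PATTERN_RE.match(pattern_string.strip().upper())
    if not m:
        raise ValueError(
            f"malformed motif pattern {pattern_string!r}; expected ARM1[N]{{a,b}}ARM2"
        )
    left, smin, smax, right = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
    return MotifPattern(left, right, smin, smax)


def _arm_regex(arm: str) -> re.Pattern:
    # overlapping matches via lookahead; pattern N deliberately excludes
    # sequence N (unknown bases never satisfy the consensus)
    classes = "".join(f"[{IUPAC[c]}]" for c in arm)
    return re.compile(f"(?=({classes}))")


def scan_sequence(seq: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All (offset, spacer_len) dyad matches in ``seq``, + strand.

    Every combination of offset and admissible spacer length is reported (no
    collapsing of overlapping hits), sorted by offset then spacer length.
    """
    seq = seq.upper()
    left_starts = [m.start() for m in _arm_regex(pattern.left_arm).finditer(seq)]
    right_starts = {m.start() for m in _arm_regex(pattern.right_arm).finditer(seq)}
    la = len(pattern.left_arm)
    n = len(seq)
    hits: list[tuple[int, int]] = []
    for off in left_starts:
        for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
            rstart = off + la + spacer
            if rstart + len(pattern.right_arm) > n:
                break
            if rstart in right_starts:
                # spacer bases must be known sequence
                if "N" in seq[off + la : rstart]:
                    continue
                hits.append((off, spacer))
    hits.sort()
    return hits


def collapse_hits(
    hits: list[tuple[int, int]], pattern: MotifPattern
) -> list[tuple[int, int]]:
    """Optional greedy collapse: leftmost hit wins, then shortest spacer;
    any hit overlapping an already accepted one is dropped."""
    accepted: list[tuple[int, int]] = []
    occupied: set[int] = set()
    for off, spacer in sorted(hits):
        span = range(off, off + pattern.hit_length(spacer))
        if any(p in occupied for p in span):
            continue
        accepted.append((off, spacer))
        occupied.update(span)
    return accepted


def scan_peaks(
    genome: GenomeSequence,
    peaks: list[GenomicInterval],
    pattern: MotifPattern,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Scan each peak's + strand subsequence; hits become genome-coordinate
    :class:`MotifHit` records with ids ``<peak_id>.<k>`` numbered 5'->3'.

    ``both_strands`` additionally scans the reverse complement and mirrors
    coordinates (identical intervals deduplicated) — needed only for
    non-palindromic patterns.
    """
    hits: list[MotifHit] = []
    motifless = 0
    for peak in peaks:
        seq = genome.fetch(peak)
        found = scan_sequence(seq, pattern)
        if both_strands and not pattern.is_palindromic():
            L = len(seq)
            for off, spacer in scan_sequence(revcomp(seq), pattern):
                mirrored = L - (off + pattern.hit_length(spacer))
                if (mirrored, spacer) not in found:
                    found.append((mirrored, spacer))
            found.sort()
        peak_hits = []
        for off, spacer in found:
            iv = GenomicInterval(
                peak.chrom,
                peak.start + off,
                peak.start + off + pattern.hit_length(spacer),
                "+",
            )
            peak_hits.append((iv, spacer))
        if not peak_hits:
            motifless += 1
        for k, (iv, spacer) in enumerate(peak_hits, start=1):
            motif_id = f"{peak.id}.{k}"
            hits.append(
                MotifHit(
                    interval=GenomicInterval(iv.chrom, iv.start, iv.end, "+", motif_id),
                    spacer_len=spacer,
                    peak_id=peak.id,
                    motif_id=motif_id,
                )
            )
    logger.info(
        "scanned %d peaks: %d motif hits, %d motifless peaks",
        len(peaks), len(hits), motifless,
    )
    return hits


def motifless_peaks(peaks: list[GenomicInterval], hits: list[MotifHit]) -> list[str]:
    """Ids of peaks with no motif hit (bookkeeping for the design summary)."""
    with_hits = {h.peak_id for h in hits}
    return [p.id for p in peaks if p.id not in with_hits]


def hits_to_bed(hits: list[MotifHit], path) -> None:
    """Export motif hits as BED6 (name=motif_id, score=spacer_len)."""
    from .io import write_bed

    write_bed([h.interval for h in hits], path, scores=[h.spacer_len for h in hits])
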