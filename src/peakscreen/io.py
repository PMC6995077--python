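"""Readers/writers for the plain-text formats the toolkit touches.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based coordinates appear only in human-readable reports.  Every
other module consumes the containers defined here and never re-parses files.

Supported formats: FASTA (genome), BED3/4/6 (peaks, intergenic sites,
motif/guide loci), TSV (gene table, library table, count table).  All readers
transparently accept gzip-compressed input (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

DNA_ALPHABET = frozenset("ACGTN")

#: columns of the library table, in on-disk order
LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "pam",
    "chrom",
    "start",
    "end",
    "strand",
    "cut_pos",
    "category",
    "peak_id",
    "motif_ids",
]

GUIDE_CATEGORIES = frozenset(
    {"peak", "intergenic_control", "nontargeting_control", "gene", "gene_control"}
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path) -> Iterator[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# core coordinate types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic region.

    ``strand`` is one of ``+``, ``-``, ``.`` (unstranded).  ``id`` is a free
    label, unique within any one collection (peaks, motifs, guides).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeSequence:
    """Ordered mapping contig name -> uppercase DNA over {A,C,G,T,N}."""

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains characters outside "
                    f"{{A,C,G,T,N}}: {sorted(bad)}"
                )
        self.contigs: dict[str, str] = dict(contigs)

    def __getitem__(self, chrom: str) -> str:
        return self.contigs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of an interval (genome + strand; no reverse complement)."""
        if iv.chrom not in self.contigs:
            raise KeyError(f"unknown contig {iv.chrom!r} for interval {iv.id!r}")
        if iv.end > len(self.contigs[iv.chrom]):
            raise ValueError(
                f"interval {iv.id or iv} extends past end of contig "
                f"{iv.chrom} (length {len(self.contigs[iv.chrom])})"
            )
        return self.contigs[iv.chrom][iv.start : iv.end]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its body span and a width-1 TSS interval.

    The TSS sits at the body start for ``+`` genes and at ``end - 1`` for
    ``-`` genes; ``coding`` flags protein-coding status (used by the
    off-target exclusion rules).
    """

    gene_id: str
    body: GenomicInterval
    coding: bool

    @property
    def tss(self) -> GenomicInterval:
        pos = self.body.start if self.body.strand == "+" else self.body.end - 1
        return GenomicInterval(
            self.body.chrom, pos, pos + 1, self.body.strand, f"{self.gene_id}.tss"
        )

    @property
    def tss_pos(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeSequence:
    """Read a (possibly gzipped) FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and U is converted to T.  Characters outside
    {A,C,G,T,N} and duplicate contig names are rejected; parse errors name
    the offending line number.
    """
    contigs: dict[str, list[str]] = {}
    current: str | None = None
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in contigs:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate contig name {name!r}"
                    )
                contigs[name] = []
                current = name
            else:
                if current is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence before first FASTA header"
                    )
                seq = line.upper().replace("U", "T")
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters "
                        f"{sorted(bad)} in contig {current!r}"
                    )
                contigs[current].append(seq)
    empties = [n for n, parts in contigs.items() if not parts]
    if empties:
        raise ParseError(f"{path}: empty record(s): {empties}")
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence({n: "".join(p) for n, p in contigs.items()})


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, id_prefix: str = "peak") -> list[GenomicInterval]:
    """Read BED3/4/6 into intervals; unnamed lines get ids ``<prefix>_<n>``."""
    out: list[GenomicInterval] = []
    seen_ids: set[str] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else (
                f"{id_prefix}_{len(out) + 1}"
            )
            strand = fields[5] if len(fields) >= 6 else "."
            if name in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate interval id {name!r}")
            seen_ids.add(name)
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, scores=None) -> None:
    """Write BED6; ``scores`` is an optional parallel sequence for column 5."""
    intervals = list(intervals)
    if scores is None:
        scores = [0] * len(intervals)
    with open(path, "wt") as fh:
        for iv, score in zip(intervals, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "coding"]


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read the TSV gene annotation (gene_id, chrom, start, end, strand, coding)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: gene {row.gene_id!r} has unknown strand {row.strand!r}"
            )
        body = GenomicInterval(
            row.chrom, int(row.start), int(row.end), row.strand, row.gene_id
        )
        genes.append(GeneAnnotation(row.gene_id, body, bool(row.coding)))
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.body.chrom,
            "start": g.body.start,
            "end": g.body.end,
            "strand": g.body.strand,
            "coding": g.coding,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# library table
# ---------------------------------------------------------------------------


def library_to_frame(guides) -> pd.DataFrame:
    """Convert a list of GuideRecord into the on-disk library table layout."""
    rows = []
    for g in guides:
        rows.append(
            {
                "guide_id": g.guide_id,
                "spacer": g.spacer,
                "pam": g.pam,
                "chrom": g.locus.chrom if g.locus is not None else ".",
                "start": g.locus.start if g.locus is not None else -1,
                "end": g.locus.end if g.locus is not None else -1,
                "strand": g.strand if g.locus is not None else ".",
                "cut_pos": g.cut_pos if g.cut_pos is not None else -1,
                "category": g.category,
                "peak_id": g.peak_id or ".",
                "motif_ids": ",".join(g.motif_ids) if g.motif_ids else ".",
            }
        )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(guides, path) -> None:
    library_to_frame(guides).to_csv(path, sep="\t", index=False)


def read_library(path) -> list:
    """Read a library TSV back into GuideRecord rows."""
    from .guides import GuideRecord  # deferred: avoids a module cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "peak_id": str}, na_filter=False)
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: library table missing columns {sorted(missing)}")
    guides = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.guide_id in seen:
            raise ParseError(f"{path}: duplicate guide_id {row.guide_id!r}")
        seen.add(row.guide_id)
        if len(row.spacer) != 20:
            raise ParseError(
                f"{path}: guide {row.guide_id!r} spacer length {len(row.spacer)} != 20"
            )
        if row.category not in GUIDE_CATEGORIES:
            raise ParseError(
                f"{path}: guide {row.guide_id!r} has unknown category {row.category!r}"
            )
        locus = None
        cut_pos = None
        strand = "."
        if int(row.start) >= 0:
            locus = GenomicInterval(
                str(row.chrom), int(row.start), int(row.end), row.strand, row.guide_id
            )
            strand = row.strand
            cut_pos = int(row.cut_pos)
        motif_ids = tuple() if row.motif_ids == "." else tuple(str(row.motif_ids).split(","))
        guides.append(
            GuideRecord(
                guide_id=row.guide_id,
                spacer=row.spacer,
                pam=row.pam,
                locus=locus,
                strand=strand,
                cut_pos=cut_pos,
                category=row.category,
                peak_id=None if row.peak_id == "." else row.peak_id,
                motif_ids=motif_ids,
            )
        )
    return guides


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------


def read_count_table(path, pdna_column: str, library=None):
    """Read an sgRNA x sample count TSV into a :class:`~peakscreen.screen.CountMatrix`.

    First column must be ``guide_id``; every other column is an integer count
    column.  ``pdna_column`` designates the plasmid-library reference sample.
    When ``library`` (a list of GuideRecord) is given, count-table guide ids
    are reconciled against it and unmatched ids are reported as a warning.
    """
    from .screen import CountMatrix  # deferred: avoids a module cycle

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "guide_id":
        raise ParseError(f"{path}: first column must be 'guide_id', got {df.columns[0]!r}")
    if pdna_column not in df.columns:
        raise ParseError(f"{path}: designated pDNA column {pdna_column!r} not present")
    df = df.set_index("guide_id")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_integer_dtype(vals):
            raise ParseError(f"{path}: column {col!r} contains non-integer counts")
        if (vals < 0).any():
            bad = vals[vals < 0].index[0]
            raise ParseError(f"{path}: negative count for guide {bad!r} in column {col!r}")
    if library is not None:
        lib_ids = {g.guide_id for g in library}
        unmatched = [gid for gid in df.index if gid not in lib_ids]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} guide id(s) in count table absent from library: "
                f"{unmatched[:10]}{'...' if len(unmatched) > 10 else ''}",
                stacklevel=2,
            )
    return CountMatrix.from_frame(df, pdna_column=pdna_column)
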