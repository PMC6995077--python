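"""CFD off-target scoring, exclusion rules, and control-guide construction.

The cutting frequency determination (CFD) score of a candidate off-target
site is the product, over spacer positions 1-20, of a per-position
(guide-RNA base, site base) mismatch penalty, times a PAM 2-mer penalty.
Watson-Crick matches contribute 1.0; a site with CFD = 1 is treated as fully
tolerated and counts as a potential off-target.

Library filtering applies two exclusion rules to each candidate guide:

* rule A — any CFD = 1 site overlapping a protein-coding gene body rejects
  the guide;
* rule B — more than one CFD = 1 site in unrelated noncoding sequence
  (outside coding genes; by default a site inside another *targeted* peak
  also counts, ``exempt_targeted_peaks`` relaxes this) rejects the guide.

The packaged penalty table (``data/cfd_weights_synthetic.tsv``) is a
synthetic stand-in constructed for this package: it has the published
tables' schema and invariants (unit penalty for matches and for the GG PAM,
all penalties in [0,1], full tolerance confined to a few PAM-distal wobble
pairs) but its numeric entries are not the published measurements.  Supply
your own table for production designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .guides import GuideRecord, SPACER_LEN
from .io import GenomeSequence, GenomicInterval, GeneAnnotation
from .motifs import revcomp

logger = logging.getLogger(__name__)

CFD_ONE_TOL = 1e-9

_BASE2IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_DNA2RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


class CfdTable:
    """Position- and base-pair-specific mismatch penalties plus PAM penalties."""

    def __init__(self, mismatch_penalty: dict, pam_penalty: dict):
        for (pos, r, d), v in mismatch_penalty.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"penalty out of [0,1] at ({pos},{r},{d}): {v}")
        for two, v in pam_penalty.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"PAM penalty out of [0,1] for {two}: {v}")
        if abs(pam_penalty.get("GG", 0.0) - 1.0) > CFD_ONE_TOL:
            raise ValueError("PAM penalty for GG must be 1.0")
        self.mismatch_penalty = dict(mismatch_penalty)
        self.pam_penalty = dict(pam_penalty)
        # positions at which some mismatch is fully tolerated; bounds the
        # number of mismatches any CFD = 1 site can carry
        self.full_tolerance_positions = sorted(
            {pos for (pos, _, _), v in mismatch_penalty.items() if v >= 1.0 - CFD_ONE_TOL}
        )

    @classmethod
    def load(cls, path=None) -> "CfdTable":
        """Load a penalty TSV (kind, position, rna_base, dna_base, pam, penalty);
        default is the packaged synthetic table."""
        if path is None:
            ref = resources.files("peakscreen.data") / "cfd_weights_synthetic.tsv"
            with resources.as_file(ref) as p:
                df = pd.read_csv(p, sep="\t")
        else:
            df = pd.read_csv(path, sep="\t")
        mm = {}
        pam = {}
        for row in df.itertuples(index=False):
            if row.kind == "mm":
                mm[(int(row.position), row.rna_base, row.dna_base)] = float(row.penalty)
            elif row.kind == "pam":
                pam[row.pam] = float(row.penalty)
            else:
                raise ValueError(f"unknown row kind {row.kind!r} in CFD table")
        return cls(mm, pam)

    def max_mismatches_at_cfd1(self) -> int:
        return len(self.full_tolerance_positions)

    def penalty_matrix(self) -> np.ndarray:
        """(20, 4, 4) array: [pos-1, spacer base idx, site base idx] -> penalty.

        Matches are 1.0; mismatches come from the table (missing entries 0.0).
        Spacer bases are DNA-sense and converted to RNA for the lookup.
        """
        mat = np.zeros((SPACER_LEN, 4, 4))
        for i in range(SPACER_LEN):
            for sb, si in _BASE2IDX.items():
                for db, di in _BASE2IDX.items():
                    if sb == db:
                        mat[i, si, di] = 1.0
                    else:
                        mat[i, si, di] = self.mismatch_penalty.get(
                            (i + 1, _DNA2RNA[sb], db), 0.0
                        )
        return mat


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic site resembling a guide's target, with its CFD score and
    annotation context (coding_gene / targeted_peak / other_noncoding)."""

    locus: GenomicInterval
    strand: str
    site_seq: str
    pam: str
    n_mismatches: int
    cfd: float
    context: str


def cfd_score(spacer: str, site_seq: str, pam: str, table: CfdTable) -> float:
    """CFD score of ``site_seq`` (protospacer-strand, 5'->3') + ``pam``
    against a 20-nt spacer.  Product form; all factors in [0,1]."""
    if len(spacer) != SPACER_LEN or len(site_seq) != SPACER_LEN:
        raise ValueError("spacer and site_seq must both be 20 nt")
    if len(pam) != 3:
        raise ValueError("PAM must be 3 nt")
    score = 1.0
    for i, (sb, db) in enumerate(zip(spacer, site_seq), start=1):
        if sb == db:
            continue
        try:
            score *= table.mismatch_penalty[(i, _DNA2RNA[sb], db)]
        except KeyError as exc:
            raise KeyError(f"no penalty entry for position {i}, r{_DNA2RNA[sb]}:d{db}") from exc
    try:
        score *= table.pam_penalty[pam[1:3]]
    except KeyError as exc:
        raise KeyError(f"no PAM penalty entry for {pam[1:3]!r}") from exc
    return score


# ---------------------------------------------------------------------------
# genome-wide site search
# ---------------------------------------------------------------------------


class SiteIndex:
    """All PAM-adjacent 20-mers of a genome, as integer arrays for fast
    vectorized mismatch counting.  NGG and NAG PAMs are both enumerated (NAG
    is discounted by its PAM penalty); sites containing N are excluded."""

    def __init__(self, genome: GenomeSequence):
        self.chroms: list[str] = []
        self.chrom_idx: np.ndarray
        self.starts: np.ndarray
        self.strands: np.ndarray  # 0 = +, 1 = -
        self.seqs: np.ndarray  # (n_sites, 20) uint8 base codes, spacer-sense
        self.pam2: np.ndarray  # PAM 2-mer string array
        chrom_parts, start_parts, strand_parts, seq_parts, pam_parts = [], [], [], [], []
        for ci, (chrom, seq) in enumerate(genome.contigs.items()):
            self.chroms.append(chrom)
            code = np.frombuffer(seq.encode(), dtype=np.uint8)
            arr = np.full(code.shape, 255, dtype=np.uint8)
            for b, i in _BASE2IDX.items():
                arr[code == ord(b)] = i
            n = len(arr)
            if n < SPACER_LEN + 3:
                continue
            valid = arr != 255
            ok20 = np.ones(n, dtype=bool)  # ok20[i]: [i, i+20) all ACGT
            w = np.lib.stride_tricks.sliding_window_view(valid, SPACER_LEN)
            ok20[: n - SPACER_LEN + 1] = w.all(axis=1)
            ok20[n - SPACER_LEN + 1 :] = False
            # + strand: PAM N[G/A]G at p, protospacer [p-20, p)
            pam_ok = (
                valid[:-2]
                & ((arr[1:-1] == _BASE2IDX["G"]) | (arr[1:-1] == _BASE2IDX["A"]))
                & (arr[2:] == _BASE2IDX["G"])
            )
            p_pos = np.nonzero(pam_ok)[0]
            p_pos = p_pos[(p_pos >= SPACER_LEN) & ok20[p_pos - SPACER_LEN]]
            if p_pos.size:
                offs = np.arange(SPACER_LEN)
                seq_parts.append(arr[(p_pos - SPACER_LEN)[:, None] + offs])
                start_parts.append(p_pos - SPACER_LEN)
                strand_parts.append(np.zeros(p_pos.size, dtype=np.uint8))
                chrom_parts.append(np.full(p_pos.size, ci, dtype=np.int32))
                pam_parts.append(
                    np.array([seq[p + 1 : p + 3] for p in p_pos], dtype=object)
                )
            # - strand: PAM reads C[C/T]N on + at p, protospacer [p+3, p+23)
            pam_ok_m = (
                (arr[:-2] == _BASE2IDX["C"])
                & ((arr[1:-1] == _BASE2IDX["C"]) | (arr[1:-1] == _BASE2IDX["T"]))
                & valid[2:]
            )
            m_pos = np.nonzero(pam_ok_m)[0]
            m_pos = m_pos[m_pos + 3 + SPACER_LEN <= n]
            m_pos = m_pos[ok20[m_pos + 3]]
            if m_pos.size:
                offs = np.arange(SPACER_LEN)
                fwd = arr[(m_pos + 3)[:, None] + offs]
                seq_parts.append(3 - fwd[:, ::-1])  # reverse complement in codes
                start_parts.append(m_pos + 3)
                strand_parts.append(np.ones(m_pos.size, dtype=np.uint8))
                chrom_parts.append(np.full(m_pos.size, ci, dtype=np.int32))
                pam_parts.append(
                    np.array(
                        [revcomp(seq[p : p + 2]) for p in m_pos], dtype=object
                    )
                )
        if seq_parts:
            self.seqs = np.concatenate(seq_parts, axis=0)
            self.starts = np.concatenate(start_parts)
            self.strands = np.concatenate(strand_parts)
            self.chrom_idx = np.concatenate(chrom_parts)
            self.pam2 = np.concatenate(pam_parts)
        else:
            self.seqs = np.zeros((0, SPACER_LEN), dtype=np.uint8)
            self.starts = np.zeros(0, dtype=np.int64)
            self.strands = np.zeros(0, dtype=np.uint8)
            self.chrom_idx = np.zeros(0, dtype=np.int32)
            self.pam2 = np.zeros(0, dtype=object)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def query(self, spacer: str, max_mm: int):
        """Indices of sites within ``max_mm`` mismatches, with mismatch counts."""
        vec = np.array([_BASE2IDX[b] for b in spacer], dtype=np.uint8)
        mm = (self.seqs != vec).sum(axis=1)
        idx = np.nonzero(mm <= max_mm)[0]
        return idx, mm[idx]


class _ContextIndex:
    """Interval trees for labeling site context."""

    def __init__(self, genes: list[GeneAnnotation], peaks: list[GenomicInterval]):
        self.coding: dict[str, IntervalTree] = {}
        self.peaks: dict[str, IntervalTree] = {}
        for g in genes:
            if g.coding:
                self.coding.setdefault(g.body.chrom, IntervalTree()).addi(
                    g.body.start, g.body.end, g.gene_id
                )
        for p in peaks:
            self.peaks.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p.id)

    def context(self, chrom: str, start: int, end: int) -> str:
        if chrom in self.coding and self.coding[chrom].overlap(start, end):
            return "coding_gene"
        if chrom in self.peaks and self.peaks[chrom].overlap(start, end):
            return "targeted_peak"
        return "other_noncoding"


def find_offtargets(
    genome: GenomeSequence,
    spacer: str,
    max_mm: int = 3,
    table: CfdTable | None = None,
    genes: list[GeneAnnotation] | None = None,
    peaks: list[GenomicInterval] | None = None,
    exclude_locus: tuple[str, int, str] | None = None,
    site_index: SiteIndex | None = None,
    context_index: "_ContextIndex | None" = None,
) -> list[OffTargetSite]:
    """Every genomic site (both strands, NGG/NAG PAM) within ``max_mm``
    mismatches of ``spacer``, CFD-scored and context-labeled.

    ``exclude_locus`` = (chrom, start, strand) removes the guide's own
    intended site by coordinate identity.  Pass a prebuilt ``site_index`` /
    ``context_index`` when scoring many guides against one genome.
    """
    if table is None:
        table = CfdTable.load()
    if site_index is None:
        site_index = SiteIndex(genome)
    if context_index is None:
        context_index = _ContextIndex(genes or [], peaks or [])
    pmat = table.penalty_matrix()
    vec = np.array([_BASE2IDX[b] for b in spacer], dtype=np.uint8)
    idx, mms = site_index.query(spacer, max_mm)
    out = []
    pos_range = np.arange(SPACER_LEN)
    for i, n_mm in zip(idx, mms):
        chrom = site_index.chroms[site_index.chrom_idx[i]]
        start = int(site_index.starts[i])
        strand = "+" if site_index.strands[i] == 0 else "-"
        if exclude_locus is not None and (chrom, start, strand) == exclude_locus:
            continue
        site_codes = site_index.seqs[i]
        score = float(np.prod(pmat[pos_range, vec, site_codes]))
        score *= table.pam_penalty.get(str(site_index.pam2[i]), 0.0)
        site_seq = "".join("ACGT"[c] for c in site_codes)
        pam = "N" + str(site_index.pam2[i])
        out.append(
            OffTargetSite(
                locus=GenomicInterval(chrom, start, start + SPACER_LEN, strand),
                strand=strand,
                site_seq=site_seq,
                pam=pam,
                n_mismatches=int(n_mm),
                cfd=score,
                context=context_index.context(chrom, start, start + SPACER_LEN),
            )
        )
    out.sort(key=lambda s: (s.locus.chrom, s.locus.start, s.strand))
    return out


@dataclass(frozen=True)
class RejectedGuide:
    guide: GuideRecord
    rule: str  # "A" or "B"
    sites: tuple[OffTargetSite, ...]


def filter_guides(
    guides: list[GuideRecord],
    genome: GenomeSequence,
    genes: list[GeneAnnotation],
    peaks: list[GenomicInterval],
    table: CfdTable | None = None,
    max_mm: int = 3,
    exempt_targeted_peaks: bool = False,
    site_index: SiteIndex | None = None,
) -> tuple[list[GuideRecord], list[RejectedGuide]]:
    """Partition guides into (kept, rejected) under the two exclusion rules.

    A site counts as a potential off-target when its CFD equals 1 (within
    1e-9).  Rule A rejects on any such site inside a coding gene body; rule
    B rejects when more than one such site lies in noncoding sequence
    (including other targeted peaks unless ``exempt_targeted_peaks``).
    ``max_mm`` must cover every mismatch count a CFD = 1 site can have,
    which is asserted against the loaded table.
    """
    if table is None:
        table = CfdTable.load()
    if table.max_mismatches_at_cfd1() > max_mm:
        raise ValueError(
            f"max_mm={max_mm} cannot contain all CFD=1 sites: table has fully "
            f"tolerated entries at {len(table.full_tolerance_positions)} positions"
        )
    if site_index is None:
        site_index = SiteIndex(genome)
    ctx_index = _ContextIndex(genes, peaks)
    kept: list[GuideRecord] = []
    rejected: list[RejectedGuide] = []
    for g in guides:
        exclude = None
        if g.locus is not None:
            exclude = (g.locus.chrom, g.locus.start, g.strand)
        sites = find_offtargets(
            genome,
            g.spacer,
            max_mm=max_mm,
            table=table,
            exclude_locus=exclude,
            site_index=site_index,
            context_index=ctx_index,
        )
        cfd1 = [s for s in sites if s.cfd >= 1.0 - CFD_ONE_TOL]
        rule_a = [s for s in cfd1 if s.context == "coding_gene"]
        if rule_a:
            rejected.append(RejectedGuide(g, "A", tuple(rule_a)))
            continue
        noncoding_ctx = {"other_noncoding"} if exempt_targeted_peaks else {
            "other_noncoding",
            "targeted_peak",
        }
        rule_b = [s for s in cfd1 if s.context in noncoding_ctx]
        if len(rule_b) > 1:
            rejected.append(RejectedGuide(g, "B", tuple(rule_b)))
            continue
        kept.append(g)
    logger.info(
        "off-target filter: kept %d, rejected %d (%d rule A, %d rule B)",
        len(kept),
        len(rejected),
        sum(1 for r in rejected if r.rule == "A"),
        sum(1 for r in rejected if r.rule == "B"),
    )
    return kept, rejected


def write_rejection_report(rejected: list[RejectedGuide], path) -> None:
    rows = []
    for r in rejected:
        for s in r.sites:
            rows.append(
                {
                    "guide_id": r.guide.guide_id,
                    "spacer": r.guide.spacer,
                    "rule": r.rule,
                    "site_chrom": s.locus.chrom,
                    "site_start": s.locus.start,
                    "site_strand": s.strand,
                    "site_context": s.context,
                    "n_mismatches": s.n_mismatches,
                    "cfd": s.cfd,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "guide_id", "spacer", "rule", "site_chrom", "site_start",
            "site_strand", "site_context", "n_mismatches", "cfd",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# control guides
# ---------------------------------------------------------------------------


def make_intergenic_controls(
    genome: GenomeSequence,
    genes: list[GeneAnnotation],
    peaks: list[GenomicInterval],
    n: int,
    min_gene_distance: int = 5000,
    table: CfdTable | None = None,
    max_mm: int = 3,
    rng_seed: int = 0,
) -> list[GuideRecord]:
    """``n`` guides at real NGG sites that are >= ``min_gene_distance`` bp
    from every gene body, outside all targeted peaks, and that pass the
    off-target filter.  Deterministic under ``rng_seed``."""
    if n == 0:
        return []
    if table is None:
        table = CfdTable.load()
    rng = np.random.default_rng(rng_seed)
    site_index = SiteIndex(genome)
    ctx_index = _ContextIndex(genes, peaks)
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.body.chrom, IntervalTree()).addi(
            max(0, g.body.start - min_gene_distance), g.body.end + min_gene_distance
        )
    order = rng.permutation(len(site_index))
    controls: list[GuideRecord] = []
    for i in order:
        if len(controls) >= n:
            break
        chrom = site_index.chroms[site_index.chrom_idx[i]]
        start = int(site_index.starts[i])
        strand = "+" if site_index.strands[i] == 0 else "-"
        pam2 = str(site_index.pam2[i])
        if pam2 != "GG":  # controls use canonical NGG sites only
            continue
        end = start + SPACER_LEN
        if chrom in gene_trees and gene_trees[chrom].overlap(start, end):
            continue
        if ctx_index.context(chrom, start, end) != "other_noncoding":
            continue
        spacer = "".join("ACGT"[c] for c in site_index.seqs[i])
        if strand == "+":
            pam = genome[chrom][end : end + 3]
            cut = start + 16
        else:
            pam = revcomp(genome[chrom][start - 3 : start])
            cut = start - 3 + 5
        guide = GuideRecord(
            guide_id=f"intergenic-{len(controls) + 1}",
            spacer=spacer,
            pam=pam,
            locus=GenomicInterval(chrom, start, end, strand),
            strand=strand,
            cut_pos=cut,
            category="intergenic_control",
        )
        kept, _ = filter_guides(
            [guide], genome, genes, peaks, table=table, max_mm=max_mm,
            site_index=site_index,
        )
        if kept:
            controls.append(guide)
    if len(controls) < n:
        raise ValueError(
            f"genome yields only {len(controls)} intergenic control sites "
            f"(requested {n})"
        )
    return controls


def make_nontargeting_controls(
    genome: GenomeSequence,
    n: int,
    max_mm_clearance: int = 2,
    rng_seed: int = 0,
    max_attempts_per_guide: int = 200,
) -> list[GuideRecord]:
    """``n`` random 20-mers with no PAM-adjacent genomic site within
    ``max_mm_clearance`` mismatches.  Deterministic under ``rng_seed``."""
    if n == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    site_index = SiteIndex(genome)
    controls: list[GuideRecord] = []
    attempts = 0
    budget = n * max_attempts_per_guide
    while len(controls) < n:
        if attempts >= budget:
            raise ValueError(
                f"could not find {n} non-targeting spacers with clearance "
                f"{max_mm_clearance} within {budget} attempts "
                f"(found {len(controls)})"
            )
        attempts += 1
        spacer = "".join(rng.choice(list("ACGT"), size=SPACER_LEN))
        idx, _ = site_index.query(spacer, max_mm_clearance)
        if idx.size:
            continue
        controls.append(
            GuideRecord(
                guide_id=f"nontargeting-{len(controls) + 1}",
                spacer=spacer,
                pam="NNN",
                locus=None,
                strand=".",
                cut_pos=None,
                category="nontargeting_control",
            )
        )
    return controls
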