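"""Enumeration of candidate sgRNAs around dyad motifs.

A candidate is every PAM-containing site (NGG by default, SpCas9) whose 3-bp
PAM lies entirely within the motif interval extended by ``window`` bp (16 by
default) on each side, on either strand, with the full 20-nt protospacer on
the contig.  No on-target efficacy scoring is applied: all candidates are
kept and thinned only by the off-target filter.

Spacers are reported guide-sense: the genome subsequence for + guides, its
reverse complement for - guides.  The blunt SpCas9 cut falls between
protospacer positions 17 and 18 (3 bp 5' of the PAM); ``cut_pos`` records
the + strand coordinate of the base immediately 5' of the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .io import GenomeSequence, GenomicInterval
from .motifs import IUPAC, MotifHit, revcomp

logger = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: 20-nt spacer, observed PAM, genomic locus and attribution.

    ``category`` is one of peak / intergenic_control / nontargeting_control /
    gene / gene_control.  ``locus`` and ``cut_pos`` are None for
    non-targeting controls (no genomic site).  ``motif_ids`` lists every
    motif whose extended window contains the PAM, 5'-most first.
    """

    guide_id: str
    spacer: str
    pam: str
    locus: GenomicInterval | None
    strand: str
    cut_pos: int | None
    category: str
    peak_id: str | None = None
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(
                f"spacer must be {SPACER_LEN} nt, got {len(self.spacer)}"
            )


def _pam_matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        s in IUPAC.get(p, "") for s, p in zip(seq, pattern)
    )


def enumerate_guides(
    genome: GenomeSequence,
    motif_hits: list[MotifHit],
    window: int = 16,
    pam_pattern: str = "NGG",
    anchor: str = "pam",
) -> list[GuideRecord]:
    """Every candidate sgRNA whose PAM (or cut site, ``anchor='cut'``) lies
    within ``window`` bp of a motif.

    With the default PAM anchoring, a + strand candidate with PAM at
    [p, p+3) is admitted when motif.start - window <= p and
    p + 3 <= motif.end + window; the - strand mirror applies to CCN sites.
    Candidates sharing (locus, strand) across motifs are merged with the
    union of their motif ids.  Spacers containing N are dropped and logged.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rc_pam = revcomp(pam_pattern)  # e.g. NGG -> CCN, as it reads on + strand
    by_site: dict[tuple[str, int, str], dict] = {}
    n_dropped = 0
    for hit in motif_hits:
        chrom = hit.interval.chrom
        seq = genome[chrom]
        clen = len(seq)
        lo = max(0, hit.interval.start - window)
        hi = min(clen, hit.interval.end + window)
        # cut anchoring admits PAMs slightly outside [lo, hi); widen the scan
        margin = 0 if anchor == "pam" else 8
        for p in range(max(0, lo - margin), min(clen, hi + margin) - PAM_LEN + 1):
            pam_fwd = seq[p : p + PAM_LEN]
            # + strand: protospacer immediately 5' of the PAM
            if _pam_matches(pam_fwd, pam_pattern) and p - SPACER_LEN >= 0:
                start = p - SPACER_LEN
                cut = start + 16  # base 5' of the blunt cut
                admitted = (lo <= p and p + PAM_LEN <= hi) if anchor == "pam" else (lo <= cut < hi)
                if admitted:
                    spacer = seq[start:p]
                    if "N" in spacer or "N" in pam_fwd:
                        n_dropped += 1
                    else:
                        _add_site(by_site, chrom, start, "+", spacer, pam_fwd, cut, hit)
            # - strand: PAM reads as revcomp(pam_pattern) on +, protospacer 3' of it
            if _pam_matches(pam_fwd, rc_pam) and p + PAM_LEN + SPACER_LEN <= clen:
                start = p + PAM_LEN
                cut = p + 5  # between protospacer positions 17/18 on the - strand
                admitted = (lo <= p and p + PAM_LEN <= hi) if anchor == "pam" else (lo <= cut < hi)
                if admitted:
                    proto_fwd = seq[start : start + SPACER_LEN]
                    pam_obs = revcomp(pam_fwd)
                    if "N" in proto_fwd or "N" in pam_obs:
                        n_dropped += 1
                    else:
                        _add_site(
                            by_site, chrom, start, "-", revcomp(proto_fwd), pam_obs, cut, hit
                        )
    if n_dropped:
        logger.info("dropped %d candidate guides overlapping N bases", n_dropped)
    guides = []
    for (chrom, start, strand), rec in sorted(by_site.items()):
        motifs = sorted(rec["motifs"], key=lambda m: (m.interval.start, m.motif_id))
        primary = motifs[0]
        guides.append(
            GuideRecord(
                guide_id=f"{chrom}:{start}:{strand}",  # provisional; see assign_guide_ids
                spacer=rec["spacer"],
                pam=rec["pam"],
                locus=GenomicInterval(chrom, start, start + SPACER_LEN, strand),
                strand=strand,
                cut_pos=rec["cut"],
                category="peak",
                peak_id=primary.peak_id,
                motif_ids=tuple(m.motif_id for m in motifs),
            )
        )
    return guides


def _add_site(by_site, chrom, start, strand, spacer, pam, cut, hit):
    key = (chrom, start, strand)
    rec = by_site.setdefault(
        key, {"spacer": spacer, "pam": pam, "cut": cut, "motifs": []}
    )
    rec["motifs"].append(hit)


def assign_guide_ids(guides: list[GuideRecord]) -> list[GuideRecord]:
    """Stable ids ``<peak>.<motif index>-<running index>``.

    The motif index is the 5'->3' rank of the guide's 5'-most motif within
    its peak (the suffix of the motif id); the running index numbers the
    guides of that motif in coordinate order.  Non-targeting records keep
    their existing ids.
    """
    counters: dict[str, int] = {}
    out = []

    def sort_key(g: GuideRecord):
        if g.locus is None:
            return ("", 0, "")
        return (g.locus.chrom, g.locus.start, g.strand)

    for g in sorted(guides, key=sort_key):
        if g.category != "peak" or not g.motif_ids:
            out.append(g)
            continue
        primary = g.motif_ids[0]
        n = counters.get(primary, 0) + 1
        counters[primary] = n
        out.append(replace(g, guide_id=f"{primary}-{n}"))
    return out


def summarize_library(
    guides: list[GuideRecord],
    peaks: list[GenomicInterval] | None = None,
    motifs: list[MotifHit] | None = None,
    genes=None,
) -> dict:
    """Design summary: guides-per-peak and guides-per-motif histograms,
    multiply-targeted counts, category totals, and (when a gene table is
    supplied) the distance-to-TSS distribution of the targeting guides."""
    peak_counts: dict[str, int] = {}
    motif_counts: dict[str, int] = {}
    for g in guides:
        if g.category == "peak":
            peak_counts[g.peak_id] = peak_counts.get(g.peak_id, 0) + 1
            for m in g.motif_ids:
                motif_counts[m] = motif_counts.get(m, 0) + 1
    peak_hist = pd.Series(list(peak_counts.values()), dtype=int).value_counts().sort_index()
    motif_hist = pd.Series(list(motif_counts.values()), dtype=int).value_counts().sort_index()
    category_totals = pd.Series([g.category for g in guides]).value_counts().to_dict() if guides else {}
    summary = {
        "n_guides": len(guides),
        "category_totals": category_totals,
        "guides_per_peak_hist": peak_hist.to_dict(),
        "guides_per_motif_hist": motif_hist.to_dict(),
        "peaks_targeted": len(peak_counts),
        "motifs_targeted": len(motif_counts),
        "peaks_multiply_targeted": sum(1 for v in peak_counts.values() if v >= 2),
        "motifs_multiply_targeted": sum(1 for v in motif_counts.values() if v >= 2),
    }
    if peaks is not None:
        summary["peaks_total"] = len(peaks)
        summary["peaks_untargeted"] = len(peaks) - len(peak_counts)
    if motifs is not None:
        summary["motifs_total"] = len(motifs)
        summary["motifs_untargeted"] = len(motifs) - len(motif_counts)
    if genes:
        from .screen import tss_distance_guides

        dists = tss_distance_guides(
            [g for g in guides if g.category == "peak" and g.cut_pos is not None], genes
        )
        valid = [d for d in dists.values() if d is not None]
        if valid:
            s = pd.Series(valid)
            summary["tss_distance"] = {
                "n": int(s.size),
                "median_bp": float(s.median()),
                "within_10kb": int((s <= 10_000).sum()),
                "beyond_10kb": int((s > 10_000).sum()),
            }
    return summary
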