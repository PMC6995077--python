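"""Independent brute-force reference implementations used only by tests.

Each oracle is written as directly as possible (double loops, explicit
definitions) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _matches(seq: str, pos: int, arm: str) -> bool:
    if pos + len(arm) > len(seq):
        return False
    return all(seq[pos + i] in IUPAC[c] for i, c in enumerate(arm))


def naive_scan(seq, left_arm, right_arm, spacer_min, spacer_max):
    """Double-loop dyad matcher: every (offset, spacer_len) combination."""
    seq = seq.upper()
    hits = []
    for off in range(len(seq)):
        if not _matches(seq, off, left_arm):
            continue
        for spacer in range(spacer_min, spacer_max + 1):
            rpos = off + len(left_arm) + spacer
            if rpos + len(right_arm) > len(seq):
                break
            if "N" in seq[off + len(left_arm) : rpos]:
                continue
            if _matches(seq, rpos, right_arm):
                hits.append((off, spacer))
    return sorted(hits)


def brute_force_guides(contig_seq, motif_start, motif_end, window, pam_pattern="NGG"):
    """Every (protospacer_start, strand, spacer, pam) whose 3-bp PAM lies
    entirely within [motif_start - window, motif_end + window)."""
    n = len(contig_seq)
    lo, hi = max(0, motif_start - window), min(n, motif_end + window)
    out = []
    for p in range(n - 2):
        pam_fwd = contig_seq[p : p + 3]
        # + strand guide: PAM on forward strand, protospacer 5' of it
        if (
            all(pam_fwd[i] in IUPAC[pam_pattern[i]] for i in range(3))
            and "N" not in pam_fwd
            and p - 20 >= 0
            and lo <= p
            and p + 3 <= hi
        ):
            spacer = contig_seq[p - 20 : p]
            if "N" not in spacer:
                out.append((p - 20, "+", spacer, pam_fwd))
        # - strand guide: PAM is rc(pam_pattern) read on forward strand
        pam_rev = rc(pam_fwd)
        if (
            all(pam_rev[i] in IUPAC[pam_pattern[i]] for i in range(3))
            and "N" not in pam_fwd
            and p + 3 + 20 <= n
            and lo <= p
            and p + 3 <= hi
        ):
            proto_fwd = contig_seq[p + 3 : p + 23]
            if "N" not in proto_fwd:
                out.append((p + 3, "-", rc(proto_fwd), pam_rev))
    return sorted(set(out))


def brute_force_offtargets(genome_contigs, spacer, max_mm):
    """Every site on either strand with <= max_mm mismatches and an N[G/A]G
    PAM, as (chrom, start, strand, site_seq, pam, n_mm)."""
    out = []
    for chrom, seq in genome_contigs.items():
        n = len(seq)
        for s in range(n - 22):
            site = seq[s : s + 20]
            pam = seq[s + 20 : s + 23]
            if "N" not in site and pam[1] in "GA" and pam[2] == "G" and pam[0] != "N":
                mm = sum(1 for a, b in zip(spacer, site) if a != b)
                if mm <= max_mm:
                    out.append((chrom, s, "+", site, pam, mm))
        for s in range(3, n - 19):
            pam_fwd = seq[s - 3 : s]
            site_fwd = seq[s : s + 20]
            pam = rc(pam_fwd)
            site = rc(site_fwd)
            if "N" not in site and pam[1] in "GA" and pam[2] == "G" and pam[0] != "N":
                mm = sum(1 for a, b in zip(spacer, site) if a != b)
                if mm <= max_mm:
                    out.append((chrom, s, "-", site, pam, mm))
    return sorted(out)


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg adjusted p-values: sort, scale by m/rank,
    take running minimum from the largest p down, clip at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
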