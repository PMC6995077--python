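"""Pooled-screen readout analysis: spacer counting, normalization, log2
fold change versus the plasmid library, and guide/peak-level significance.

The analysis contract mirrors common pooled-screen practice: counts are
median-ratio normalized, each guide's log2 fold change (lfc) is taken
relative to its abundance in the initial plasmid DNA (pDNA) pool, peaks are
summarized by the median lfc of their member guides, and multiple testing
is controlled with Benjamini-Hochberg FDR.  Significance is anchored on the
non-targeting control guides: guide p-values are two-sided empirical tail
probabilities against the control lfc distribution, and peak p-values
compare each peak's median against medians of random same-size draws from
the control pool.  This control-anchored statistic is deliberately simple
and fully specified; it does not reproduce the numeric output of
negative-binomial screen tools.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .guides import GuideRecord, SPACER_LEN
from .io import GeneAnnotation, GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """sgRNA x sample integer counts with a designated pDNA reference column
    and a sample -> condition grouping for the non-pDNA samples."""

    counts: pd.DataFrame  # index guide_id, integer columns
    pdna: str
    conditions: dict[str, str]  # sample -> condition label (pDNA excluded)

    def __post_init__(self):
        if self.pdna not in self.counts.columns:
            raise ValueError(f"pDNA column {self.pdna!r} not in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.conditions:
            if s not in self.counts.columns:
                raise ValueError(f"condition sample {s!r} not in count matrix")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, pdna_column: str, condition_map: dict | None = None
    ) -> "CountMatrix":
        """Wrap a guides x samples frame.  Without an explicit map, sample
        names of the form ``<condition>_r<k>`` group by their prefix and any
        other non-pDNA column becomes its own condition."""
        if condition_map is None:
            condition_map = {}
            for col in df.columns:
                if col == pdna_column:
                    continue
                base, _, rep = col.rpartition("_r")
                condition_map[col] = base if base and rep.isdigit() else col
        return cls(df.copy(), pdna_column, condition_map)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    def replicates(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_names(self) -> list[str]:
        seen = []
        for c in self.conditions.values():
            if c not in seen:
                seen.append(c)
        return seen

    def write(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "guide_id", out.index)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spacer counting from reads
# ---------------------------------------------------------------------------


@dataclass
class SpacerLocator:
    """How to find the 20-nt spacer in a read: either a fixed 0-based
    ``offset``, or an ``anchor`` sequence that immediately precedes it
    (the spacer starts right after the first anchor occurrence)."""

    offset: int | None = None
    anchor: str | None = None

    def __post_init__(self):
        if (self.offset is None) == (self.anchor is None):
            raise ValueError("provide exactly one of offset or anchor")

    def extract(self, read: str) -> str | None:
        if self.offset is not None:
            start = self.offset
        else:
            pos = read.find(self.anchor)
            if pos < 0:
                return None
            start = pos + len(self.anchor)
        spacer = read[start : start + SPACER_LEN]
        return spacer if len(spacer) == SPACER_LEN else None


def _iter_fastq(path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{i + 1}: {exc}") from exc
            i += 1
            yield rec


def count_spacers(
    reads, library: list[GuideRecord], locator: SpacerLocator
) -> tuple[pd.Series, dict]:
    """Exact-match assignment of extracted 20-mers to library spacers.

    ``reads`` is a FASTQ path or an iterable of read strings.  Returns a
    counts Series over the library guide ids plus a report with assigned /
    unassigned / ambiguous totals.  Spacer sequences shared by several
    library entries route to a shared ambiguity bin rather than being split.
    """
    spacer_map: dict[str, str | None] = {}
    for g in library:
        if g.spacer in spacer_map:
            spacer_map[g.spacer] = None  # ambiguous
        else:
            spacer_map[g.spacer] = g.guide_id
    counts = {g.guide_id: 0 for g in library}
    report = {"total": 0, "assigned": 0, "unassigned": 0, "ambiguous": 0}
    if isinstance(reads, (str, Path)):
        reads = (seq for _, seq, _ in _iter_fastq(reads))
    for read in reads:
        report["total"] += 1
        spacer = locator.extract(read.upper())
        if spacer is None:
            report["unassigned"] += 1
            continue
        hit = spacer_map.get(spacer, "absent")
        if hit == "absent":
            report["unassigned"] += 1
        elif hit is None:
            report["ambiguous"] += 1
        else:
            counts[hit] += 1
            report["assigned"] += 1
    return pd.Series(counts, name="count"), report


# ---------------------------------------------------------------------------
# normalization and fold change
# ---------------------------------------------------------------------------


def normalize_counts(
    cm: CountMatrix, method: str = "median_ratio", min_common: int = 100
) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors plus the normalized matrix.

    ``median_ratio`` follows the DESeq construction: per-sample median of
    count / geometric-mean-reference over guides with nonzero counts in all
    samples, falling back to total-count scaling when fewer than
    ``min_common`` such guides exist.  ``total`` forces library-size scaling.
    """
    counts = cm.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    if method == "median_ratio":
        common = (counts > 0).all(axis=1)
        if common.sum() < min_common:
            logger.info(
                "median-ratio: only %d all-nonzero guides (< %d); "
                "falling back to total-count scaling",
                common.sum(), min_common,
            )
            method = "total"
        else:
            sub = counts.loc[common]
            log_ref = np.log(sub).mean(axis=1)
            factors = np.exp(np.log(sub).sub(log_ref, axis=0).median(axis=0))
    if method == "total":
        totals = counts.sum(axis=0)
        factors = totals / totals.mean()
    elif method != "median_ratio":
        raise ValueError(f"unknown normalization method {method!r}")
    factors.name = "size_factor"
    logger.info("size factors: %s", dict(factors.round(4)))
    return factors, counts.div(factors, axis=1)


def guide_log2fc(
    cm: CountMatrix,
    condition: str | None = None,
    pseudocount: float = 0.5,
    method: str = "median_ratio",
) -> pd.DataFrame:
    """Per-guide log2 fold change of each replicate versus the pDNA pool.

    Returns a frame indexed by guide_id with one ``lfc_<sample>`` column per
    replicate of ``condition`` (default: the first condition) plus their
    ``mean_lfc``.
    """
    if condition is None:
        condition = cm.condition_names()[0]
    reps = cm.replicates(condition)
    if not reps:
        raise ValueError(f"no replicate samples for condition {condition!r}")
    if pseudocount <= 0 and (cm.counts.to_numpy() == 0).any():
        raise ValueError("pseudocount must be > 0 when zero counts are present")
    _, norm = normalize_counts(cm, method=method)
    ref = norm[cm.pdna] + pseudocount
    out = pd.DataFrame(index=cm.counts.index)
    for s in reps:
        out[f"lfc_{s}"] = np.log2((norm[s] + pseudocount) / ref)
    out["mean_lfc"] = out[[f"lfc_{s}" for s in reps]].mean(axis=1)
    return out


def replicate_correlation(
    lfc: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation of per-replicate lfc vectors for every replicate pair.

    Zero-variance vectors yield a flagged undefined value (r = None) rather
    than propagating NaN.
    """
    cols = [c for c in lfc.columns if c.startswith("lfc_")]
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x, y = lfc[cols[i]].to_numpy(), lfc[cols[j]].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r, defined = None, False
            else:
                if method == "pearson":
                    r = float(sps.pearsonr(x, y).statistic)
                elif method == "spearman":
                    r = float(sps.spearmanr(x, y).statistic)
                else:
                    raise ValueError(f"unknown correlation method {method!r}")
                defined = True
            rows.append(
                {
                    "sample_a": cols[i].removeprefix("lfc_"),
                    "sample_b": cols[j].removeprefix("lfc_"),
                    "r": r,
                    "method": method,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "method", "defined"])


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def empirical_p(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Two-sided add-one-smoothed empirical p:
    p = (1 + #{|null| >= |obs|}) / (1 + n_null)."""
    null_abs = np.sort(np.abs(np.asarray(null)))
    obs_abs = np.abs(np.asarray(observed))
    n = null_abs.size
    ge = n - np.searchsorted(null_abs, obs_abs, side="left")
    return (1.0 + ge) / (1.0 + n)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals), method="fdr_bh")[1]


def guide_significance(
    lfc: pd.DataFrame, control_ids: list[str]
) -> pd.DataFrame:
    """Empirical p and BH FDR for every non-control guide's mean lfc against
    the non-targeting control lfc distribution."""
    controls = [c for c in control_ids if c in lfc.index]
    if not controls:
        raise ValueError("empty non-targeting null set")
    if len(controls) < 50:
        logger.warning(
            "only %d non-targeting controls; empirical p-values will be coarse",
            len(controls),
        )
    null = lfc.loc[controls, "mean_lfc"].to_numpy()
    targeting = lfc.index.difference(controls, sort=False)
    out = lfc.copy()
    out["empirical_p"] = np.nan
    out["fdr"] = np.nan
    pvals = empirical_p(lfc.loc[targeting, "mean_lfc"].to_numpy(), null)
    out.loc[targeting, "empirical_p"] = pvals
    out.loc[targeting, "fdr"] = bh_adjust(pvals)
    return out


def resolve_peak_attribution(library: list[GuideRecord], motif_hits=None) -> dict[str, str]:
    """guide_id -> single owning peak.

    When motif coordinates are available and a guide's motifs span several
    peaks, the peak whose motif lies closest to the cut site wins; ties go
    to the lexicographically lower peak id.  Otherwise the stored peak_id
    (5'-most motif's peak) is used.
    """
    motif_by_id = {m.motif_id: m for m in motif_hits} if motif_hits else {}
    attribution = {}
    for g in library:
        if g.category != "peak" or g.peak_id is None:
            continue
        if motif_by_id and g.cut_pos is not None and len(g.motif_ids) > 1:
            best = None
            for mid in g.motif_ids:
                m = motif_by_id.get(mid)
                if m is None:
                    continue
                center = (m.interval.start + m.interval.end) / 2
                key = (abs(g.cut_pos - center), m.peak_id)
                if best is None or key < best[0:2]:
                    best = (key[0], key[1])
            if best is not None:
                attribution[g.guide_id] = best[1]
                continue
        attribution[g.guide_id] = g.peak_id
    return attribution


def aggregate_peaks(
    lfc: pd.DataFrame,
    library: list[GuideRecord],
    control_ids: list[str],
    n_perm: int = 10_000,
    rng_seed: int = 0,
    genes: list[GeneAnnotation] | None = None,
    peaks: list[GenomicInterval] | None = None,
    motif_hits=None,
) -> pd.DataFrame:
    """Peak-level statistics: median member-guide lfc, permutation p against
    same-size draws from the control pool, BH FDR, and (optionally) distance
    from the peak midpoint to the nearest TSS.

    Reproducible under ``rng_seed``; p-values are two-sided add-one
    smoothed, so they lie in (0, 1].
    """
    controls = [c for c in control_ids if c in lfc.index]
    if not controls:
        raise ValueError("empty non-targeting null set")
    null_pool = lfc.loc[controls, "mean_lfc"].to_numpy()
    attribution = resolve_peak_attribution(library, motif_hits)
    members: dict[str, list[float]] = {}
    for gid, pid in attribution.items():
        if gid in lfc.index:
            members.setdefault(pid, []).append(float(lfc.loc[gid, "mean_lfc"]))
    dropped = [g.peak_id for g in library if g.category == "peak" and g.guide_id not in lfc.index]
    if dropped:
        logger.info("%d targeting guides absent from lfc table (filtered)", len(dropped))
    rng = np.random.default_rng(rng_seed)
    null_medians_by_size: dict[int, np.ndarray] = {}
    rows = []
    for pid in sorted(members):
        vals = members[pid]
        k = len(vals)
        if k not in null_medians_by_size:
            draws = rng.choice(null_pool, size=(n_perm, k), replace=True)
            null_medians_by_size[k] = np.median(draws, axis=1)
        med = float(np.median(vals))
        p = float(empirical_p(np.array([med]), null_medians_by_size[k])[0])
        rows.append({"peak_id": pid, "n_guides": k, "median_lfc": med, "empirical_p": p})
    out = pd.DataFrame(rows, columns=["peak_id", "n_guides", "median_lfc", "empirical_p"])
    if len(out):
        out["fdr"] = bh_adjust(out["empirical_p"].to_numpy())
    else:
        out["fdr"] = []
    if genes and peaks:
        dists = tss_distance_peaks(peaks, genes)
        out["tss_distance"] = [dists.get(pid) for pid in out["peak_id"]]
    return out.set_index("peak_id")


# ---------------------------------------------------------------------------
# TSS distances
# ---------------------------------------------------------------------------


def _tss_by_chrom(genes: list[GeneAnnotation]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g.tss_pos)
    return {c: np.sort(np.array(v)) for c, v in by_chrom.items()}


def tss_distance_guides(
    guides: list[GuideRecord], genes: list[GeneAnnotation]
) -> dict[str, int | None]:
    """Unsigned bp from each guide's cut position to the nearest TSS;
    None (flagged unavailable) on contigs without genes."""
    if not genes:
        raise ValueError("gene table is empty")
    tss_map = _tss_by_chrom(genes)
    out: dict[str, int | None] = {}
    for g in guides:
        if g.locus is None or g.cut_pos is None:
            out[g.guide_id] = None
            continue
        tss = tss_map.get(g.locus.chrom)
        if tss is None:
            out[g.guide_id] = None
            continue
        i = int(np.searchsorted(tss, g.cut_pos))
        cands = []
        if i < tss.size:
            cands.append(abs(int(tss[i]) - g.cut_pos))
        if i > 0:
            cands.append(abs(int(tss[i - 1]) - g.cut_pos))
        out[g.guide_id] = min(cands)
    return out


def tss_distance_peaks(
    peaks: list[GenomicInterval], genes: list[GeneAnnotation]
) -> dict[str, int | None]:
    """Unsigned bp from each peak midpoint to the nearest TSS."""
    if not genes:
        raise ValueError("gene table is empty")
    tss_map = _tss_by_chrom(genes)
    out: dict[str, int | None] = {}
    for p in peaks:
        tss = tss_map.get(p.chrom)
        if tss is None:
            out[p.id] = None
            continue
        mid = p.midpoint
        i = int(np.searchsorted(tss, mid))
        cands = []
        if i < tss.size:
            cands.append(abs(int(tss[i]) - mid))
        if i > 0:
            cands.append(abs(int(tss[i - 1]) - mid))
        out[p.id] = min(cands)
    return out


def classify_tss_proximity(distance_bp: int, threshold: int = 10_000) -> str:
    """Proximal/distal call at the conventional 10-kb boundary; exactly
    10,000 bp counts as proximal (<= threshold)."""
    return "proximal" if distance_bp <= threshold else "distal"
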