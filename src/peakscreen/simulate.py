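"""Synthetic genomes, libraries, and screen counts with known ground truth.

The generator emulates the study design the toolkit analyzes: a genome with
transcription-factor ChIP-Seq-like peaks, each seeded with one or more dyad
consensus motifs (CWWG[N]{2,12}CWWG with W drawn uniformly from {A,T} and
spacer length uniform on 2-12); a gene annotation with TSSs both proximal
(< 10 kb) and distal (> 100 kb) to peaks; and negative-binomial screen
counts for a designed library against a log-normal plasmid (pDNA) baseline,
with a subset of peaks planted as enriched or depleted.

Defaults are the screen conditions every recovery check in the test suite
uses: 200 peaks of which 10 are enriched at +1.5 and 10 depleted at -1.5
log2 units, 4 guides per peak, 3 replicates at a mean depth of 500 reads
per guide, negative-binomial dispersion 0.1, and per-guide efficiency
multipliers drawn from Beta(2, 1) to emulate the large guide-to-guide
variability seen when targeting regulatory elements.  All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .guides import GuideRecord, SPACER_LEN
from .io import GeneAnnotation, GenomeSequence, GenomicInterval
from .motifs import MotifPattern, compile_pattern
from .screen import CountMatrix


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 1_000_000
    n_contigs: int = 1
    gc_content: float = 0.41          # human-like background
    n_peaks: int = 200
    peak_width: int = 300
    motifs_per_peak_mean: float = 2.4  # law: 1 + Poisson(mean - 1)
    n_genes: int = 40
    fraction_coding: float = 0.8
    n_enriched_peaks: int = 10
    n_depleted_peaks: int = 10
    effect_lfc: float = 1.5
    guides_per_peak: int = 4
    n_nontargeting: int = 500
    n_replicates: int = 3
    mean_depth: float = 500.0
    nb_dispersion: float = 0.1
    pdna_log_sd: float = 0.5
    condition: str = "screen"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for name in (
            "genome_length", "n_contigs", "n_peaks", "peak_width", "n_genes",
            "n_enriched_peaks", "n_depleted_peaks", "guides_per_peak",
            "n_nontargeting", "n_replicates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.effect_lfc):
            raise ValueError("effect_lfc must be finite")


@dataclass
class GroundTruth:
    """What the generator planted: motif coordinates, per-peak true effects,
    and (after count simulation) per-guide efficiency multipliers."""

    planted_motifs: list[GenomicInterval] = field(default_factory=list)
    motif_peak: dict[str, str] = field(default_factory=dict)       # motif id -> peak id
    peak_effects: dict[str, float] = field(default_factory=dict)   # nonzero only if planted
    enriched_peaks: list[str] = field(default_factory=list)
    depleted_peaks: list[str] = field(default_factory=list)
    guide_efficiency: dict[str, float] = field(default_factory=dict)

    def true_lfc(self, guide: GuideRecord) -> float:
        if guide.category != "peak" or guide.peak_id is None:
            return 0.0
        return self.peak_effects.get(guide.peak_id, 0.0)

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"peak_id": list(self.peak_effects), "true_lfc": list(self.peak_effects.values())}
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator, region: tuple[int, int], width: int, n: int, max_tries: int = 10_000
) -> list[int]:
    lo, hi = region
    if hi - lo < width:
        raise ValueError(f"region of {hi - lo} bp cannot hold a {width} bp feature")
    placed: list[int] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} non-overlapping features of width {width} "
                f"in {hi - lo} bp (placed {len(placed)})"
            )
        tries += 1
        s = int(rng.integers(lo, hi - width + 1))
        if all(s + width <= q or q + width <= s for q in placed):
            placed.append(s)
    return sorted(placed)


def _plant_motif(
    rng: np.random.Generator, pattern: MotifPattern
) -> tuple[str, int]:
    """A concrete dyad instance: CWWG arms with W in {A,T}, random spacer."""

    def realize(arm: str) -> str:
        from .motifs import IUPAC

        return "".join(str(rng.choice(list(IUPAC[c]))) for c in arm)

    spacer_len = int(rng.integers(pattern.spacer_min, pattern.spacer_max + 1))
    spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
    return realize(pattern.left_arm) + spacer + realize(pattern.right_arm), spacer_len


def simulate_genome(
    config: SimulationConfig, pattern: MotifPattern | None = None
) -> tuple[GenomeSequence, list[GenomicInterval], list[GeneAnnotation], GroundTruth]:
    """Genome + peaks + genes + ground truth, deterministic under the seed.

    Peaks are confined to the left ~55% of each contig and distal genes are
    placed >= 100 kb to their right (when the contig is long enough), so
    proximal and distal TSS-distance strata both exist.
    """
    if pattern is None:
        pattern = compile_pattern()
    rng = np.random.default_rng(config.rng_seed)
    contig_len = config.genome_length // max(config.n_contigs, 1)
    contigs: dict[str, np.ndarray] = {}
    peaks: list[GenomicInterval] = []
    genes: list[GeneAnnotation] = []
    truth = GroundTruth()

    peaks_per_contig = [
        config.n_peaks // config.n_contigs
        + (1 if i < config.n_peaks % config.n_contigs else 0)
        for i in range(config.n_contigs)
    ]
    genes_per_contig = [
        config.n_genes // config.n_contigs
        + (1 if i < config.n_genes % config.n_contigs else 0)
        for i in range(config.n_contigs)
    ]

    peak_counter = gene_counter = 0
    for ci in range(config.n_contigs):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(rng, contig_len, config.gc_content)
        npk = peaks_per_contig[ci]
        peak_region = (0, max(int(contig_len * 0.35), config.peak_width + 1))
        starts = _place_nonoverlapping(rng, peak_region, config.peak_width, npk)
        contig_peaks = []
        for s in starts:
            peak_counter += 1
            pid = f"peak_{peak_counter}"
            peak = GenomicInterval(chrom, s, s + config.peak_width, ".", pid)
            contig_peaks.append(peak)
            n_motifs = 1 + int(rng.poisson(max(config.motifs_per_peak_mean - 1, 0)))
            # plant motifs at non-overlapping offsets inside the peak
            occupied: list[tuple[int, int]] = []
            for _ in range(n_motifs):
                inst, spacer_len = _plant_motif(rng, pattern)
                width = len(inst)
                for _try in range(200):
                    off = int(rng.integers(0, config.peak_width - width + 1))
                    if all(off + width <= a or b <= off for a, b in occupied):
                        occupied.append((off, off + width))
                        seq[s + off : s + off + width] = np.frombuffer(
                            inst.encode(), dtype="S1"
                        )
                        iv = GenomicInterval(chrom, s + off, s + off + width, "+")
                        truth.planted_motifs.append(iv)
                        truth.motif_peak[f"{pid}@{s + off}"] = pid
                        break
        peaks.extend(contig_peaks)

        ngn = genes_per_contig[ci]
        # proximal genes anchor only to peaks in the left part of the peak
        # region, keeping the right part as a gene-distal (>100 kb) stratum
        anchor_peaks = [
            p for p in contig_peaks if p.end <= int(contig_len * 0.15)
        ] or contig_peaks
        n_proximal = ngn // 2 if contig_peaks else 0
        peak_region_end = max((p.end for p in contig_peaks), default=0)
        distal_lo = peak_region_end + 100_000
        for gi in range(ngn):
            gene_counter += 1
            gid = f"gene_{gene_counter}"
            length = int(rng.integers(2_000, 15_000))
            if gi < n_proximal:
                anchor = anchor_peaks[int(rng.integers(0, len(anchor_peaks)))]
                d = int(rng.integers(500, 9_500))
                start = min(anchor.end + d, contig_len - length - 1)
                strand = "+"
            else:
                if distal_lo + length + 1 < contig_len:
                    start = int(rng.integers(distal_lo, contig_len - length))
                else:  # contig too short for a distal stratum
                    start = int(rng.integers(peak_region_end + 1, contig_len - length))
                strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + length, strand, gid)
            coding = gi < round(config.fraction_coding * ngn)
            genes.append(GeneAnnotation(gid, body, coding))
        contigs[chrom] = seq

    genome = GenomeSequence(
        {c: arr.tobytes().decode() for c, arr in contigs.items()}
    )
    _assign_effects(rng, truth, [p.id for p in peaks], config)
    return genome, peaks, genes, truth


def _assign_effects(rng, truth: GroundTruth, peak_ids: list[str], config: SimulationConfig):
    n_eff = config.n_enriched_peaks + config.n_depleted_peaks
    if n_eff > len(peak_ids):
        raise ValueError("more effect peaks requested than peaks exist")
    chosen = rng.choice(len(peak_ids), size=n_eff, replace=False)
    for j, idx in enumerate(chosen):
        pid = peak_ids[int(idx)]
        if j < config.n_enriched_peaks:
            truth.peak_effects[pid] = config.effect_lfc
            truth.enriched_peaks.append(pid)
        else:
            truth.peak_effects[pid] = -config.effect_lfc
            truth.depleted_peaks.append(pid)


def make_screen_library(
    config: SimulationConfig, rng_seed: int | None = None, peak_ids: list[str] | None = None
) -> tuple[list[GuideRecord], GroundTruth]:
    """A screen-ready synthetic library without a genome: ``guides_per_peak``
    random-spacer guides per peak plus non-targeting controls, with planted
    peak effects.  Used for statistics-only simulations."""
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    if peak_ids is None:
        peak_ids = [f"peak_{i + 1}" for i in range(config.n_peaks)]
    truth = GroundTruth()
    _assign_effects(rng, truth, peak_ids, config)
    seen: set[str] = set()

    def fresh_spacer() -> str:
        while True:
            sp = "".join(rng.choice(list("ACGT"), size=SPACER_LEN))
            if sp not in seen:
                seen.add(sp)
                return sp

    library: list[GuideRecord] = []
    for pid in peak_ids:
        for k in range(config.guides_per_peak):
            library.append(
                GuideRecord(
                    guide_id=f"{pid}.1-{k + 1}",
                    spacer=fresh_spacer(),
                    pam="AGG",
                    locus=None,
                    strand=".",
                    cut_pos=None,
                    category="peak",
                    peak_id=pid,
                    motif_ids=(f"{pid}.1",),
                )
            )
    for k in range(config.n_nontargeting):
        library.append(
            GuideRecord(
                guide_id=f"nontargeting-{k + 1}",
                spacer=fresh_spacer(),
                pam="NNN",
                locus=None,
                strand=".",
                cut_pos=None,
                category="nontargeting_control",
            )
        )
    return library, truth


def simulate_counts(
    library: list[GuideRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng_seed: int | None = None,
) -> CountMatrix:
    """Negative-binomial counts for a library under the planted effects.

    Per guide: pDNA abundance ~ LogNormal(0, pdna_log_sd^2) scaled to
    ``mean_depth``; the pDNA sample is that abundance with pure counting
    (Poisson) noise, since a plasmid pool carries no biological
    overdispersion; each screen replicate has mean pdna abundance x
    2^(true lfc x efficiency) and negative-binomial noise with the
    configured dispersion (variance mu + alpha mu^2; Poisson at alpha = 0).
    Efficiency ~ Beta(2, 1) for targeting guides, 1.0 for controls,
    recorded into ``truth.guide_efficiency``.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(
        config.rng_seed + 1 if rng_seed is None else rng_seed
    )
    n = len(library)
    baseline = rng.lognormal(mean=0.0, sigma=config.pdna_log_sd, size=n)
    baseline *= config.mean_depth / baseline.mean()
    eff = np.ones(n)
    lfc = np.zeros(n)
    for i, g in enumerate(library):
        t = truth.true_lfc(g)
        if g.category == "peak":
            eff[i] = rng.beta(2.0, 1.0)
        lfc[i] = t * eff[i]
        truth.guide_efficiency[g.guide_id] = float(eff[i])

    def draw_nb(mu: np.ndarray) -> np.ndarray:
        if config.nb_dispersion <= 0:
            return rng.poisson(mu)
        size = 1.0 / config.nb_dispersion
        return rng.negative_binomial(size, size / (size + mu))

    cols = {"pdna": rng.poisson(baseline)}
    cond_mu = baseline * np.exp2(lfc)
    for r in range(config.n_replicates):
        cols[f"{config.condition}_r{r + 1}"] = draw_nb(cond_mu)
    df = pd.DataFrame(cols, index=[g.guide_id for g in library]).astype(int)
    df.index.name = "guide_id"
    return CountMatrix.from_frame(df, pdna_column="pdna")


@dataclass(frozen=True)
class ReadLayout:
    """Read structure for simulated sequencing: an anchor sequence directly
    5' of the 20-nt spacer, padded to ``read_length`` with background."""

    anchor: str = "GGAAAGGACGAAACACCG"  # 3' end of the vector tracrRNA scaffold promoter side
    read_length: int = 50
    prefix: str = ""  # fixed bases before the anchor


def simulate_reads(
    counts: pd.Series,
    library: list[GuideRecord],
    layout: ReadLayout | None = None,
    rng_seed: int = 0,
    error_rate: float = 0.0,
    path=None,
):
    """Emit exactly ``counts[g]`` reads per guide with the spacer embedded at
    the layout position, optionally with per-base substitution errors.

    Writes FASTQ to ``path`` when given, else returns the list of read
    strings; either way returns a manifest with the true per-guide counts.
    """
    if layout is None:
        layout = ReadLayout()
    rng = np.random.default_rng(rng_seed)
    spacer_of = {g.guide_id: g.spacer for g in library}
    reads: list[tuple[str, str]] = []
    for gid, c in counts.items():
        spacer = spacer_of[gid]
        core = layout.prefix + layout.anchor + spacer
        pad = layout.read_length - len(core)
        for j in range(int(c)):
            tail = "".join(rng.choice(list("ACGT"), size=pad)) if pad > 0 else ""
            seq = (core + tail)[: layout.read_length]
            if error_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(arr.size) < error_rate
                if hit.any():
                    arr[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
                    seq = "".join(arr)
            reads.append((f"{gid}:{j}", seq))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    manifest = {"true_counts": counts.astype(int).to_dict(), "n_reads": len(reads)}
    if path is not None:
        with open(path, "wt") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        return manifest
    return [seq for _, seq in reads], manifest
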