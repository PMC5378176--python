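"""Truth-labelled synthetic data for the whole analysis pipeline.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* two mouse strains (B6 carrying the PRDM9 Dom2 allele, RJ2 carrying Cst)
  with allele-specific hotspot sites (class 1: planted binding motif, a DMC1
  peak and strain-specific H3K4me3), promoter-residing class 2A sites
  (H3K4me3 in both strains, no DMC1, mostly CpG-island-overlapping) and
  class 2B sites carrying neither mark, a configurable fraction of which
  contain a CTCF motif;
* a Prdm9-KO peak set containing only nonspecific background peaks (which
  also contaminate both strains' sets), and a Spo11-KO PRDM9 set containing
  the class 1 and class 2B sites but no class 2A sites;
* Poisson coverage tracks with a symmetric unimodal enrichment kernel under
  peaks plus a matched input track;
* a three-species substitution table (domesticus, castaneus, M. spretus
  outgroup) with single-event per-branch substitutions whose weak-to-strong
  rate is multiplied within +-h bp of class 1 centers on the lineage
  carrying the matching PRDM9 allele -- the planted GC-biased gene
  conversion signal, with planted GC* = m*u_WS / (m*u_WS + u_SW).

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, PeakSet
from .motifs import PWM, decode, encode

__all__ = [
    "PeakWidthLaw", "StrengthLaw", "CoverageConfig", "DivergenceConfig",
    "SimulationConfig", "SimulatedData", "default_motifs",
    "simulate_genome", "write_fasta", "load_fasta",
    "simulate_sites_and_peaks", "simulate_coverage", "simulate_divergence",
    "write_triples", "read_triples",
]

# built-in allele motifs: synthetic stand-ins with hotspot-motif-like
# width and information content (not the alleles' true consensus sequences)
DOM2_CONSENSUS = "CCTCCCTAGCCAC"
CST_CONSENSUS = "TGGAATCGTACTA"
CTCF_CONSENSUS = "CCGCGAGGTGGCAG"

STRAINS = ("B6", "RJ2")
# which focal lineage carries each strain's PRDM9 allele
STRAIN_LINEAGE = {"B6": "domesticus", "RJ2": "castaneus"}
STRAIN_ALLELE = {"B6": "Dom2", "RJ2": "Cst"}


def default_motifs() -> dict[str, PWM]:
    return {
        "Dom2": PWM.from_consensus(DOM2_CONSENSUS, name="Dom2"),
        "Cst": PWM.from_consensus(CST_CONSENSUS, name="Cst"),
        "CTCF": PWM.from_consensus(CTCF_CONSENSUS, name="CTCF"),
    }


@dataclass
class PeakWidthLaw:
    """Normal peak-width law (bp), truncated below at ``minimum``."""

    mean: float = 300.0
    sd: float = 60.0
    minimum: int = 120

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = rng.normal(self.mean, self.sd, size=n)
        return np.maximum(w, self.minimum).astype(int)


@dataclass
class StrengthLaw:
    """Log-normal peak-strength law (opaque ordinal units)."""

    mu: float = 1.0
    sigma: float = 0.5

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass
class CoverageConfig:
    """Poisson coverage model: background rate per bp, peak enrichment
    factor and a Gaussian kernel whose sd is a fraction of the peak width."""

    background_rate: float = 0.05
    enrichment: float = 20.0
    kernel_sd_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")


@dataclass
class DivergenceConfig:
    """Per-branch substitution model.

    ``u_ws`` / ``u_sw`` are background per-site probabilities of a weak->
    strong / strong->weak substitution on each focal branch;
    ``hotspot_multiplier`` scales ``u_ws`` within ``hotspot_halfwidth`` bp
    of class 1 centers on the lineage carrying the matching allele.
    ``u_conservative`` (off by default) adds W->W / S->S substitutions,
    which must never move GC*. ``outgroup_rate`` (off by default) adds
    outgroup-branch substitutions that break polarizability.
    """

    u_ws: float = 0.01
    u_sw: float = 0.01
    hotspot_multiplier: float = 3.0
    hotspot_halfwidth: int = 300
    u_conservative: float = 0.0
    outgroup_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_ws", "u_sw", "u_conservative", "outgroup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hotspot_multiplier < 1.0:
            raise ValueError("hotspot_multiplier must be >= 1")
        if self.hotspot_multiplier * self.u_ws + self.u_conservative > 1.0:
            raise ValueError("hotspot_multiplier * u_ws exceeds 1")

    @property
    def gc_star_hotspot(self) -> float:
        m = self.hotspot_multiplier
        total = m * self.u_ws + self.u_sw
        return m * self.u_ws / total if total > 0 else float("nan")

    @property
    def gc_star_background(self) -> float:
        total = self.u_ws + self.u_sw
        return self.u_ws / total if total > 0 else float("nan")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults are the study
    conditions the package's tests assume."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    background_gc: float = 0.42
    n_sites: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("B6", "1"): 50, ("B6", "2A"): 20, ("B6", "2B"): 30,
            ("RJ2", "1"): 50, ("RJ2", "2A"): 20, ("RJ2", "2B"): 30,
        }
    )
    n_common: int = 5
    n_nonspecific: int = 10
    n_background_promoters: int = 25
    n_background_cpg: int = 25
    n_genes: int = 15
    gene_width: int = 20_000
    promoter_width: int = 2_000
    cpg_width: int = 800
    cpg_frac_2a: float = 0.85
    ctcf_frac: dict[str, float] = field(
        default_factory=lambda: {"B6": 0.60, "RJ2": 0.11}
    )
    min_separation: int = 4_500
    edge_margin: int = 3_000
    peak_width: PeakWidthLaw = field(default_factory=PeakWidthLaw)
    strength: dict[str, StrengthLaw] = field(
        default_factory=lambda: {
            "1": StrengthLaw(2.0, 0.5),
            "2A": StrengthLaw(1.5, 0.5),
            "2B": StrengthLaw(1.0, 0.5),
        }
    )
    dmc1_width: int = 600
    h3k4me3_width: int = 1_000
    coverage: CoverageConfig = field(default_factory=CoverageConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    motifs: dict[str, PWM] = field(default_factory=default_motifs)

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic RNG stream keyed by (stream, seed)."""
        return np.random.default_rng([stream, self.seed])


@dataclass
class SimulatedData:
    """Bundle of generator outputs: genome, truth table, peak sets,
    annotations."""

    config: SimulationConfig
    genome: dict[str, np.ndarray]  # uint8 base codes per chromosome
    truth: pd.DataFrame
    peaksets: dict[str, PeakSet]
    annotations: AnnotationSet

    def class_centers(self, strain: str, class_label: str) -> list[tuple[str, int]]:
        sub = self.truth[
            (self.truth["strain"] == strain) & (self.truth["class"] == class_label)
        ]
        return list(zip(sub["chrom"], sub["center"]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> dict[str, np.ndarray]:
    """I.i.d. random genome with the configured GC fraction (uint8 codes)."""
    rng = config.rng(1)
    gc = config.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        chrom: rng.choice(4, size=size, p=p).astype(np.uint8)
        for chrom, size in config.chrom_sizes.items()
    }


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path,
                seed: int | None = None, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            desc = f" seed={seed}" if seed is not None else ""
            fh.write(f">{chrom}{desc}\n")
            seq = decode(np.asarray(genome[chrom], dtype=np.uint8))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Load a FASTA into uint8 code arrays (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: encode(str(fa[name][:])) for name in fa.keys()}


# ---------------------------------------------------------------------------
# site placement
# ---------------------------------------------------------------------------

class _Placer:
    """Rejection sampler for mutually separated positions on a genome."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.rng = rng
        self.chroms = list(config.chrom_sizes)
        self.sizes = np.array([config.chrom_sizes[c] for c in self.chroms], float)
        self.weights = self.sizes / self.sizes.sum()
        self.margin = config.edge_margin
        self.min_sep = config.min_separation
        self.taken: dict[str, list[int]] = {c: [] for c in self.chroms}

    def place(self, n: int, max_tries: int = 200_000) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        tries = 0
        while len(out) < n:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "insufficient genome space for requested site counts"
                )
            ci = self.rng.choice(len(self.chroms), p=self.weights)
            chrom = self.chroms[ci]
            size = int(self.sizes[ci])
            if size <= 2 * self.margin:
                continue
            pos = int(self.rng.integers(self.margin, size - self.margin))
            lst = self.taken[chrom]
            i = bisect.bisect_left(lst, pos)
            if i > 0 and pos - lst[i - 1] < self.min_sep:
                continue
            if i < len(lst) and lst[i] - pos < self.min_sep:
                continue
            lst.insert(i, pos)
            out.append((chrom, pos))
        return out


def _interval(chrom: str, center: int, width: int, name: str,
              score: float | None = None) -> GenomicInterval:
    half = width // 2
    return GenomicInterval(chrom, max(0, center - half), center - half + width,
                           name=name, score=score)


def _plant(genome: dict[str, np.ndarray], chrom: str, center: int, pwm: PWM) -> None:
    """Overwrite the genome with the PWM consensus centered on ``center``."""
    seq = encode(pwm.consensus)
    start = center - pwm.width // 2
    genome[chrom][start : start + pwm.width] = seq


def simulate_sites_and_peaks(
    config: SimulationConfig, genome: dict[str, np.ndarray]
) -> SimulatedData:
    """Plant truth-labelled sites and derive every peak set from them.

    Mutates ``genome`` in place (motif planting) and returns the bundle of
    peak sets: PRDM9 per strain/genotype, DMC1 and H3K4me3 per strain,
    H3K36me3, plus annotations and the truth table.
    """
    rng = config.rng(2)
    placer = _Placer(config, rng)

    truth_rows: list[dict] = []
    peaks: dict[str, list[GenomicInterval]] = {
        "PRDM9_B6": [], "PRDM9_RJ2": [], "PRDM9_Prdm9KO": [], "PRDM9_B6_Spo11KO": [],
        "DMC1_B6": [], "DMC1_RJ2": [],
        "H3K4me3_B6": [], "H3K4me3_RJ2": [], "H3K36me3_B6": [],
    }
    promoters: list[GenomicInterval] = []
    cpg_islands: list[GenomicInterval] = []
    ctcf_sites: list[GenomicInterval] = []
    tss: list[tuple[str, int, str]] = []
    div = config.divergence

    def prdm9_peak(chrom, center, label, cls, score=None):
        width = int(config.peak_width.sample(rng, 1)[0])
        if score is None:
            score = float(config.strength[cls].sample(rng, 1)[0])
        return _interval(chrom, center, width, label, score)

    site_id = 0
    for strain in STRAINS:
        other = "RJ2" if strain == "B6" else "B6"
        allele = STRAIN_ALLELE[strain]
        for cls in ("1", "2A", "2B"):
            n = config.n_sites.get((strain, cls), 0)
            for chrom, center in placer.place(n):
                site_id += 1
                name = f"{strain}_c{cls}_{site_id}"
                motif = ""
                if cls == "1":
                    _plant(genome, chrom, center, config.motifs[allele])
                    motif = allele
                    peaks[f"DMC1_{strain}"].append(
                        _interval(chrom, center, config.dmc1_width, name)
                    )
                    peaks[f"H3K4me3_{strain}"].append(
                        _interval(chrom, center, config.h3k4me3_width, name)
                    )
                    if strain == "B6":
                        peaks["H3K36me3_B6"].append(
                            _interval(chrom, center, config.h3k4me3_width, name)
                        )
                elif cls == "2A":
                    prom = _interval(chrom, center, config.promoter_width, name)
                    promoters.append(prom)
                    tss.append((chrom, center, "+"))
                    for s in STRAINS:
                        peaks[f"H3K4me3_{s}"].append(
                            _interval(chrom, center, config.h3k4me3_width, name)
                        )
                    if rng.random() < config.cpg_frac_2a:
                        cpg_islands.append(
                            _interval(chrom, center, config.cpg_width, name)
                        )
                else:  # 2B
                    if rng.random() < config.ctcf_frac.get(strain, 0.0):
                        _plant(genome, chrom, center, config.motifs["CTCF"])
                        motif = "CTCF"
                        ctcf_sites.append(
                            _interval(chrom, center, config.motifs["CTCF"].width, name)
                        )
                iv = prdm9_peak(chrom, center, name, cls)
                peaks[f"PRDM9_{strain}"].append(iv)
                if strain == "B6" and cls in ("1", "2B"):
                    # Spo11-KO retains DSB-independent binding only
                    peaks["PRDM9_B6_Spo11KO"].append(iv)
                truth_rows.append(
                    {
                        "chrom": chrom, "center": center, "strain": strain,
                        "class": cls, "motif": motif,
                        "gc_star":
                            div.gc_star_hotspot if cls == "1"
                            else div.gc_star_background,
                    }
                )

    # peaks shared between strains but absent from the Prdm9-KO set
    for chrom, center in placer.place(config.n_common):
        site_id += 1
        name = f"common_{site_id}"
        for strain in STRAINS:
            peaks[f"PRDM9_{strain}"].append(prdm9_peak(chrom, center, name, "2B"))

    # nonspecific background peaks: present in both strains and in the KO
    for chrom, center in placer.place(config.n_nonspecific):
        site_id += 1
        name = f"nonspecific_{site_id}"
        for key in ("PRDM9_B6", "PRDM9_RJ2", "PRDM9_Prdm9KO", "PRDM9_B6_Spo11KO"):
            peaks[key].append(prdm9_peak(chrom, center, name, "2B"))

    # background annotation features, away from planted sites
    for chrom, center in placer.place(config.n_background_promoters):
        site_id += 1
        name = f"bg_prom_{site_id}"
        promoters.append(_interval(chrom, center, config.promoter_width, name))
        tss.append((chrom, center, "+"))
        for s in STRAINS:
            peaks[f"H3K4me3_{s}"].append(
                _interval(chrom, center, config.h3k4me3_width, name)
            )
    for chrom, center in placer.place(config.n_background_cpg):
        site_id += 1
        cpg_islands.append(_interval(chrom, center, config.cpg_width, f"bg_cpg_{site_id}"))

    # genes: wide features needing extra clearance on both sides
    genes: list[GenomicInterval] = []
    gene_placer = _Placer(config, rng)
    gene_placer.taken = {c: sorted(v) for c, v in placer.taken.items()}
    gene_placer.min_sep = config.min_separation + config.gene_width // 2 + 500
    gene_placer.margin = config.edge_margin + config.gene_width // 2
    for chrom, center in gene_placer.place(config.n_genes):
        site_id += 1
        name = f"gene_{site_id}"
        g = _interval(chrom, center, config.gene_width, name)
        genes.append(g)
        peaks["H3K36me3_B6"].append(g)  # transcription-coupled mark on gene bodies

    ann = AnnotationSet(
        promoters=sorted(promoters, key=lambda iv: (iv.chrom, iv.start)),
        genes=sorted(genes, key=lambda iv: (iv.chrom, iv.start)),
        cpg_islands=sorted(cpg_islands, key=lambda iv: (iv.chrom, iv.start)),
        ctcf_motifs=sorted(ctcf_sites, key=lambda iv: (iv.chrom, iv.start)),
        tss=sorted(tss),
    )
    meta = {
        "PRDM9_B6": ("B6", "PRDM9", "WT"),
        "PRDM9_RJ2": ("RJ2", "PRDM9", "WT"),
        "PRDM9_Prdm9KO": ("B6", "PRDM9", "Prdm9KO"),
        "PRDM9_B6_Spo11KO": ("B6", "PRDM9", "Spo11KO"),
        "DMC1_B6": ("B6", "DMC1", "WT"),
        "DMC1_RJ2": ("RJ2", "DMC1", "WT"),
        "H3K4me3_B6": ("B6", "H3K4me3", "WT"),
        "H3K4me3_RJ2": ("RJ2", "H3K4me3", "WT"),
        "H3K36me3_B6": ("B6", "H3K36me3", "WT"),
    }
    peaksets = {
        key: PeakSet(label=key, strain=m[0], target=m[1], genotype=m[2],
                     intervals=ivs)
        for (key, ivs), m in ((kv, meta[kv[0]]) for kv in peaks.items())
    }
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "center", "strain", "class", "motif", "gc_star"]
    ).sort_values(["chrom", "center"], ignore_index=True)
    return SimulatedData(
        config=config, genome=genome, truth=truth,
        peaksets=peaksets, annotations=ann,
    )


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    peaks: PeakSet,
    config: SimulationConfig,
    seed_stream: int = 3,
):
    """Poisson ChIP + matched input coverage for one peak set.

    Rate is ``lambda0`` everywhere plus, under each peak,
    ``lambda0 * enrichment * exp(-d^2 / (2 sd^2))`` with ``sd`` a fraction
    of the peak width. Returns ``(chip_track, input_track)`` as
    :class:`~hotspotclass.coverage.CoverageTrack` objects whose library
    sizes are the realized total counts.
    """
    from .coverage import CoverageTrack

    cov = config.coverage
    rng = config.rng(seed_stream)
    lam: dict[str, np.ndarray] = {
        chrom: np.full(size, cov.background_rate)
        for chrom, size in config.chrom_sizes.items()
    }
    for iv in peaks:
        sd = max(1.0, cov.kernel_sd_fraction * iv.length)
        halfspan = int(4 * sd)
        c = iv.center
        lo = max(0, c - halfspan)
        hi = min(config.chrom_sizes[iv.chrom], c + halfspan + 1)
        d = np.arange(lo, hi) - c
        lam[iv.chrom][lo:hi] += (
            cov.background_rate * cov.enrichment * np.exp(-(d ** 2) / (2 * sd ** 2))
        )
    chip = {chrom: rng.poisson(l).astype(np.int64) for chrom, l in lam.items()}
    inp = {
        chrom: rng.poisson(cov.background_rate, size=size).astype(np.int64)
        for chrom, size in config.chrom_sizes.items()
    }
    chip_track = CoverageTrack(chip, library_size=int(sum(a.sum() for a in chip.values())))
    input_track = CoverageTrack(inp, library_size=int(sum(a.sum() for a in inp.values())))
    return chip_track, input_track


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

_WEAK = np.array([True, False, False, True])  # A, C, G, T


def _merge_regions(regions: Sequence[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=int)
    return merged


def simulate_divergence(
    genome: Mapping[str, np.ndarray],
    truth: pd.DataFrame,
    config: SimulationConfig,
    regions: Sequence[tuple[str, int, int]] | None = None,
    seed_stream: int = 4,
) -> pd.DataFrame:
    """Three-species per-site base table with planted gBGC at class 1 sites.

    The ancestral base at each position is the genome base. On each focal
    branch (domesticus, castaneus) a substitution occurs independently with
    probability ``u_ws`` (weak ancestral, toward a random strong base) or
    ``u_sw`` (strong ancestral, toward a random weak base); ``u_ws`` is
    multiplied by the hotspot multiplier within the halfwidth of class 1
    centers of the strain whose PRDM9 allele that lineage carries. The
    outgroup base stays ancestral unless ``outgroup_rate`` > 0.

    ``regions`` restricts the table to the given half-open spans (merged);
    by default the whole genome is tabulated. Base columns are uint8 codes.
    """
    div = config.divergence
    rng = config.rng(seed_stream)
    if regions is None:
        spans = {c: np.array([[0, len(a)]]) for c, a in genome.items()}
    else:
        spans = _merge_regions(regions)

    hot_centers: dict[str, dict[str, np.ndarray]] = {}
    for lineage in ("domesticus", "castaneus"):
        strain = {v: k for k, v in STRAIN_LINEAGE.items()}[lineage]
        sub = truth[(truth["strain"] == strain) & (truth["class"] == "1")]
        hot_centers[lineage] = {
            chrom: np.sort(grp["center"].to_numpy())
            for chrom, grp in sub.groupby("chrom")
        }

    frames = []
    for chrom, chrom_spans in spans.items():
        base = np.asarray(genome[chrom], dtype=np.uint8)
        pos = np.concatenate(
            [np.arange(s, min(e, base.size)) for s, e in chrom_spans]
        )
        anc = base[pos]
        weak = _WEAK[np.minimum(anc, 3)] & (anc < 4)
        strong = ~_WEAK[np.minimum(anc, 3)] & (anc < 4)
        cols = {"chrom": chrom, "pos": pos}
        lineage_bases = {}
        for lineage in ("domesticus", "castaneus"):
            mult = np.ones(pos.size)
            centers = hot_centers[lineage].get(chrom, np.empty(0))
            if centers.size:  # pos is sorted: window membership via bisection
                lo = np.searchsorted(pos, centers - div.hotspot_halfwidth, "left")
                hi = np.searchsorted(pos, centers + div.hotspot_halfwidth, "right")
                for l, h in zip(lo, hi):
                    mult[l:h] = div.hotspot_multiplier
            p_ws = np.where(weak, div.u_ws * mult, 0.0)
            p_sw = np.where(strong, div.u_sw, 0.0)
            u = rng.random(pos.size)
            derived = anc.copy()
            ws = u < p_ws
            sw = (~ws) & (u < p_ws + p_sw)
            # toward a uniformly chosen strong / weak base
            derived[ws] = rng.choice(np.array([1, 2], np.uint8), size=int(ws.sum()))
            derived[sw] = rng.choice(np.array([0, 3], np.uint8), size=int(sw.sum()))
            if div.u_conservative > 0:
                cons = (~ws) & (~sw) & (u < p_ws + p_sw + div.u_conservative) & (anc < 4)
                flip = {0: 3, 3: 0, 1: 2, 2: 1}  # A<->T, C<->G
                lut = np.array([3, 2, 1, 0, 4], np.uint8)
                derived[cons] = lut[anc[cons]]
            lineage_bases[lineage] = derived
        outg = anc.copy()
        if div.outgroup_rate > 0:
            u = rng.random(pos.size)
            mut = (u < div.outgroup_rate) & (anc < 4)
            shift = rng.integers(1, 4, size=int(mut.sum())).astype(np.uint8)
            outg[mut] = (anc[mut] + shift) % 4
        cols["base_lineage1"] = lineage_bases["domesticus"]
        cols["base_lineage2"] = lineage_bases["castaneus"]
        cols["base_outgroup"] = outg
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], ignore_index=True)


TRIPLE_COLUMNS = ["chrom", "pos", "base_lineage1", "base_lineage2", "base_outgroup"]


def write_triples(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write the triple-alignment table as tab-delimited text with the
    canonical header."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    out = df.copy()
    for col in TRIPLE_COLUMNS[2:]:
        vals = out[col].to_numpy()
        if vals.dtype != object and np.issubdtype(vals.dtype, np.integer):
            out[col] = [chr(lut[v]) for v in vals]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False, columns=TRIPLE_COLUMNS)


def read_triples(path: str | Path) -> pd.DataFrame:
    """Read a triple-alignment table back into coded form."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRIPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in TRIPLE_COLUMNS[2:]:
        df[col] = encode("".join(df[col].astype(str).str.upper()))
    return df
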