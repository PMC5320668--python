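"""Synthetic bisulfite/NOMe read generator with full ground truth.

The generator emulates the physical process the inference model inverts:
a reference window carries 1-3 epi-alleles, each with its own per-CpG
methylation state, per-GpC accessibility state (NOMe), and optional SNVs.
Fragments are drawn uniformly, assigned an allele by frequency and a
strand uniformly; bisulfite conversion is applied per strand with a
failed-conversion rate (1 - conversion_rate) and an inappropriate-
conversion rate beta, then per-base sequencing error at the Phred-derived
rate.  Reads are emitted forward-mapped, exactly as a bisulfite mapper
would present them, and every read carries a truth record.

All randomness flows through one seeded generator: identical config and
seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BASE_CODE,
    CODE_BASE,
    ConversionParams,
    ReadUnit,
    Segment,
    conversion_matrix,
    phred_to_epsilon,
)
from .reference import ReferenceWindow, classify_contexts

__all__ = [
    "EpiAlleleSpec",
    "SimConfig",
    "SimTruth",
    "make_reference",
    "simulate_reads",
    "asm_scenario",
    "nome_scenario",
    "empirical_conversion_rates",
]

_MEC = 4
_MEG = 5


@dataclass
class EpiAlleleSpec:
    """One epi-allele: methylation, accessibility, and sequence variants.

    ``methylation`` maps the C position of each reference CpG to its
    state; ``accessibility`` maps the C position of GpC sites (NOMe).
    ``snvs`` maps positions to substituted nucleotides.
    """

    allele_id: str
    frequency: float
    methylation: dict[int, bool] = field(default_factory=dict)
    accessibility: dict[int, bool] = field(default_factory=dict)
    snvs: dict[int, str] = field(default_factory=dict)

    @classmethod
    def uniform(
        cls,
        window: ReferenceWindow,
        allele_id: str,
        frequency: float,
        methylated: bool,
        accessible: bool | None = None,
        snvs: dict[int, str] | None = None,
    ) -> "EpiAlleleSpec":
        """An allele with one methylation state at every CpG (and GpC)."""
        ctx = classify_contexts(window)
        w0 = window.start
        meth = {int(p) + w0: methylated for p in np.flatnonzero(ctx.cpg_c)}
        acc = {}
        if accessible is not None:
            acc = {int(p) + w0: accessible for p in np.flatnonzero(ctx.gpc_c)}
        return cls(allele_id, frequency, meth, acc, dict(snvs or {}))


@dataclass
class SimConfig:
    """Simulation settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    length: int = 3000
    chrom: str = "sim"
    start: int = 0
    sequence: str | None = None  # explicit reference (passthrough)
    cpg_density: float | None = None  # expected CG dinucleotides per bp
    cpg_positions: list[int] | None = None  # explicit C positions (absolute)
    gpc_density: float | None = None
    gpc_positions: list[int] | None = None
    isolated_sites: bool = True  # plant sites with isolating flanks
    depth: float = 20.0
    read_length: int = 100
    layout: str = "paired"  # 'single' | 'paired'
    fragment_length: int | None = None  # paired span; default 2.5 * read_length
    conversion_rate: float = 0.95
    beta: float = 0.05
    phred: int = 30

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError("layout must be 'single' or 'paired'")
        if self.depth <= 0 or self.read_length <= 0 or self.length <= 0:
            raise ValueError("depth, read_length and length must be positive")
        for d in (self.cpg_density, self.gpc_density):
            if d is not None and not 0.0 <= d <= 0.5:
                raise ValueError("dinucleotide density must be in [0, 0.5]")

    @property
    def span(self) -> int:
        if self.layout == "single":
            return self.read_length
        return self.fragment_length or int(2.5 * self.read_length)


@dataclass
class SimTruth:
    window: ReferenceWindow
    alleles: dict[str, EpiAlleleSpec]
    read_truth: dict[str, tuple[str, str]]  # read id -> (allele id, strand)


def _plant(seq: np.ndarray, pos: int, dinuc: str, isolate: bool, rng) -> None:
    a, b = BASE_CODE[dinuc[0]], BASE_CODE[dinuc[1]]
    seq[pos], seq[pos + 1] = a, b
    if isolate:
        # flanks A/T are simultaneously H (not G) and D (not C)
        if pos - 1 >= 0:
            seq[pos - 1] = rng.choice([BASE_CODE["A"], BASE_CODE["T"]])
        if pos + 2 < len(seq):
            seq[pos + 2] = rng.choice([BASE_CODE["A"], BASE_CODE["T"]])


def make_reference(config: SimConfig, rng: np.random.Generator | None = None) -> ReferenceWindow:
    """Random reference window with controlled CpG (and GpC) placement.

    Accidental CG dinucleotides are scrubbed so the realized CpG set is
    exactly the planted one; planted sites optionally get A/T flanks so
    they are isolated (HCGD / DGCH).
    """
    if config.sequence is not None:
        return ReferenceWindow(config.chrom, config.start, config.sequence)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W = config.length
    seq = rng.integers(0, 4, size=W).astype(np.int8)
    # scrub accidental CGs by replacing the C (cannot create new CGs)
    for j in range(W - 1):
        if seq[j] == BASE_CODE["C"] and seq[j + 1] == BASE_CODE["G"]:
            seq[j] = rng.choice([BASE_CODE["A"], BASE_CODE["T"]])

    def chosen(density, positions):
        if positions is not None:
            return [p - config.start for p in positions]
        if density:
            # non-overlapping 3 bp slots so isolating flanks of one planted
            # site can never destroy a neighbouring one
            slots = np.arange(0, W - 3, 3)
            return list(slots[rng.random(len(slots)) < min(1.0, 3.0 * density)])
        return []

    cpg_sites = chosen(config.cpg_density, config.cpg_positions)
    gpc_sites = chosen(config.gpc_density, config.gpc_positions)
    for p in cpg_sites:
        _plant(seq, p, "CG", config.isolated_sites, rng)
    for p in gpc_sites:
        _plant(seq, p, "GC", config.isolated_sites, rng)
    # planting may have re-created stray CGs at flank boundaries; rescrub
    planted = set(cpg_sites)
    for j in range(W - 1):
        if j not in planted and seq[j] == BASE_CODE["C"] and seq[j + 1] == BASE_CODE["G"]:
            seq[j] = rng.choice([BASE_CODE["A"], BASE_CODE["T"]])
    return ReferenceWindow(config.chrom, config.start, "".join(CODE_BASE[c] for c in seq))


def _allele_epigenotypes(window: ReferenceWindow, allele: EpiAlleleSpec) -> np.ndarray:
    """Per-position epigenotype codes of one allele over the window."""
    g = window.codes.copy()
    w0 = window.start
    for pos, base in allele.snvs.items():
        g[pos - w0] = BASE_CODE[base]
    C, G = BASE_CODE["C"], BASE_CODE["G"]
    for pos, meth in allele.methylation.items():
        j = pos - w0
        if meth and 0 <= j < len(g) - 1 and g[j] == C and g[j + 1] == G:
            g[j], g[j + 1] = _MEC, _MEG
    for pos, acc in allele.accessibility.items():
        j = pos - w0  # C position of a GpC: the G sits at j-1
        if acc and 1 <= j < len(g) and g[j] == C and g[j - 1] == G:
            g[j] = _MEC
            g[j - 1] = _MEG
    return g


def simulate_reads(
    alleles: list[EpiAlleleSpec], config: SimConfig, window: ReferenceWindow | None = None
) -> tuple[list[ReadUnit], SimTruth]:
    """Draw fragments, convert, sequence, and emit forward-mapped reads."""
    freqs = np.array([a.frequency for a in alleles])
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    rng = np.random.default_rng(config.seed)
    if window is None:
        window = make_reference(config, rng)
    W = len(window)
    span = config.span
    if span > W:
        raise ValueError("fragment span exceeds window length")
    conv = conversion_matrix(ConversionParams(config.conversion_rate, config.beta))
    gmats = [_allele_epigenotypes(window, a) for a in alleles]
    eps = float(phred_to_epsilon(config.phred))

    n_bases = config.read_length * (1 if config.layout == "single" else 2)
    n_frags = max(1, round(config.depth * W / n_bases))
    reads: list[ReadUnit] = []
    truth: dict[str, tuple[str, str]] = {}
    for k in range(n_frags):
        ai = int(rng.choice(len(alleles), p=freqs))
        strand = int(rng.integers(0, 2))  # 0 fwd, 1 rev
        s = int(rng.integers(0, W - span + 1))
        g = gmats[ai][s : s + span]
        # conversion + PCR: sample Z per position from the conversion table
        probs = conv[:, g, strand]  # (4, span)
        u = rng.random(span)
        z = (u[:, None] < np.cumsum(probs, axis=0).T).argmax(axis=1).astype(np.int8)
        # sequencing error: uniform over the three other bases
        err = rng.random(span) < eps
        shift = rng.integers(1, 4, size=span).astype(np.int8)
        d = np.where(err, (z + shift) % 4, z).astype(np.int8)
        epsarr = np.full(span, eps)
        rid = f"frag{k:06d}"
        w0 = window.start
        if config.layout == "single":
            segs = [Segment(w0 + s, d, epsarr)]
        else:
            rl = config.read_length
            segs = [
                Segment(w0 + s, d[:rl].copy(), epsarr[:rl].copy()),
                Segment(w0 + s + span - rl, d[span - rl :].copy(), epsarr[span - rl :].copy()),
            ]
        reads.append(ReadUnit(id=rid, segments=segs, truth={"allele": alleles[ai].allele_id}))
        truth[rid] = (alleles[ai].allele_id, "fwd" if strand == 0 else "rev")
    return reads, SimTruth(window, {a.allele_id: a for a in alleles}, truth)


def asm_scenario(
    seed: int, n_epialleles: int = 2
) -> tuple[list[ReadUnit], SimTruth, SimConfig]:
    """Imprinted-DMR-like allele-specific-methylation benchmark.

    A 3 kb window carrying a central CpG island of 30 CpGs (28 bp apart,
    the dense clustering typical of imprinted differentially methylated
    regions), paired 100 bp reads on 250 bp fragments at depth 20,
    conversion success 0.95, inappropriate rate 0.05, Phred 30.  With two
    epi-alleles, one is fully methylated and one unmethylated (frequency
    1/2 each) and the unmethylated one carries a distinguishing SNV in the
    island; with one epi-allele the window is homogeneously methylated.
    """
    spacing, n_cpg, length = 28, 30, 3000
    start = (length - spacing * (n_cpg - 1)) // 2
    cps = [start + spacing * k for k in range(n_cpg)]
    cfg = SimConfig(
        seed=seed,
        length=length,
        cpg_positions=cps,
        depth=20.0,
        read_length=100,
        layout="paired",
        fragment_length=250,
        conversion_rate=0.95,
        beta=0.05,
        phred=30,
    )
    window = make_reference(cfg)
    if n_epialleles == 1:
        alleles = [EpiAlleleSpec.uniform(window, "meth", 1.0, methylated=True)]
    elif n_epialleles == 2:
        snv_pos = cps[n_cpg // 2] + spacing // 2  # inside the island, off-CpG
        ref = window.seq[snv_pos]
        alt = "T" if ref != "T" else "A"
        alleles = [
            EpiAlleleSpec.uniform(window, "meth", 0.5, methylated=True),
            EpiAlleleSpec.uniform(
                window, "unmeth", 0.5, methylated=False, snvs={snv_pos: alt}
            ),
        ]
    else:
        raise ValueError("asm_scenario supports 1 or 2 epi-alleles")
    reads, truth = simulate_reads(alleles, cfg, window)
    return reads, truth, cfg


def nome_scenario(
    seed: int, block_length: int = 147, depth: float = 30.0
) -> tuple[list[ReadUnit], SimTruth, SimConfig, tuple[int, int]]:
    """Nucleosome-footprint benchmark for NOMe mode.

    A 1.5 kb window with isolated GpC sites every ~15 bp; one epi-allele
    whose GpCs are enzymatically methylated (accessible) except inside a
    central protected block of ``block_length`` bp (a nucleosome or bound
    protein).  Returns the truth block interval alongside reads/config.
    """
    length, spacing = 1500, 15
    gps = list(range(30, length - 32, spacing))
    cfg = SimConfig(
        seed=seed,
        length=length,
        gpc_positions=gps,
        depth=depth,
        read_length=100,
        layout="paired",
        fragment_length=250,
        conversion_rate=0.95,
        beta=0.05,
        phred=30,
    )
    window = make_reference(cfg)
    ctx = classify_contexts(window)
    block = (length // 2 - block_length // 2, length // 2 + (block_length + 1) // 2)
    acc = {}
    for p in np.flatnonzero(ctx.gpc_c):
        p = int(p) + window.start
        acc[p] = not (block[0] <= p < block[1])
    allele = EpiAlleleSpec(
        "nuc", 1.0, methylation={}, accessibility=acc, snvs={}
    )
    reads, truth = simulate_reads([allele], cfg, window)
    return reads, truth, cfg, block


def empirical_conversion_rates(
    reads: list[ReadUnit], truth: SimTruth
) -> dict[str, float | int]:
    """Method-of-moments estimates of the conversion rates from truth.

    At unmethylated CpG cytosines, reads from the strand carrying the C
    show C only when conversion failed; at methylated ones they show T
    only under inappropriate conversion.  Requires (near) error-free
    sequencing.  Both strand orientations contribute (C positions on
    forward-strand reads, G positions on reverse-strand reads).
    """
    window = truth.window
    ctx = classify_contexts(window)
    w0 = window.start
    cpg_c = np.flatnonzero(ctx.cpg_c) + w0
    n_unmeth = c_unmeth = 0  # failed conversions at unmethylated sites
    n_meth = t_meth = 0  # inappropriate conversions at methylated sites
    for read in reads:
        allele_id, strand = truth.read_truth[read.id]
        allele = truth.alleles[allele_id]
        for cpos in cpg_c:
            cpos = int(cpos)
            if cpos in allele.snvs or (cpos + 1) in allele.snvs:
                continue
            # the informative position depends on the read's strand
            pos = cpos if strand == "fwd" else cpos + 1
            stay, conv_to = ("C", "T") if strand == "fwd" else ("G", "A")
            base = None
            for seg in read.segments:
                if seg.start <= pos < seg.end:
                    base = CODE_BASE[int(seg.bases[pos - seg.start])]
            if base is None:
                continue
            if allele.methylation.get(cpos, False):
                if base == stay:
                    n_meth += 1
                elif base == conv_to:
                    n_meth += 1
                    t_meth += 1
            else:
                if base == conv_to:
                    n_unmeth += 1
                elif base == stay:
                    n_unmeth += 1
                    c_unmeth += 1
    return {
        "alpha_fail": c_unmeth / n_unmeth if n_unmeth else float("nan"),
        "beta": t_meth / n_meth if n_meth else float("nan"),
        "n_unmethylated": n_unmeth,
        "n_methylated": n_meth,
    }
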