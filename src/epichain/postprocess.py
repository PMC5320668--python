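"""Post-inference processing: noise filtering, fit-ratios, position-wise calls,
and NOMe accessibility profiling.

The noise filter keeps a chain when ``a <= chain length + b * depth fraction``;
the depth fraction is the read-bp in the chain divided by the read-bp of all
chains whose ranges overlap it (including itself), so a lone chain has depth
fraction 1.  Filtering is post-inference only and never re-runs the fit.

Position-wise confidence is assessed with log fit-ratios: with
``l(x)`` the summed log emission of a chain's reads at a position under
epigenotype x,

    F   = 2 (max_{x not in {g, proj(g)}} l(x) - max_{x in {g, proj(g)}} l(x))
    F_R = the same with {y, y_me} for the reference nucleotide y
    F_A = the same for the alternative nucleotide, when one is known.

The combined genotype at a position is formed from the kept chains with
F <= -15 or |F_R - F_A| >= 15.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chains import FitResult, HaplotypeChain
from .model import BASE_CODE, CODE_BASE, EPIGENOTYPES, Epigenotype, PROJECTION_CODE

log = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "FitRatios",
    "depth_fraction",
    "filter_chains",
    "position_loglik",
    "fit_ratios",
    "combined_genotype",
    "methylation_level",
    "accessibility_profile",
    "chain_table",
    "read_table",
    "call_table",
]

_MEC = 4
_MEG = 5


@dataclass(frozen=True)
class FilterParams:
    """Noise-filter constants (bp scale)."""

    a: float = 10_000.0
    b: float = 28_500.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("filter constants must be non-negative")


def depth_fraction(
    chain: HaplotypeChain,
    all_chains: list[HaplotypeChain],
    res: FitResult | None = None,
) -> float:
    """Read-bp in the chain over read-bp of all chains overlapping its range.

    The denominator sums, over every chain whose range overlaps this
    chain's range (including itself), the read base pairs falling inside
    this chain's range; with ``res`` omitted, full read lengths of
    overlapping chains are used instead.  A lone chain has fraction 1.
    """
    denom = 0
    for c in all_chains:
        if not (c.start < chain.end and c.end > chain.start):
            continue
        if res is None:
            denom += c.total_read_bp
        else:
            for i in c.member_idx:
                for seg in res.reads[i].segments:
                    denom += max(0, min(seg.end, chain.end) - max(seg.start, chain.start))
    if denom == 0:
        raise ValueError("chain not present in all_chains")
    return chain.total_read_bp / denom


def filter_chains(
    chains: list[HaplotypeChain],
    params: FilterParams,
    res: FitResult | None = None,
) -> tuple[list[HaplotypeChain], list[HaplotypeChain]]:
    """Partition chains into (kept, removed) by the a/b noise rule."""
    kept, removed = [], []
    for c in chains:
        df = depth_fraction(c, chains, res)
        (kept if params.a <= c.length + params.b * df else removed).append(c)
    return kept, removed


def _strand_code(res: FitResult, read_id: str) -> int:
    return 0 if res.strands[read_id] == "fwd" else 1


def position_loglik(
    chain: HaplotypeChain,
    res: FitResult,
    pos: int,
    x: Epigenotype | int | None = None,
    allow_uncovered: bool = False,
):
    """l(x): summed log emission of the chain's reads at an absolute position.

    Returns the 6-vector over epigenotype states (canonical order), or a
    scalar when ``x`` is given.  Observed N bases contribute log 1 = 0.
    Raises when no read of the chain has a sequenced base at ``pos``
    unless ``allow_uncovered`` (mate insert gaps make this possible).
    """
    if not chain.start <= pos < chain.end:
        raise IndexError(f"position {pos} outside chain [{chain.start},{chain.end})")
    wm = res.wm
    out = np.zeros(6)
    covered = False
    for i in chain.member_idx:
        read = res.reads[i]
        r = _strand_code(res, read.id)
        for seg in read.segments:
            if seg.start <= pos < seg.end:
                covered = True
                z = int(seg.bases[pos - seg.start])
                if z < 4:
                    eps = float(seg.epsilons[pos - seg.start])
                    p = wm.conv[z, :, r]
                    out += np.log((1.0 - 4.0 * eps / 3.0) * p + eps / 3.0)
    if not covered and not allow_uncovered:
        raise ValueError(f"no read of chain {chain.id} covers position {pos}")
    if x is None:
        return out
    xi = x if isinstance(x, (int, np.integer)) else EPIGENOTYPES.index(x)
    return float(out[xi])


@dataclass(frozen=True)
class FitRatios:
    F: float
    F_R: float
    F_A: float  # NaN when no alternative allele is known
    y: str  # reference nucleotide
    alt: str | None = None

    @property
    def passes(self) -> bool:
        """The chain-inclusion rule for combined genotyping (threshold 15)."""
        return self.F <= -15.0 or (
            not math.isnan(self.F_A) and abs(self.F_R - self.F_A) >= 15.0
        )


def _ratio(loglik: np.ndarray, inside: set[int]) -> float:
    outside = [s for s in range(6) if s not in inside]
    return 2.0 * (max(loglik[s] for s in outside) - max(loglik[s] for s in inside))


def _genotype_set(code: int) -> set[int]:
    """{y, y_me} state indices for a plain nucleotide code."""
    s = {code}
    if code == BASE_CODE["C"]:
        s.add(_MEC)
    elif code == BASE_CODE["G"]:
        s.add(_MEG)
    return s


def fit_ratios(
    chain: HaplotypeChain,
    res: FitResult,
    pos: int,
    ref_base: str | None = None,
    alt_base: str | None = None,
) -> FitRatios:
    """Log fit-ratios F, F_R, F_A of a chain at an absolute position."""
    wm = res.wm
    if ref_base is None:
        ref_base = wm.window.seq[pos - wm.window.start]
    ll = position_loglik(chain, res, pos, allow_uncovered=True)
    g = chain.state_at(pos)
    F = _ratio(ll, {g, int(PROJECTION_CODE[g])})
    if ref_base in "ACGT":
        F_R = _ratio(ll, _genotype_set(BASE_CODE[ref_base]))
    else:
        F_R = math.nan
    F_A = (
        _ratio(ll, _genotype_set(BASE_CODE[alt_base]))
        if alt_base in ("A", "C", "G", "T")
        else math.nan
    )
    return FitRatios(F=F, F_R=F_R, F_A=F_A, y=ref_base, alt=alt_base)


def combined_genotype(
    pos: int,
    kept_chains: list[HaplotypeChain],
    res: FitResult,
    alt_base: str | None = None,
    threshold: float = 15.0,
) -> str | None:
    """Combined genotype across confident chains at a position, or None (no-call).

    A chain participates when F <= -threshold or |F_R - F_A| >= threshold.
    One distinct nucleotide projection -> homozygous (e.g. "AA"), two ->
    an unordered heterozygous pair (e.g. "CT"); more than two distinct
    alleles are reported with all alleles listed.
    """
    alleles = set()
    for c in kept_chains:
        if not c.start <= pos < c.end:
            continue
        fr = fit_ratios(c, res, pos, alt_base=alt_base)
        ok = fr.F <= -threshold or (
            not math.isnan(fr.F_A) and abs(fr.F_R - fr.F_A) >= threshold
        )
        if ok:
            alleles.add(CODE_BASE[int(PROJECTION_CODE[c.state_at(pos)])])
    if not alleles:
        return None
    if len(alleles) == 1:
        return 2 * alleles.pop()
    if len(alleles) > 2:
        log.info("ambiguous genotype at %d: %s", pos + 1, sorted(alleles))
    return "".join(sorted(alleles))


def _covering_reads(chain: HaplotypeChain, res: FitResult, pos: int) -> tuple[int, int]:
    """(#reads with a sequenced non-N base at pos, #with only N)."""
    n, n_only = 0, 0
    for i in chain.member_idx:
        seen = False
        informative = False
        for seg in res.reads[i].segments:
            if seg.start <= pos < seg.end:
                seen = True
                if int(seg.bases[pos - seg.start]) < 4:
                    informative = True
        if informative:
            n += 1
        elif seen:
            n_only += 1
    return n, n_only


def methylation_level(
    pos: int, res: FitResult, chains: list[HaplotypeChain] | None = None
) -> tuple[float | None, int]:
    """Fraction of covering reads whose chain is methylated at ``pos``.

    ``pos`` must be the C or G of a CpG (WGBS modes; in NOMe mode GpC
    positions are also accepted).  Returns (level, coverage); level is
    None (no-call) when no read has an informative base there.
    """
    wm = res.wm
    j = pos - wm.window.start
    ok = wm.ctx.cpg_c[j] or wm.ctx.cpg_g[j]
    if wm.config.nome:
        ok = ok or wm.ctx.gpc_c[j] or wm.ctx.gpc_g[j]
    if not ok:
        raise ValueError(f"position {pos} is not a CpG site")
    if chains is None:
        chains = res.chains
    cov = 0
    meth = 0
    for c in chains:
        if not c.start <= pos < c.end:
            continue
        n, _ = _covering_reads(c, res, pos)
        cov += n
        if c.state_at(pos) in (_MEC, _MEG):
            meth += n
    if cov == 0:
        return None, 0
    return meth / cov, cov


@dataclass(frozen=True)
class InaccessibleInterval:
    chain_id: int
    chrom: str
    start: int  # absolute, 0-based half-open
    end: int
    n_sites: int

    @property
    def span(self) -> int:
        return self.end - self.start


def accessibility_profile(
    chains: list[HaplotypeChain], res: FitResult
) -> tuple[pd.DataFrame, list[InaccessibleInterval]]:
    """Per-isolated-GpC accessibility and inaccessible intervals (NOMe mode).

    A chain is accessible at an isolated GpC when the site's epigenotype
    pair is methylated (the M.CviPI enzyme only reaches open chromatin).
    The site table reports two consensus variants: the fraction of
    covering chains that are accessible and the fraction of covering
    reads.  Inaccessible intervals are maximal runs of inaccessible
    isolated GpCs within one chain; their end points are the midpoints
    between the run and the flanking accessible sites (or the outermost
    run sites where no accessible flank exists).
    """
    wm = res.wm
    if not wm.config.nome:
        raise ValueError("accessibility profiling requires NOMe mode")
    w0 = wm.window.start
    site_pos = np.flatnonzero(wm.ctx.iso_gpc_c) + w0  # C positions, absolute
    rows = []
    intervals: list[InaccessibleInterval] = []
    per_site: dict[int, list[tuple[int, bool]]] = {int(p): [] for p in site_pos}

    for c in chains:
        sites = [int(p) for p in site_pos if c.start <= p < c.end]
        if not sites:
            continue
        acc = []
        for p in sites:
            a = c.state_at(p) == _MEC
            acc.append(a)
            n_reads, _ = _covering_reads(c, res, p)
            per_site[p].append((n_reads, a))
        # maximal runs of inaccessible sites
        k = 0
        while k < len(sites):
            if acc[k]:
                k += 1
                continue
            k2 = k
            while k2 + 1 < len(sites) and not acc[k2 + 1]:
                k2 += 1
            left = (sites[k - 1] + sites[k]) // 2 if k > 0 else sites[k]
            right = (sites[k2] + sites[k2 + 1] + 1) // 2 if k2 + 1 < len(sites) else sites[k2] + 1
            intervals.append(
                InaccessibleInterval(c.id, c.chrom, left, right, k2 - k + 1)
            )
            k = k2 + 1

    for p in sorted(per_site):
        obs = per_site[p]
        if not obs:
            continue
        n_chains = len(obs)
        n_reads = sum(n for n, _ in obs)
        rows.append(
            {
                "chrom": wm.window.chrom,
                "pos": p + 1,
                "chain_consensus": sum(a for _, a in obs) / n_chains,
                "read_consensus": (
                    sum(n for n, a in obs if a) / n_reads if n_reads else math.nan
                ),
                "n_chains": n_chains,
                "n_reads": n_reads,
            }
        )
    return pd.DataFrame(rows), intervals


# -- tabular summaries ----------------------------------------------------


def chain_table(res: FitResult, chains: list[HaplotypeChain] | None = None) -> pd.DataFrame:
    """Chain summary (1-based inclusive coordinates)."""
    if chains is None:
        chains = res.chains
    wm = res.wm
    rows = []
    for c in chains:
        cpg = np.flatnonzero(wm.ctx.cpg_c) + wm.window.start
        cpg = cpg[(cpg >= c.start) & (cpg < c.end)]
        mean_meth = (
            float(np.mean([c.state_at(int(p)) == _MEC for p in cpg])) if len(cpg) else math.nan
        )
        rows.append(
            {
                "chain": c.id,
                "chrom": c.chrom,
                "start": c.start + 1,
                "end": c.end,
                "n_reads": c.n_reads,
                "depth_fraction": depth_fraction(c, res.chains, res),
                "mean_methylation": mean_meth,
                "epigenotype": c.epigenotype_string,
            }
        )
    return pd.DataFrame(rows)


def read_table(res: FitResult) -> pd.DataFrame:
    rows = [
        {"read": rid, "chain": cid, "strand": res.strands[rid]}
        for rid, cid in sorted(res.assignment.items())
    ]
    return pd.DataFrame(rows)


def call_table(
    res: FitResult,
    chains: list[HaplotypeChain] | None = None,
    threshold: float = 15.0,
) -> pd.DataFrame:
    """Per-position calls over the union of the given chains.

    Methylation levels are reported at CpG positions (plus GpC positions
    in NOMe mode); the combined genotype and per-chain fit-ratios at
    every covered position.
    """
    if chains is None:
        chains = res.chains
    wm = res.wm
    w0 = wm.window.start
    alt_by_pos = {p: sorted(a)[0] for p, a in wm.variants.alt_alleles.items()} if wm.variants.use_db else {}
    positions = sorted({p for c in chains for p in range(c.start, c.end)})
    rows = []
    for pos in positions:
        j = pos - w0
        labels = ";".join(sorted(wm.ctx.labels(j)))
        is_meth_site = wm.ctx.cpg_c[j] or wm.ctx.cpg_g[j]
        if wm.config.nome:
            is_meth_site = is_meth_site or wm.ctx.gpc_c[j] or wm.ctx.gpc_g[j]
        level, cov = (
            methylation_level(pos, res, chains) if is_meth_site else (math.nan, 0)
        )
        alt = alt_by_pos.get(pos)
        geno = combined_genotype(pos, chains, res, alt_base=alt, threshold=threshold)
        details = []
        for c in chains:
            if not c.start <= pos < c.end:
                continue
            fr = fit_ratios(c, res, pos, alt_base=alt)
            sym = c.epigenotype_string[pos - c.start]
            details.append(
                f"{c.id}:{sym}:{fr.F:.2f}:{fr.F_R:.2f}:{fr.F_A:.2f}"
            )
        rows.append(
            {
                "chrom": wm.window.chrom,
                "pos": pos + 1,
                "ref": wm.window.seq[j],
                "context": labels,
                "methylation_level": level if level is not None else math.nan,
                "coverage": cov,
                "combined_genotype": geno if geno is not None else ".",
                "chains": ";".join(details),
            }
        )
    return pd.DataFrame(rows)
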