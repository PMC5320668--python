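"""Haplotype-chain inference by constrained maximum-posterior coordinate ascent.

A *haplotype chain* is a cluster of reads believed to originate from DNA
fragments sharing one epigenetic haplotype, together with a single
epigenotype sequence over its genomic range.  The unknowns are the
haplotype structure B (which chain each read belongs to), the strand
assignment R (which fragment strand each read came from), and the
epigenotype assignment G (one six-state sequence per chain).  They are
estimated by maximizing the posterior

    Lambda(B, G, R) = pi0(B) * pi1(G | B) * L(B, G, R)

where pi0 rewards chains containing many/long reads, pi1 weights each
chain position by q (nucleotide known from the reference or a variant
database) or 1-q (private mutation), and L is the product of per-base
emission probabilities of the bisulfite observation model.

Optimization starts from the all-singleton structure (always feasible)
and sweeps reads in genomic order, re-assigning one read unit (a mate
pair moves as a unit) at a time to the best strictly-improving feasible
destination; given B and R, the optimal G of a chain is computed exactly
by a constrained Viterbi pass.  The posterior is non-decreasing and the
algorithm terminates in finitely many steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import chain_viterbi, empty_block
from .config import FeasibilityParams, ModelConfig, PriorParams  # noqa: F401  (re-export)
from .model import ReadUnit, conversion_matrix
from .reference import (
    KnownVariantSet,
    ReferenceWindow,
    SiteContext,
    classify_contexts,
)

log = logging.getLogger(__name__)

__all__ = [
    "WindowModel",
    "HaplotypeChain",
    "FitResult",
    "fit",
    "brute_force_fit",
    "optimal_epigenotype_chain",
    "overlap_stats",
    "is_feasible_addition",
    "log_prior_B",
    "log_prior_G",
    "log_posterior",
]

_TOL = 1e-7  # strict-improvement threshold for accepting a move

#: symbols used in epigenotype strings (M = meC, W = meG)
G_SYMBOLS = "ACGTMW"


def _prefix(mask: np.ndarray) -> np.ndarray:
    return np.concatenate(([0], np.cumsum(mask, dtype=np.int64)))


class WindowModel:
    """Precomputed per-window quantities shared by all inference steps.

    Bundles the reference window, its CpG/GpC context classification, the
    genotype prior matrix, and the conversion model, all in
    window-relative coordinates.
    """

    def __init__(
        self,
        window: ReferenceWindow,
        config: ModelConfig,
        variants: KnownVariantSet | None = None,
    ) -> None:
        self.window = window
        self.config = config
        self.ctx = classify_contexts(window)
        if variants is None:
            variants = KnownVariantSet(window, {}, use_db=False)
        self.variants = variants
        self.prior6 = np.ascontiguousarray(variants.log_prior_matrix(config.q))
        W = len(window)
        if config.nome:
            self.enforce = np.ascontiguousarray(self.ctx.iso_site, dtype=np.uint8)
        else:
            self.enforce = np.ones(W, dtype=np.uint8)
        self.allow_gpc = config.nome
        self.conv = conversion_matrix(config.conversion)
        self.cum_cpg = _prefix(self.ctx.cpg_c)
        self.cum_iso_cpg = _prefix(self.ctx.iso_cpg_c)
        self.cum_iso_gpc = _prefix(self.ctx.iso_gpc_g)


@dataclass
class _PRead:
    """A read unit prepared for inference (window-relative)."""

    idx: int
    read: ReadUnit
    lo: int
    hi: int
    length: int  # sequenced bases
    segs: list[tuple[int, int]]
    blocks: tuple[np.ndarray, np.ndarray]  # per-strand (span, 6) log-emission


def _prepare_reads(reads: list[ReadUnit], wm: WindowModel) -> list[_PRead]:
    w0, w1 = wm.window.start, wm.window.end
    out = []
    for idx, read in enumerate(reads):
        if read.span_start < w0 or read.span_end > w1:
            raise ValueError(
                f"read {read.id} [{read.span_start},{read.span_end}) outside "
                f"window [{w0},{w1})"
            )
        lo, hi = read.span_start - w0, read.span_end - w0
        blocks = []
        for r in (0, 1):
            B = np.zeros((hi - lo, 6))
            for seg in read.segments:
                z = seg.bases
                eps = seg.epsilons
                known = z < 4
                p = wm.conv[z[known], :, r]  # (n, 6)
                e = eps[known][:, None]
                vals = np.log((1.0 - 4.0 * e / 3.0) * p + e / 3.0)
                rows = (np.arange(len(z))[known]) + (seg.start - w0 - lo)
                B[rows] += vals
            blocks.append(B)
        segs = [(s.start - w0, s.end - w0) for s in read.segments]
        out.append(_PRead(idx, read, lo, hi, read.length, segs, tuple(blocks)))
    return out


def overlap_stats(chain, read: ReadUnit, ctx: SiteContext) -> tuple[int, int, int, int]:
    """(bp overlap, #CpG, #isolated CpG, #isolated GpC) between a chain and a read.

    ``chain`` is anything with absolute ``start``/``end`` attributes or an
    (start, end) tuple.  The read's footprint is the union of its mates'
    aligned (sequenced) intervals.  A CpG counts once per dinucleotide
    whose C position lies in the overlap; a GpC is counted at its G
    position.
    """
    if hasattr(chain, "start"):
        c_lo, c_hi = chain.start, chain.end
    else:
        c_lo, c_hi = chain
    w0 = ctx.window.start
    cum = (_prefix(ctx.cpg_c), _prefix(ctx.iso_cpg_c), _prefix(ctx.iso_gpc_g))
    bp, n1, n2, n3 = 0, 0, 0, 0
    for seg in read.segments:
        a, b = max(seg.start, c_lo) - w0, min(seg.end, c_hi) - w0
        if b > a:
            bp += b - a
            n1 += int(cum[0][b] - cum[0][a])
            n2 += int(cum[1][b] - cum[1][a])
            n3 += int(cum[2][b] - cum[2][a])
    return bp, n1, n2, n3


def is_feasible_addition(
    chain, read: ReadUnit, K: FeasibilityParams, ctx: SiteContext
) -> bool:
    """Whether adding ``read`` to ``chain`` satisfies the K0-K3 thresholds."""
    bp, n1, n2, n3 = overlap_stats(chain, read, ctx)
    return bp >= K.K0 and n1 >= K.K1 and n2 >= K.K2 and n3 >= K.K3


@dataclass
class HaplotypeChain:
    """A fitted haplotype chain with its epigenotype sequence."""

    id: int
    chrom: str
    start: int  # absolute, 0-based half-open
    end: int
    member_ids: list[str]
    member_idx: list[int]
    g: np.ndarray  # logical state codes over [start, end)
    score: float  # Viterbi score (log-likelihood + log genotype prior)
    total_read_bp: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_reads(self) -> int:
        return len(self.member_idx)

    @property
    def epigenotype_string(self) -> str:
        return "".join(G_SYMBOLS[c] for c in self.g)

    def state_at(self, pos: int) -> int:
        """Logical state code at absolute position ``pos``."""
        if not self.start <= pos < self.end:
            raise IndexError(f"position {pos} outside chain [{self.start},{self.end})")
        return int(self.g[pos - self.start])


@dataclass
class FitResult:
    chains: list[HaplotypeChain]
    reads: list[ReadUnit]
    assignment: dict[str, int]  # read id -> chain id
    strands: dict[str, str]  # read id -> 'fwd' / 'rev'
    log_lambda: float
    trajectory: list[float]  # posterior after initialization and each accepted move
    n_passes: int
    converged: bool
    wm: WindowModel


class _ChainState:
    """Mutable working representation of one chain during optimization."""

    __slots__ = ("members", "lo", "hi", "M", "score", "total_len")

    def __init__(self, members, lo, hi, M, score, total_len):
        self.members = members
        self.lo = lo
        self.hi = hi
        self.M = M
        self.score = score
        self.total_len = total_len


class _Engine:
    def __init__(self, reads: list[ReadUnit], wm: WindowModel):
        self.wm = wm
        self.cfg = wm.config
        self.K = self.cfg.feasibility
        order = sorted(range(len(reads)), key=lambda i: (reads[i].span_start, reads[i].id))
        self.reads = [reads[i] for i in order]
        self.pr = _prepare_reads(self.reads, wm)
        self.n = len(self.reads)
        self.strands = np.zeros(self.n, dtype=np.int8)
        self.chains: dict[int, _ChainState] = {}
        self.assign = np.full(self.n, -1, dtype=np.int64)
        self._next_id = 0
        self._feas_memo: dict[frozenset, bool] = {}
        self._dummy_path = np.zeros(1, dtype=np.int8)

    # -- scoring ---------------------------------------------------------

    def _viterbi(self, M, mc, B, bo, lo, hi, path=None):
        want = path is not None
        return chain_viterbi(
            self.wm.prior6,
            M,
            mc,
            B,
            bo,
            lo,
            hi,
            self.wm.enforce,
            self.wm.allow_gpc,
            path if want else self._dummy_path,
            want,
        )

    def _build_M(self, members, strands) -> tuple[int, int, np.ndarray]:
        lo = min(self.pr[i].lo for i in members)
        hi = max(self.pr[i].hi for i in members)
        M = np.zeros((hi - lo, 6))
        for i in members:
            p = self.pr[i]
            M[p.lo - lo : p.hi - lo] += p.blocks[strands[i]]
        return lo, hi, M

    def _make_state(self, members, strands) -> _ChainState:
        lo, hi, M = self._build_M(members, strands)
        score = self._viterbi(M, lo, empty_block(), 0, lo, hi)
        tot = sum(self.pr[i].length for i in members)
        return _ChainState(list(members), lo, hi, M, score, tot)

    def _score_add(self, cs: _ChainState, i: int, strand: int) -> float:
        p = self.pr[i]
        lo, hi = min(cs.lo, p.lo), max(cs.hi, p.hi)
        return self._viterbi(cs.M, cs.lo, p.blocks[strand], p.lo, lo, hi)

    def _score_single(self, i: int, strand: int) -> float:
        p = self.pr[i]
        return self._viterbi(empty_block(), 0, p.blocks[strand], p.lo, p.lo, p.hi)

    def _pi0(self, n_reads: int, L: int, total_len: int) -> float:
        # each read contributes its chain's factor sqrt(L) * (sum read len)^2
        return n_reads * (0.5 * math.log(L) + 2.0 * math.log(total_len))

    def _pi0_state(self, cs: _ChainState) -> float:
        return self._pi0(len(cs.members), cs.hi - cs.lo, cs.total_len)

    def _contrib(self, cs: _ChainState) -> float:
        return cs.score + self._pi0_state(cs)

    def total(self) -> float:
        return sum(self._contrib(c) for c in self.chains.values())

    # -- feasibility -----------------------------------------------------

    def _span(self, members) -> tuple[int, int]:
        return (
            min(self.pr[i].lo for i in members),
            max(self.pr[i].hi for i in members),
        )

    def _feasible_addition(self, lo: int, hi: int, i: int) -> bool:
        p = self.pr[i]
        if p.lo > hi or p.hi < lo:  # would leave a coverage gap
            return False
        wm = self.wm
        bp, n1, n2, n3 = 0, 0, 0, 0
        for a, b in p.segs:
            oa, ob = max(a, lo), min(b, hi)
            if ob > oa:
                bp += ob - oa
                n1 += int(wm.cum_cpg[ob] - wm.cum_cpg[oa])
                n2 += int(wm.cum_iso_cpg[ob] - wm.cum_iso_cpg[oa])
                n3 += int(wm.cum_iso_gpc[ob] - wm.cum_iso_gpc[oa])
        K = self.K
        return bp >= K.K0 and n1 >= K.K1 and n2 >= K.K2 and n3 >= K.K3

    def _split(self, members) -> list[list[int]]:
        """Maximal gap-free segments of a member set (by unit spans)."""
        ms = sorted(members, key=lambda i: (self.pr[i].lo, self.pr[i].hi))
        segs: list[list[int]] = []
        cur: list[int] = []
        cur_end = -1
        for i in ms:
            if cur and self.pr[i].lo > cur_end:
                segs.append(cur)
                cur = []
            cur.append(i)
            cur_end = max(cur_end, self.pr[i].hi)
        if cur:
            segs.append(cur)
        return segs

    def _block_feasible(self, fs: frozenset, exact_limit: int = 10) -> bool:
        """Whether a read set admits a build order of feasible additions."""
        if len(fs) <= 1:
            return True
        if len(fs) > exact_limit:
            return True  # assumed; exact check is exponential
        hit = self._feas_memo.get(fs)
        if hit is not None:
            return hit
        ok = False
        for i in fs:
            rest = fs - {i}
            if len(self._split(rest)) != 1:
                continue
            lo, hi = self._span(rest)
            if self._feasible_addition(lo, hi, i) and self._block_feasible(
                rest, exact_limit
            ):
                ok = True
                break
        self._feas_memo[fs] = ok
        return ok

    # -- optimization ----------------------------------------------------

    def _add_chain(self, cs: _ChainState) -> int:
        cid = self._next_id
        self._next_id += 1
        self.chains[cid] = cs
        for i in cs.members:
            self.assign[i] = cid
        return cid

    def initialize(self) -> None:
        for i in range(self.n):
            s0 = self._score_single(i, 0)
            s1 = self._score_single(i, 1)
            self.strands[i] = 0 if s0 >= s1 else 1
            p = self.pr[i]
            cs = _ChainState(
                [i], p.lo, p.hi, p.blocks[self.strands[i]].copy(), max(s0, s1), p.length
            )
            self._add_chain(cs)

    def _try_move(self, i: int) -> float:
        """Evaluate all destinations for read i; apply the best improving move.

        Returns the accepted improvement (0.0 if the read stays put).
        """
        cid = int(self.assign[i])
        c = self.chains[cid]
        cur = self._contrib(c)
        p = self.pr[i]

        if len(c.members) == 1:
            seg_states: list[_ChainState] = []
            rem = 0.0
        else:
            rest = [j for j in c.members if j != i]
            seg_members = self._split(rest)
            for sm in seg_members:
                if not self._block_feasible(frozenset(sm)):
                    return 0.0  # detaching would strand an infeasible segment
            seg_states = [self._make_state(sm, self.strands) for sm in seg_members]
            rem = sum(self._contrib(s) for s in seg_states)

        best_delta = _TOL
        best = None  # (kind, payload, strand)

        # become (or stay) a singleton, either strand
        for r in (0, 1):
            if len(c.members) == 1 and r == self.strands[i]:
                continue  # identical to the current configuration
            sc = self._score_single(i, r)
            delta = rem + sc + self._pi0(1, p.hi - p.lo, p.length) - cur
            if delta > best_delta:
                best_delta, best = delta, ("single", None, r)

        # join another existing chain
        for cid2, c2 in self.chains.items():
            if cid2 == cid or c2.lo >= p.hi or c2.hi <= p.lo:
                continue
            if not self._feasible_addition(c2.lo, c2.hi, i):
                continue
            pi0_new = self._pi0(
                len(c2.members) + 1,
                max(c2.hi, p.hi) - min(c2.lo, p.lo),
                c2.total_len + p.length,
            )
            for r in (0, 1):
                sc = self._score_add(c2, i, r)
                delta = rem + sc + pi0_new - cur - self._contrib(c2)
                if delta > best_delta:
                    best_delta, best = delta, ("chain", cid2, r)

        # re-attach to a remainder segment (covers in-chain strand flips)
        for k, s in enumerate(seg_states):
            if not self._feasible_addition(s.lo, s.hi, i):
                continue
            pi0_new = self._pi0(
                len(s.members) + 1,
                max(s.hi, p.hi) - min(s.lo, p.lo),
                s.total_len + p.length,
            )
            for r in (0, 1):
                sc = self._score_add(s, i, r)
                delta = rem - self._contrib(s) + sc + pi0_new - cur
                if delta > best_delta:
                    best_delta, best = delta, ("seg", k, r)

        if best is None:
            return 0.0

        kind, payload, r = best
        del self.chains[cid]
        self.strands[i] = r
        if kind == "seg":
            for k, sm in enumerate(seg_states):
                if k == payload:
                    self._add_chain(self._make_state(sm.members + [i], self.strands))
                else:
                    self._add_chain(sm)
        else:
            for sm in seg_states:
                self._add_chain(sm)
            if kind == "single":
                pblk = self.pr[i]
                cs = _ChainState(
                    [i],
                    pblk.lo,
                    pblk.hi,
                    pblk.blocks[r].copy(),
                    self._score_single(i, r),
                    pblk.length,
                )
                self._add_chain(cs)
            else:  # join existing chain
                c2 = self.chains.pop(payload)
                self._add_chain(self._make_state(c2.members + [i], self.strands))
        return best_delta

    def _members_feasible(self, members: list[int]) -> bool:
        """Whether a read set can be built by feasible single-read additions.

        Exact (order-exhaustive) for small sets; larger sets use a greedy
        left-to-right build order, which is sufficient but not exhaustive.
        """
        if len(members) <= 10:
            return self._block_feasible(frozenset(members))
        ms = sorted(members, key=lambda i: (self.pr[i].lo, self.pr[i].hi))
        lo, hi = self.pr[ms[0]].lo, self.pr[ms[0]].hi
        remaining = ms[1:]
        while remaining:
            for k, i in enumerate(remaining):
                if self._feasible_addition(lo, hi, i):
                    lo = min(lo, self.pr[i].lo)
                    hi = max(hi, self.pr[i].hi)
                    del remaining[k]
                    break
            else:
                return False
        return True

    def _merge_feasible(self, a: _ChainState, b: _ChainState) -> bool:
        """Whether two chains may be fused into one feasible chain."""
        if min(a.hi, b.hi) < max(a.lo, b.lo):  # ranges must touch (no gap)
            return False
        return self._members_feasible(a.members + b.members)

    def _merge_sweep(self, trajectory: list[float]) -> bool:
        """Fuse overlapping chain pairs while the posterior improves."""
        any_accept = False
        improved = True
        while improved:
            improved = False
            ids = sorted(self.chains, key=lambda cid: self.chains[cid].lo)
            for ka in range(len(ids)):
                ca = self.chains.get(ids[ka])
                if ca is None:
                    continue
                for kb in range(ka + 1, len(ids)):
                    cb = self.chains.get(ids[kb])
                    if cb is None:
                        continue
                    if cb.lo > ca.hi:
                        break  # later chains start even further right
                    if not self._merge_feasible(ca, cb):
                        continue
                    merged = self._make_state(ca.members + cb.members, self.strands)
                    delta = (
                        self._contrib(merged) - self._contrib(ca) - self._contrib(cb)
                    )
                    if delta > _TOL:
                        del self.chains[ids[ka]]
                        del self.chains[ids[kb]]
                        self._add_chain(merged)
                        trajectory.append(trajectory[-1] + delta)
                        any_accept = True
                        improved = True
                        break
                if improved:
                    break
            if improved:
                continue
            # escape noise-overfit states: propose fusing whole overlap
            # clusters at once (pairwise steps can be individually downhill
            # even when the full fusion increases the posterior)
            for cid in list(self.chains):
                ca = self.chains.get(cid)
                if ca is None:
                    continue
                group = [
                    c2id
                    for c2id, c2 in self.chains.items()
                    if c2id != cid and c2.lo < ca.hi and c2.hi > ca.lo
                ]
                if len(group) < 2:
                    continue
                members = list(ca.members)
                cur = self._contrib(ca)
                for c2id in group:
                    c2 = self.chains[c2id]
                    members += c2.members
                    cur += self._contrib(c2)
                if not self._members_feasible(members):
                    continue
                merged = self._make_state(members, self.strands)
                delta = self._contrib(merged) - cur
                if delta > _TOL:
                    del self.chains[cid]
                    for c2id in group:
                        del self.chains[c2id]
                    self._add_chain(merged)
                    trajectory.append(trajectory[-1] + delta)
                    any_accept = True
                    improved = True
                    break
        return any_accept

    def _switch_cuts(self, cs: _ChainState) -> list[int]:
        """Candidate cut positions: midpoints between consecutive methylation
        sites whose inferred state differs (chimera boundaries)."""
        path = np.zeros(cs.hi - cs.lo, dtype=np.int8)
        self._viterbi(cs.M, cs.lo, empty_block(), 0, cs.lo, cs.hi, path)
        mask = self.wm.ctx.cpg_c.copy()
        if self.wm.config.nome:
            mask |= self.wm.ctx.iso_gpc_c
        sites = [j for j in np.flatnonzero(mask) if cs.lo <= j < cs.hi]
        cuts = []
        for a, b in zip(sites, sites[1:]):
            if (path[a - cs.lo] == 4) != (path[b - cs.lo] == 4):
                cuts.append((a + b) // 2)
        return cuts

    def _resolve_sweep(self, trajectory: list[float]) -> bool:
        """Split chimeric chains at state switchpoints and re-home the halves.

        A chain that absorbed reads of two different epi-alleles on its two
        sides is locally stable under single-read moves; cutting it and
        merging each half into a matching overlapping chain can raise the
        posterior in one step.  The move is accepted only on exact
        improvement of the full posterior.
        """
        any_accept = False
        for cid in list(self.chains):
            cs = self.chains.get(cid)
            if cs is None or len(cs.members) < 6:
                continue
            for cut in self._switch_cuts(cs):
                left = [i for i in cs.members if self.pr[i].lo + self.pr[i].hi < 2 * cut]
                right = [i for i in cs.members if i not in left]
                if not left or not right:
                    continue
                if len(self._split(left)) != 1 or len(self._split(right)) != 1:
                    continue
                if not (self._members_feasible(left) and self._members_feasible(right)):
                    continue
                halves = [self._make_state(left, self.strands),
                          self._make_state(right, self.strands)]
                base = self._contrib(cs)
                # best destination per half: stand alone or fuse with an
                # overlapping chain (distinct targets for the two halves)
                options = []
                for h in halves:
                    opts = [(self._contrib(h), None)]
                    for tid, t in self.chains.items():
                        if tid == cid or t.lo >= h.hi or t.hi <= h.lo:
                            continue
                        if not self._merge_feasible(t, h):
                            continue
                        fused = self._make_state(t.members + h.members, self.strands)
                        opts.append((self._contrib(fused) - self._contrib(t), tid))
                    options.append(sorted(opts, reverse=True, key=lambda x: x[0]))
                best = None
                for dl, tl in options[0][:3]:
                    for dr, tr in options[1][:3]:
                        if tl is not None and tl == tr:
                            continue
                        delta = dl + dr - base
                        if best is None or delta > best[0]:
                            best = (delta, tl, tr)
                if best is None or best[0] <= _TOL:
                    continue
                delta, tl, tr = best
                del self.chains[cid]
                for h, t in zip(halves, (tl, tr)):
                    if t is None:
                        self._add_chain(h)
                    else:
                        tgt = self.chains.pop(t)
                        self._add_chain(
                            self._make_state(tgt.members + h.members, self.strands)
                        )
                trajectory.append(trajectory[-1] + delta)
                any_accept = True
                break  # chain ids changed; re-enter via the next sweep
        return any_accept

    def run(self, pass_limit: int) -> tuple[list[float], int, bool]:
        self.initialize()
        total = self.total()
        trajectory = [total]
        converged = False
        n_passes = 0
        for _ in range(pass_limit):
            n_passes += 1
            any_accept = False
            for i in range(self.n):  # reads are stored in genomic order
                delta = self._try_move(i)
                if delta > 0.0:
                    total = trajectory[-1] + delta
                    trajectory.append(total)
                    any_accept = True
            any_accept |= self._merge_sweep(trajectory)
            any_accept |= self._resolve_sweep(trajectory)
            if not any_accept:
                converged = True
                break
        if not converged:
            log.warning("pass limit %d reached before convergence", pass_limit)
        return trajectory, n_passes, converged

    def result(self, trajectory, n_passes, converged) -> FitResult:
        w0 = self.wm.window.start
        chains = []
        assignment: dict[str, int] = {}
        strand_names: dict[str, str] = {}
        # deterministic ids: order chains by (start, end, first member id)
        items = sorted(
            self.chains.items(),
            key=lambda kv: (kv[1].lo, kv[1].hi, min(self.reads[i].id for i in kv[1].members)),
        )
        for new_id, (_, cs) in enumerate(items):
            path = np.zeros(cs.hi - cs.lo, dtype=np.int8)
            score = self._viterbi(cs.M, cs.lo, empty_block(), 0, cs.lo, cs.hi, path)
            member_idx = sorted(cs.members, key=lambda i: (self.pr[i].lo, self.reads[i].id))
            hc = HaplotypeChain(
                id=new_id,
                chrom=self.wm.window.chrom,
                start=cs.lo + w0,
                end=cs.hi + w0,
                member_ids=[self.reads[i].id for i in member_idx],
                member_idx=member_idx,
                g=path,
                score=score,
                total_read_bp=cs.total_len,
            )
            chains.append(hc)
            for i in member_idx:
                assignment[self.reads[i].id] = new_id
                strand_names[self.reads[i].id] = "fwd" if self.strands[i] == 0 else "rev"
        log_lambda = self.total()
        return FitResult(
            chains=chains,
            reads=self.reads,
            assignment=assignment,
            strands=strand_names,
            log_lambda=log_lambda,
            trajectory=trajectory,
            n_passes=n_passes,
            converged=converged,
            wm=self.wm,
        )


def fit(reads: list[ReadUnit], wm: WindowModel) -> FitResult:
    """Run the coordinate-ascent haplotype-chain inference."""
    if not reads:
        raise ValueError("no reads to fit")
    eng = _Engine(reads, wm)
    trajectory, n_passes, converged = eng.run(wm.config.pass_limit)
    return eng.result(trajectory, n_passes, converged)


def brute_force_fit(
    reads: list[ReadUnit], wm: WindowModel, max_reads: int = 6, max_window: int = 120
) -> FitResult:
    """Exhaustive maximum-posterior search (test oracle for small instances).

    Enumerates all set partitions of the reads into feasible chains and
    all strand assignments, computing the optimal epigenotype chain for
    every block.  Guarded to tiny instances.
    """
    if len(reads) > max_reads:
        raise ValueError(f"brute force limited to {max_reads} reads")
    if len(wm.window) > max_window:
        raise ValueError(f"brute force limited to {max_window} bp windows")
    eng = _Engine(reads, wm)
    n = eng.n

    block_memo: dict[frozenset, tuple[float, tuple[int, ...]]] = {}

    def block_best(fs: frozenset) -> tuple[float, tuple[int, ...]]:
        hit = block_memo.get(fs)
        if hit is not None:
            return hit
        members = sorted(fs)
        strands = np.zeros(n, dtype=np.int8)
        best = (-math.inf, ())
        for bits in range(1 << len(members)):
            for k, i in enumerate(members):
                strands[i] = (bits >> k) & 1
            cs = eng._make_state(members, strands)
            tot = eng._contrib(cs)
            if tot > best[0]:
                best = (tot, tuple((bits >> k) & 1 for k in range(len(members))))
        block_memo[fs] = best
        return best

    def partitions(items: list[int]):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [first]] + part[k + 1 :]
            yield part + [[first]]

    best_total = -math.inf
    best_config = None
    for part in partitions(list(range(n))):
        ok = True
        total = 0.0
        strands_choice = []
        for block in part:
            fs = frozenset(block)
            if len(eng._split(block)) != 1 or not eng._block_feasible(fs, exact_limit=n):
                ok = False
                break
            sc, strands_bits = block_best(fs)
            total += sc
            strands_choice.append((sorted(block), strands_bits))
        if ok and total > best_total:
            best_total = total
            best_config = strands_choice
    assert best_config is not None  # singletons are always feasible

    eng2 = _Engine(reads, wm)
    for members, bits in best_config:
        for k, i in enumerate(members):
            eng2.strands[i] = bits[k]
        eng2._add_chain(eng2._make_state(members, eng2.strands))
    return eng2.result([best_total], 0, True)


def optimal_epigenotype_chain(
    reads: list[ReadUnit], strands: list[str], wm: WindowModel
) -> tuple[np.ndarray, float]:
    """Optimal strand-compatible epigenotype chain for a fixed read cluster.

    Returns logical state codes over the union span and the Viterbi score
    (log-likelihood plus log genotype prior).
    """
    eng = _Engine(reads, wm)
    smap = {r.id: s for r, s in zip(reads, strands)}
    sv = np.array(
        [0 if smap[r.id] == "fwd" else 1 for r in eng.reads], dtype=np.int8
    )
    if len(eng._split(list(range(eng.n)))) != 1:
        raise ValueError("read set has a coverage gap; not a feasible chain")
    cs = eng._make_state(list(range(eng.n)), sv)
    path = np.zeros(cs.hi - cs.lo, dtype=np.int8)
    score = eng._viterbi(cs.M, cs.lo, empty_block(), 0, cs.lo, cs.hi, path)
    return path, score


def log_prior_B(chains: list[tuple[int, list[int]]]) -> float:
    """log pi0 for a haplotype structure, up to its normalizing constant.

    ``chains`` is a list of (chain length L_b, [member read lengths]).
    Each read contributes sqrt(L) * (sum of read lengths in its chain)^2.
    """
    out = 0.0
    for L, lens in chains:
        if not lens:
            raise ValueError("empty chain in haplotype structure")
        out += len(lens) * (0.5 * math.log(L) + 2.0 * math.log(sum(lens)))
    return out


def log_prior_G(chains: list[tuple[np.ndarray, int]], wm: WindowModel) -> float:
    """log pi1(G | B): per chain position, log q if the nucleotide projection
    is an allowed genotype there, else log(1-q).

    ``chains`` is a list of (logical state codes, absolute start).
    """
    w0 = wm.window.start
    out = 0.0
    for g, start in chains:
        lo = start - w0
        out += float(wm.prior6[np.arange(lo, lo + len(g)), g].sum())
    return out


def log_posterior(res: FitResult) -> float:
    """Recompute log Lambda(B, G, R) of a fit result from its parts."""
    from .postprocess import position_loglik  # local import to avoid a cycle

    total = log_prior_B(
        [
            (c.length, [res.reads[i].length for i in c.member_idx])
            for c in res.chains
        ]
    )
    total += log_prior_G([(c.g, c.start) for c in res.chains], res.wm)
    for c in res.chains:
        for pos in range(c.start, c.end):
            lik = position_loglik(c, res, pos, allow_uncovered=True)
            total += lik[c.state_at(pos)]
    return total
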