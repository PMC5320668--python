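"""Reference sequence access and CpG/GpC context classification.

Positions are 0-based half-open internally; output tables use 1-based
inclusive coordinates.

A CpG site (C at j, G at j+1) is *isolated* if its context is HCGD: the
preceding base is H (not G) and the following base is D (not C).  A GpC
site (G at j, C at j+1) is isolated if its context is DGCH.  Isolated
sites are the ones where endogenous CpG methylation cannot be confused
with enzymatic GpC methylation (NOMe-seq).  N anywhere in the context, or
a window edge, makes a site non-isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import BASE_CODE, PROJECTION_CODE

log = logging.getLogger(__name__)

__all__ = [
    "ReferenceWindow",
    "SiteContext",
    "KnownVariantSet",
    "classify_contexts",
    "prior_indicator",
    "load_reference_window",
    "load_known_variants",
]


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of the reference genome."""

    chrom: str
    start: int  # 0-based
    seq: str  # upper-case, over {A,C,G,T,N}

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"unexpected reference characters: {sorted(bad)}")

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return np.frombuffer(
            self.seq.encode().translate(_TRANS), dtype=np.uint8
        ).astype(np.int8)


_TRANS = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))

#: stacked per-position context labels
LABELS = (
    "CPG_C",
    "CPG_G",
    "ISO_CPG_C",
    "ISO_CPG_G",
    "GPC_G",
    "GPC_C",
    "ISO_GPC_G",
    "ISO_GPC_C",
)


@dataclass
class SiteContext:
    """Per-position boolean context masks over a reference window.

    ``cpg_c[j]`` is true when j is the C of a CG dinucleotide, etc.
    ISO_* masks imply the corresponding non-isolated mask.
    """

    window: ReferenceWindow
    cpg_c: np.ndarray
    cpg_g: np.ndarray
    iso_cpg_c: np.ndarray
    iso_cpg_g: np.ndarray
    gpc_g: np.ndarray
    gpc_c: np.ndarray
    iso_gpc_g: np.ndarray
    iso_gpc_c: np.ndarray

    def labels(self, j: int) -> set[str]:
        """All labels that apply at window-relative position j."""
        out = set()
        for name in LABELS:
            if getattr(self, name.lower())[j]:
                out.add(name)
        return out or {"OTHER"}

    @property
    def iso_site(self) -> np.ndarray:
        """Positions belonging to any isolated CpG or isolated GpC."""
        return self.iso_cpg_c | self.iso_cpg_g | self.iso_gpc_g | self.iso_gpc_c


def classify_contexts(window: ReferenceWindow) -> SiteContext:
    """Label every CG and GC dinucleotide of a reference window.

    H is any nucleotide different from G, D any nucleotide different
    from C; N never counts as H or D, so N in the flanking context makes
    a site non-isolated, as do window edges.
    """
    s = window.codes
    L = len(s)
    A, C, G, T = (BASE_CODE[b] for b in "ACGT")
    z = np.zeros(L, dtype=bool)
    ctx = SiteContext(window, *[z.copy() for _ in range(8)])
    if L < 2:
        return ctx

    is_c, is_g = s == C, s == G
    cg = is_c[:-1] & is_g[1:]  # CG starting at j
    gc = is_g[:-1] & is_c[1:]  # GC starting at j
    ctx.cpg_c[:-1] = cg
    ctx.cpg_g[1:] = cg
    ctx.gpc_g[:-1] = gc
    ctx.gpc_c[1:] = gc

    is_h = (s == A) | (s == C) | (s == T)  # not G, not N
    is_d = (s == A) | (s == G) | (s == T)  # not C, not N
    # interior dinucleotides at (j, j+1) with full context (j-1, j+2)
    j = np.arange(1, L - 2)
    iso_cg = cg[j] & is_h[j - 1] & is_d[j + 2]
    iso_gc = gc[j] & is_d[j - 1] & is_h[j + 2]
    ctx.iso_cpg_c[j] = iso_cg
    ctx.iso_cpg_g[j + 1] = iso_cg
    ctx.iso_gpc_g[j] = iso_gc
    ctx.iso_gpc_c[j + 1] = iso_gc
    return ctx


@dataclass
class KnownVariantSet:
    """Allowed nucleotides per genomic position (reference plus known SNVs).

    When ``use_db`` is false only the reference allele is allowed at every
    position (private mutations are still possible, at prior cost).  N in
    the reference places no constraint: any nucleotide is allowed there.
    """

    window: ReferenceWindow
    alt_alleles: dict[int, set[str]] = field(default_factory=dict)  # genomic pos -> alts
    use_db: bool = True

    def allowed(self, pos: int) -> set[str]:
        """Allowed nucleotides at genomic position ``pos``."""
        j = pos - self.window.start
        if not 0 <= j < len(self.window):
            raise IndexError(f"position {pos} outside window")
        ref = self.window.seq[j]
        if ref == "N":
            return {"A", "C", "G", "T"}
        out = {ref}
        if self.use_db:
            out |= self.alt_alleles.get(pos, set())
        return out

    def allowed_matrix(self) -> np.ndarray:
        """Boolean (window length, 4) matrix of allowed base codes."""
        W = len(self.window)
        codes = self.window.codes
        M = np.zeros((W, 4), dtype=bool)
        valid = codes < 4
        M[np.arange(W)[valid], codes[valid]] = True
        M[~valid] = True  # N reference: unconstrained
        if self.use_db:
            for pos, alts in self.alt_alleles.items():
                j = pos - self.window.start
                if 0 <= j < W:
                    for a in alts:
                        M[j, BASE_CODE[a]] = True
        return M

    def log_prior_matrix(self, q: float) -> np.ndarray:
        """(window length, 6) matrix of log q / log(1-q) per epigenotype state."""
        M = self.allowed_matrix()[:, PROJECTION_CODE]  # project meC->C, meG->G
        return np.where(M, np.log(q), np.log1p(-q))


def prior_indicator(pos: int, nucleotide: str, variants: KnownVariantSet) -> int:
    """1 if ``nucleotide`` is a known genotype at ``pos``, else 0."""
    if nucleotide not in "ACGT":
        raise ValueError(f"invalid nucleotide {nucleotide!r}")
    return int(nucleotide in variants.allowed(pos))


def load_reference_window(fasta_path, chrom: str, start: int, end: int) -> ReferenceWindow:
    """Read a window from an (indexed) FASTA file; the index is built if absent."""
    from pyfaidx import Fasta

    with Fasta(str(fasta_path)) as fa:
        if chrom not in fa:
            raise KeyError(f"{chrom!r} not found in {fasta_path}")
        seq = str(fa[chrom][start:end])
    return ReferenceWindow(chrom, start, seq)


def load_known_variants(
    vcf_path, window: ReferenceWindow, use_db: bool = True
) -> KnownVariantSet:
    """Collect SNV alternate alleles inside the window from a VCF.

    Indels and other non-SNV records are skipped (counted in the log).
    """
    from cyvcf2 import VCF

    alts: dict[int, set[str]] = {}
    n_skipped = 0
    for rec in VCF(str(vcf_path)):
        pos = rec.POS - 1  # VCF is 1-based
        if rec.CHROM != window.chrom or not window.start <= pos < window.end:
            continue
        if len(rec.REF) != 1:
            n_skipped += 1
            continue
        snv_alts = {a for a in rec.ALT if len(a) == 1 and a in "ACGT"}
        if len(snv_alts) < len(rec.ALT):
            n_skipped += 1
        if snv_alts:
            alts.setdefault(pos, set()).update(snv_alts)
    if n_skipped:
        log.info("skipped %d non-SNV variant records", n_skipped)
    return KnownVariantSet(window, alts, use_db=use_db)
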