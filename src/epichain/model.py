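"""Six-state epigenotype space and the two-stage bisulfite observation model.

The per-position state of a DNA fragment is one of six *epigenotypes*:
the four nucleotides A, C, G, T plus meC (a methylated cytosine on the
forward strand) and meG (a guanine whose complementary reverse-strand
cytosine is methylated).  A sequenced base is observed through two noise
channels applied in order:

1. bisulfite conversion + PCR: an unmethylated C is converted to U (read
   as T) unless conversion fails (rate ``alpha_fail``); a methylated C is
   protected unless inappropriately converted (rate ``beta``).  Which
   positions are affected depends on the strand the read originates from,
   since conversion acts on each strand's own cytosines.
2. sequencing: the base is miscalled with probability ``epsilon`` (from
   the Phred quality), uniformly over the three other bases.

Reads are always considered in forward-mapped orientation; a read from
the reverse strand shows the complement of the (converted) reverse-strand
base at each position.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "Epigenotype",
    "StrandLabel",
    "ConversionParams",
    "ObservedBase",
    "Segment",
    "ReadUnit",
    "NUCLEOTIDES",
    "EPIGENOTYPES",
    "BASE_CODE",
    "CODE_BASE",
    "N_CODE",
    "conversion_prob",
    "conversion_matrix",
    "emission_prob",
    "phred_to_epsilon",
    "enumerate_error_free_observables",
]


class Epigenotype(enum.Enum):
    """One of the six per-position epigenetic states."""

    A = "A"
    C = "C"
    G = "G"
    T = "T"
    meC = "meC"
    meG = "meG"

    @property
    def nucleotide_projection(self) -> str:
        """The plain nucleotide of the state (meC -> C, meG -> G)."""
        return _PROJECTION[self]

    @property
    def is_methylated(self) -> bool:
        return self in (Epigenotype.meC, Epigenotype.meG)


_PROJECTION = {
    Epigenotype.A: "A",
    Epigenotype.C: "C",
    Epigenotype.G: "G",
    Epigenotype.T: "T",
    Epigenotype.meC: "C",
    Epigenotype.meG: "G",
}

#: canonical state order used by all array-based code
EPIGENOTYPES: tuple[Epigenotype, ...] = (
    Epigenotype.A,
    Epigenotype.C,
    Epigenotype.G,
    Epigenotype.T,
    Epigenotype.meC,
    Epigenotype.meG,
)
STATE_INDEX = {g: i for i, g in enumerate(EPIGENOTYPES)}

NUCLEOTIDES = ("A", "C", "G", "T")
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASE = "ACGTN"
N_CODE = 4

#: projection of state index -> base code (meC -> C, meG -> G)
PROJECTION_CODE = np.array([0, 1, 2, 3, 1, 2], dtype=np.int8)


class StrandLabel(enum.Enum):
    """Fragment strand a read originates from.

    ``rho`` is 0 for the forward strand and 1 for the reverse strand;
    ``rho_hat = 1 - rho``.
    """

    fwd = 0
    rev = 1

    @property
    def rho(self) -> int:
        return self.value

    @property
    def rho_hat(self) -> int:
        return 1 - self.value


@dataclass(frozen=True)
class ConversionParams:
    """Bisulfite conversion rates.

    ``conversion_rate`` is the probability that an unmethylated cytosine is
    successfully converted (config default 0.95); its complement
    ``alpha_fail`` is the failed-conversion rate appearing in the
    conversion table.  ``beta`` is the rate of inappropriate conversion of
    a methylated cytosine.
    """

    conversion_rate: float = 0.95
    beta: float = 0.05

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")

    @property
    def alpha_fail(self) -> float:
        return 1.0 - self.conversion_rate


@dataclass(frozen=True)
class ObservedBase:
    """A sequenced base with its Phred-derived error probability."""

    base: str
    epsilon: float

    def __post_init__(self) -> None:
        if self.base not in BASE_CODE:
            raise ValueError(f"invalid base {self.base!r}")
        if not 0.0 < self.epsilon <= 0.75:
            raise ValueError(f"epsilon must be in (0, 0.75], got {self.epsilon!r}")


@dataclass(frozen=True)
class Segment:
    """One aligned, ungapped stretch of a read unit."""

    start: int  # 0-based genomic start
    bases: np.ndarray  # int8 codes (A=0, C=1, G=2, T=3, N=4)
    epsilons: np.ndarray  # per-base error probability

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("segment must contain at least one base")
        if len(self.bases) != len(self.epsilons):
            raise ValueError("bases and epsilons must have equal length")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)


@dataclass
class ReadUnit:
    """A mapped read, or a joined mate pair, treated as one unit.

    The two segments of a pair share a single (inferred) fragment strand.
    Segments must not disagree where they overlap.
    """

    id: str
    segments: list[Segment]
    source_flags: int = 0
    truth: dict = field(default_factory=dict)  # simulator-only metadata

    def __post_init__(self) -> None:
        if not 1 <= len(self.segments) <= 2:
            raise ValueError("a read unit has one or two segments")
        self.segments = sorted(self.segments, key=lambda s: s.start)
        if len(self.segments) == 2:
            a, b = self.segments
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo < hi:  # overlapping mates must agree or be N
                xa = a.bases[lo - a.start : hi - a.start]
                xb = b.bases[lo - b.start : hi - b.start]
                bad = (xa != xb) & (xa != N_CODE) & (xb != N_CODE)
                if bad.any():
                    raise ValueError(f"mate segments of {self.id} disagree in overlap")

    @property
    def span_start(self) -> int:
        return self.segments[0].start

    @property
    def span_end(self) -> int:
        return max(s.end for s in self.segments)

    @property
    def length(self) -> int:
        """Total number of sequenced bases (excludes any insert gap)."""
        return sum(len(s.bases) for s in self.segments)


def phred_to_epsilon(q) -> float:
    """Map a Phred quality score to an error probability.

    epsilon = 10^(-q/10), clamped to [1e-6, 0.75] so that the emission
    model stays a proper, non-degenerate distribution.
    """
    q = np.asarray(q)
    if np.any(q < 0):
        raise ValueError("Phred scores must be non-negative")
    eps = np.power(10.0, -q / 10.0)
    return np.clip(eps, 1e-6, 0.75)[()] if eps.ndim == 0 else np.clip(eps, 1e-6, 0.75)


@lru_cache(maxsize=64)
def conversion_matrix(params: ConversionParams) -> np.ndarray:
    """P(Z = z | g, r) as an array of shape (4 bases, 6 states, 2 strands).

    ``Z`` is the fragment base after conversion and PCR, presented in
    forward-mapped orientation.  For each strand the columns sum to one.
    """
    a = params.alpha_fail
    b = params.beta
    M = np.zeros((4, 6, 2))
    for r, (rho, rho_hat) in enumerate(((0.0, 1.0), (1.0, 0.0))):
        iA, iC, iG, iT, imC, imG = range(6)
        # plain A / T are never touched by conversion
        M[BASE_CODE["A"], iA, r] = 1.0
        M[BASE_CODE["T"], iT, r] = 1.0
        # unmethylated C: converted on the forward strand only
        M[BASE_CODE["C"], iC, r] = rho + rho_hat * a
        M[BASE_CODE["T"], iC, r] = rho_hat * (1.0 - a)
        # unmethylated G: its reverse-strand C is converted on reverse-strand reads
        M[BASE_CODE["G"], iG, r] = rho_hat + rho * a
        M[BASE_CODE["A"], iG, r] = rho * (1.0 - a)
        # methylated C: protected, inappropriate conversion on forward reads
        M[BASE_CODE["C"], imC, r] = 1.0 - rho_hat * b
        M[BASE_CODE["T"], imC, r] = rho_hat * b
        # methylated G (reverse-strand meC): inappropriate conversion on reverse reads
        M[BASE_CODE["G"], imG, r] = 1.0 - rho * b
        M[BASE_CODE["A"], imG, r] = rho * b
    return M


def conversion_prob(
    z: str, g: Epigenotype, r: StrandLabel, params: ConversionParams
) -> float:
    """P(Z = z | g, r) for a single entry of the conversion table."""
    if z not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide {z!r}")
    if not isinstance(g, Epigenotype) or not isinstance(r, StrandLabel):
        raise TypeError("g must be an Epigenotype and r a StrandLabel")
    M = conversion_matrix(params)
    return float(M[BASE_CODE[z], STATE_INDEX[g], r.value])


def emission_prob(
    d: ObservedBase | str,
    g: Epigenotype,
    r: StrandLabel,
    params: ConversionParams,
    epsilon: float | None = None,
) -> float:
    """P(D = d | g, r): the conversion model composed with sequencing error.

    P(D=d|g,r) = (1 - 4/3 eps) P(Z=d|g,r) + eps/3 for d in {A,C,G,T};
    an observed N carries no information and has probability 1.
    """
    if isinstance(d, ObservedBase):
        base, eps = d.base, d.epsilon
    else:
        base, eps = d, epsilon
        if eps is None:
            raise TypeError("epsilon required when d is a plain base")
    if base == "N":
        return 1.0
    p = conversion_prob(base, g, r, params)
    return (1.0 - 4.0 * eps / 3.0) * p + eps / 3.0


def enumerate_error_free_observables(
    nome: bool = False,
) -> dict[tuple[str, str], tuple[Epigenotype, ...]]:
    """The six observable (forward-read, reverse-read) base pairs.

    With all error rates zero, each of the six epigenotypes produces a
    deterministic base on a forward-strand read and on a reverse-strand
    read.  The resulting six pairs are distinct, so observing error-free
    reads from both strands identifies the epigenotype uniquely.  Returns
    the inverse map from observed pair to epigenotype(s).
    """
    params = ConversionParams(conversion_rate=1.0, beta=0.0)
    M = conversion_matrix(params)
    out: dict[tuple[str, str], tuple[Epigenotype, ...]] = {}
    for gi, g in enumerate(EPIGENOTYPES):
        zf = CODE_BASE[int(np.argmax(M[:, gi, StrandLabel.fwd.value]))]
        zr = CODE_BASE[int(np.argmax(M[:, gi, StrandLabel.rev.value]))]
        out.setdefault((zf, zr), tuple())
        out[(zf, zr)] = out[(zf, zr)] + (g,)
    return out
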