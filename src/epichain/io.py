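"""Standard-format I/O and the windowed analysis pipeline.

Alignments are consumed from SAM/BAM restricted to a genomic window;
reads with indels or clipping are excluded (the observation model is
strictly columnar), and in paired mode only properly paired mates are
joined into read units.  Outputs are plain-text tables (TSV, 1-based
inclusive positions), BED/bedGraph tracks (0-based half-open), and a
JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .chains import FitResult, WindowModel, fit
from .config import ModelConfig
from .model import ReadUnit, Segment, phred_to_epsilon
from .reference import ReferenceWindow, load_known_variants, load_reference_window
from .postprocess import (
    FilterParams,
    accessibility_profile,
    call_table,
    chain_table,
    filter_chains,
    read_table,
)
from .simulate import SimTruth

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_alignments",
    "run_pipeline",
    "write_sam",
    "write_fasta",
    "write_truth",
    "write_snv_vcf",
    "parse_region",
]

_ALLOWED_CIGAR_OPS = {0, 7, 8}  # M, =, X


def parse_region(region: str) -> tuple[str, int, int]:
    """'chrom:start-end' (1-based inclusive) -> (chrom, start0, end) half-open."""
    try:
        chrom, span = region.rsplit(":", 1)
        a, b = span.replace(",", "").split("-")
        start, end = int(a), int(b)
    except ValueError as e:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end") from e
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start - 1, end


def _record_to_segment(rec) -> Segment:
    seq = rec.query_sequence.upper()
    quals = rec.query_qualities
    eps = phred_to_epsilon(np.array(quals, dtype=float))
    bases = np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    ).astype(np.int8)
    return Segment(rec.reference_start, bases, np.asarray(eps, dtype=float))


def load_alignments(
    path,
    region: tuple[str, int, int],
    mode: str = "wgbs-paired",
    contained: bool = True,
) -> tuple[list[ReadUnit], dict[str, int]]:
    """Read units overlapping a window, plus exclusion counts.

    Paired modes join properly paired mates into one unit and drop
    improperly paired or orphaned records; reads with indels/clipping are
    dropped in all modes.  With ``contained`` (the default used by the
    pipeline) units must lie fully inside the window.
    """
    chrom, start, end = region
    counts = {"used": 0, "indel_clip": 0, "improper": 0, "orphan": 0, "boundary": 0}
    paired_mode = mode in ("wgbs-paired", "nome")
    af = pysam.AlignmentFile(str(path), check_sq=False)
    if chrom not in af.references:
        raise ValueError(f"region chromosome {chrom!r} not in alignment header")
    try:
        it = af.fetch(chrom, start, end)
    except ValueError:  # no index (plain SAM): stream and filter
        it = (
            r
            for r in af.fetch(until_eof=True)
            if r.reference_name == chrom
            and r.reference_start < end
            and (r.reference_end or r.reference_start) > start
        )

    singles: list[ReadUnit] = []
    pending: dict[str, object] = {}
    for rec in it:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        if rec.cigartuples is None or any(
            op not in _ALLOWED_CIGAR_OPS for op, _ in rec.cigartuples
        ):
            counts["indel_clip"] += 1
            continue
        if paired_mode:
            if not (rec.is_paired and rec.is_proper_pair):
                counts["improper"] += 1
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
            else:
                try:
                    singles.append(
                        ReadUnit(
                            id=rec.query_name,
                            segments=[_record_to_segment(mate), _record_to_segment(rec)],
                            source_flags=rec.flag,
                        )
                    )
                except ValueError:  # mates disagree in their overlap
                    counts["improper"] += 1
        else:
            singles.append(
                ReadUnit(id=rec.query_name, segments=[_record_to_segment(rec)], source_flags=rec.flag)
            )
    counts["orphan"] = len(pending)
    af.close()

    out = []
    for u in singles:
        if contained and not (start <= u.span_start and u.span_end <= end):
            counts["boundary"] += 1
            continue
        out.append(u)
    counts["used"] = len(out)
    for k in ("indel_clip", "improper", "orphan", "boundary"):
        if counts[k]:
            log.info("excluded %d reads (%s)", counts[k], k)
    return out, counts


# -- writers ---------------------------------------------------------------


def write_fasta(window: ReferenceWindow, path) -> None:
    """Write the window as a FASTA chromosome padded to its genomic offset."""
    with open(path, "w") as f:
        f.write(f">{window.chrom}\n")
        seq = "N" * window.start + window.seq
        for k in range(0, len(seq), 60):
            f.write(seq[k : k + 60] + "\n")


def write_sam(reads: list[ReadUnit], window: ReferenceWindow, path) -> None:
    """Write read units as coordinate-sorted SAM (paired units as two records)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": window.chrom, "LN": window.end}],
    }
    recs = []
    with pysam.AlignmentFile(str(path), "w", header=header) as f:
        for u in reads:
            paired = len(u.segments) == 2
            for k, seg in enumerate(u.segments):
                a = pysam.AlignedSegment(f.header)
                a.query_name = u.id
                a.reference_id = 0
                a.reference_start = seg.start
                a.mapping_quality = 60
                a.cigartuples = [(0, len(seg.bases))]
                a.query_sequence = "".join("ACGTN"[b] for b in seg.bases)
                q = np.rint(-10.0 * np.log10(seg.epsilons)).astype(int)
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(min(int(x), 93) + 33) for x in q)
                )
                if paired:
                    other = u.segments[1 - k]
                    a.flag = 0x1 | 0x2 | (0x40 if k == 0 else 0x80)
                    a.next_reference_id = 0
                    a.next_reference_start = other.start
                    a.template_length = (
                        u.span_end - u.span_start if k == 0 else -(u.span_end - u.span_start)
                    )
                recs.append(a)
        for a in sorted(recs, key=lambda r: (r.reference_start, r.query_name, r.flag)):
            f.write(a)


def write_truth(truth: SimTruth, path) -> None:
    """Truth table: read id, allele, fragment strand (TSV)."""
    with open(path, "w") as f:
        f.write("read\tallele\tstrand\n")
        for rid in sorted(truth.read_truth):
            allele, strand = truth.read_truth[rid]
            f.write(f"{rid}\t{allele}\t{strand}\n")


def write_snv_vcf(truth: SimTruth, path) -> None:
    """Simulated SNVs as a minimal VCF (1-based positions)."""
    window = truth.window
    w0 = window.start
    recs = {}
    for allele in truth.alleles.values():
        for pos, alt in allele.snvs.items():
            ref = window.seq[pos - w0]
            if alt != ref:
                recs.setdefault(pos, (ref, set()))[1].add(alt)
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##contig=<ID={window.chrom},length={window.end}>\n")
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos in sorted(recs):
            ref, alts = recs[pos]
            f.write(
                f"{window.chrom}\t{pos + 1}\t.\t{ref}\t{','.join(sorted(alts))}\t.\t.\t.\n"
            )


# -- pipeline --------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one windowed run needs (paths, region, model settings)."""

    alignments: str
    reference: str
    region: str  # chrom:start-end, 1-based inclusive
    out_prefix: str
    mode: str = "wgbs-paired"
    variants: str | None = None
    overrides: dict = field(default_factory=dict)  # ModelConfig field overrides

    def model_config(self) -> ModelConfig:
        return ModelConfig.from_mode(self.mode, **self.overrides)


def run_pipeline(rc: RunConfig) -> dict:
    """load -> fit -> filter -> call -> write tables; returns the run report."""
    cfg = rc.model_config()
    cfg.log_settings()
    chrom, start, end = parse_region(rc.region)
    window = load_reference_window(rc.reference, chrom, start, end)
    variants = None
    if rc.variants and cfg.use_db:
        variants = load_known_variants(rc.variants, window, use_db=True)
    wm = WindowModel(window, cfg, variants)
    reads, counts = load_alignments(rc.alignments, (chrom, start, end), cfg.mode)
    if not reads:
        raise RuntimeError(f"no usable reads in {rc.region}")
    res = fit(reads, wm)
    kept, removed = filter_chains(res.chains, FilterParams(cfg.filter_a, cfg.filter_b), res)
    prefix = Path(rc.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    ct = chain_table(res)
    ct["kept"] = [c in kept for c in res.chains]
    ct.to_csv(f"{prefix}.chains.tsv", sep="\t", index=False)
    read_table(res).to_csv(f"{prefix}.reads.tsv", sep="\t", index=False)
    call_table(res, kept).to_csv(f"{prefix}.calls.tsv", sep="\t", index=False)
    with open(f"{prefix}.chains.bed", "w") as f:
        for c in kept:
            f.write(f"{c.chrom}\t{c.start}\t{c.end}\tchain{c.id}\t{min(c.n_reads, 1000)}\t.\n")
    if cfg.nome:
        sites, intervals = accessibility_profile(kept, res)
        with open(f"{prefix}.accessibility.bedgraph", "w") as f:
            for row in sites.itertuples():
                f.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.chain_consensus:.4f}\n")
        with open(f"{prefix}.inaccessible.bed", "w") as f:
            for iv in intervals:
                f.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tchain{iv.chain_id}\t{iv.n_sites}\t.\n")

    report = {
        "region": rc.region,
        "mode": cfg.mode,
        "parameters": dataclasses.asdict(cfg),
        "read_counts": counts,
        "n_chains": len(res.chains),
        "n_chains_kept": len(kept),
        "n_chains_removed": len(removed),
        "log_lambda": res.log_lambda,
        "log_lambda_trajectory": res.trajectory,
        "n_passes": res.n_passes,
        "converged": res.converged,
    }
    with open(f"{prefix}.report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report
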