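"""Non-reference Numt detection from discordant paired-end alignments.

The caller follows the classic insertion-calling recipe: keep nuclear
reads with mapping quality ≥10 whose mate maps to the mitochondrial
contig, cluster them by strand within a fragment-length window, pair a
forward (left-flank) cluster with the nearest downstream reverse
(right-flank) cluster into one event, and filter candidate calls on
Phred-scaled quality (≥50), supporting read pairs (≥4), and local read
depth (≥5×) around the insertion point.  Failing calls are emitted with
explanatory filter flags rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord", "Cluster", "NumtCall", "CallerParams",
    "scan_discordant", "call_numts", "compute_vaf", "anchored_span_check",
    "depth_track_from_records", "calls_to_frame",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one aligned read of a pair."""

    qname: str
    chrom: str
    pos: int          # 0-based leftmost reference position
    is_reverse: bool
    mapq: int
    read_len: int
    span: int         # aligned reference span in bp (≤ read_len if clipped)
    mate_chrom: str
    mate_pos: int

    def __post_init__(self):
        if not 0 <= self.mapq <= 255:
            raise ValueError("MAPQ outside [0, 255]")
        if self.pos < 0:
            raise ValueError("negative position")

    @property
    def end(self) -> int:
        return self.pos + self.span


@dataclass
class Cluster:
    """Strand-aware cluster of nuclear anchors with mtDNA-mapped mates."""

    chrom: str
    is_reverse: bool
    reads: list[AlignmentRecord]

    @property
    def start(self) -> int:
        return min(r.pos for r in self.reads)

    @property
    def end(self) -> int:
        return max(r.end for r in self.reads)

    @property
    def n_support(self) -> int:
        return len(self.reads)

    @property
    def breakpoint(self) -> int:
        # left-flank (forward) anchors end just before the junction; the
        # right-flank (reverse) anchors start at it
        return self.start if self.is_reverse else self.end

    def mt_span(self) -> tuple[int, int]:
        mpos = [r.mate_pos for r in self.reads]
        return min(mpos), max(mpos)


@dataclass(frozen=True)
class CallerParams:
    min_mapq: int = 10
    min_support: int = 4
    min_depth: float = 5.0
    min_qual: float = 50.0
    min_anchor_span: int = 150
    cluster_window: int = 750    # fragment mean + 3 sd by default
    pairing_window: int = 750
    depth_flank: int = 300       # half-width for local depth median
    mt_name: str = "chrM"
    max_qual: float = 99.0
    vaf_denominator: str = "local"  # "local" depth or "sample" mean coverage


@dataclass
class NumtCall:
    """One candidate non-reference Numt insertion."""

    chrom: str
    breakpoint: int
    ci: tuple[int, int]
    mt_start: int
    mt_end: int
    length: int
    n_support: int
    depth: float
    qual: float
    vaf: float
    anchored_span: int
    sample_id: str = "sample"
    filters: list[str] = field(default_factory=list)

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def filter_field(self) -> str:
        return "PASS" if self.is_pass else ";".join(self.filters)


def scan_discordant(
    records,
    params: CallerParams | None = None,
) -> list[Cluster]:
    """Collect mt-mated nuclear anchors and group them into clusters.

    Input must be sorted by (chrom, position) with chromosomes grouped;
    the first out-of-order record raises.  Retained reads are nuclear
    anchors with MAPQ ≥ ``params.min_mapq`` whose mate maps to the mtDNA
    contig.  Clustering is single-linkage per (chrom, strand): consecutive
    anchors more than ``cluster_window`` bp apart start a new cluster, so
    each retained read lands in exactly one cluster.
    """
    params = params or CallerParams()
    open_clusters: dict[tuple[str, bool], Cluster] = {}
    done: list[Cluster] = []
    last: tuple | None = None
    seen_chroms: set[str] = set()
    for i, rec in enumerate(records):
        if last is not None:
            lchrom, lpos = last
            if rec.chrom == lchrom and rec.pos < lpos:
                raise ValueError(
                    f"input not coordinate-sorted: record {i} ({rec.qname}) at "
                    f"{rec.chrom}:{rec.pos} after {lchrom}:{lpos}"
                )
            if rec.chrom != lchrom and rec.chrom in seen_chroms:
                raise ValueError(
                    f"input not coordinate-sorted: record {i} ({rec.qname}) "
                    f"revisits chromosome {rec.chrom}"
                )
        if rec.chrom != (last[0] if last else None):
            done.extend(open_clusters.values())
            open_clusters.clear()
        seen_chroms.add(rec.chrom)
        last = (rec.chrom, rec.pos)
        if rec.chrom == params.mt_name:
            continue
        if rec.mate_chrom != params.mt_name or rec.mapq < params.min_mapq:
            continue
        key = (rec.chrom, rec.is_reverse)
        cl = open_clusters.get(key)
        if cl is not None and rec.pos - cl.end <= params.cluster_window:
            cl.reads.append(rec)
        else:
            if cl is not None:
                done.append(cl)
            open_clusters[key] = Cluster(rec.chrom, rec.is_reverse, [rec])
    done.extend(open_clusters.values())
    done.sort(key=lambda c: (c.chrom, c.start))
    return done


def _union_span(intervals) -> int:
    total, cur_start, cur_end = 0, None, None
    for a, b in sorted(intervals):
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def anchored_span_check(
    reads: list[AlignmentRecord], min_span: int = 150
) -> tuple[bool, int]:
    """Union length of nuclear-aligned segments of the supporting reads.

    A call is trusted only when at least ``min_span`` bp of sequence is
    anchored to nuclear chromosomes, which rules out spurious junctions
    from non-human (e.g., bacterial) mitochondria-like fragments.
    """
    span = _union_span((r.pos, r.end) for r in reads)
    return span >= min_span, span


def compute_vaf(supporting: int, coverage: float) -> float:
    """Variant allele fraction: supporting read pairs over read coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if supporting < 0:
        raise ValueError("supporting count must be non-negative")
    return float(min(supporting / coverage, 1.0))


def depth_track_from_records(records, chrom_lengths: dict[str, int], min_mapq: int = 1):
    """Per-base read coverage per chromosome from alignment records.

    Reads below ``min_mapq`` are excluded (MAPQ 0 never contributes).
    Returned arrays cover each chromosome end to end.
    """
    tracks = {c: np.zeros(l, dtype=np.int32) for c, l in chrom_lengths.items()}
    for rec in records:
        tr = tracks.get(rec.chrom)
        if tr is None or rec.mapq < min_mapq:
            continue
        a = max(rec.pos, 0)
        b = min(rec.end, len(tr))
        if b > a:
            tr[a:b] += 1
    return tracks


def _local_depth(depth_track, chrom: str, pos: int, flank: int) -> float:
    tr = depth_track.get(chrom) if hasattr(depth_track, "get") else None
    if tr is None:
        raise ValueError(f"no depth track for {chrom}")
    a, b = max(pos - flank, 0), min(pos + flank + 1, len(tr))
    if b <= a:
        raise ValueError(f"depth track does not cover {chrom}:{pos}")
    return float(np.median(tr[a:b]))


def _make_call(fwd, rev, depth_track, params, sample_id, mean_coverage):
    reads = (fwd.reads if fwd else []) + (rev.reads if rev else [])
    chrom = (fwd or rev).chrom
    bp_f = fwd.breakpoint if fwd else None
    bp_r = rev.breakpoint if rev else None
    if fwd and rev:
        lo, hi = min(bp_f, bp_r), max(bp_f, bp_r)
        bp = (bp_f + bp_r) // 2
    else:
        bp = bp_f if fwd else bp_r
        lo = hi = bp
    mpos = [r.mate_pos for r in reads]
    mlen = [r.read_len for r in reads]
    mt_start, mt_end = min(mpos), max(mpos) + max(mlen)
    depth = _local_depth(depth_track, chrom, bp, params.depth_flank)
    qual = min(float(sum(r.mapq for r in reads)), params.max_qual)
    denom = depth if params.vaf_denominator == "local" else float(mean_coverage)
    vaf = compute_vaf(len(reads), denom) if denom > 0 else 0.0
    ok_anchor, span = anchored_span_check(reads, params.min_anchor_span)
    filters = []
    if len(reads) < params.min_support:
        filters.append("min_support")
    if depth < params.min_depth:
        filters.append("min_depth")
    if qual < params.min_qual:
        filters.append("min_qual")
    if not (fwd and rev):
        filters.append("one_sided")
    if not ok_anchor:
        filters.append("anchor_lt150")
    return NumtCall(
        chrom=chrom, breakpoint=int(bp), ci=(int(lo), int(hi)),
        mt_start=int(mt_start), mt_end=int(mt_end),
        length=int(mt_end - mt_start), n_support=len(reads),
        depth=depth, qual=qual, vaf=vaf, anchored_span=span,
        sample_id=sample_id, filters=filters,
    )


def call_numts(
    clusters: list[Cluster],
    depth_track,
    params: CallerParams | None = None,
    sample_id: str = "sample",
    mean_coverage: float | None = None,
) -> list[NumtCall]:
    """Pair clusters into insertion calls and apply quality filters.

    A forward cluster is paired with the nearest reverse cluster whose
    left-flank/right-flank geometry is consistent within
    ``params.pairing_window``; unpaired clusters yield one-sided calls.
    ``depth_track`` maps chromosome → per-base coverage array; local depth
    is the median in ±``depth_flank`` bp around the breakpoint.
    """
    params = params or CallerParams()
    if params.vaf_denominator == "sample" and not mean_coverage:
        raise ValueError("mean_coverage required for sample-level VAF denominator")
    calls = []
    by_chrom: dict[str, dict[bool, list[Cluster]]] = {}
    for cl in clusters:
        by_chrom.setdefault(cl.chrom, {True: [], False: []})[cl.is_reverse].append(cl)
    for chrom in sorted(by_chrom):
        fwds = sorted(by_chrom[chrom][False], key=lambda c: c.breakpoint)
        revs = sorted(by_chrom[chrom][True], key=lambda c: c.breakpoint)
        used_rev: set[int] = set()
        for fwd in fwds:
            best_j, best_d = None, None
            for j, rev in enumerate(revs):
                if j in used_rev:
                    continue
                d = rev.breakpoint - fwd.breakpoint
                if -params.cluster_window <= d <= params.pairing_window:
                    if best_d is None or abs(d) < best_d:
                        best_j, best_d = j, abs(d)
            if best_j is not None:
                used_rev.add(best_j)
                calls.append(
                    _make_call(fwd, revs[best_j], depth_track, params,
                               sample_id, mean_coverage)
                )
            else:
                calls.append(
                    _make_call(fwd, None, depth_track, params, sample_id, mean_coverage)
                )
        for j, rev in enumerate(revs):
            if j not in used_rev:
                calls.append(
                    _make_call(None, rev, depth_track, params, sample_id, mean_coverage)
                )
    calls.sort(key=lambda c: (c.chrom, c.breakpoint))
    return calls


def calls_to_frame(calls: list[NumtCall]) -> pd.DataFrame:
    """Tabulate calls, one row per call (``pos`` is the breakpoint)."""
    return pd.DataFrame(
        [
            dict(sample_id=c.sample_id, chrom=c.chrom, pos=c.breakpoint,
                 ci_lo=c.ci[0], ci_hi=c.ci[1], mt_start=c.mt_start,
                 mt_end=c.mt_end, length=c.length, support=c.n_support,
                 depth=c.depth, qual=c.qual, vaf=round(c.vaf, 4),
                 anchored_span=c.anchored_span, filter=c.filter_field)
            for c in calls
        ],
        columns=["sample_id", "chrom", "pos", "ci_lo", "ci_hi", "mt_start",
                 "mt_end", "length", "support", "depth", "qual", "vaf",
                 "anchored_span", "filter"],
    )
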