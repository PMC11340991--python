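"""mtDNA copy-number estimation from WGS coverage.

Copies per cell are estimated as mtDNAcn = (cov_MT / cov_autosomal) × 2,
where both terms are median per-base coverages; MAPQ-0 reads never
contribute and masked (ambiguous) positions are excluded from the
autosomal median.  Cross-batch values are variance-stabilized with a
log10 transform and z-standardized within each batch (brain region ×
extraction kit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["CoverageSummary", "coverage_summary", "compute_mtdnacn",
           "standardize_mtdnacn"]


@dataclass(frozen=True)
class CoverageSummary:
    cov_mt: float
    cov_autosomal: float


def _masked_median(values: np.ndarray, mask_intervals) -> float:
    if mask_intervals:
        keep = np.ones(values.size, dtype=bool)
        for a, b in mask_intervals:
            keep[a:b] = False
        values = values[keep]
    if values.size == 0:
        raise ValueError("no unmasked positions")
    return float(np.median(values))


def coverage_summary(
    depth_track: dict[str, np.ndarray],
    model: GenomeModel,
    center: str = "median",
) -> CoverageSummary:
    """Median (or mean/mode) per-base coverage of autosomes and mtDNA.

    ``depth_track`` maps contig → per-base coverage built from MAPQ>0
    reads (see :func:`numtpipe.caller.depth_track_from_records`).  Masked
    positions of the genome model are excluded from the autosomal pool;
    sex chromosomes are never part of "autosomal".
    """
    if model.mt_name not in depth_track:
        raise ValueError(f"no coverage for mtDNA contig {model.mt_name!r}")
    auto = [
        (c, np.asarray(depth_track[c]))
        for c in model.autosomes() if c in depth_track
    ]
    if not auto:
        raise ValueError("no autosomal coverage available")
    pooled = []
    for chrom, values in auto:
        mask = model.mask.get(chrom, [])
        if mask:
            keep = np.ones(values.size, bool)
            for a, b in mask:
                keep[a:b] = False
            values = values[keep]
        pooled.append(values)
    pooled = np.concatenate(pooled)
    mt = np.asarray(depth_track[model.mt_name])
    if center == "median":
        c_auto, c_mt = float(np.median(pooled)), float(np.median(mt))
    elif center == "mean":
        c_auto, c_mt = float(pooled.mean()), float(mt.mean())
    elif center == "mode":
        c_auto = float(np.bincount(pooled.astype(int)).argmax())
        c_mt = float(np.bincount(mt.astype(int)).argmax())
    else:
        raise ValueError("center must be median, mean, or mode")
    return CoverageSummary(cov_mt=c_mt, cov_autosomal=c_auto)


def compute_mtdnacn(cov: CoverageSummary) -> float:
    """mtDNA copies per cell: (cov_MT / cov_autosomal) × 2."""
    if cov.cov_autosomal <= 0:
        raise ValueError("autosomal coverage must be positive")
    return 2.0 * cov.cov_mt / cov.cov_autosomal


def standardize_mtdnacn(
    values,
    batches,
    order: str = "log_first",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Within-batch standardization of copy-number estimates.

    ``order="log_first"`` (default) applies log10 then z-standardizes
    within each batch — z-scores are signed, so logarithmizing them
    directly is undefined.  ``order="z_first"`` keeps the literal
    z-then-log order by shifting each batch's z-scores by (min + 1) before
    the log.  Returns the transformed vector and a per-batch table of the
    centering statistics.
    """
    values = np.asarray(values, dtype=float)
    batches = np.asarray(batches)
    if values.size != batches.size:
        raise ValueError("values and batches must have equal length")
    if order not in ("log_first", "z_first"):
        raise ValueError("order must be 'log_first' or 'z_first'")
    if order == "log_first" and np.any(values <= 0):
        raise ValueError("copy numbers must be positive for the log transform")
    out = np.empty_like(values)
    rows = []
    for b in pd.unique(batches):
        sel = batches == b
        if sel.sum() < 2:
            raise ValueError(f"batch {b!r} needs at least 2 samples")
        v = values[sel]
        if order == "log_first":
            v = np.log10(v)
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in batch {b!r}")
        z = (v - mu) / sd
        if order == "z_first":
            z = np.log10(z - z.min() + 1.0)
        out[sel] = z
        rows.append(dict(batch=b, n=int(sel.sum()), mean=float(mu), sd=float(sd)))
    return out, pd.DataFrame(rows)
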