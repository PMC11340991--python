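"""Cohort-level call-set operations.

Per-sample Numt calls are merged into cohort loci by single-linkage
closure of the "within ±50 bp on the same chromosome" relation, screened
against population-scale reference Numt lists to remove germline
polymorphisms, and reduced to tissue- (or cell-line-) exclusive candidate
somatic insertions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UnifiedCallSet", "merge_callsets", "filter_population",
    "exclusive_calls", "per_sample_counts",
]

MERGE_WINDOW = 50  # bp, the ±50 bp proximity rule


@dataclass
class UnifiedCallSet:
    """Merged cohort loci plus a locus × sample presence matrix.

    ``loci`` has one row per merged locus (``locus_id``, ``chrom``, ``pos``
    = median member breakpoint, ``n_members``); ``presence`` is a boolean
    DataFrame indexed by ``locus_id`` with one column per sample;
    ``members`` keeps the provenance of every input call
    (``locus_id`` + original columns).
    """

    loci: pd.DataFrame
    presence: pd.DataFrame
    members: pd.DataFrame

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, locus_ids) -> "UnifiedCallSet":
        keep = self.loci.locus_id.isin(set(locus_ids))
        ids = self.loci.loc[keep, "locus_id"]
        return UnifiedCallSet(
            loci=self.loci[keep].reset_index(drop=True),
            presence=self.presence.loc[ids],
            members=self.members[self.members.locus_id.isin(set(ids))].reset_index(drop=True),
        )


def _single_linkage(positions: np.ndarray, window: int) -> np.ndarray:
    """Cluster ids for sorted positions: gap > window starts a new cluster."""
    if positions.size == 0:
        return np.array([], dtype=int)
    new = np.concatenate([[True], np.diff(positions) > window])
    return np.cumsum(new) - 1


def merge_callsets(
    calls: pd.DataFrame | list[pd.DataFrame],
    window: int = MERGE_WINDOW,
    samples: list[str] | None = None,
) -> UnifiedCallSet:
    """Merge per-sample calls into cohort loci.

    ``calls`` is one concatenated frame (or a list of per-sample frames)
    with at least ``sample_id``, ``chrom``, ``pos``.  Two calls on the same
    chromosome within ±``window`` bp belong to the same locus, transitively
    closed; the representative position is the median member breakpoint.
    The result is invariant to input row order.
    """
    if isinstance(calls, list):
        calls = (
            pd.concat(calls, ignore_index=True)
            if calls else pd.DataFrame(columns=["sample_id", "chrom", "pos"])
        )
    if "genome_build" in calls.columns and calls["genome_build"].nunique() > 1:
        raise ValueError("mixed genome builds in input call sets")
    calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    members = calls.copy()
    members["locus_id"] = -1
    next_id = 0
    loci_rows = []
    for chrom, grp in members.groupby("chrom", sort=True):
        cl = _single_linkage(grp["pos"].to_numpy(), window)
        members.loc[grp.index, "locus_id"] = cl + next_id
        for k in range(cl.max() + 1 if cl.size else 0):
            pos = grp["pos"].to_numpy()[cl == k]
            loci_rows.append(
                dict(locus_id=next_id + k, chrom=chrom,
                     pos=int(np.median(pos)), n_members=int(pos.size))
            )
        next_id += int(cl.max()) + 1 if cl.size else 0
    loci = pd.DataFrame(loci_rows, columns=["locus_id", "chrom", "pos", "n_members"])
    all_samples = samples if samples is not None else sorted(calls["sample_id"].unique())
    presence = pd.DataFrame(
        False, index=loci["locus_id"], columns=pd.Index(all_samples, name="sample_id")
    )
    for (lid, sid) in members[["locus_id", "sample_id"]].itertuples(index=False):
        presence.at[lid, sid] = True
    return UnifiedCallSet(loci=loci, presence=presence, members=members)


def filter_population(
    unified: UnifiedCallSet,
    refs: pd.DataFrame,
    window: int = MERGE_WINDOW,
) -> tuple[UnifiedCallSet, int]:
    """Drop loci within ±``window`` bp of any population-reference Numt.

    ``refs`` needs ``chrom`` and ``pos`` columns.  Returns the filtered set
    and the number of loci removed.
    """
    if refs is None or len(refs) == 0:
        warnings.warn("empty population reference: no loci filtered", stacklevel=2)
        return unified, 0
    keep = []
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in refs.groupby("chrom")}
    for row in unified.loci.itertuples(index=False):
        ref = by_chrom.get(row.chrom)
        if ref is None:
            keep.append(row.locus_id)
            continue
        i = np.searchsorted(ref, row.pos)
        near = min(
            abs(int(ref[j]) - row.pos) for j in (i - 1, i) if 0 <= j < ref.size
        )
        if near > window:
            keep.append(row.locus_id)
    removed = unified.n_loci - len(keep)
    return unified.subset(keep), removed


def exclusive_calls(
    unified: UnifiedCallSet,
    meta: pd.DataFrame,
    grouping: str = "tissue",
    max_carriers: int | None = None,
) -> UnifiedCallSet:
    """Retain loci whose carrier samples all share one group label.

    ``meta`` maps ``sample_id`` to a ``grouping`` column (e.g., tissue, or
    a donor×treatment label).  Loci present in two or more groups are
    germline-like and dropped.  ``max_carriers`` optionally also drops
    loci recurring in more than that many samples of a single group.
    """
    labels = meta.set_index("sample_id")[grouping]
    missing = [s for s in unified.presence.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without a {grouping!r} label: {missing[:5]}")
    col_groups = labels.loc[unified.presence.columns].to_numpy()
    keep = []
    for lid, row in unified.presence.iterrows():
        carriers = row.to_numpy()
        groups = set(col_groups[carriers])
        if len(groups) == 1 and (max_carriers is None or carriers.sum() <= max_carriers):
            keep.append(lid)
    return unified.subset(keep)


def per_sample_counts(
    unified: UnifiedCallSet,
    exclusive: UnifiedCallSet | None = None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample totals (and exclusive counts) from presence-matrix margins."""
    out = pd.DataFrame({"total": unified.presence.sum(axis=0).astype(int)})
    if exclusive is not None:
        out["exclusive"] = exclusive.presence.sum(axis=0).reindex(out.index).fillna(0).astype(int)
    out.index.name = "sample_id"
    out = out.reset_index()
    if meta is not None:
        out = out.merge(meta, on="sample_id", how="left")
    return out
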