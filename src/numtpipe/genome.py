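"""Genome models: chromosome sizes, circular mtDNA, annotation, and masks.

A :class:`GenomeModel` is the shared coordinate frame for simulation,
hotspot binning, and genic-content classification.  Annotation is stored as
disjoint, sorted intervals per category (``CDS``, ``UTR``, ``intron``);
``intergenic`` is the implicit complement, so the four categories tile each
chromosome by construction.  Overlaps between categories are resolved at
build time with the precedence CDS > UTR > intron.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

MT_LENGTH = 16_569  # rCRS human mitochondrial genome
GENIC_CATEGORIES = ("CDS", "UTR", "intron")
CATEGORIES = GENIC_CATEGORIES + ("intergenic",)

# GRCh37 primary-assembly chromosome lengths (bp).
GRCH37_LENGTHS = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
}

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def _check_disjoint(name: str, ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivals = sorted((int(a), int(b)) for a, b in ivals)
    for (a, b), (c, d) in zip(ivals, ivals[1:]):
        if c < b:
            raise ValueError(
                f"overlapping {name} intervals after normalization: "
                f"({a},{b}) and ({c},{d})"
            )
        if b <= a:
            raise ValueError(f"empty or inverted {name} interval ({a},{b})")
    if ivals and ivals[0][0] < 0:
        raise ValueError(f"negative coordinate in {name} interval {ivals[0]}")
    return ivals


def _subtract(ivals, higher):
    """Subtract union of `higher` from each interval in `ivals` (both sorted)."""
    out = []
    for a, b in ivals:
        cuts = [(c, d) for c, d in higher if c < b and d > a]
        pos = a
        for c, d in cuts:
            if c > pos:
                out.append((pos, c))
            pos = max(pos, d)
        if pos < b:
            out.append((pos, b))
    return out


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus (optional) annotation and ambiguity mask.

    Parameters
    ----------
    chromosomes
        Mapping of nuclear chromosome name to length in bp (order preserved).
    mt_name, mt_length
        Name and length of the circular mitochondrial contig.
    annotation
        ``{category: {chrom: [(start, end), ...]}}`` for the genic
        categories.  Intervals are half-open, 0-based, and must be disjoint
        within a category after precedence resolution.
    mask
        Ambiguity-mask intervals per chromosome (excluded from coverage
        medians; optionally from permutation placement).
    """

    chromosomes: dict[str, int]
    mt_name: str = "chrM"
    mt_length: int = MT_LENGTH
    annotation: dict[str, dict[str, list[tuple[int, int]]]] | None = None
    mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("at least one nuclear chromosome is required")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.mt_length <= 0:
            raise ValueError("mt_length must be positive")
        if self.mt_name in self.chromosomes:
            raise ValueError("mtDNA contig duplicated among nuclear chromosomes")
        for chrom, ivals in self.mask.items():
            self._require_chrom(chrom)
            for a, b in _check_disjoint(f"mask[{chrom}]", ivals):
                if b > self.chromosomes[chrom]:
                    raise ValueError(f"mask interval ({a},{b}) exceeds {chrom}")

    def _require_chrom(self, chrom: str) -> None:
        if chrom not in self.chromosomes:
            raise ValueError(f"unknown chromosome {chrom!r}")

    # -- coordinate helpers -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(list(self.chromosomes.values()), dtype=np.int64)

    @property
    def nuclear_length(self) -> int:
        return int(self.lengths.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome in the concatenated genome."""
        return np.concatenate([[0], np.cumsum(self.lengths)[:-1]])

    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in SEX_CHROMOSOMES]

    def global_to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated-genome positions to (chrom index, position)."""
        gpos = np.asarray(gpos, dtype=np.int64)
        edges = np.cumsum(self.lengths)
        if gpos.size and (gpos.min() < 0 or gpos.max() >= edges[-1]):
            raise ValueError("global position outside nuclear genome")
        idx = np.searchsorted(edges, gpos, side="right")
        return idx, gpos - self.offsets[idx]

    def local_to_global(self, chroms, positions) -> np.ndarray:
        order = {c: i for i, c in enumerate(self.chromosomes)}
        off = self.offsets
        out = np.empty(len(positions), dtype=np.int64)
        for i, (c, p) in enumerate(zip(chroms, positions)):
            if c not in order:
                raise ValueError(f"unknown chromosome {c!r}")
            if not 0 <= p < self.chromosomes[c]:
                raise ValueError(f"position {p} outside {c}")
            out[i] = off[order[c]] + p
        return out

    # -- annotation ---------------------------------------------------------
    def category_bp(self, category: str) -> int:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if self.annotation is None:
            return self.nuclear_length if category == "intergenic" else 0
        if category == "intergenic":
            genic = sum(self.category_bp(c) for c in GENIC_CATEGORIES)
            return self.nuclear_length - genic
        return sum(
            b - a
            for ivals in self.annotation.get(category, {}).values()
            for a, b in ivals
        )

    def category_fractions(self) -> dict[str, float]:
        total = self.nuclear_length
        return {c: self.category_bp(c) / total for c in CATEGORIES}

    def classify(self, chrom: str, pos: int) -> str:
        """Genic category of a point, applying CDS > UTR > intron > intergenic."""
        self._require_chrom(chrom)
        if not 0 <= pos < self.chromosomes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        if self.annotation is None:
            return "intergenic"
        for cat in GENIC_CATEGORIES:
            ivals = self.annotation.get(cat, {}).get(chrom)
            if not ivals:
                continue
            i = bisect_right(ivals, (pos, float("inf"))) - 1
            if i >= 0 and ivals[i][0] <= pos < ivals[i][1]:
                return cat
        return "intergenic"


def make_genome_model(config: dict) -> GenomeModel:
    """Build a validated :class:`GenomeModel` from a plain configuration dict.

    ``config`` keys: ``chromosomes`` (name→length), optional ``mt_name``,
    ``mt_length``, ``annotation`` (category→chrom→interval pairs, possibly
    overlapping *between* categories), ``mask``.  Between-category overlaps
    are resolved by precedence; within-category overlaps raise.
    """
    chroms = {str(k): int(v) for k, v in dict(config["chromosomes"]).items()}
    raw = config.get("annotation")
    annotation = None
    if raw is not None:
        annotation = {}
        per_chrom_higher: dict[str, list[tuple[int, int]]] = {}
        for cat in GENIC_CATEGORIES:
            annotation[cat] = {}
            for chrom, ivals in dict(raw.get(cat, {})).items():
                ivals = _check_disjoint(f"{cat}[{chrom}]", [tuple(iv) for iv in ivals])
                if any(b > chroms.get(chrom, -1) for _, b in ivals):
                    raise ValueError(f"{cat} interval exceeds {chrom}")
                resolved = _subtract(ivals, per_chrom_higher.get(chrom, []))
                if resolved:
                    annotation[cat][chrom] = resolved
                merged = sorted(per_chrom_higher.get(chrom, []) + resolved)
                per_chrom_higher[chrom] = merged
    mask = {
        chrom: [tuple(iv) for iv in ivals]
        for chrom, ivals in dict(config.get("mask", {})).items()
    }
    return GenomeModel(
        chromosomes=chroms,
        mt_name=str(config.get("mt_name", "chrM")),
        mt_length=int(config.get("mt_length", MT_LENGTH)),
        annotation=annotation,
        mask=mask,
    )


def _unit_annotation(length: int, unit: int = 100_000) -> dict[str, list[tuple[int, int]]]:
    """Deterministic repeating gene structure used by the human-like presets.

    Each 100-kb unit is 63,920 bp intergenic followed by a 36,080-bp "gene"
    (250 bp UTR5, three 220-bp CDS exons separated by two 17,460-bp introns,
    250 bp UTR3), yielding genome fractions intergenic 63.92%, intron
    34.92%, CDS 0.66%, UTR 0.50% — matching genome-wide Ensembl-style
    expectations for a human reference.
    """
    gene = [
        ("UTR", 250), ("CDS", 220), ("intron", 17_460), ("CDS", 220),
        ("intron", 17_460), ("CDS", 220), ("UTR", 250),
    ]
    out: dict[str, list[tuple[int, int]]] = {"CDS": [], "UTR": [], "intron": []}
    start = 0
    while start < length:
        pos = start + 63_920
        for cat, w in gene:
            if pos >= length:
                break
            end = min(pos + w, length)
            out[cat].append((pos, end))
            pos = end
        start += unit
    return out


def human_like_model(scale: float = 1.0, annotated: bool = True) -> GenomeModel:
    """GRCh37-like genome model, optionally scaled down for desk-size runs.

    With ``scale=1`` the nuclear genome is the true ~3.1 Gb GRCh37 assembly;
    smaller scales shrink every chromosome proportionally (minimum 1 Mb).
    """
    chroms = {c: max(int(round(l * scale)), 1_000_000) for c, l in GRCH37_LENGTHS.items()}
    annotation = None
    if annotated:
        annotation = {"CDS": {}, "UTR": {}, "intron": {}}
        for chrom, length in chroms.items():
            per = _unit_annotation(length)
            for cat, ivals in per.items():
                if ivals:
                    annotation[cat][chrom] = ivals
    return GenomeModel(chromosomes=chroms, annotation=annotation)


def demo_genome(n_chroms: int = 3, length: int = 20_000_000) -> GenomeModel:
    """Small annotated genome for examples and fast tests."""
    chroms = {f"chr{i + 1}": length for i in range(n_chroms)}
    annotation = {"CDS": {}, "UTR": {}, "intron": {}}
    for chrom in chroms:
        for cat, ivals in _unit_annotation(length).items():
            annotation[cat][chrom] = ivals
    return GenomeModel(chromosomes=chroms, annotation=annotation)
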