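"""Shared domain containers used across the pipeline.

Coordinate conventions
----------------------
Internal genomic intervals are 1-based inclusive (``GenomicInterval``); BED
input/output uses the usual 0-based half-open convention (``MotifTrack``
stores BED coordinates and converts on demand).  VCF positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("1-based interval must start at >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        """Interval length in kb, rounded to 0.1 kb."""
        return round(self.length_bp / 1000.0, 1)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class GeneticMap:
    """Ordered marker map: genetic (Kosambi cM) and physical (bp) positions.

    Markers are stored sorted by chromosome then genetic position; both the
    genetic and the physical coordinate must be strictly increasing within a
    chromosome.
    """

    def __init__(self, chrom, name, cm, bp):
        self.chrom = np.asarray(chrom, dtype=object)
        self.name = np.asarray(name, dtype=object)
        self.cm = np.asarray(cm, dtype=float)
        self.bp = np.asarray(bp, dtype=np.int64)
        if not (len(self.chrom) == len(self.name) == len(self.cm) == len(self.bp)):
            raise ValueError("map columns must have equal length")
        if np.any(self.cm < 0):
            raise ValueError("genetic positions must be >= 0")
        for c in self.chromosomes:
            sl = self.chrom_slice(c)
            if np.any(np.diff(self.cm[sl]) <= 0) or np.any(np.diff(self.bp[sl]) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_markers(self) -> int:
        return len(self.name)

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        if np.any(np.diff(idx) != 1):
            raise ValueError("markers of one chromosome must be contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def marker_index(self, name: str) -> int:
        hits = np.flatnonzero(self.name == name)
        if hits.size == 0:
            raise KeyError(name)
        return int(hits[0])

    def index_at(self, chrom, bp: int) -> int:
        """Index of the marker at an exact physical position."""
        sl = self.chrom_slice(chrom)
        hits = np.flatnonzero(self.bp[sl] == bp)
        if hits.size == 0:
            raise KeyError(f"no marker at {chrom}:{bp}")
        return sl.start + int(hits[0])

    def cm_to_bp(self, chrom, cm: float) -> int:
        """Physical position interpolated linearly between flanking markers."""
        sl = self.chrom_slice(chrom)
        return int(round(float(np.interp(cm, self.cm[sl], self.bp[sl]))))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneticMap)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.name, other.name)
            and np.allclose(self.cm, other.cm)
            and np.array_equal(self.bp, other.bp)
        )


@dataclass
class VariantPanel:
    """Sequence variants in a focal region with per-sample genotypes.

    ``genotypes`` has shape (n_variants, n_samples, 2) holding allele indices
    into ``[ref] + alt`` (0 = ref); -1 marks a missing allele call.
    """

    chrom: str
    positions: np.ndarray          # (n_variants,) int64, 1-based
    ref: list                      # str per variant
    alt: list                      # list[str] per variant
    sample_ids: list
    genotypes: np.ndarray          # (n_variants, n_samples, 2) int8
    region: GenomicInterval | None = None
    cross_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.positions)
        if not (len(self.ref) == len(self.alt) == n):
            raise ValueError("ref/alt length mismatch")
        if self.genotypes.shape != (n, len(self.sample_ids), 2):
            raise ValueError("genotype array shape mismatch")
        if len(np.unique(self.positions)) != n:
            raise ValueError("one record per position required")
        if self.region is not None and n:
            if self.positions.min() < self.region.start or self.positions.max() > self.region.end:
                raise ValueError("variant position outside region")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def alleles(self, i: int) -> list:
        return [self.ref[i]] + list(self.alt[i])

    def n_alt(self, i: int) -> int:
        return len(self.alt[i])

    def observed_allele_count(self, i: int) -> int:
        """Number of distinct alleles actually called among the samples."""
        g = self.genotypes[i]
        return len(np.unique(g[g >= 0]))

    def sample_genotype(self, i: int, sample_id: str) -> tuple:
        j = self.sample_ids.index(sample_id)
        return tuple(int(a) for a in self.genotypes[i, j])

    def variant_span(self, i: int) -> GenomicInterval:
        """1-based footprint; a deletion (len(ref) > 1) spans its deleted bases."""
        pos = int(self.positions[i])
        ref_len = len(self.ref[i])
        if ref_len > 1:
            return GenomicInterval(self.chrom, pos + 1, pos + ref_len - 1)
        return GenomicInterval(self.chrom, pos, pos)

    def subset(self, idx) -> "VariantPanel":
        idx = np.asarray(idx, dtype=int)
        return VariantPanel(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            sample_ids=list(self.sample_ids),
            genotypes=self.genotypes[idx],
            region=self.region,
            cross_id=self.cross_id,
        )

    def variant_key(self, i: int) -> tuple:
        return (int(self.positions[i]), self.ref[i], tuple(self.alt[i]))


@dataclass
class MotifTrack:
    """Motif intervals in BED convention (0-based, half-open)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if np.any(self.starts < 0):
            raise ValueError("negative BED coordinate")
        if np.any(self.starts >= self.ends):
            raise ValueError("BED requires start < end")
        if not self.labels:
            self.labels = [f"motif_{i}" for i in range(len(self.starts))]

    def __len__(self) -> int:
        return len(self.starts)

    def to_intervals(self) -> list:
        """Convert to 1-based inclusive ``GenomicInterval`` objects."""
        return [
            GenomicInterval(self.chrom, int(s) + 1, int(e))
            for s, e in zip(self.starts, self.ends)
        ]

    def overlaps(self, interval: GenomicInterval) -> bool:
        if interval.chrom != self.chrom:
            return False
        return bool(
            np.any((self.starts + 1 <= interval.end) & (self.ends >= interval.start))
        )
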