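"""Interval algebra for ChIP peak sets.

Coordinates are 0-based half-open throughout (BED convention).  A peak may
carry a summit as an offset from its start; when absent the interval midpoint
is used wherever a summit anchor is required (matching the narrowPeak
convention that column 10 == -1 means "no summit called").

The operations here are the substrate of consensus-peak construction:
merging within a sample, support filtering of a reference set against other
antibodies / open-chromatin sets, summit-centred windows, and strand-aware
nearest-gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CATEGORIES = ("upstream_distal", "upstream_proximal", "tss", "intragenic", "downstream")


class ValidationError(ValueError):
    """Raised when an interval, peak set or gene model violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with optional signal and summit.

    Parameters
    ----------
    chrom : chromosome label.
    start, end : 0-based half-open coordinates, ``start < end``.
    peak_id : opaque label, unique within a :class:`PeakSet`.
    signal : nonnegative pileup/CPM-scale value.
    summit_offset : offset of the summit from ``start``, or ``None``.
    """

    chrom: str
    start: int
    end: int
    peak_id: str = ""
    signal: float = 0.0
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.peak_id or '<unnamed>'}: start {self.start} >= end {self.end}"
            )
        if self.signal < 0:
            raise ValidationError(f"interval {self.peak_id}: negative signal {self.signal}")
        if self.summit_offset is not None and not (0 <= self.summit_offset < self.end - self.start):
            raise ValidationError(
                f"interval {self.peak_id}: summit_offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint fallback when no summit was called."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """A named collection of peaks from one sample/antibody."""

    set_id: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [iv.peak_id for iv in self.intervals if iv.peak_id]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})[:3]
            raise ValidationError(f"peak set {self.set_id}: duplicate peak_ids {dup}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.set_id,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
        )


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene body; the TSS is derived from strand."""

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.body_start >= self.body_end:
            raise ValidationError(f"gene {self.gene_id}: body_start >= body_end")

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak mapped to its nearest gene.

    ``signed_distance`` is summit − TSS in the gene's reading direction:
    negative means the summit lies 5' (upstream) of the TSS.  ``gene_id`` is
    ``None`` when no gene lay within the search radius.
    """

    peak_id: str
    gene_id: str | None
    signed_distance: int | None
    category: str | None


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Merge overlapping intervals within a set.

    The result is disjoint, sorted, and covers exactly the union of input
    bases.  The merged signal is the max of the constituents and the summit is
    inherited from the highest-signal constituent.
    """
    if not peaks.intervals:
        return PeakSet(peaks.set_id, [])
    merged: list[GenomicInterval] = []
    out_idx = 0
    for iv in peaks.sorted():
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            best = prev if prev.signal >= iv.signal else iv
            merged[-1] = GenomicInterval(
                chrom=prev.chrom,
                start=prev.start,
                end=max(prev.end, iv.end),
                peak_id=prev.peak_id,
                signal=max(prev.signal, iv.signal),
                summit_offset=(
                    best.summit - prev.start if best.summit_offset is not None else None
                ),
            )
        else:
            pid = iv.peak_id or f"{peaks.set_id}_merged_{out_idx}"
            out_idx += 1
            merged.append(replace(iv, peak_id=pid))
    return PeakSet(peaks.set_id, merged)


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


def _overlaps_any(
    peak: GenomicInterval,
    starts: np.ndarray,
    ends: np.ndarray,
    min_frac: float,
) -> bool:
    """Any-overlap test against a sorted interval array of one chromosome."""
    if starts.size == 0:
        return False
    lo = int(np.searchsorted(ends, peak.start, side="right"))
    hi = int(np.searchsorted(starts, peak.end, side="left"))
    if lo >= hi:
        return False
    if min_frac <= 0:
        return True
    ov = np.minimum(ends[lo:hi], peak.end) - np.maximum(starts[lo:hi], peak.start)
    return bool(np.any(ov >= min_frac * peak.length))


def _chrom_index(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome coordinate-merged interval arrays; merging makes both
    the start and end arrays sorted, so binary search is valid even when the
    raw intervals nest."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def support_filter(
    reference: PeakSet,
    others: Sequence[PeakSet],
    min_support: int,
    min_overlap_fraction: float = 0.0,
) -> tuple[PeakSet, dict[str, int]]:
    """Keep reference peaks overlapped by at least ``min_support`` other sets.

    Overlap means >= 1 shared base by default; ``min_overlap_fraction`` can
    require a minimum fraction of the reference peak to be covered by one
    contiguous overlapping region of the other set.  Returns the filtered set
    and a peak_id -> support
    count map (computed for every reference peak, kept or not).
    """
    if min_support > len(others):
        raise ValidationError(
            f"min_support={min_support} exceeds number of other sets ({len(others)})"
        )
    if not reference.intervals:
        logger.warning("support_filter: empty reference set %s", reference.set_id)
        return PeakSet(reference.set_id, []), {}
    indexes = [_chrom_index(o) for o in others]
    support: dict[str, int] = {}
    kept: list[GenomicInterval] = []
    for iv in reference.sorted():
        n = 0
        for idx in indexes:
            if iv.chrom in idx and _overlaps_any(iv, *idx[iv.chrom], min_overlap_fraction):
                n += 1
        support[iv.peak_id] = n
        if n >= min_support:
            kept.append(iv)
    return PeakSet(reference.set_id, kept), support


def summit_window(peak: GenomicInterval, width: int) -> GenomicInterval:
    """A ``width``-bp window centred on the peak summit, clipped at 0.

    ``width`` must be odd so the summit sits exactly at the centre (e.g. the
    501 bp windows used for motif scans or 3 kb windows for signal heatmaps).
    """
    if width < 1 or width % 2 == 0:
        raise ValidationError(f"summit window width must be odd and >= 1, got {width}")
    half = width // 2
    start = max(0, peak.summit - half)
    return GenomicInterval(
        chrom=peak.chrom,
        start=start,
        end=peak.summit + half + 1,
        peak_id=peak.peak_id,
        signal=peak.signal,
        summit_offset=peak.summit - start,
    )


def categorize(
    signed_distance: int,
    summit_in_body: bool,
    tss_cutoff: int = 1000,
    proximal_cutoff: int = 10000,
) -> str:
    """Category from signed TSS distance and gene-body containment.

    Order: tss (|d| <= tss_cutoff), then intragenic, then upstream bands,
    then downstream.
    """
    if abs(signed_distance) <= tss_cutoff:
        return "tss"
    if summit_in_body:
        return "intragenic"
    if signed_distance < -proximal_cutoff:
        return "upstream_distal"
    if signed_distance < -tss_cutoff:
        return "upstream_proximal"
    return "downstream"


def nearest_gene(
    peak: GenomicInterval,
    genes: Iterable[GeneModel],
    max_distance: int = 100_000,
    tss_cutoff: int = 1000,
    proximal_cutoff: int = 10000,
) -> AnnotatedPeak:
    """Annotate a peak with its nearest gene by summit-to-TSS distance.

    The nearest gene minimises |summit − TSS| among same-chromosome genes
    within ``max_distance``; ties break by lexicographic gene_id.  The signed
    distance is oriented by the gene's strand (negative = upstream of the
    TSS).  Returns a null annotation when no gene qualifies.
    """
    summit = peak.summit
    best: GeneModel | None = None
    best_abs = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d_abs = abs(summit - g.tss)
        if d_abs > max_distance:
            continue
        if best is None or d_abs < best_abs or (d_abs == best_abs and g.gene_id < best.gene_id):
            best, best_abs = g, d_abs
    if best is None:
        logger.debug("nearest_gene: no gene within %d bp of peak %s", max_distance, peak.peak_id)
        return AnnotatedPeak(peak.peak_id, None, None, None)
    d = summit - best.tss if best.strand == "+" else best.tss - summit
    in_body = best.body_start <= summit < best.body_end
    return AnnotatedPeak(
        peak.peak_id, best.gene_id, d, categorize(d, in_body, tss_cutoff, proximal_cutoff)
    )


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    max_distance: int = 100_000,
    tss_cutoff: int = 1000,
    proximal_cutoff: int = 10000,
) -> list[AnnotatedPeak]:
    """Vector convenience: :func:`nearest_gene` for every peak in a set."""
    anns = [
        nearest_gene(iv, genes, max_distance, tss_cutoff, proximal_cutoff) for iv in peaks
    ]
    n_null = sum(1 for a in anns if a.gene_id is None)
    if n_null:
        logger.info(
            "annotate_peaks: %d/%d peaks had no gene within %d bp",
            n_null, len(anns), max_distance,
        )
    return anns
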