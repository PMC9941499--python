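"""Enhancer TSS scoring and orientation classification from stranded reads.

Works on 0-based half-open genomic intervals (BED convention).  The score of
an enhancer is its exon-filtered 5'-read count normalized to enhancer length
(reads per kb); orientation classes describe whether non-coding transcription
initiated near a TF-binding site proceeds toward ("inward") or away from
("outward") the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["chrom", "start", "end", "name", "raw_count",
                  "filtered_count", "tss_score", "transcribed",
                  "orientation_class"]


@dataclass(frozen=True)
class GenomicInterval:
    """Stranded 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom and self.start < other.end
                and other.start < self.end)


@dataclass
class EnhancerTSSRecord:
    enhancer: GenomicInterval
    raw_count: int = 0
    filtered_count: int = 0
    tss_score: float = 0.0
    transcribed: bool = False
    orientation_class: str = "none"


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need >= 3 BED columns")
            try:
                iv = GenomicInterval(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 else ".",
                    score=float(parts[4]) if len(parts) > 4
                    and parts[4] != "." else 0.0,
                    strand=parts[5] if len(parts) > 5 else ".")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{iv.score:g}\t{iv.strand}\n")


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping (start, end) pairs; returns sorted start/end arrays."""
    if not intervals:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    intervals = sorted(intervals)
    starts, ends = [intervals[0][0]], [intervals[0][1]]
    for s, e in intervals[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def filter_exonic_reads(reads, exons, margin_bp: int = 50):
    """Drop reads overlapping any exon expanded by ``margin_bp`` on each side.

    Half-open semantics: a read whose end abuts the expanded exon start
    exactly does not overlap and is retained.  Idempotent.
    """
    expanded: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ex in exons:
        by_chrom.setdefault(ex.chrom, []).append(
            (max(ex.start - margin_bp, 0), ex.end + margin_bp))
    for chrom, ivs in by_chrom.items():
        expanded[chrom] = _merge(ivs)
    kept = []
    for rd in reads:
        starts, ends = expanded.get(rd.chrom, (None, None))
        if starts is None or len(starts) == 0:
            kept.append(rd)
            continue
        # candidate merged interval: the last one starting before read end
        j = int(np.searchsorted(starts, rd.end, side="left")) - 1
        if j >= 0 and ends[j] > rd.start:
            continue
        kept.append(rd)
    return kept


def _count_overlaps(queries, targets) -> np.ndarray:
    """Number of ``targets`` overlapping each query (>= 1 bp)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {t.chrom for t in targets}:
        sel = [t for t in targets if t.chrom == chrom]
        by_chrom[chrom] = (np.sort([t.start for t in sel]),
                           np.sort([t.end for t in sel]))
    counts = np.zeros(len(queries), dtype=int)
    for i, q in enumerate(queries):
        if q.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[q.chrom]
        n = len(starts)
        # overlap iff target.start < q.end and target.end > q.start
        n_start_ge = n - int(np.searchsorted(starts, q.end, side="left"))
        n_end_le = int(np.searchsorted(ends, q.start, side="right"))
        counts[i] = n - n_start_ge - n_end_le
    return counts


def score_enhancers(filtered_reads, enhancers,
                    raw_reads=None) -> list[EnhancerTSSRecord]:
    """Count reads per enhancer and normalize to enhancer length (per kb).

    ``filtered_reads`` should already have passed :func:`filter_exonic_reads`;
    ``raw_reads`` (optional) provides the pre-filter counts for bookkeeping.
    """
    filt = _count_overlaps(enhancers, filtered_reads)
    raw = _count_overlaps(enhancers, raw_reads) if raw_reads is not None \
        else filt
    records = []
    for enh, fc, rc in zip(enhancers, filt, raw):
        length_kb = (enh.end - enh.start) / 1000.0
        records.append(EnhancerTSSRecord(
            enhancer=enh, raw_count=int(rc), filtered_count=int(fc),
            tss_score=float(fc) / length_kb))
    return records


def call_transcribed(records, threshold_score: float):
    """Flag transcribed enhancers and return the cumulative score curve.

    ``transcribed`` is ``tss_score >= threshold`` for a positive threshold;
    with threshold 0 the comparison is strict so that zero-score enhancers
    are never called transcribed.  Returns ``(records, curve)`` where curve
    is a DataFrame of sorted scores vs. cumulative fraction of enhancers.
    """
    if threshold_score < 0:
        raise ValueError("threshold_score must be >= 0")
    for rec in records:
        rec.transcribed = (rec.tss_score >= threshold_score
                           if threshold_score > 0 else rec.tss_score > 0)
    scores = np.sort([rec.tss_score for rec in records])
    curve = pd.DataFrame({
        "tss_score": scores,
        "cumulative_fraction": np.arange(1, len(scores) + 1) / len(scores),
    })
    return records, curve


def _is_inward(site: GenomicInterval, peak: GenomicInterval) -> bool:
    """Does transcription from the TSS peak proceed toward the TF site?

    Peaks overlapping the site itself count as inward.  Otherwise a
    plus-strand TSS left of the site midpoint, or a minus-strand TSS right
    of it, transcribes toward the site.
    """
    if peak.overlaps(site):
        return True
    m, p = site.midpoint(), peak.midpoint()
    return (peak.strand == "+" and p < m) or (peak.strand == "-" and p > m)


def classify_tss_orientation(enhancers, tf_sites, tss_peaks,
                             window_bp: int = 500) -> dict[str, str]:
    """Classify each enhancer by the orientation of nearby TSS peaks.

    TF sites are assigned to enhancers by >= 1 bp overlap; stranded TSS peaks
    within +/- ``window_bp`` of a site midpoint (midpoint distance, inclusive)
    vote inward/outward for that site.  The enhancer class aggregates over
    its sites: "inward" if any inward TSS, else "outward" if any outward,
    "both" when both kinds occur, "none" otherwise.  Returns a mapping from
    enhancer name to class.
    """
    stranded = []
    for pk in tss_peaks:
        if pk.strand == ".":
            log.warning("TSS peak %s has no strand; skipped", pk.name)
            continue
        stranded.append(pk)
    classes: dict[str, str] = {}
    for enh in enhancers:
        has_in = has_out = False
        for site in tf_sites:
            if not site.overlaps(enh):
                continue
            m = site.midpoint()
            for pk in stranded:
                if pk.chrom != site.chrom:
                    continue
                if abs(pk.midpoint() - m) > window_bp:
                    continue
                if _is_inward(site, pk):
                    has_in = True
                else:
                    has_out = True
        if has_in and has_out:
            classes[enh.name] = "both"
        elif has_in:
            classes[enh.name] = "inward"
        elif has_out:
            classes[enh.name] = "outward"
        else:
            classes[enh.name] = "none"
    return classes


def records_table(records) -> pd.DataFrame:
    """Flatten records to the documented TSV column order.

    tss_score is in reads per kb of enhancer.
    """
    rows = [{
        "chrom": r.enhancer.chrom, "start": r.enhancer.start,
        "end": r.enhancer.end, "name": r.enhancer.name,
        "raw_count": r.raw_count, "filtered_count": r.filtered_count,
        "tss_score": r.tss_score, "transcribed": r.transcribed,
        "orientation_class": r.orientation_class,
    } for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
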