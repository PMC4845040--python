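"""Condition-unique ChIP-seq peak extraction and promoter overlap.

The workflow mirrors the in-silico binding-site analysis: peaks called in the
treated condition are kept only if they share no base with any vehicle peak
(half-open interval semantics), then intersected with strand-aware promoter
windows; each hit reports the signed distance from the peak center to the
TSS at 0.5-base resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import PromoterWindow

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PromoterHit",
    "load_peaks",
    "write_peaks",
    "unique_peaks",
    "peak_center",
    "intersect_promoters",
    "distance_report",
]


@dataclass(frozen=True)
class Peak:
    """A called binding interval in 0-based half-open BED coordinates."""

    chrom: str
    start: int
    end: int
    condition: str
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak start must be < end ({self.start} >= {self.end})")
        if not self.condition:
            raise ValueError("peak condition label must be non-empty")


@dataclass(frozen=True)
class PromoterHit:
    """A (peak, promoter window) pair with >= 1 base of intersection.

    ``signed_distance`` is from the peak center to the TSS; its magnitude can
    exceed the window flank when the center lies outside a window the
    interval still reaches into.
    """

    transcript_id: str
    gene_symbol: str
    peak: Peak
    tss: int
    strand: str
    signed_distance: float


def load_peaks(path: str | Path, condition: str) -> list[Peak]:
    """Read BED3+ / narrowPeak peaks; rows with end <= start are rejected."""
    peaks: list[Peak] = []
    n_bad = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("line %d: fewer than 3 BED fields, skipped", line_no)
                n_bad += 1
                continue
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("line %d: non-integer coordinates, skipped", line_no)
                n_bad += 1
                continue
            if start >= end:
                logger.warning(
                    "line %d: start >= end (%d >= %d), skipped", line_no, start, end
                )
                n_bad += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            peaks.append(Peak(chrom, start, end, condition, score=score, name=name))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    logger.info(
        "loaded %d %s peaks from %s (%d rows rejected)", len(peaks), condition, path, n_bad
    )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t"
                f"{p.score if p.score is not None else 0}\n"
            )


def _tree_by_chrom(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def unique_peaks(treated: Sequence[Peak], control: Sequence[Peak]) -> list[Peak]:
    """Treated peaks with zero-base overlap against every control peak.

    Half-open semantics: a treated peak book-ended against a control peak
    (shared boundary, no shared base) is retained.
    """
    trees = _tree_by_chrom(control)
    kept = [
        p
        for p in treated
        if p.chrom not in trees or not trees[p.chrom].overlap(p.start, p.end)
    ]
    logger.info(
        "unique_peaks: kept %d of %d treated peaks (%d removed by control overlap)",
        len(kept),
        len(treated),
        len(treated) - len(kept),
    )
    return kept


def peak_center(p: Peak) -> float:
    """Midpoint of the peak, reported at 0.5-base resolution, never rounded."""
    return (p.start + p.end) / 2


def _check_chrom_styles(peaks: Sequence[Peak], windows: Sequence[PromoterWindow]) -> None:
    pk = {p.chrom for p in peaks}
    wn = {w.chrom for w in windows}
    if not pk or not wn or pk & wn:
        return
    strip = lambda s: s[3:] if s.startswith("chr") else s  # noqa: E731
    if {strip(c) for c in pk} & {strip(c) for c in wn}:
        raise ValueError(
            "no shared chromosome names between peaks and promoter windows, "
            "but names match after stripping 'chr' — normalize one side "
            "(e.g. 'chr1' vs '1') before intersecting"
        )


def intersect_promoters(
    peaks: Sequence[Peak],
    windows: Sequence[PromoterWindow],
    distance_mode: Literal["stranded", "genomic"] = "stranded",
) -> list[PromoterHit]:
    """All (peak, window) pairs sharing at least one base.

    A window covers 1-based bases ``[start, end]``; a peak covers
    ``[start+1, end]``.  ``signed_distance`` is ``center - tss`` oriented by
    transcription direction in ``stranded`` mode (downstream positive), or
    purely genomic ``center - tss`` in ``genomic`` mode.
    """
    _check_chrom_styles(peaks, windows)
    # index windows as half-open [start-1, end) so tree overlap == base sharing
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start - 1, w.end, w)
    hits: list[PromoterHit] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(p.start, p.end)):
            w: PromoterWindow = iv.data
            center = peak_center(p)
            d = center - w.tss
            if distance_mode == "stranded" and w.strand == "-":
                d = -d
            hits.append(
                PromoterHit(
                    transcript_id=w.transcript_id,
                    gene_symbol=w.gene_symbol,
                    peak=p,
                    tss=w.tss,
                    strand=w.strand,
                    signed_distance=d,
                )
            )
    return hits


def _hit_frame(hits: Sequence[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_symbol": [h.gene_symbol for h in hits],
            "transcript_id": [h.transcript_id for h in hits],
            "chrom": [h.peak.chrom for h in hits],
            "tss": [h.tss for h in hits],
            "strand": [h.strand for h in hits],
            "peak_start": [h.peak.start for h in hits],
            "peak_end": [h.peak.end for h in hits],
            "peak_center": [peak_center(h.peak) for h in hits],
            "signed_distance": [h.signed_distance for h in hits],
        }
    )


def distance_report(hits: Sequence[PromoterHit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene and per-isoform distance tables.

    The per-gene table keeps one representative isoform per symbol — the hit
    with the smallest ``|signed_distance|`` (ties broken by transcript id) —
    while the per-isoform table lists every hit.
    """
    columns = [
        "gene_symbol",
        "transcript_id",
        "chrom",
        "tss",
        "strand",
        "peak_start",
        "peak_end",
        "peak_center",
        "signed_distance",
    ]
    if not hits:
        empty = pd.DataFrame(columns=columns)
        return empty, empty.copy()
    per_isoform = _hit_frame(hits).sort_values(
        ["gene_symbol", "transcript_id", "peak_start"], kind="mergesort"
    )
    ranked = per_isoform.assign(_absd=per_isoform["signed_distance"].abs()).sort_values(
        ["_absd", "transcript_id"], kind="mergesort"
    )
    per_gene = (
        ranked.groupby("gene_symbol", sort=True)
        .head(1)
        .drop(columns="_absd")
        .sort_values("gene_symbol", kind="mergesort")
        .reset_index(drop=True)
    )
    return per_gene, per_isoform.reset_index(drop=True)
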