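"""Gene-model and transporter-catalogue ingestion.

Gene models are read from UCSC refGene-style tables (0-based half-open
``txStart``/``txEnd``).  Transcription start sites and promoter windows are
reported in 1-based inclusive coordinates, which is the convention the
downstream peak-overlap stage and all exported tables use; BED export
converts back to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "PromoterWindow",
    "TransporterCatalogue",
    "load_refgene",
    "write_refgene",
    "tss_of",
    "promoter_window",
    "promoter_windows",
    "windows_to_bed",
    "load_catalogue",
    "default_catalogue",
]

REFGENE_COLUMNS = ("name", "chrom", "strand", "txStart", "txEnd", "name2")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform of a gene.

    ``tx_start``/``tx_end`` keep the annotation file's 0-based half-open
    coordinates; conversion to 1-based happens only at TSS/window level.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"tx_start must be < tx_end ({self.tx_start} >= {self.tx_end})"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """1-based inclusive window of ``flank`` bases either side of a TSS.

    The window is clipped at base 1 near the chromosome start, so
    ``end - start`` can be smaller than ``2 * flank`` there.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    flank: int

    def __post_init__(self) -> None:
        if not (self.start <= self.tss <= self.end):
            raise ValueError("TSS must lie inside the promoter window")


def tss_of(t: TranscriptModel) -> int:
    """1-based transcription start site of a transcript.

    On the plus strand this is ``txStart`` converted from 0-based; on the
    minus strand transcription starts at the far end, which in 0-based
    half-open coordinates is ``txEnd`` (already the 1-based last base).
    """
    if t.strand == "+":
        return t.tx_start + 1
    return t.tx_end


def promoter_window(t: TranscriptModel, flank: int = 2000) -> PromoterWindow:
    """Promoter window of ``flank`` bases around the transcript's TSS."""
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    tss = tss_of(t)
    return PromoterWindow(
        transcript_id=t.transcript_id,
        gene_symbol=t.gene_symbol,
        chrom=t.chrom,
        strand=t.strand,
        start=max(1, tss - flank),
        end=tss + flank,
        tss=tss,
        flank=flank,
    )


def promoter_windows(
    transcripts: Iterable[TranscriptModel], flank: int = 2000
) -> list[PromoterWindow]:
    return [promoter_window(t, flank) for t in transcripts]


def load_refgene(path: str | Path) -> list[TranscriptModel]:
    """Read a refGene-style TSV into transcript models.

    The file must carry the columns ``name, chrom, strand, txStart, txEnd,
    name2``; extra columns (bin, exon structure, ...) are ignored.  Malformed
    rows are skipped with a log message naming the offending line; duplicate
    transcript ids keep the first occurrence.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"annotation file {path} is empty") from None
    missing = [c for c in REFGENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"annotation file {path} is missing required column(s): "
            + ", ".join(missing)
        )
    if df.empty:
        raise ValueError(f"annotation file {path} has no data rows")

    out: list[TranscriptModel] = []
    seen: set[str] = set()
    n_bad = 0
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            t = TranscriptModel(
                transcript_id=str(row["name"]),
                gene_symbol=str(row["name2"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                tx_start=int(row["txStart"]),
                tx_end=int(row["txEnd"]),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed row at line %d: %s", line_no, exc)
            n_bad += 1
            continue
        if t.transcript_id in seen:
            logger.warning(
                "duplicate transcript id %r at line %d; keeping first occurrence",
                t.transcript_id,
                line_no,
            )
            continue
        seen.add(t.transcript_id)
        out.append(t)
    logger.info("loaded %d transcripts from %s (%d rows rejected)", len(out), path, n_bad)
    return out


def write_refgene(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models back to a refGene-style TSV (round-trips)."""
    df = pd.DataFrame(
        {
            "name": [t.transcript_id for t in transcripts],
            "chrom": [t.chrom for t in transcripts],
            "strand": [t.strand for t in transcripts],
            "txStart": [t.tx_start for t in transcripts],
            "txEnd": [t.tx_end for t in transcripts],
            "name2": [t.gene_symbol for t in transcripts],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def windows_to_bed(windows: Sequence[PromoterWindow], path: str | Path) -> None:
    """Export promoter windows as BED6 (0-based half-open on write)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start - 1}\t{w.end}\t"
                f"{w.gene_symbol}|{w.transcript_id}\t0\t{w.strand}\n"
            )


class TransporterCatalogue:
    """The registry of transporter genes forming the testing universe.

    Wraps a table with one row per gene symbol carrying the transporter
    family, a clinical-relevance flag and an optional influx/efflux class.
    The catalogue defines the gene set over which the subset FDR correction
    is applied downstream.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"gene_symbol", "family", "clinically_relevant"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"catalogue is missing column(s): {sorted(missing)}")
        dup = frame["gene_symbol"][frame["gene_symbol"].duplicated()]
        if len(dup):
            raise ValueError(
                "duplicate gene symbols in catalogue: " + ", ".join(sorted(set(dup)))
            )
        frame = frame.copy()
        if "transport_class" not in frame.columns:
            frame["transport_class"] = "none"
        frame["transport_class"] = (
            frame["transport_class"].fillna("none").replace("", "none")
        )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.frame["gene_symbol"])

    @property
    def symbols(self) -> list[str]:
        return list(self.frame["gene_symbol"])

    @property
    def families(self) -> pd.Series:
        """Gene counts per family (sums to the catalogue size)."""
        return self.frame["family"].value_counts()

    @property
    def n_families(self) -> int:
        return self.frame["family"].nunique()

    @property
    def clinically_relevant(self) -> list[str]:
        mask = self.frame["clinically_relevant"].astype(bool)
        return list(self.frame.loc[mask, "gene_symbol"])

    def subset(self, symbols: Iterable[str]) -> "TransporterCatalogue":
        keep = set(symbols)
        return TransporterCatalogue(
            self.frame[self.frame["gene_symbol"].isin(keep)].reset_index(drop=True)
        )


def _parse_flag(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def load_catalogue(path: str | Path) -> TransporterCatalogue:
    """Load a transporter-catalogue TSV (gene_symbol, family, clinically_relevant[, transport_class])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "clinically_relevant" in df.columns:
        df["clinically_relevant"] = df["clinically_relevant"].map(_parse_flag)
    return TransporterCatalogue(df)


def default_catalogue() -> TransporterCatalogue:
    """The packaged 410-gene / 19-family transporter catalogue.

    A synthetic-completed assembly: the clinically relevant drug transporters
    and the genes named in the published tables are real symbols, and the
    remainder of each family is filled with systematically named members so
    that the family structure and totals match the study universe.  Users
    with their own curated list should pass it to :func:`load_catalogue`.
    """
    with resources.files("xenoduct.data").joinpath(
        "transporter_catalogue_synthetic.tsv"
    ).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    df["clinically_relevant"] = df["clinically_relevant"].map(_parse_flag)
    return TransporterCatalogue(df)
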