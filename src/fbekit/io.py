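"""Readers, writers and the pipeline driver.

Tabular dialect: tab-delimited, headered, UTF-8, "." decimal.  All
user-facing coordinates are 1-based inclusive; internal coordinates are
0-based half-open.  FASTA I/O goes through Biopython SeqIO.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from fbekit.adjacency import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_GAP,
    AdjacentPair,
    PeakRecord,
    ScanSummary,
    scan_peak,
    summarize,
)
from fbekit.motif import normalize_sequence

logger = logging.getLogger("fbekit")

PEAK_TABLE_REQUIRED = ("peak_id", "gene_id", "region", "height_wt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, normalized to the RNA alphabet.

    Duplicate ids and empty records are rejected with the record named.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        out[rec.id] = normalize_sequence(seq)
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peak_table(
    path: str | Path, sequences: Mapping[str, str]
) -> list[PeakRecord]:
    """Typed peak records from a headered TSV joined with FASTA sequences.

    Required columns: peak_id, gene_id, region, height_wt; optional:
    height_mut, category.  Errors name the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEAK_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing column(s): {missing}")
    peaks: list[PeakRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        peak_id = getattr(row, "peak_id")
        try:
            height_wt = float(getattr(row, "height_wt"))
        except (TypeError, ValueError):
            raise ValueError(
                f"row {row_no}, column height_wt: non-numeric value "
                f"{getattr(row, 'height_wt')!r}"
            ) from None
        if height_wt < 0:
            raise ValueError(
                f"row {row_no}, column height_wt: negative height {height_wt}"
            )
        height_mut: Optional[float] = None
        if "height_mut" in df.columns:
            raw = getattr(row, "height_mut")
            if raw is not None and not pd.isna(raw) and raw != "":
                try:
                    height_mut = float(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"row {row_no}, column height_mut: non-numeric {raw!r}"
                    ) from None
        category = None
        if "category" in df.columns:
            raw = getattr(row, "category")
            if raw is not None and not pd.isna(raw) and raw != "":
                category = str(raw)
        if peak_id not in sequences:
            raise ValueError(
                f"row {row_no}: peak_id {peak_id!r} has no FASTA sequence"
            )
        peaks.append(
            PeakRecord(
                peak_id=peak_id,
                gene_id=getattr(row, "gene_id"),
                region=getattr(row, "region"),
                sequence=sequences[peak_id],
                height_wt=height_wt,
                height_mut=height_mut,
                category=category,
            )
        )
    return peaks


def peaks_to_table(peaks: Iterable[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
            "region": [p.region for p in peaks],
            "height_wt": [p.height_wt for p in peaks],
            "height_mut": [p.height_mut for p in peaks],
            "category": [p.category for p in peaks],
        }
    )


def pairs_to_table(
    pairs: Iterable[AdjacentPair], peaks_by_id: Mapping[str, PeakRecord]
) -> pd.DataFrame:
    """Pair records as a 1-based-inclusive coordinate table."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "peak_id": p.peak_id,
                "gene_id": peaks_by_id[p.peak_id].gene_id,
                "upstream_class": p.upstream.pattern_name,
                "upstream_start": p.upstream.start + 1,
                "upstream_end": p.upstream.end,
                "upstream_seq": p.upstream.matched_text,
                "downstream_class": p.downstream.pattern_name,
                "downstream_start": p.downstream.start + 1,
                "downstream_end": p.downstream.end,
                "downstream_seq": p.downstream.matched_text,
                "gap": p.gap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id", "gene_id",
            "upstream_class", "upstream_start", "upstream_end", "upstream_seq",
            "downstream_class", "downstream_start", "downstream_end",
            "downstream_seq", "gap",
        ],
    )


def summary_to_table(summary: ScanSummary) -> pd.DataFrame:
    row = {
        "n_peaks_scanned": summary.n_peaks_scanned,
        "n_peaks_with_pairs": summary.n_peaks_with_pairs,
        "n_distinct_genes": summary.n_distinct_genes,
    }
    for region, count in summary.n_by_region.items():
        row[f"n_{region}"] = count
    return pd.DataFrame([row])


@dataclass
class PipelineConfig:
    """Validated settings for the scan pipeline.

    Defaults reproduce the published search settings: gap bounds 1-20 nt,
    assay temperature 293.15 K, comparison windows 0-10 / 70-80 /
    90-100 um.
    """

    fasta: Optional[str] = None
    peaks: Optional[str] = None
    min_gap: int = DEFAULT_MIN_GAP
    max_gap: int = DEFAULT_MAX_GAP
    temperature: float = 293.15
    windows: tuple[tuple[float, float], ...] = (
        (0.0, 10.0), (70.0, 80.0), (90.0, 100.0)
    )
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_gap <= self.max_gap:
            raise ValueError(
                f"invalid gap bounds [{self.min_gap}, {self.max_gap}]"
            )
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> ScanSummary:
    """Scan -> pairs -> summary, writing TSV outputs and a run log."""
    if config.fasta is None or config.peaks is None:
        raise ValueError("config must set fasta and peaks paths")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sequences = read_fasta(config.fasta)
    peaks = read_peak_table(config.peaks, sequences)
    scanned = [scan_peak(p, config.min_gap, config.max_gap) for p in peaks]
    summary = summarize(scanned)

    peaks_by_id = {p.peak_id: p for p in peaks}
    pairs_df = pairs_to_table(summary.pairs, peaks_by_id)
    pairs_df.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    summary_to_table(summary).to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_peaks_scanned": summary.n_peaks_scanned,
        "n_peaks_with_pairs": summary.n_peaks_with_pairs,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    logger.info("scan complete: %s", log)
    return summary


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("fbekit")
    root.handlers[:] = [handler]
    root.setLevel(level)
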