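"""Readers and writers: FASTA, benchmark TSV, predictions TSV.

The canonical machine-readable benchmark format is a TSV with columns
``protein_id``, ``site`` (1-based), ``peptide`` (the ``(2*xi+1)``-mer) and
``label`` (``positive`` / ``negative``); one row per cysteine window,
``(protein_id, site)`` unique.  Published benchmarks distributed as PDF
tables are converted to this schema once, by hand or script, outside the
package.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .evaluation import ProteinReport
from .windowing import DEFAULT_XI, PeptideWindow, ProteinRecord, sanitize_sequence

logger = logging.getLogger(__name__)

#: Query sequences shorter than this are flagged as fragments (warning only):
#: flank composition near artificial termini is not representative.
FRAGMENT_LENGTH = 50

BENCHMARK_COLUMNS = ["protein_id", "site", "peptide", "label"]
PREDICTION_COLUMNS = ["protein_id", "site", "peptide", "score", "call"]


def _as_handle(source, mode: str = "r"):
    """Accept a path, str path, or file-like; returns (handle, should_close)."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8"), True


@dataclass(frozen=True)
class BenchmarkTable:
    """Parsed benchmark rows, split by class."""

    positives: tuple[PeptideWindow, ...]
    negatives: tuple[PeptideWindow, ...]

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    @property
    def n_proteins(self) -> int:
        return len({w.protein_id for w in self.positives + self.negatives})

    @property
    def windows(self) -> list[PeptideWindow]:
        return list(self.positives) + list(self.negatives)


# --- FASTA -----------------------------------------------------------------


def read_fasta(source) -> list[ProteinRecord]:
    """Parse FASTA into sanitized :class:`ProteinRecord` objects.

    The description line after ``>`` becomes the record id (a generated id
    if empty).  Body characters outside the native alphabet are mapped to X
    by :func:`~snosite.windowing.sanitize_sequence`; records with an empty
    body raise :class:`~snosite.errors.FormatError`.
    """
    handle, should_close = _as_handle(source)
    try:
        text = handle.read()
    finally:
        if should_close:
            handle.close()
    if ">" not in text:
        raise FormatError("not FASTA: no '>' header line found")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if not first.startswith(">"):
        raise FormatError("not FASTA: data precedes the first '>' header")
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(_stdio.StringIO(text), "fasta")):
        rec_id = rec.description.strip() or f"record_{i + 1}"
        body = str(rec.seq)
        if not body:
            raise FormatError(f"FASTA record {rec_id!r} has an empty body")
        seq = sanitize_sequence(body)
        if len(seq) < FRAGMENT_LENGTH:
            logger.warning(
                "sequence %r has %d residues (< %d): likely a fragment, "
                "flank context near its termini may be unrepresentative",
                rec_id, len(seq), FRAGMENT_LENGTH,
            )
        records.append(ProteinRecord(id=rec_id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], sink, wrap: int = 80) -> None:
    """Write records as FASTA with line wrapping at ``wrap`` columns."""
    handle, should_close = _as_handle(sink, "w")
    try:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), wrap):
                handle.write(rec.sequence[i : i + wrap] + "\n")
    finally:
        if should_close:
            handle.close()


# --- benchmark TSV ---------------------------------------------------------


def read_benchmark(source, xi: int = DEFAULT_XI) -> BenchmarkTable:
    """Parse and validate the benchmark TSV.

    Row errors (wrong peptide length, non-C center, bad label, duplicate
    (protein_id, site)) name the offending data row (1-based, excluding the
    header).
    """
    handle, should_close = _as_handle(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse benchmark TSV: {exc}") from exc
    finally:
        if should_close:
            handle.close()
    missing = [c for c in BENCHMARK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"benchmark TSV lacks column(s) {missing}")
    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    seen: set[tuple[str, int]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row.protein_id)
        try:
            site = int(row.site)
        except (TypeError, ValueError):
            raise FormatError(f"row {row_no}: site {row.site!r} is not an integer")
        peptide = str(row.peptide).strip().upper()
        label = str(row.label).strip().lower()
        if label not in ("positive", "negative"):
            raise FormatError(f"row {row_no}: label {row.label!r} not positive/negative")
        if len(peptide) != 2 * xi + 1:
            raise FormatError(
                f"row {row_no}: peptide length {len(peptide)} != {2 * xi + 1} for xi={xi}"
            )
        if peptide[xi] != "C":
            raise FormatError(f"row {row_no}: peptide center {peptide[xi]!r} is not 'C'")
        if site < 1:
            raise FormatError(f"row {row_no}: site {site} is not a 1-based position")
        key = (pid, site)
        if key in seen:
            raise FormatError(f"row {row_no}: duplicate (protein_id, site) = {key}")
        seen.add(key)
        window = PeptideWindow(
            protein_id=pid, site=site, residues=peptide, xi=xi, label=label
        )
        (positives if label == "positive" else negatives).append(window)
    table = BenchmarkTable(positives=tuple(positives), negatives=tuple(negatives))
    logger.info(
        "benchmark: %d positive, %d negative windows over %d proteins",
        table.n_pos, table.n_neg, table.n_proteins,
    )
    return table


def write_benchmark(windows: Sequence[PeptideWindow], sink) -> None:
    """Write windows to the benchmark TSV schema."""
    df = pd.DataFrame(
        [(w.protein_id, w.site, w.residues, w.label) for w in windows],
        columns=BENCHMARK_COLUMNS,
    )
    handle, should_close = _as_handle(sink, "w")
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if should_close:
            handle.close()


# --- predictions TSV -------------------------------------------------------


def write_predictions(reports: Sequence[ProteinReport], sink) -> None:
    """One row per cysteine site: id, site, peptide, score (4 dp), call.

    Rows follow protein order, then ascending site.  Cysteine-free proteins
    contribute no site rows (their flag is visible in the protein report
    API, not this table).
    """
    rows = []
    for rep in reports:
        for call in sorted(rep.sites, key=lambda c: c.site):
            rows.append(
                (rep.protein_id, call.site, call.peptide, f"{call.score:.4f}", call.call)
            )
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    handle, should_close = _as_handle(sink, "w")
    try:
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if should_close:
            handle.close()


def read_predictions(source) -> pd.DataFrame:
    """Read back a predictions TSV (round-trip convenience)."""
    handle, should_close = _as_handle(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype={"site": int, "score": float})
    finally:
        if should_close:
            handle.close()
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"predictions TSV lacks column(s) {missing}")
    return df
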