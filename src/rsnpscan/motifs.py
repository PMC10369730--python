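"""Transcription-factor motif handling.

Count matrices (PFMs) are read from TRANSFAC-format text (the format JASPAR
exports for bulk motif downloads) and converted to position weight matrices:
per-position base frequencies, base-2 log-odds against a background
distribution, and per-position Shannon entropy in bits. Flanking positions
whose entropy exceeds a threshold (default 1.9 bits, out of a 2-bit maximum
for DNA) carry almost no binding information and are trimmed before any
scanning or null-model calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, TextIO

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: log-odds assigned to a zero-frequency cell when no pseudocount is used;
#: stands in for -inf so downstream sums stay finite.
NEG_SENTINEL = -100.0

UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed; names the motif and line."""


@dataclass
class MotifCounts:
    """Raw per-position nucleotide counts for one motif (columns A,C,G,T)."""

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"motif {self.id}: counts must be positions x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"motif {self.id}: needs at least one position")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.id}: negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError(f"motif {self.id}: zero-sum count row")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax base (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))


@dataclass
class PWM:
    """Position weight matrix with frequencies, log-odds and entropies.

    ``trimmed_range`` records which span of the original count matrix is
    kept (0-based half-open); it is the identity span until
    :func:`trim_flanks` is applied.
    """

    id: str
    name: str
    freq: np.ndarray
    logodds: np.ndarray
    background: np.ndarray
    entropy: np.ndarray
    trimmed_range: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trimmed_range is None:
            self.trimmed_range = (0, self.freq.shape[0])

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.freq, axis=1))

    @property
    def max_score(self) -> float:
        """Best achievable window score (sum of per-position maxima)."""
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())


def column_entropy(freq_row: np.ndarray) -> float:
    """Shannon entropy of one frequency column in bits, 0*log2(0) = 0."""
    f = np.asarray(freq_row, dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def counts_to_pwm(
    m: MotifCounts,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PWM:
    """Convert a count matrix to a PWM.

    freq[p, b] = (counts[p, b] + pseudocount) / (rowsum + 4 * pseudocount);
    logodds[p, b] = log2(freq[p, b] / background[b]). A zero frequency
    (possible only with pseudocount 0) maps to :data:`NEG_SENTINEL`.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    rowsums = m.counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and np.any(rowsums == 0):
        raise ValueError(f"motif {m.id}: zero row sum with pseudocount=0")
    freq = (m.counts + pseudocount) / (rowsums + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(freq / bg)
    logodds[~np.isfinite(logodds)] = NEG_SENTINEL
    entropy = np.array([column_entropy(row) for row in freq])
    return PWM(id=m.id, name=m.name, freq=freq, logodds=logodds,
               background=bg, entropy=entropy)


def trim_flanks(pwm: PWM, threshold: float = 1.9) -> PWM:
    """Drop uninformative flanking positions (entropy > ``threshold`` bits).

    Positions are removed iteratively from each end while their entropy
    exceeds the threshold; interior positions are never touched. A motif
    whose every position is uninformative comes back with length 0 and a
    warning — the pipeline excludes such motifs.
    """
    n = len(pwm)
    start, end = 0, n
    while start < end and pwm.entropy[start] > threshold:
        start += 1
    while end > start and pwm.entropy[end - 1] > threshold:
        end -= 1
    if start == 0 and end == n:
        return pwm
    if start == end:
        warnings.warn(f"motif {pwm.id}: all positions above entropy "
                      f"{threshold}, motif dropped")
    base = pwm.trimmed_range[0]
    return PWM(
        id=pwm.id, name=pwm.name,
        freq=pwm.freq[start:end], logodds=pwm.logodds[start:end],
        background=pwm.background, entropy=pwm.entropy[start:end],
        trimmed_range=(base + start, base + end),
    )


# ---------------------------------------------------------------------------
# TRANSFAC / JASPAR I/O


def _finish_record(motif_id, name, rows, out, lineno):
    if motif_id is None and not rows:
        return
    if motif_id is None:
        raise MotifParseError(f"line {lineno}: count rows before any ID line")
    if not rows:
        raise MotifParseError(f"motif {motif_id}: record has no count rows")
    out.append(MotifCounts(id=motif_id, name=name or motif_id,
                           counts=np.array(rows, dtype=float)))


def read_transfac(stream: TextIO | str) -> list[MotifCounts]:
    """Parse TRANSFAC-format motif records (ID/DE ... P0 rows ... //)."""
    if isinstance(stream, str):
        stream = StringIO(stream)
    motifs: list[MotifCounts] = []
    motif_id: str | None = None
    name: str | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line in ("XX",):
            continue
        tag = line.split(maxsplit=1)[0]
        if tag == "//":
            _finish_record(motif_id, name, rows, motifs, lineno)
            motif_id, name, rows = None, None, []
        elif tag == "ID":
            motif_id = line.split(maxsplit=1)[1].strip() if " " in line else ""
        elif tag in ("DE", "NA"):
            name = line.split(maxsplit=1)[1].strip() if " " in line else ""
        elif tag in ("P0", "PO", "BF", "AC", "CC"):
            continue
        elif tag[0].isdigit():
            fields = line.split()
            # position index, 4 counts, optional consensus letter
            if len(fields) not in (5, 6):
                raise MotifParseError(
                    f"motif {motif_id}: line {lineno}: expected 4 count "
                    f"columns, got {len(fields) - 1}")
            try:
                rows.append([float(x) for x in fields[1:5]])
            except ValueError as exc:
                raise MotifParseError(
                    f"motif {motif_id}: line {lineno}: non-numeric count "
                    f"in {line!r}") from exc
        else:
            # unknown tag lines are tolerated, as in TRANSFAC flat files
            continue
    if motif_id is not None or rows:
        _finish_record(motif_id, name, rows, motifs, lineno)
    return motifs


def write_transfac(motifs: Iterable[MotifCounts], stream: TextIO) -> None:
    """Write motifs back out in TRANSFAC format (inverse of read_transfac)."""
    for m in motifs:
        stream.write(f"ID {m.id}\n")
        stream.write(f"DE {m.name}\n")
        stream.write("P0\tA\tC\tG\tT\n")
        for i, row in enumerate(m.counts):
            vals = "\t".join(f"{v:g}" for v in row)
            stream.write(f"{i + 1:02d}\t{vals}\n")
        stream.write("XX\n//\n")


def read_jaspar(stream: TextIO | str) -> list[MotifCounts]:
    """Parse JASPAR raw-count records: a '>' header then 4 base rows."""
    if isinstance(stream, str):
        stream = StringIO(stream)
    motifs: list[MotifCounts] = []
    header: str | None = None
    base_rows: dict[str, list[float]] = {}

    def flush(lineno):
        if header is None:
            return
        if set(base_rows) != set(BASES):
            raise MotifParseError(
                f"motif {header}: line {lineno}: expected rows for A,C,G,T")
        counts = np.array([base_rows[b] for b in BASES], dtype=float).T
        parts = header.split(maxsplit=1)
        motifs.append(MotifCounts(id=parts[0],
                                  name=parts[1] if len(parts) > 1 else parts[0],
                                  counts=counts))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            header = line[1:].strip()
            base_rows = {}
        else:
            base = line[0].upper()
            if base not in BASE_INDEX:
                raise MotifParseError(f"line {lineno}: unexpected row {line!r}")
            body = line[1:].strip().strip("[]").replace("[", " ").replace("]", " ")
            try:
                base_rows[base] = [float(x) for x in body.split()]
            except ValueError as exc:
                raise MotifParseError(
                    f"motif {header}: line {lineno}: non-numeric count") from exc
    flush(-1)
    return motifs


def read_motifs(path_or_stream, dialect: str = "transfac") -> list[MotifCounts]:
    """Read motifs from a file path or an open stream in the given dialect."""
    from pathlib import Path

    readers = {"transfac": read_transfac, "jaspar": read_jaspar}
    if dialect not in readers:
        raise ValueError(f"unknown motif dialect {dialect!r}")
    if isinstance(path_or_stream, Path) or (
            isinstance(path_or_stream, str) and "\n" not in path_or_stream):
        with open(path_or_stream) as fh:
            return readers[dialect](fh)
    return readers[dialect](path_or_stream)
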