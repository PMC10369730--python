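"""Random-access genome sequence, backed by pyfaidx or an in-memory dict."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> integer code; anything else (N, gaps) -> -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes A=0 C=1 G=2 T=3, other = -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class Genome:
    """Uniform fetch interface over a FASTA file or a dict of sequences.

    Coordinates are 0-based half-open throughout.
    """

    def __init__(self, source: str | Path | dict[str, str]):
        if isinstance(source, dict):
            self._seqs = {k: v.upper() for k, v in source.items()}
            self._fasta = None
        else:
            self._fasta = Fasta(str(source), sequence_always_upper=True)
            self._seqs = None

    def chroms(self) -> list[str]:
        if self._seqs is not None:
            return list(self._seqs)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(start, 0)
        end = min(end, self.length(chrom))
        if start >= end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end])

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
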