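"""Cycle-labelled pools of fixed-layout SELEX ligand sequences."""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

import numpy as np

from ._alphabet import encode_many


@dataclass
class ReadPool:
    """A collection of equal-length ligand reads from one selection cycle.

    Parameters
    ----------
    reads : list of str
        Ligand sequences (barcode5 + randomized region + barcode3).
    cycle : int
        Selection cycle the pool was sampled from (0 = unselected library).
    """

    reads: List[str]
    cycle: int = 0
    _codes: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.cycle < 0:
            raise ValueError("cycle must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def read_length(self) -> int:
        return len(self.reads[0]) if self.reads else 0

    def codes(self) -> np.ndarray:
        """Encoded (n, L) int8 matrix, cached after first use."""
        if self._codes is None:
            object.__setattr__(self, "_codes", encode_many(self.reads))
        return self._codes

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_text(cls, path, cycle: int | None = None) -> "ReadPool":
        """Read a plain-text pool, one sequence per line (.gz transparent).

        The cycle index is taken from a ``_cN`` filename suffix when not
        given explicitly.
        """
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            reads = [line.strip().upper() for line in fh if line.strip()]
        return cls(reads, cycle=_infer_cycle(path) if cycle is None else cycle)

    @classmethod
    def from_fastq(cls, path, cycle: int | None = None) -> "ReadPool":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        reads = []
        with opener(path, "rt") as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    reads.append(line.strip().upper())
        return cls(reads, cycle=_infer_cycle(path) if cycle is None else cycle)

    def to_text(self, path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for r in self.reads:
                fh.write(r + "\n")

    def to_fastq(self, path) -> None:
        """Write as FASTQ with a constant dummy quality of 'I' (Q40)."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for i, r in enumerate(self.reads):
                fh.write(f"@read{i}_c{self.cycle}\n{r}\n+\n{'I' * len(r)}\n")


def _infer_cycle(path: Path) -> int:
    stem = path.name
    for suffix in (".gz", ".fastq", ".fq", ".txt"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    if "_c" in stem:
        tail = stem.rsplit("_c", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 0


def load_pool(path, cycle: int | None = None) -> ReadPool:
    """Dispatch on extension: .fastq/.fq -> FASTQ, otherwise plain text."""
    name = str(path)
    if name.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")):
        return ReadPool.from_fastq(path, cycle=cycle)
    return ReadPool.from_text(path, cycle=cycle)
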