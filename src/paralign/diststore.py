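"""Symmetric N x N distance storage with interchangeable backends.

The memory backend holds the strict upper triangle as a flat float64 array;
the disk backend is a single fixed-size binary file (documented header +
offset-addressed float64 cells, little-endian) so the distance phase can
run out-of-core.  Unwritten cells hold NaN — a bit pattern outside [0, 1] —
so reading an incomplete matrix is an error, not a silent zero.

Also here: the canonical pair enumeration shared by every stage, and the
per-pair FASTA spool used by disk-mode jobs.
"""
from __future__ import annotations

import math
import os
import shutil
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .io_formats import SequenceSet, write_fasta

MAGIC = b"DMX1"
VERSION = 1
CELL_WIDTH = 8
HEADER = struct.Struct("<4sIQI")  # magic, version, N, cell width
DEFAULT_STORE_NAME = "matrix-file080.tmp"


class IncompleteMatrixError(RuntimeError):
    pass


def n_pairs(N: int) -> int:
    """Number of unordered pairs over N sequences: N(N-1)/2."""
    return N * (N - 1) // 2


def pair_index(i: int, j: int, N: int) -> int:
    """Canonical rank of pair (i, j), row-major over i < j."""
    if not (0 <= i < j < N):
        raise ValueError(f"need 0 <= i < j < N, got (i={i}, j={j}, N={N})")
    return i * (2 * N - i - 1) // 2 + (j - i - 1)


def pair_from_index(P: int, N: int) -> Tuple[int, int]:
    """Inverse of :func:`pair_index`."""
    if not (0 <= P < n_pairs(N)):
        raise ValueError(f"pair rank {P} out of range for N={N}")
    # smallest i with cumulative pairs past P: solve the triangular rank
    i = int(N - 2 - math.floor((math.sqrt(8.0 * (n_pairs(N) - 1 - P) + 1) - 1) / 2))
    i = min(max(i, 0), N - 2)
    base = pair_index(i, i + 1, N)
    while base > P:  # guard float roundoff at large N
        i -= 1
        base = pair_index(i, i + 1, N)
    while i < N - 2 and pair_index(i + 1, i + 2, N) <= P:
        i += 1
        base = pair_index(i, i + 1, N)
    return i, i + 1 + (P - base)


def iter_pairs(N: int) -> Iterator[Tuple[int, int, int]]:
    """Yield (P, i, j) in canonical order."""
    P = 0
    for i in range(N - 1):
        for j in range(i + 1, N):
            yield P, i, j
            P += 1


class DistanceStore:
    """Common behaviour of both backends: symmetric addressing, zero
    diagonal, completeness accounting."""

    N: int
    mode: str

    def _canon(self, i: int, j: int) -> Tuple[int, int]:
        if not (0 <= i < self.N and 0 <= j < self.N):
            raise ValueError(f"indices ({i}, {j}) out of range for N={self.N}")
        return (i, j) if i < j else (j, i)

    def put(self, i: int, j: int, d: float) -> None:
        if i == j:
            raise ValueError("diagonal cells are fixed at 0 and never written")
        if not (0.0 <= d <= 1.0) or math.isnan(d):
            raise ValueError(f"distance must lie in [0, 1], got {d!r}")
        i, j = self._canon(i, j)
        self._write_cell(pair_index(i, j, self.N), d)

    def get(self, i: int, j: int) -> float:
        if i == j:
            if not 0 <= i < self.N:
                raise ValueError(f"index {i} out of range for N={self.N}")
            return 0.0
        i, j = self._canon(i, j)
        val = self._read_cell(pair_index(i, j, self.N))
        if math.isnan(val):
            raise IncompleteMatrixError(f"distance cell ({i}, {j}) was never written")
        return val

    def cells(self) -> np.ndarray:
        raise NotImplementedError

    def _write_cell(self, P: int, d: float) -> None:
        raise NotImplementedError

    def _read_cell(self, P: int) -> float:
        raise NotImplementedError

    def n_written(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.cells())))

    def is_complete(self) -> bool:
        return self.n_written() == n_pairs(self.N)

    def to_array(self) -> np.ndarray:
        """Full symmetric N x N matrix; raises on unwritten cells."""
        flat = self.cells()
        if np.isnan(flat).any():
            P = int(np.flatnonzero(np.isnan(flat))[0])
            i, j = pair_from_index(P, self.N)
            raise IncompleteMatrixError(f"distance cell ({i}, {j}) was never written")
        D = np.zeros((self.N, self.N))
        iu = np.triu_indices(self.N, k=1)
        D[iu] = flat
        D[(iu[1], iu[0])] = flat
        return D

    def close(self) -> None:
        pass

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class MemoryDistanceStore(DistanceStore):
    mode = "memory"

    def __init__(self, N: int):
        self.N = N
        self._cells = np.full(n_pairs(N), np.nan)

    def _write_cell(self, P: int, d: float) -> None:
        self._cells[P] = d

    def _read_cell(self, P: int) -> float:
        return float(self._cells[P])

    def cells(self) -> np.ndarray:
        return self._cells.copy()


class DiskDistanceStore(DistanceStore):
    mode = "disk"

    def __init__(self, path, N: int, _create: bool):
        self.path = Path(path)
        self.N = N
        self._fh = open(self.path, "r+b")

    def _offset(self, P: int) -> int:
        return HEADER.size + CELL_WIDTH * P

    def _write_cell(self, P: int, d: float) -> None:
        self._fh.seek(self._offset(P))
        self._fh.write(struct.pack("<d", d))

    def _read_cell(self, P: int) -> float:
        self._fh.seek(self._offset(P))
        return struct.unpack("<d", self._fh.read(CELL_WIDTH))[0]

    def cells(self) -> np.ndarray:
        self._fh.flush()
        self._fh.seek(HEADER.size)
        return np.fromfile(self._fh, dtype="<f8", count=n_pairs(self.N))

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.flush()
            self._fh.close()

    @classmethod
    def create(cls, path, N: int) -> "DiskDistanceStore":
        path = Path(path)
        required = HEADER.size + CELL_WIDTH * n_pairs(N)
        free = shutil.disk_usage(path.parent).free
        if required > free:
            raise OSError(
                f"insufficient disk capacity for distance store: required bytes = "
                f"header + 8*N(N-1)/2 = {required}, free = {free}"
            )
        with open(path, "wb") as fh:
            fh.write(HEADER.pack(MAGIC, VERSION, N, CELL_WIDTH))
            sentinel = np.full(min(n_pairs(N), 1 << 16), np.nan, dtype="<f8")
            remaining = n_pairs(N)
            while remaining > 0:
                chunk = min(remaining, len(sentinel))
                fh.write(sentinel[:chunk].tobytes())
                remaining -= chunk
        return cls(path, N, _create=False)

    @classmethod
    def open_existing(cls, path) -> "DiskDistanceStore":
        path = Path(path)
        with open(path, "rb") as fh:
            magic, version, N, width = HEADER.unpack(fh.read(HEADER.size))
        if magic != MAGIC or width != CELL_WIDTH:
            raise ValueError(f"{path} is not a distance-store file")
        return cls(path, int(N), _create=False)


def store_create(N: int, mode: str = "memory", path: Optional[os.PathLike] = None,
                 filename: str = DEFAULT_STORE_NAME) -> DistanceStore:
    """Create an empty store for N sequences in the requested mode.  Disk
    mode places the single matrix file inside the ``path`` workspace."""
    if N < 2:
        raise ValueError(f"a distance store needs N >= 2 sequences, got {N}")
    if mode == "memory":
        return MemoryDistanceStore(N)
    if mode == "disk":
        if path is None:
            raise ValueError("disk mode needs a workspace path")
        workspace = Path(path)
        workspace.mkdir(parents=True, exist_ok=True)
        return DiskDistanceStore.create(workspace / filename, N)
    raise ValueError(f"unknown storage mode {mode!r}")


def store_open(path) -> DiskDistanceStore:
    """Reopen a disk store written by a previous process."""
    return DiskDistanceStore.open_existing(path)


# ---------------------------------------------------------------------------
# Pair spool


@dataclass
class PairSpool:
    """One two-record FASTA file per pair task, named ``<stem>%09d.fa`` with
    the 9-digit suffix equal to the pair rank P (strictly increasing)."""

    directory: Path
    stem: str = "pair-"
    count: int = 0

    def path_for(self, P: int) -> Path:
        return self.directory / f"{self.stem}{P:09d}.fa"

    def files(self) -> List[Path]:
        return sorted(self.directory.glob(f"{self.stem}*.fa"))


def iter_spool_pairs(seqset: SequenceSet, spool: PairSpool) -> Iterator[Path]:
    """Write pair files lazily, yielding each path as it is created — the
    full spool never needs to exist at once."""
    spool.directory.mkdir(parents=True, exist_ok=True)
    if not os.access(spool.directory, os.W_OK):
        raise OSError(f"spool directory {spool.directory} is not writable")
    for P, i, j in iter_pairs(seqset.N):
        path = spool.path_for(P)
        write_fasta([seqset[i], seqset[j]], path)
        spool.count = P + 1
        yield path


def spool_pairs(seqset: SequenceSet, directory, stem: str = "pair-") -> PairSpool:
    """Eagerly write the whole spool (N(N-1)/2 files) and return it."""
    spool = PairSpool(Path(directory), stem=stem)
    spool.directory.mkdir(parents=True, exist_ok=True)
    if not os.access(spool.directory, os.W_OK):
        raise OSError(f"spool directory {spool.directory} is not writable")
    for _ in iter_spool_pairs(seqset, spool):
        pass
    return spool
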