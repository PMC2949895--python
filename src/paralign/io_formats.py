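"""Sequence and alignment I/O: FASTA, Clustal ``.aln``, Newick, and the
bundled substitution-matrix catalogue.

FASTA parsing is delegated to :mod:`Bio.SeqIO`; the Clustal and Newick
readers here are deliberately minimal — they exist so that every writer in
the package has an in-house round-trip check.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

PROTEIN_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
DNA_RESIDUES = "ACGT"
UNKNOWN = {"protein": "X", "dna": "N"}
GAP = "-"

#: ClustalX conservation groups: a column scores ':' when all of its
#: residues fall inside one strong group, '.' for a weak group.
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
WEAK_GROUPS = (
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
    "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
)

_MATRIX_DIR = Path(__file__).parent / "matrices"
_NEWICK_META = set("()[]':;, \t\n")


class DuplicateIdError(ValueError):
    pass


class InvalidResidueError(ValueError):
    pass


class UnknownMatrixError(KeyError):
    pass


def alphabet_residues(alphabet: str, with_unknown: bool = True) -> str:
    if alphabet == "protein":
        base = PROTEIN_RESIDUES
    elif alphabet == "dna":
        base = DNA_RESIDUES
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return base + UNKNOWN[alphabet] if with_unknown else base


@dataclass(frozen=True)
class SequenceRecord:
    """One named, ungapped sequence."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self):
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        valid = set(alphabet_residues(self.alphabet))
        for pos, ch in enumerate(self.residues):
            if ch not in valid:
                raise InvalidResidueError(
                    f"sequence {self.id!r}: invalid {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of records sharing one alphabet; the unit of an
    alignment job."""

    records: List[SequenceRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("a SequenceSet needs at least one record")
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
        alphabets = {rec.alphabet for rec in self.records}
        if len(alphabets) != 1:
            raise ValueError(f"mixed alphabets in one set: {sorted(alphabets)}")

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def alphabet(self) -> str:
        return self.records[0].alphabet

    @property
    def ids(self) -> List[str]:
        return [rec.id for rec in self.records]

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    def __len__(self) -> int:
        return len(self.records)


def _guess_alphabet(residue_text: str) -> str:
    return "dna" if set(residue_text) <= set(DNA_RESIDUES + "N") else "protein"


def read_fasta(path, alphabet: Optional[str] = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Ids are the first whitespace-delimited token after ``>``; residues are
    uppercased with line breaks removed.  With ``alphabet=None`` the
    alphabet is inferred (pure ACGT/N content reads as DNA).
    """
    raw = [(r.id, r.description, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise ValueError(f"no FASTA records found in {path}")
    if alphabet is None:
        alphabet = _guess_alphabet("".join(seq for _, _, seq in raw))
    records = []
    for rid, desc, seq in raw:
        desc = desc[len(rid):].strip() if desc.startswith(rid) else desc
        records.append(SequenceRecord(rid, seq, desc, alphabet))
    return SequenceSet(records)


def write_fasta(seqset: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in seqset:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for start in range(0, len(rec.residues), width):
                fh.write(rec.residues[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# Clustal .aln


def _conservation_char(column: str, alphabet: str) -> str:
    if GAP in column:
        return " "
    if len(set(column)) == 1:
        return "*"
    if alphabet == "protein":
        residues = set(column)
        if any(residues <= set(g) for g in STRONG_GROUPS):
            return ":"
        if any(residues <= set(g) for g in WEAK_GROUPS):
            return "."
    return " "


def write_clustal_aln(rows: Mapping[str, str], path, alphabet: str = "protein") -> None:
    """Write an alignment (ordered mapping id -> gapped row) in Clustal
    format: 60-column blocks, fixed-width name column, conservation line."""
    rows = dict(rows)
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    L = lengths.pop()
    names = {rid: rid[:30] for rid in rows}
    width = max(len(n) for n in names.values()) + 3
    cons = "".join(
        _conservation_char("".join(row[c] for row in rows.values()), alphabet)
        for c in range(L)
    )
    with open(path, "w") as fh:
        fh.write("CLUSTAL multiple sequence alignment\n\n")
        for start in range(0, L, 60):
            for rid, row in rows.items():
                fh.write(f"{names[rid]:<{width}}{row[start:start + 60]}\n")
            fh.write(f"{'':<{width}}{cons[start:start + 60]}\n\n")


def read_clustal_aln(path) -> Dict[str, str]:
    """Minimal Clustal reader (round-trip checks): returns id -> gapped row."""
    rows: Dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].upper().startswith("CLUSTAL"):
        raise ValueError(f"{path} is not a Clustal alignment file")
    for line in lines[1:]:
        if not line.strip() or line.startswith((" ", "\t")):
            continue  # blank or conservation line
        name, _, chunk = line.partition(" ")
        chunk = chunk.strip().split()[0] if chunk.strip() else ""
        if chunk:
            rows[name] = rows.get(name, "") + chunk
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return rows


# ---------------------------------------------------------------------------
# Newick


@dataclass
class Clade:
    """Tree node: leaves carry a ``name``; ``length`` is the branch to the
    parent (``None`` at the root)."""

    name: Optional[str] = None
    length: Optional[float] = None
    children: List["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["Clade"]:
        if self.is_leaf:
            return [self]
        out: List[Clade] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> List[str]:
        return [lf.name for lf in self.leaves()]


def _quote_label(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: Clade) -> str:
    if node.is_leaf:
        s = _quote_label(node.name or "")
    else:
        s = "(" + ",".join(_newick_node(ch) for ch in node.children) + ")"
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree, path=None) -> str:
    """Serialize a tree (a :class:`Clade` or anything with a ``root``
    attribute) to Newick.  Returns the string; writes it when ``path``."""
    root = getattr(tree, "root", tree)
    text = _newick_node(root) + ";\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> Clade:
    """Minimal Newick parser (round-trip checks). ``source`` is a path or a
    Newick string."""
    text = str(source)
    try:
        p = Path(text)
        if p.exists() and not text.rstrip().endswith(";"):
            text = p.read_text()
    except OSError:
        pass
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0

    def parse_clade() -> Clade:
        nonlocal pos
        node = Clade()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if text[pos] == ",":
                    pos += 1
                elif text[pos] == ")":
                    pos += 1
                    break
        node.name = parse_label() or None
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", text[pos:])
            node.length = float(m.group())
            pos += m.end()
        return node

    def parse_label() -> str:
        nonlocal pos
        if pos < len(text) and text[pos] == "'":
            pos += 1
            out = []
            while True:
                if text[pos] == "'":
                    if pos + 1 < len(text) and text[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                    else:
                        pos += 1
                        break
                else:
                    out.append(text[pos])
                    pos += 1
            return "".join(out)
        m = re.match(r"[^():,;\[\]]*", text[pos:])
        pos += m.end()
        return m.group().strip()

    root = parse_clade()
    if text[pos] != ";":
        raise ValueError(f"trailing characters in Newick at offset {pos}")
    return root


# ---------------------------------------------------------------------------
# Substitution matrices


class SubstitutionMatrix:
    """Symmetric residue scoring table over one alphabet.

    Unknown residues (X for protein, N for DNA) missing from the source grid
    are scored at the matrix minimum.
    """

    def __init__(self, name: str, alphabet: str, residues: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (len(residues), len(residues)):
            raise ValueError("score grid shape does not match residue list")
        if not np.array_equal(scores, scores.T):
            raise ValueError(f"matrix {name} is not symmetric")
        unknown = UNKNOWN[alphabet]
        if unknown not in residues:
            lo = scores.min()
            k = len(residues)
            ext = np.full((k + 1, k + 1), lo)
            ext[:k, :k] = scores
            residues += unknown
            scores = ext
        expected = set(alphabet_residues(alphabet))
        if not expected <= set(residues):
            missing = "".join(sorted(expected - set(residues)))
            raise ValueError(f"matrix {name} misses residues {missing!r}")
        self.name = name
        self.alphabet = alphabet
        self.residues = residues
        self.scores = scores
        self._index = {r: i for i, r in enumerate(residues)}

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to integer codes into the score grid."""
        try:
            return np.fromiter(
                (self._index[ch] for ch in residues), dtype=np.int64, count=len(residues)
            )
        except KeyError as exc:
            raise InvalidResidueError(
                f"residue {exc.args[0]!r} is not scored by matrix {self.name}"
            ) from None

    def min_score(self) -> float:
        return float(self.scores.min())

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name}, {self.alphabet}, {len(self.residues)} residues)"


def list_weight_matrices(alphabet: Optional[str] = None) -> List[str]:
    """Names of every bundled matrix, optionally filtered by alphabet."""
    names = []
    for path in sorted(_MATRIX_DIR.glob("*.mat")):
        if alphabet is not None:
            header = path.read_text().splitlines()[0]
            if f"({alphabet})" not in header:
                continue
        names.append(path.stem)
    return names


def load_weight_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled matrix grid by name (e.g. ``BLOSUM62``, ``GONNET250``)."""
    path = _MATRIX_DIR / f"{name}.mat"
    if not path.exists():
        raise UnknownMatrixError(
            f"no bundled matrix named {name!r}; available: {', '.join(list_weight_matrices())}"
        )
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0]
    alphabet = "dna" if "(dna)" in header else "protein"
    residues = "".join(lines[1].split())
    grid = []
    for ln in lines[2:]:
        parts = ln.split()
        if parts[0] != residues[len(grid)]:
            raise ValueError(f"malformed matrix grid in {path}")
        grid.append([float(x) for x in parts[1:]])
    return SubstitutionMatrix(name, alphabet, residues, np.array(grid))


# ---------------------------------------------------------------------------
# Sequence search


def find_records(seqset: SequenceSet, query: str) -> List[Tuple[str, int]]:
    """All exact occurrences of ``query`` (0-based positions, record order)."""
    if not query:
        raise ValueError("query must be non-empty")
    query = query.upper()
    hits: List[Tuple[str, int]] = []
    for rec in seqset:
        start = rec.residues.find(query)
        while start != -1:
            hits.append((rec.id, start))
            start = rec.residues.find(query, start + 1)
    return hits
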