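"""Baum-Ragan MRP matrix construction and relaxed-PHYLIP / NEXUS I/O.

Each internal edge of each source tree contributes one column over {0,1,?}:
0 for the taxa on one side of the edge, 1 for the taxa on the other side,
and ? for every taxon absent from that tree. Under reversible Fitch
parsimony the polarity of each column is irrelevant, so it is fixed by a
deterministic rule: state 1 goes to the canonical side of the bipartition
(the side excluding the lexicographically smallest taxon of that source
tree's leaf set).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trees import SourceProfile, Tree

# cell codes
ZERO, ONE, MISSING = 0, 1, 2
_SYMBOLS = {ZERO: "0", ONE: "1", MISSING: "?"}


@dataclass
class CharacterMatrix:
    """A taxa x columns matrix over {0,1,?} with per-column provenance.

    ``data`` is a (ntax, ncol) uint8 array with codes 0, 1 and 2 ('?').
    ``provenance[j]`` records where column j came from: a
    ``(source_tree_index, edge_id)`` pair, or ``("external", j)`` for
    matrices read from disk.
    """

    taxa: list
    data: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxon list")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon label in matrix")
        if self.data.size and self.data.max() > MISSING:
            raise ValueError("matrix entries must be 0, 1 or ? codes")
        if not self.provenance:
            self.provenance = [("external", j) for j in range(self.ncol)]

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def ncol(self) -> int:
        return self.data.shape[1]

    def row(self, taxon) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def column_bipartition_sides(self):
        """For each column, the frozenset of taxa in state 1 and in state 0."""
        out = []
        arr = self.data
        for j in range(self.ncol):
            ones = frozenset(t for i, t in enumerate(self.taxa) if arr[i, j] == ONE)
            zeros = frozenset(t for i, t in enumerate(self.taxa) if arr[i, j] == ZERO)
            out.append((ones, zeros))
        return out


def encode_baum_ragan(profile: SourceProfile) -> CharacterMatrix:
    """Build the MRP matrix of a source-tree profile.

    Columns are ordered by source tree (profile order) and, within a tree,
    by a deterministic preorder traversal from the tree's anchor; every
    column has at least two 0s and two 1s because only internal (non-trivial)
    edges are encoded.
    """
    taxa = sorted(profile.taxa)
    index = {t: i for i, t in enumerate(taxa)}
    columns = []
    provenance = []
    for ti, tree in enumerate(profile):
        leafset = tree.leaf_labels
        ref = min(leafset)
        below = {}
        edge_id = 0
        # preorder for deterministic edge ids, postorder leafsets first
        for node in tree.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        for node in tree.preorder():
            if node.parent is None:
                continue
            side = below[id(node)]
            if not 2 <= len(side) <= len(leafset) - 2:
                continue
            if ref in side:
                side = leafset - side  # canonical: state 1 excludes ref
            col = np.full(len(taxa), MISSING, dtype=np.uint8)
            for t in leafset:
                col[index[t]] = ONE if t in side else ZERO
            columns.append(col)
            provenance.append((ti, edge_id))
            edge_id += 1
    data = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(taxa), 0), dtype=np.uint8)
    )
    return CharacterMatrix(taxa=taxa, data=data, provenance=provenance)


# ---------------------------------------------------------------------- #
# I/O: relaxed PHYLIP and NEXUS (datatype=standard)
# ---------------------------------------------------------------------- #
def _sanitize_names(taxa):
    """Replace whitespace in labels; emit a name map warning when needed."""
    name_map = {}
    seen = set()
    for t in taxa:
        clean = re.sub(r"\s+", "_", t)
        while clean in seen:
            clean += "_"
        seen.add(clean)
        name_map[t] = clean
    if any(k != v for k, v in name_map.items()):
        changed = {k: v for k, v in name_map.items() if k != v}
        warnings.warn(f"taxon labels sanitized for output: {changed}")
    return name_map


def write_matrix(matrix: CharacterMatrix, format: str = "relaxed-phylip") -> str:
    """Serialize to relaxed-PHYLIP or NEXUS (datatype=standard) text."""
    name_map = _sanitize_names(matrix.taxa)
    rows = [
        (name_map[t], "".join(_SYMBOLS[c] for c in matrix.data[i]))
        for i, t in enumerate(matrix.taxa)
    ]
    if format == "relaxed-phylip":
        width = max(len(n) for n, _ in rows) + 2
        lines = [f"{matrix.ntax} {matrix.ncol}"]
        lines += [f"{n:<{width}}{s}" for n, s in rows]
        return "\n".join(lines) + "\n"
    if format == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.ncol};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "    MATRIX",
        ]
        width = max(len(n) for n, _ in rows) + 2
        lines += [f"        {n:<{width}}{s}" for n, s in rows]
        lines += ["    ;", "END;"]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown matrix format: {format}")


def write_matrix_file(matrix: CharacterMatrix, path, format: str = "relaxed-phylip") -> None:
    with open(path, "w") as fh:
        fh.write(write_matrix(matrix, format))


_DECODE = {"0": ZERO, "1": ONE, "?": MISSING, "-": MISSING}


def _decode_row(name, symbols):
    try:
        return name, np.array([_DECODE[ch] for ch in symbols], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid state symbol {exc} in row for {name!r}") from None


def read_matrix(text: str, format: str = "relaxed-phylip") -> CharacterMatrix:
    """Parse a {0,1,?} matrix; '-' is accepted as an alias of '?'."""
    if format == "relaxed-phylip":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty matrix file")
        header = lines[0].split()
        if len(header) != 2:
            raise ValueError("relaxed-PHYLIP header must be 'ntax ncol'")
        ntax, ncol = int(header[0]), int(header[1])
        body = lines[1:]
        if len(body) != ntax:
            raise ValueError(f"header says {ntax} taxa but found {len(body)} rows")
        taxa, cols = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 2:
                raise ValueError(f"malformed matrix row: {ln!r}")
            name, symbols = parts[0], "".join(parts[1:])
            if len(symbols) != ncol:
                raise ValueError(
                    f"row for {name!r} has {len(symbols)} states, expected {ncol}"
                )
            name, row = _decode_row(name, symbols)
            taxa.append(name)
            cols.append(row)
        return CharacterMatrix(taxa=taxa, data=np.vstack(cols))
    if format == "nexus":
        m = re.search(r"MATRIX(.*?);", text, flags=re.S | re.I)
        if m is None:
            raise ValueError("no MATRIX block found in NEXUS input")
        dim = re.search(r"NTAX\s*=\s*(\d+)\s+NCHAR\s*=\s*(\d+)", text, flags=re.I)
        taxa, cols = [], []
        for ln in m.group(1).splitlines():
            parts = ln.split()
            if not parts:
                continue
            name, row = _decode_row(parts[0], "".join(parts[1:]))
            taxa.append(name)
            cols.append(row)
        matrix = CharacterMatrix(taxa=taxa, data=np.vstack(cols))
        if dim is not None and (matrix.ntax, matrix.ncol) != (int(dim.group(1)), int(dim.group(2))):
            raise ValueError("NEXUS DIMENSIONS do not match the MATRIX block")
        return matrix
    raise ValueError(f"unknown matrix format: {format}")


def read_matrix_file(path, format: str = "relaxed-phylip") -> CharacterMatrix:
    with open(path) as fh:
        return read_matrix(fh.read(), format)
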