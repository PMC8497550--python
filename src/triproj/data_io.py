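"""Edge-list parsing, adjacency construction, and miRNA-axis alignment.

The package consumes two binary association networks given as 2-column
delimited text files: lncRNA--miRNA pairs and miRNA--disease pairs.  This
module cleans those edge lists, builds indexed 0/1 adjacency matrices and
reconciles the two networks onto a single ordered miRNA axis, which is the
shape every downstream stage assumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParseError

_DELIMITERS = ("\t", ",", ";")

#: identifier kinds understood by the normaliser: RNA symbols are
#: conventionally upper-case, disease names lower-case.
_CASEFOLD = {"rna": str.upper, "disease": str.lower}


def _clean_name(raw: str, kind: str | None) -> str:
    """Trim, collapse internal whitespace runs, and case-fold by kind."""
    name = " ".join(raw.split())
    if kind is not None:
        try:
            name = _CASEFOLD[kind](name)
        except KeyError:
            raise ValueError(f"unknown identifier kind {kind!r}") from None
    return name


@dataclass
class BipartiteNetwork:
    """Binary association network between two ordered entity axes.

    ``adjacency[i, j] == 1`` iff the pair ``(row_names[i], col_names[j])``
    appears in the cleaned edge list; all entries are 0/1 and the name
    lists contain no duplicates.
    """

    row_names: list[str]
    col_names: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.row_names = list(self.row_names)
        self.col_names = list(self.col_names)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (len(self.row_names), len(self.col_names)):
            raise DataError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"name lists ({len(self.row_names)} x {len(self.col_names)})"
            )
        if len(set(self.row_names)) != len(self.row_names):
            raise DataError("duplicate row names")
        if len(set(self.col_names)) != len(self.col_names):
            raise DataError("duplicate column names")
        if not np.isin(self.adjacency, (0.0, 1.0)).all():
            raise DataError("adjacency entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.adjacency.shape

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Edge list in row-major order."""
        rows, cols = np.nonzero(self.adjacency)
        return [(self.row_names[i], self.col_names[j]) for i, j in zip(rows, cols)]


@dataclass
class AlignedTriple:
    """The two bipartite layers reconciled onto one shared miRNA axis."""

    a_lm: BipartiteNetwork  # lncRNA x miRNA
    a_md: BipartiteNetwork  # miRNA x disease

    def __post_init__(self) -> None:
        if self.a_lm.col_names != self.a_md.row_names:
            raise DataError("miRNA axes of the two networks differ")

    @property
    def lncrna_names(self) -> list[str]:
        return self.a_lm.row_names

    @property
    def mirna_names(self) -> list[str]:
        return self.a_lm.col_names

    @property
    def disease_names(self) -> list[str]:
        return self.a_md.col_names


def _detect_delimiter(line: str) -> str:
    for d in _DELIMITERS:
        if d in line:
            return d
    raise ParseError(
        "could not detect a delimiter (tried tab, comma, semicolon) "
        f"in line: {line!r}"
    )


def _looks_like_header(rows: list[tuple[str, str]]) -> bool:
    """Line 1 is a header iff neither of its fields reappears in its column."""
    if len(rows) < 2:
        return False
    first_a, first_b = rows[0]
    col_a = {a for a, _ in rows[1:]}
    col_b = {b for _, b in rows[1:]}
    return first_a not in col_a and first_b not in col_b


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    normalize: bool = False,
    kinds: tuple[str, str] = ("rna", "rna"),
) -> list[tuple[str, str]]:
    """Parse a 2-column delimited edge list into deduplicated pairs.

    Parameters
    ----------
    path:
        Text file; each non-empty line holds at least two delimited fields.
        An optional single header line is auto-detected (its fields never
        reappear as identifiers).
    delimiter:
        Field separator.  When ``None`` it is auto-detected among tab,
        comma and semicolon.
    normalize:
        When true, identifiers are trimmed, internal whitespace runs are
        collapsed, and they are case-folded according to ``kinds``
        (``"rna"`` -> upper case, ``"disease"`` -> lower case) before
        deduplication.
    kinds:
        Identifier kind of the first and second column; only consulted
        when ``normalize`` is on.

    Returns
    -------
    Deduplicated ``(first, second)`` pairs in order of first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    raw_lines = path.read_text().splitlines()

    rows: list[tuple[str, str]] = []
    sep = delimiter
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.strip():
            continue
        if sep is None:
            sep = _detect_delimiter(line)
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected >= 2 fields, got {line!r}")
        rows.append((fields[0], fields[1]))

    if not rows:
        raise ParseError(f"{path}: empty edge list")
    if _looks_like_header(rows):
        rows = rows[1:]

    if normalize:
        ka, kb = kinds
        rows = [(_clean_name(a, ka), _clean_name(b, kb)) for a, b in rows]

    return list(dict.fromkeys(rows))


def write_edge_list(
    pairs: Iterable[tuple[str, str]] | BipartiteNetwork,
    path: str | Path,
    delimiter: str = "\t",
    header: tuple[str, str] | None = ("source", "target"),
) -> None:
    """Write pairs (or a network's edges) as 2-column delimited text.

    A header line is written by default so that the reader's header
    auto-detection can never mistake a data line for one (round-trip
    safety); pass ``header=None`` to suppress it.
    """
    if isinstance(pairs, BipartiteNetwork):
        pairs = pairs.pairs()
    lines = []
    if header is not None:
        lines.append(delimiter.join(header))
    lines.extend(delimiter.join(p) for p in pairs)
    Path(path).write_text("\n".join(lines) + "\n")


def build_network(pairs: Sequence[tuple[str, str]]) -> BipartiteNetwork:
    """Build a binary adjacency matrix from an edge list.

    Row/column name order follows first appearance in ``pairs``; the sum of
    the adjacency equals the number of distinct pairs.
    """
    pairs = list(dict.fromkeys(tuple(p) for p in pairs))
    if not pairs:
        raise DataError("empty pair list")
    row_names = list(dict.fromkeys(a for a, _ in pairs))
    col_names = list(dict.fromkeys(b for _, b in pairs))
    ri = {n: i for i, n in enumerate(row_names)}
    ci = {n: j for j, n in enumerate(col_names)}
    adj = np.zeros((len(row_names), len(col_names)))
    for a, b in pairs:
        adj[ri[a], ci[b]] = 1.0
    return BipartiteNetwork(row_names, col_names, adj)


def _reindex_cols(net: BipartiteNetwork, cols: list[str]) -> np.ndarray:
    out = np.zeros((len(net.row_names), len(cols)))
    idx = {n: j for j, n in enumerate(net.col_names)}
    for j, name in enumerate(cols):
        if name in idx:
            out[:, j] = net.adjacency[:, idx[name]]
    return out


def _reindex_rows(net: BipartiteNetwork, rows: list[str]) -> np.ndarray:
    out = np.zeros((len(rows), len(net.col_names)))
    idx = {n: i for i, n in enumerate(net.row_names)}
    for i, name in enumerate(rows):
        if name in idx:
            out[i, :] = net.adjacency[idx[name], :]
    return out


def align_on_mirna(
    lm: BipartiteNetwork,
    md: BipartiteNetwork,
    mode: str = "intersection",
) -> AlignedTriple:
    """Reconcile the lncRNA--miRNA and miRNA--disease layers on one axis.

    In ``intersection`` mode (default), miRNAs absent from either network
    are dropped from both; lncRNAs and diseases left with all-zero
    profiles are retained (their similarity is defined as 0 downstream).
    In ``union`` mode, missing miRNA columns/rows are zero-padded.  The
    shared axis keeps ``lm`` column order, with union extras appended in
    ``md`` row order.
    """
    if mode not in ("intersection", "union"):
        raise DataError(f"unknown alignment mode {mode!r}")
    md_set = set(md.row_names)
    if mode == "intersection":
        shared = [m for m in lm.col_names if m in md_set]
        if not shared:
            raise DataError("no shared miRNAs between the two networks")
    else:
        lm_set = set(lm.col_names)
        shared = list(lm.col_names) + [m for m in md.row_names if m not in lm_set]
    a_lm = BipartiteNetwork(lm.row_names, shared, _reindex_cols(lm, shared))
    a_md = BipartiteNetwork(shared, md.col_names, _reindex_rows(md, shared))
    return AlignedTriple(a_lm, a_md)


def write_matrix(
    row_names: Sequence[str],
    col_names: Sequence[str],
    values: np.ndarray,
    path: str | Path,
) -> None:
    """Dump a labeled dense matrix as tab-separated text."""
    df = pd.DataFrame(np.asarray(values), index=list(row_names), columns=list(col_names))
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a labeled dense matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(n) for n in df.index], [str(n) for n in df.columns], df.to_numpy(dtype=float)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
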