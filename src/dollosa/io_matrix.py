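"""Reading and writing single-cell genotype matrices, rate files and DOT trees.

Matrix files are plain text, whitespace separated, over the tokens
``0`` (mutation absent), ``1`` (present), ``2`` or ``?`` (missing).  Two
layouts are supported: cells-as-rows (default) and mutations-as-rows,
which is transposed on load.  Labels come from optional one-name-per-line
side files, keeping the matrix purely numeric.  Trees are emitted as
Graphviz DOT digraphs with loss nodes styled red; a reader for the DOT
subset this package emits allows round trips for scoring and display.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .dollo_tree import DolloPhylogeny, NodeKind, NodeLabel

__all__ = [
    "MISSING",
    "SCSMatrix",
    "ErrorRates",
    "MatrixFormatError",
    "read_scs_matrix",
    "write_scs_matrix",
    "read_rate_file",
    "read_labels",
    "write_dot",
    "read_dot",
]

#: sentinel for an unobserved matrix entry ("?" / "2" in files)
MISSING: int = -1

_TOKEN_MAP = {"0": 0, "1": 1, "2": MISSING, "?": MISSING}


class MatrixFormatError(ValueError):
    """Malformed matrix / rate / label file."""


@dataclass
class SCSMatrix:
    """Observed n×m ternary single-cell genotype matrix I.

    ``entries`` holds 0 (absent), 1 (present) or :data:`MISSING`; rows are
    cells, columns are mutations.
    """

    entries: np.ndarray
    cell_labels: list[str] = field(default_factory=list)
    mutation_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2 or self.entries.shape[0] < 1 or self.entries.shape[1] < 1:
            raise ValueError("matrix must be 2-D with n >= 1 and m >= 1")
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"entry ({i},{j}) is not 0, 1 or MISSING")
        n, m = self.entries.shape
        if not self.cell_labels:
            self.cell_labels = [f"cell{i}" for i in range(n)]
        if not self.mutation_labels:
            self.mutation_labels = [f"mut{j}" for j in range(m)]
        if len(self.cell_labels) != n:
            raise ValueError("cell_labels length must equal n")
        if len(self.mutation_labels) != m:
            raise ValueError("mutation_labels length must equal m")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def m(self) -> int:
        return self.entries.shape[1]


@dataclass
class ErrorRates:
    """Error model parameters: per-mutation false-negative rates alpha_j
    (allelic dropout), a global false-positive rate beta, and per-mutation
    prior loss probabilities gamma_j (gamma_j = 0 marks a mutation the user
    declares unlosable)."""

    alpha: np.ndarray
    beta: float
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = float(self.beta)
        if self.alpha.ndim != 1 or self.gamma.ndim != 1:
            raise ValueError("alpha and gamma must be 1-D")
        if self.alpha.shape != self.gamma.shape:
            raise ValueError("alpha and gamma must have equal length m")
        for name, arr in (("alpha", self.alpha), ("gamma", self.gamma)):
            if ((arr < 0) | (arr >= 1)).any():
                raise ValueError(f"{name} rates must lie in [0, 1)")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must lie in [0, 1)")

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @classmethod
    def homogeneous(cls, m: int, alpha: float, beta: float, gamma: float) -> "ErrorRates":
        return cls(np.full(m, alpha), beta, np.full(m, gamma))


# ----------------------------------------------------------------------
# matrix / rate files
# ----------------------------------------------------------------------

def read_scs_matrix(
    path,
    dialect: str = "cells-as-rows",
    cell_labels_path=None,
    mutation_labels_path=None,
) -> SCSMatrix:
    """Read a ternary matrix file; ``2`` and ``?`` both map to MISSING.

    ``dialect="mutations-as-rows"`` transposes on load (several mutation-
    tree tools store one mutation per row).
    """
    if dialect not in ("cells-as-rows", "mutations-as-rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            row = []
            for col, tok in enumerate(toks):
                try:
                    row.append(_TOKEN_MAP[tok])
                except KeyError:
                    raise MatrixFormatError(
                        f"{path}: invalid token {tok!r} at line {lineno}, "
                        f"column {col + 1} (expected 0, 1, 2 or ?)"
                    ) from None
            if rows and len(row) != len(rows[0]):
                raise MatrixFormatError(
                    f"{path}: ragged row at line {lineno}: "
                    f"{len(row)} tokens, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    entries = np.array(rows, dtype=np.int8)
    if dialect == "mutations-as-rows":
        entries = entries.T
    cells = read_labels(cell_labels_path) if cell_labels_path else []
    muts = read_labels(mutation_labels_path) if mutation_labels_path else []
    return SCSMatrix(entries, cell_labels=cells, mutation_labels=muts)


def write_scs_matrix(matrix: SCSMatrix, path, dialect: str = "cells-as-rows") -> None:
    entries = matrix.entries
    if dialect == "mutations-as-rows":
        entries = entries.T
    elif dialect != "cells-as-rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for row in entries:
            fh.write(" ".join("?" if e == MISSING else str(int(e)) for e in row))
            fh.write("\n")


def read_rate_file(path, m: int) -> list[float]:
    """Read per-mutation rates: one value per line, either a single value
    broadcast to all m mutations or exactly m values."""
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                x = float(tok)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: {tok!r} is not a number"
                ) from None
            if not 0 <= x < 1:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: rate {x} outside [0, 1)"
                )
            values.append(x)
    if len(values) == 1:
        return values * m
    if len(values) != m:
        raise MatrixFormatError(
            f"{path}: found {len(values)} rates, expected 1 or {m}"
        )
    return values


def read_labels(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ----------------------------------------------------------------------
# DOT
# ----------------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def write_dot(tree: DolloPhylogeny, sigma=None, path=None) -> str:
    """Emit the phylogeny as a Graphviz digraph.

    Gain nodes are labeled with the mutation name; loss nodes with the name
    plus a trailing loss mark and styled red.  If an attachment map
    ``sigma`` is given, per-node cell counts are annotated.  Returns the
    DOT text; writes it to ``path`` when given.
    """
    counts: dict[int, int] = {}
    if sigma is not None:
        node_of = getattr(sigma, "sigma", sigma)
        for node in np.asarray(node_of).ravel():
            counts[int(node)] = counts.get(int(node), 0) + 1
    lines = ["digraph dollo_phylogeny {"]
    lines.append(f'  graph [k={tree.k}, d={tree.d}];')
    for u in tree.nodes():
        lab = tree.label(u)
        if lab.kind is NodeKind.ROOT:
            text, extra = "germline", ", shape=box"
        elif lab.kind is NodeKind.GAIN:
            text, extra = tree.mutation_names[lab.mutation], ""
        else:
            text = tree.mutation_names[lab.mutation] + "-"
            extra = ", color=red, fontcolor=red"
        label = _dot_escape(text)
        if u in counts:
            label += f"\\n({counts[u]} cells)"  # DOT line break, added post-escape
        cells = f', cells={counts[u]}' if u in counts else ""
        lines.append(f'  n{u} [label="{label}"{extra}{cells}];')
    for u in tree.nodes():
        for c in tree.children(u):
            lines.append(f"  n{u} -> n{c};")
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


_NODE_RE = re.compile(r'^\s*n(\d+)\s*\[(.*)\];\s*$')
_EDGE_RE = re.compile(r'^\s*n(\d+)\s*->\s*n(\d+);\s*$')
_GRAPH_RE = re.compile(r'^\s*graph\s*\[k=(\d+),\s*d=(\d+)\];\s*$')
_LABEL_RE = re.compile(r'label="((?:[^"\\]|\\.)*)"')


def read_dot(path) -> tuple[DolloPhylogeny, dict[int, int]]:
    """Parse a tree written by :func:`write_dot`.

    Only the emitted DOT subset is supported.  Returns the phylogeny and a
    per-node cell-count map (empty if no counts were annotated).
    """
    k = d = 0
    node_attrs: dict[int, str] = {}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            m = _GRAPH_RE.match(line)
            if m:
                k, d = int(m.group(1)), int(m.group(2))
                continue
            m = _NODE_RE.match(line)
            if m:
                node_attrs[int(m.group(1))] = m.group(2)
                continue
            m = _EDGE_RE.match(line)
            if m:
                edges.append((int(m.group(1)), int(m.group(2))))

    def parse_label(attrs: str) -> str:
        lm = _LABEL_RE.search(attrs)
        if lm is None:
            raise MatrixFormatError(f"{path}: DOT node without label")
        raw = lm.group(1).split("\\n")[0]
        return raw.replace('\\"', '"').replace("\\\\", "\\")

    gains: list[tuple[int, str]] = []
    losses: list[tuple[int, str]] = []
    root_dot = None
    counts: dict[int, int] = {}
    for u, attrs in node_attrs.items():
        text = parse_label(attrs)
        cm = re.search(r"cells=(\d+)", attrs)
        if cm:
            counts[u] = int(cm.group(1))
        if "shape=box" in attrs or text == "germline":
            root_dot = u
        elif "color=red" in attrs:
            losses.append((u, text.rstrip("-")))
        else:
            gains.append((u, text))
    if root_dot is None:
        raise MatrixFormatError(f"{path}: no germline root node found")
    names = [name for _, name in sorted(gains)]
    index = {name: j for j, name in enumerate(names)}
    c_total = len(losses)
    per_mut: dict[str, int] = {}
    for _, name in losses:
        per_mut[name] = per_mut.get(name, 0) + 1
    k = max([k] + list(per_mut.values()))
    d = max(d, c_total)
    tree = DolloPhylogeny(len(names), k=k, d=d, mutation_names=names)
    parent_of: dict[int, int] = {}
    for a, b in edges:
        parent_of[b] = a
    order = [root_dot]
    children: dict[int, list[int]] = {}
    for b, a in parent_of.items():
        children.setdefault(a, []).append(b)
    id_map = {root_dot: tree.root}
    stack = [root_dot]
    seen_losses: dict[str, int] = {}
    while stack:
        u = stack.pop(0)
        for c in sorted(children.get(u, [])):
            text = parse_label(node_attrs[c])
            if "color=red" in node_attrs[c]:
                name = text.rstrip("-")
                seen_losses[name] = seen_losses.get(name, 0) + 1
                lab = NodeLabel(NodeKind.LOSS, index[name], seen_losses[name])
            else:
                lab = NodeLabel(NodeKind.GAIN, index[text])
            id_map[c] = tree.add_child(id_map[u], lab)
            stack.append(c)
    return tree, {id_map[u]: c for u, c in counts.items() if u in id_map}
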