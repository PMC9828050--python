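"""Reading, validating, writing, and subsetting SWC reconstructions.

The SWC format stores one tracing point per line::

    index  type  x  y  z  radius  parent

with ``#`` comment lines.  Coordinates and radii are in micrometers (μm);
``parent`` is the index of the parent point, or ``-1`` for a root.  Common
type codes: 1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite, 7 glial
process; any other integer code is passed through unchanged.

Files produced by different tracing systems vary in node ordering (children
may precede parents), so parsing is two-pass: all nodes are read first and
the parent/child structure is resolved afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4
GLIAL_PROCESS = 7

#: type codes selected when analyzing neuronal dendrites
DENDRITE_CODES = frozenset({BASAL_DENDRITE, APICAL_DENDRITE})
#: type codes selected when analyzing glial processes
GLIA_CODES = frozenset({GLIAL_PROCESS})


class SWCError(ValueError):
    """Base class for SWC reading/writing problems."""


class SWCParseError(SWCError):
    """A line could not be parsed; the message names the line number."""


class MorphologyError(SWCError):
    """A structural invariant of a reconstruction is violated."""


class EmptySelectionError(MorphologyError):
    """An arbor selection removed every non-soma node."""


@dataclass(frozen=True)
class SWCNode:
    """One tracing point of a reconstruction."""

    index: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def is_root(self) -> bool:
        return self.parent == -1

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Morphology:
    """A rooted tree (or forest) of SWC nodes representing one cell."""

    nodes: list[SWCNode]
    cell_id: str = ""
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        self._by_index = {n.index: n for n in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, index: int) -> SWCNode:
        return self._by_index[index]

    def __contains__(self, index: int) -> bool:
        return index in self._by_index

    @property
    def roots(self) -> list[SWCNode]:
        return [n for n in self.nodes if n.is_root]

    @property
    def soma_nodes(self) -> list[SWCNode]:
        return [n for n in self.nodes if n.type_code == SOMA]

    def children_map(self) -> dict[int, list[int]]:
        """Parent index -> list of child indices, in node order."""
        out: dict[int, list[int]] = {n.index: [] for n in self.nodes}
        for n in self.nodes:
            if not n.is_root and n.parent in out:
                out[n.parent].append(n.index)
        return out


@dataclass
class ValidationReport:
    """Outcome of structural validation of a morphology.

    ``issues`` is empty iff every node/graph invariant holds.  A missing soma
    is *not* an issue: a sizeable minority of curated reconstructions
    (glia especially) are traced without a cell body, and such arbors are
    analyzed with the first root of each tree as the distance reference.
    """

    n_nodes: int
    n_roots: int
    n_soma_nodes: int
    has_soma: bool
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


# ---------------------------------------------------------------------------
# reading / writing


def _parse_line(raw: str, lineno: int) -> SWCNode:
    parts = raw.split()
    if len(parts) != 7:
        raise SWCParseError(
            f"line {lineno}: expected 7 fields (index type x y z radius parent), "
            f"got {len(parts)}: {raw!r}"
        )
    try:
        return SWCNode(
            index=int(parts[0]),
            type_code=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent=int(parts[6]),
        )
    except ValueError as exc:
        raise SWCParseError(f"line {lineno}: {exc}") from None


def read_swc(path: str | Path, cell_id: str | None = None) -> Morphology:
    """Read an SWC file into a :class:`Morphology`.

    Comment (``#``) and blank lines are skipped; node order is preserved.
    Files where children precede their parents are accepted (structure is
    resolved after all lines are read).

    Raises
    ------
    SWCParseError
        A data line is malformed (the message names the line number).
    MorphologyError
        The file holds no nodes, an index is duplicated, a parent index
        does not exist, or the parent graph has a cycle.
    """
    path = Path(path)
    nodes: list[SWCNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            nodes.append(_parse_line(stripped, lineno))
    if not nodes:
        raise MorphologyError(f"{path}: no SWC data lines (empty morphology)")
    m = Morphology(nodes, cell_id=cell_id if cell_id is not None else path.stem)
    report = validate_morphology(m)
    if not report.ok:
        raise MorphologyError(f"{path}: " + "; ".join(report.issues))
    return m


def write_swc(m: Morphology, path: str | Path, header: str | None = None) -> None:
    """Write a morphology as standard 7-column SWC text.

    Nodes are emitted in stored order when every parent already precedes its
    children; otherwise they are re-ordered topologically (parents first)
    keeping the original indices.
    """
    if not m.nodes:
        raise MorphologyError("refusing to write an empty morphology")
    report = validate_morphology(m)
    if not report.ok:
        raise MorphologyError("refusing to write invalid morphology: " + "; ".join(report.issues))

    seen: set[int] = set()
    ordered = True
    for n in m.nodes:
        if not n.is_root and n.parent not in seen:
            ordered = False
            break
        seen.add(n.index)
    nodes = m.nodes if ordered else _topological_order(m)

    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for n in nodes:
            fh.write(
                f"{n.index} {n.type_code} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
                f"{n.radius:.6f} {n.parent}\n"
            )


def _topological_order(m: Morphology) -> list[SWCNode]:
    children = m.children_map()
    out: list[SWCNode] = []
    stack = [r.index for r in reversed(m.roots)]
    while stack:
        idx = stack.pop()
        out.append(m.node(idx))
        stack.extend(reversed(children[idx]))
    return out


# ---------------------------------------------------------------------------
# validation


def validate_morphology(m: Morphology) -> ValidationReport:
    """Enumerate every structural invariant violation of ``m``.

    Checks: duplicate indices, orphan parent references, self-parenting and
    longer cycles, negative radii, and the presence of a root.  Node order
    (child before parent) is not an invariant: unordered files are accepted
    on read and re-ordered topologically on write.
    """
    issues: list[str] = []
    counts: dict[int, int] = {}
    for n in m.nodes:
        counts[n.index] = counts.get(n.index, 0) + 1
    for idx, c in counts.items():
        if c > 1:
            issues.append(f"duplicate index {idx} ({c} occurrences)")

    index_set = set(counts)
    for n in m.nodes:
        if not n.is_root and n.parent not in index_set:
            issues.append(f"orphan parent: node {n.index} references missing {n.parent}")
        if n.parent == n.index:
            issues.append(f"cycle: node {n.index} is its own parent")
        if n.radius < 0:
            issues.append(f"negative radius at node {n.index}")

    # cycle detection over the parent graph (skip self-loops already reported)
    state: dict[int, int] = {}  # 0 visiting, 1 done
    parent_of = {n.index: n.parent for n in m.nodes}
    for start in parent_of:
        chain = []
        idx = start
        while idx in parent_of and idx not in state:
            state[idx] = 0
            chain.append(idx)
            nxt = parent_of[idx]
            if nxt == -1 or nxt not in parent_of or nxt == idx:
                break
            if nxt in state and state[nxt] == 0:
                issues.append(f"cycle involving node {nxt}")
                break
            idx = nxt
        for c in chain:
            state[c] = 1

    n_roots = sum(1 for n in m.nodes if n.is_root)
    if m.nodes and n_roots == 0:
        issues.append("no root node (parent -1) present")
    n_soma = sum(1 for n in m.nodes if n.type_code == SOMA)
    return ValidationReport(
        n_nodes=len(m.nodes),
        n_roots=n_roots,
        n_soma_nodes=n_soma,
        has_soma=n_soma > 0,
        issues=issues,
    )


# ---------------------------------------------------------------------------
# arbor selection


def select_arbor(m: Morphology, include_type_codes: Iterable[int]) -> Morphology:
    """Keep only the arbor subtrees of the requested type codes.

    A node is kept when it is a soma node (retained as the root reference)
    or when its type code is included *and* its path to the root runs only
    through kept nodes.  A dendritic subtree hanging off an excluded axon
    node is therefore dropped together with the axon.

    Raises :class:`EmptySelectionError` when no non-soma node survives.
    """
    include = set(include_type_codes)
    children = m.children_map()
    kept: set[int] = set()
    stack = [r.index for r in m.roots]
    while stack:
        idx = stack.pop()
        node = m.node(idx)
        ok = node.type_code == SOMA or node.type_code in include
        if not ok:
            continue  # whole subtree dropped
        kept.add(idx)
        stack.extend(children[idx])

    new_nodes = []
    for n in m.nodes:
        if n.index not in kept:
            continue
        if not n.is_root and n.parent not in kept:
            n = replace(n, parent=-1)  # re-root at the attachment point
        new_nodes.append(n)
    if not any(n.type_code != SOMA for n in new_nodes):
        raise EmptySelectionError(
            f"selection {sorted(include)} leaves no non-soma nodes in {m.cell_id!r}"
        )
    return Morphology(new_nodes, cell_id=m.cell_id, unit_scale=m.unit_scale)


# ---------------------------------------------------------------------------
# scale correction

#: features rescaled by a per-archive conversion factor when a file's
#: coordinates are in pixels rather than μm.  The same single multiplicative
#: factor is applied to each listed feature; for surface (μm²) and volume
#: (μm³) this linear correction is approximate.
SIZE_FEATURES = (
    "width",
    "height",
    "length",
    "surface",
    "volume",
    "euc_distance",
    "path_distance",
)


def scale_size_features(v, factor: float):
    """Return a copy of a morphometric vector with size features rescaled.

    Exactly the features in :data:`SIZE_FEATURES` are multiplied by
    ``factor``; scale-invariant features (counts, contraction, angles,
    asymmetry, fractal dimension, Rall's ratio) and diameter are unchanged.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return replace(v, **{name: getattr(v, name) * factor for name in SIZE_FEATURES})


# ---------------------------------------------------------------------------
# label table


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited cell-label table.

    Expected columns: ``cell_id``, ``label`` (``neuron``/``glia``); optional
    metadata columns (species, region, sex, archive, ...) and an optional
    ``scale_factor`` column (missing entries default to 1.0).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"cell_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table {path} lacks required columns: {sorted(missing)}")
    df["cell_id"] = df["cell_id"].astype(str)
    if "scale_factor" in df.columns:
        df["scale_factor"] = df["scale_factor"].fillna(1.0).astype(float)
    return df
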