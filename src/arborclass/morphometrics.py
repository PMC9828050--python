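"""Branch decomposition and per-cell arbor morphometrics.

A *branch* is a maximal unbranched path between a stem start (the first
non-soma node of a tree) or a bifurcation, and the next bifurcation or
termination.  The 19 per-cell features computed here are the standard
L-Measure-style descriptors used to characterize neuronal dendrites and
glial processes: counts (stems, bifurcations, branches, fragmentation,
branch order), spatial extents (width, height, maximum Euclidean and path
distance from the cell body), cable quantities (total length, surface,
volume, mean diameter), and scale-free shape descriptors (contraction,
partition asymmetry, fractal dimension, Rall's ratio, local and remote
bifurcation amplitudes).

Conventions, fixed for reproducibility:

* Multi-node somas are collapsed to a single reference point at their
  centroid; all distances "from the cell body" are measured from it.  For
  soma-less reconstructions the first root node of each tree is the
  reference.
* Width/height use the 97.5th minus 2.5th coordinate percentile with linear
  interpolation between order statistics, on the literal X and Y data axes.
* A k-furcation (k > 2 children) counts as (k - 1) bifurcations in the
  counts; angle, Rall and asymmetry terms use its first two children only.
* Diameter is compartment-weighted: the plain mean of 2*radius over all
  non-soma tracing points.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .swc_io import SOMA, Morphology, MorphologyError, SWCNode

logger = logging.getLogger(__name__)

#: the 19 per-cell features, in canonical column order
FEATURE_NAMES = (
    "n_stems",
    "n_bifs",
    "n_branch",
    "width",
    "height",
    "diameter",
    "length",
    "surface",
    "volume",
    "euc_distance",
    "path_distance",
    "branch_order",
    "contraction",
    "fragmentation",
    "partition_asymmetry",
    "pk_classic",
    "bif_ampl_local",
    "bif_ampl_remote",
    "fractal_dim",
)


@dataclass(frozen=True)
class Branch:
    """A maximal unbranched path of an arbor.

    ``node_path`` runs from the start point (stem start or bifurcation node)
    to the end point (bifurcation or termination), inclusive.
    ``terminal_degree`` is the number of terminations in the subtree hanging
    from the end node; terminal branches have ``terminal_degree == 1``.
    """

    node_path: tuple[int, ...]
    path_length: float
    euclidean_length: float
    branch_order: int
    terminal_degree: int

    @property
    def contraction(self) -> float:
        if self.path_length == 0:
            return 1.0
        return self.euclidean_length / self.path_length

    @property
    def is_terminal(self) -> bool:
        return self.terminal_degree == 1


@dataclass(frozen=True)
class MorphometricVector:
    """The 19 morphometric features of one cell.

    ``missing`` names features that were undefined for this cell (e.g. the
    bifurcation-dependent ones on an unbranched arbor); such features carry
    the value 0 so that feature tables stay rectangular.
    """

    n_stems: float
    n_bifs: float
    n_branch: float
    width: float
    height: float
    diameter: float
    length: float
    surface: float
    volume: float
    euc_distance: float
    path_distance: float
    branch_order: float
    contraction: float
    fragmentation: float
    partition_asymmetry: float
    pk_classic: float
    bif_ampl_local: float
    bif_ampl_remote: float
    fractal_dim: float
    missing: tuple[str, ...] = ()

    def to_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# tree scaffolding


def _arbor_structure(m: Morphology):
    """Filtered (soma-free) children map, stem starts, and reference point.

    Soma nodes are collapsed out of the graph: every non-soma child of any
    soma node becomes a stem start, as do non-soma roots.  The distance
    reference is the soma centroid, or the first root when no soma exists.
    """
    soma = m.soma_nodes
    if soma:
        ref = np.mean([[n.x, n.y, n.z] for n in soma], axis=0)
    else:
        roots = m.roots
        if not roots:
            raise MorphologyError(f"{m.cell_id!r}: no root node")
        r = roots[0]
        ref = np.array([r.x, r.y, r.z])

    children: dict[int, list[int]] = {}
    stems: list[int] = []
    for n in m.nodes:
        if n.type_code == SOMA:
            continue
        children.setdefault(n.index, [])
        if n.is_root:
            stems.append(n.index)
        else:
            parent = m.node(n.parent)
            if parent.type_code == SOMA:
                stems.append(n.index)
            else:
                children.setdefault(parent.index, []).append(n.index)
    # preserve node order within each child list
    order = {n.index: i for i, n in enumerate(m.nodes)}
    for lst in children.values():
        lst.sort(key=order.__getitem__)
    return children, stems, ref


def _positions(m: Morphology) -> dict[int, np.ndarray]:
    return {n.index: np.array([n.x, n.y, n.z]) for n in m.nodes}


def _tip_counts(children: dict[int, list[int]], stems: Sequence[int]) -> dict[int, int]:
    """Number of terminations in the subtree rooted at each node."""
    counts: dict[int, int] = {}
    for s in stems:
        # iterative post-order
        stack = [(s, False)]
        while stack:
            idx, done = stack.pop()
            if done:
                ch = children[idx]
                counts[idx] = sum(counts[c] for c in ch) if ch else 1
            else:
                stack.append((idx, True))
                stack.extend((c, False) for c in children[idx])
    return counts


# ---------------------------------------------------------------------------
# branch decomposition


def decompose_branches(m: Morphology) -> list[Branch]:
    """Split an arbor into its maximal unbranched branches.

    Every non-soma segment belongs to exactly one branch; for binary trees
    the branch count equals bifurcations plus terminations.  Raises
    :class:`MorphologyError` on an arbor with no non-soma segments.
    """
    children, stems, _ = _arbor_structure(m)
    if not stems:
        raise MorphologyError(f"{m.cell_id!r}: empty arbor (no non-soma nodes)")
    pos = _positions(m)
    tips = _tip_counts(children, stems)

    branches: list[Branch] = []
    # work items: (start node, first body node or None for stems, order)
    queue: list[tuple[int, int | None, int]] = [(s, None, 0) for s in stems]
    while queue:
        start, first, order = queue.pop()
        path = [start]
        cur = start
        if first is not None:
            path.append(first)
            cur = first
        while len(children[cur]) == 1:
            cur = children[cur][0]
            path.append(cur)
        if len(path) >= 2:
            pts = np.array([pos[i] for i in path])
            seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            branches.append(
                Branch(
                    node_path=tuple(path),
                    path_length=float(seglens.sum()),
                    euclidean_length=float(np.linalg.norm(pts[-1] - pts[0])),
                    branch_order=order,
                    terminal_degree=tips[cur],
                )
            )
            next_order = order + 1
        else:
            # a stem start that bifurcates immediately: no segments of its
            # own, its children are first-order branches
            next_order = order + 1 if len(children[cur]) >= 2 else order
        for c in children[cur]:
            queue.append((cur, c, next_order))
    if not branches:
        raise MorphologyError(f"{m.cell_id!r}: arbor has no segments")
    return branches


# ---------------------------------------------------------------------------
# feature groups


def compute_counts(m: Morphology) -> tuple[int, int, int, int, int]:
    """(n_stems, n_bifs, n_branch, fragmentation, branch_order)."""
    children, stems, _ = _arbor_structure(m)
    if not stems:
        raise MorphologyError(f"{m.cell_id!r}: empty arbor")
    n_stems = len(stems)
    n_bifs = sum(len(ch) - 1 for ch in children.values() if len(ch) >= 2)
    n_tips = sum(1 for ch in children.values() if not ch)
    n_branch = n_bifs + n_tips
    fragmentation = len(children)

    branch_order = 0
    for s in stems:
        stack = [(s, 0)]
        while stack:
            idx, order = stack.pop()
            ch = children[idx]
            if not ch:
                branch_order = max(branch_order, order)
            else:
                bump = 1 if len(ch) >= 2 else 0
                stack.extend((c, order + bump) for c in ch)
    return n_stems, n_bifs, n_branch, fragmentation, branch_order


def compute_extents(m: Morphology) -> tuple[float, float, float, float]:
    """(width, height, euc_distance, path_distance).

    Spans are 97.5th minus 2.5th percentile of the X (width) and Y (height)
    coordinates over non-soma nodes; distances are measured from the cell
    body reference point (soma centroid, or first root when soma is absent).
    """
    children, stems, ref = _arbor_structure(m)
    if not stems:
        raise MorphologyError(f"{m.cell_id!r}: empty arbor")
    pos = _positions(m)
    coords = np.array([pos[i] for i in children])
    width = float(np.percentile(coords[:, 0], 97.5) - np.percentile(coords[:, 0], 2.5))
    height = float(np.percentile(coords[:, 1], 97.5) - np.percentile(coords[:, 1], 2.5))
    euc = float(np.max(np.linalg.norm(coords - ref, axis=1)))

    path_max = 0.0
    for s in stems:
        stack = [(s, float(np.linalg.norm(pos[s] - ref)))]
        while stack:
            idx, d = stack.pop()
            path_max = max(path_max, d)
            for c in children[idx]:
                stack.append((c, d + float(np.linalg.norm(pos[c] - pos[idx]))))
    return width, height, euc, path_max


def compute_cable(m: Morphology) -> tuple[float, float, float, float]:
    """(length, surface, volume, diameter).

    Length sums all non-soma segments; surface and volume model each segment
    as a truncated cone (frustum); diameter is the compartment-weighted mean
    of 2*radius over non-soma tracing points.
    """
    radii = {n.index: n.radius for n in m.nodes}
    children, stems, _ = _arbor_structure(m)
    if not stems:
        raise MorphologyError(f"{m.cell_id!r}: empty arbor")
    pos = _positions(m)

    length = surface = volume = 0.0
    for parent, ch in children.items():
        for c in ch:
            h = float(np.linalg.norm(pos[c] - pos[parent]))
            r1, r2 = radii[parent], radii[c]
            length += h
            slant = math.sqrt(h * h + (r1 - r2) ** 2)
            surface += math.pi * (r1 + r2) * slant
            volume += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    node_radii = np.array([radii[i] for i in children])
    diameter = float(np.mean(2.0 * node_radii)) if len(node_radii) else 0.0
    if node_radii.size and not np.any(node_radii > 0):
        logger.warning("%s: all radii are zero; surface and volume are 0", m.cell_id)
    return length, surface, volume, diameter


def compute_topology(m: Morphology) -> float:
    """Mean partition asymmetry |n1 - n2| / (n1 + n2) over bifurcations.

    ``n1``/``n2`` are termination counts of the two daughter subtrees (first
    two children at a multifurcation).  Returns 0.0 when the arbor has no
    bifurcation (the caller flags the feature as missing).
    """
    children, stems, _ = _arbor_structure(m)
    tips = _tip_counts(children, stems)
    vals = []
    for idx, ch in children.items():
        if len(ch) >= 2:
            n1, n2 = tips[ch[0]], tips[ch[1]]
            vals.append(abs(n1 - n2) / (n1 + n2))
    return float(np.mean(vals)) if vals else 0.0


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float | None:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return None
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def compute_geometry(
    m: Morphology, branches: Sequence[Branch]
) -> tuple[float, float, float, float, float, list[str]]:
    """(contraction, fractal_dim, bif_ampl_local, bif_ampl_remote, pk_classic,
    missing-feature names).

    * contraction: mean over branches of Euclidean / path length.
    * bifurcation amplitudes: local uses the first compartment of each of the
      first two daughters; remote uses the end points of the two daughter
      branches.
    * pk_classic (Rall's ratio): mean over bifurcations of
      (d1^1.5 + d2^1.5) / dp^1.5 on diameters.
    * fractal_dim: mean over branches (>= 3 tracing points) of the regression
      slope of log10 path distance on log10 Euclidean distance of each point
      from the branch start.

    Degenerate terms (zero-length daughter segments, zero parent diameter)
    are skipped with a logged warning.
    """
    missing: list[str] = []
    pos = _positions(m)
    radii = {n.index: n.radius for n in m.nodes}

    contraction = float(np.mean([b.contraction for b in branches]))

    # index daughter branches by (start node, first body node)
    daughters: dict[tuple[int, int], Branch] = {}
    for b in branches:
        if len(b.node_path) >= 2:
            daughters[(b.node_path[0], b.node_path[1])] = b

    children, _, _ = _arbor_structure(m)
    local_angles: list[float] = []
    remote_angles: list[float] = []
    pk_vals: list[float] = []
    n_bif = 0
    for idx, ch in children.items():
        if len(ch) < 2:
            continue
        n_bif += 1
        c1, c2 = ch[0], ch[1]
        ang = _angle_deg(pos[c1] - pos[idx], pos[c2] - pos[idx])
        if ang is None:
            logger.warning("%s: zero-length daughter segment at node %d", m.cell_id, idx)
        else:
            local_angles.append(ang)
        b1, b2 = daughters.get((idx, c1)), daughters.get((idx, c2))
        if b1 is not None and b2 is not None:
            ang = _angle_deg(
                pos[b1.node_path[-1]] - pos[idx], pos[b2.node_path[-1]] - pos[idx]
            )
            if ang is not None:
                remote_angles.append(ang)
        dp, d1, d2 = 2 * radii[idx], 2 * radii[c1], 2 * radii[c2]
        if dp > 0:
            pk_vals.append((d1**1.5 + d2**1.5) / dp**1.5)

    slopes: list[float] = []
    for b in branches:
        if len(b.node_path) < 3:
            continue
        pts = np.array([pos[i] for i in b.node_path])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        pathd = np.cumsum(seg)
        eucd = np.linalg.norm(pts[1:] - pts[0], axis=1)
        ok = (eucd > 0) & (pathd > 0)
        if ok.sum() < 2:
            continue
        x = np.log10(eucd[ok])
        y = np.log10(pathd[ok])
        if np.ptp(x) == 0:
            slopes.append(1.0 if np.ptp(y) == 0 else 0.0)
        else:
            slopes.append(float(np.polyfit(x, y, 1)[0]))

    if n_bif == 0:
        missing += ["bif_ampl_local", "bif_ampl_remote", "pk_classic", "partition_asymmetry"]
    if not pk_vals and n_bif > 0:
        missing.append("pk_classic")
    if not slopes:
        missing.append("fractal_dim")

    return (
        contraction,
        float(np.mean(slopes)) if slopes else 0.0,
        float(np.mean(local_angles)) if local_angles else 0.0,
        float(np.mean(remote_angles)) if remote_angles else 0.0,
        float(np.mean(pk_vals)) if pk_vals else 0.0,
        missing,
    )


# ---------------------------------------------------------------------------
# assembly


def compute_morphometrics(m: Morphology) -> MorphometricVector:
    """Compute the full 19-feature vector for one cell."""
    branches = decompose_branches(m)
    n_stems, n_bifs, n_branch, fragmentation, branch_order = compute_counts(m)
    width, height, euc_distance, path_distance = compute_extents(m)
    length, surface, volume, diameter = compute_cable(m)
    partition_asymmetry = compute_topology(m)
    contraction, fractal_dim, bif_local, bif_remote, pk, missing = compute_geometry(
        m, branches
    )
    return MorphometricVector(
        n_stems=n_stems,
        n_bifs=n_bifs,
        n_branch=n_branch,
        width=width,
        height=height,
        diameter=diameter,
        length=length,
        surface=surface,
        volume=volume,
        euc_distance=euc_distance,
        path_distance=path_distance,
        branch_order=branch_order,
        contraction=contraction,
        fragmentation=fragmentation,
        partition_asymmetry=partition_asymmetry,
        pk_classic=pk,
        bif_ampl_local=bif_local,
        bif_ampl_remote=bif_remote,
        fractal_dim=fractal_dim,
        missing=tuple(missing),
    )


def morphometrics_table(morphologies: Iterable[Morphology]) -> pd.DataFrame:
    """Feature table: one row per cell_id, 19 named columns in canonical order."""
    rows = {}
    for m in morphologies:
        rows[m.cell_id] = compute_morphometrics(m).to_series()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "cell_id"
    return df


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise R² (squared Pearson correlation) between feature columns.

    Constant columns yield NaN rows/columns with a warning; the diagonal is
    1 for non-constant features and the matrix is symmetric.
    """
    if len(table) < 3:
        raise ValueError("correlation matrix needs at least 3 cells")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(table.columns, sd) if s == 0]
        warnings.warn(f"constant feature columns give undefined R²: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(r**2, index=table.columns, columns=table.columns)
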