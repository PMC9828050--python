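"""Shared tree-building helpers and fixtures.

`random_small_tree` is an independent miniature tree builder (plain
`random`, no package code) used to confront the implementation with the
brute-force oracles on many small arbors.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from arborclass import Morphology, SWCNode


def make_morphology(rows, cell_id="test"):
    """Build a Morphology from (index, type, x, y, z, radius, parent) rows."""
    return Morphology([SWCNode(*row) for row in rows], cell_id=cell_id)


@pytest.fixture
def y_tree():
    """Soma + straight 10 μm stem + two straight 6 μm terminal branches at 90°.

    ABEL = (10 + 6 + 6)/3; terminal ABEL 6; internal ABEL 10; 1 stem, 1
    bifurcation, 3 branches, branch order 1.
    """
    h = 6 * math.sqrt(2) / 2
    return make_morphology(
        [
            (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            (2, 3, 0.0, 0.0, 0.0, 0.5, 1),
            (3, 3, 0.0, 5.0, 0.0, 0.5, 2),
            (4, 3, 0.0, 10.0, 0.0, 0.5, 3),
            (5, 3, h, 10.0 + h, 0.0, 0.4, 4),
            (6, 3, -h, 10.0 + h, 0.0, 0.4, 4),
        ],
        cell_id="y_tree",
    )


@pytest.fixture
def cable():
    """Unbranched straight cable of length 10 along +z, radius 1 (a cylinder)."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    for i in range(5):
        rows.append((i + 2, 3, 0.0, 0.0, 2.5 * i, 1.0, i + 1))
    return make_morphology(rows, cell_id="cable")


def random_small_tree(seed: int, max_nodes: int = 20) -> Morphology:
    """An independent random arbor with at most ``max_nodes`` nodes.

    Occasionally soma-less or with a 3-node soma contour, so the soma
    conventions get exercised too.  Coordinates are generic floats, making
    degenerate geometry (coincident points, exact ties) improbable.
    """
    rnd = random.Random(seed)
    rows: list[tuple] = []
    idx = 1

    soma_ids: list[int] = []
    if rnd.random() < 0.85:
        for k in range(rnd.choice([1, 1, 1, 3])):
            rows.append(
                (
                    idx,
                    1,
                    rnd.uniform(-2, 2),
                    rnd.uniform(-2, 2),
                    rnd.uniform(-2, 2),
                    rnd.uniform(1.0, 3.0),
                    -1 if not soma_ids else soma_ids[0],
                )
            )
            soma_ids.append(idx)
            idx += 1

    def new_node(parent: int) -> int:
        nonlocal idx
        rows.append(
            (
                idx,
                3,
                rnd.uniform(-50, 50),
                rnd.uniform(-50, 50),
                rnd.uniform(-50, 50),
                rnd.uniform(0.1, 2.0),
                parent,
            )
        )
        idx += 1
        return idx - 1

    leaves = []
    for _ in range(rnd.randint(1, 2)):
        parent = rnd.choice(soma_ids) if soma_ids else -1
        stem = new_node(parent)
        leaves.append(new_node(stem))  # every stem has at least one segment

    budget = rnd.randint(12, max_nodes)
    while leaves and idx <= budget:
        leaf = leaves.pop(rnd.randrange(len(leaves)))
        action = rnd.random()
        if action < 0.5:  # extend
            leaves.append(new_node(leaf))
        elif action < 0.85 and idx + 1 <= budget:  # bifurcate
            leaves.append(new_node(leaf))
            leaves.append(new_node(leaf))
        # else: terminate this leaf
    return Morphology([SWCNode(*r) for r in rows], cell_id=f"rand{seed}")


def transform_morphology(m: Morphology, rotation=None, translation=(0.0, 0.0, 0.0),
                         scale: float = 1.0) -> Morphology:
    """Apply p -> R @ (scale * p) + t to coordinates; radii scale too."""
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    t = np.asarray(translation, dtype=float)
    nodes = []
    for n in m.nodes:
        p = R @ (scale * np.array([n.x, n.y, n.z])) + t
        nodes.append(
            SWCNode(n.index, n.type_code, float(p[0]), float(p[1]), float(p[2]),
                    n.radius * scale, n.parent)
        )
    return Morphology(nodes, cell_id=m.cell_id, unit_scale=m.unit_scale)


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)
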