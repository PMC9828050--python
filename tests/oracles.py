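"""Independent brute-force oracles for morphometrics and threshold fitting.

Everything here is deliberately written from first principles (recursive
path enumeration, hand-rolled percentiles and least squares, O(n^2) scans)
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

SOMA = 1


def _structure(m):
    """(children, stems, ref) mirroring the documented soma conventions:
    soma nodes collapse out of the graph, distances are measured from the
    soma centroid or, soma-less, from the first root."""
    soma = [n for n in m.nodes if n.type_code == SOMA]
    if soma:
        ref = tuple(sum(getattr(n, ax) for n in soma) / len(soma) for ax in "xyz")
    else:
        r = m.roots[0]
        ref = (r.x, r.y, r.z)
    children = {}
    stems = []
    order = {n.index: i for i, n in enumerate(m.nodes)}
    for n in m.nodes:
        if n.type_code == SOMA:
            continue
        children.setdefault(n.index, [])
        if n.parent == -1 or m.node(n.parent).type_code == SOMA:
            stems.append(n.index)
        else:
            children.setdefault(n.parent, []).append(n.index)
    for lst in children.values():
        lst.sort(key=order.__getitem__)
    return children, stems, ref


def _pos(m, idx):
    n = m.node(idx)
    return (n.x, n.y, n.z)


def _dist(a, b):
    return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))


def _root_to_tip_paths(children, stems):
    paths = []

    def walk(idx, acc):
        acc = acc + [idx]
        if not children[idx]:
            paths.append(acc)
        for c in children[idx]:
            walk(c, acc)

    for s in stems:
        walk(s, [])
    return paths


def oracle_branches(m):
    """Branch node-paths by walking every root-to-tip path and splitting at
    bifurcations; duplicates (shared prefixes) removed."""
    children, stems, _ = _structure(m)
    seen = set()
    out = []
    for path in _root_to_tip_paths(children, stems):
        cut = [0] + [i for i, idx in enumerate(path) if len(children[idx]) >= 2] + [
            len(path) - 1
        ]
        cut = sorted(set(cut))
        for a, b in zip(cut[:-1], cut[1:]):
            seg = tuple(path[a : b + 1])
            if len(seg) >= 2 and seg not in seen:
                seen.add(seg)
                out.append(seg)
    return out


def oracle_tip_count(children, idx):
    if not children[idx]:
        return 1
    return sum(oracle_tip_count(children, c) for c in children[idx])


def _percentile(xs, q):
    """Linear interpolation between order statistics (numpy's default)."""
    s = sorted(xs)
    if len(s) == 1:
        return s[0]
    rank = q / 100.0 * (len(s) - 1)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    frac = rank - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def _lstsq_slope(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return sxy / sxx


def oracle_morphometrics(m):
    """All 19 features of one cell, computed by exhaustive enumeration."""
    children, stems, ref = _structure(m)
    paths = _root_to_tip_paths(children, stems)
    branches = oracle_branches(m)

    n_stems = len(stems)
    n_bifs = sum(len(ch) - 1 for ch in children.values() if len(ch) >= 2)
    n_tips = sum(1 for ch in children.values() if not ch)
    n_branch = n_bifs + n_tips
    fragmentation = len(children)
    branch_order = max(
        sum(1 for idx in path if len(children[idx]) >= 2) for path in paths
    )

    xs = [m.node(i).x for i in children]
    ys = [m.node(i).y for i in children]
    width = _percentile(xs, 97.5) - _percentile(xs, 2.5)
    height = _percentile(ys, 97.5) - _percentile(ys, 2.5)
    euc_distance = max(_dist(_pos(m, i), ref) for i in children)
    path_distance = 0.0
    for path in paths:
        d = _dist(_pos(m, path[0]), ref)
        for a, b in zip(path[:-1], path[1:]):
            d += _dist(_pos(m, a), _pos(m, b))
        path_distance = max(path_distance, d)

    length = surface = volume = 0.0
    for parent, ch in children.items():
        for c in ch:
            h = _dist(_pos(m, parent), _pos(m, c))
            r1, r2 = m.node(parent).radius, m.node(c).radius
            length += h
            surface += math.pi * (r1 + r2) * math.sqrt(h * h + (r1 - r2) ** 2)
            volume += math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    diameter = sum(2 * m.node(i).radius for i in children) / len(children)

    bifs = [idx for idx, ch in children.items() if len(ch) >= 2]
    if bifs:
        pa_vals = []
        for b in bifs:
            n1 = oracle_tip_count(children, children[b][0])
            n2 = oracle_tip_count(children, children[b][1])
            pa_vals.append(abs(n1 - n2) / (n1 + n2))
        partition_asymmetry = sum(pa_vals) / len(pa_vals)
    else:
        partition_asymmetry = 0.0

    def angle(v1, v2):
        n1 = math.sqrt(sum(x * x for x in v1))
        n2 = math.sqrt(sum(x * x for x in v2))
        c = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    def vec(a, b):
        return tuple(x - y for x, y in zip(b, a))

    by_start = {(seg[0], seg[1]): seg for seg in branches}
    locals_, remotes, pks = [], [], []
    for b in bifs:
        c1, c2 = children[b][0], children[b][1]
        p = _pos(m, b)
        locals_.append(angle(vec(p, _pos(m, c1)), vec(p, _pos(m, c2))))
        s1, s2 = by_start.get((b, c1)), by_start.get((b, c2))
        if s1 and s2:
            remotes.append(angle(vec(p, _pos(m, s1[-1])), vec(p, _pos(m, s2[-1]))))
        dp = 2 * m.node(b).radius
        if dp > 0:
            d1, d2 = 2 * m.node(c1).radius, 2 * m.node(c2).radius
            pks.append((d1**1.5 + d2**1.5) / dp**1.5)

    contr = []
    slopes = []
    for seg in branches:
        pl = sum(_dist(_pos(m, a), _pos(m, b)) for a, b in zip(seg[:-1], seg[1:]))
        el = _dist(_pos(m, seg[0]), _pos(m, seg[-1]))
        contr.append(el / pl if pl > 0 else 1.0)
        if len(seg) < 3:
            continue
        eucs, pathds = [], []
        d = 0.0
        for a, b in zip(seg[:-1], seg[1:]):
            d += _dist(_pos(m, a), _pos(m, b))
            e = _dist(_pos(m, seg[0]), _pos(m, b))
            if e > 0 and d > 0:
                eucs.append(math.log10(e))
                pathds.append(math.log10(d))
        if len(eucs) < 2:
            continue
        if max(eucs) - min(eucs) == 0:
            slopes.append(1.0 if max(pathds) - min(pathds) == 0 else 0.0)
        else:
            slopes.append(_lstsq_slope(eucs, pathds))

    return {
        "n_stems": n_stems,
        "n_bifs": n_bifs,
        "n_branch": n_branch,
        "width": width,
        "height": height,
        "diameter": diameter,
        "length": length,
        "surface": surface,
        "volume": volume,
        "euc_distance": euc_distance,
        "path_distance": path_distance,
        "branch_order": branch_order,
        "contraction": sum(contr) / len(contr),
        "fragmentation": fragmentation,
        "partition_asymmetry": partition_asymmetry,
        "pk_classic": sum(pks) / len(pks) if pks else 0.0,
        "bif_ampl_local": sum(locals_) / len(locals_) if locals_ else 0.0,
        "bif_ampl_remote": sum(remotes) / len(remotes) if remotes else 0.0,
        "fractal_dim": sum(slopes) / len(slopes) if slopes else 0.0,
    }


def oracle_abel(m):
    """Mean per-branch Euclidean length, straight from the geometry."""
    segs = oracle_branches(m)
    eucs = [_dist(_pos(m, s[0]), _pos(m, s[-1])) for s in segs]
    return sum(eucs) / len(eucs)


def oracle_threshold(values, labels):
    """Exhaustive O(n^2) scan over every midpoint cut and both polarities.

    Returns (threshold, polarity, accuracy) with ties resolved exactly as
    documented: smallest threshold first, glia_below before neuron_below.
    """
    vs = sorted(set(values))
    mids = [(a + b) / 2 for a, b in zip(vs[:-1], vs[1:])]
    cands = [vs[0] - 1.0] + mids + [vs[-1] + 1.0]
    n = len(values)
    best = None
    for polarity in ("glia_below", "neuron_below"):
        below = "glia" if polarity == "glia_below" else "neuron"
        above = "neuron" if polarity == "glia_below" else "glia"
        for t in cands:
            correct = sum(
                1
                for v, lab in zip(values, labels)
                if (below if v < t else above) == lab
            )
            acc = correct / n
            if best is None or acc > best[2]:
                best = (t, polarity, acc)
    return best
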