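"""Average Branch Euclidean Length (ABEL) and threshold/boundary classifiers.

ABEL is the mean, over all branches of a cell, of the straight-line distance
between the start and end point of each branch.  It is computed here as

    ABEL = sum_i (contraction_i * path_length_i) / NB

where NB is the branch count — algebraically identical to the mean
per-branch Euclidean length, since contraction = Euclidean / path length.
Glial processes have markedly smaller ABEL than neuronal dendrites, which
makes a single ABEL cut a strong neuron/glia classifier; combining ABEL
with arbor height in a linear boundary A = slope*H + intercept improves it
marginally.

Terminal branches (terminal degree 1, bifurcation to tip) and internal
branches (between consecutive bifurcations) get separate ABEL values; the
terminal/internal ratio is itself informative (about 2 for neurons, about 1
for glia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometrics import Branch

GLIA = "glia"
NEURON = "neuron"

GLIA_BELOW = "glia_below"
NEURON_BELOW = "neuron_below"


@dataclass(frozen=True)
class ABELProfile:
    """Overall / terminal / internal ABEL of one cell, all in μm."""

    abel: float
    abel_terminal: float
    abel_internal: float
    ratio_terminal_internal: float  # NaN when the cell has no internal branch
    n_branches: int

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio_terminal_internal)


@dataclass(frozen=True)
class SubsampleEstimate:
    """ABEL estimated from repeated small samples of branches."""

    n_sampled: int
    n_sets: int
    mean_abel: float
    sd_abel: float
    seed: int | None


@dataclass(frozen=True)
class ThresholdModel:
    """Univariate cut: cells with value < threshold are called glia
    (``glia_below`` polarity; the boundary value itself goes to the neuron
    side)."""

    threshold: float
    polarity: str = GLIA_BELOW
    training_accuracy: float = float("nan")


@dataclass(frozen=True)
class LinearBoundaryModel:
    """Line A = slope*H + intercept in the (height, ABEL) plane; under
    ``glia_below`` polarity a cell is glia iff A - slope*H - intercept < 0."""

    slope: float
    intercept: float
    polarity: str = GLIA_BELOW
    training_accuracy: float = float("nan")
    seed: int | None = None


@dataclass(frozen=True)
class BoundarySearchConfig:
    """Search space and method for the linear-boundary fit.

    The default method is a deterministic coarse-to-fine grid search;
    ``method="swarm"`` uses a seeded particle swarm instead.
    """

    slope_bounds: tuple[float, float] = (-2.0, 2.0)
    intercept_bounds: tuple[float, float] = (-50.0, 200.0)
    grid_size: int = 41
    refine_levels: int = 4
    method: str = "grid"
    n_particles: int = 40
    n_iterations: int = 80
    seed: int | None = 0


# ---------------------------------------------------------------------------
# ABEL computation


def compute_abel(branches: Sequence[Branch]) -> ABELProfile:
    """ABEL profile of one cell from its decomposed branches."""
    if not branches:
        raise ValueError("compute_abel needs at least one branch")
    prod = np.array([b.contraction * b.path_length for b in branches])
    nb = len(branches)
    abel = float(prod.sum() / nb)

    term = prod[[b.is_terminal for b in branches]]
    internal = prod[[not b.is_terminal for b in branches]]
    abel_t = float(term.mean()) if term.size else float("nan")
    abel_i = float(internal.mean()) if internal.size else float("nan")
    ratio = abel_t / abel_i if internal.size and term.size and abel_i != 0 else float("nan")
    return ABELProfile(
        abel=abel,
        abel_terminal=abel_t,
        abel_internal=abel_i,
        ratio_terminal_internal=ratio,
        n_branches=nb,
    )


def branch_euclidean_lengths(branches: Sequence[Branch]) -> np.ndarray:
    """Per-branch Euclidean lengths (contraction × path length), in μm."""
    return np.array([b.contraction * b.path_length for b in branches])


def subsample_abel(
    branch_euclidean_lengths: Sequence[float],
    N: int,
    n_sets: int = 100,
    seed: int | None | np.random.Generator = None,
) -> SubsampleEstimate:
    """Estimate ABEL from ``n_sets`` random samples of ``N`` branches each.

    Within a set, branches are drawn without replacement; the set mean is an
    ABEL estimate, and the mean and standard deviation over sets are
    reported.  Mirrors using only a handful of branches to classify a cell
    instead of tracing the full arbor.
    """
    lengths = np.asarray(branch_euclidean_lengths, dtype=float)
    nb = lengths.size
    if not 1 <= N <= nb:
        raise ValueError(f"N={N} must be between 1 and the branch count NB={nb}")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    means = np.array([rng.choice(lengths, size=N, replace=False).mean() for _ in range(n_sets)])
    sd = float(means.std(ddof=1)) if n_sets > 1 else 0.0
    return SubsampleEstimate(
        n_sampled=N, n_sets=n_sets, mean_abel=float(means.mean()), sd_abel=sd, seed=seed_out
    )


# ---------------------------------------------------------------------------
# threshold classifier


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    is_glia = arr == GLIA
    is_neuron = arr == NEURON
    if not (is_glia | is_neuron).all():
        bad = sorted(set(arr[~(is_glia | is_neuron)]))
        raise ValueError(f"labels must be '{GLIA}' or '{NEURON}'; got {bad}")
    return is_glia


def fit_threshold(values: Sequence[float], labels: Sequence[str]) -> ThresholdModel:
    """Exhaustively fit the accuracy-maximizing univariate cut.

    Candidate thresholds are the midpoints between adjacent sorted unique
    values plus one sentinel below the minimum and one above the maximum.
    Both polarities are scored; ties go to the smallest threshold, and
    between polarities of equal accuracy to ``glia_below``.
    """
    v = np.asarray(values, dtype=float)
    is_glia = _as_binary(labels)
    if is_glia.all() or not is_glia.any():
        raise ValueError("both classes must be present to fit a threshold")
    n = v.size

    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    order = np.argsort(v, kind="stable")
    sorted_glia = is_glia[order].astype(int)
    # for threshold t, cells with value < t are "below"
    n_below = np.searchsorted(np.sort(v), candidates, side="left")
    glia_below_cum = np.concatenate(([0], np.cumsum(sorted_glia)))
    glia_below = glia_below_cum[n_below]
    neuron_above = (n - n_below) - (is_glia.sum() - glia_below)

    correct_gb = glia_below + neuron_above  # integer counts: glia called below t
    acc_gb = correct_gb / n
    acc_nb = (n - correct_gb) / n           # neuron called below t

    best_gb = int(np.argmax(acc_gb))  # argmax takes the first (smallest t) tie
    best_nb = int(np.argmax(acc_nb))
    if acc_gb[best_gb] >= acc_nb[best_nb]:
        return ThresholdModel(
            threshold=float(candidates[best_gb]),
            polarity=GLIA_BELOW,
            training_accuracy=float(acc_gb[best_gb]),
        )
    return ThresholdModel(
        threshold=float(candidates[best_nb]),
        polarity=NEURON_BELOW,
        training_accuracy=float(acc_nb[best_nb]),
    )


def classify_threshold(model: ThresholdModel, values):
    """Classify value(s); a value exactly at the threshold is assigned to the
    class *above* the cut (the neuron side under ``glia_below`` polarity)."""
    v = np.asarray(values, dtype=float)
    below, above = (GLIA, NEURON) if model.polarity == GLIA_BELOW else (NEURON, GLIA)
    out = np.where(v < model.threshold, below, above)
    return out.item() if np.isscalar(values) or v.ndim == 0 else out


# ---------------------------------------------------------------------------
# linear boundary classifier


def _boundary_accuracy(
    abel: np.ndarray, height: np.ndarray, is_glia: np.ndarray,
    slopes: np.ndarray, intercepts: np.ndarray, polarity: str,
) -> np.ndarray:
    """Training accuracy for every (slope, intercept) pair (broadcast)."""
    # residual r = A - slope*H - intercept; glia iff r < 0 under glia_below
    r = abel[:, None] - np.outer(height, slopes) - intercepts[None, :]
    pred_glia = r < 0 if polarity == GLIA_BELOW else r >= 0
    return (pred_glia == is_glia[:, None]).mean(axis=0)


def fit_linear_boundary(
    abel: Sequence[float],
    height: Sequence[float],
    labels: Sequence[str],
    config: BoundarySearchConfig | None = None,
) -> LinearBoundaryModel:
    """Fit the accuracy-maximizing line A = slope*H + intercept.

    The default deterministic optimizer is a coarse-to-fine grid search over
    the configured slope/intercept bounds; ``config.method="swarm"`` runs a
    seeded particle swarm instead.  In both cases the ABEL-only threshold
    (slope = 0) is evaluated as an explicit candidate, so the reported
    training accuracy never falls below the best univariate ABEL cut.
    """
    config = config or BoundarySearchConfig()
    A = np.asarray(abel, dtype=float)
    H = np.asarray(height, dtype=float)
    is_glia = _as_binary(labels)
    if is_glia.all() or not is_glia.any():
        raise ValueError("both classes must be present")
    if np.ptp(A) == 0 and np.ptp(H) == 0:
        raise ValueError("degenerate constant predictors")

    if config.method == "grid":
        best = _grid_search(A, H, is_glia, config)
    elif config.method == "swarm":
        best = _swarm_search(A, H, is_glia, config)
    else:
        raise ValueError(f"unknown boundary search method {config.method!r}")
    slope, intercept, polarity, acc = best

    # nesting guarantee: the univariate ABEL threshold as a slope-0 boundary
    tm = fit_threshold(A, np.where(is_glia, GLIA, NEURON))
    t_polarity = GLIA_BELOW if tm.polarity == GLIA_BELOW else NEURON_BELOW
    if tm.training_accuracy > acc:
        slope, intercept, polarity, acc = 0.0, tm.threshold, t_polarity, tm.training_accuracy

    return LinearBoundaryModel(
        slope=float(slope),
        intercept=float(intercept),
        polarity=polarity,
        training_accuracy=float(acc),
        seed=config.seed if config.method == "swarm" else None,
    )


def _grid_search(A, H, is_glia, config: BoundarySearchConfig):
    slo, shi = config.slope_bounds
    ilo, ihi = config.intercept_bounds
    best = (0.0, 0.0, GLIA_BELOW, -1.0)
    for _ in range(config.refine_levels):
        slopes = np.linspace(slo, shi, config.grid_size)
        intercepts = np.linspace(ilo, ihi, config.grid_size)
        sg, ig = np.meshgrid(slopes, intercepts, indexing="ij")
        for polarity in (GLIA_BELOW, NEURON_BELOW):
            acc = _boundary_accuracy(A, H, is_glia, sg.ravel(), ig.ravel(), polarity)
            k = int(np.argmax(acc))
            if acc[k] > best[3]:
                best = (sg.ravel()[k], ig.ravel()[k], polarity, float(acc[k]))
        # zoom on the current optimum
        sstep = (shi - slo) / (config.grid_size - 1)
        istep = (ihi - ilo) / (config.grid_size - 1)
        slo, shi = best[0] - 2 * sstep, best[0] + 2 * sstep
        ilo, ihi = best[1] - 2 * istep, best[1] + 2 * istep
    return best


def _swarm_search(A, H, is_glia, config: BoundarySearchConfig):
    """Plain global-best particle swarm over (slope, intercept), seeded."""
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.slope_bounds[0], config.intercept_bounds[0]])
    hi = np.array([config.slope_bounds[1], config.intercept_bounds[1]])
    best = (0.0, 0.0, GLIA_BELOW, -1.0)
    for polarity in (GLIA_BELOW, NEURON_BELOW):
        x = rng.uniform(lo, hi, size=(config.n_particles, 2))
        v = np.zeros_like(x)
        pbest = x.copy()
        pbest_acc = _boundary_accuracy(A, H, is_glia, x[:, 0], x[:, 1], polarity)
        g = int(np.argmax(pbest_acc))
        gbest, gbest_acc = pbest[g].copy(), float(pbest_acc[g])
        w, c1, c2 = 0.72, 1.49, 1.49
        for _ in range(config.n_iterations):
            r1 = rng.random(x.shape)
            r2 = rng.random(x.shape)
            v = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
            x = np.clip(x + v, lo, hi)
            acc = _boundary_accuracy(A, H, is_glia, x[:, 0], x[:, 1], polarity)
            improved = acc > pbest_acc
            pbest[improved] = x[improved]
            pbest_acc[improved] = acc[improved]
            g = int(np.argmax(pbest_acc))
            if pbest_acc[g] > gbest_acc:
                gbest, gbest_acc = pbest[g].copy(), float(pbest_acc[g])
        if gbest_acc > best[3]:
            best = (float(gbest[0]), float(gbest[1]), polarity, gbest_acc)
    return best


def classify_linear_boundary(model: LinearBoundaryModel, abel, height):
    """Classify cells by which side of the line A = slope*H + intercept they
    fall on; points exactly on the line go to the side above it."""
    A = np.asarray(abel, dtype=float)
    H = np.asarray(height, dtype=float)
    r = A - model.slope * H - model.intercept
    below, above = (GLIA, NEURON) if model.polarity == GLIA_BELOW else (NEURON, GLIA)
    out = np.where(r < 0, below, above)
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# diagnostics


def misclassification_profile(
    values: Sequence[float],
    labels: Sequence[str],
    model: ThresholdModel,
    bin_width: float,
) -> pd.DataFrame:
    """Histogram of misclassified cells by value bin.

    Returns a frame with ``bin_left``, ``bin_right``, ``n_misclassified``
    covering the observed value range; useful for showing that errors
    concentrate in a narrow band around the threshold.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pred = classify_threshold(model, v)
    lo = math.floor(v.min() / bin_width) * bin_width
    hi = math.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v[pred != y], bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_misclassified": counts}
    )


def misclassified_fraction_in_interval(
    values, labels, model: ThresholdModel, lo: float, hi: float
) -> float:
    """Fraction of all misclassified cells whose value lies in [lo, hi)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    mis = v[classify_threshold(model, v) != y]
    if mis.size == 0:
        return float("nan")
    return float(((mis >= lo) & (mis < hi)).mean())


def grouped_accuracy(values, labels, groups, model: ThresholdModel) -> pd.DataFrame:
    """Per-group classification accuracy table (accuracy, n, n_misclassified).

    ``groups`` is any per-cell key (species, sex, archive, ...); grouping by
    the label itself yields per-class sensitivity/specificity.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    correct = classify_threshold(model, v) == y
    df = pd.DataFrame({"group": np.asarray(groups), "correct": correct})
    out = df.groupby("group", sort=True)["correct"].agg(
        n="size", n_misclassified=lambda c: int((~c).sum()), accuracy="mean"
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# reports and model persistence


def abel_table(profiles: dict[str, ABELProfile]) -> pd.DataFrame:
    """One row per cell: abel, abel_terminal, abel_internal, ratio, NB."""
    rows = {
        cid: {
            "abel": p.abel,
            "abel_terminal": p.abel_terminal,
            "abel_internal": p.abel_internal,
            "ratio_terminal_internal": p.ratio_terminal_internal,
            "n_branches": p.n_branches,
        }
        for cid, p in profiles.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cell_id"
    return df


def save_model(model: ThresholdModel | LinearBoundaryModel, path: str | Path) -> None:
    """Write a model as plain-text ``key = value`` lines for exact reload."""
    lines = [f"kind = {type(model).__name__}"]
    for name, val in vars(model).items():
        lines.append(f"{name} = {val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path):
    pairs = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        pairs[key.strip()] = val.strip()
    kind = pairs.pop("kind")
    cls = {"ThresholdModel": ThresholdModel, "LinearBoundaryModel": LinearBoundaryModel}[kind]
    import ast

    return cls(**{k: ast.literal_eval(v) for k, v in pairs.items()})
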