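"""Selection features, snapshot ranking, phase switching, edge expansion.

Each cycle every generated snapshot gets a scalar selection feature
(RMSD to a target, RMSD from the start, inter-group centre-of-mass
distance, or a user-supplied template feature); snapshots are rank ordered
and the top ``n_replica`` become the seeds of the next cycle.  The
association/dissociation variant alternates the ranking direction through
a small state machine, and the edge-expansion variant picks convex-hull
vertices of the accumulated conformational cloud instead of a scalar
ranking.
"""

from __future__ import annotations

import dataclasses
import importlib.util
import re
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .config_io import Config, Snapshot
from .geometry import (AtomGroup, DegenerateFitError, com_distance,
                       convex_hull, pca_project, rmsd, rmsd_after_fit)

__all__ = [
    "ADState", "FeatureValue", "RankedCandidate", "SelectionError",
    "SelectionSpec", "ad_update", "build_spec", "direction_of",
    "evaluate_feature", "ee_select", "rank_and_select", "resolve_selection",
    "template_hook",
]

Direction = Literal["minimize", "maximize"]


class SelectionError(ValueError):
    """Unresolvable selection string, group, or feature specification."""


# ---------------------------------------------------------------------------
# Atom-group selection dialect
# ---------------------------------------------------------------------------

_RANGE = re.compile(r"^(\d+)(?:-(\d+))?$")


def _parse_ranges(spec: str, what: str) -> set[int]:
    out: set[int] = set()
    for token in spec.split(","):
        m = _RANGE.match(token.strip())
        if m is None:
            raise SelectionError(f"bad {what} range '{token}'")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if hi < lo:
            raise SelectionError(f"empty {what} range '{token}'")
        out.update(range(lo, hi + 1))
    return out


def resolve_selection(snapshot: Snapshot, expr: str) -> AtomGroup:
    """Resolve a group-selection string against a structure.

    One internal dialect is implemented: clauses joined by ``and``, each of
    ``all``, ``resid 1-68,70``, ``name CA,CB`` or ``index 0-5`` (0-based
    atom indices).  Example: ``"resid 1-68 and name CA"``.
    """
    n = snapshot.n_atoms
    mask = np.ones(n, dtype=bool)
    expr = expr.strip()
    if not expr:
        raise SelectionError("empty selection string")
    for clause in re.split(r"\band\b", expr):
        clause = clause.strip()
        if clause == "all":
            continue
        parts = clause.split(None, 1)
        if len(parts) != 2:
            raise SelectionError(f"cannot parse selection clause '{clause}'")
        key, arg = parts
        if key == "resid":
            if snapshot.resids is None:
                raise SelectionError("structure has no residue numbers")
            wanted = _parse_ranges(arg, "resid")
            mask &= np.isin(snapshot.resids, sorted(wanted))
        elif key == "name":
            if snapshot.atom_names is None:
                raise SelectionError("structure has no atom names")
            wanted_names = {t.strip() for t in arg.split(",")}
            mask &= np.isin(np.asarray(snapshot.atom_names), sorted(wanted_names))
        elif key == "index":
            wanted = _parse_ranges(arg, "index")
            mask &= np.isin(np.arange(n), sorted(wanted))
        else:
            raise SelectionError(f"unknown selection keyword '{key}'")
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(f"selection '{expr}' matches no atoms")
    masses = (np.asarray(snapshot.masses, dtype=float)[indices]
              if snapshot.masses is not None else np.ones(len(indices)))
    return AtomGroup(indices, masses)


# ---------------------------------------------------------------------------
# Feature values and ranking
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, order=True)
class FeatureValue:
    """Selection-feature value of one snapshot with its provenance."""

    trial: int
    cycle: int
    replica: int
    frame: int
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("feature value must be finite")
        if min(self.trial, self.cycle, self.replica, self.frame) < 0:
            raise ValueError("provenance indices must be non-negative")


@dataclasses.dataclass(frozen=True)
class RankedCandidate:
    feature: FeatureValue
    rank: int  # 1-based; rank 1 is the best in the feature direction


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Resolved selection setup for one run.

    ``kind`` is one of the cascade variants; groups are resolved atom
    groups (``group3``/``group4`` remap the reference numbering); the
    template variant carries the user evaluator instead.
    """

    kind: str
    group1: AtomGroup | None = None
    group2: AtomGroup | None = None
    group3: AtomGroup | None = None
    group4: AtomGroup | None = None
    reference: Snapshot | None = None
    evaluator: Callable[[Sequence[Snapshot]], np.ndarray] | None = None
    direction: Direction = "minimize"
    mass_weighted_rmsd: bool = False


_DIRECTIONS: dict[str, Direction] = {
    "target": "minimize",
    "association": "minimize",
    "rmsd": "maximize",
    "dissociation": "maximize",
}


def direction_of(kind: str, ad_phase: str | None = None,
                 template_direction: Direction | None = None) -> Direction:
    """Ranking direction for a cascade variant."""
    if kind == "a_d":
        if ad_phase not in ("dissociation", "association"):
            raise SelectionError("a_d direction requires the current phase")
        return _DIRECTIONS[ad_phase]
    if kind == "template":
        if template_direction is None:
            raise SelectionError("template direction not provided")
        return template_direction
    if kind == "ee":
        return "maximize"  # hull-vertex distance from centroid
    try:
        return _DIRECTIONS[kind]
    except KeyError:
        raise SelectionError(f"unknown selection kind '{kind}'") from None


def build_spec(cfg: Config, initial: Snapshot,
               reference: Snapshot | None = None,
               evaluator=None) -> SelectionSpec:
    """Resolve configuration selections against the initial structure."""
    kind = cfg.type
    if kind == "template":
        if evaluator is None:
            raise SelectionError("template type requires a loaded template "
                                 "module (see template_hook)")
        return SelectionSpec(kind=kind, evaluator=evaluator.evaluate,
                             direction=evaluator.direction())

    g1 = resolve_selection(initial, cfg.selection1 or "all")
    g2 = resolve_selection(initial, cfg.selection2 or "all")
    if kind in ("dissociation", "association", "a_d", "ee"):
        return SelectionSpec(kind=kind, group1=g1, group2=g2,
                             direction=direction_of(kind, ad_phase="dissociation"
                                                    if kind == "a_d" else None))
    # RMSD-type features
    if kind == "rmsd":
        reference = initial
    if reference is None:
        raise SelectionError(f"type '{kind}' requires a reference structure")
    g3 = resolve_selection(reference, cfg.selection3 or cfg.selection1 or "all")
    g4 = resolve_selection(reference, cfg.selection4 or cfg.selection2 or "all")
    if len(g3) != len(g1) or len(g4) != len(g2):
        raise SelectionError("reference selections (selection3/selection4) "
                             "must match selection1/selection2 in size")
    return SelectionSpec(kind=kind, group1=g1, group2=g2, group3=g3,
                         group4=g4, reference=reference,
                         direction=direction_of(kind))


def _rmsd_feature(snap: Snapshot, spec: SelectionSpec) -> float:
    ref = spec.reference
    assert ref is not None
    # A best fit needs three non-collinear atoms; tiny toy systems fall
    # back to plain RMSD over the measured group.
    try:
        return rmsd_after_fit(snap.coords, ref.coords, spec.group1,
                              rmsd_group=spec.group2,
                              ref_fit_group=spec.group3,
                              ref_rmsd_group=spec.group4,
                              mass_weighted=spec.mass_weighted_rmsd)
    except DegenerateFitError:
        return rmsd(snap.coords, ref.coords, spec.group2,
                    ref_group=spec.group4,
                    mass_weighted=spec.mass_weighted_rmsd)


def evaluate_feature(traj: Sequence[Snapshot],
                     spec: SelectionSpec) -> list[FeatureValue]:
    """Selection feature for every frame of one replica trajectory."""
    traj = list(traj)
    if not traj:
        raise ValueError("empty trajectory")
    if spec.kind == "template":
        assert spec.evaluator is not None
        values = np.asarray(spec.evaluator(traj), dtype=float)
        if values.shape != (len(traj),):
            raise SelectionError("template evaluator must return one scalar "
                                 "per frame")
    elif spec.kind in ("dissociation", "association", "a_d"):
        values = np.array([com_distance(s.coords, spec.group1, spec.group2)
                           for s in traj])
    elif spec.kind in ("target", "rmsd"):
        values = np.array([_rmsd_feature(s, spec) for s in traj])
    else:
        raise SelectionError(f"no scalar feature for kind '{spec.kind}'")
    return [FeatureValue(trial=s.trial, cycle=s.cycle, replica=s.replica,
                         frame=s.frame, value=float(v))
            for s, v in zip(traj, values)]


def rank_and_select(values: Sequence[FeatureValue], n_rep: int,
                    direction: Direction) -> list[RankedCandidate]:
    """Rank candidates and pick seeds for the next cycle.

    Sorted by value (ascending for ``minimize``, descending for
    ``maximize``) with ties broken by (cycle, replica, frame) ascending.
    If there are fewer candidates than ``n_rep``, seeds are reused
    cyclically so exactly ``n_rep`` seeds emerge; ranks stay unique.
    """
    values = list(values)
    if not values:
        raise ValueError("no candidate feature values")
    if direction not in ("minimize", "maximize"):
        raise ValueError(f"unknown direction '{direction}'")
    sign = 1.0 if direction == "minimize" else -1.0
    ordered = sorted(values, key=lambda f: (sign * f.value, f.cycle,
                                            f.replica, f.frame))
    picked = ordered[:n_rep]
    out = []
    for r in range(n_rep):
        out.append(RankedCandidate(feature=picked[r % len(picked)],
                                   rank=r + 1))
    return out


# ---------------------------------------------------------------------------
# Association/dissociation phase switching
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ADState:
    """State machine of the alternating association/dissociation variant.

    In the dissociation phase the pair is driven apart until the cycle-best
    d_com reaches ``d_threshold``; then association cycles pull it back in.
    Association "stacks" when the cycle best (minimum d_com over the first
    ``frame_sel`` frames of each replica) stops decreasing; after
    ``bound_threshold`` consecutive stacked cycles the walk flips back to
    dissociation.
    """

    phase: Literal["dissociation", "association"] = "dissociation"
    stack_counter: int = 0
    best_history: tuple[float, ...] = ()


def ad_update(state: ADState, cycle_values: Sequence[Sequence[FeatureValue]],
              cfg: Config) -> ADState:
    """Advance the a/d state machine with one cycle of per-replica values."""
    if cfg.type != "a_d":
        raise SelectionError("ad_update only applies to type 'a_d'")
    for key in ("d_threshold", "bound_threshold", "frame_sel"):
        if getattr(cfg, key) is None:
            raise SelectionError(f"a_d requires the '{key}' keyword")
    per_replica = [list(v) for v in cycle_values]
    if not per_replica or any(not v for v in per_replica):
        raise ValueError("cycle_values must hold values for every replica")

    if state.phase == "dissociation":
        best = max(f.value for rep in per_replica for f in rep)
        if best >= cfg.d_threshold:
            return ADState(phase="association", stack_counter=0,
                           best_history=())
        return ADState(phase="dissociation", stack_counter=0,
                       best_history=state.best_history + (best,))

    # association: compare per-replica minima over the first frame_sel frames
    best = min(min(f.value for f in rep[:cfg.frame_sel]) for rep in per_replica)
    history = state.best_history + (best,)
    prev = state.best_history[-1] if state.best_history else None
    improved = prev is None or best < prev
    counter = 0 if improved else state.stack_counter + 1
    if counter >= cfg.bound_threshold:
        return ADState(phase="dissociation", stack_counter=0, best_history=())
    return ADState(phase="association", stack_counter=counter,
                   best_history=history)


# ---------------------------------------------------------------------------
# Edge expansion
# ---------------------------------------------------------------------------


def ee_select(features: np.ndarray, meta: Sequence[tuple[int, int, int]],
              n_rep: int, dims: int = 2,
              trial: int = 1) -> list[RankedCandidate]:
    """Edge-expansion selection over the accumulated conformational cloud.

    ``features`` is the (M, D) descriptor matrix of every snapshot sampled
    so far and ``meta`` the matching (cycle, replica, frame) provenance.
    Snapshots are projected onto ``dims`` principal components; the convex
    hull vertices of the projection, ranked by descending distance from the
    projected centroid, become the seeds.  If the hull has fewer vertices
    than ``n_rep``, the remaining slots are filled with the non-vertex
    points closest to the hull facets.
    """
    features = np.asarray(features, dtype=float)
    if len(meta) != features.shape[0]:
        raise ValueError("meta must match the feature matrix")
    if features.shape[0] < dims + 1:
        raise ValueError("need at least dims + 1 accumulated snapshots")
    scores, _ = pca_project(features, dims)
    hull = convex_hull(scores)
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)

    def order_key(i: int, primary: float):
        c, r, f = meta[i]
        return (primary, c, r, f)

    vertices = sorted(hull.vertex_indices,
                      key=lambda i: order_key(i, -dist[i]))
    chosen = vertices[:n_rep]
    if len(chosen) < n_rep:
        inside = [i for i in range(len(meta)) if i not in set(vertices)]
        # fill with points nearest to the hull boundary
        boundary_dist = hull.distance_inside(scores)
        inside.sort(key=lambda i: order_key(i, boundary_dist[i]))
        chosen = chosen + inside[: n_rep - len(chosen)]
    out = []
    for rank, i in enumerate((chosen * (n_rep // max(len(chosen), 1) + 1))[:n_rep],
                             start=1):
        c, r, f = meta[i]
        out.append(RankedCandidate(
            feature=FeatureValue(trial=trial, cycle=c, replica=r, frame=f,
                                 value=float(dist[i])),
            rank=rank))
    return out


# ---------------------------------------------------------------------------
# Template hook
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TemplateFeature:
    """User feature loaded from a template module."""

    prepare: Callable
    evaluate: Callable
    direction: Callable[[], Direction]
    context: object = None

    def bind(self, cfg: Config) -> "TemplateFeature":
        self.context = self.prepare(cfg)
        ctx = self.context
        raw = self.evaluate
        self.evaluate = lambda traj: raw(traj, ctx)
        return self


def template_hook(user_module: str | Path) -> TemplateFeature:
    """Load a user feature module defining ``prepare``, ``evaluate`` and
    ``direction``; a missing callable raises an error naming it."""
    path = Path(user_module)
    if not path.exists():
        raise SelectionError(f"template module not found: {path}")
    spec = importlib.util.spec_from_file_location(path.stem, path)
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)  # type: ignore[union-attr]
    missing = [name for name in ("prepare", "evaluate", "direction")
               if not callable(getattr(module, name, None))]
    if missing:
        raise SelectionError(
            f"template module {path} is missing callable(s): "
            f"{', '.join(missing)}")
    return TemplateFeature(prepare=module.prepare, evaluate=module.evaluate,
                           direction=module.direction)
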