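"""Post-cascade utilities: representative pathways, refitting, COM
trajectories, atom-subset reduction, file cleanup, and MSM feature export.

All tools operate on a completed (or at least partially completed) trial
directory written by :func:`pacsmd.engine.run_trial`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config_io import Snapshot, read_trajectory, write_trajectory
from .engine import (LINEAGE_NAME, STATE_NAME, SUMMARY_NAME, LineageRecord,
                     load_lineage, load_summary)
from .geometry import (AtomGroup, apply_transform, center_of_mass, rmsd,
                       superpose)
from .selection import resolve_selection

__all__ = [
    "LineageError", "RepresentativePath", "DeletionReport", "fit_trajectory",
    "gencom", "genfeature", "genrepresent", "load_feature_arrays", "rmfile",
    "rmmol",
]


class LineageError(RuntimeError):
    """A parent link needed for pathway reconstruction is missing."""


@dataclasses.dataclass
class RepresentativePath:
    """One conformational pathway from cycle 0 to the terminal snapshot.

    ``frames`` run in cycle order; ``provenance`` holds the matching
    (cycle, replica, frame) triples and ``values`` the per-frame selection
    feature.
    """

    frames: list[Snapshot]
    provenance: list[tuple[int, int, int]]
    values: list[float]


def _trial_info(trial_dir: Path) -> dict:
    state_path = Path(trial_dir) / STATE_NAME
    if not state_path.exists():
        raise LineageError(f"{trial_dir}: no trial state file")
    return json.loads(state_path.read_text())


def _cycles(trial_dir: Path) -> list[int]:
    return sorted(int(p.name[5:]) for p in Path(trial_dir).glob("cycle???")
                  if (p / SUMMARY_NAME).exists())


def _replica_traj(trial_dir: Path, cycle: int, replica: int) -> list[Snapshot]:
    path = (Path(trial_dir) / f"cycle{cycle:03d}" / f"replica{replica:03d}"
            / "traj.npz")
    if not path.exists():
        raise LineageError(f"missing trajectory: cycle {cycle} "
                           f"replica {replica}")
    traj = read_trajectory(path)
    return [s.with_provenance(cycle=cycle, replica=replica, frame=i)
            for i, s in enumerate(traj)]


def genrepresent(trial_dir: str | Path,
                 criterion: str = "final") -> RepresentativePath:
    """Extract the representative pathway of a trial.

    ``criterion='final'`` picks the snapshot optimising the selection
    feature in the final cycle; ``'global'`` optimises over all cycles.
    The pathway walks the lineage back to cycle 0 and concatenates each
    ancestor replica's frames up to and including its selected frame — the
    part of each branch that is actually on the path — ending at the
    terminal snapshot.  Ties are broken by the lower (replica, frame).
    """
    trial_dir = Path(trial_dir)
    info = _trial_info(trial_dir)
    direction = info.get("direction", "minimize")
    sign = 1.0 if direction == "minimize" else -1.0
    cycles = _cycles(trial_dir)
    if not cycles:
        raise LineageError(f"{trial_dir}: no completed cycles")

    if criterion == "final":
        search = [cycles[-1]]
    elif criterion == "global":
        search = cycles
    else:
        raise ValueError(f"unknown criterion '{criterion}'")
    candidates = []
    for c in search:
        candidates.extend(load_summary(trial_dir / f"cycle{c:03d}"))
    best = min(candidates, key=lambda f: (sign * f.value, f.cycle, f.replica,
                                          f.frame))

    lineage = {(rec.child_cycle, rec.child_replica): rec
               for rec in load_lineage(trial_dir)}
    # walk back to cycle 0 collecting (cycle, replica, last_frame)
    segments: list[tuple[int, int, int]] = [(best.cycle, best.replica,
                                             best.frame)]
    cycle, replica = best.cycle, best.replica
    while cycle > 0:
        rec = lineage.get((cycle, replica))
        if rec is None:
            raise LineageError(f"broken lineage: no parent recorded for "
                               f"cycle {cycle} replica {replica}")
        segments.append((rec.parent_cycle, rec.parent_replica,
                         rec.parent_frame))
        cycle, replica = rec.parent_cycle, rec.parent_replica
    segments.reverse()

    values_by_cycle = {
        c: {(f.replica, f.frame): f.value
            for f in load_summary(trial_dir / f"cycle{c:03d}")}
        for c in {s[0] for s in segments}
    }
    frames: list[Snapshot] = []
    provenance: list[tuple[int, int, int]] = []
    values: list[float] = []
    for c, r, last in segments:
        traj = _replica_traj(trial_dir, c, r)
        for snap in traj[: last + 1]:
            frames.append(snap)
            provenance.append((c, r, snap.frame))
            values.append(values_by_cycle[c].get((r, snap.frame), np.nan))
    return RepresentativePath(frames=frames, provenance=provenance,
                              values=values)


def fit_trajectory(traj: Sequence[Snapshot], reference: Snapshot,
                   fit_group: AtomGroup,
                   ref_fit_group: AtomGroup | None = None,
                   mass_weighted: bool = False) -> list[Snapshot]:
    """Superpose every frame onto the reference over the fit group."""
    out = []
    for snap in traj:
        rot, trans = superpose(snap.coords, reference.coords, fit_group,
                               ref_fit_group=ref_fit_group,
                               mass_weighted=mass_weighted)
        fitted = snap.copy()
        fitted.coords = apply_transform(snap.coords, rot, trans)
        if fitted.velocities is not None:
            fitted.velocities = fitted.velocities @ rot.T
        out.append(fitted)
    return out


def gencom(traj: Sequence[Snapshot], group: AtomGroup,
           path: str | Path | None = None) -> np.ndarray:
    """Centre-of-mass pseudo-trajectory of a group.

    Returns the (n_frames, 3) COM positions; when ``path`` is given, also
    writes them as a multi-model PDB with one pseudo-atom per model.
    """
    traj = list(traj)
    if not traj:
        raise ValueError("empty trajectory")
    coms = np.array([center_of_mass(s.coords, group) for s in traj])
    if path is not None:
        frames = [Snapshot(coords=c[None, :], atom_names=["COM"],
                           resids=np.array([1]), frame=i)
                  for i, c in enumerate(coms)]
        write_trajectory(frames, path, "pdb")
    return coms


def rmmol(traj: Sequence[Snapshot], keep_group: AtomGroup) -> list[Snapshot]:
    """Reduce every frame to the kept atom group, preserving coordinates."""
    if len(keep_group) == 0:
        raise ValueError("keep_group is empty")
    out = []
    idx = keep_group.indices
    for snap in traj:
        red = Snapshot(
            coords=snap.coords[idx].copy(),
            velocities=None if snap.velocities is None
            else snap.velocities[idx].copy(),
            masses=None if snap.masses is None
            else np.asarray(snap.masses)[idx].copy(),
            atom_names=None if snap.atom_names is None
            else [snap.atom_names[i] for i in idx],
            resids=None if snap.resids is None
            else np.asarray(snap.resids)[idx].copy(),
            trial=snap.trial, cycle=snap.cycle, replica=snap.replica,
            frame=snap.frame)
        out.append(red)
    return out


@dataclasses.dataclass
class DeletionReport:
    targets: list[Path]
    deleted: list[Path]


#: Files rmfile must never touch.
_PROTECTED = (SUMMARY_NAME, LINEAGE_NAME, STATE_NAME)


def rmfile(trial_dir: str | Path, policy: str = "dry-run") -> DeletionReport:
    """Remove files unnecessary after a finished trial.

    Targets the raw full trajectories and seed/final structure files inside
    the replica directories.  Ranking CSVs, lineage records, the trial
    state, and reduced trajectories (``*_reduced.*``) are never deleted.
    ``dry-run`` lists the targets without removing anything; an unfinished
    trial is refused.
    """
    if policy not in ("dry-run", "execute"):
        raise ValueError("policy must be 'dry-run' or 'execute'")
    trial_dir = Path(trial_dir)
    info = _trial_info(trial_dir)
    if info.get("stop_reason") is None:
        raise RuntimeError(f"{trial_dir}: trial has not finished; refusing "
                           "to clean up")
    targets = []
    for path in sorted(trial_dir.glob("cycle???/replica???/*")):
        if not path.is_file():
            continue
        if path.name in _PROTECTED or "_reduced" in path.name:
            continue
        targets.append(path)
    deleted = []
    if policy == "execute":
        for path in targets:
            path.unlink()
            deleted.append(path)
    return DeletionReport(targets=targets, deleted=deleted)


FeatureFn = Callable[[list[Snapshot]], np.ndarray]


def _com_distance_feature(sel1: str, sel2: str) -> FeatureFn:
    def fn(traj: list[Snapshot]) -> np.ndarray:
        from .geometry import com_distance

        g1 = resolve_selection(traj[0], sel1)
        g2 = resolve_selection(traj[0], sel2)
        return np.array([com_distance(s.coords, g1, g2) for s in traj])
    return fn


def _rmsd_feature(reference: Snapshot, fit_sel: str, measure_sel: str,
                  mass_weighted: bool = False) -> FeatureFn:
    def fn(traj: list[Snapshot]) -> np.ndarray:
        from .selection import SelectionSpec, evaluate_feature

        g1 = resolve_selection(traj[0], fit_sel)
        g2 = resolve_selection(traj[0], measure_sel)
        g3 = resolve_selection(reference, fit_sel)
        g4 = resolve_selection(reference, measure_sel)
        spec = SelectionSpec(kind="target", group1=g1, group2=g2, group3=g3,
                             group4=g4, reference=reference,
                             mass_weighted_rmsd=mass_weighted)
        return np.array([f.value for f in evaluate_feature(traj, spec)])
    return fn


def genfeature(trial_dir: str | Path, feature: str | FeatureFn,
               out_dir: str | Path | None = None, *,
               selection1: str = "all", selection2: str = "all",
               reference: Snapshot | None = None) -> pd.DataFrame:
    """Compute an MSM feature for every (cycle, replica) trajectory.

    The MSM feature may differ from the selection feature of the run.
    ``feature`` is ``"com_distance"``, ``"rmsd"`` (needs ``reference``), or
    a callable mapping a trajectory to one scalar per frame.  One ``.npy``
    array per (cycle, replica) is written to ``out_dir`` together with an
    ``index.csv``; the index DataFrame is returned.
    """
    trial_dir = Path(trial_dir)
    out_dir = Path(out_dir) if out_dir is not None else trial_dir / "features"
    out_dir.mkdir(parents=True, exist_ok=True)

    if callable(feature):
        fn = feature
    elif feature == "com_distance":
        fn = _com_distance_feature(selection1, selection2)
    elif feature == "rmsd":
        if reference is None:
            raise ValueError("rmsd feature requires a reference snapshot")
        fn = _rmsd_feature(reference, selection1, selection2)
    else:
        raise ValueError(f"unresolvable feature spec '{feature}'")

    rows = []
    cycles = _cycles(trial_dir)
    if not cycles:
        raise LineageError(f"{trial_dir}: no completed cycles")
    for c in cycles:
        cdir = trial_dir / f"cycle{c:03d}"
        replicas = sorted(int(p.name[7:]) for p in cdir.glob("replica???"))
        summary = pd.read_csv(cdir / SUMMARY_NAME)
        expected = sorted(summary["replica"].unique())
        for r in expected:
            if r not in replicas:
                raise LineageError(f"missing replica directory: cycle {c} "
                                   f"replica {r}")
            traj = _replica_traj(trial_dir, c, r)
            values = np.asarray(fn(traj), dtype=float)
            if values.shape != (len(traj),):
                raise ValueError("feature function must return one value "
                                 "per frame")
            name = f"cycle{c:03d}_replica{r:03d}.npy"
            np.save(out_dir / name, values)
            rows.append({"cycle": c, "replica": r, "file": name,
                         "n_frames": len(values)})
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "index.csv", index=False)
    return index


def load_feature_arrays(feature_dir: str | Path) -> list[np.ndarray]:
    """Load the per-replica feature arrays written by :func:`genfeature`."""
    feature_dir = Path(feature_dir)
    index = pd.read_csv(feature_dir / "index.csv")
    return [np.load(feature_dir / row.file) for row in index.itertuples()]
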