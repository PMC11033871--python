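"""The cascade loop: run replicas, rank snapshots, reseed, record lineage.

A trial starts with cycle 0 (by default a single replica propagated from
the initial structure with freshly drawn velocities).  Each subsequent
cycle runs ``n_replica`` replicas from the exported seeds, evaluates the
selection feature on every snapshot, writes a per-cycle ranking CSV, and
stops when the threshold condition is met or ``max_cycle`` is reached.
Parent links (which snapshot seeded which replica) are recorded as the
lineage, the basis of representative-pathway reconstruction.
"""

from __future__ import annotations

import dataclasses
import json
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config_io import (Config, RunLayout, Snapshot, read_structure,
                        read_trajectory, write_structure)
from .dynamics import Backend, make_backend
from .selection import (ADState, FeatureValue, RankedCandidate, SelectionSpec,
                        ad_update, build_spec, direction_of, ee_select,
                        evaluate_feature, rank_and_select, template_hook)

__all__ = ["EngineError", "LineageRecord", "TrialState", "check_stop",
           "child_seed", "export_seeds", "run_trial", "load_lineage",
           "load_summary"]

SUMMARY_NAME = "summary.csv"
LINEAGE_NAME = "lineage.csv"
STATE_NAME = "state.json"
SEED_NAME = "seed.npz"


class EngineError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class LineageRecord:
    """Parent link: which (cycle, replica, frame) seeded which replica."""

    child_cycle: int
    child_replica: int
    parent_cycle: int
    parent_replica: int
    parent_frame: int
    feature_at_selection: float


@dataclasses.dataclass
class TrialState:
    trial: int
    current_cycle: int = 0
    stop_reason: Optional[str] = None  # None | "threshold" | "max_cycle"
    lineage: list[LineageRecord] = dataclasses.field(default_factory=list)
    ad_state: Optional[ADState] = None
    best_values: list[float] = dataclasses.field(default_factory=list)
    direction: str = "minimize"


def child_seed(root_seed: int, trial: int, cycle: int, replica: int) -> int:
    """Deterministic per-replica RNG seed, split from the trial root seed.

    Uses numpy's SeedSequence spawning so replicas are statistically
    independent and a rerun with the same root seed is bit-identical.
    """
    ss = np.random.SeedSequence(entropy=root_seed,
                                spawn_key=(trial, cycle, replica))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def check_stop(best_value: float, cfg: Config, cycle: int,
               direction: str) -> Optional[str]:
    """Stop decision after a cycle.

    The threshold is inclusive: best RMSD <= threshold for minimize types,
    best distance >= threshold for maximize types.  The edge-expansion and
    a/d variants only stop at ``max_cycle``.
    """
    if cfg.type not in ("ee", "a_d") and cfg.threshold is not None:
        if direction == "minimize" and best_value <= cfg.threshold:
            return "threshold"
        if direction == "maximize" and best_value >= cfg.threshold:
            return "threshold"
    if cycle >= cfg.max_cycle:
        return "max_cycle"
    return None


def export_seeds(selected: Sequence[RankedCandidate],
                 trajectories: dict[int, list[Snapshot]],
                 layout: RunLayout, next_cycle: int,
                 lineage: list[LineageRecord]) -> list[Snapshot]:
    """Write the seed structure of every next-cycle replica and append the
    lineage records.

    Seed ``r`` of the next cycle gets the coordinates of ``selected[r]``;
    velocities are *not* copied — they are freshly drawn by the backend
    from the Maxwell-Boltzmann distribution with the child seed, so
    replicas duplicated from the same parent frame still diverge.
    """
    seeds = []
    for cand in selected:
        fv = cand.feature
        source = trajectories.get((fv.cycle, fv.replica))
        if source is None or fv.frame >= len(source):
            raise EngineError(
                f"missing trajectory frame for seed: cycle {fv.cycle} "
                f"replica {fv.replica} frame {fv.frame}")
        parent = source[fv.frame]
        replica = cand.rank - 1
        seed = parent.with_provenance(cycle=next_cycle, replica=replica,
                                      frame=0)
        seed.velocities = None
        rdir = layout.replica_dir(next_cycle, replica)
        rdir.mkdir(parents=True, exist_ok=True)
        write_structure(seed, rdir / SEED_NAME)
        lineage.append(LineageRecord(
            child_cycle=next_cycle, child_replica=replica,
            parent_cycle=fv.cycle, parent_replica=fv.replica,
            parent_frame=fv.frame, feature_at_selection=fv.value))
        seeds.append(seed)
    return seeds


def _run_one(backend: Backend, seed: Snapshot, rng_seed: int,
             workdir: Path) -> Path:
    return backend.run(seed, rng_seed, workdir)


def _write_summary(cycle_dir: Path, values: list[FeatureValue],
                   direction: str) -> None:
    sign = 1.0 if direction == "minimize" else -1.0
    ordered = sorted(values, key=lambda f: (sign * f.value, f.cycle,
                                            f.replica, f.frame))
    rank = {id(f): i + 1 for i, f in enumerate(ordered)}
    df = pd.DataFrame({
        "cycle": [f.cycle for f in values],
        "replica": [f.replica for f in values],
        "frame": [f.frame for f in values],
        "value": [f.value for f in values],
        "rank": [rank[id(f)] for f in values],
    })
    df.to_csv(cycle_dir / SUMMARY_NAME, index=False)


def _write_lineage(trial_dir: Path, lineage: list[LineageRecord]) -> None:
    df = pd.DataFrame([dataclasses.asdict(rec) for rec in lineage],
                      columns=["child_cycle", "child_replica", "parent_cycle",
                               "parent_replica", "parent_frame",
                               "feature_at_selection"])
    df.to_csv(trial_dir / LINEAGE_NAME, index=False)


def _write_state(trial_dir: Path, cfg: Config, state: TrialState) -> None:
    payload = {
        "trial": state.trial,
        "type": cfg.type,
        "n_replica": cfg.n_replica,
        "max_cycle": cfg.max_cycle,
        "threshold": cfg.threshold,
        "direction": state.direction,
        "current_cycle": state.current_cycle,
        "stop_reason": state.stop_reason,
        "best_values": state.best_values,
        "seed": cfg.seed,
    }
    if state.ad_state is not None:
        payload["ad_phase"] = state.ad_state.phase
        payload["ad_stack_counter"] = state.ad_state.stack_counter
    (trial_dir / STATE_NAME).write_text(json.dumps(payload, indent=1))


def load_summary(cycle_dir: Path) -> list[FeatureValue]:
    df = pd.read_csv(Path(cycle_dir) / SUMMARY_NAME)
    trial = RunLayout.parse(str(Path(cycle_dir) / "replica000"))[0]
    return [FeatureValue(trial=trial, cycle=int(r.cycle),
                         replica=int(r.replica), frame=int(r.frame),
                         value=float(r.value))
            for r in df.itertuples()]


def load_lineage(trial_dir: Path) -> list[LineageRecord]:
    path = Path(trial_dir) / LINEAGE_NAME
    if not path.exists():
        return []
    df = pd.read_csv(path)
    return [LineageRecord(int(r.child_cycle), int(r.child_replica),
                          int(r.parent_cycle), int(r.parent_replica),
                          int(r.parent_frame), float(r.feature_at_selection))
            for r in df.itertuples()]


def _ee_descriptor(snap: Snapshot, spec: SelectionSpec) -> np.ndarray:
    return snap.coords[spec.group1.indices].ravel()


def run_trial(cfg: Config, root: str | Path = ".", n_workers: int = 1,
              cycle0_replicas: int = 1, ee_dims: int = 2) -> TrialState:
    """Execute one cascade trial under ``root`` and return its final state.

    Already-completed cycles (detected from their ranking CSVs) are loaded
    from disk rather than re-run, so an interrupted trial can resume
    idempotently.  With ``n_workers > 1`` the replicas of a cycle run in a
    process pool; every replica is seeded individually, so the results are
    identical regardless of the worker count.
    """
    layout = RunLayout(Path(root), cfg.trial)
    backend = make_backend(cfg)
    layout.trial_dir().mkdir(parents=True, exist_ok=True)

    if cfg.structure:
        initial = read_structure(cfg.structure)
    else:
        initial = backend.initial_snapshot()
    initial = initial.with_provenance(trial=cfg.trial, cycle=0, replica=0,
                                      frame=0)
    if initial.masses is None:
        initial.masses = np.ones(initial.n_atoms)

    reference = read_structure(cfg.reference) if cfg.reference else None
    evaluator = None
    if cfg.type == "template":
        evaluator = template_hook(cfg.template or "template.py").bind(cfg)
    spec = build_spec(cfg, initial, reference, evaluator=evaluator)

    state = TrialState(trial=cfg.trial, direction=spec.direction)
    if cfg.type == "a_d":
        state.ad_state = ADState()
        state.direction = direction_of("a_d", ad_phase=state.ad_state.phase)

    lineage = state.lineage
    ee_pool: list[np.ndarray] = []
    ee_meta: list[tuple[int, int, int]] = []

    seeds: list[Snapshot] = [
        initial.with_provenance(replica=r) for r in range(cycle0_replicas)
    ]
    cycle = 0
    while True:
        cdir = layout.cycle_dir(cycle)
        resumed = (cdir / SUMMARY_NAME).exists()
        n_rep = len(seeds) if seeds else cfg.n_replica

        # --- run replicas -------------------------------------------------
        jobs = []
        for r in range(n_rep):
            rdir = layout.replica_dir(cycle, r)
            if resumed or (rdir / "traj.npz").exists():
                continue
            seed_snap = seeds[r]
            jobs.append((seed_snap, child_seed(cfg.seed, cfg.trial, cycle, r),
                         rdir))
        if jobs:
            if n_workers > 1:
                with ProcessPoolExecutor(max_workers=n_workers) as pool:
                    futures = [pool.submit(_run_one, backend, *job)
                               for job in jobs]
                    for fut in futures:
                        fut.result()
            else:
                for job in jobs:
                    _run_one(backend, *job)

        # --- analyze ------------------------------------------------------
        trajectories: dict[tuple[int, int], list[Snapshot]] = {}
        per_replica_values: list[list[FeatureValue]] = []
        for r in range(n_rep):
            traj_path = layout.replica_dir(cycle, r) / "traj.npz"
            if not traj_path.exists():
                raise EngineError(f"missing trajectory for cycle {cycle} "
                                  f"replica {r}: {traj_path}")
            traj = read_trajectory(traj_path)
            traj = [s.with_provenance(trial=cfg.trial, cycle=cycle, replica=r,
                                      frame=i) for i, s in enumerate(traj)]
            trajectories[(cycle, r)] = traj
            if cfg.type == "ee":
                for s in traj:
                    ee_pool.append(_ee_descriptor(s, spec))
                    ee_meta.append((cycle, r, s.frame))
            per_replica_values.append(evaluate_feature(traj, spec)
                                      if cfg.type != "ee" else [])

        if cfg.type == "ee":
            # audit value: distance from the projected centroid is only
            # defined collectively, so the summary stores d_com of group1/2
            per_replica_values = [
                evaluate_feature(trajectories[(cycle, r)],
                                 dataclasses.replace(spec, kind="dissociation"))
                for r in range(n_rep)]

        values = [fv for rep in per_replica_values for fv in rep]
        _write_summary(cdir, values, state.direction)

        best = (min if state.direction == "minimize" else max)(
            fv.value for fv in values)
        state.best_values.append(best)
        state.current_cycle = cycle

        stop = check_stop(best, cfg, cycle, state.direction)
        if stop is not None:
            state.stop_reason = stop
            break

        # --- select and export seeds for the next cycle -------------------
        if cfg.type == "ee":
            selected = ee_select(np.array(ee_pool), ee_meta, cfg.n_replica,
                                 dims=ee_dims, trial=cfg.trial)
            # edge seeds may come from any earlier cycle; fetch trajectories
            for cand in selected:
                key = (cand.feature.cycle, cand.feature.replica)
                if key not in trajectories:
                    tp = layout.replica_dir(*key) / "traj.npz"
                    traj = read_trajectory(tp)
                    trajectories[key] = [
                        s.with_provenance(trial=cfg.trial, cycle=key[0],
                                          replica=key[1], frame=i)
                        for i, s in enumerate(traj)]
        else:
            selected = rank_and_select(values, cfg.n_replica, state.direction)
        seeds = export_seeds(selected, trajectories, layout, cycle + 1,
                             lineage)
        _write_lineage(layout.trial_dir(), lineage)

        if cfg.type == "a_d":
            state.ad_state = ad_update(state.ad_state, per_replica_values, cfg)
            state.direction = direction_of("a_d",
                                           ad_phase=state.ad_state.phase)

        _write_state(layout.trial_dir(), cfg, state)
        cycle += 1

    _write_lineage(layout.trial_dir(), lineage)
    _write_state(layout.trial_dir(), cfg, state)
    return state
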