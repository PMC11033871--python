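"""Dynamics backends: a built-in Langevin toy engine and analytic test systems.

The cascade engine talks to molecular-dynamics software through a small
backend contract (:func:`make_backend` / :meth:`Backend.run`).  The built-in
``toy`` backend integrates underdamped Langevin dynamics with the BAOAB
splitting on a family of low-dimensional analytic potentials, so that every
part of the cascade machinery can be exercised on a desktop without any
external MD package.  External engines plug in through the same contract; a
``mock`` backend that replays canned trajectories is provided for testing
that seam.

Velocities are (re)initialised from the Maxwell-Boltzmann distribution at
the start of every replica, which is what decorrelates the branches of a
cascade run.
"""

from __future__ import annotations

import dataclasses
import shutil
import tomllib
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .config_io import Snapshot, read_trajectory, write_structure, write_trajectory
from .units import KB


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


class BackendError(RuntimeError):
    """Raised for unknown backends or backend process failures."""


# ---------------------------------------------------------------------------
# Analytic toy systems
# ---------------------------------------------------------------------------


class ToySystem:
    """Base class for analytic test systems.

    Subclasses define ``potential(x)`` and ``gradient(x)`` on coordinate
    arrays of shape ``(n_atoms, dim)``.  Coordinates handed to the rest of
    the package are always embedded in 3-D (unused components are zero).
    """

    name: str = "abstract"
    dim: int = 3

    def __init__(self, masses: np.ndarray):
        self.masses = np.asarray(masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def potential(self, x: np.ndarray) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def initial_coords(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- metadata used for selections and structure output ----------------
    def atom_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_atoms)]

    def resids(self) -> np.ndarray:
        return np.arange(1, self.n_atoms + 1)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Pad ``(n_atoms, dim)`` coordinates with zeros to ``(n_atoms, 3)``."""
        out = np.zeros((self.n_atoms, 3))
        out[:, : self.dim] = x
        return out

    def to_snapshot(self, x: np.ndarray, v: np.ndarray | None = None,
                    **provenance: int) -> Snapshot:
        return Snapshot(
            coords=self.embed(x),
            velocities=None if v is None else self.embed(v),
            masses=self.masses.copy(),
            atom_names=self.atom_names(),
            resids=self.resids(),
            **provenance,
        )

    def check_gradient(self, x: np.ndarray, h: float = 1e-6) -> float:
        """Max relative error of the analytic gradient vs central differences."""
        g = self.gradient(x)
        num = np.zeros_like(g)
        for idx in np.ndindex(x.shape):
            xp = x.copy(); xp[idx] += h
            xm = x.copy(); xm[idx] -= h
            num[idx] = (self.potential(xp) - self.potential(xm)) / (2 * h)
        scale = max(np.abs(g).max(), 1.0)
        return float(np.abs(g - num).max() / scale)


class DoubleWell1D(ToySystem):
    """Independent particles in the quartic double well
    ``V(x) = h * (x^2 - a^2)^2 / a^4``.

    Minima at ``x = +-a`` and a barrier of height ``h`` at ``x = 0``.  With
    the defaults (``h`` = 20 kJ/mol ~ 8 k_B T at 300 K, ``a`` = 1 nm,
    ``m`` = 40 g/mol, friction 1/ps) spontaneous barrier crossing is a rare
    event on the picosecond timescale of a single cascade replica, which is
    exactly the regime where greedy snapshot selection pays off.  Several
    atoms are propagated as independent copies of the same well, which is
    convenient for equilibrium statistics.
    """

    name = "double_well_1d"
    dim = 1

    def __init__(self, barrier: float = 20.0, half_separation: float = 1.0,
                 mass: float = 40.0, n_atoms: int = 1):
        super().__init__(np.full(n_atoms, float(mass)))
        if barrier <= 0 or half_separation <= 0:
            raise ValueError("barrier and half_separation must be positive")
        self.barrier = float(barrier)
        self.a = float(half_separation)

    def potential(self, x: np.ndarray) -> float:
        u = x[:, 0] ** 2 - self.a ** 2
        return float(self.barrier * np.sum(u ** 2) / self.a ** 4)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[:, 0] = 4 * self.barrier * x[:, 0] * (x[:, 0] ** 2 - self.a ** 2) / self.a ** 4
        return g

    def initial_coords(self) -> np.ndarray:
        return np.full((self.n_atoms, 1), -self.a)

    def boltzmann_density(self, x: np.ndarray, temperature: float) -> np.ndarray:
        """Unnormalised equilibrium density exp(-V(x)/kT) for one particle."""
        v = self.barrier * (x ** 2 - self.a ** 2) ** 2 / self.a ** 4
        return np.exp(-v / (KB * temperature))


class DoubleWell2D(ToySystem):
    """Double well along x, harmonic confinement (``k_y``) along y."""

    name = "double_well_2d"
    dim = 2

    def __init__(self, barrier: float = 20.0, half_separation: float = 1.0,
                 k_y: float = 100.0, mass: float = 10.0, n_atoms: int = 1):
        super().__init__(np.full(n_atoms, float(mass)))
        self.barrier = float(barrier)
        self.a = float(half_separation)
        self.k_y = float(k_y)

    def potential(self, x: np.ndarray) -> float:
        u = x[:, 0] ** 2 - self.a ** 2
        return float(np.sum(self.barrier * u ** 2 / self.a ** 4
                            + 0.5 * self.k_y * x[:, 1] ** 2))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        g[:, 0] = 4 * self.barrier * x[:, 0] * (x[:, 0] ** 2 - self.a ** 2) / self.a ** 4
        g[:, 1] = self.k_y * x[:, 1]
        return g

    def initial_coords(self) -> np.ndarray:
        out = np.zeros((self.n_atoms, 2))
        out[:, 0] = -self.a
        return out


class LJDimer(ToySystem):
    """Two beads bound by a Lennard-Jones well, confined by a spherical wall.

    ``u(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]`` acts on the separation
    ``r``; beyond ``wall_radius`` a half-harmonic wall with force constant
    ``wall_k`` keeps the pair from drifting apart forever, mimicking the
    finite box of a solvated dissociation run.  The default well depth of
    25 kJ/mol (~10 k_B T at 300 K) makes spontaneous dissociation a rare
    event, so the dissociation-cascade speed-up is measurable.
    """

    name = "lj_dimer"
    dim = 3

    def __init__(self, epsilon: float = 25.0, sigma: float = 0.3,
                 wall_radius: float = 2.0, wall_k: float = 1000.0,
                 mass: float = 10.0):
        super().__init__(np.full(2, float(mass)))
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.wall_radius = float(wall_radius)
        self.wall_k = float(wall_k)

    def pair_potential(self, r: np.ndarray) -> np.ndarray:
        sr6 = (self.sigma / r) ** 6
        u = 4 * self.epsilon * (sr6 ** 2 - sr6)
        wall = np.where(r > self.wall_radius,
                        0.5 * self.wall_k * (r - self.wall_radius) ** 2, 0.0)
        return u + wall

    def _dudr(self, r: float) -> float:
        sr6 = (self.sigma / r) ** 6
        du = 24 * self.epsilon * (sr6 - 2 * sr6 ** 2) / r
        if r > self.wall_radius:
            du += self.wall_k * (r - self.wall_radius)
        return du

    def potential(self, x: np.ndarray) -> float:
        r = float(np.linalg.norm(x[1] - x[0]))
        return float(self.pair_potential(np.array([r]))[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        d = x[1] - x[0]
        r = float(np.linalg.norm(d))
        u = d / r
        g = np.zeros_like(x)
        g[1] = self._dudr(r) * u
        g[0] = -g[1]
        return g

    def initial_coords(self) -> np.ndarray:
        r0 = 2 ** (1 / 6) * self.sigma
        return np.array([[-r0 / 2, 0.0, 0.0], [r0 / 2, 0.0, 0.0]])


class BeadChain(ToySystem):
    """Six-bead Go-like chain whose native state is a two-strand hairpin.

    Consecutive beads are joined by stiff harmonic bonds; bead pairs that
    are close in the native structure and at least three bonds apart
    interact through a 12-10 Go contact potential with its minimum at the
    native distance.  The native structure serves as the reference for
    targeted-cascade folding tests.
    """

    name = "bead_chain"
    dim = 3

    _NATIVE = np.array([
        [0.00, 0.00, 0.0],
        [0.38, 0.00, 0.0],
        [0.76, 0.00, 0.0],
        [0.76, 0.45, 0.0],
        [0.38, 0.45, 0.0],
        [0.00, 0.45, 0.0],
    ])

    def __init__(self, k_bond: float = 1000.0, epsilon_contact: float = 15.0,
                 mass: float = 12.0, contact_cutoff: float = 0.6):
        super().__init__(np.full(6, float(mass)))
        self.k_bond = float(k_bond)
        self.epsilon_contact = float(epsilon_contact)
        n = len(self._NATIVE)
        self.bonds = [(i, i + 1, float(np.linalg.norm(self._NATIVE[i + 1] - self._NATIVE[i])))
                      for i in range(n - 1)]
        self.contacts = []
        for i in range(n):
            for j in range(i + 3, n):
                r0 = float(np.linalg.norm(self._NATIVE[j] - self._NATIVE[i]))
                if r0 < contact_cutoff:
                    self.contacts.append((i, j, r0))

    def native_coords(self) -> np.ndarray:
        return self._NATIVE.copy()

    def native_snapshot(self) -> Snapshot:
        return self.to_snapshot(self.native_coords())

    def potential(self, x: np.ndarray) -> float:
        e = 0.0
        for i, j, r0 in self.bonds:
            r = np.linalg.norm(x[j] - x[i])
            e += 0.5 * self.k_bond * (r - r0) ** 2
        for i, j, r0 in self.contacts:
            r = np.linalg.norm(x[j] - x[i])
            q = r0 / r
            e += self.epsilon_contact * (5 * q ** 12 - 6 * q ** 10)
        return float(e)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        for i, j, r0 in self.bonds:
            d = x[j] - x[i]
            r = float(np.linalg.norm(d))
            f = self.k_bond * (r - r0) * d / r
            g[j] += f
            g[i] -= f
        for i, j, r0 in self.contacts:
            d = x[j] - x[i]
            r = float(np.linalg.norm(d))
            dudr = self.epsilon_contact * 60.0 * (r0 ** 10 / r ** 11) * (1.0 - (r0 / r) ** 2)
            f = dudr * d / r
            g[j] += f
            g[i] -= f
        return g

    def initial_coords(self) -> np.ndarray:
        # fully extended chain
        out = np.zeros((6, 3))
        out[:, 0] = 0.38 * np.arange(6)
        return out


_SYSTEMS: dict[str, type[ToySystem]] = {
    "double_well_1d": DoubleWell1D,
    "double_well_2d": DoubleWell2D,
    "lj_dimer": LJDimer,
    "bead_chain": BeadChain,
}


def make_system(name: str, **kwargs) -> ToySystem:
    """Instantiate a toy system by name with keyword overrides."""
    try:
        cls = _SYSTEMS[name]
    except KeyError:
        raise BackendError(
            f"unknown toy system '{name}'; available: {sorted(_SYSTEMS)}") from None
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# Langevin integration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MDParams:
    """Parameters of one short dynamics run.

    dt in ps, temperature in K, friction in 1/ps.  ``friction = 0`` turns
    the thermostat off, reducing BAOAB to velocity Verlet.
    """

    dt: float
    n_steps: int
    save_interval: int = 1
    temperature: float = 300.0
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.n_steps and self.n_steps < self.save_interval:
            raise ValueError("n_steps must be >= save_interval")


def mb_velocities(masses: np.ndarray, temperature: float,
                  seed: int | np.random.SeedSequence, dim: int = 3) -> np.ndarray:
    """Draw Maxwell-Boltzmann velocities, shape ``(n_atoms, dim)`` in nm/ps.

    Each component is an independent normal with variance k_B*T/m.
    Deterministic for a given seed.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * temperature / masses)
    return rng.standard_normal((len(masses), dim)) * sigma[:, None]


def propagate(system: ToySystem, x0: np.ndarray, v0: np.ndarray,
              params: MDParams) -> tuple[np.ndarray, np.ndarray]:
    """Integrate underdamped Langevin dynamics with the BAOAB splitting.

    Returns ``(positions, velocities)`` of shape ``(n_frames, n_atoms, dim)``
    where frame 0 is the initial state and one frame is stored every
    ``save_interval`` steps.  Bitwise deterministic given ``params.seed``.
    """
    x = np.array(x0, dtype=float)
    v = np.array(v0, dtype=float)
    if x.shape != (system.n_atoms, system.dim):
        raise ValueError(
            f"x0 shape {x.shape} does not match system "
            f"({system.n_atoms}, {system.dim})")
    if v.shape != x.shape:
        raise ValueError("v0 shape must match x0")

    n_frames = params.n_steps // params.save_interval + 1
    xs = np.empty((n_frames, *x.shape))
    vs = np.empty((n_frames, *x.shape))
    xs[0], vs[0] = x, v
    if params.n_steps == 0:
        return xs, vs

    dt = params.dt
    m = system.masses[:, None]
    gamma = params.friction
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * params.temperature / m)
        noise = np.random.default_rng(params.seed).standard_normal(
            (params.n_steps, *x.shape))
    else:
        c1, c2, noise = 1.0, 0.0, None

    half = 0.5 * dt
    frame = 1
    with np.errstate(over="ignore", invalid="ignore"):
        force = -system.gradient(x)
        for step in range(params.n_steps):
            v = v + half * force / m              # B
            x = x + half * v                      # A
            if noise is not None:                 # O
                v = c1 * v + c2 * noise[step]
            x = x + half * v                      # A
            force = -system.gradient(x)
            v = v + half * force / m              # B
            if (step + 1) % params.save_interval == 0:
                if not np.isfinite(x).all():
                    raise IntegrationError(
                        f"non-finite coordinates at step {step + 1}")
                xs[frame], vs[frame] = x, v
                frame += 1
    return xs, vs


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy (kJ/mol) of one frame of shape ``(n_atoms, dim)``."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2))


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------


class Backend:
    """Contract a dynamics backend fulfils for the cascade engine.

    ``run`` propagates one replica from a seed structure with freshly drawn
    velocities and leaves a trajectory file (plus a final-state structure)
    in ``workdir``, returning the trajectory path.
    """

    name = "abstract"

    def initial_snapshot(self) -> Snapshot:  # pragma: no cover - abstract
        raise NotImplementedError

    def run(self, seed: Snapshot, rng_seed: int, workdir: Path) -> Path:
        raise NotImplementedError  # pragma: no cover


class ToyBackend(Backend):
    """Built-in Langevin backend over the analytic toy systems."""

    name = "toy"

    def __init__(self, system: ToySystem, params: MDParams):
        self.system = system
        self.params = params

    @classmethod
    def from_mdconf(cls, path: str | Path) -> "ToyBackend":
        """Load a toy run definition from a TOML file.

        Expected layout::

            [system]
            name = "double_well_1d"
            barrier = 20.0        # further keys are system parameters

            [md]
            dt = 0.01
            n_steps = 200
            save_interval = 10
            temperature = 300.0
            friction = 1.0
        """
        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except FileNotFoundError:
            raise BackendError(f"mdconf file not found: {path}") from None
        except tomllib.TOMLDecodeError as exc:
            raise BackendError(f"{path}: {exc}") from None
        try:
            sys_spec = dict(data["system"])
            md_spec = dict(data["md"])
        except KeyError as exc:
            raise BackendError(f"{path}: missing [{exc.args[0]}] table") from None
        name = sys_spec.pop("name", None)
        if name is None:
            raise BackendError(f"{path}: [system] table needs a 'name' key")
        system = make_system(name, **sys_spec)
        return cls(system, MDParams(**md_spec))

    def initial_snapshot(self) -> Snapshot:
        return self.system.to_snapshot(self.system.initial_coords())

    def run(self, seed: Snapshot, rng_seed: int, workdir: Path) -> Path:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        ss = np.random.SeedSequence(rng_seed)
        vel_seed, noise_seed = ss.spawn(2)
        sysm = self.system
        x0 = np.array(seed.coords[:, : sysm.dim], dtype=float)
        v0 = mb_velocities(sysm.masses, self.params.temperature, vel_seed,
                           dim=sysm.dim)
        params = dataclasses.replace(
            self.params, seed=int(noise_seed.generate_state(1)[0]))
        try:
            xs, vs = propagate(sysm, x0, v0, params)
        except IntegrationError as exc:
            raise BackendError(f"toy backend failed in {workdir}: {exc}") from exc
        frames = [
            sysm.to_snapshot(xs[i], vs[i],
                             trial=seed.trial, cycle=seed.cycle,
                             replica=seed.replica, frame=i)
            for i in range(len(xs))
        ]
        traj_path = workdir / "traj.npz"
        write_trajectory(frames, traj_path, "table")
        write_structure(frames[-1], workdir / "final.npz")
        return traj_path


class MockBackend(Backend):
    """Test double for an external engine: replays a canned trajectory."""

    name = "mock"

    def __init__(self, canned_trajectory: str | Path,
                 initial: Snapshot | None = None):
        self.canned = Path(canned_trajectory)
        self._initial = initial

    def initial_snapshot(self) -> Snapshot:
        if self._initial is not None:
            return self._initial
        return read_trajectory(self.canned)[0]

    def run(self, seed: Snapshot, rng_seed: int, workdir: Path) -> Path:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        dest = workdir / ("traj" + self.canned.suffix)
        shutil.copy(self.canned, dest)
        return dest


_BACKEND_FACTORIES: dict[str, Callable] = {}


def register_backend(name: str, factory: Callable) -> None:
    """Register ``factory(config) -> Backend`` under a simulator name."""
    _BACKEND_FACTORIES[name] = factory


def make_backend(config) -> Backend:
    """Build the backend named by ``config.simulator``.

    ``toy`` is built in and reads its run definition from ``config.mdconf``.
    Anything else must have been registered with :func:`register_backend`.
    """
    name = config.simulator
    if name == "toy":
        if not config.mdconf:
            raise BackendError("toy backend requires the 'mdconf' keyword")
        return ToyBackend.from_mdconf(config.mdconf)
    if name in _BACKEND_FACTORIES:
        return _BACKEND_FACTORIES[name](config)
    known = sorted({"toy", *_BACKEND_FACTORIES})
    raise BackendError(f"unknown simulator '{name}'; registered: {known}")
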