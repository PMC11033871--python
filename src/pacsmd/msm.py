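"""Markov-state-model construction and free-energy analysis.

Cascade trajectories are short segments that are disconnected in phase
space (velocities are redrawn at every branch) but connected in
conformational space, so a Markov state model estimated from
within-segment transition counts is the natural post-processing route:
k-means(++) discretisation, a count matrix at lag tau, a row-stochastic
transition matrix on the largest strongly connected state set, implied
timescales, stationary populations, 1-D potentials of mean force, and a
convex-hull volume-corrected standard binding free energy.

The default transition-matrix estimator is the simple maximum-likelihood
row normalisation; a symmetrised (detailed-balance) estimator is offered
as an option.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.csgraph import connected_components

from .geometry import convex_hull
from .units import KB, KJ_PER_KCAL, R_KCAL, STANDARD_VOLUME

__all__ = [
    "AccelerationResult", "BindingFreeEnergy", "FreeEnergyProfile",
    "MarkovModel", "MSMError", "acceleration_ratio", "count_matrix",
    "dG_to_kd", "estimate_msm", "free_energy_profile", "implied_timescales",
    "kd_to_dG", "kmeans_pp", "order_of_magnitude", "sample_markov_chain",
    "stationary_distribution", "standard_binding_dG", "transition_matrix",
]


class MSMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------


def kmeans_pp(data: np.ndarray, k: int, seed: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """k-means clustering with k-means++ initialisation.

    ``data`` is (M,) or (M, d).  Returns ``(centers, assignments)``;
    deterministic for a given seed, every center non-empty.
    """
    from sklearn.cluster import KMeans

    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    m = data.shape[0]
    if not 1 <= k <= m:
        raise MSMError(f"need 1 <= k <= n_points, got k={k}, n={m}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                tol=1e-12, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(data)
    return km.cluster_centers_, labels


def assign_to_centers(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center (Voronoi) assignment of points to existing centers."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# Count and transition matrices
# ---------------------------------------------------------------------------


def count_matrix(dtrajs: Sequence[np.ndarray], lag: int,
                 n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at lag ``lag`` (frames).

    Pairs are counted within each discrete trajectory only, never across
    segment boundaries — cascade segments are disconnected in phase space.
    """
    if lag < 1:
        raise MSMError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) + 1 for d in dtrajs if len(d)), default=0)
    c = np.zeros((n_states, n_states), dtype=np.int64)
    counted = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        counted = True
        np.add.at(c, (d[:-lag], d[lag:]), 1)
    if not counted:
        raise MSMError(f"no trajectory longer than the lag ({lag} frames)")
    return c


def largest_connected_set(c: np.ndarray, directed: bool = True) -> np.ndarray:
    """States of the largest (strongly) connected component of the count
    graph, preferring the component with the most counts on ties."""
    adj = sparse.csr_matrix(c > 0)
    n, labels = connected_components(adj, directed=directed,
                                     connection="strong" if directed else "weak")
    best, best_key = None, None
    for comp in range(n):
        states = np.flatnonzero(labels == comp)
        key = (len(states), c[np.ix_(states, states)].sum())
        if best_key is None or key > best_key:
            best, best_key = states, key
    return best


def transition_matrix(c: np.ndarray,
                      estimator: Literal["mle", "symmetrized"] = "mle"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition matrix on the largest connected state set.

    ``mle`` row-normalises the counts; ``symmetrized`` row-normalises
    ``(C + C.T) / 2``, which satisfies detailed balance by construction.
    Returns ``(T, active)`` where ``active`` maps rows of ``T`` back to the
    original state indices.
    """
    c = np.asarray(c)
    if np.any(c < 0):
        raise MSMError("count matrix must be non-negative")
    if estimator == "symmetrized":
        c = (c + c.T) / 2.0
    elif estimator != "mle":
        raise MSMError(f"unknown estimator '{estimator}'")
    active = largest_connected_set(c)
    if active is None or len(active) == 0:
        raise MSMError("count matrix has no connected set")
    sub = c[np.ix_(active, active)].astype(float)
    rows = sub.sum(axis=1)
    if np.any(rows == 0):
        raise MSMError("zero-row state inside the connected set")
    return sub / rows[:, None], active


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi @ T = pi, sum(pi) = 1.

    Requires an irreducible row-stochastic matrix (as produced by
    :func:`transition_matrix`).
    """
    t = np.asarray(t, dtype=float)
    vals, vecs = linalg.eig(t.T)
    order = np.argsort(-vals.real)
    near_one = np.isclose(vals, 1.0, atol=1e-8)
    if near_one.sum() == 0:
        raise MSMError("no unit eigenvalue: matrix is not stochastic")
    if near_one.sum() > 1:
        raise MSMError("multiple unit eigenvalues: matrix is reducible")
    v = vecs[:, order[0]].real
    pi = v / v.sum()
    if np.any(pi < -1e-10):
        raise MSMError("stationary vector has negative entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def implied_timescales(t: np.ndarray, lag: int, n: int) -> np.ndarray:
    """Implied timescales t_i = -lag / ln(lambda_{i+1}), in frames.

    The unit eigenvalue is excluded; complex eigenvalues are reported by
    modulus with a warning; eigenvalues >= 1 give +inf and eigenvalues
    <= 0 give NaN.
    """
    t = np.asarray(t, dtype=float)
    vals = linalg.eigvals(t)
    if n > len(vals) - 1:
        raise MSMError(f"requested {n} timescales but only {len(vals) - 1} "
                       "non-stationary eigenvalues exist")
    if np.any(np.abs(vals.imag) > 1e-12):
        warnings.warn("complex eigenvalues; timescales use their moduli",
                      stacklevel=2)
        mags = np.abs(vals)
    else:
        mags = vals.real
    mags = np.sort(mags)[::-1][1:n + 1]  # drop the stationary eigenvalue
    out = np.empty(n)
    for i, lam in enumerate(mags):
        if lam >= 1.0:
            out[i] = np.inf
        elif lam <= 0.0:
            out[i] = np.nan
        else:
            out[i] = -lag / np.log(lam)
    return out


# ---------------------------------------------------------------------------
# Bundled model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MarkovModel:
    """A discretised model: centers, discrete trajectories, count and
    transition matrices at one lag, and the stationary distribution on the
    active (largest connected) state set."""

    centers: np.ndarray
    dtrajs: list[np.ndarray]
    lag: int
    counts: np.ndarray
    transition: np.ndarray
    active: np.ndarray
    pi: np.ndarray
    temperature: float

    @property
    def active_centers(self) -> np.ndarray:
        return self.centers[self.active]


def estimate_msm(features: Sequence[np.ndarray], k: int, lag: int,
                 temperature: float = 300.0, seed: int = 0,
                 estimator: Literal["mle", "symmetrized"] = "mle"
                 ) -> MarkovModel:
    """Discretise feature trajectories with k-means++ and estimate an MSM."""
    features = [np.asarray(f, dtype=float) for f in features]
    flat = np.concatenate(features)
    centers, _ = kmeans_pp(flat, k, seed)
    dtrajs = [assign_to_centers(f, centers) for f in features]
    c = count_matrix(dtrajs, lag, n_states=k)
    t, active = transition_matrix(c, estimator=estimator)
    pi = stationary_distribution(t)
    return MarkovModel(centers=centers, dtrajs=dtrajs, lag=lag, counts=c,
                       transition=t, active=active, pi=pi,
                       temperature=temperature)


# ---------------------------------------------------------------------------
# Free energies
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FreeEnergyProfile:
    """1-D potential of mean force: F_i = -kT ln(pi_i), min-shifted to 0,
    bins ordered by center."""

    centers: np.ndarray
    f: np.ndarray  # kJ/mol
    temperature: float


def free_energy_profile(pi: np.ndarray, centers: np.ndarray,
                        temperature: float) -> FreeEnergyProfile:
    """Potential of mean force from stationary populations.

    Zero-probability states are excluded (not mapped to infinity); the
    profile is shifted so its minimum is zero and sorted by bin center.
    """
    pi = np.asarray(pi, dtype=float)
    centers = np.asarray(centers, dtype=float).reshape(len(pi), -1)
    if centers.shape[1] != 1:
        raise MSMError("free_energy_profile expects 1-D bin centers")
    centers = centers[:, 0]
    mask = pi > 0
    if not mask.any():
        raise MSMError("all states have zero probability")
    centers, pi = centers[mask], pi[mask]
    order = np.argsort(centers)
    centers, pi = centers[order], pi[order]
    f = -KB * temperature * np.log(pi)
    f -= f.min()
    return FreeEnergyProfile(centers=centers, f=f, temperature=temperature)


@dataclasses.dataclass
class BindingFreeEnergy:
    dG_kcal: float          # volume-corrected standard binding free energy
    dW_kJ: float            # PMF depth: F(plateau) - F(bound minimum)
    v_sim: float            # sampled unbound volume, nm^3
    correction_kcal: float  # -RT ln(V_sim / V0) in kcal/mol
    plateau_value: float    # plateau free energy, kJ/mol


def standard_binding_dG(profile: FreeEnergyProfile,
                        unbound_points: np.ndarray,
                        temperature: float | None = None,
                        plateau_fraction: float = 0.2,
                        plateau_tol: float = 0.5) -> BindingFreeEnergy:
    """Standard binding free energy from a d_com PMF with volume correction.

    The unbound plateau is the last ``plateau_fraction`` of the d_com range
    and must be flat within ``plateau_tol`` (kJ/mol); its mean is the
    unbound reference.  ``dW = F(plateau) - F(bound minimum)``.  The
    sampled unbound volume ``V_sim`` is the Quickhull convex-hull volume of
    the unbound-shell points (ligand COM positions), and

        dG0 = -dW - R*T*ln(V_sim / V0),   V0 = 1.661 nm^3 (1 M)

    reported in kcal/mol.
    """
    temperature = profile.temperature if temperature is None else temperature
    centers, f = profile.centers, profile.f
    if len(centers) < 4:
        raise MSMError("profile has too few bins")
    span = centers.max() - centers.min()
    cut = centers.max() - plateau_fraction * span
    plateau_mask = centers >= cut
    if plateau_mask.sum() < 2:
        raise MSMError("no resolvable unbound plateau region")
    f_plat = f[plateau_mask]
    if f_plat.max() - f_plat.min() > plateau_tol:
        raise MSMError(
            f"profile not converged: plateau varies by "
            f"{f_plat.max() - f_plat.min():.2f} kJ/mol (> {plateau_tol})")
    plateau = float(f_plat.mean())
    bound_min = float(f[~plateau_mask].min())
    dw = plateau - bound_min

    unbound_points = np.asarray(unbound_points, dtype=float)
    if unbound_points.shape[0] < 4:
        raise MSMError("need at least 4 unbound points for the hull volume")
    v_sim = convex_hull(unbound_points).volume
    rt_kcal = R_KCAL * temperature
    correction = -rt_kcal * np.log(v_sim / STANDARD_VOLUME)
    dg = -dw / KJ_PER_KCAL + correction
    return BindingFreeEnergy(dG_kcal=float(dg), dW_kJ=float(dw),
                             v_sim=float(v_sim),
                             correction_kcal=float(correction),
                             plateau_value=plateau)


# ---------------------------------------------------------------------------
# Thermodynamic and kinetic conversions
# ---------------------------------------------------------------------------


def kd_to_dG(kd: float, temperature: float) -> float:
    """Standard binding free energy (kcal/mol) from a dissociation constant.

    dG0 = R*T*ln(KD / c0) with c0 = 1 M; a KD of 19 nM at 300 K gives
    -10.6 kcal/mol.
    """
    if kd <= 0:
        raise ValueError("KD must be positive")
    return R_KCAL * temperature * np.log(kd / 1.0)


def dG_to_kd(dg_kcal: float, temperature: float) -> float:
    """Inverse of :func:`kd_to_dG` (returns molar units)."""
    return float(np.exp(dg_kcal / (R_KCAL * temperature)))


def order_of_magnitude(x: float) -> float:
    """The order of magnitude 10^floor(log10 x), e.g. 375 -> 100."""
    if x <= 0:
        raise ValueError("x must be positive")
    return float(10.0 ** np.floor(np.log10(x)))


@dataclasses.dataclass
class AccelerationResult:
    event_time: float        # 1 / k_off, seconds
    ratio: float             # event time / simulation time
    event_time_order: float  # 10^floor(log10 event_time)
    ratio_order: float       # 10^floor(log10 ratio)


def acceleration_ratio(k_off: float, simulation_time: float
                       ) -> AccelerationResult:
    """Sampling acceleration of a cascade run.

    The experimentally observed event timescale (1/k_off, seconds) divided
    by the simulation time that produced the event.  A k_off of
    0.16 min^-1 (2.67e-3 s^-1) means dissociation takes on the order of
    10^2 s; against a 3 ns run the acceleration is of order 10^11.
    """
    if k_off <= 0 or simulation_time <= 0:
        raise ValueError("k_off and simulation_time must be positive")
    event_time = 1.0 / k_off
    ratio = event_time / simulation_time
    return AccelerationResult(event_time=event_time, ratio=ratio,
                              event_time_order=order_of_magnitude(event_time),
                              ratio_order=order_of_magnitude(ratio))


# ---------------------------------------------------------------------------
# Synthetic chains (validation utility)
# ---------------------------------------------------------------------------


def sample_markov_chain(t: np.ndarray, n_steps: int, seed: int,
                        start: int = 0) -> np.ndarray:
    """Sample a discrete trajectory from a known transition matrix."""
    t = np.asarray(t, dtype=float)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise MSMError("rows must sum to 1")
    cum = np.cumsum(t, axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=int)
    out[0] = start
    s = start
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], u[i]))
        out[i + 1] = s
    return out
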