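"""Iterative history-dependent conformer sampling.

The core algorithm: conformers are optimized by simulated annealing against
additive restraint penalties derived from per-pair distance distributions,
and after each iteration the distances realized by the selected conformers
are *subtracted* from mutable working copies of the distributions as
Gaussians of area ``1/n`` (``n`` = total ensemble size).  High-probability
regions that have already been sampled are thereby lowered, driving later
iterations into the not-yet-visited parts of every distribution until the
working distributions are nearly flat and the ensemble as a whole
reproduces the experimental distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .distributions import ContinuousDistribution
from .structure import Conformer, TwoBodySystem, steric_score, wrap_angle

__all__ = [
    "ProtocolConfig",
    "SamplingState",
    "Ensemble",
    "init_state",
    "target_function",
    "optimize_structure",
    "subtract_conformer",
    "run_iteration",
    "run_protocol",
    "run_free",
    "gaussian_on_grid",
]

logger = logging.getLogger(__name__)

WORKING_GRID_STEP = 0.1
#: working p_max below this fraction of the original p_max means the
#: distribution is fully sampled and its penalty term is switched off
FLATTEN_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol constants of one conformation-space calculation."""

    n_iterations: int = 250
    n_calculated: int = 100
    n_selected: int = 10
    sigma_sub: float = 2.5  # Angstrom, std dev of the subtracted Gaussians
    A: float = 10.0  # Angstrom^2, restraint weighting factor
    c: float = 0.75  # cutoff on normalized probability
    anneal_steps: int = 500
    anneal_T_start: float = 10.0
    anneal_T_end: float = 0.01
    rng_seed: int = 0
    steric_mode: str = "coarse"
    steric_stiffness: float = 1.0
    move_rot_sigma: float = 25.0  # deg, proposal rotation half-width
    move_torsion_sigma: float = 30.0  # deg
    move_bend_sigma: float = 20.0  # deg

    def __post_init__(self) -> None:
        if self.n_selected > self.n_calculated:
            raise ValueError("n_selected must not exceed n_calculated")
        if self.n_iterations < 1 or self.n_selected < 1:
            raise ValueError("protocol sizes must be positive")

    @property
    def ensemble_size(self) -> int:
        return self.n_iterations * self.n_selected

    @property
    def subtraction_area(self) -> float:
        return 1.0 / self.ensemble_size


@dataclass
class _WorkingDistribution:
    """Mutable gridded copy of one experimental distribution."""

    grid: np.ndarray
    density: np.ndarray
    p_max: float
    original_p_max: float
    subtracted_area: float = 0.0  # pre-clamp bookkeeping

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    @property
    def flattened(self) -> bool:
        return self.p_max < FLATTEN_THRESHOLD * self.original_p_max


@dataclass
class SamplingState:
    """Per-restraint working distributions mutated across iterations."""

    originals: dict[str, ContinuousDistribution]
    working: dict[str, _WorkingDistribution]
    history: int = 0

    def residual_areas(self) -> dict[str, float]:
        return {label: w.area for label, w in self.working.items()}


@dataclass
class Ensemble:
    """Ordered conformer collection with its protocol provenance."""

    conformers: list[Conformer]
    restraint_labels: tuple[str, ...]
    config: ProtocolConfig | None = None

    def __len__(self) -> int:
        return len(self.conformers)

    def distances(self, label: str) -> np.ndarray:
        return np.array([c.pair_distances[label] for c in self.conformers])


def gaussian_on_grid(grid: np.ndarray, mu: float, sigma: float, area: float) -> np.ndarray:
    """Gaussian of given total area evaluated on a grid."""
    amp = area / (sigma * math.sqrt(2.0 * math.pi))
    return amp * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)


def init_state(restraints: dict[str, ContinuousDistribution],
               cfg: ProtocolConfig) -> SamplingState:
    """Initialize working distributions from the originals.

    Each working distribution is the original density sampled on a fixed
    0.1 Angstrom grid spanning the measured support; originals must be
    unit-area.  Raises on an empty restraint list or duplicate labels
    (duplicates cannot survive the dict type, so sequence input is also
    accepted and checked).
    """
    if not isinstance(restraints, dict):
        items = list(restraints)
        labels = [lab for lab, _ in items]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate restraint labels: {dupes}")
        restraints = dict(items)
    if not restraints:
        raise ValueError("empty restraint list")
    working = {}
    for label, dist in restraints.items():
        area = float(np.trapezoid(dist.evaluate(
            np.linspace(*dist.support, 2001)), np.linspace(*dist.support, 2001)))
        if abs(area - 1.0) > 0.05:
            raise ValueError(f"restraint {label!r} is not unit-area (got {area:.4f}); "
                             "normalize before sampling")
        lo, hi = dist.support
        n = int(round((hi - lo) / WORKING_GRID_STEP)) + 1
        grid = np.linspace(lo, lo + (n - 1) * WORKING_GRID_STEP, n)
        density = np.asarray(dist.evaluate(grid), dtype=float)
        working[label] = _WorkingDistribution(
            grid=grid, density=density,
            p_max=float(density.max()), original_p_max=float(density.max()))
    return SamplingState(originals=dict(restraints), working=working)


def _support_tether(r: float, lo: float, hi: float) -> float:
    """Quadratic growth beyond the measured support.

    Within the support the restraint term is exactly the bounded penalty
    formula; beyond it the engine adds a growing term so that a distance
    never observed experimentally is always worse than any distance inside
    the measured range, pulling the annealer back (the same treatment
    simulated-annealing engines give upper/lower distance limits).
    """
    if r < lo:
        return (lo - r) ** 2
    if r > hi:
        return (r - hi) ** 2
    return 0.0


def _working_penalty(w: _WorkingDistribution, r: float, A: float, c: float) -> float:
    """Penalty of one working distribution at distance r (0 if flattened)."""
    if w.flattened:
        return 0.0
    dens = np.interp(r, w.grid, w.density, left=0.0, right=0.0)
    return (A * max(0.0, 1.0 - dens / (w.p_max * c))
            + _support_tether(r, w.grid[0], w.grid[-1]))


def target_function(conformer: Conformer, state: SamplingState | None,
                    cfg: ProtocolConfig, system: TwoBodySystem) -> float:
    """Sum of restraint penalties plus the steric clash score."""
    placement = system.place(conformer)
    conformer.pair_distances = system.pair_distances(placement)
    total = steric_score(placement, system.stationary, system.moving,
                         mode=cfg.steric_mode, stiffness=cfg.steric_stiffness)
    if state is not None:
        for label, w in state.working.items():
            total += _working_penalty(w, conformer.pair_distances[label], cfg.A, cfg.c)
    return total


class _Evaluator:
    """Precomputed fast path for the annealing energy."""

    def __init__(self, system: TwoBodySystem, state: SamplingState | None,
                 cfg: ProtocolConfig):
        from .structure import build_linker_chain, _coarse_index

        self.system = system
        self.cfg = cfg
        self.linker = system.linker
        self.triad = system.stationary.anchor_triad
        self.anchor_local = system.moving.anchor
        self._build_chain = build_linker_chain
        if cfg.steric_mode == "coarse":
            self.stat_pts = system.stationary.coords[_coarse_index(system.stationary)]
            self.mov_pts = system.moving.coords[_coarse_index(system.moving)]
            self.dmin = 6.0
            self.r_sum = None
        else:
            self.stat_pts = system.stationary.coords
            self.mov_pts = system.moving.coords
            from .structure import ELEMENT_RADII
            rs = np.array([ELEMENT_RADII.get(e, 1.7) for e in system.stationary.elements])
            rm = np.array([ELEMENT_RADII.get(e, 1.7) for e in system.moving.elements])
            self.r_sum = rs[:, None] + rm[None, :]
        self.pair_labels = list(system.pairs)
        stat_pos, mov_local = [], []
        for pair, (sa, sb) in system.pairs.items():
            site_a, site_b = system.labels[sa], system.labels[sb]
            if site_a.body_role == "moving":
                site_a, site_b = site_b, site_a
            stat_pos.append(site_a.effective_position())
            mov_local.append(site_b.effective_position())
        self.stat_pos = np.array(stat_pos).reshape(-1, 3)
        self.mov_local = np.array(mov_local).reshape(-1, 3)
        # penalties apply only to pairs that actually carry a restraint;
        # distances are still recorded for every declared pair (e.g. the
        # withheld pair of a leave-one-out run)
        self.workings = [] if state is None else \
            [(i, state.working[lab]) for i, lab in enumerate(self.pair_labels)
             if lab in state.working]

    def chain_end(self, bends, torsions) -> np.ndarray:
        return self._build_chain(self.triad, self.linker, bends, torsions)[-1]

    def energy(self, R: np.ndarray, chain_end: np.ndarray):
        """Return (energy, pair distances) for rotation matrix R."""
        from scipy.spatial.distance import cdist

        t = chain_end - R @ self.anchor_local
        dists = np.empty(len(self.pair_labels))
        if len(self.pair_labels):
            mov_world = self.mov_local @ R.T + t
            diff = mov_world - self.stat_pos
            dists = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        d2 = cdist(self.stat_pts, self.mov_pts @ R.T + t, "sqeuclidean")
        if self.r_sum is None:
            close = d2 < self.dmin * self.dmin
            overlap = self.dmin - np.sqrt(d2[close])
        else:
            close = d2 < self.r_sum * self.r_sum
            overlap = self.r_sum[close] - np.sqrt(d2[close])
        e = self.cfg.steric_stiffness * float(np.dot(overlap, overlap))
        A, c = self.cfg.A, self.cfg.c
        for i, w in self.workings:
            if w.flattened:
                continue
            r = dists[i]
            grid = w.grid
            # uniform grid: manual linear interpolation beats np.interp here
            x = (r - grid[0]) / WORKING_GRID_STEP
            if x <= 0.0 or x >= len(grid) - 1:
                dens = 0.0
                e += _support_tether(r, grid[0], grid[-1])
            else:
                i = int(x)
                frac = x - i
                dens = w.density[i] * (1.0 - frac) + w.density[i + 1] * frac
            raw = 1.0 - dens / (w.p_max * c)
            if raw > 0.0:
                e += A * raw
        return e, dists


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)

_I3 = np.eye(3)


def _rotmat(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _perturb_quaternion(q: np.ndarray, sigma_deg: float,
                        rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    half = 0.5 * math.radians(rng.normal(0.0, sigma_deg))
    dq = np.array([*(math.sin(half) * axis), math.cos(half)])
    x1, y1, z1, w1 = dq
    x2, y2, z2, w2 = q
    out = np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])
    return out / np.linalg.norm(out)


def optimize_structure(system: TwoBodySystem, state: SamplingState | None,
                       cfg: ProtocolConfig, seed) -> Conformer:
    """Simulated annealing from a random start; returns the best conformer.

    The linker torsions (and bends) are set to random values at the start
    of each calculation; proposals perturb either the moving body's
    orientation or one linker joint under a geometric cooling schedule.
    Identical seeds give bitwise-identical trajectories.
    """
    rng = np.random.default_rng(seed)
    ev = _Evaluator(system, state, cfg)
    linker = system.linker

    q = _random_quaternion(rng)
    torsions = rng.uniform(-180.0, 180.0, linker.n_residues)
    bends = rng.uniform(0.0, linker.max_bend, linker.n_residues)
    chain_end = ev.chain_end(bends, torsions)
    energy, dists = ev.energy(_rotmat(q), chain_end)

    best = (energy, q.copy(), torsions.copy(), bends.copy(), chain_end.copy(), dists.copy())
    n_steps = max(cfg.anneal_steps, 1)
    ratio = cfg.anneal_T_end / cfg.anneal_T_start
    for step in range(n_steps):
        T = cfg.anneal_T_start * ratio ** (step / max(n_steps - 1, 1))
        move = rng.integers(0, 2)
        if move == 0:  # orientation move
            q_new = _perturb_quaternion(q, cfg.move_rot_sigma, rng)
            t_new, b_new, end_new = torsions, bends, chain_end
        else:  # one linker joint
            j = int(rng.integers(0, linker.n_residues))
            t_new = torsions.copy()
            b_new = bends.copy()
            t_new[j] = wrap_angle(t_new[j] + rng.normal(0.0, cfg.move_torsion_sigma))
            b_new[j] = min(max(b_new[j] + rng.normal(0.0, cfg.move_bend_sigma), 0.0),
                           linker.max_bend)
            end_new = ev.chain_end(b_new, t_new)
            q_new = q
        e_new, d_new = ev.energy(_rotmat(q_new), end_new)
        if e_new <= energy or rng.random() < math.exp(-(e_new - energy) / T):
            q, torsions, bends, chain_end = q_new, t_new, b_new, end_new
            energy, dists = e_new, d_new
            if energy < best[0]:
                best = (energy, q.copy(), torsions.copy(), bends.copy(),
                        chain_end.copy(), dists.copy())

    energy, q, torsions, bends, chain_end, dists = best
    R = _rotmat(q)
    conf = Conformer(quaternion=q, translation=chain_end - R @ ev.anchor_local,
                     linker_torsions=torsions, linker_bends=bends,
                     pair_distances=dict(zip(ev.pair_labels, map(float, dists))),
                     target_value=float(energy))
    return conf


def subtract_conformer(state: SamplingState, conformer: Conformer,
                       cfg: ProtocolConfig) -> SamplingState:
    """Subtract one conformer's Gaussian correction from every working
    distribution, clamping at zero, and refresh each p_max."""
    area = cfg.subtraction_area
    for label, w in state.working.items():
        if label not in conformer.pair_distances:
            raise KeyError(f"conformer lacks a distance for restraint {label!r}")
        mu = conformer.pair_distances[label]
        g = gaussian_on_grid(w.grid, mu, cfg.sigma_sub, area)
        np.maximum(w.density - g, 0.0, out=w.density)
        w.p_max = float(w.density.max())
        w.subtracted_area += area
    state.history += 1
    return state


def _structure_seed(rng_seed: int, iteration: int, index: int) -> np.random.SeedSequence:
    # stable, parallelizable per-structure stream
    return np.random.SeedSequence(entropy=rng_seed, spawn_key=(iteration, index))


def run_iteration(system: TwoBodySystem, state: SamplingState | None,
                  cfg: ProtocolConfig, iteration: int = 0,
                  subtract: bool = True) -> list[Conformer]:
    """One protocol iteration: calculate ``n_calculated`` structures from
    independent seeds, keep the ``n_selected`` with the lowest target
    values (ties broken by lower structure index), subtract each selected
    conformer in selection order."""
    conformers = [optimize_structure(system, state, cfg,
                                     _structure_seed(cfg.rng_seed, iteration, i))
                  for i in range(cfg.n_calculated)]
    order = sorted(range(len(conformers)),
                   key=lambda i: (conformers[i].target_value, i))
    selected = [conformers[i] for i in order[:cfg.n_selected]]
    if subtract and state is not None:
        for conf in selected:
            subtract_conformer(state, conf, cfg)
    return selected


def run_protocol(system: TwoBodySystem,
                 restraints: dict[str, ContinuousDistribution],
                 cfg: ProtocolConfig,
                 callback=None) -> Ensemble:
    """Full iterative protocol; returns the ensemble of
    ``n_iterations * n_selected`` conformers."""
    state = init_state(restraints, cfg)
    ensemble: list[Conformer] = []
    for it in range(cfg.n_iterations):
        selected = run_iteration(system, state, cfg, iteration=it)
        ensemble.extend(selected)
        targets = [c.target_value for c in selected]
        logger.info("iteration %d/%d: best target %.3f, median %.3f, residual areas %s",
                    it + 1, cfg.n_iterations, min(targets), float(np.median(targets)),
                    {k: round(v, 3) for k, v in state.residual_areas().items()})
        if callback is not None:
            callback(it, state, selected)
    return Ensemble(conformers=ensemble,
                    restraint_labels=tuple(restraints), config=cfg)


def run_free(system: TwoBodySystem, cfg: ProtocolConfig) -> Ensemble:
    """Reference calculation without any distance restraints.

    Same iteration structure and selection as the restrained protocol but
    the target function contains only the steric term, so the ensemble
    samples everything the linker geometry allows.
    """
    ensemble: list[Conformer] = []
    for it in range(cfg.n_iterations):
        selected = run_iteration(system, None, cfg, iteration=it, subtract=False)
        ensemble.extend(selected)
    return Ensemble(conformers=ensemble, restraint_labels=(), config=cfg)
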