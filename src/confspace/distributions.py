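"""Distance probability distributions and their penalty-term representation.

Experimental inter-label distance distributions arrive as two-column text
files (distance, probability density).  They are normalized to unit area,
interpolated into a smooth continuous density with an analytic first
derivative, and finally wrapped into a bounded restraint penalty

    T(r) = A * max(0, 1 - P(r) / (p_max * c))

which is zero wherever the normalized probability ``P(r)/p_max`` is at
least the cutoff ``c`` and rises to the full weight ``A`` where the
density vanishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DistanceDistribution",
    "ContinuousDistribution",
    "PenaltyFunction",
    "FlattenedDistributionError",
    "read_distribution",
    "write_distribution",
    "normalize_unit_area",
    "make_continuous",
]

logger = logging.getLogger(__name__)

#: default restraint weight (squared length units)
DEFAULT_WEIGHT = 10.0
#: default cutoff on the normalized probability below which a penalty applies
DEFAULT_CUTOFF = 0.75
#: evaluation-grid step used to locate the density maximum
PMAX_GRID_STEP = 0.01


class FlattenedDistributionError(ValueError):
    """Raised when a penalty is requested from a distribution with no mass."""


@dataclass(frozen=True)
class DistanceDistribution:
    """A discrete distance probability density.

    Parameters
    ----------
    r : ndarray
        Distances in Angstrom, strictly increasing, length >= 3.
    p : ndarray
        Non-negative probability densities (per Angstrom), same length.
    label : str
        Identifier of the spin pair the distribution belongs to.
    """

    r: np.ndarray
    p: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        if r.ndim != 1 or p.ndim != 1 or r.shape != p.shape:
            raise ValueError("r and p must be 1-D arrays of equal length")
        if len(r) < 3:
            raise ValueError(f"need at least 3 points, got {len(r)}")
        if not np.all(np.diff(r) > 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("densities must be non-negative")

    @property
    def area(self) -> float:
        """Trapezoidal integral of the density over the support."""
        return float(np.trapezoid(self.p, self.r))

    def with_label(self, label: str) -> "DistanceDistribution":
        return replace(self, label=label)


def read_distribution(path, unit: str = "angstrom", label: str | None = None) -> DistanceDistribution:
    """Read a two-column (distance, density) text file.

    Comment lines starting with ``#`` or ``%`` are skipped; columns may be
    separated by whitespace or commas.  ``unit`` declares the distance unit
    in the file (``"angstrom"`` or ``"nanometre"``); distances are returned
    in Angstrom.  Rows with negative density are clamped to zero with a
    warning.  Densities are returned as read, *not* normalized.
    """
    if unit not in ("angstrom", "nanometre", "nm", "A", "ang"):
        raise ValueError(f"unknown unit {unit!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line[0] in "#%":
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric data {line!r}") from exc
    if len(rows) < 3:
        raise ValueError(f"{path}: need at least 3 data rows, got {len(rows)}")
    arr = np.array(rows, dtype=float)
    r, p = arr[:, 0], arr[:, 1]
    if unit in ("nanometre", "nm"):
        r = r * 10.0
    if not np.all(np.diff(r) > 0):
        raise ValueError(f"{path}: distances are not strictly increasing")
    if np.any(p < 0):
        logger.warning("%s: %d negative density values clamped to 0", path, int(np.sum(p < 0)))
        p = np.clip(p, 0.0, None)
    return DistanceDistribution(r=r, p=p, label=label if label is not None else str(path))


def write_distribution(dist: DistanceDistribution, path) -> None:
    """Write a distribution in the same two-column dialect (Angstrom)."""
    with open(path, "w") as fh:
        fh.write(f"# distance_A  probability_density_per_A  ({dist.label})\n")
        for ri, pi in zip(dist.r, dist.p):
            fh.write(f"{ri:.4f} {pi:.8e}\n")


def normalize_unit_area(d: DistanceDistribution) -> DistanceDistribution:
    """Rescale the density so its trapezoidal integral equals one."""
    area = d.area
    if area <= 0:
        raise ValueError(f"distribution {d.label!r} has no probability mass")
    return replace(d, p=d.p / area)


@dataclass(frozen=True)
class ContinuousDistribution:
    """Smooth non-negative interpolant of a discrete distance distribution.

    The density is a shape-preserving piecewise cubic through the knots,
    clamped to be non-negative, and identically zero outside the measured
    support ``[r_min, r_max]``.  ``p_max`` is the maximum density found on
    a fine evaluation grid (not only at the knots, so interpolation
    overshoot cannot yield normalized probabilities above one).
    """

    source: DistanceDistribution
    _spline: PchipInterpolator = field(repr=False)
    _deriv: PchipInterpolator = field(repr=False)
    support: tuple[float, float] = (0.0, 0.0)
    p_max: float = 0.0

    def evaluate(self, r) -> np.ndarray | float:
        """Density (per Angstrom) at distance(s) ``r``; zero off-support."""
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        inside = (r >= self.support[0]) & (r <= self.support[1])
        if np.any(inside):
            out[inside] = np.clip(self._spline(r[inside]), 0.0, None)
        return float(out[0]) if scalar else out

    def derivative(self, r) -> np.ndarray | float:
        """d(density)/dr; zero off-support and wherever the density is clamped."""
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.zeros_like(r)
        inside = (r >= self.support[0]) & (r <= self.support[1])
        if np.any(inside):
            raw = self._spline(r[inside])
            der = self._deriv(r[inside])
            der[raw < 0.0] = 0.0  # clamped region is flat
            out[inside] = der
        return float(out[0]) if scalar else out


def make_continuous(d: DistanceDistribution) -> ContinuousDistribution:
    """Build the continuous representation of a (normalized) distribution."""
    spline = PchipInterpolator(d.r, d.p, extrapolate=False)
    deriv = spline.derivative()
    lo, hi = float(d.r[0]), float(d.r[-1])
    n = max(int(np.ceil((hi - lo) / PMAX_GRID_STEP)) + 1, len(d.r))
    grid = np.linspace(lo, hi, n)
    p_max = float(np.clip(spline(grid), 0.0, None).max())
    return ContinuousDistribution(source=d, _spline=spline, _deriv=deriv,
                                  support=(lo, hi), p_max=p_max)


@dataclass(frozen=True)
class PenaltyFunction:
    """Bounded restraint penalty derived from a continuous distribution."""

    dist: ContinuousDistribution
    A: float = DEFAULT_WEIGHT
    c: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.A <= 0 or not (0 < self.c <= 1):
            raise ValueError("require A > 0 and 0 < c <= 1")
        if self.dist.p_max <= 0:
            raise FlattenedDistributionError(
                f"distribution {self.dist.source.label!r} has p_max = 0; "
                "a penalty term cannot be formed from a fully flat density")

    def __call__(self, r: float) -> tuple[float, float]:
        """Return ``(value, d(value)/dr)`` at distance ``r``.

        The value is ``A * max(0, 1 - P(r)/(p_max*c))``; the gradient is
        analytic and defined to be zero on the plateau where the ``max``
        selects zero.
        """
        scale = self.dist.p_max * self.c
        raw = 1.0 - self.dist.evaluate(r) / scale
        if raw <= 0.0:
            return 0.0, 0.0
        return self.A * raw, -self.A * self.dist.derivative(r) / scale

    def value(self, r: float) -> float:
        return self(r)[0]
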