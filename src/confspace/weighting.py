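"""Relative conformer probabilities from the original distributions.

Each conformer's probability is the product over restraints of the area
under the *original* (unit-area) distance distribution in a +/- 2.5 A
window around the conformer's realized distance; dividing by the ensemble
maximum yields relative probabilities with the most probable conformer at
exactly one.  Products of many small windows are accumulated in log space
to avoid underflow; conformers whose joint probability is zero are kept
with relative probability zero.
"""

from __future__ import annotations

import math

import numpy as np

from .distributions import ContinuousDistribution
from .structure import Conformer

__all__ = [
    "window_probability",
    "joint_probability",
    "log_joint_probability",
    "assign_relative",
    "write_weight_table",
]

DEFAULT_HALF_WIDTH = 2.5  # Angstrom


def window_probability(dist: ContinuousDistribution, r: float,
                       half_width: float = DEFAULT_HALF_WIDTH) -> float:
    """Probability mass of ``dist`` in the window ``[r - hw, r + hw]``.

    Quadrature on a 0.01 A grid over the intersection of the window with
    the support; clipped to [0, 1].
    """
    lo = max(r - half_width, dist.support[0])
    hi = min(r + half_width, dist.support[1])
    if hi <= lo:
        return 0.0
    # the interpolant is piecewise polynomial, so its antiderivative is
    # exact; the shape-preserving construction cannot undershoot zero,
    # hence no clamping correction is needed
    mass = float(dist._spline.integrate(lo, hi))
    return min(max(mass, 0.0), 1.0)


def log_joint_probability(conformer: Conformer,
                          originals: dict[str, ContinuousDistribution],
                          half_width: float = DEFAULT_HALF_WIDTH) -> float:
    """Natural log of the product of window probabilities (-inf if any is 0)."""
    total = 0.0
    for label, dist in originals.items():
        w = window_probability(dist, conformer.pair_distances[label], half_width)
        if w <= 0.0:
            return -math.inf
        total += math.log(w)
    return total


def joint_probability(conformer: Conformer,
                      originals: dict[str, ContinuousDistribution],
                      half_width: float = DEFAULT_HALF_WIDTH) -> float:
    """Product over restraints of the window probabilities."""
    lp = log_joint_probability(conformer, originals, half_width)
    return 0.0 if lp == -math.inf else math.exp(lp)


def assign_relative(ensemble, originals: dict[str, ContinuousDistribution],
                    half_width: float = DEFAULT_HALF_WIDTH):
    """Set each conformer's ``relative_probability`` in place.

    The conformer with the largest joint probability gets exactly 1;
    zero-probability conformers are retained with relative 0.  Raises if
    every conformer has zero joint probability, naming the restraints
    whose windows fail most often.
    """
    conformers = ensemble.conformers if hasattr(ensemble, "conformers") else list(ensemble)
    if not conformers:
        raise ValueError("empty ensemble")
    logs = np.array([log_joint_probability(c, originals, half_width)
                     for c in conformers])
    if np.all(np.isneginf(logs)):
        zero_counts = {
            label: sum(1 for c in conformers
                       if window_probability(dist, c.pair_distances[label], half_width) <= 0)
            for label, dist in originals.items()}
        worst = sorted(zero_counts, key=zero_counts.get, reverse=True)[:5]
        raise ValueError(
            "all conformers have zero joint probability; "
            f"worst-offending restraints: {worst} (zero-window counts {zero_counts})")
    log_max = float(np.max(logs[np.isfinite(logs)]))
    for conf, lp in zip(conformers, logs):
        conf.relative_probability = 0.0 if lp == -math.inf else math.exp(lp - log_max)
    return ensemble


def write_weight_table(path, ensemble, originals: dict[str, ContinuousDistribution],
                       half_width: float = DEFAULT_HALF_WIDTH) -> None:
    """Per-conformer TSV: model index, distances, windows, joint, relative."""
    labels = list(originals)
    with open(path, "w") as fh:
        cols = ["model"]
        for lab in labels:
            cols += [f"d_{lab}", f"w_{lab}"]
        cols += ["joint", "relative"]
        fh.write("\t".join(cols) + "\n")
        for i, conf in enumerate(ensemble.conformers, 1):
            row = [str(i)]
            for lab in labels:
                d = conf.pair_distances[lab]
                row += [f"{d:.3f}",
                        f"{window_probability(originals[lab], d, half_width):.6e}"]
            row += [f"{joint_probability(conf, originals, half_width):.6e}",
                    f"{conf.relative_probability if conf.relative_probability is not None else float('nan'):.6f}"]
            fh.write("\t".join(row) + "\n")
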