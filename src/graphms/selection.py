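"""Data-driven choice of streamline count f and binarization threshold tau.

Two scans drive the choices: (1) mean weighted-graph density versus the
number of sampled streamlines f, looking for the regime where density
has saturated; (2) the across-subject coefficient of variation (CV) of
the five binarized-graph metrics versus tau.  The threshold is picked so
inter-subject variability is low and stable: tau values exceeding the
cohort's mean weighted density are rejected outright, and among the rest
the smallest tau whose metric-averaged CV sits within a relative
tolerance of the scan minimum is returned.

Also provides the spherical-harmonic order cap used when planning a
diffusion acquisition: the largest even order h whose coefficient count
(h+1)(h+2)/2 stays below the number of gradient directions d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import graph_from_matrix, proportional_threshold
from .matrices import ConnectivityMatrix
from . import metrics as gm

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """Raised when no admissible threshold satisfies the selection rules."""


@dataclass(frozen=True)
class ThresholdScan:
    """CV-versus-tau scan over a cohort.

    ``cv_curves`` is indexed by tau with one column per binarized-graph
    metric (r, T, Eg, Q, CPL); ``mean_density`` is the cohort's mean
    weighted-graph density.
    """

    tau_grid: tuple[float, ...]
    cv_curves: pd.DataFrame
    mean_density: float

    def mean_cv(self) -> pd.Series:
        """CV averaged over the five metrics at each tau."""
        return self.cv_curves.mean(axis=1)


@dataclass(frozen=True)
class FiberScan:
    """Density statistics of simulated cohorts across streamline counts."""

    f_grid: tuple[int, ...]
    mean_density: tuple[float, ...]
    sd_density: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f": self.f_grid,
                "mean_density": self.mean_density,
                "sd_density": self.sd_density,
            }
        )


def default_tau_grid() -> tuple[float, ...]:
    """The 20 thresholds 0.05, 0.10, ..., 1.00."""
    return tuple(round(0.05 * k, 2) for k in range(1, 21))


def default_fiber_grid() -> tuple[int, ...]:
    """1000..10,000 by 1000, 10,000..100,000 by 10,000, 100,000..1,000,000 by 100,000."""
    grid = sorted(
        {
            *range(1_000, 10_001, 1_000),
            *range(10_000, 100_001, 10_000),
            *range(100_000, 1_000_001, 100_000),
        }
    )
    return tuple(grid)


def metric_cv_curve(
    cohort: Sequence[ConnectivityMatrix],
    tau_grid: Sequence[float] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> ThresholdScan:
    """Across-subject CV of each binarized-graph metric at each tau.

    CV = sample SD / |mean|.  Undefined metric values (NaN flags) are
    excluded from both moments, with the exclusion count logged.
    """
    if len(cohort) < 2:
        raise ValueError("CV scan needs at least 2 subjects")
    taus = tuple(tau_grid) if tau_grid is not None else default_tau_grid()
    graphs = [graph_from_matrix(m) for m in cohort]
    mean_density = float(np.mean([g.density() for g in graphs]))
    curves = {}
    for tau in taus:
        vals = {name: [] for name in gm.BINARY_METRICS}
        for g in graphs:
            gb = proportional_threshold(g, tau)
            vals["r"].append(gm.assortativity(gb))
            vals["T"].append(gm.transitivity(gb))
            vals["Eg"].append(gm.global_efficiency(gb))
            qv, _ = gm.modularity(gb, seed=seed, n_restarts=n_restarts)
            vals["Q"].append(qv)
            cpl, _ = gm.characteristic_path_length(gb)
            vals["CPL"].append(cpl)
        row = {}
        for name, xs in vals.items():
            xs = np.asarray(xs, dtype=float)
            ok = np.isfinite(xs)
            dropped = int((~ok).sum())
            if dropped:
                logger.info("tau=%.2f metric=%s: excluded %d undefined values", tau, name, dropped)
            if ok.sum() < 2 or np.isclose(np.mean(xs[ok]), 0.0):
                row[name] = np.nan
                continue
            row[name] = float(np.std(xs[ok], ddof=1) / abs(np.mean(xs[ok])))
        curves[tau] = row
    cv = pd.DataFrame.from_dict(curves, orient="index")[list(gm.BINARY_METRICS)]
    cv.index.name = "tau"
    return ThresholdScan(taus, cv, mean_density)


def select_threshold(scan: ThresholdScan, stability_rtol: float = 0.10) -> float:
    """Pick the binarization threshold from a CV scan.

    Thresholds strictly above the cohort mean weighted density are
    rejected.  Among the rest, the smallest tau whose metric-averaged CV
    is within ``stability_rtol`` (relative) of the admissible minimum is
    returned.
    """
    mean_cv = scan.mean_cv()
    admissible = [t for t in scan.tau_grid if t <= scan.mean_density]
    admissible = [t for t in admissible if np.isfinite(mean_cv.loc[t])]
    if not admissible:
        raise SelectionError(
            f"no admissible tau: grid {scan.tau_grid} vs mean density {scan.mean_density:.3f}"
        )
    floor_cv = min(mean_cv.loc[t] for t in admissible)
    for t in admissible:
        if mean_cv.loc[t] <= floor_cv * (1.0 + stability_rtol):
            return t
    return admissible[-1]  # unreachable: the minimum itself always qualifies


def density_vs_fibers(
    base_weights: ConnectivityMatrix,
    f_grid: Sequence[int] | None = None,
    n_subjects: int = 20,
    seed: int = 0,
) -> FiberScan:
    """Mean +/- SD weighted-graph density as the streamline budget grows.

    For each f, ``n_subjects`` matrices are drawn by distributing f
    streamlines multinomially over node pairs in proportion to the base
    weights; density saturates at the base support density once every
    positive pair is hit.
    """
    iu = np.triu_indices(base_weights.q, k=1)
    w = base_weights.values[iu]
    total = w.sum()
    if total <= 0:
        raise ValueError("base matrix has no positive weights")
    p = w / total
    n_pairs = len(w)
    fs = tuple(f_grid) if f_grid is not None else default_fiber_grid()
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for f in fs:
        counts = rng.multinomial(int(f), p, size=n_subjects)
        dens = (counts > 0).sum(axis=1) / n_pairs
        means.append(float(dens.mean()))
        sds.append(float(dens.std(ddof=1)) if n_subjects > 1 else 0.0)
    return FiberScan(fs, tuple(means), tuple(sds))


def max_sh_order(d: int) -> int:
    """Largest even spherical-harmonic order h with (h+1)(h+2)/2 < d."""
    if d < 2:
        raise ValueError(f"need at least 2 diffusion directions, got {d}")
    h = 0
    while (h + 3) * (h + 4) / 2 < d:
        h += 2
    return h
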