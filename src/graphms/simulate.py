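"""Synthetic weighted-connectome cohorts with planted group structure.

Each subject's matrix emulates streamline-count tractography: a latent
nonnegative intensity is laid over node pairs, and f streamlines are
distributed over the pairs by a single multinomial draw, so counts sum
to f exactly and the number-of-fibers scans are cheap.  The latent
intensity carries the planted group differences:

* a support mask (Bernoulli per pair, within-module pairs more likely
  than between-module pairs, rescaled to the profile's target support
  density) sets the weighted-graph density;
* within-module pairs get ``weight_concentration`` times the intensity
  of between-module pairs, so strong edges concentrate inside modules
  and the thresholded graph inherits modular structure;
* node propensities u_i ~ N(0, 1) enter as
  exp(heterogeneity*(u_i + u_j) + hub_tilt*u_i*u_j): heterogeneity
  creates hubs that attach to everything (negative degree
  assortativity, the healthy-network signature), while a positive
  hub_tilt makes similar-propensity nodes prefer each other and drives
  assortativity upward;
* a ring-locality penalty exp(-locality * ringdist(i, j)) favors
  short-range edges, lengthening paths and lowering global efficiency
  without touching the edge budget.

Group effects are planted on these latent intensities, never on metric
values directly — the metrics are emergent, which is what makes
downstream recovery a real test.  Between-subject variability comes
from per-subject log-normal jitter of pair intensities and a jitter of
the support density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .matrices import GROUP_LABELS, ConnectivityMatrix, SubjectRecord


@dataclass(frozen=True)
class GroupProfile:
    """Latent-structure parameters of one subject group.

    Parameters
    ----------
    label : str
        Group name (one of HC, CIS, RR, SP, PP for the preset cohort).
    n_modules : int
        Number of planted modules (nodes assigned round-robin, so module
        membership is interleaved with ring position).
    p_within, p_between : float
        Relative support-mask probabilities for within- and
        between-module pairs; rescaled so the expected support density
        matches ``support_density``.  ``p_within >= p_between``.
    weight_concentration : float
        Intensity ratio within- vs between-module pairs (>= 1); the
        modularity dial.
    hub_tilt : float
        Coefficient of the u_i*u_j propensity product; positive values
        push degree assortativity upward, 0 leaves the disassortative
        hub signature of ``degree_heterogeneity``.
    support_density : float
        Target fraction of node pairs with a nonzero connection.
    degree_heterogeneity : float
        Scale of the additive node-propensity term (hub strength).
    locality : float
        Ring-locality penalty rate; larger values favor short-range
        edges (longer paths, lower efficiency).
    subject_jitter_sigma : float
        Sigma of the per-pair log-normal intensity jitter between
        subjects.
    density_jitter_sigma : float
        SD of the per-subject support-density perturbation.
    """

    label: str
    n_modules: int = 4
    p_within: float = 0.75
    p_between: float = 0.55
    weight_concentration: float = 1.5
    hub_tilt: float = 0.0
    support_density: float = 0.58
    degree_heterogeneity: float = 0.30
    locality: float = 0.0
    subject_jitter_sigma: float = 0.35
    density_jitter_sigma: float = 0.04

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "support_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_within < self.p_between:
            raise ValueError("modular profiles need p_within >= p_between")
        if self.weight_concentration < 1.0:
            raise ValueError("weight_concentration must be >= 1")
        if self.n_modules < 1 or self.n_modules > 50:
            raise ValueError("n_modules out of range")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    Defaults emulate the study conditions: 84 parcels, 500,000 sampled
    streamlines per subject, and group sizes HC 24 / CIS 12 / RR 24 /
    SP 24 / PP 17.
    """

    q: int = 84
    f: int = 500_000
    profiles: Mapping[str, GroupProfile] = field(default_factory=lambda: preset_profiles())
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 24, "CIS": 12, "RR": 24, "SP": 24, "PP": 17}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.f < 1:
            raise ValueError("f must be >= 1")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        missing = [g for g in self.group_sizes if g not in self.profiles]
        if missing:
            raise ValueError(f"no profile for groups {missing}")


def preset_profiles() -> dict[str, GroupProfile]:
    """The five built-in group profiles.

    Calibrated so that, on default-size cohorts, the direction of the
    planted group contrasts matches the clinical pattern: lower density
    in the progressive groups (SP most), assortativity pushed upward in
    SP and PP, modularity raised in RR and lowered in CIS, and longer /
    less efficient paths in every patient group relative to HC.
    """
    return {
        "HC": GroupProfile("HC", support_density=0.58, weight_concentration=1.50,
                           hub_tilt=0.00, degree_heterogeneity=0.20),
        "CIS": GroupProfile("CIS", support_density=0.58, weight_concentration=1.18,
                            hub_tilt=0.00, degree_heterogeneity=0.36),
        "RR": GroupProfile("RR", support_density=0.56, weight_concentration=1.95,
                           hub_tilt=0.00, degree_heterogeneity=0.30),
        "SP": GroupProfile("SP", support_density=0.51, weight_concentration=1.65,
                           hub_tilt=0.30, degree_heterogeneity=0.30),
        "PP": GroupProfile("PP", support_density=0.53, weight_concentration=1.50,
                           hub_tilt=0.50, degree_heterogeneity=0.32),
    }


def planted_partition(q: int, n_modules: int) -> tuple[int, ...]:
    """Round-robin module assignment used by the generator."""
    return tuple(i % n_modules for i in range(q))


def _pair_intensity(profile: GroupProfile, q: int, rng: np.random.Generator):
    """Latent intensity and support probability per upper-triangle pair."""
    iu, ju = np.triu_indices(q, k=1)
    mods = np.asarray(planted_partition(q, profile.n_modules))
    within = mods[iu] == mods[ju]
    intensity = np.where(within, profile.weight_concentration, 1.0)
    u = rng.normal(size=q)
    intensity = intensity * np.exp(
        profile.degree_heterogeneity * (u[iu] + u[ju]) + profile.hub_tilt * u[iu] * u[ju]
    )
    ring = np.minimum(np.abs(iu - ju), q - np.abs(iu - ju)) / (q / 2.0)
    intensity = intensity * np.exp(-profile.locality * ring)
    p_raw = np.where(within, profile.p_within, profile.p_between)
    rho = float(np.clip(
        profile.support_density + rng.normal(0.0, profile.density_jitter_sigma),
        0.05, 0.98,
    ))
    p_mask = np.clip(p_raw * (rho / p_raw.mean()), 0.0, 1.0)
    return iu, ju, intensity, p_mask


def sample_connectome(
    profile: GroupProfile, q: int = 84, f: int = 500_000, seed: int | np.random.Generator = 0
) -> ConnectivityMatrix:
    """Draw one subject's streamline-count matrix from a group profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju, intensity, p_mask = _pair_intensity(profile, q, rng)
    mask = rng.random(len(intensity)) < p_mask
    intensity = intensity * np.exp(rng.normal(0.0, profile.subject_jitter_sigma, len(intensity)))
    p = np.where(mask, intensity, 0.0)
    if p.sum() <= 0:  # pathological density jitter: keep one pair alive
        p[0] = 1.0
    counts = rng.multinomial(int(f), p / p.sum())
    m = np.zeros((q, q))
    m[iu, ju] = counts
    m = m + m.T
    return ConnectivityMatrix(m)


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the full cohort; child seeds derive from the master seed."""
    root = np.random.SeedSequence(config.seed)
    records: list[SubjectRecord] = []
    order = [g for g in GROUP_LABELS if g in config.group_sizes] + [
        g for g in config.group_sizes if g not in GROUP_LABELS
    ]
    streams = root.spawn(len(order))
    for group, ss in zip(order, streams):
        n = config.group_sizes[group]
        child = ss.spawn(n)
        for k in range(n):
            rng = np.random.default_rng(child[k])
            mat = sample_connectome(config.profiles[group], config.q, config.f, rng)
            records.append(SubjectRecord(f"{group}{k + 1:02d}", group, mat))
    return records


def scale_contrast(profile: GroupProfile, factor: float) -> GroupProfile:
    """Scale the within/between intensity contrast (the modularity dial)."""
    return replace(profile, weight_concentration=1.0 + (profile.weight_concentration - 1.0) * factor)
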