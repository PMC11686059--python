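"""Synthetic signed functional-connectivity cohorts.

Generates subject x condition Pearson-correlation matrices with
community structure over named sub-networks, a tunable level of triangle
frustration per condition, and an age covariate, so every pipeline stage
is testable without any real data.

Frustration mechanism.  A naive "flip the sign of a region's signal"
does NOT plant imbalanced triangles: negating x_i maps every correlation
r_ij -> s_i s_j r_ij, a gauge transformation under which all triangle
products are invariant.  Instead, a region selected with probability
``conflict_kappa`` is rotated inside the plane spanned by its community
signal and a shared per-community conflict latent, by an angle of 120 or
240 degrees.  Regions at three mutually separated angles are pairwise
negatively correlated, which is the canonical genuinely frustrated
(imbalanced) correlation structure; the fraction of such triangles, and
hence the energy, grows with kappa.

All randomness descends from a single root seed via
``numpy.random.SeedSequence`` keyed by (subject, condition, stream), so
cohorts are fully reproducible, latent community signals can be shared
between two parcellations of different region counts (for reliability
analysis), and per-subject effects are shared too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .core_energy import (
    CANONICAL_NETWORKS,
    CONDITIONS,
    ConnectivityMatrix,
    Parcellation,
)

#: Default per-condition conflict levels: rest lowest, tasks higher.
DEFAULT_KAPPA: dict[str, float] = {
    "rest": 0.05,
    "shifting": 0.15,
    "nback0": 0.20,
    "gng_initiation": 0.22,
    "nback1": 0.25,
    "gng_inhibition": 0.28,
    "nback2": 0.30,
}

# stream tags for SeedSequence spawning
_STREAM_LATENTS = 7
_STREAM_REGIONS = 11
_STREAM_AGES = 13
_STREAM_SUBJECT = 17

_CONFLICT_ANGLES = (2 * np.pi / 3, 4 * np.pi / 3)


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the cohort generator; all effects are seed-reproducible."""

    n_subjects: int = 20
    n_regions: int = 229
    n_networks: int = 10
    t_points: int = 200
    conflict_kappa: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KAPPA)
    )
    within_coupling: float = 0.8
    cross_coupling: float = 0.15
    noise_sd: float = 0.6
    age_range: tuple[float, float] = (20.0, 86.0)
    age_effect_beta: float = 0.0
    subject_kappa_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_networks < 1:
            raise ValueError("need at least 1 network")
        if self.n_regions < 3 * self.n_networks:
            raise ValueError(
                f"{self.n_regions} regions cannot give every one of "
                f"{self.n_networks} networks >= 3 members"
            )
        if self.t_points <= self.n_networks:
            raise ValueError("t_points must exceed n_networks")
        for cond, kap in self.conflict_kappa.items():
            if not 0.0 <= kap <= 1.0:
                raise ValueError(f"kappa for {cond!r} must be in [0, 1], got {kap}")
        if not 0.0 < self.within_coupling < 1.0:
            raise ValueError("within_coupling must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be ordered (low, high)")


@dataclass
class SyntheticCohort:
    """Generated subjects with per-condition matrices and ground truth."""

    params: SyntheticParams
    parcellation: Parcellation
    subject_ids: tuple[str, ...]
    ages: dict[str, float]
    matrices: dict[tuple[str, str], ConnectivityMatrix]
    kappas: dict[tuple[str, str], float]  # effective kappa per (subject, condition)

    def matrix(self, subject_id: str, condition: str) -> ConnectivityMatrix:
        return self.matrices[(subject_id, condition)]

    def all_matrices(self) -> list[ConnectivityMatrix]:
        return list(self.matrices.values())


def _network_names(n_networks: int) -> tuple[str, ...]:
    names = list(CANONICAL_NETWORKS[:n_networks])
    for i in range(len(names), n_networks):
        names.append(f"NET{i + 1:02d}")
    return tuple(names)


def make_parcellation(
    n_regions: int, n_networks: int, seed: int = 0, atlas_name: str | None = None
) -> Parcellation:
    """Near-balanced seeded assignment of regions to named networks.

    Sizes differ by at most one region; every network gets >= 3 regions
    or a ValueError is raised.  Region-to-network assignment is a seeded
    permutation, deterministic given the seed.
    """
    if n_regions < 3 * n_networks:
        raise ValueError(
            f"{n_regions} regions cannot give {n_networks} networks >= 3 regions each"
        )
    names = _network_names(n_networks)
    base = np.arange(n_regions) % n_networks  # balanced within +/- 1
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(base)
    labels = {
        f"r{i:03d}": names[assignment[i]] for i in range(n_regions)
    }
    return Parcellation(
        labels=labels, atlas_name=atlas_name or f"synthetic{n_regions}"
    )


def _mixing_matrix(n_networks: int) -> np.ndarray:
    """Fixed signed cross-network mixing; networks 0 and 1 anti-correlated."""
    m = np.ones((n_networks, n_networks))
    np.fill_diagonal(m, 0.0)
    if n_networks >= 2:
        m[0, 1] = m[1, 0] = -1.0
    return m


def _membership(parcellation: Parcellation, names: tuple[str, ...]) -> np.ndarray:
    name_idx = {nm: c for c, nm in enumerate(names)}
    return np.array(
        [name_idx[parcellation.labels[r]] for r in parcellation.labels]
    )


def simulate_fc(
    p: SyntheticParams,
    subject_idx: int,
    condition: str,
    kappa: float | None = None,
    parcellation: Parcellation | None = None,
) -> ConnectivityMatrix:
    """One signed correlation matrix for (subject, condition).

    Region signals are built from i.i.d. Gaussian latent community
    signals plus a fixed signed cross-community mixing (including one
    anti-correlated pair, so negative edges exist at kappa = 0), then a
    kappa-fraction of regions is rotated into the conflict plane (see
    module docstring) and observation noise is added.  The output is the
    region-wise Pearson correlation matrix with zeroed diagonal, clipped
    to [-1, 1].

    Latent signals depend only on (seed, subject, condition) — not on the
    parcellation — so two parcellations of different sizes share them.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if kappa is None:
        kappa = float(p.conflict_kappa.get(condition, 0.0))
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    if parcellation is None:
        parcellation = make_parcellation(p.n_regions, p.n_networks, seed=p.seed)
    names = _network_names(p.n_networks)
    member = _membership(parcellation, names)
    n_regions = len(member)
    cond_idx = CONDITIONS.index(condition)

    # latent community signals: shared across parcellations
    rng_lat = np.random.default_rng(
        np.random.SeedSequence([p.seed, _STREAM_LATENTS, subject_idx, cond_idx])
    )
    g = rng_lat.standard_normal((p.n_networks, p.t_points))
    h = rng_lat.standard_normal((p.n_networks, p.t_points))  # conflict latents

    # region-level randomness: parcellation-size specific
    rng_reg = np.random.default_rng(
        np.random.SeedSequence(
            [p.seed, _STREAM_REGIONS, subject_idx, cond_idx, n_regions]
        )
    )
    mix = _mixing_matrix(p.n_networks)
    base_community = p.within_coupling * g + p.cross_coupling * (mix @ g)
    base = base_community[member]  # (n_regions, t)
    base_sd = float(
        np.sqrt(p.within_coupling**2 + p.cross_coupling**2 * (p.n_networks - 1))
    )

    conflicted = rng_reg.random(n_regions) < kappa
    angles = np.zeros(n_regions)
    angles[conflicted] = rng_reg.choice(_CONFLICT_ANGLES, size=int(conflicted.sum()))
    x = (
        np.cos(angles)[:, None] * base
        + np.sin(angles)[:, None] * base_sd * h[member]
        + p.noise_sd * rng_reg.standard_normal((n_regions, p.t_points))
    )
    corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(
        weights=corr,
        region_ids=tuple(parcellation.labels),
        subject_id=f"sub-{subject_idx + 1:03d}",
        condition=condition,
    )


def _effective_kappas(
    p: SyntheticParams, ages: np.ndarray
) -> dict[tuple[int, str], float]:
    """Per-(subject, condition) kappa with subject jitter and age effect.

    The subject-level multiplier is keyed by (seed, subject) only, so it
    is shared by any re-parcellation of the same cohort.
    """
    age_mid = (p.age_range[0] + p.age_range[1]) / 2.0
    out: dict[tuple[int, str], float] = {}
    for s in range(p.n_subjects):
        rng_s = np.random.default_rng(
            np.random.SeedSequence([p.seed, _STREAM_SUBJECT, s])
        )
        jitter = 1.0 + p.subject_kappa_jitter * (2.0 * rng_s.random() - 1.0)
        age_shift = p.age_effect_beta * (ages[s] - age_mid)
        for cond in CONDITIONS:
            base = float(p.conflict_kappa.get(cond, 0.0))
            out[(s, cond)] = float(np.clip(base * jitter + age_shift, 0.0, 1.0))
    return out


def generate_cohort(p: SyntheticParams) -> SyntheticCohort:
    """Full cohort: ages, 7 condition matrices per subject, ground truth.

    Ages are Uniform(age_range); condition-specific conflict levels come
    from ``p.conflict_kappa`` scaled by a per-subject jitter and shifted
    linearly with age when ``age_effect_beta`` is nonzero.  Fully
    reproducible from ``p.seed``.
    """
    parcellation = make_parcellation(p.n_regions, p.n_networks, seed=p.seed)
    rng_ages = np.random.default_rng(np.random.SeedSequence([p.seed, _STREAM_AGES]))
    ages_arr = rng_ages.uniform(p.age_range[0], p.age_range[1], size=p.n_subjects)
    subject_ids = tuple(f"sub-{s + 1:03d}" for s in range(p.n_subjects))
    kappas_idx = _effective_kappas(p, ages_arr)
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    kappas: dict[tuple[str, str], float] = {}
    for s, sid in enumerate(subject_ids):
        for cond in CONDITIONS:
            kap = kappas_idx[(s, cond)]
            matrices[(sid, cond)] = simulate_fc(
                p, s, cond, kappa=kap, parcellation=parcellation
            )
            kappas[(sid, cond)] = kap
    return SyntheticCohort(
        params=p,
        parcellation=parcellation,
        subject_ids=subject_ids,
        ages={sid: float(a) for sid, a in zip(subject_ids, ages_arr)},
        matrices=matrices,
        kappas=kappas,
    )


def reparcellate(
    cohort: SyntheticCohort, n_regions_b: int, seed: int | None = None
) -> SyntheticCohort:
    """Paired cohort under a second parcellation of the same latents.

    Region-level polarity/noise draws are re-sampled, but the latent
    community signals, subject ages and effective conflict levels are
    shared with the source cohort, so energies agree up to region-level
    sampling noise — the setting for reliability (ICC) analysis.
    """
    p = cohort.params
    p_b = replace(p, n_regions=n_regions_b)
    parc_seed = p.seed if seed is None else seed
    parcellation_b = make_parcellation(n_regions_b, p.n_networks, seed=parc_seed)
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}
    for s, sid in enumerate(cohort.subject_ids):
        for cond in CONDITIONS:
            kap = cohort.kappas[(sid, cond)]
            matrices[(sid, cond)] = simulate_fc(
                p_b, s, cond, kappa=kap, parcellation=parcellation_b
            )
    return SyntheticCohort(
        params=p_b,
        parcellation=parcellation_b,
        subject_ids=cohort.subject_ids,
        ages=dict(cohort.ages),
        matrices=matrices,
        kappas=dict(cohort.kappas),
    )
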