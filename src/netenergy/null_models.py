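"""Random-topology surrogate networks.

A surrogate preserves the exact multiset of off-diagonal upper-triangle
weights while scrambling their placement, destroying any organised sign
structure.  Energies of structured networks sit well below their
surrogate ensemble; energies of unstructured networks do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_energy import ConnectivityMatrix, network_energy

SCHEMES = ("weight-permute", "sign-shuffle")


def permute_weights(
    m: ConnectivityMatrix, seed: int, scheme: str = "weight-permute"
) -> ConnectivityMatrix:
    """Seeded random surrogate of ``m``.

    ``weight-permute`` (default): uniformly permute the C(N, 2)
    upper-triangle weights over edge positions and mirror.
    ``sign-shuffle``: permute only the signs, keeping each ``|w|`` in place.
    Both preserve the weight-magnitude multiset; ``weight-permute`` also
    preserves the exact weight multiset.  Deterministic given the seed.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    rng = np.random.default_rng(seed)  # raises TypeError/ValueError on bad seed
    n = m.n_regions
    iu = np.triu_indices(n, k=1)
    vals = m.weights[iu]
    if scheme == "weight-permute":
        new_vals = rng.permutation(vals)
    else:
        signs = np.sign(vals)
        new_vals = rng.permutation(signs) * np.abs(vals)
    w = np.zeros_like(m.weights)
    w[iu] = new_vals
    w = w + w.T
    return ConnectivityMatrix(
        weights=w,
        region_ids=m.region_ids,
        subject_id=m.subject_id,
        condition=m.condition,
        allow_unbounded=m.allow_unbounded,
    )


@dataclass(frozen=True)
class NullEnsemble:
    """Seeded surrogates' energies for one source network."""

    subject_id: str
    condition: str
    seeds: tuple[int, ...]
    null_energies: tuple[float, ...]
    scheme: str = "weight-permute"

    @property
    def median(self) -> float:
        return float(np.median(self.null_energies))


def null_energy_ensemble(
    m: ConnectivityMatrix,
    n_perms: int = 1,
    base_seed: int = 0,
    scheme: str = "weight-permute",
) -> NullEnsemble:
    """Energies of ``n_perms`` surrogates seeded ``base_seed .. base_seed+n_perms-1``.

    ``n_perms=1`` mirrors a one-null-per-network pairing; larger
    ensembles support distributional inference.
    """
    if n_perms < 1:
        raise ValueError(f"n_perms must be >= 1, got {n_perms}")
    seeds = tuple(int(base_seed) + i for i in range(n_perms))
    energies = tuple(
        network_energy(permute_weights(m, s, scheme=scheme)) for s in seeds
    )
    return NullEnsemble(
        subject_id=m.subject_id,
        condition=m.condition,
        seeds=seeds,
        null_energies=energies,
        scheme=scheme,
    )
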