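"""Triangle-balance energy of signed weighted networks.

The central statistic is the network energy

    U = -(1 / C(N, 3)) * sum over unordered triangles {i,j,k} of
        cbrt(S_ij * S_ik * S_jk)

where ``S`` is a symmetric signed weight matrix with zero diagonal and
``cbrt`` is the real (signed) cube root.  Because the real cube root is
multiplicative over the reals, the triangle sum can be evaluated as
``-trace(T^3) / (N (N-1) (N-2))`` with ``T = cbrt(S)`` element-wise: the
trace counts each unordered triangle six times (3! ordered traversals).

``U`` lies in [-1, 1] for weights in [-1, 1]; -1 is attained by a
complete all-positive unit-weight network (every triangle balanced at
unit intensity) and +1 by the all-negative counterpart.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven scan conditions, in canonical order. "rest" is the reference
#: condition for energy deltas.
CONDITIONS = (
    "nback0",
    "nback1",
    "nback2",
    "gng_initiation",
    "gng_inhibition",
    "shifting",
    "rest",
)
REST_CONDITION = "rest"
TASK_CONDITIONS = tuple(c for c in CONDITIONS if c != REST_CONDITION)

#: Canonical sub-network names (ten functional systems).
CANONICAL_NETWORKS = (
    "AUD", "COP", "DAN", "DMN", "FPC", "SAL", "SM", "SC", "VAN", "VIS",
)
WHOLE_BRAIN = "whole_brain"

ASYMMETRY_TOL = 1e-8
BOUND_TOL = 1e-8


def signed_cbrt(x):
    """Real (signed) cube root, ``sign(x) * |x|**(1/3)``.

    Multiplicative over the reals, so the cube root of a triangle product
    equals the product of the edge cube roots.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any input element is not finite.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("signed_cbrt requires finite input")
    out = np.cbrt(arr)  # numpy's cbrt is the real cube root
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class ConnectivityMatrix:
    """Signed symmetric weighted adjacency for one subject x condition.

    On construction the matrix is validated: it must be square with
    N >= 3, finite, symmetric within ``ASYMMETRY_TOL`` (then symmetrized
    by averaging), and its diagonal is zeroed (self-connections carry no
    triangle information; correlation matrices arrive with unit
    diagonals).  Off-diagonal weights must lie in [-1, 1] within
    ``BOUND_TOL`` unless ``allow_unbounded`` is set.
    """

    weights: np.ndarray
    region_ids: tuple[str, ...] = ()
    subject_id: str = ""
    condition: str = REST_CONDITION
    allow_unbounded: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 regions, got {n}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        asym = np.abs(w - w.T).max()
        if asym > ASYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL:g}"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if not self.allow_unbounded:
            overshoot = np.abs(w).max() - 1.0
            if overshoot > BOUND_TOL:
                raise ValueError(
                    f"weights exceed [-1, 1] by {overshoot:.3g}; "
                    "pass allow_unbounded=True to accept"
                )
            w = np.clip(w, -1.0, 1.0)
        self.weights = w
        if not self.region_ids:
            self.region_ids = tuple(f"r{i:03d}" for i in range(n))
        else:
            self.region_ids = tuple(str(r) for r in self.region_ids)
            if len(self.region_ids) != n:
                raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def submatrix(self, region_ids: Sequence[str]) -> "ConnectivityMatrix":
        """Principal submatrix restricted to ``region_ids`` (order kept)."""
        index = {r: i for i, r in enumerate(self.region_ids)}
        missing = [r for r in region_ids if r not in index]
        if missing:
            raise KeyError(f"unknown region ids: {missing}")
        idx = np.array([index[r] for r in region_ids])
        return ConnectivityMatrix(
            weights=self.weights[np.ix_(idx, idx)],
            region_ids=tuple(region_ids),
            subject_id=self.subject_id,
            condition=self.condition,
            allow_unbounded=self.allow_unbounded,
        )


@dataclass(frozen=True)
class Parcellation:
    """Mapping region_id -> canonical sub-network label."""

    labels: Mapping[str, str]
    atlas_name: str = "atlas"

    @property
    def networks(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels.values():
            seen.setdefault(lab, None)
        return tuple(seen)

    def members(self, network: str) -> tuple[str, ...]:
        return tuple(r for r, lab in self.labels.items() if lab == network)

    @classmethod
    def from_tsv(cls, path, atlas_name: str | None = None) -> "Parcellation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"region_id", "network_label"}.issubset(df.columns):
            raise ValueError(
                "parcellation TSV needs columns region_id and network_label"
            )
        labels = dict(zip(df["region_id"], df["network_label"]))
        if len(labels) != len(df):
            raise ValueError("duplicate region_id in parcellation")
        return cls(labels=labels, atlas_name=atlas_name or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"region_id": list(self.labels), "network_label": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TriangleCensus:
    """Counts and cube-rooted intensities of balanced vs imbalanced triangles."""

    n_balanced: int
    n_imbalanced: int
    intensity_balanced: float
    intensity_imbalanced: float
    n_triangles_possible: int

    def energy(self) -> float:
        """Energy implied by the census; equals :func:`network_energy`."""
        return -(self.intensity_balanced - self.intensity_imbalanced) / (
            self.n_triangles_possible
        )


def network_energy(m: ConnectivityMatrix) -> float:
    """Triangle-balance energy via the trace identity.

    ``U = -trace(T^3) / (N (N-1) (N-2))`` with ``T`` the element-wise
    signed cube root of the weights.  Agrees with
    :func:`brute_force_energy` to 1e-10.
    """
    t = signed_cbrt(m.weights)
    n = m.n_regions
    return float(-np.trace(t @ t @ t) / (n * (n - 1) * (n - 2)))


def brute_force_energy(m: ConnectivityMatrix) -> float:
    """Reference oracle: explicit loop over all C(N, 3) unordered triples."""
    t = signed_cbrt(m.weights)
    n = m.n_regions
    total = 0.0
    for i, j, k in itertools.combinations(range(n), 3):
        total += t[i, j] * t[i, k] * t[j, k]
    return -total / comb(n, 3)


def triangle_census(m: ConnectivityMatrix) -> TriangleCensus:
    """Classify every triangle by the sign of its weight product.

    Triangles whose product is exactly zero are counted as neither
    balanced nor imbalanced.  Intensities are sums of cube-rooted
    products, so ``-(I_bal - I_imb) / C(N, 3)`` recovers the energy.
    """
    t = signed_cbrt(m.weights)
    n = m.n_regions
    n_bal = n_imb = 0
    i_bal = i_imb = 0.0
    # vectorized over the third vertex; O(N^2) python iterations
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            prods = t[i, j] * t[i, j + 1 :] * t[j, j + 1 :]
            pos = prods > 0
            neg = prods < 0
            n_bal += int(pos.sum())
            n_imb += int(neg.sum())
            i_bal += float(prods[pos].sum())
            i_imb += float(-prods[neg].sum())
    return TriangleCensus(
        n_balanced=n_bal,
        n_imbalanced=n_imb,
        intensity_balanced=i_bal,
        intensity_imbalanced=i_imb,
        n_triangles_possible=comb(n, 3),
    )


def subnetwork_energy(m: ConnectivityMatrix, p: Parcellation, scope: str) -> float:
    """Energy of the principal submatrix for a canonical sub-network.

    ``scope == WHOLE_BRAIN`` returns the whole-matrix energy; otherwise
    the scope must be a parcellation label with >= 3 member regions
    present in the matrix.  Normalization uses the sub-network's own N.
    """
    if scope == WHOLE_BRAIN:
        return network_energy(m)
    members = [r for r in p.members(scope) if r in set(m.region_ids)]
    if len(members) < 3:
        raise ValueError(
            f"sub-network {scope!r} has {len(members)} regions in this matrix; "
            "need at least 3"
        )
    return network_energy(m.submatrix(members))


def energy_delta(task_u: float, rest_u: float) -> float:
    """Rest-to-task energy change, ``U_task - U_rest``."""
    if not (np.isfinite(task_u) and np.isfinite(rest_u)):
        raise ValueError("energy_delta requires finite inputs")
    return float(task_u) - float(rest_u)


def energy_table(
    cohort: Iterable[ConnectivityMatrix],
    p: Parcellation,
    scopes: Sequence[str] | None = None,
    include_delta: bool = True,
) -> pd.DataFrame:
    """Long-format energy table over a cohort of matrices.

    One row per (subject, condition, scope) with columns
    ``subject_id, condition, scope, U, dU``.  Deltas are relative to the
    same subject's rest matrix at the same scope.

    Raises
    ------
    ValueError
        If ``include_delta`` and some subject lacks a rest condition;
        the message lists the offending subjects.
    """
    matrices = list(cohort)
    if scopes is None:
        scopes = (WHOLE_BRAIN,) + tuple(p.networks)
    rows = []
    for m in matrices:
        for scope in scopes:
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "condition": m.condition,
                    "scope": scope,
                    "U": subnetwork_energy(m, p, scope),
                }
            )
    df = pd.DataFrame(rows)
    dup = df.duplicated(["subject_id", "condition", "scope"])
    if dup.any():
        raise ValueError("duplicate (subject, condition, scope) records in cohort")
    if include_delta:
        rest = df[df["condition"] == REST_CONDITION].set_index(
            ["subject_id", "scope"]
        )["U"]
        missing = sorted(
            set(df["subject_id"]) - set(rest.index.get_level_values(0))
        )
        if missing:
            raise ValueError(
                f"delta requested but subjects lack a rest condition: {missing}"
            )
        key = pd.MultiIndex.from_frame(df[["subject_id", "scope"]])
        df["dU"] = df["U"].to_numpy() - rest.reindex(key).to_numpy()
        df.loc[df["condition"] == REST_CONDITION, "dU"] = np.nan
    return df
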