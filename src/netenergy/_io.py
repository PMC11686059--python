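"""Plain-text I/O for matrices, parcellations and cohort directories.

Matrices live one per file as square numeric CSV/TSV (headerless, or
headered with a leading index column), named ``<subject>_<condition>.csv``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core_energy import CONDITIONS, ConnectivityMatrix, Parcellation
from .synthetic_data import SyntheticCohort

_FNAME_RE = re.compile(
    r"^(?P<subject>.+)_(?P<condition>" + "|".join(CONDITIONS) + r")\.(csv|tsv)$"
)


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if ("\t" in head and path.suffix == ".tsv") or "\t" in head else ","


def read_matrix(
    path,
    subject_id: str | None = None,
    condition: str | None = None,
    region_ids=None,
    allow_unbounded: bool = False,
) -> ConnectivityMatrix:
    """Read one square numeric CSV/TSV; header row/index column detected."""
    path = Path(path)
    if subject_id is None or condition is None:
        m = _FNAME_RE.match(path.name)
        if m is None:
            raise ValueError(
                f"cannot infer subject/condition from filename {path.name!r}; "
                "expected <subject>_<condition>.csv"
            )
        subject_id = subject_id or m.group("subject")
        condition = condition or m.group("condition")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        # headered: first row are column labels, first column row labels
        df = pd.read_csv(path, sep=sep, index_col=0)
        if region_ids is None:
            region_ids = tuple(str(c) for c in df.columns)
    w = df.to_numpy(dtype=float)
    return ConnectivityMatrix(
        weights=w,
        region_ids=tuple(region_ids) if region_ids else (),
        subject_id=subject_id,
        condition=condition,
        allow_unbounded=allow_unbounded,
    )


def write_matrix(m: ConnectivityMatrix, path) -> None:
    np.savetxt(path, m.weights, delimiter=",", fmt="%.17g")


def read_matrix_dir(
    directory, parcellation: Parcellation | None = None, allow_unbounded=False
) -> list[ConnectivityMatrix]:
    """All ``<subject>_<condition>.csv`` matrices in a directory, sorted."""
    directory = Path(directory)
    region_ids = tuple(parcellation.labels) if parcellation else None
    out = []
    for path in sorted(directory.iterdir()):
        if _FNAME_RE.match(path.name):
            out.append(
                read_matrix(
                    path, region_ids=region_ids, allow_unbounded=allow_unbounded
                )
            )
    if not out:
        raise FileNotFoundError(
            f"no <subject>_<condition>.csv matrices found in {directory}"
        )
    return out


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a synthetic cohort as matrices + parcellation + metadata.

    Returns a manifest dict of written files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (sid, cond), m in sorted(cohort.matrices.items()):
        fname = f"{sid}_{cond}.csv"
        write_matrix(m, directory / fname)
        written.append(fname)
    cohort.parcellation.to_tsv(directory / "parcellation.tsv")
    written.append("parcellation.tsv")
    pd.DataFrame(
        {
            "subject_id": list(cohort.subject_ids),
            "age": [cohort.ages[s] for s in cohort.subject_ids],
        }
    ).to_csv(directory / "subjects.csv", index=False)
    written.append("subjects.csv")
    p = cohort.params
    provenance = {
        "n_subjects": p.n_subjects,
        "n_regions": p.n_regions,
        "n_networks": p.n_networks,
        "t_points": p.t_points,
        "conflict_kappa": dict(p.conflict_kappa),
        "within_coupling": p.within_coupling,
        "cross_coupling": p.cross_coupling,
        "noise_sd": p.noise_sd,
        "age_range": list(p.age_range),
        "age_effect_beta": p.age_effect_beta,
        "subject_kappa_jitter": p.subject_kappa_jitter,
        "seed": p.seed,
    }
    (directory / "provenance.json").write_text(json.dumps(provenance, indent=2))
    written.append("provenance.json")
    return {"directory": str(directory), "files": written}


def read_ages(path) -> dict[str, float]:
    df = pd.read_csv(path)
    if not {"subject_id", "age"}.issubset(df.columns):
        raise ValueError("subjects CSV needs columns subject_id, age")
    return dict(zip(df["subject_id"].astype(str), df["age"].astype(float)))
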