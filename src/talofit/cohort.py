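"""Cohort database, per-node statistics and V_sum representativeness.

A cohort pools joint-space profiles from many cases.  Per node j the cohort
mean ``H_ave,j`` and sample SD (denominator n-1) summarise the population;
the representativeness score of a case is

    V_sum = sum_j |H_ave,j - H_j|,   j = 1..9  (mm)

and the case with the smallest V_sum is the cohort's representative
morphology (its joint surface is closest to the average across all nine
nodes).  The candidate case is *not* excluded from the means when scoring.

A transcription of the reference 30-case cohort ships with the package and
is loaded by :func:`load_reference_cohort`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .morphometry import JointSpaceProfile

logger = logging.getLogger("talofit")

H_COLUMNS = [f"H{j}" for j in range(1, 10)]


@dataclass(frozen=True)
class CohortTable:
    """An ordered collection of complete joint-space profiles."""

    profiles: tuple[JointSpaceProfile, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        ids = [p.case_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        nonpos = [p.case_id for p in profiles if np.any(p.H <= 0)]
        if nonpos:
            logger.warning(
                "cohort contains non-positive joint-space values in case(s): %s",
                ", ".join(nonpos),
            )
        object.__setattr__(self, "profiles", profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def case(self, case_id: str) -> JointSpaceProfile:
        for p in self.profiles:
            if p.case_id == case_id:
                return p
        raise KeyError(case_id)

    def matrix(self) -> np.ndarray:
        """(n, 9) array of heights in table order."""
        return np.stack([p.H for p in self.profiles])

    # -- CSV schema: case_id, side, sex, H1..H9 ---------------------------

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "CohortTable":
        df = pd.read_csv(path, dtype={"case_id": str, "side": str, "sex": str})
        missing = [c for c in ["case_id", *H_COLUMNS] if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        profiles = []
        for _, row in df.iterrows():
            side = row.get("side")
            sex = row.get("sex")
            profiles.append(
                JointSpaceProfile(
                    case_id=str(row["case_id"]),
                    H=row[H_COLUMNS].to_numpy(dtype=float),
                    side="" if pd.isna(side) else str(side),
                    sex=None if pd.isna(sex) else str(sex),
                )
            )
        return cls(tuple(profiles), provenance or str(path))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [
                {"case_id": p.case_id, "side": p.side, "sex": p.sex or "",
                 **{c: h for c, h in zip(H_COLUMNS, p.H)}}
                for p in self.profiles
            ]
        )
        df.to_csv(path, index=False)


def load_reference_cohort() -> CohortTable:
    """The packaged 30-case reference cohort of H1-H9 measurements."""
    with resources.files("talofit.data").joinpath("table2.csv").open("rb") as fh:
        return CohortTable.from_csv(fh, provenance="talofit reference cohort (n=30)")


@dataclass(frozen=True)
class CohortSummary:
    """Per-node means and sample SDs across a cohort."""

    H_ave: np.ndarray
    H_sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        ave = np.asarray(self.H_ave, dtype=float).reshape(-1)
        sd = np.asarray(self.H_sd, dtype=float).reshape(-1)
        if ave.shape != (9,) or sd.shape != (9,):
            raise ValueError("summary holds exactly nine means and nine SDs")
        if np.any(sd < 0):
            raise ValueError("SDs must be non-negative")
        object.__setattr__(self, "H_ave", ave)
        object.__setattr__(self, "H_sd", sd)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n": self.n, "H_ave": self.H_ave.tolist(), "H_sd": self.H_sd.tolist()},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CohortSummary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["H_ave"]), np.asarray(d["H_sd"]), int(d["n"]))


@dataclass(frozen=True)
class RepresentativenessResult:
    """V_sum per case and the representative (minimum-V_sum) case."""

    v_sum_by_case: dict[str, float]
    representative_case: str
    v_min: float
    v_max: float


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Per-node mean and sample SD (denominator n-1) over the cohort."""
    if len(cohort) < 2:
        raise ValueError("cohort summary needs at least two cases (SD undefined)")
    m = cohort.matrix()
    return CohortSummary(m.mean(axis=0), m.std(axis=0, ddof=1), len(cohort))


def compute_vsum(profile: JointSpaceProfile, summary: CohortSummary) -> float:
    """Sum of absolute per-node differences from the cohort means (mm)."""
    return float(np.abs(summary.H_ave - profile.H).sum())


def select_representative(cohort: CohortTable) -> RepresentativenessResult:
    """Score every case against the full-cohort means; smallest V_sum wins.

    Ties are broken by table order (the first case attaining the minimum).
    """
    summary = summarize_cohort(cohort)
    v = {p.case_id: compute_vsum(p, summary) for p in cohort}
    values = np.array(list(v.values()))
    ids = list(v.keys())
    best = ids[int(np.argmin(values))]
    return RepresentativenessResult(
        v_sum_by_case=v,
        representative_case=best,
        v_min=float(values.min()),
        v_max=float(values.max()),
    )
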