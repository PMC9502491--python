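"""Event-stream dataset container shared by simulation, estimation and I/O.

The canonical layout follows the NONMEM event-record convention: one row per
event, ``EVID = 1`` for a dose (amount in ``AMT``, mg) and ``EVID = 0`` for an
observation (value in ``DV``, ng/mL), with subject-constant covariate columns
``AGE`` (years), ``BMI`` (kg/m^2) and ``GENO`` (CYP2D6 class: EM/IM/PM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "AGE", "BMI", "GENO"]
GENOTYPES = ("EM", "IM", "PM")


@dataclass
class SubjectData:
    """Per-subject view used by the vectorised likelihood kernels."""

    subject_id: object
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    dv: np.ndarray
    age: float
    bmi: float
    geno: str


class Dataset:
    """Concentration-time event stream for a study population.

    Wraps a :class:`pandas.DataFrame` with the canonical NONMEM-style columns
    and validates the structural invariants: non-negative, within-subject
    non-decreasing times; every subject carries at least one dose and one
    observation (unless ``allow_incomplete``).
    """

    def __init__(self, df: pd.DataFrame, allow_incomplete: bool = False):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing mandatory column(s): {', '.join(missing)}")
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["TIME"] < 0).any():
                bad = int(df.index[df["TIME"] < 0][0])
                raise ValueError(f"negative time at row {bad}")
            for sid, grp in df.groupby("ID", sort=False):
                t = grp["TIME"].to_numpy()
                if np.any(np.diff(t) < 0):
                    row = int(grp.index[1:][np.diff(t) < 0][0])
                    raise ValueError(
                        f"non-monotone times within subject {sid!r} at row {row}"
                    )
                if not allow_incomplete:
                    if not (grp["EVID"] == 1).any():
                        raise ValueError(f"subject {sid!r} has no dose record")
                    if not (grp["EVID"] == 0).any():
                        raise ValueError(f"subject {sid!r} has no observation record")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def subject(self, sid) -> SubjectData:
        grp = self.df[self.df["ID"] == sid]
        doses = grp[grp["EVID"] == 1]
        obs = grp[grp["EVID"] == 0]
        first = grp.iloc[0]
        return SubjectData(
            subject_id=sid,
            dose_times=doses["TIME"].to_numpy(float),
            dose_amounts=doses["AMT"].to_numpy(float),
            obs_times=obs["TIME"].to_numpy(float),
            dv=obs["DV"].to_numpy(float),
            age=float(first["AGE"]),
            bmi=float(first["BMI"]),
            geno=str(first["GENO"]),
        )

    def subjects(self) -> list[SubjectData]:
        return [self.subject(sid) for sid in self.subject_ids]

    def covariates(self) -> pd.DataFrame:
        """One row per subject with AGE, BMI, GENO."""
        return (
            self.df.groupby("ID", sort=False)[["AGE", "BMI", "GENO"]]
            .first()
            .reset_index()
        )

    def padded_arrays(self):
        """Rectangular (padded) arrays for vectorised likelihood evaluation.

        Returns a dict with ``dose_t``/``dose_amt`` of shape (n, Dmax) (unused
        slots have amount 0), ``obs_t``/``dv``/``obs_mask`` of shape (n, Mmax).
        """
        subs = self.subjects()
        n = len(subs)
        dmax = max((len(s.dose_times) for s in subs), default=0)
        mmax = max((len(s.obs_times) for s in subs), default=0)
        dose_t = np.zeros((n, max(dmax, 1)))
        dose_a = np.zeros((n, max(dmax, 1)))
        obs_t = np.zeros((n, max(mmax, 1)))
        dv = np.zeros((n, max(mmax, 1)))
        mask = np.zeros((n, max(mmax, 1)), dtype=bool)
        for i, s in enumerate(subs):
            dose_t[i, : len(s.dose_times)] = s.dose_times
            dose_a[i, : len(s.dose_amounts)] = s.dose_amounts
            obs_t[i, : len(s.obs_times)] = s.obs_times
            dv[i, : len(s.dv)] = s.dv
            mask[i, : len(s.obs_times)] = True
        return {
            "dose_t": dose_t,
            "dose_amt": dose_a,
            "obs_t": obs_t,
            "dv": dv,
            "obs_mask": mask,
            "subject_ids": [s.subject_id for s in subs],
        }

    @classmethod
    def from_rows(cls, rows: list[dict], **kwargs) -> "Dataset":
        if not rows:
            warnings.warn("building an empty Dataset", stacklevel=2)
            return cls.empty()
        return cls(pd.DataFrame(rows), **kwargs)

    @classmethod
    def empty(cls) -> "Dataset":
        return cls(pd.DataFrame({c: [] for c in COLUMNS}))
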