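"""Event-record dataset: NONMEM-convention CSV reader/writer and validation.

One row per dose or observation.  Columns (fixed order):

    ID, OCC, TIME, EVID, AMT, DV, CENS, SEX, BW, BH, AGE, PREP

* ``TIME`` is occasion-relative hours (the dose row of each occasion sits at
  its own TIME; predose samples at 0).  The >= 9-day washout between the two
  crossover periods is represented purely as occasion separation with a full
  system reset — single-dose kinetics, no carryover.
* ``EVID`` 1 = dose (AMT in mg, DV empty), 0 = observation (DV in mg/L).
* ``CENS`` 1 = below the limit of quantification; such rows carry DV = LLOQ
  and enter the likelihood as interval-censored on [0, LLOQ).  Predose
  samples are expected BQL and are kept as censored rows, not dropped.
* ``SEX`` in {female, male}, ``BW`` kg, ``BH`` m, ``AGE`` years, ``PREP`` in
  {test, reference} (may differ between occasions of a subject).

BMI, BSA and FFM are derived on read, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import bsa_mosteller, ffm, weighted_mean

__all__ = [
    "COLUMNS",
    "NOMINAL_TIMES",
    "SubjectCovariates",
    "StudyConfig",
    "EventTable",
    "read_event_table",
    "write_event_table",
    "censored_percentage",
]

COLUMNS = ["ID", "OCC", "TIME", "EVID", "AMT", "DV", "CENS",
           "SEX", "BW", "BH", "AGE", "PREP"]

#: nominal post-dose sampling grid (h); predose (0 h) is sampled in addition
NOMINAL_TIMES = (
    0.16, 0.33, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5,
    3.0, 3.5, 4.0, 6.0, 9.0, 12.0, 16.0, 24.0,
)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """A row violates the event-record invariants."""


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics of one subject; FFM/BMI/BSA derived from BW, BH, sex."""

    sex: str
    bw: float
    bh: float
    age: float
    preparation: tuple[str, ...] = ("test", "reference")

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.bw <= 0 or self.bh <= 0 or self.age < 0:
            raise ValueError("bw, bh must be positive and age nonnegative")

    @property
    def bmi(self) -> float:
        return self.bw / self.bh**2

    @property
    def bsa(self) -> float:
        return bsa_mosteller(self.bw, self.bh)

    @property
    def ffm(self) -> float:
        return ffm(self.sex, self.bw, self.bmi)

    def as_dict(self, occasion: int = 1) -> dict:
        """Covariate mapping for one occasion, as consumed by covariate terms."""
        return {
            "sex": self.sex,
            "BW": self.bw,
            "BH": self.bh,
            "age": self.age,
            "BMI": self.bmi,
            "BSA": self.bsa,
            "FFM": self.ffm,
            "preparation": self.preparation[min(occasion - 1, len(self.preparation) - 1)],
        }


@dataclass
class StudyConfig:
    """Run configuration: design constants, tolerances and SAEM schedule."""

    dose_mg: float = 600.0
    lloq: float = 0.1
    sampling_times: tuple[float, ...] = (0.0,) + NOMINAL_TIMES
    n_subjects: int = 24
    n_occasions: int = 2
    seed: int = 12345
    ode_rtol: float = 1e-10
    count_predose: bool = False  # whether predose rows count as "observations"
    saem: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        st = tuple(float(t) for t in self.sampling_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        self.sampling_times = st


class EventTable:
    """Validated tidy event-record dataset for one study."""

    def __init__(self, df: pd.DataFrame, lloq: float = 0.1, validate: bool = True):
        self.lloq = float(lloq)
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        df = df[COLUMNS]
        # normalize dtypes so write -> read is the identity
        for col in ("TIME", "AMT", "DV", "BW", "BH", "AGE"):
            df[col] = df[col].astype(float)
        for col in ("OCC", "EVID", "CENS"):
            df[col] = df[col].fillna(0).astype(np.int64)
        for col in ("ID", "SEX", "PREP"):
            df[col] = df[col].astype(str)
        df = df.sort_values(["ID", "OCC", "TIME", "EVID"],
                            kind="stable").reset_index(drop=True)
        self.df = df
        if validate:
            self.validate()

    # ---- accessors -----------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    @property
    def n_occasions(self) -> int:
        return int(self.df["OCC"].max())

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def n_obs(self, count_predose: bool = True) -> int:
        obs = self.observations()
        if not count_predose:
            obs = obs[obs["TIME"] > 0]
        return len(obs)

    def n_censored(self) -> int:
        return int((self.observations()["CENS"] == 1).sum())

    def covariates(self) -> dict[str, SubjectCovariates]:
        out = {}
        for sid, grp in self.df.groupby("ID", sort=False):
            preps = tuple(
                grp[grp["OCC"] == occ]["PREP"].iloc[0]
                for occ in sorted(grp["OCC"].unique())
            )
            row = grp.iloc[0]
            out[sid] = SubjectCovariates(
                sex=row["SEX"], bw=float(row["BW"]), bh=float(row["BH"]),
                age=float(row["AGE"]), preparation=preps,
            )
        return out

    def weighted_mean_covariate(self, name: str) -> float:
        """Observation-weighted mean of a continuous covariate across subjects."""
        covs = self.covariates()
        obs_counts = self.observations().groupby("ID", sort=False).size()
        vals = [covs[sid].as_dict()[name] for sid in obs_counts.index]
        return weighted_mean(vals, obs_counts.to_numpy())

    def reference_values(self) -> dict[str, float]:
        return {
            name: self.weighted_mean_covariate(name)
            for name in ("BW", "BH", "age", "BMI", "BSA", "FFM")
        }

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if (df["TIME"] < 0).any():
            idx = int(df.index[df["TIME"] < 0][0])
            raise ValidationError(f"negative TIME at row {idx}")
        if (df.loc[df["EVID"] == 1, "AMT"] <= 0).any():
            idx = int(df.index[(df["EVID"] == 1) & (df["AMT"] <= 0)][0])
            raise ValidationError(f"nonpositive dose AMT at row {idx}")
        obs = df[df["EVID"] == 0]
        if obs["DV"].isna().any():
            idx = int(obs.index[obs["DV"].isna()][0])
            raise ValidationError(f"missing DV on observation row {idx}")
        if (obs["DV"] <= 0).any():
            idx = int(obs.index[obs["DV"] <= 0][0])
            raise ValidationError(f"nonpositive DV on observation row {idx}")
        bad = obs[(obs["CENS"] == 1)
                  & (np.abs(obs["DV"] - self.lloq) > 1e-9 * self.lloq)]
        if len(bad):
            raise ValidationError(
                f"censored row {int(bad.index[0])} must carry DV = LLOQ"
            )
        for (sid, occ), grp in df.groupby(["ID", "OCC"], sort=False):
            ndose = int((grp["EVID"] == 1).sum())
            if ndose != 1:
                raise ValidationError(
                    f"subject {sid} occasion {occ}: expected exactly one dose "
                    f"row, found {ndose}"
                )
        for col, allowed in (("SEX", {"female", "male"}),
                             ("PREP", {"test", "reference"})):
            extra = set(df[col].unique()) - allowed
            if extra:
                raise ValidationError(f"unexpected {col} levels {sorted(extra)}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_like=False)
        except AssertionError:
            return False
        return self.lloq == other.lloq

    def __len__(self) -> int:
        return len(self.df)


def censored_percentage(n_censored: int, n_obs: int) -> float:
    """Percentage of observations below the limit of quantification."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return 100.0 * n_censored / n_obs


def read_event_table(path, config: StudyConfig | None = None,
                     lloq: float | None = None) -> EventTable:
    """Read the event-record CSV, apply the censoring rule, validate.

    Observation rows with DV below the LLOQ are flagged ``CENS = 1`` and their
    DV replaced by the LLOQ value (interval-censored bookkeeping).
    """
    if lloq is None:
        lloq = config.lloq if config is not None else 0.1
    df = pd.read_csv(path, float_precision="round_trip")
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    df["CENS"] = df["CENS"].fillna(0).astype(int)
    is_obs = df["EVID"] == 0
    below = is_obs & (df["DV"] < lloq)
    df.loc[below, "CENS"] = 1
    df.loc[below, "DV"] = lloq
    return EventTable(df, lloq=lloq)


def write_event_table(table: EventTable, path) -> Path:
    """Write the table in the fixed column order; lossless round-trip."""
    path = Path(path)
    df = table.df.copy()
    # default float formatting = shortest round-trip repr
    df.to_csv(path, index=False)
    return path
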