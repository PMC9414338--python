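"""Event-record dataset I/O in a NONMEM-conventional CSV dialect.

The on-disk format uses the column names ID, OCC, TIME, DV, AMT, SS, II,
EVID, MDV plus the covariate columns AGE, SEX, WT, SCR, CRCL (and optionally
BMI).  Missing values are written as '.', DV is stored in ng/mL, SEX is coded
1 = male / 0 = female, and occasions are numbered from 1.  This is the unit
and dialect boundary of the package: everything downstream of this module
works on validated, typed in-memory data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = [
    "ID", "OCC", "TIME", "DV", "AMT", "SS", "II", "EVID", "MDV",
    "AGE", "SEX", "WT", "SCR", "CRCL",
]
OPTIONAL_COLUMNS = ["BMI"]
MISSING_TOKEN = "."


class SchemaError(ValueError):
    """The file or frame does not have the expected columns/structure."""


class ParseError(ValueError):
    """A value could not be parsed; the message lists offending lines."""


@dataclass
class SubjectData:
    """Per-subject arrays prepared for estimation (one row per observation)."""

    id: int
    times: np.ndarray  # h after dose
    dv: np.ndarray  # ng/mL
    dose: np.ndarray  # mg, dose of the occasion each observation belongs to
    occ: np.ndarray
    age: float
    sex_male: int
    wt: float
    scr: float
    crcl: float
    bmi: float


class EventDataset:
    """Validated event-record dataset (dose and observation rows)."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate(df)
        self.df = df

    # -- construction ---------------------------------------------------
    @classmethod
    def read(cls, path) -> "EventDataset":
        """Read a CSV event file; malformed numeric values are reported with
        1-based data line numbers (header is line 1)."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        df = pd.DataFrame(index=raw.index)
        bad_lines: list[str] = []
        cols = [c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in raw.columns]
        for col in cols:
            s = raw[col].str.strip().replace({MISSING_TOKEN: None, "": None})
            num = pd.to_numeric(s, errors="coerce")
            bad = s.notna() & num.isna()
            if bad.any():
                for i in np.flatnonzero(bad.to_numpy()):
                    bad_lines.append(f"line {i + 2}: {col}={s.iloc[i]!r}")
            df[col] = num
        if bad_lines:
            raise ParseError(
                f"{path}: non-numeric values: " + "; ".join(bad_lines)
            )
        return cls(df)

    # -- output ---------------------------------------------------------
    def write(self, path) -> Path:
        """Write CSV with deterministic column order; missing values as '.'."""
        path = Path(path)
        cols = [c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS
                if c in self.df.columns]
        out = self.df[cols].copy()
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for _, row in out.iterrows():
                fields = []
                for c in cols:
                    v = row[c]
                    fields.append(MISSING_TOKEN if pd.isna(v) else f"{v:.12g}")
                fh.write(",".join(fields) + "\n")
        return path

    # -- views ----------------------------------------------------------
    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def dv_as(self, unit: str) -> np.ndarray:
        """Observed concentrations in 'ng/mL' (stored) or 'mg/L'."""
        dv = self.observations["DV"].to_numpy(dtype=float)
        if unit == "ng/mL":
            return dv
        if unit == "mg/L":
            return dv / 1000.0
        raise ValueError(f"unknown unit {unit!r}")

    def to_subjects(self) -> list[SubjectData]:
        """Group into per-subject arrays, mapping each observation to the dose
        amount of its occasion."""
        subjects = []
        for sid, g in self.df.groupby("ID", sort=False):
            doses = g[g["EVID"] == 1].set_index("OCC")["AMT"]
            obs = g[g["EVID"] == 0]
            amt = obs["OCC"].map(doses).to_numpy(dtype=float)
            first = g.iloc[0]
            bmi = float(first["BMI"]) if "BMI" in g.columns else float("nan")
            subjects.append(SubjectData(
                id=int(sid),
                times=obs["TIME"].to_numpy(dtype=float),
                dv=obs["DV"].to_numpy(dtype=float),
                dose=amt,
                occ=obs["OCC"].to_numpy(dtype=float),
                age=float(first["AGE"]),
                sex_male=int(first["SEX"]),
                wt=float(first["WT"]),
                scr=float(first["SCR"]),
                crcl=float(first["CRCL"]),
                bmi=bmi,
            ))
        return subjects

    def subset(self, ids, renumber: bool = True) -> "EventDataset":
        """Dataset with the given subject ids (with repetition allowed, for
        bootstrap resampling); repeated subjects get fresh ids."""
        parts = []
        groups = dict(tuple(self.df.groupby("ID", sort=False)))
        for new_id, sid in enumerate(ids, start=1):
            g = groups[sid].copy()
            if renumber:
                g["ID"] = new_id
            parts.append(g)
        return EventDataset(pd.concat(parts, ignore_index=True))

    def __len__(self) -> int:
        return len(self.df)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.reset_index(drop=True)
    if len(df) == 0:
        return df
    # contiguous subject grouping
    ids = df["ID"].to_numpy()
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    seen: set = set()
    prev_blocks = [ids[0]] + [ids[i] for i in change]
    for b in prev_blocks:
        if b in seen:
            raise SchemaError(f"subject id {b} appears in non-contiguous blocks")
        seen.add(b)
    obs = df[df["EVID"] == 0]
    if obs["DV"].isna().any():
        bad = obs.index[obs["DV"].isna()].tolist()
        raise SchemaError(f"observation rows with missing DV at rows {bad}")
    # every observation occasion must have a dose record
    dose_keys = set(zip(df.loc[df["EVID"] == 1, "ID"],
                        df.loc[df["EVID"] == 1, "OCC"]))
    obs_keys = set(zip(obs["ID"], obs["OCC"]))
    orphans = sorted(obs_keys - dose_keys)
    if orphans:
        raise SchemaError(
            f"observations without a dose record for (ID, OCC): {orphans[:5]}"
        )
    ii = df["II"].dropna()
    tmax = float(ii.max()) if len(ii) else 24.0
    if (df["TIME"] < 0).any() or (df["TIME"] > tmax).any():
        raise SchemaError(f"TIME values outside [0, {tmax}]")
    return df


def build_dataset(rows: list[dict]) -> EventDataset:
    """Assemble an EventDataset from row dictionaries (missing fields -> NaN)."""
    cols = MANDATORY_COLUMNS + [
        c for c in OPTIONAL_COLUMNS if any(c in r for r in rows)
    ]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return EventDataset(df[cols])
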