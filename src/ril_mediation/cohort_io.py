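"""Read, validate, and write patient-level cohort tables.

One row per patient: baseline covariates, exposure (radiation modality,
0 = IMRT photons / 1 = PBT protons), binary mediator (grade-4
radiation-induced lymphopenia, G4RIL), and a right-censored overall-survival
outcome in months. The schema is fixed and shared by every downstream stage;
rows failing validation are rejected and counted, mirroring the exclusion of
patients with missing baseline blood records in the kind of single-center
retrospective cohort this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order of the cohort CSV
COLUMNS = [
    "id", "age", "sex", "baseline_alc", "ptv", "ecog", "location", "stage",
    "chemo_cycles", "barretts", "histology", "surgery", "modality", "g4ril",
    "os_months", "event",
]

CONTINUOUS = ["age", "baseline_alc", "ptv", "chemo_cycles", "os_months"]

#: categorical columns -> canonical levels
CATEGORICAL_LEVELS = {
    "sex": ["female", "male"],
    "ecog": ["0", "1-2"],
    "location": ["upper-middle", "lower"],
    "stage": ["I", "II", "III"],
    "histology": ["adeno", "scc"],
    "barretts": [0, 1],
    "surgery": [0, 1],
    "modality": [0, 1],
    "g4ril": [0, 1],
    "event": [0, 1],
}

#: accepted synonyms, lowercased, mapped to canonical labels
_SYNONYMS = {
    "sex": {"f": "female", "m": "male", "female": "female", "male": "male"},
    "ecog": {"0": "0", "1": "1-2", "2": "1-2", "1-2": "1-2", "1 and 2": "1-2",
             "1and2": "1-2"},
    "location": {"upper-middle": "upper-middle", "upper/middle": "upper-middle",
                 "upper": "upper-middle", "middle": "upper-middle",
                 "lower": "lower"},
    "stage": {"i": "I", "1": "I", "ii": "II", "2": "II", "iii": "III", "3": "III"},
    "histology": {"adeno": "adeno", "adenocarcinoma": "adeno", "scc": "scc",
                  "squamous": "scc", "squamous cell carcinoma": "scc"},
    "modality": {"0": 0, "1": 1, "imrt": 0, "pbt": 1, "photon": 0, "proton": 1},
}
for _col in ("barretts", "surgery", "g4ril", "event"):
    _SYNONYMS[_col] = {"0": 0, "1": 1, "no": 0, "yes": 1, "false": 0, "true": 1}


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


@dataclass
class Cohort:
    """An ordered, validated patient table plus provenance.

    ``df`` always carries the canonical columns in canonical order with a
    unique string ``id``; ``n_rejected`` counts input rows dropped during
    validation (0 for simulated cohorts).
    """

    df: pd.DataFrame
    provenance: str = "observed"  # {observed, simulated, matched}
    note: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.provenance not in ("observed", "simulated", "matched"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.df["id"].duplicated().any():
            dups = self.df.loc[self.df["id"].duplicated(), "id"].tolist()[:5]
            raise ValueError(f"duplicate patient ids, e.g. {dups}")

    def __len__(self) -> int:
        return len(self.df)

    def arm(self, modality: int) -> pd.DataFrame:
        return self.df[self.df["modality"] == modality]


def _normalize_categorical(series: pd.Series, col: str) -> pd.Series:
    syn = _SYNONYMS[col]
    def conv(v):
        if pd.isna(v):
            return np.nan
        key = str(v).strip().lower()
        if key.endswith(".0"):  # "1.0" from numeric CSV round-trips
            key = key[:-2]
        return syn.get(key, np.nan)
    return series.map(conv)


def validate_frame(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Normalize labels and drop invalid rows; returns (clean, n_rejected)."""
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw[COLUMNS].copy()
    df["id"] = df["id"].astype(str)

    bad = pd.Series(False, index=df.index)
    for col in CONTINUOUS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad |= df[col].isna()
    bad |= df["age"] < 0
    bad |= df["baseline_alc"] <= 0
    bad |= df["ptv"] <= 0
    bad |= df["os_months"] <= 0
    bad |= (df["chemo_cycles"] < 1) | (df["chemo_cycles"] % 1 != 0)
    for col in CATEGORICAL_LEVELS:
        df[col] = _normalize_categorical(df[col], col)
        bad |= df[col].isna()

    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("rejected %d row(s) failing validation", n_rejected)
    clean = df[~bad].reset_index(drop=True)
    clean["chemo_cycles"] = clean["chemo_cycles"].astype(int)
    for col in ("barretts", "surgery", "modality", "g4ril", "event"):
        clean[col] = clean[col].astype(int)
    return clean, n_rejected


def read_cohort(path, column_map: dict | None = None,
                provenance: str = "observed", note: str = "") -> Cohort:
    """Read a cohort CSV, validate it, and report rejected-row counts.

    ``column_map`` renames external headers to the canonical schema, e.g.
    ``{"Age at diagnosis": "age"}``.
    """
    raw = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if column_map:
        raw = raw.rename(columns=column_map)
    clean, n_rejected = validate_frame(raw)
    return Cohort(df=clean, provenance=provenance, note=note,
                  n_rejected=n_rejected)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical CSV (UTF-8, '.' decimal, header row).

    Floats are written with 17 significant digits so read(write(cohort))
    is bit-identical."""
    cohort.df[COLUMNS].to_csv(path, index=False, float_format="%.17g")


def summarize_cohort(cohort: Cohort, by: str = "modality",
                     welch: bool = True, correction: bool = True) -> pd.DataFrame:
    """Per-group descriptive table with between-group tests.

    Continuous fields: mean/SD/min/max per group and a t-test p-value
    (Welch by default, pooled-variance optional). Categorical fields:
    count (percent) per level and a Pearson chi-square p-value, with the
    continuity correction applied to 2x2 tables only. Groups with fewer than
    two records get an undefined SD and no test.
    """
    from scipy import stats

    df = cohort.df
    if by not in df.columns:
        raise KeyError(f"grouping column {by!r} not in cohort")
    groups = list(pd.unique(df[by]))
    rows = []
    for col in CONTINUOUS:
        if col == "os_months":
            continue  # outcome, not a baseline characteristic
        cells, samples = {}, []
        for g in groups:
            x = df.loc[df[by] == g, col].to_numpy(dtype=float)
            samples.append(x)
            sd = np.std(x, ddof=1) if len(x) >= 2 else np.nan
            cells[g] = (
                f"{np.mean(x):.1f}, {sd:.1f}" if len(x) >= 2 else "n<2"
            )
        if all(len(x) >= 2 for x in samples) and len(samples) == 2:
            p = stats.ttest_ind(*samples, equal_var=not welch).pvalue
        else:
            p = np.nan
        rows.append({"variable": col, "level": "mean, SD",
                     **{f"group={g}": cells[g] for g in groups}, "p": p})
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in (by, "event", "os_months"):
            continue
        table = np.array([
            [(df[by].eq(g) & df[col].eq(lev)).sum() for g in groups]
            for lev in levels
        ])
        col_tot = table.sum(axis=0)
        if table.sum() and (table.sum(axis=1) > 0).sum() >= 2 and \
                (col_tot > 0).all() and len(groups) >= 2:
            t = table[table.sum(axis=1) > 0]
            corr = correction and t.shape == (2, 2)
            p = stats.chi2_contingency(t, correction=corr).pvalue
        else:
            p = np.nan
        for i, lev in enumerate(levels):
            cells = {}
            for j, g in enumerate(groups):
                pct = 100 * table[i, j] / col_tot[j] if col_tot[j] else np.nan
                cells[f"group={g}"] = f"{table[i, j]} ({pct:.1f})"
            rows.append({"variable": col, "level": str(lev), **cells,
                         "p": p if i == 0 else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["group_sizes"] = {g: int(df[by].eq(g).sum()) for g in groups}
    return out
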