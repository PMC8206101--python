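"""Long-format trial tables: container, CSV dialect, validation, derived columns.

One row per trial.  The native dialect is plain UTF-8 CSV with a single
header row and '.' decimals:

    subject_id, pair_id, subject_role, beneficiary, audience, trial_index,
    xL, yL, pL, xR, yR, pR, choice, obtained, counterfactual, rating

``choice`` is 1 (left wheel) / 0 (right wheel); ``rating`` may be empty for
lapsed responses.  External deposits with a different schema are ingested
through a user-supplied column mapping (see :func:`read_dataset`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NATIVE_COLUMNS = [
    "subject_id", "pair_id", "subject_role", "beneficiary", "audience",
    "trial_index", "xL", "yL", "pL", "xR", "yR", "pR",
    "choice", "obtained", "counterfactual", "rating",
]

#: Minimal columns a mapped external file must provide.
REQUIRED_COLUMNS = [
    "subject_id", "beneficiary", "audience", "trial_index",
    "xL", "yL", "pL", "xR", "yR", "pR", "choice", "obtained", "counterfactual",
]

CONDITIONS = [
    ("self", "absent"), ("self", "present"), ("partner", "absent"), ("partner", "present"),
]

#: The control cell the study treats as baseline: decisions for self, partner absent.
BASELINE_CONDITION = ("self", "absent")


@dataclass
class Dataset:
    """A validated long-format trial table plus provenance.

    ``df`` carries at least :data:`REQUIRED_COLUMNS`; ``provenance`` echoes
    the generating configuration (seed included) or the source file path.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def condition(self, beneficiary: str, audience: str) -> pd.DataFrame:
        """Rows of one 2x2 cell."""
        m = (self.df["beneficiary"] == beneficiary) & (self.df["audience"] == audience)
        return self.df.loc[m]

    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()


def derive_trial_statistics(df: pd.DataFrame) -> pd.DataFrame:
    """Append the derived per-trial columns used by the models.

    Adds dEV, dSD, AR, AD (choice regressors) and regret / disappointment
    (post-outcome emotion factors).  Vectorised equivalent of the scalar
    operations in :mod:`regretchoice.task`.
    """
    out = df.copy()
    evl = df["pL"] * df["xL"] + (1 - df["pL"]) * df["yL"]
    evr = df["pR"] * df["xR"] + (1 - df["pR"]) * df["yR"]
    sdl = np.sqrt(df["pL"] * (df["xL"] - evl) ** 2 + (1 - df["pL"]) * (df["yL"] - evl) ** 2)
    sdr = np.sqrt(df["pR"] * (df["xR"] - evr) ** 2 + (1 - df["pR"]) * (df["yR"] - evr) ** 2)
    out["dEV"] = evl - evr
    out["dSD"] = sdr - sdl
    out["AR"] = (df["yR"] - df["xL"]).abs() - (df["yL"] - df["xR"]).abs()
    out["AD"] = (df["xL"] - df["yL"]) - (df["xR"] - df["yR"])
    out["regret"] = out["counterfactual"] - out["obtained"]
    # unobtained outcome of the chosen wheel
    chose_left = out["choice"] == 1
    cx = np.where(chose_left, df["xL"], df["xR"])
    cy = np.where(chose_left, df["yL"], df["yR"])
    unobtained = np.where(out["obtained"] == cx, cy, cx)
    out["disappointment"] = unobtained - out["obtained"]
    return out


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating the trial invariants; return (clean, drop counts).

    Checked per row: x > y within each wheel, 0 < p < 1, choice in {0, 1}
    and present, obtained/counterfactual members of the respective wheels.
    """
    counts: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, reason: str) -> None:
        bad = mask & keep
        n = int(bad.sum())
        if n:
            counts[reason] = n
            keep[bad] = False

    drop(df["choice"].isna() | ~df["choice"].isin([0, 1]), "missing_or_invalid_choice")
    drop(~(df["xL"] > df["yL"]) | ~(df["xR"] > df["yR"]), "x_not_greater_than_y")
    drop(
        ~((df["pL"] > 0) & (df["pL"] < 1)) | ~((df["pR"] > 0) & (df["pR"] < 1)),
        "probability_outside_unit_interval",
    )
    chose_left = df["choice"] == 1
    cx = df["xL"].where(chose_left, df["xR"])
    cy = df["yL"].where(chose_left, df["yR"])
    ux = df["xR"].where(chose_left, df["xL"])
    uy = df["yR"].where(chose_left, df["yL"])
    drop(~((df["obtained"] == cx) | (df["obtained"] == cy)), "obtained_not_in_chosen_wheel")
    drop(
        ~((df["counterfactual"] == ux) | (df["counterfactual"] == uy)),
        "counterfactual_not_in_unchosen_wheel",
    )
    for reason, n in counts.items():
        logger.warning("dropped %d rows: %s", n, reason)
    return df.loc[keep].copy(), counts


def read_dataset(
    path,
    dialect: str = "native",
    column_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a long-format trial CSV into a validated :class:`Dataset`.

    ``dialect='native'`` expects the package's own column names.
    ``dialect='mapped'`` ingests an external deposit: ``column_map`` maps
    native names (:data:`REQUIRED_COLUMNS`, optionally ``rating``) to the
    file's column names.  Rows failing validation are dropped with
    per-reason counts recorded in the provenance block and logged.
    """
    if dialect == "native":
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"native file {path} lacks required columns: {missing}")
    elif dialect == "mapped":
        if column_map is None:
            raise ValueError("dialect='mapped' requires a column_map (native name -> file column)")
        raw = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in column_map]
        if missing:
            raise ValueError(f"column_map lacks required native columns: {missing}")
        absent = [v for v in column_map.values() if v not in raw.columns]
        if absent:
            raise ValueError(f"mapped file {path} lacks columns: {absent}")
        df = pd.DataFrame({native: raw[src] for native, src in column_map.items()})
    else:
        raise ValueError(f"unknown dialect {dialect!r}; supported: 'native', 'mapped'")
    if len(df) == 0:
        raise ValueError(f"{path} contains no data rows")
    if "rating" not in df.columns:
        df["rating"] = np.nan
    clean, counts = validate_rows(df)
    if len(clean) == 0:
        raise ValueError(f"{path}: no rows survived validation ({counts})")
    return Dataset(clean.reset_index(drop=True),
                   provenance={"source": str(path), "dialect": dialect, "dropped": counts})


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset to native-dialect CSV (UTF-8, one header row)."""
    cols = [c for c in NATIVE_COLUMNS if c in dataset.df.columns]
    extra = [c for c in dataset.df.columns if c not in cols]
    dataset.df[cols + extra].to_csv(path, index=False)
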