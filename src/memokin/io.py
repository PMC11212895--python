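"""CSV readers/writers and YAML configuration for the observation tables.

CSV is the canonical interchange format, one row per
mouse x subset x lineage x timepoint.  Column names follow the fixed
schemas below; a ``rename`` map in the schema options adapts foreign
headers.  Rows violating invariants are either skipped with a
row-indexed diagnostic (default) or fatal, per ``on_invalid``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .datamodel import (
    ChimerismObservation,
    Cohort,
    DilutionObservation,
    LabellingObservation,
    Lineage,
    Subset,
    ValidationError,
)

logger = logging.getLogger("memokin")

LABELLING_COLUMNS = [
    "mouse_id",
    "cohort",
    "subset",
    "lineage",
    "t_label",
    "frac_brdu",
    "frac_brdu_in_ki67hi",
    "frac_brdu_in_ki67lo",
    "frac_ki67hi",
    "n_events",
]
CHIMERISM_COLUMNS = ["mouse_id", "t_bmt", "subset", "donor_fraction"]
DILUTION_COLUMNS = ["mouse_id", "t_tam", "subset", "labelled_fraction"]

_LABELLING_FRACTIONS = [
    "frac_brdu",
    "frac_brdu_in_ki67hi",
    "frac_brdu_in_ki67lo",
    "frac_ki67hi",
]


class SchemaError(ValueError):
    """The table is missing a mandatory column."""


def _load_frame(
    path: Union[str, Path],
    required: Sequence[str],
    rename: Optional[dict] = None,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        logger.warning("%s: valid header but no data rows", path)
    return df


def _build_rows(df, builder, on_invalid: str):
    out, problems = [], []
    for i, row in df.iterrows():
        try:
            out.append(builder(row))
        except (ValidationError, ValueError, KeyError) as exc:
            problems.append((i, str(exc)))
            if on_invalid == "fatal":
                raise ValidationError(f"row {i}: {exc}") from exc
            logger.warning("row %d skipped: %s", i, exc)
    return out, problems


def read_labelling_table(
    path: Union[str, Path],
    rename: Optional[dict] = None,
    percent: bool = False,
    on_invalid: str = "skip",
) -> list[LabellingObservation]:
    """Read a BrdU/Ki67 labelling table into validated observations.

    ``percent=True`` divides the fraction columns by 100.  Ordering of
    valid rows is preserved; invalid rows are skipped (with a logged,
    row-indexed diagnostic) or fatal per ``on_invalid``.
    """
    df = _load_frame(path, LABELLING_COLUMNS, rename)
    if percent:
        df = df.copy()
        df[_LABELLING_FRACTIONS] = df[_LABELLING_FRACTIONS] / 100.0

    def build(row):
        return LabellingObservation(
            mouse_id=str(row["mouse_id"]),
            cohort=Cohort(row["cohort"]),
            subset=Subset(row["subset"]),
            lineage=Lineage(row["lineage"]),
            t_label=float(row["t_label"]),
            frac_brdu=float(row["frac_brdu"]),
            frac_brdu_in_ki67hi=float(row["frac_brdu_in_ki67hi"]),
            frac_brdu_in_ki67lo=float(row["frac_brdu_in_ki67lo"]),
            frac_ki67hi=float(row["frac_ki67hi"]),
            n_events=int(row["n_events"]),
        )

    obs, _ = _build_rows(df, build, on_invalid)
    return obs


def write_labelling_table(
    obs: Sequence[LabellingObservation], path: Union[str, Path]
) -> None:
    rows = [
        {
            "mouse_id": o.mouse_id,
            "cohort": o.cohort.value,
            "subset": o.subset.value,
            "lineage": o.lineage.value,
            "t_label": o.t_label,
            "frac_brdu": o.frac_brdu,
            "frac_brdu_in_ki67hi": o.frac_brdu_in_ki67hi,
            "frac_brdu_in_ki67lo": o.frac_brdu_in_ki67lo,
            "frac_ki67hi": o.frac_ki67hi,
            "n_events": o.n_events,
        }
        for o in obs
    ]
    pd.DataFrame(rows, columns=LABELLING_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_chimerism_table(
    path: Union[str, Path],
    rename: Optional[dict] = None,
    percent: bool = False,
    on_invalid: str = "skip",
) -> list[ChimerismObservation]:
    """Read a donor-fraction (chimerism) timecourse table."""
    df = _load_frame(path, CHIMERISM_COLUMNS, rename)
    if percent:
        df = df.copy()
        df["donor_fraction"] = df["donor_fraction"] / 100.0

    def build(row):
        return ChimerismObservation(
            mouse_id=str(row["mouse_id"]),
            t_bmt=float(row["t_bmt"]),
            subset=Subset(row["subset"]),
            donor_fraction=float(row["donor_fraction"]),
        )

    obs, _ = _build_rows(df, build, on_invalid)
    return obs


def write_chimerism_table(
    obs: Sequence[ChimerismObservation], path: Union[str, Path]
) -> None:
    rows = [
        {
            "mouse_id": o.mouse_id,
            "t_bmt": o.t_bmt,
            "subset": o.subset.value,
            "donor_fraction": o.donor_fraction,
        }
        for o in obs
    ]
    pd.DataFrame(rows, columns=CHIMERISM_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_dilution_table(
    path: Union[str, Path],
    rename: Optional[dict] = None,
    percent: bool = False,
    on_invalid: str = "skip",
) -> list[DilutionObservation]:
    """Read a reporter-dilution (mTom+/YFP+) timecourse table."""
    df = _load_frame(path, DILUTION_COLUMNS, rename)
    if percent:
        df = df.copy()
        df["labelled_fraction"] = df["labelled_fraction"] / 100.0

    def build(row):
        return DilutionObservation(
            mouse_id=str(row["mouse_id"]),
            t_tam=float(row["t_tam"]),
            subset=Subset(row["subset"]),
            labelled_fraction=float(row["labelled_fraction"]),
        )

    obs, _ = _build_rows(df, build, on_invalid)
    return obs


def write_dilution_table(
    obs: Sequence[DilutionObservation], path: Union[str, Path]
) -> None:
    rows = [
        {
            "mouse_id": o.mouse_id,
            "t_tam": o.t_tam,
            "subset": o.subset.value,
            "labelled_fraction": o.labelled_fraction,
        }
        for o in obs
    ]
    pd.DataFrame(rows, columns=DILUTION_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def group_by_subset(obs: Sequence[ChimerismObservation]) -> dict:
    """Chimerism observations keyed by subset."""
    groups: dict = {}
    for o in obs:
        groups.setdefault(o.subset, []).append(o)
    return groups


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
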