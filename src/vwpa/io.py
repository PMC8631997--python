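"""Readers, writers and validation for the pipeline's delimited-text tables.

Three input tables are consumed:

* gaze samples — one row per eye-tracker sample (participant, session
  language, trial, time in ms, event type, and either a pre-coded AOI label
  or screen coordinates);
* trial metadata — one row per trial (item, condition, target side,
  pointing response);
* vocabulary scores — one row per child (CDI expressive-vocabulary counts
  for each language).

All outputs are re-emitted as TSV.  The delimiter of input files is
auto-detected among tab/comma/semicolon (decimal point only) and can be
forced.  Validation never silently coerces enums: an unexpected value names
the offending column and row, with the single documented exception that
unknown AOI strings map to 'other' with a logged warning (the statistics
only consume target/distractor counts).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import AoiLayout, map_coordinates_to_aoi_array

logger = logging.getLogger(__name__)

LANGUAGES = ("norwegian", "english")
EVENT_TYPES = ("fixation", "saccade", "other")
AOIS = ("target", "distractor", "fixation_picture", "other")
CONDITIONS = ("constraining", "neutral")
SIDES = ("left", "right")
FIGURES = ("boy", "girl")

#: CDI-II instrument lengths (words); scores above these are suspicious.
CDI_MAX_WORDS = {"norwegian": 680, "english": 680}

SAMPLE_COLUMNS = ["participant_id", "session_language", "trial_id", "t_ms",
                  "event_type", "gaze_x", "gaze_y", "aoi"]
TRIAL_COLUMNS = ["participant_id", "session_language", "trial_id", "item_id",
                 "condition", "target_side", "pointed_correct",
                 "subject_figure"]
VOCAB_COLUMNS = ["participant_id", "cdi_norwegian", "cdi_english",
                 "age_months", "gender"]


class SchemaError(ValueError):
    """A table violates its schema; the message names column and/or row."""


def sniff_delimiter(path) -> str:
    """Pick the delimiter among tab/comma/semicolon from the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise SchemaError(f"{path}: could not detect a delimiter in the header")
    return best


def _read(path, delimiter=None) -> pd.DataFrame:
    delimiter = delimiter or sniff_delimiter(path)
    return pd.read_csv(path, sep=delimiter, dtype={"participant_id": str,
                                                   "trial_id": str,
                                                   "item_id": str})


def _require(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _check_enum(df: pd.DataFrame, col: str, allowed, path) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: column '{col}' holds invalid value "
            f"{df[col].iloc[row]!r} at row {row} (allowed: {sorted(allowed)})"
        )


def _parse_bool(df: pd.DataFrame, col: str, path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               True: True, False: False, 1: True, 0: False}
    vals = df[col].map(
        lambda v: mapping.get(v.strip().lower() if isinstance(v, str) else v)
    )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise SchemaError(
            f"{path}: column '{col}' holds non-boolean value "
            f"{df[col].iloc[row]!r} at row {row}"
        )
    return vals.astype(bool)


# ---------------------------------------------------------------- samples

def read_gaze_samples(
    path,
    layout: AoiLayout | None = None,
    trials: pd.DataFrame | None = None,
    delimiter: str | None = None,
    tick_ms: float | None = None,
    trial_onset_column: str | None = None,
) -> pd.DataFrame:
    """Read and validate a gaze-sample table.

    Parameters
    ----------
    layout
        Screen geometry; required to derive AOI labels from coordinates.
    trials
        Trial metadata; required together with ``layout`` to resolve
        left/right pictures into target/distractor via each trial's
        ``target_side``.
    tick_ms
        If the time column is in device ticks, its duration in ms.
    trial_onset_column
        Name of a column holding each row's trial onset on the same clock as
        ``t_ms``; when given, times are re-based to trial-relative ms.
    """
    df = _read(path, delimiter)
    _require(df, ["participant_id", "session_language", "trial_id", "t_ms",
                  "event_type"], path)
    if tick_ms is not None:
        df["t_ms"] = df["t_ms"] * float(tick_ms)
    if trial_onset_column is not None:
        if trial_onset_column not in df.columns:
            raise SchemaError(
                f"{path}: missing trial-onset column '{trial_onset_column}'"
            )
        df["t_ms"] = df["t_ms"] - df[trial_onset_column]
        df = df.drop(columns=[trial_onset_column])
    return validate_samples(df, layout=layout, trials=trials, source=str(path))


def validate_samples(
    df: pd.DataFrame,
    layout: AoiLayout | None = None,
    trials: pd.DataFrame | None = None,
    source: str = "<samples>",
) -> pd.DataFrame:
    df = df.copy()
    _check_enum(df, "session_language", LANGUAGES, source)
    _check_enum(df, "event_type", EVENT_TYPES, source)
    if (df["t_ms"] < 0).any():
        row = int(np.flatnonzero((df["t_ms"] < 0).to_numpy())[0])
        raise SchemaError(f"{source}: negative t_ms at row {row}")

    has_aoi = "aoi" in df.columns and df["aoi"].notna().any()
    has_xy = {"gaze_x", "gaze_y"}.issubset(df.columns) and \
        df[["gaze_x", "gaze_y"]].notna().all(axis=None)
    if not has_aoi and not has_xy:
        raise SchemaError(
            f"{source}: samples need either an 'aoi' column or complete "
            "'gaze_x'/'gaze_y' columns"
        )
    if has_aoi:
        unknown = ~df["aoi"].isin(AOIS) & df["aoi"].notna()
        if unknown.any():
            logger.warning(
                "%s: %d unknown AOI labels mapped to 'other' (e.g. %r)",
                source, int(unknown.sum()), df.loc[unknown, "aoi"].iloc[0],
            )
            df.loc[unknown, "aoi"] = "other"

    # sortedness within (participant, trial)
    order_cols = ["participant_id", "trial_id", "t_ms"]
    grouped = df.groupby(["participant_id", "session_language", "trial_id"],
                         sort=False)["t_ms"]
    bad = grouped.apply(lambda s: (s.diff().dropna() < 0).any())
    if bad.any():
        offending = df.groupby(
            ["participant_id", "session_language", "trial_id"], sort=False
        )["t_ms"].transform(lambda s: s.diff().fillna(0) < 0)
        row = int(np.flatnonzero(offending.to_numpy())[0])
        raise SchemaError(
            f"{source}: timestamps not sorted within trial; first offending "
            f"row {row} (participant {df['participant_id'].iloc[row]!r}, "
            f"trial {df['trial_id'].iloc[row]!r}, t_ms {df['t_ms'].iloc[row]})"
        )
    df = df.sort_values(order_cols, kind="stable").reset_index(drop=True)

    if trials is not None:
        keys = ["participant_id", "session_language", "trial_id"]
        known = df[keys].merge(trials[keys].drop_duplicates(), on=keys,
                               how="left", indicator=True)["_merge"] == "both"
        if not known.all():
            row = int(np.flatnonzero(~known.to_numpy())[0])
            raise SchemaError(
                f"{source}: sample row {row} references unknown trial "
                f"{df['trial_id'].iloc[row]!r} for participant "
                f"{df['participant_id'].iloc[row]!r}"
            )
    if has_xy and layout is not None and trials is not None:
        side = df.merge(
            trials[["participant_id", "session_language", "trial_id",
                    "target_side"]],
            on=["participant_id", "session_language", "trial_id"], how="left",
        )["target_side"].to_numpy()
        derived = map_coordinates_to_aoi_array(
            df["gaze_x"].to_numpy(), df["gaze_y"].to_numpy(), layout, side
        )
        if has_aoi:
            mismatch = df["aoi"].to_numpy() != derived
            if mismatch.any():
                row = int(np.flatnonzero(mismatch)[0])
                raise SchemaError(
                    f"{source}: aoi column disagrees with coordinates under "
                    f"the layout at row {row}: {df['aoi'].iloc[row]!r} vs "
                    f"{derived[row]!r}"
                )
        else:
            df["aoi"] = derived
    for col in SAMPLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[SAMPLE_COLUMNS]


# ----------------------------------------------------------------- trials

def read_trial_metadata(path, delimiter: str | None = None) -> pd.DataFrame:
    df = _read(path, delimiter)
    _require(df, [c for c in TRIAL_COLUMNS if c != "subject_figure"], path)
    return validate_trials(df, source=str(path))


def validate_trials(df: pd.DataFrame, source: str = "<trials>") -> pd.DataFrame:
    df = df.copy()
    _check_enum(df, "session_language", LANGUAGES, source)
    _check_enum(df, "condition", CONDITIONS, source)
    _check_enum(df, "target_side", SIDES, source)
    if "subject_figure" in df.columns:
        _check_enum(df, "subject_figure", FIGURES, source)
    else:
        df["subject_figure"] = "boy"
    df["pointed_correct"] = _parse_bool(df, "pointed_correct", source)

    keys = ["participant_id", "session_language", "trial_id"]
    dup = df.duplicated(keys, keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"{source}: duplicated (participant, language, trial) key at row "
            f"{row}: {tuple(df.loc[df.index[row], keys])}"
        )
    # study design check: 7 constraining / 7 neutral per session
    balance = df.groupby(["participant_id", "session_language"],
                         sort=False)["condition"].value_counts().unstack(
        fill_value=0)
    for cond in CONDITIONS:
        if cond not in balance.columns:
            balance[cond] = 0
    off = balance[(balance["constraining"] != balance["neutral"]) |
                  (balance["constraining"] + balance["neutral"] != 14)]
    if len(off):
        logger.warning(
            "%s: %d sessions deviate from the 7 constraining : 7 neutral "
            "design (first: %s)", source, len(off), off.index[0],
        )
    return df[TRIAL_COLUMNS].reset_index(drop=True)


# ------------------------------------------------------------------ vocab

def read_cdi_scores(path, delimiter: str | None = None) -> pd.DataFrame:
    df = _read(path, delimiter)
    _require(df, ["participant_id", "cdi_norwegian", "cdi_english"], path)
    return validate_vocab(df, source=str(path))


def validate_vocab(df: pd.DataFrame, source: str = "<vocab>") -> pd.DataFrame:
    df = df.copy()
    for lang in LANGUAGES:
        col = f"cdi_{lang}"
        vals = df[col]
        if vals.notna().any():
            neg = vals < 0
            if neg.any():
                row = int(np.flatnonzero(neg.to_numpy())[0])
                raise SchemaError(
                    f"{source}: negative CDI count in '{col}' at row {row}"
                )
            over = vals > CDI_MAX_WORDS[lang]
            if over.any():
                logger.warning(
                    "%s: %d values in '%s' exceed the instrument length (%d)",
                    source, int(over.sum()), col, CDI_MAX_WORDS[lang],
                )
    dup = df.duplicated("participant_id", keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(f"{source}: duplicated participant_id at row {row}")
    for col in VOCAB_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[VOCAB_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------- writers

def _write(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_samples(df: pd.DataFrame, path) -> Path:
    df = df.copy()
    df["t_ms"] = _int_if_integral(df["t_ms"])
    optional = ("gaze_x", "gaze_y", "aoi")
    keep = [c for c in SAMPLE_COLUMNS
            if c not in optional or (c in df.columns and df[c].notna().any())]
    return _write(df[keep], path)


def write_trials(df: pd.DataFrame, path) -> Path:
    return _write(df[TRIAL_COLUMNS], path)


def write_vocab(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    for col in ("cdi_norwegian", "cdi_english", "age_months"):
        if col in out.columns:
            out[col] = _int_if_integral(out[col])
    return _write(out[[c for c in VOCAB_COLUMNS if c in out.columns]], path)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write any result table as TSV."""
    return _write(df, path)


def _int_if_integral(s: pd.Series) -> pd.Series:
    vals = pd.to_numeric(s, errors="coerce")
    if vals.notna().all() and (vals == vals.round()).all():
        return vals.astype(np.int64)
    return s


# ------------------------------------------------------------------- YAML

def read_layout(path) -> AoiLayout:
    with open(path, "r", encoding="utf-8") as fh:
        return AoiLayout.from_dict(yaml.safe_load(fh))


def write_layout(layout: AoiLayout, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(layout.to_dict(), fh)
    return path
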