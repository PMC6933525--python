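"""Canonical trial-table CSV format, validation, and run manifests.

The interchange format is long-format CSV, one row per trial, with the
documented header (see FORMATS.md at the repository root).  Reads are
validated: enum domains, per-subject trial contiguity, and -- when a
task variant is named -- consistency of each row's transition label with
its (Stage-1 choice, Stage-2 state) pair.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .task import TaskSpec, STAGE1_ACTIONS, STAGE2_ACTIONS, STAGE2_STATES

__all__ = ["TrialTableError", "read_trials", "write_trials", "write_manifest"]

REQUIRED_COLUMNS = ["subject", "trial", "s1_choice", "transition", "s2_state", "s2_choice", "reward"]
OPTIONAL_COLUMNS = ["rt1", "rt2", "option_latent"]
_ENUMS = {
    "s1_choice": set(STAGE1_ACTIONS),
    "transition": {"common", "rare"},
    "s2_state": set(STAGE2_STATES),
    "s2_choice": set(STAGE2_ACTIONS),
}


class TrialTableError(ValueError):
    """The trial table violates the documented schema."""


def validate_trials(table: pd.DataFrame, spec: TaskSpec | None = None) -> pd.DataFrame:
    """Validate (and lightly normalize) a trial table in place contract.

    Raises :class:`TrialTableError` with row-level diagnostics.
    """
    if len(table) == 0:
        raise TrialTableError("empty trial table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    df = table.copy()
    for col, domain in _ENUMS.items():
        bad = ~df[col].isin(domain)
        if bad.any():
            row = int(df.index[bad][0])
            raise TrialTableError(
                f"row {row}: invalid {col} value {df.loc[row, col]!r}; allowed: {sorted(domain)}"
            )
    if df.duplicated(["subject", "trial"]).any():
        dup = df[df.duplicated(["subject", "trial"])].iloc[0]
        raise TrialTableError(f"duplicate (subject, trial) key: ({dup['subject']}, {dup['trial']})")
    for subj, sub in df.groupby("subject"):
        t = sub["trial"].to_numpy()
        expected = range(1, len(t) + 1)
        if sorted(t) != list(expected):
            raise TrialTableError(
                f"subject {subj}: trials must be consecutive 1..{len(t)}, got {sorted(t)[:5]}..."
            )
    if spec is not None:
        _check_transitions(df, spec)
    return df


def _check_transitions(df: pd.DataFrame, spec: TaskSpec) -> None:
    a1_idx = {"L1": 0, "R1": 1}
    state_idx = {"green": 0, "yellow": 1, "red": 2}
    for row in df.itertuples():
        a1 = a1_idx[row.s1_choice]
        s2 = state_idx[row.s2_state]
        if s2 == 2 and not spec.has_red_state:
            raise TrialTableError(f"row {row.Index}: red state is not part of variant {spec.variant}")
        if s2 == spec.designated_state(a1):
            expected = "common"
        elif s2 == spec.rare_state(a1):
            expected = "rare"
        else:
            raise TrialTableError(
                f"row {row.Index}: state {row.s2_state!r} is unreachable from {row.s1_choice!r}"
            )
        if row.transition != expected:
            raise TrialTableError(
                f"row {row.Index}: transition labelled {row.transition!r} but "
                f"({row.s1_choice}, {row.s2_state}) is a {expected} transition"
            )


def read_trials(path, spec: TaskSpec | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise TrialTableError(f"{path} is empty")
    df = pd.read_csv(path)
    if "option_latent" in df.columns:
        df["option_latent"] = df["option_latent"].fillna("")
    return validate_trials(df, spec)


def write_trials(table: pd.DataFrame, path, observed: bool = False) -> None:
    """Write a trial table as CSV: fixed column order, fixed float
    precision, UTF-8, LF newlines -- byte-identical across runs.

    ``observed=True`` drops latent columns (``option_latent``), producing
    the schema a real dataset would have.
    """
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.columns]
    if observed:
        cols = [c for c in cols if c != "option_latent"]
    out = table[cols]
    out.to_csv(path, index=False, float_format="%.6f", lineterminator="\n", encoding="utf-8")


def write_manifest(path, config: dict, seed: int | None) -> dict:
    """Write a reproducibility manifest (config hash, seed, version)."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "seqhabit",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return manifest
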