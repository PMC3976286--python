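"""Delimited-text file formats: case listings, size-stage tables, fixtures.

Case listings are plain CSV with the column dictionary of
:data:`lunghist.population.CASE_COLUMNS` (units embedded in the names).
Size-stage tables are CSV with one row per stage and one column per 1-cm
diameter bin; the case count travels in a ``# n_cases=`` comment line so
the file round-trips losslessly.
"""

from __future__ import annotations

import io as _io
from typing import Optional

import numpy as np
import pandas as pd

from .detection import DetectionParams, simulate_tumors
from .estimation import N_BINS, SizeStageTable, histogram_cases
from .population import CASE_COLUMNS
from .progression import ProgressionParams
from .smoking import sample_gompertz

__all__ = [
    "write_case_listing",
    "read_case_listing",
    "write_size_stage_table",
    "read_size_stage_table",
    "make_fixture_table",
    "simulate_detected_cases",
]


def write_case_listing(records: pd.DataFrame, path: str) -> None:
    missing = [c for c in CASE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"case listing is missing columns: {missing}")
    records[list(CASE_COLUMNS)].to_csv(path, index=False)


def read_case_listing(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed case listing {path}: {e}") from None
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case listing {path} is missing columns: {missing}")
    bad = df.index[df["stage"].isna() | ~df["stage"].isin(("N0M0", "NxM0", "M1"))]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"malformed stage values at lines {lines} of {path}")
    return df


def write_size_stage_table(table: SizeStageTable, path: str) -> None:
    frame = table.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# n_cases={table.n_cases}\n")
        buf = _io.StringIO()
        frame.to_csv(buf, index_label="stage")
        fh.write(buf.getvalue())


def read_size_stage_table(path: str) -> SizeStageTable:
    n_cases = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# n_cases="):
            n_cases = int(first.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), index_col="stage")
    if df.shape != (3, N_BINS):
        raise ValueError(
            f"size-stage table {path} must be 3 stages x {N_BINS} bins, got {df.shape}"
        )
    return SizeStageTable(probs=df.to_numpy(dtype=float), n_cases=n_cases)


def simulate_detected_cases(
    pp: ProgressionParams,
    dp: DetectionParams,
    n: int,
    rng: np.random.Generator,
    onset_age_range=(40.0, 80.0),
    gompertz_b: float = 8.0e-5,
    gompertz_c: float = 0.085,
    max_rounds: int = 20,
) -> pd.DataFrame:
    """Simulate until at least ``n`` detected cases are collected and
    return exactly ``n`` of them (onset ages uniform over
    ``onset_age_range``, other-cause censoring from the Gompertz law)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    frames = []
    got = 0
    batch = max(2 * n, 1000)
    for _ in range(max_rounds):
        onset = rng.uniform(*onset_age_range, size=batch)
        censor = sample_gompertz(rng, gompertz_b, gompertz_c, size=batch, min_age=onset)
        df = simulate_tumors(pp, dp, rng, onset, censor)
        det = df[df["detected"]]
        frames.append(det)
        got += len(det)
        if got >= n:
            break
    if got < n:
        raise RuntimeError(
            f"collected only {got}/{n} detected cases in {max_rounds} rounds; "
            "detection hazards may be degenerate"
        )
    return pd.concat(frames, ignore_index=True).iloc[:n].reset_index(drop=True)


def make_fixture_table(
    pp: ProgressionParams,
    dp: DetectionParams,
    n: int,
    seed: int,
    onset_age_range=(40.0, 80.0),
) -> SizeStageTable:
    """Synthetic 'observed' size-stage table from ``n`` detected cases
    simulated under known parameters — the recovery-test fixture."""
    rng = np.random.default_rng(seed)
    det = simulate_detected_cases(pp, dp, n, rng, onset_age_range=onset_age_range)
    return histogram_cases(det)
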