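"""Text reports and stage-conditional size-distribution plots."""

from __future__ import annotations

import logging
import os
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .estimation import N_BINS, size_bin
from .population import summarize_observables, summarize_unobservables

__all__ = ["report"]

log = logging.getLogger("lunghist.reporting")


def report(
    records: pd.DataFrame,
    out_dir: Optional[str] = None,
    make_plots: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Build the observable/unobservable summary tables and per-stage size
    histograms for a detected-case listing; optionally write them (and
    stage-conditional plots) under ``out_dir``.

    Plot generation is optional and headless; a missing plotting backend
    degrades to text-only output with a warning.
    """
    obs = summarize_observables(records)
    unobs = summarize_unobservables(records)

    if len(records):
        bins = size_bin(records["diameter_cm"])
        counts = (
            pd.DataFrame({"stage": records["stage"], "size_bin_cm": bins})
            .groupby(["stage", "size_bin_cm"], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=range(N_BINS), fill_value=0)
        )
    else:
        counts = pd.DataFrame(columns=range(N_BINS))
    out = {
        "observables": obs,
        "size_by_stage": counts,
        **unobs,
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, frame in out.items():
            frame.to_csv(os.path.join(out_dir, f"{name}.csv"))
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            for name, frame in out.items():
                fh.write(f"== {name} ==\n{frame.to_string()}\n\n")
        if make_plots:
            _plots(records, counts, out_dir)
    return out


def _plots(records: pd.DataFrame, counts: pd.DataFrame, out_dir: str) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as e:  # pragma: no cover - depends on environment
        log.warning("plotting backend unavailable (%s); text-only report", e)
        return
    if len(records) == 0:
        return
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    x = np.arange(counts.shape[1])
    for stage in counts.index:
        row = counts.loc[stage].to_numpy(dtype=float)
        frac = row / row.sum() if row.sum() else row
        axes[0].step(x, frac, where="post", label=stage)
    axes[0].set_xlabel("tumor diameter bin (cm)")
    axes[0].set_ylabel("within-stage fraction")
    axes[0].legend()
    axes[0].set_title("size distribution conditional on stage")

    col_tot = counts.sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = counts.to_numpy(dtype=float) / col_tot
    for i, stage in enumerate(counts.index):
        axes[1].step(x, np.nan_to_num(cond[i]), where="post", label=stage)
    axes[1].set_xlabel("tumor diameter bin (cm)")
    axes[1].set_ylabel("stage fraction within bin")
    axes[1].legend()
    axes[1].set_title("stage distribution conditional on size")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "size_stage.png"), dpi=120)
    plt.close(fig)
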