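"""Bioreactor process-performance arithmetic.

Two-stage partial-nitritation/anammox (PNA) systems are monitored by the
inorganic nitrogen species (ammonia, nitrite, nitrate, all as mg N/l) at
each stage boundary. Total nitrogen removal across a stage is

    removal = 1 - TN_effluent / TN_influent,

with TN the sum of the three species. For the anammox stage the influent
is the partial-nitritation effluent.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

NITROGEN_SPECIES = ("ammonia_mgN_l", "nitrite_mgN_l", "nitrate_mgN_l")


def read_process_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a process-performance table (sample x nitrogen species, TSV).

    Columns: sample, ammonia_mgN_l, nitrite_mgN_l, nitrate_mgN_l. With no
    path, loads the packaged steady-state measurements of the two-stage
    PNA bioreactor the pipeline was developed around.
    """
    if path is None:
        ref = resources.files("magtx").joinpath(
            "data/process_performance.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample",) + NITROGEN_SPECIES
               if c not in df.columns]
    if missing:
        raise ValueError(f"process table missing column(s) {missing}")
    return df.set_index("sample")


def total_nitrogen(df: pd.DataFrame, sample: str) -> float:
    """Total inorganic nitrogen (mg N/l) of one sample."""
    return float(df.loc[sample, list(NITROGEN_SPECIES)].sum())


def stage_nitrogen_removal(df: pd.DataFrame, influent: str,
                           effluent: str) -> float:
    """Fractional total-nitrogen removal across one treatment stage."""
    tn_in = total_nitrogen(df, influent)
    if tn_in <= 0:
        raise ValueError(f"influent {influent!r} has no nitrogen")
    return 1.0 - total_nitrogen(df, effluent) / tn_in


def anammox_stage_removal(df: pd.DataFrame | None = None) -> float:
    """Total-nitrogen removal across the anammox stage (PN effluent in,
    anammox effluent out)."""
    if df is None:
        df = read_process_table()
    return stage_nitrogen_removal(df, "PN-effluent", "Anammox-effluent")
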