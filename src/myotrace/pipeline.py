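"""Cohort-level orchestration: tables of per-strip estimates.

Thin glue between the per-strip quantifiers and the group statistics /
CLI: each function maps a list of bundles to a tidy DataFrame with one row
per strip, catching per-strip stage failures into a flags column instead of
aborting the cohort.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .drugs import quantify_drug_effect
from .efs import cholinergic_dissection, duration_response
from .errors import MyotraceError
from .spontaneous import quantify_spontaneous
from .trace_model import TraceBundle


def spontaneous_table(bundles: Sequence[TraceBundle],
                      band: tuple = (0.005, 0.5)) -> pd.DataFrame:
    """Per-strip A_SC / f_SC / T_SC table (NaN + flag on stage failure)."""
    rows = []
    for b in bundles:
        meta = b.trace.strip_meta
        row = {"strip_id": meta.strip_id, "group": meta.group,
               "urothelium": meta.urothelium,
               "A_SC_pct": np.nan, "f_SC_Hz": np.nan, "T_SC_s": np.nan,
               "flags": ""}
        try:
            st = quantify_spontaneous(b, band=band)
            row.update(A_SC_pct=st.A_SC, f_SC_Hz=st.f_SC, T_SC_s=st.T_SC,
                       flags=";".join(st.flags))
        except MyotraceError as exc:
            row["flags"] = f"error:{exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def dissection_table(bundles: Sequence[TraceBundle]) -> pd.DataFrame:
    """Per-strip cholinergic plateau fraction from a duration-series bundle."""
    rows = []
    for b in bundles:
        meta = b.trace.strip_meta
        row = {"strip_id": meta.strip_id, "group": meta.group,
               "plateau_fraction": np.nan, "chol_amplitude_pct": np.nan,
               "nonchol_amplitude_pct": np.nan, "flags": ""}
        try:
            pre = duration_response([b], "pre-ATR")
            atr = duration_response([b], "post-ATR")
            dis = cholinergic_dissection(pre, atr)
            row.update(plateau_fraction=dis.plateau_fraction,
                       chol_amplitude_pct=dis.chol_amplitude,
                       nonchol_amplitude_pct=dis.nonchol_amplitude,
                       flags=";".join(dis.flags))
        except MyotraceError as exc:
            row["flags"] = f"error:{exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def drug_table(bundles: Sequence[TraceBundle], drug: str) -> pd.DataFrame:
    """Per-strip drug-effect table: delta tension + A_SC/f_SC/A_EFS folds."""
    rows = []
    for b in bundles:
        meta = b.trace.strip_meta
        row = {"strip_id": meta.strip_id, "group": meta.group,
               "urothelium": meta.urothelium, "drug": drug,
               "delta_tension_pct": np.nan, "asc_fold": np.nan,
               "fsc_fold": np.nan, "efs_fold": np.nan, "flags": ""}
        try:
            eff = quantify_drug_effect(b, drug)
            row.update(delta_tension_pct=eff.delta_tension,
                       asc_fold=eff.asc_fold, fsc_fold=eff.fsc_fold,
                       efs_fold=eff.efs_fold, flags=";".join(eff.flags))
        except MyotraceError as exc:
            row["flags"] = f"error:{exc}"
        rows.append(row)
    return pd.DataFrame(rows)
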