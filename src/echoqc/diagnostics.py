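"""Diagnostic data tables: per-parameter histograms and pairwise scatters.

These are the tabular counterparts of the graphical displays used to audit
raw echo data (identity plots, per-parameter histograms showing the two
unit modes, and pairwise scatterplots revealing unit-discordant points).
They are emitted as CSV so any plotting front-end can render them.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .model import EchoDataset, PARAMETERS

__all__ = ["histogram_tables", "scatter_table", "export_diagnostics"]


def _values(ds: EchoDataset, p, harmonized: bool) -> List[float]:
    out = []
    for r in ds.reports:
        m = r.measurements[p]
        if not m.is_live:
            continue
        v = m.value_mm if harmonized else m.effective_raw
        if v is not None:
            out.append(v)
    return out


def histogram_tables(ds: EchoDataset, bins: int = 60,
                     harmonized: bool = False) -> pd.DataFrame:
    rows = []
    for p in PARAMETERS:
        vals = np.asarray(_values(ds, p, harmonized))
        if len(vals) == 0:
            continue
        counts, edges = np.histogram(vals, bins=bins)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"parameter": p.value, "bin_lo": lo, "bin_hi": hi,
                         "count": int(c)})
    return pd.DataFrame(rows, columns=["parameter", "bin_lo", "bin_hi", "count"])


def scatter_table(ds: EchoDataset, harmonized: bool = False) -> pd.DataFrame:
    """Long-format pairwise scatter data for all 15 parameter pairs."""
    rows = []
    for px, py in combinations(PARAMETERS, 2):
        for r in ds.reports:
            mx, my = r.measurements[px], r.measurements[py]
            if not (mx.is_live and my.is_live):
                continue
            vx = mx.value_mm if harmonized else mx.effective_raw
            vy = my.value_mm if harmonized else my.effective_raw
            if vx is None or vy is None:
                continue
            rows.append({"x_parameter": px.value, "y_parameter": py.value,
                         "report_id": r.report_id, "x": vx, "y": vy})
    return pd.DataFrame(rows, columns=["x_parameter", "y_parameter",
                                       "report_id", "x", "y"])


def export_diagnostics(ds: EchoDataset, out_dir,
                       harmonized: bool = False) -> List[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = "mm" if harmonized else "raw"
    paths = []
    for name, frame in (("histograms", histogram_tables(ds, harmonized=harmonized)),
                        ("scatters", scatter_table(ds, harmonized=harmonized))):
        fp = out / f"{name}_{suffix}.csv"
        frame.to_csv(fp, index=False)
        paths.append(fp)
    return paths
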