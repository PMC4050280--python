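"""emPAI-based relative protein abundance.

The exponentially modified protein abundance index is
``emPAI = 10^(n_observed / n_observable) - 1``; relative abundance of a
protein within one preparation is its emPAI as a percentage of the sum of
emPAI values over all detected proteins in that preparation. Not-detected
entries are excluded (not treated as zero). Reported percentages are
rounded half-up to integers; full precision is kept in a separate column.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import EmpaiTable


def empai(n_observed: int, n_observable: int) -> float:
    """Exponentially modified protein abundance index."""
    if n_observable < 1:
        raise ValueError("n_observable must be at least 1")
    if n_observed < 0:
        raise ValueError("n_observed must be non-negative")
    return float(10.0 ** (n_observed / n_observable) - 1.0)


def relative_abundance(table: EmpaiTable) -> EmpaiTable:
    """Add relative-abundance percentages over the detected entries.

    ``relative_abundance_pct`` holds the full-precision percentage;
    ``relative_abundance_int`` the half-up-rounded integer for reporting.
    Unrounded percentages over detected entries sum to 100.
    """
    df = table.df.copy()
    vals = df["empai"].to_numpy(float)
    detected = np.isfinite(vals)
    if not detected.any():
        raise ValueError("no detected entries: relative abundance undefined")
    denom = vals[detected].sum()
    pct = np.full(len(df), np.nan)
    pct[detected] = 100.0 * vals[detected] / denom
    df["relative_abundance_pct"] = pct
    rounded = np.full(len(df), np.nan)
    rounded[detected] = np.floor(pct[detected] + 0.5)
    df["relative_abundance_int"] = rounded
    return EmpaiTable(df)


def load_vesicle_proteomics(preparation: str | None = None,
                            path: str | Path | None = None) -> EmpaiTable:
    """Load the packaged fusogen-vesicle mass-spectrometry emPAI table.

    The fixture holds one row per protein with one emPAI column per
    vesicle preparation ('AFF-1', 'EFF-1'); empty cells mean not detected.
    With ``preparation`` given, returns a single-preparation
    :class:`EmpaiTable` restricted to detected-or-ND rows of that column.
    """
    if path is None:
        src = resources.files("memtomo.data").joinpath("empai_vesicles.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if preparation is None:
        first = [c for c in df.columns if c.startswith("empai_")][0]
        return EmpaiTable(df.rename(columns={first: "empai"}))
    col = f"empai_{preparation.lower().replace('-', '')}"
    if col not in df.columns:
        raise KeyError(f"no emPAI column for preparation {preparation!r}")
    out = df[["protein", "accession", col]].rename(columns={col: "empai"})
    return EmpaiTable(out)
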