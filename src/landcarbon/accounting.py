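"""Ecosystem carbon-balance accounting identities and summaries.

Sign conventions follow the reporting style of statewide assessments: positive
values denote net gains of carbon by terrestrial ecosystems; losses from land
use, land-use change, disturbance and leaching (the "LULCC" column) are stored
as positive removals, so NECB = NEP - LULCC.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "accounting_nep",
    "accounting_necb",
    "window_mean",
    "load_historical_ledger",
    "summarize_history",
]


def accounting_nep(npp, rh):
    """Net ecosystem productivity: NPP minus heterotrophic respiration."""
    return np.asarray(npp) - np.asarray(rh) if np.ndim(npp) else float(npp) - float(rh)


def accounting_necb(nep, lulcc):
    """Net ecosystem carbon balance: NEP minus LULCC removals (positive losses)."""
    return np.asarray(nep) - np.asarray(lulcc) if np.ndim(nep) else float(nep) - float(lulcc)


def window_mean(values: pd.Series, window: tuple[int, int]) -> float:
    """Mean annual value over an inclusive year window (flux-years)."""
    y0, y1 = window
    sel = values.loc[(values.index >= y0) & (values.index <= y1)]
    if sel.empty:
        raise ValueError(f"window {window} selects no years")
    return float(sel.sum() / len(sel))


def load_historical_ledger() -> pd.DataFrame:
    """Published statewide annual carbon ledger for California, 2001-2015.

    Stocks (live, DOM, soil, TEC) in Tg C; fluxes (NPP, Rh, NEP, LULCC, NECB)
    in Tg C/yr; the transfer column is cumulative carbon moved from ecosystem
    to non-ecosystem classes.  The 2001 row carries initial stocks only.
    """
    with resources.files("landcarbon.data").joinpath("ca_historical_ledger.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("year")


def summarize_history(ledger: pd.DataFrame) -> dict[str, float]:
    """Headline accounting statistics from an annual ledger table.

    Computes cumulative and window-mean NECB, the minimum annual NECB, mean
    NPP/Rh/NEP, mean and cumulative LULCC removals, and the percentage
    reduction of the worst drought-year NEP (2013) relative to the 2002-2010
    mean.  All quantities are recomputed from the ledger's columns, not read
    from any stored summary.
    """
    flux = ledger.dropna(subset=["necb"])
    necb = flux["necb"]
    nep = accounting_nep(flux["npp"], flux["rh"])
    nep = pd.Series(nep, index=flux.index)
    out = {
        "cumulative_necb": float(necb.sum()),
        "mean_necb_2002_2015": window_mean(necb, (2002, 2015)),
        "mean_necb_2002_2011": window_mean(necb, (2002, 2011)),
        "mean_necb_2012_2015": window_mean(necb, (2012, 2015)),
        "cumulative_necb_2012_2015": float(necb.loc[2012:2015].sum()),
        "min_annual_necb": float(necb.min()),
        "mean_npp": float(flux["npp"].mean()),
        "mean_rh": float(flux["rh"].mean()),
        "mean_nep": float(flux["nep"].mean()),
        "mean_lulcc": float(flux["lulcc"].mean()),
        "cumulative_lulcc": float(flux["lulcc"].sum()),
    }
    nep_ref = window_mean(flux["nep"], (2002, 2010))
    out["nep_2013_reduction_pct"] = 100.0 * (nep_ref - flux["nep"].loc[2013]) / nep_ref
    return out
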