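"""Published Karonga HDSS summary counts, bundled as worked-example inputs.

These are the printed sending/receiving household-composition counts (short
moves only) and the moved-with-parents counts for the study population, by
life stage, sex, move length and independence.  They serve as fixed inputs
to the tabulation code — recomputing each printed percent from its column
counts, and checking cross-table closure (the accompanied flow totals equal
the short parent-accompaniment totals stratum by stratum).  They are not
outputs of the synthetic pipeline.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with importlib.resources.files("hdssmig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def flow_counts() -> pd.DataFrame:
    """Sending/receiving composition counts and printed percents."""
    return _load("published_flow_counts.csv")


def parent_accompaniment_counts() -> pd.DataFrame:
    """Moved-with-parents counts and printed percents (accompanied moves)."""
    return _load("published_parent_accompaniment.csv")


def recompute_flow_percents() -> pd.DataFrame:
    """Printed flow counts with percents recomputed by the tabulation code."""
    from .descriptives import marginal_percents

    df = flow_counts().copy()
    out = []
    for _, grp in df.groupby(["life_stage", "independence", "side", "sex"],
                             sort=False):
        grp = grp.copy()
        grp["pct_recomputed"] = marginal_percents(grp["n"])
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def recompute_parent_percents() -> pd.DataFrame:
    from .descriptives import marginal_percents

    df = parent_accompaniment_counts().copy()
    out = []
    for _, grp in df.groupby(["life_stage", "length", "sex"], sort=False):
        grp = grp.copy()
        grp["pct_recomputed"] = marginal_percents(grp["n"])
        out.append(grp)
    return pd.concat(out, ignore_index=True)
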