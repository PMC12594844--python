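"""Readers for paired-observation data and RSS resampling of populations.

Real paired data arrive as a two-column numeric table (x = the cheap
ranking/concomitant variable, y = the study variable).  For ingested data
the diagonal branch of the model requires exact ties x == y; near-ties can
be declared with an explicit tolerance, since continuous measurements
essentially never tie exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sampling import RSSSample, SRSSample, compute_indicators

__all__ = ["read_paired_csv", "rss_from_population_csv"]

log = logging.getLogger("biwrss")


def _validate_paired_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            "expected a header with numeric columns 'x' and 'y'"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row(s) "
                f"{(bad + 1).tolist()[:10]}"
            )
        nonpos = np.flatnonzero((vals <= 0).to_numpy())
        if nonpos.size:
            raise ValueError(
                f"{path}: non-positive value in column {col!r} at data row(s) "
                f"{(nonpos + 1).tolist()[:10]}; both variables must be > 0"
            )
        df[col] = vals
    return df


def read_paired_csv(path, tie_tol: float = 0.0) -> SRSSample:
    """Read a paired-observation CSV (columns x, y) as an SRS sample.

    Parameters
    ----------
    path : file path
    tie_tol : float, default 0.0
        Pairs with |x - y| <= tie_tol are treated as ties (the diagonal
        branch); the default recognises exact equality only.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file; expected a header with columns x, y")
    df = _validate_paired_frame(df, path)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if tie_tol > 0:
        near = np.abs(x - y) <= tie_tol
        y = np.where(near, x, y)
    d1, d2, d3 = compute_indicators(x, y)
    n_ties = int(d3.sum())
    if n_ties:
        log.info("%s: %d tied pair(s) routed to the diagonal branch", path, n_ties)
    return SRSSample(x, y, d1, d2, d3)


def rss_from_population_csv(path, m: int, r: int, seed=None, tie_tol: float = 0.0) -> RSSSample:
    """Ranked-set resampling (with replacement) from a population table.

    Per cycle: sample m*m rows with replacement, partition into m sets of m,
    rank each set by x, keep the i-th ranked pair of set i.  Reproducible
    under a fixed seed.
    """
    pop = read_paired_csv(path, tie_tol=tie_tol)
    if pop.n < m * m:
        raise ValueError(
            f"{path}: population has {pop.n} rows but m^2 = {m * m} are "
            "drawn per cycle"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pop.n, size=(r, m, m))
    x = pop.x[idx]
    y = pop.y[idx]
    order = np.argsort(x, axis=-1, kind="stable")
    xs = np.take_along_axis(x, order, -1)
    ys = np.take_along_axis(y, order, -1)
    sel = np.arange(m)
    xk = xs[:, sel, sel].ravel()
    yk = ys[:, sel, sel].ravel()
    d1, d2, d3 = compute_indicators(xk, yk)
    rank = np.tile(sel + 1, r)
    cycle = np.repeat(np.arange(1, r + 1), m)
    return RSSSample(xk, yk, d1, d2, d3, rank, cycle, m=m, r=r)
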