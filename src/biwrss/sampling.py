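"""Samplers and sample containers for SRS and ranked-set sampling (RSS).

Simple random samples are drawn by inverse transform on the three latent
inverse Weibull lifetimes: with U ~ Uniform(0, 1),

    Z_k = (-lam_k / ln U_k) ** (1 / alpha) ~ IW(alpha, lam_k),

and X = max(Z1, Z3), Y = max(Z2, Z3).  Ties X = Y arise exactly (both equal
Z3 in floating point) whenever the shock dominates both components, so event
indicators are computed by literal equality.

A ranked-set sample of set size m and r cycles draws m*m pairs per cycle,
partitions them into m sets of m, ranks each set by the X coordinate, and
keeps the i-th order statistic of set i together with its concomitant Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import BIWParams

__all__ = [
    "SRSSample",
    "RSSSample",
    "compute_indicators",
    "draw_srs",
    "draw_rss",
    "write_sample_csv",
    "read_sample_csv",
]


def compute_indicators(x, y):
    """Event indicators (delta1, delta2, delta3) for x<y, x>y, x==y.

    Exactly one indicator is 1 per pair.  For simulated data the tie branch
    fires on exact floating-point equality (both coordinates equal the shock
    draw by construction); ingested real data use exact equality as well.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("coordinates must be strictly positive")
    d1 = (x < y).astype(np.int8)
    d2 = (x > y).astype(np.int8)
    d3 = (x == y).astype(np.int8)
    return d1, d2, d3


@dataclass
class SRSSample:
    """A bivariate simple random sample with event indicators."""

    x: np.ndarray
    y: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    delta3: np.ndarray

    @classmethod
    def from_xy(cls, x, y) -> "SRSSample":
        d1, d2, d3 = compute_indicators(x, y)
        return cls(np.asarray(x, float), np.asarray(y, float), d1, d2, d3)

    def __post_init__(self):
        n = len(self.x)
        for arr in (self.y, self.delta1, self.delta2, self.delta3):
            if len(arr) != n:
                raise ValueError("all component arrays must share one length")
        if np.any(self.delta1 + self.delta2 + self.delta3 != 1):
            raise ValueError("exactly one indicator must be 1 per observation")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n1(self) -> int:
        return int(self.delta1.sum())

    @property
    def n2(self) -> int:
        return int(self.delta2.sum())

    @property
    def n3(self) -> int:
        return int(self.delta3.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n),
                "x": self.x,
                "y": self.y,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "delta3": self.delta3,
            }
        )


@dataclass
class RSSSample:
    """A balanced ranked-set sample; observation (i, j) is the i-th ranked X
    of its size-m set in cycle j, with its concomitant Y."""

    x: np.ndarray
    y: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    delta3: np.ndarray
    rank: np.ndarray  # 1-based rank i within the cycle
    cycle: np.ndarray  # 1-based cycle j
    m: int
    r: int

    def __post_init__(self):
        if len(self.x) != self.m * self.r:
            raise ValueError("RSS sample must contain m*r observations")
        if np.any(self.delta1 + self.delta2 + self.delta3 != 1):
            raise ValueError("exactly one indicator must be 1 per observation")
        if np.any((self.rank < 1) | (self.rank > self.m)):
            raise ValueError("ranks must lie in 1..m")

    @property
    def n(self) -> int:
        return self.m * self.r

    @property
    def n1(self) -> int:
        return int(self.delta1.sum())

    @property
    def n2(self) -> int:
        return int(self.delta2.sum())

    @property
    def n3(self) -> int:
        return int(self.delta3.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "rank": self.rank,
                "x": self.x,
                "y": self.y,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "delta3": self.delta3,
            }
        )


def _latent_iw(u, alpha, lam):
    # inverse transform; lam == 0 degenerates to 0 (never wins a max)
    if lam == 0.0:
        return np.zeros_like(u)
    return (-lam / np.log(u)) ** (1.0 / alpha)


def draw_xy(params: BIWParams, size, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw raw (X, Y) arrays of the given shape from the BIW model."""
    u = rng.random(size=(3,) + tuple(np.atleast_1d(size)))
    z1 = _latent_iw(u[0], params.alpha, params.lam1)
    z2 = _latent_iw(u[1], params.alpha, params.lam2)
    z3 = _latent_iw(u[2], params.alpha, params.lam3)
    return np.maximum(z1, z3), np.maximum(z2, z3)


def draw_srs(params: BIWParams, n: int, seed=None) -> SRSSample:
    """Draw a simple random sample of n pairs from BIW(params)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x, y = draw_xy(params, n, rng)
    return SRSSample.from_xy(x, y)


def draw_rss(params: BIWParams, m: int, r: int, seed=None) -> RSSSample:
    """Draw a ranked-set sample of set size m and r cycles from BIW(params)."""
    if m < 1 or r < 1:
        raise ValueError("m and r must be >= 1")
    rng = np.random.default_rng(seed)
    # (r, m, m): cycle, set, unit-within-set
    x, y = draw_xy(params, (r, m, m), rng)
    order = np.argsort(x, axis=-1, kind="stable")  # ties by draw order
    xs = np.take_along_axis(x, order, axis=-1)
    ys = np.take_along_axis(y, order, axis=-1)
    # from set i (0-based) keep the i-th order statistic and its concomitant
    idx = np.arange(m)
    xk = xs[:, idx, idx].ravel()
    yk = ys[:, idx, idx].ravel()
    rank = np.tile(idx + 1, r)
    cycle = np.repeat(np.arange(1, r + 1), m)
    d1, d2, d3 = compute_indicators(xk, yk)
    return RSSSample(xk, yk, d1, d2, d3, rank, cycle, m=m, r=r)


def write_sample_csv(sample, path) -> None:
    """Write a sample to CSV (UTF-8, '.' decimal, header mandatory)."""
    # default float formatting is shortest-round-trip repr; parse with
    # round_trip precision on the way back so values survive exactly
    sample.to_frame().to_csv(path, index=False)


def read_sample_csv(path):
    """Read a sample CSV written by :func:`write_sample_csv`.

    Returns an :class:`RSSSample` if the file has cycle/rank columns,
    otherwise an :class:`SRSSample`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if {"cycle", "rank"}.issubset(df.columns):
        m = int(df["rank"].max())
        r = int(df["cycle"].max())
        d1, d2, d3 = compute_indicators(df["x"].to_numpy(), df["y"].to_numpy())
        return RSSSample(
            df["x"].to_numpy(float), df["y"].to_numpy(float), d1, d2, d3,
            df["rank"].to_numpy(int), df["cycle"].to_numpy(int), m=m, r=r,
        )
    return SRSSample.from_xy(df["x"].to_numpy(float), df["y"].to_numpy(float))
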