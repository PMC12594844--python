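"""Parameter container for the Marshall-Olkin bivariate inverse Weibull model."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BIWParams"]


@dataclass(frozen=True)
class BIWParams:
    """Parameters of the BIW(alpha, lam1, lam2, lam3) distribution.

    The model is built from three independent inverse Weibull latent lifetimes
    U_k ~ IW(alpha, lam_k) via X = max(U1, U3), Y = max(U2, U3); lam3 is the
    common-shock rate that induces dependence and a positive-probability
    diagonal {X = Y}.

    Parameters
    ----------
    alpha : float
        Common shape parameter, > 0.
    lam1, lam2 : float
        Component rates, > 0.
    lam3 : float
        Common-shock rate, > 0; lam3 = 0 is accepted as the explicit
        independence limit (no diagonal mass).
    """

    alpha: float
    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self) -> None:
        for name in ("alpha", "lam1", "lam2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.lam3) or self.lam3 < 0:
            raise ValueError(f"lam3 must be >= 0, got {self.lam3!r}")

    @property
    def lam13(self) -> float:
        return self.lam1 + self.lam3

    @property
    def lam23(self) -> float:
        return self.lam2 + self.lam3

    @property
    def lam123(self) -> float:
        return self.lam1 + self.lam2 + self.lam3

    def as_array(self) -> np.ndarray:
        """Return (alpha, lam1, lam2, lam3) as a float array."""
        return np.array([self.alpha, self.lam1, self.lam2, self.lam3], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "BIWParams":
        a, l1, l2, l3 = np.asarray(theta, dtype=float)
        return cls(a, l1, l2, l3)
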