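"""One-dimensional sampling laws used by the conformation generator.

A law is a point mass, a Gaussian or a uniform distribution, with optional
hard support bounds enforced by rejection. Laws are the generative stand-ins
for the empirically observed distributions of antibody domain distances and
angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class Law:
    """A 1-D sampling law: ``delta``, ``gaussian`` or ``uniform``.

    Parameters
    ----------
    kind : {"delta", "gaussian", "uniform"}
    loc : float
        Point mass (delta), mean (gaussian) or lower bound (uniform).
    scale : float
        Unused for delta; standard deviation (gaussian) or width (uniform).
    lo, hi : float, optional
        Hard support bounds enforced by rejection sampling.
    """

    kind: str
    loc: float
    scale: float = 0.0
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.kind not in ("delta", "gaussian", "uniform"):
            raise ValueError(f"unknown law kind {self.kind!r}")
        if self.kind != "delta" and self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.lo is not None and self.hi is not None and self.lo >= self.hi:
            raise ValueError("empty support: lo >= hi")

    def _raw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "delta":
            return np.full(size, self.loc, dtype=float)
        if self.kind == "gaussian":
            return rng.normal(self.loc, self.scale, size)
        return rng.uniform(self.loc, self.loc + self.scale, size)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw samples; scalars when ``size`` is None."""
        n = 1 if size is None else int(size)
        out = np.empty(n, dtype=float)
        filled = 0
        for _ in range(_MAX_REJECTION_ROUNDS):
            draw = self._raw(rng, n - filled)
            if self.lo is not None:
                draw = draw[draw >= self.lo]
            if self.hi is not None:
                draw = draw[draw <= self.hi]
            out[filled : filled + draw.size] = draw
            filled += draw.size
            if filled == n:
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed: law {self} is inconsistent with "
                f"its support bounds"
            )
        return out[0] if size is None else out

    def mean(self) -> float:
        if self.kind == "uniform":
            return self.loc + 0.5 * self.scale
        return self.loc


def delta(value: float) -> Law:
    return Law("delta", float(value))


def gaussian(mean: float, sd: float, lo: float | None = None,
             hi: float | None = None) -> Law:
    return Law("gaussian", float(mean), float(sd), lo, hi)


def uniform(lo: float, hi: float) -> Law:
    if hi <= lo:
        raise ValueError("uniform law needs hi > lo")
    return Law("uniform", float(lo), float(hi - lo))


# kept around for callers that want a quick fit-free sanity check
def law_sd(law: Law) -> float:
    if law.kind == "delta":
        return 0.0
    if law.kind == "gaussian":
        return law.scale
    return law.scale / np.sqrt(12.0)


__all__ = ["Law", "delta", "gaussian", "uniform", "law_sd"]
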