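"""Scalar physicochemical summaries of a vesicle size distribution.

Dynamic light scattering instruments report a particle-size distribution;
the polydispersity index PDI = (sigma / d)^2 — the squared coefficient of
variation of particle diameter — summarises its heterogeneity (PDI near 0:
monodisperse; PDI above ~0.3: heterogeneous, typical of extracellular
vesicle preparations). Zeta-potential values are instrument-derived and are
carried through unmodified; no electrophoretic-mobility model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SizeDistribution", "compute_pdi", "summarize_sizes"]


@dataclass(frozen=True)
class SizeDistribution:
    """A particle-size distribution, as raw diameters or a (sigma, d) summary.

    Parameters
    ----------
    diameters
        Individual particle diameters in nm (all > 0), or None when only
        the summary pair is available.
    sigma
        Standard deviation of the diameter distribution in nm.
    d
        Mean particle diameter in nm (> 0).

    Exactly one of ``diameters`` or the ``(sigma, d)`` pair must be given.
    When raw diameters are supplied, ``sigma`` is the sample standard
    deviation (n-1 denominator) and ``d`` the arithmetic mean.
    """

    diameters: tuple[float, ...] | None = None
    sigma: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        if self.diameters is not None:
            if self.sigma is not None or self.d is not None:
                raise ValueError("give raw diameters or (sigma, d), not both")
            arr = np.asarray(self.diameters, dtype=float)
            if arr.size == 0:
                raise ValueError("empty diameter list")
            if np.any(arr <= 0):
                raise ValueError("all diameters must be positive")
        else:
            if self.sigma is None or self.d is None:
                raise ValueError("need either diameters or both sigma and d")
            if self.sigma < 0:
                raise ValueError("sigma must be non-negative")
            if self.d <= 0:
                raise ValueError("mean diameter d must be positive")

    def moments(self) -> tuple[float, float]:
        """Return (sigma, d); computed from raw diameters when present."""
        if self.diameters is not None:
            arr = np.asarray(self.diameters, dtype=float)
            sigma = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            return sigma, float(arr.mean())
        return float(self.sigma), float(self.d)  # type: ignore[arg-type]


def compute_pdi(dist: SizeDistribution) -> float:
    """Polydispersity index (sigma / d)^2 of a size distribution.

    Scale-invariant: rescaling every diameter by c > 0 leaves the PDI
    unchanged. Always >= 0.
    """
    sigma, d = dist.moments()
    if d <= 0:
        raise ValueError("mean diameter must be positive")
    return (sigma / d) ** 2


def summarize_sizes(dist: SizeDistribution) -> dict[str, float]:
    """Mean, sample SD, min and max diameter (nm) of raw size data."""
    if dist.diameters is None:
        raise ValueError("summarize_sizes requires raw diameters")
    arr = np.asarray(dist.diameters, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "mean_nm": float(arr.mean()),
        "sd_nm": sd,
        "min_nm": float(arr.min()),
        "max_nm": float(arr.max()),
        "n": int(arr.size),
    }
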