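"""Quenching models and shared data types.

Two forward models are implemented on the ``I0/I`` ratio scale:

* :func:`sv_ratio` — collisional quenching of a fully exposed fluorophore,
  ``I0/I = 1 + Kq*[Q]``.
* :func:`orientation_ratio` — a two-population mixture in which a fraction
  ``x`` of fluorophores is shielded from the quencher (inside vesicles) and
  the remainder ``1 - x`` is exposed,
  ``I0/I = (1 + Kq*[Q]) / ((1 + Kq*[Q])*x + 1 - x)``.

Both are pure functions of molar quencher concentration; no I/O or fitting
happens at this layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Condition",
    "QuenchParams",
    "TitrationSeries",
    "sv_ratio",
    "orientation_ratio",
    "invert_point",
]

#: Lipid species supported by the condition metadata.
LIPIDS = ("POPC", "POPG", "DOPC")


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata for one reconstitution.

    Parameters
    ----------
    lipid
        Vesicle lipid species, one of ``POPC``, ``POPG``, ``DOPC``.
    ionic_strength
        Buffer ionic strength in mM.
    ph
        Buffer pH.
    vesicle_diameter
        Nominal vesicle diameter in nm.
    """

    lipid: str
    ionic_strength: float
    ph: float
    vesicle_diameter: float

    def __post_init__(self) -> None:
        if self.lipid not in LIPIDS:
            raise ValueError(f"unknown lipid {self.lipid!r}; expected one of {LIPIDS}")
        if not 0.0 < self.ph < 14.0:
            raise ValueError(f"pH must lie in (0, 14), got {self.ph}")
        if self.vesicle_diameter <= 0:
            raise ValueError("vesicle_diameter must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")

    def label(self) -> str:
        return (
            f"{self.lipid} {self.ionic_strength:g}mM "
            f"pH{self.ph:g} {self.vesicle_diameter:g}nm"
        )


@dataclass(frozen=True)
class QuenchParams:
    """Parameter pair of the two-population quenching model.

    ``Kq`` is the Stern-Volmer quenching constant in M^-1; ``x`` is the
    protected (inward-facing) fraction, dimensionless in [0, 1].
    """

    Kq: float
    x: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Kq) and self.Kq > 0):
            raise ValueError(f"Kq must be finite and positive, got {self.Kq}")
        if not (math.isfinite(self.x) and 0.0 <= self.x <= 1.0):
            raise ValueError(f"x must lie in [0, 1], got {self.x}")


@dataclass
class TitrationSeries:
    """One quenching titration: ordered (quencher concentration, intensity) pairs.

    A zero-quencher point is required; its intensity defines the unquenched
    baseline ``I0``. Concentrations are molar, intensities arbitrary units.
    """

    sample_id: str
    points: Sequence[Tuple[float, float]]
    condition: Optional[Condition] = None

    _Q: np.ndarray = field(init=False, repr=False)
    _I: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = list(self.points)
        if not pts:
            raise ValueError("titration series has no points")
        Q = np.asarray([p[0] for p in pts], dtype=float)
        I = np.asarray([p[1] for p in pts], dtype=float)
        if not np.all(np.isfinite(Q)) or not np.all(np.isfinite(I)):
            raise ValueError("non-finite concentration or intensity")
        if np.any(Q < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if np.any(I <= 0):
            raise ValueError("intensities must be strictly positive")
        if np.unique(Q).size != Q.size:
            raise ValueError("duplicate quencher concentrations in series")
        if not np.any(Q == 0.0):
            raise ValueError("no zero-quencher baseline (a [Q] = 0 row is required)")
        order = np.argsort(Q)
        self.points = [(float(Q[i]), float(I[i])) for i in order]
        self._Q = Q[order]
        self._I = I[order]

    @property
    def Q(self) -> np.ndarray:
        """Sorted quencher concentrations (M)."""
        return self._Q

    @property
    def intensity(self) -> np.ndarray:
        """Intensities ordered to match :attr:`Q`."""
        return self._I

    @property
    def I0(self) -> float:
        """Unquenched intensity, taken from the [Q] = 0 point."""
        return float(self._I[0])

    @property
    def ratio(self) -> np.ndarray:
        """Observed ``I0/I`` at each concentration."""
        return self.I0 / self._I

    @property
    def n_points(self) -> int:
        return int(self._Q.size)

    def nonzero(self) -> Tuple[np.ndarray, np.ndarray]:
        """(Q, I0/I) restricted to the nonzero-quencher points."""
        mask = self._Q > 0
        return self._Q[mask], self.ratio[mask]


def _check_kq_q(Kq: float, Q) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if not (np.isfinite(Kq) and Kq > 0):
        raise ValueError(f"Kq must be finite and positive, got {Kq}")
    if not np.all(np.isfinite(Q)) or np.any(Q < 0):
        raise ValueError("quencher concentration must be finite and non-negative")
    return Q


def sv_ratio(Kq: float, Q):
    """Stern-Volmer ratio ``I0/I = 1 + Kq*Q`` for a fully exposed fluorophore.

    Parameters
    ----------
    Kq
        Quenching constant (M^-1), > 0.
    Q
        Quencher concentration (M), scalar or array, >= 0.
    """
    Qa = _check_kq_q(Kq, Q)
    out = 1.0 + Kq * Qa
    return out if out.ndim else float(out)


def orientation_ratio(params: QuenchParams, Q):
    """Mixture-model ratio ``I0/I`` with a protected fraction ``params.x``.

    Reduces to :func:`sv_ratio` at ``x = 0`` and to 1 at ``x = 1``; the value
    always lies in ``[1, 1 + Kq*Q]`` and decreases monotonically in ``x``.
    """
    Qa = _check_kq_q(params.Kq, Q)
    s = 1.0 + params.Kq * Qa
    out = s / (s * params.x + 1.0 - params.x)
    return out if out.ndim else float(out)


def invert_point(Kq: float, Q: float, ratio: float) -> float:
    """Solve the mixture model for ``x`` from a single (Q, I0/I) observation.

    Exact inverse of :func:`orientation_ratio` on noise-free input. The result
    is returned *unclipped*: on noisy data it may fall outside [0, 1], which
    callers use as a diagnostic.

    Raises
    ------
    ValueError
        If ``Q == 0`` (x is not identifiable without quencher) or inputs are
        invalid.
    """
    Qa = _check_kq_q(Kq, Q)
    if float(Qa) == 0.0:
        raise ValueError("x is not identifiable at zero quencher concentration")
    # tolerate rounding just below 1 from computed ratios
    if not (math.isfinite(ratio) and ratio >= 1.0 - 1e-9):
        raise ValueError(f"ratio must be finite and >= 1, got {ratio}")
    s = 1.0 + Kq * float(Qa)
    return (s / ratio - 1.0) / (Kq * float(Qa))
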