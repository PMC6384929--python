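"""Seeded generators for synthetic quenching titrations.

Titrations follow the same forward models the fitters assume: a quencher-only
calibration series (pure Stern-Volmer decay) and a vesicle series in which a
fraction ``x_true`` of fluorophores is shielded from the quencher. Intensity
noise is multiplicative log-normal, parametrised by its coefficient of
variation and mean-one so the noise-free curve is the expectation. Every
generator takes an explicit seed; no module-level random state exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import Condition, QuenchParams, TitrationSeries, orientation_ratio, sv_ratio
from .study import Preset

__all__ = [
    "SyntheticSpec",
    "generate_calibration_series",
    "generate_orientation_series",
    "generate_study",
    "generate_three_state_series",
]

DEFAULT_N_POINTS = 11
DEFAULT_Q_MAX = 1e-6  # M; Kq*Q spans 0..10 at Kq = 1e7 M^-1
DEFAULT_I0 = 1000.0  # a.u.

#: Relative quenchability of the third ("buried probe") state.
BURIED_ACCESSIBILITY = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for one synthetic titration series.

    ``x_true`` must be None for a calibration (no-vesicle) series and set for
    an orientation series. ``noise_cv`` is the coefficient of variation of
    the multiplicative log-normal intensity noise.
    """

    Kq_true: float
    x_true: Optional[float] = None
    n_points: int = DEFAULT_N_POINTS
    Q_max: float = DEFAULT_Q_MAX
    noise_cv: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    I0_true: float = DEFAULT_I0

    def __post_init__(self) -> None:
        if self.Kq_true <= 0:
            raise ValueError("Kq_true must be positive")
        if self.n_points < 3:
            raise ValueError("need at least 3 titration points")
        if self.Q_max <= 0:
            raise ValueError("Q_max must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.I0_true <= 0:
            raise ValueError("I0_true must be positive")
        if self.x_true is not None and not 0.0 <= self.x_true <= 1.0:
            raise ValueError("x_true must lie in [0, 1]")


def _design(spec: SyntheticSpec) -> np.ndarray:
    return np.linspace(0.0, spec.Q_max, spec.n_points)


def _noise_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _series_from_ideal(
    sample_id: str,
    Q: np.ndarray,
    ideal: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    condition: Optional[Condition] = None,
) -> TitrationSeries:
    # the zero-quencher baseline is the reference measurement and stays
    # noise-free; otherwise its error is shared by every I0/I ratio and the
    # per-point resampling bootstrap cannot see it
    factors = _noise_factors(Q.size, spec.noise_cv, rng)
    factors[Q == 0.0] = 1.0
    I = ideal * factors
    return TitrationSeries(
        sample_id=sample_id,
        points=list(zip(Q.tolist(), I.tolist())),
        condition=condition,
    )


def generate_calibration_series(spec: SyntheticSpec, sample_id: str = "calibration") -> TitrationSeries:
    """Quencher-only series: ``I = I0 / (1 + Kq*Q)`` times noise."""
    if spec.x_true is not None:
        raise ValueError("calibration series must not carry x_true")
    rng = np.random.default_rng(spec.seed)
    Q = _design(spec)
    ideal = spec.I0_true / sv_ratio(spec.Kq_true, Q)
    return _series_from_ideal(sample_id, Q, ideal, spec, rng)


def generate_orientation_series(
    spec: SyntheticSpec,
    sample_id: str = "orientation",
    condition: Optional[Condition] = None,
) -> TitrationSeries:
    """Vesicle series with protected fraction ``x_true``."""
    if spec.x_true is None:
        raise ValueError("orientation series requires x_true")
    rng = np.random.default_rng(spec.seed)
    Q = _design(spec)
    params = QuenchParams(Kq=spec.Kq_true, x=spec.x_true)
    ideal = spec.I0_true / orientation_ratio(params, Q)
    return _series_from_ideal(sample_id, Q, ideal, spec, rng, condition)


def generate_study(
    presets: Sequence[Preset],
    Kq_true: float,
    noise_cv: float,
    n_replicates: int,
    seed: int,
    n_points: int = DEFAULT_N_POINTS,
    Q_max: float = DEFAULT_Q_MAX,
    I0_true: float = DEFAULT_I0,
) -> List[Tuple[Condition, List[TitrationSeries]]]:
    """Replicated orientation series for every available preset.

    Per-replicate seeds are spawned deterministically from the master seed
    via ``numpy.random.SeedSequence`` keyed by (condition index, replicate
    index), so adding conditions or replicates never perturbs earlier series.
    """
    if not presets:
        raise ValueError("no presets supplied")
    out: List[Tuple[Condition, List[TitrationSeries]]] = []
    for ci, preset in enumerate(presets):
        if not preset.available or preset.x_true is None:
            raise ValueError(f"preset {preset.condition.label()} has no reported x")
        reps: List[TitrationSeries] = []
        for ri in range(n_replicates):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ci, ri))
            sub_seed = int(child.generate_state(1)[0])
            spec = SyntheticSpec(
                Kq_true=Kq_true,
                x_true=preset.x_true,
                n_points=n_points,
                Q_max=Q_max,
                noise_cv=noise_cv,
                seed=sub_seed,
                I0_true=I0_true,
            )
            reps.append(
                generate_orientation_series(
                    spec,
                    sample_id=f"{preset.condition.label()} rep{ri + 1}",
                    condition=preset.condition,
                )
            )
        out.append((preset.condition, reps))
    return out


def generate_three_state_series(
    Kq: float,
    f_exposed: float,
    f_protected: float,
    f_buried: float,
    spec: SyntheticSpec,
    sample_id: str = "three-state",
) -> TitrationSeries:
    """Mixture with a third, partially quenchable ("buried probe") state.

    The buried state sees an effective quencher accessibility of
    ``BURIED_ACCESSIBILITY`` (0.5). Reduces to the two-state orientation
    model at ``f_buried = 0`` and to pure Stern-Volmer at ``f_exposed = 1``.
    Used to quantify the bias the two-state fit incurs when the assumption
    of fully-exposed-or-fully-protected probes is violated.
    """
    for name, f in (("f_exposed", f_exposed), ("f_protected", f_protected), ("f_buried", f_buried)):
        if f < 0:
            raise ValueError(f"{name} must be non-negative")
    if abs(f_exposed + f_protected + f_buried - 1.0) > 1e-9:
        raise ValueError("state fractions must sum to 1 (tolerance 1e-9)")
    rng = np.random.default_rng(spec.seed)
    Q = _design(spec)
    rel = (
        f_exposed / (1.0 + Kq * Q)
        + f_protected
        + f_buried / (1.0 + BURIED_ACCESSIBILITY * Kq * Q)
    )
    ideal = spec.I0_true * rel
    return _series_from_ideal(sample_id, Q, ideal, spec, rng)
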