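"""Synthetic bioreactor datasets emulating the low-cell-density AAV6
production culture: five metabolite profiles (glutamine, glutamic acid,
glucose, lactate, ammonium) sampled every 24 h, with heteroscedastic
measurement noise.

The generator exists because the study's raw bioreactor dataset is not
publicly deposited; it produces pseudo-experimental data from the shipped
(or any) parameter set so that the fitting and sensitivity stages can be
exercised and validated end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, ParameterSet
from .simulate import DEFAULT_T_GRID, ObservedProfiles, observe, simulate

__all__ = ["NoiseModel", "SyntheticDataset", "ShapeWarning", "apply_noise",
           "generate", "perturb_parameters"]


class ShapeWarning(UserWarning):
    """Generated profiles do not show the expected culture trends."""


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic Gaussian measurement error.

    Per point the standard deviation is max(relative_sd * value,
    absolute_sd_floor) mM — a relative component typical of enzymatic
    bioanalyzers plus a floor for readings near the detection limit.
    """

    relative_sd: float = 0.05
    absolute_sd_floor: float = 0.02  # mM
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0 or self.absolute_sd_floor < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def sd(self, values: np.ndarray) -> np.ndarray:
        return np.maximum(self.relative_sd * np.abs(values), self.absolute_sd_floor)


@dataclass
class SyntheticDataset:
    """Ground truth plus its clean and noisy observed profiles."""

    truth: ParameterSet
    clean: ObservedProfiles
    noisy: ObservedProfiles
    noise: NoiseModel
    provenance: dict = field(default_factory=dict)


# trends a healthy batch culture shows over the sampled horizon
_EXPECTED_TRENDS = {"Glc": -1, "Gln": -1, "Lac": +1, "NH4": +1}


def apply_noise(
    values: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Add heteroscedastic Gaussian noise, truncating at 0."""
    eps = rng.normal(0.0, 1.0, size=values.shape) * noise.sd(values)
    return np.maximum(values + eps, 0.0)


def generate(
    model: MetabolicModel,
    truth_params: ParameterSet | None = None,
    t_grid: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    check_shape: bool = True,
) -> SyntheticDataset:
    """Simulate a culture and add seeded measurement noise.

    Noisy values are the clean profiles plus N(0, sd^2) draws truncated at
    0 (concentrations are nonnegative measurements).  With the shipped
    parameters the generated glucose/glutamine profiles are expected to be
    non-increasing and lactate/ammonium non-decreasing; a deviation is an
    empirical property of the parameter set and raises a ShapeWarning
    rather than an error.
    """
    if truth_params is None:
        truth_params = model.parameter_set()
    t = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)

    clean = observe(simulate(model, truth_params, t), order=model.observation_order)
    if check_shape:
        tol = 1e-9
        for sp, sign in _EXPECTED_TRENDS.items():
            if sp not in clean.species:
                continue
            d = np.diff(clean.column(sp)) * sign
            if np.any(d < -tol):
                warnings.warn(
                    f"{sp} profile is not "
                    f"{'non-increasing' if sign < 0 else 'non-decreasing'} "
                    "under the supplied parameters",
                    ShapeWarning,
                    stacklevel=2,
                )

    rng = np.random.default_rng(noise.seed)
    noisy_values = apply_noise(clean.values, noise, rng)
    noisy = ObservedProfiles(t.copy(), noisy_values, list(clean.species))
    return SyntheticDataset(
        truth=truth_params,
        clean=clean,
        noisy=noisy,
        noise=noise,
        provenance={"seed": noise.seed, "model": model.name},
    )


def perturb_parameters(
    truth: ParameterSet,
    subset: list[str],
    multiplier_range: tuple[float, float],
    seed: int = 0,
) -> ParameterSet:
    """Multiply selected parameters by seeded random factors in a range.

    Drives parameter-recovery experiments: perturb a subset, refit, and
    compare against the generating values.
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    lo, hi = multiplier_range
    if lo <= 0 or hi < lo:
        raise ValueError("multiplier range must be positive with lo <= hi")
    unknown = [n for n in subset if n not in truth]
    if unknown:
        raise KeyError(f"unknown parameter(s): {unknown}")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(lo, hi, size=len(subset))
    return truth.updated({n: truth[n] * f for n, f in zip(subset, factors)})
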