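"""Synthetic data with known ground truth for every pipeline stage.

Generates (i) two-dye emission spectra whose per-dye intensities decline
linearly with temperature at the experimentally measured sensitivities,
(ii) calibration series of such spectra over a temperature ramp, and
(iii) labeled/control fish cohorts governed by a latent lineage simplex plus
independent background labeling, with over-dispersed (decidedly non-normal)
GFP⁺ cell counts.

Every generator is a pure function of (config, seed): identical inputs give
bitwise-identical outputs.  Cohort tables carry the latent lineage as a
``lineage_truth`` column for validation only — estimation code must never
read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .thermometry import EmissionSpectrum

__all__ = [
    "SpectraGenConfig",
    "CohortGenConfig",
    "CountModel",
    "LINEAGE_CLASSES",
    "generate_basis_spectra",
    "generate_mixture_spectrum",
    "generate_calibration_series",
    "generate_cohort",
]

#: lineage classes of a labeled hemogenic endothelial cell, in simplex order:
#: bipotent (T + myeloid), myeloid-only, T-only, no traced progeny
LINEAGE_CLASSES = ("TM", "M", "T", "none")


def _default_grid() -> np.ndarray:
    return np.arange(470.0, 660.0 + 0.5, 1.0)


@dataclass(frozen=True)
class SpectraGenConfig:
    """Parameters of the two-dye spectrum generator.

    The per-dye sensitivities default to the values measured in pure dye
    solutions: −0.882 %/°C for TAMRA (the probe) and −0.165 %/°C for FITC
    (the reference).  Peak positions and widths are synthetic placeholders
    chosen for unmixing identifiability, not measured emission shapes.
    """

    peak_center_fitc: float = 519.0   # nm
    peak_center_tamra: float = 580.0  # nm
    peak_width_fitc: float = 15.0     # nm, Gaussian sd
    peak_width_tamra: float = 15.0    # nm, Gaussian sd
    sens_fitc: float = -0.00165       # fraction per °C
    sens_tamra: float = -0.00882      # fraction per °C
    ref_temperature: float = 23.0     # °C
    noise_cv: float = 0.01
    wavelength_grid: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid, dtype=float)
        if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if self.peak_width_fitc <= 0 or self.peak_width_tamra <= 0:
            raise ValueError("peak widths must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if abs(self.sens_fitc) >= 0.05 or abs(self.sens_tamra) >= 0.05:
            raise ValueError("per-dye sensitivities above 5 %/°C are not physical here")
        object.__setattr__(self, "wavelength_grid", grid)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelength_grid"] = [float(w) for w in self.wavelength_grid]
        return d


@dataclass(frozen=True)
class CountModel:
    """Shifted negative-binomial model for GFP⁺ cell counts in a positive channel.

    A positive channel draws ``1 + NB`` so counts are always ≥ 1; ``mean`` is
    the mean of the full shifted count and ``dispersion`` the NB size
    parameter (smaller → more over-dispersed, hence non-normal).
    """

    mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ValueError("positive-channel count mean must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu = self.mean - 1.0
        if mu <= 0:
            return np.ones(size, dtype=int)
        k = self.dispersion
        p = k / (k + mu)
        return 1 + rng.negative_binomial(k, p, size=size)


@dataclass(frozen=True)
class CohortGenConfig:
    """Parameters of the labeled/control cohort generator.

    ``theta`` is the lineage simplex over ``LINEAGE_CLASSES``; ``beta_t`` and
    ``beta_m`` are the probabilities that spontaneous (background) heat-shock
    promoter activation produces GFP⁺ cells in the T and myeloid channels of
    any fish, independent of lineage and of each other.
    """

    theta: tuple[float, float, float, float] = (0.4379, 0.2841, 0.0, 0.2780)
    beta_t: float = 0.03
    beta_m: float = 0.08
    n_labeled: int = 27
    n_control: int = 109
    lineage_counts: CountModel = field(default_factory=lambda: CountModel(20.0, 1.0))
    background_counts: CountModel = field(default_factory=lambda: CountModel(2.0, 1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (4,):
            raise ValueError("theta must have 4 entries (TM, M, T, none)")
        if np.any(th < 0) or abs(th.sum() - 1.0) > 1e-12:
            raise ValueError("theta must be nonnegative and sum to 1 (tol 1e-12)")
        for b in (self.beta_t, self.beta_m):
            if not 0.0 <= b <= 1.0:
                raise ValueError("background rates must lie in [0, 1]")
        if self.n_labeled < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be nonnegative")
        object.__setattr__(self, "theta", tuple(float(t) for t in th))

    def to_dict(self) -> dict:
        return {
            "theta": list(self.theta),
            "beta_t": self.beta_t,
            "beta_m": self.beta_m,
            "n_labeled": self.n_labeled,
            "n_control": self.n_control,
            "lineage_counts": asdict(self.lineage_counts),
            "background_counts": asdict(self.background_counts),
            "seed": self.seed,
        }


def _gaussian(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def generate_basis_spectra(
    config: SpectraGenConfig,
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Noise-free unit-area pure-dye basis spectra on the config grid.

    Returns (FITC basis, TAMRA basis).  Deterministic: basis spectra carry no
    noise by construction.  Peaks closer than 1 nm are rejected because the
    two-column unmixing design would be unidentifiable.
    """
    if abs(config.peak_center_fitc - config.peak_center_tamra) < 1.0:
        raise ValueError("dye peaks closer than 1 nm make unmixing unidentifiable")
    grid = config.wavelength_grid
    fitc = _gaussian(grid, config.peak_center_fitc, config.peak_width_fitc)
    tamra = _gaussian(grid, config.peak_center_tamra, config.peak_width_tamra)
    fitc /= np.trapezoid(fitc, grid)
    tamra /= np.trapezoid(tamra, grid)
    return (
        EmissionSpectrum(grid, fitc, label="FITC basis"),
        EmissionSpectrum(grid, tamra, label="TAMRA basis"),
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_mixture_spectrum(
    a_fitc: float,
    a_tamra: float,
    temperature: float,
    config: SpectraGenConfig,
    rng: np.random.Generator | None = None,
) -> EmissionSpectrum:
    """A two-dye mixture spectrum at the given temperature.

    Each dye's contribution scales linearly with temperature::

        S = a_f·(1 + s_FITC·(T − T_ref))·B_FITC
          + a_t·(1 + s_TAMRA·(T − T_ref))·B_TAMRA

    then every wavelength bin is multiplied by independent lognormal noise of
    coefficient of variation ``noise_cv`` (unit mean, so the expected
    spectrum is the noiseless one).  With ``rng=None`` a generator seeded
    from ``config.seed`` is used, so repeated calls with the same config are
    identical; pass an explicit ``rng`` to draw a sequence of noisy replicates.
    """
    if a_fitc < 0 or a_tamra < 0:
        raise ValueError("mixing coefficients must be nonnegative")
    if not 0.0 <= temperature <= 100.0:
        raise ValueError("temperature outside [0, 100] °C")
    fitc, tamra = generate_basis_spectra(config)
    dt = temperature - config.ref_temperature
    scale_f = a_fitc * (1.0 + config.sens_fitc * dt)
    scale_t = a_tamra * (1.0 + config.sens_tamra * dt)
    if scale_f < 0 or scale_t < 0:
        raise ValueError("linear intensity model went negative at this temperature")
    intens = scale_f * fitc.intensities + scale_t * tamra.intensities
    if rng is None:
        rng = np.random.default_rng(config.seed)
    intens = intens * _lognormal_noise(rng, config.noise_cv, intens.size)
    return EmissionSpectrum(
        config.wavelength_grid,
        intens,
        label=f"mixture a_f={a_fitc:g} a_t={a_tamra:g} T={temperature:g}C",
    )


def generate_calibration_series(
    temperatures: Sequence[float],
    replicates: int,
    config: SpectraGenConfig,
    a_fitc: float = 1.0,
    a_tamra: float = 1.0,
) -> list[tuple[float, EmissionSpectrum]]:
    """Spectra over a temperature ramp at fixed mixing coefficients.

    Returns ``replicates × len(temperatures)`` pairs of (true temperature,
    spectrum), reproducible from ``config.seed``.  Requires at least two
    distinct temperatures — a calibration line cannot be fit otherwise.
    """
    temps = [float(t) for t in temperatures]
    if len(temps) == 0:
        raise ValueError("empty temperature list")
    if len(set(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures for a calibration series")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    out: list[tuple[float, EmissionSpectrum]] = []
    for rep in range(replicates):
        for t in temps:
            out.append((t, generate_mixture_spectrum(a_fitc, a_tamra, t, config, rng=rng)))
    return out


# observed 2x2 category implied by each lineage class, order (T+, M+)
_LINEAGE_IMPLIES = {
    "TM": (True, True),
    "M": (False, True),
    "T": (True, False),
    "none": (False, False),
}


def generate_cohort(config: CohortGenConfig) -> pd.DataFrame:
    """Simulate a labeled cohort and an unheated control cohort.

    Each labeled fish draws a latent lineage class from ``theta``; a channel
    is GFP⁺ iff the lineage implies it OR an independent background
    Bernoulli(β) fires.  Control fish have no lineage and show background
    positivity only.  Positive channels draw counts ≥ 1 from the
    lineage-driven or background count model (lineage takes precedence when
    both fire); negative channels have count 0.

    Returns a DataFrame with columns ``id, group, t_count, m_count,
    lineage_truth`` — the last is hidden ground truth for validation only
    and is ``NA`` for controls.
    """
    rng = np.random.default_rng(config.seed)
    n_lab, n_ctl = config.n_labeled, config.n_control

    lineage_idx = rng.choice(4, size=n_lab, p=np.asarray(config.theta))
    implies = np.array([_LINEAGE_IMPLIES[c] for c in LINEAGE_CLASSES], dtype=bool)
    lin_t = implies[lineage_idx, 0]
    lin_m = implies[lineage_idx, 1]
    bg_t = rng.random(n_lab + n_ctl) < config.beta_t
    bg_m = rng.random(n_lab + n_ctl) < config.beta_m

    lineage_pos_t = np.concatenate([lin_t, np.zeros(n_ctl, dtype=bool)])
    lineage_pos_m = np.concatenate([lin_m, np.zeros(n_ctl, dtype=bool)])

    def channel_counts(lineage_pos: np.ndarray, background_pos: np.ndarray) -> np.ndarray:
        counts = np.zeros(lineage_pos.size, dtype=int)
        # lineage takes precedence over background when both fire
        counts[lineage_pos] = config.lineage_counts.sample(rng, int(lineage_pos.sum()))
        bg_only = background_pos & ~lineage_pos
        counts[bg_only] = config.background_counts.sample(rng, int(bg_only.sum()))
        return counts

    t_counts = channel_counts(lineage_pos_t, bg_t)
    m_counts = channel_counts(lineage_pos_m, bg_m)

    ids = [f"labeled_{i:05d}" for i in range(n_lab)] + [
        f"control_{i:05d}" for i in range(n_ctl)
    ]
    groups = ["labeled"] * n_lab + ["control"] * n_ctl
    truth = [LINEAGE_CLASSES[k] for k in lineage_idx] + [pd.NA] * n_ctl
    return pd.DataFrame(
        {
            "id": ids,
            "group": groups,
            "t_count": t_counts,
            "m_count": m_counts,
            "lineage_truth": truth,
        }
    )
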