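"""Synthetic measurement series with the structure of a multi-decade campaign.

The study this package models monitored one site from 1.2 to 37 years after
the deposition event, sampling six 5-cm layers at irregular intervals with
~10% relative standard uncertainty on each mass activity. The raw series is
not public, so this module generates statistically equivalent stand-ins with
known ground truth: propagate the compartment chain to each sampling time,
apply independent multiplicative noise per layer, and (optionally) express
the result either as measurement-like fraction vectors or as raw Bq/kg soil
profiles consumable by :mod:`csmig.profiles` unchanged.

Every stochastic call demands an explicit seed; identical configs give
byte-identical output.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chain import PAPER_INIT, ChainModel, equal_rate_solution, general_chain_solution
from .profiles import (
    CHERNOBYL_DATE,
    CS137_HALF_LIFE_Y,
    DAYS_PER_YEAR,
    FractionVector,
    Layer,
    SoilProfile,
)

__all__ = [
    "SyntheticConfig",
    "default_sample_times",
    "simulate_fraction_series",
    "simulate_profile_series",
]


def default_sample_times(n: int = 24, first: float = 1.2, last: float = 37.0) -> tuple[float, ...]:
    """An irregular (log-spaced) sampling grid emulating the 1987–2023 campaigns.

    The historical campaign dates are not published; a geometric grid over
    [1.2, 37] years reproduces the denser early coverage typical of
    post-accident monitoring. Deterministic by construction.
    """
    if n < 2 or first <= 0 or last <= first:
        raise ValueError("need n >= 2 and 0 < first < last")
    return tuple(float(x) for x in np.geomspace(first, last, n))


@dataclass
class SyntheticConfig:
    """Ground-truth parameters and measurement design for one simulation.

    ``k_true`` may be a single rate (equal-rate chain) or one rate per link.
    ``noise_cv`` is the per-layer relative standard deviation of the
    multiplicative measurement noise (0.10 emulates the reported combined
    standard uncertainty). ``renormalize`` controls whether sampled fraction
    vectors are rescaled to sum 1, as measured ratios are by construction;
    disable it to expose the raw (leaky) model fractions.
    """

    seed: int
    k_true: float | Sequence[float] = 0.024
    init: Sequence[float] = PAPER_INIT
    sample_times: Sequence[float] = field(default_factory=default_sample_times)
    noise_cv: float = 0.10
    noise_model: str = "normal"  # or "lognormal"
    renormalize: bool = True
    density_g_cm3: float = 1.3
    deposition_0_kBq_m2: float = 18.6
    half_life_y: float = CS137_HALF_LIFE_Y
    layer_thickness_cm: float = 5.0
    reference_date: _dt.date = CHERNOBYL_DATE

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("an integer seed is mandatory for any stochastic call")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.noise_model not in ("normal", "lognormal"):
            raise ValueError("noise_model must be 'normal' or 'lognormal'")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size < 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing and positive")
        if self.density_g_cm3 <= 0 or self.deposition_0_kBq_m2 <= 0:
            raise ValueError("density and initial deposition must be positive")

    @property
    def chain(self) -> ChainModel:
        init = FractionVector(0.0, tuple(float(x) for x in self.init))
        if np.ndim(self.k_true) == 0:
            return ChainModel(rates=(float(self.k_true),) * len(init), init=init)
        return ChainModel(rates=tuple(float(k) for k in self.k_true), init=init)

    def propagate(self, t: float) -> FractionVector:
        model = self.chain
        if model.is_uniform:
            return equal_rate_solution(model, t)
        return general_chain_solution(model, t)


def _noise_factors(cfg: SyntheticConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if cfg.noise_cv == 0:
        return np.ones(size)
    if cfg.noise_model == "lognormal":
        sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)
    return np.maximum(0.0, 1.0 + cfg.noise_cv * rng.standard_normal(size))


def simulate_fraction_series(cfg: SyntheticConfig) -> list[FractionVector]:
    """Measurement-like fraction vectors at each sampling time.

    Model fractions are perturbed by independent multiplicative noise per
    layer and, when ``cfg.renormalize`` (the default), rescaled to sum 1 —
    measured fractional contributions are ratios of simultaneously measured
    activities and sum to 1 by construction. With renormalization off the
    noisy raw model fractions are returned (surface entry: 0.71·e^(−kt)
    times its noise factor alone).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[FractionVector] = []
    for t in cfg.sample_times:
        clean = cfg.propagate(float(t)).array
        noisy = clean * _noise_factors(cfg, rng, clean.size)
        if cfg.renormalize:
            s = noisy.sum()
            if s <= 0:
                raise RuntimeError(f"degenerate sample at t={t}: all layers zero after noise")
            noisy = noisy / s
        out.append(FractionVector(float(t), tuple(noisy)))
    return out


def _date_at(cfg: SyntheticConfig, t: float) -> _dt.date:
    return cfg.reference_date + _dt.timedelta(days=round(t * DAYS_PER_YEAR))


def simulate_profile_series(cfg: SyntheticConfig) -> list[SoilProfile]:
    """Raw Bq/kg soil profiles at each sampling time.

    The fraction vectors are scaled so the *backdated* areal deposition of a
    noiseless profile equals ``cfg.deposition_0_kBq_m2``, then decayed
    forward to each sampling date; multiplicative noise is applied at the
    activity level, so reading these profiles back through
    ``fractional_contributions`` reproduces the renormalized noisy ratios.
    """
    rng = np.random.default_rng(cfg.seed)
    loading_kg_m2 = cfg.density_g_cm3 * 1000.0 * (cfg.layer_thickness_cm / 100.0)
    # total summed mass activity at t=0 consistent with the initial inventory,
    # accounting for the init vector's own (printed) sum
    init_sum = float(np.sum(np.asarray(cfg.init, dtype=float)))
    t0_total_bq_kg = cfg.deposition_0_kBq_m2 * 1000.0 / loading_kg_m2
    profiles: list[SoilProfile] = []
    for t_req in cfg.sample_times:
        # snap to the calendar-day grid: a sampling time is a date, and the
        # snapped value is what the profile reader will recover exactly
        t = round(float(t_req) * DAYS_PER_YEAR) / DAYS_PER_YEAR
        clean_frac = cfg.propagate(t).array
        decay = 2.0 ** (-t / cfg.half_life_y)
        activities = t0_total_bq_kg * (clean_frac / init_sum) * decay
        activities = activities * _noise_factors(cfg, rng, activities.size)
        layers = [
            Layer(
                top_cm=i * cfg.layer_thickness_cm,
                bottom_cm=(i + 1) * cfg.layer_thickness_cm,
                activity=float(a),
                rel_sigma=cfg.noise_cv,
            )
            for i, a in enumerate(activities)
        ]
        profiles.append(
            SoilProfile(
                sample_date=_date_at(cfg, float(t)),
                layers=layers,
                density_g_cm3=cfg.density_g_cm3,
                half_life_y=cfg.half_life_y,
                reference_date=cfg.reference_date,
            )
        )
    return profiles
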