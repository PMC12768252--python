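"""Synthetic rupture-time data with the statistical structure of the assay.

The generator emulates the single-vesicle electroporation protocol: vesicles
of 28-32 um diameter are selected, each is put under a target tension by
choosing the field from its measured radius, and it is watched for a 60 s
window at 1 s/frame.  Under the constant-hazard model, the latent rupture
time is exponential with the Arrhenius rate determined by the generating
pore model (fixed edge tension per condition, or the biphasic
Gamma(phi) law across peptide content).  Latent times are then

* censored on the latent value (a rupture just after the window closes is
  never observed), and
* ceil-quantized to the frame grid, as a 1 s/frame camera would record them.

Trials mirror the experimental design: 12-18 vesicles per trial, 2-4
independent trials per condition, both drawn uniformly from their ranges
unless fixed.  Randomness is hierarchical -- each (condition, trial) gets
its own stream spawned from the global seed keyed by condition and trial
index -- so adding a condition leaves existing cells byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .electromechanics import MembraneConstants, field_for_target_tension
from .energetics import (
    DEFAULT_B_N_PER_M,
    BiphasicParams,
    PoreModelParams,
    biphasic_edge_tension,
    rupture_rate,
)
from .survival import VesicleRecord

__all__ = ["ExperimentDesign", "simulate_vesicle", "simulate_condition", "simulate_tension_grid"]

GammaSpec = Union[float, Mapping[float, float], BiphasicParams]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a simulated rupture-kinetics study.

    ``true_gamma`` sets the generating pore-edge tension: a single value in
    N, a mapping from peptide mole percent to Gamma (N), or a
    :class:`BiphasicParams` evaluated at the mole fraction.  ``true_A`` is
    the generating frequency factor (1/s) and ``B`` the electrostatic
    tension component (N/m).  ``n_vesicles_per_trial`` and ``n_trials``
    accept either a fixed count or an inclusive (lo, hi) range sampled per
    trial/condition.  ``tension_jitter_cv`` optionally applies lognormal
    multiplicative noise to the realized tension (coefficient of variation;
    0 disables it), modelling radius-measurement error.
    """

    gra_mole_percents: Sequence[float] = (0.0,)
    sigma_targets: Sequence[float] = (8e-3,)
    true_gamma: GammaSpec = 9.6e-12
    true_A: float = 300.0
    B: float = DEFAULT_B_N_PER_M
    n_vesicles_per_trial: Union[int, tuple[int, int]] = (12, 18)
    n_trials: Union[int, tuple[int, int]] = (2, 4)
    window: float = 60.0
    frame_step: float = 1.0
    diameter_range: tuple[float, float] = (28e-6, 32e-6)
    tension_jitter_cv: float = 0.0
    seed: int = 0
    constants: MembraneConstants = field(default_factory=MembraneConstants)

    def __post_init__(self) -> None:
        if not self.true_A > 0:
            raise ValueError("true_A must be strictly positive")
        if not self.window > 0 or not self.frame_step > 0:
            raise ValueError("window and frame_step must be positive")
        n_steps = self.window / self.frame_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("window must be an integer multiple of frame_step")
        lo, hi = self.diameter_range
        if not 0 < lo <= hi:
            raise ValueError("diameter_range must be positive and ordered")
        for name in ("n_vesicles_per_trial", "n_trials"):
            v = getattr(self, name)
            if isinstance(v, int):
                if v < 1:
                    raise ValueError(f"{name} must be >= 1")
            else:
                a, b = v
                if not (1 <= a <= b):
                    raise ValueError(f"{name} range must be ordered and >= 1")
        if self.tension_jitter_cv < 0:
            raise ValueError("tension_jitter_cv must be >= 0")

    def gamma_at(self, gra_mole_percent: float) -> float:
        """Generating edge tension (N) for a peptide mole percent."""
        if isinstance(self.true_gamma, BiphasicParams):
            return biphasic_edge_tension(gra_mole_percent / 100.0, self.true_gamma)
        if isinstance(self.true_gamma, Mapping):
            try:
                return self.true_gamma[gra_mole_percent]
            except KeyError:
                raise KeyError(
                    f"no generating Gamma given for {gra_mole_percent} mole%"
                ) from None
        return float(self.true_gamma)

    def rate_at(self, gra_mole_percent: float, sigma_e: float) -> float:
        """Generating rupture rate (1/s) in one condition cell."""
        return rupture_rate(
            PoreModelParams(
                Gamma=self.gamma_at(gra_mole_percent),
                sigma_e=sigma_e,
                B=self.B,
                A=self.true_A,
            ),
            self.constants,
        )


def _draw_count(spec: Union[int, tuple[int, int]], rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_vesicle(
    design: ExperimentDesign,
    gra_mole_percent: float,
    sigma_target: float,
    rng: np.random.Generator,
    vesicle_id: str = "v0",
    trial_id: str = "t0",
) -> VesicleRecord:
    """Simulate one vesicle in one condition cell.

    The radius is drawn uniformly on the diameter range (halved); the field
    that realizes the target tension for that radius is computed as the
    protocol would (and serves as a consistency check, not a stored field).
    The latent rupture time is exponential with the generating rate,
    censored on the latent value at the window, and ceil-quantized to the
    frame grid.
    """
    lo, hi = design.diameter_range
    radius = rng.uniform(lo, hi) / 2.0
    # protocol step: field chosen per measured radius to hit the target tension
    field_for_target_tension(radius, sigma_target, design.constants)
    sigma_actual = sigma_target
    if design.tension_jitter_cv > 0:
        s = np.sqrt(np.log1p(design.tension_jitter_cv**2))
        sigma_actual = sigma_target * rng.lognormal(mean=-0.5 * s**2, sigma=s)
    k = design.rate_at(gra_mole_percent, sigma_actual)
    latent = rng.exponential(1.0 / k) if k > 0 else np.inf
    if latent > design.window:
        return VesicleRecord(
            vesicle_id=vesicle_id,
            trial_id=trial_id,
            gra_mole_percent=gra_mole_percent,
            radius=radius,
            sigma_e=sigma_target,
            censored=True,
            window=design.window,
        )
    quantized = float(np.ceil(latent / design.frame_step) * design.frame_step)
    quantized = max(quantized, design.frame_step)  # a rupture in frame 1 is stamped 1 s
    return VesicleRecord(
        vesicle_id=vesicle_id,
        trial_id=trial_id,
        gra_mole_percent=gra_mole_percent,
        radius=radius,
        sigma_e=sigma_target,
        rupture_time=quantized,
        censored=False,
        window=design.window,
    )


def _condition_rng(design: ExperimentDesign, cond_index: int, trial_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(cond_index, trial_index))
    return np.random.default_rng(ss)


def simulate_condition(
    design: ExperimentDesign,
    gra_mole_percent: float,
    sigma_target: float,
    cond_index: int = 0,
) -> list[VesicleRecord]:
    """Simulate all trials of one (peptide content, tension) condition.

    Trial count and per-trial vesicle counts are drawn from the design's
    ranges (or fixed, if given as ints); every trial has an independent
    stream keyed by (condition index, trial index).
    """
    # dedicated stream (reserved trial index) for the trial-count draw, so the
    # per-trial streams stay aligned whatever n_trials comes out
    meta_rng = _condition_rng(design, cond_index, 0xFFFF)
    n_trials = _draw_count(design.n_trials, meta_rng)
    records: list[VesicleRecord] = []
    for t in range(n_trials):
        rng = _condition_rng(design, cond_index, t)
        n_vesicles = _draw_count(design.n_vesicles_per_trial, rng)
        for m in range(n_vesicles):
            records.append(
                simulate_vesicle(
                    design,
                    gra_mole_percent,
                    sigma_target,
                    rng,
                    vesicle_id=f"c{cond_index}t{t}m{m + 1}",
                    trial_id=f"c{cond_index}trial{t + 1}",
                )
            )
    return records


def simulate_tension_grid(
    design: ExperimentDesign,
) -> tuple[list[VesicleRecord], dict]:
    """Full factorial dataset over every (peptide content, tension) cell.

    Returns the records plus a provenance sidecar (design parameters, seed,
    generating rates per cell) suitable for writing as JSON/YAML next to
    the CSV.
    """
    records: list[VesicleRecord] = []
    cells = []
    cond_index = 0
    for gra in design.gra_mole_percents:
        for sigma in design.sigma_targets:
            cell_records = simulate_condition(design, gra, sigma, cond_index=cond_index)
            records.extend(cell_records)
            cells.append(
                {
                    "cond_index": cond_index,
                    "gra_mole_percent": gra,
                    "sigma_e_n_per_m": sigma,
                    "true_gamma_n": design.gamma_at(gra),
                    "true_rate_per_s": design.rate_at(gra, sigma),
                    "n_records": len(cell_records),
                }
            )
            cond_index += 1
    meta = {
        "seed": design.seed,
        "true_A_per_s": design.true_A,
        "B_n_per_m": design.B,
        "window_s": design.window,
        "frame_step_s": design.frame_step,
        "diameter_range_m": list(design.diameter_range),
        "n_vesicles_per_trial": design.n_vesicles_per_trial,
        "n_trials": design.n_trials,
        "tension_jitter_cv": design.tension_jitter_cv,
        "cells": cells,
    }
    return records, meta
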