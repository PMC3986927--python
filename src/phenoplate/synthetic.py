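"""Synthetic phenotype-microarray studies with known ground truth.

Real OmniLog runs for this kind of stress panel are rarely public, so
every pipeline stage is exercised against generated data whose true
tolerance structure is known.  A well's redox accumulation is modelled
as a logistic curve

    S(t) = b + θ·A / (1 + exp(−r·(t − t_m − δ))) + ε_t,   ε_t ~ N(0, σ²)

floored at zero: A is the strain's metabolic amplitude under control
glucose (drawn from the 35–75 unit range typical of healthy wells),
θ ∈ [0, 1] the per-condition tolerance multiplier, δ a stress-induced
lag in hours, and σ additive imaging noise.  A study plants a tolerant
strain block (θ ≈ 0.8–1.0), a sensitive block (θ ≈ 0.1–0.3) and an
intermediate remainder for every stress condition, with controls at
θ = 1, δ = 0.

Sampling follows the instrument: 15-min photographs (0.25 h grid) over
96 h, truncated to 24 h for 40 °C assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_io import ConditionSpec, KineticSeries, StrainRecord
from .scoring import INTERMEDIATE, SENSITIVE, TOLERANT

GRID_STEP_H = 0.25

#: run length by assay temperature: 24 h at 40 °C (evaporation), else 96 h
def run_length_hours(temperature_C: float) -> float:
    return 24.0 if temperature_C >= 40.0 else 96.0


def default_condition_panel() -> list[ConditionSpec]:
    """A stress panel patterned on lignocellulosic-fermentation screens:
    one glucose control plus nine stresses (osmotic, ethanol, heat,
    weak acids, furans, phenolics)."""
    ctrl = ConditionSpec("ctrl30", "glucose control", 6, "%w/v", 30, 50, "")
    stresses = [
        ConditionSpec("sorb10", "sorbitol", 10, "%w/v", 30, 50, "ctrl30"),
        ConditionSpec("sorb15", "sorbitol", 15, "%w/v", 30, 50, "ctrl30"),
        ConditionSpec("etoh10", "ethanol", 10, "%v/v", 30, 50, "ctrl30"),
        ConditionSpec("heat35", "temperature", 35, "C", 35, 50, "ctrl30"),
        ConditionSpec("heat40", "temperature", 40, "C", 40, 24, "ctrl30"),
        ConditionSpec("acetic25", "acetic acid", 25, "mM", 30, 50, "ctrl30"),
        ConditionSpec("formic10", "formic acid", 10, "mM", 30, 50, "ctrl30"),
        ConditionSpec("furf10", "furfural", 10, "mM", 30, 50, "ctrl30"),
        ConditionSpec("vanil10", "vanillin", 10, "mM", 30, 50, "ctrl30"),
    ]
    return [ctrl] + stresses


@dataclass
class SyntheticStudySpec:
    """Parameters of a generated study.

    Defaults emulate the screening design this package targets:
    90 strains (a reference strain included), 1 control + 9 stress
    conditions, 3 replicates, amplitudes uniform in 35–75 units and
    additive noise of 2 units (a few percent of a typical endpoint).
    """

    n_strains: int = 90
    conditions: list[ConditionSpec] = field(default_factory=default_condition_panel)
    replicates: int = 3
    amplitude_range: tuple[float, float] = (35.0, 75.0)
    rate_range: tuple[float, float] = (0.25, 0.5)  # per hour
    midpoint_range: tuple[float, float] = (8.0, 16.0)  # hours
    baseline_range: tuple[float, float] = (1.0, 5.0)  # units
    theta_tolerant: tuple[float, float] = (0.8, 1.0)
    theta_sensitive: tuple[float, float] = (0.1, 0.3)
    theta_intermediate: tuple[float, float] = (0.4, 0.7)
    lag_sensitive: tuple[float, float] = (1.0, 3.0)  # hours
    fraction_tolerant: float = 1 / 3
    fraction_sensitive: float = 1 / 3
    noise_sd: float = 2.0
    reference_id: str = "S288C"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValidationError("SyntheticStudySpec: need at least 2 strains")
        if self.replicates < 1:
            raise ValidationError("SyntheticStudySpec: replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("SyntheticStudySpec: noise_sd must be >= 0")
        for lo, hi in (
            self.theta_tolerant,
            self.theta_sensitive,
            self.theta_intermediate,
        ):
            if not (0 <= lo <= hi <= 1):
                raise ValidationError("SyntheticStudySpec: theta ranges must lie in [0, 1]")
        if self.fraction_tolerant + self.fraction_sensitive > 1:
            raise ValidationError("SyntheticStudySpec: block fractions exceed 1")

    def strain_ids(self) -> list[str]:
        others = [f"STR{i:03d}" for i in range(1, self.n_strains)]
        return [self.reference_id] + others


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic study."""

    theta: pd.DataFrame  # strains × conditions amplitude multipliers
    delta: pd.DataFrame  # strains × conditions lag (hours)
    strain_class: dict[str, str]  # tolerant / sensitive / intermediate
    curve_params: pd.DataFrame  # per-strain A, r, t_m, b


def logistic(t: np.ndarray, A: float, r: float, t_m: float) -> np.ndarray:
    return A / (1.0 + np.exp(-r * (t - t_m)))


def simulate_curve(
    strain_id: str,
    condition_id: str,
    replicate: int,
    A: float,
    r: float,
    t_m: float,
    b: float = 0.0,
    theta: float = 1.0,
    delta: float = 0.0,
    sigma: float = 0.0,
    run_hours: float = 96.0,
    seed: int | Sequence[int] = 0,
) -> KineticSeries:
    """Generate one well's logistic redox curve on the 0.25-h grid.

    Identical seeds give bitwise-identical series.
    """
    if A <= 0 or r <= 0:
        raise ValidationError("simulate_curve: A and r must be positive")
    if not 0 <= theta <= 1:
        raise ValidationError(f"simulate_curve: theta={theta} outside [0, 1]")
    if sigma < 0:
        raise ValidationError("simulate_curve: sigma must be >= 0")
    times = np.arange(0.0, run_hours + GRID_STEP_H / 2, GRID_STEP_H)
    signal = b + theta * logistic(times, A, r, t_m + delta)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, sigma, size=times.size)
    signal = np.maximum(signal, 0.0)
    return KineticSeries(
        strain_id=strain_id,
        condition_id=condition_id,
        replicate=replicate,
        times=times,
        signals=signal,
    )


def _substream(seed: int, *indices: int) -> list[int]:
    # deterministic per-curve stream: the tuple itself seeds the generator
    return [int(seed) & 0x7FFFFFFF, *[int(i) for i in indices]]


def simulate_study(
    spec: SyntheticStudySpec,
) -> tuple[list[KineticSeries], GroundTruth]:
    """Generate a full study: curves for every (strain, condition, replicate).

    Strain-level tolerance classes are assigned by a seeded shuffle;
    each stress condition then draws per-strain θ within the class's
    range (and a lag δ for sensitive strains), while controls are fixed
    at θ = 1, δ = 0.  Everything is reproducible from ``spec.seed``.
    """
    strains = spec.strain_ids()
    conds = spec.conditions
    rng = np.random.default_rng(_substream(spec.seed, 0))

    n = spec.n_strains
    n_tol = int(round(spec.fraction_tolerant * n))
    n_sen = int(round(spec.fraction_sensitive * n))
    shuffled = list(strains)
    rng.shuffle(shuffled)
    strain_class = {s: INTERMEDIATE for s in strains}
    for s in shuffled[:n_tol]:
        strain_class[s] = TOLERANT
    for s in shuffled[n_tol : n_tol + n_sen]:
        strain_class[s] = SENSITIVE

    params = pd.DataFrame(
        {
            "A": rng.uniform(*spec.amplitude_range, size=n),
            "r": rng.uniform(*spec.rate_range, size=n),
            "t_m": rng.uniform(*spec.midpoint_range, size=n),
            "b": rng.uniform(*spec.baseline_range, size=n),
        },
        index=strains,
    )

    cond_ids = [c.condition_id for c in conds]
    theta = pd.DataFrame(1.0, index=strains, columns=cond_ids)
    delta = pd.DataFrame(0.0, index=strains, columns=cond_ids)
    theta_range = {
        TOLERANT: spec.theta_tolerant,
        SENSITIVE: spec.theta_sensitive,
        INTERMEDIATE: spec.theta_intermediate,
    }
    for cond in conds:
        if cond.is_control:
            continue
        for s in strains:
            lo, hi = theta_range[strain_class[s]]
            theta.loc[s, cond.condition_id] = rng.uniform(lo, hi)
            if strain_class[s] == SENSITIVE:
                delta.loc[s, cond.condition_id] = rng.uniform(*spec.lag_sensitive)

    curves: list[KineticSeries] = []
    for si, s in enumerate(strains):
        p = params.loc[s]
        for ci, cond in enumerate(conds):
            for rep in range(1, spec.replicates + 1):
                curves.append(
                    simulate_curve(
                        strain_id=s,
                        condition_id=cond.condition_id,
                        replicate=rep,
                        A=float(p["A"]),
                        r=float(p["r"]),
                        t_m=float(p["t_m"]),
                        b=float(p["b"]),
                        theta=float(theta.loc[s, cond.condition_id]),
                        delta=float(delta.loc[s, cond.condition_id]),
                        sigma=spec.noise_sd,
                        run_hours=run_length_hours(cond.temperature_C),
                        seed=_substream(spec.seed, 1, si, ci, rep),
                    )
                )
    truth = GroundTruth(
        theta=theta, delta=delta, strain_class=strain_class, curve_params=params
    )
    return curves, truth


def simulate_logratio_blocks(
    n_strains: int = 40,
    n_conditions: int = 9,
    effect: float = 1.5,
    sigma: float = 0.3,
    seed: int = 0,
    clip: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Log-ratio matrix with two planted strain blocks of opposite profile shape.

    Block 0 strains are tolerant on the first half of the conditions
    and sensitive on the second half (±``effect`` on the log₂ scale);
    block 1 strains show the mirrored profile.  Gaussian noise of
    ``sigma`` log₂ units is added and values are clipped to ±``clip``.
    Returns the matrix and the true block label per strain.
    """
    if n_strains < 4 or n_conditions < 2:
        raise ValidationError("simulate_logratio_blocks: study too small")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    strains = [f"STR{i:03d}" for i in range(n_strains)]
    conds = [f"cond{j}" for j in range(n_conditions)]
    half = n_conditions // 2
    pattern = np.array([effect] * half + [-effect] * (n_conditions - half))
    labels = {s: (0 if i < n_strains // 2 else 1) for i, s in enumerate(strains)}
    rows = []
    for s in strains:
        sign = 1.0 if labels[s] == 0 else -1.0
        rows.append(sign * pattern + rng.normal(0.0, sigma, size=n_conditions))
    values = np.clip(np.array(rows), -clip, clip)
    return pd.DataFrame(values, index=strains, columns=conds), labels


def strain_records(spec: SyntheticStudySpec) -> list[StrainRecord]:
    """Strain metadata matching a synthetic study (species set arbitrarily)."""
    species_cycle = [
        "S. cerevisiae",
        "S. paradoxus",
        "S. kudriavzevii",
        "S. uvarum",
        "S. arboricolus",
        "S. mikatae",
    ]
    out = []
    for i, sid in enumerate(spec.strain_ids()):
        sp = "S. cerevisiae" if sid == spec.reference_id else species_cycle[i % len(species_cycle)]
        out.append(StrainRecord(strain_id=sid, species=sp, origin="synthetic"))
    return out
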