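"""Synthetic parcellated BOLD with known phase-coupling regimes.

The generator produces the minimal signal family for which every stage of
the stability pipeline has exact ground truth: each hidden regime is a
partition of regions into phase-locked communities with fixed phase
offsets; region signals are narrowband sinusoids riding a common carrier
(so relative phases — the only thing the phase-coherence estimator sees —
are exactly the planted offsets), plus white Gaussian noise. The carrier
phase accumulates continuously across regime switches, so a switch changes
only the relative-phase pattern, never resets the oscillation.

Default shapes mirror a typical lifespan fMRI protocol: 116 regions,
261 timepoints (rest and sensorimotor task) or 193 (movie), TR = 2 s,
oscillation at 0.05 Hz (the middle of the 0.01-0.1 Hz BOLD band), noise
standard deviation 0.3 relative to the unit-amplitude oscillation, and a
mean regime dwell time of 10 samples (20 s) at rest.

Also provided: a textbook AR(p) series generator for the order-selection
machinery, and synthetic lifespan cohorts in which the age-to-dwell-time
mapping plants group orderings or U-shaped lifespan trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .io import BoldTimeSeries, SubjectTable

__all__ = [
    "RegimeSpec",
    "SyntheticCohortSpec",
    "generate_regime_bold",
    "generate_ar_series",
    "generate_cohort",
]

DEFAULT_N = 116
DEFAULT_T = {"rest": 261, "smt": 261, "movie": 193, "synthetic": 261}
DEFAULT_TR = 2.0
DEFAULT_OSC_HZ = 0.05
DEFAULT_NOISE_SD = 0.3
DEFAULT_DWELL = 10


@dataclass
class RegimeSpec:
    """Hidden-regime description: per-regime community labels and offsets.

    ``memberships[r]`` maps each region to a community id under regime r;
    ``offsets[r][c]`` is the phase offset (radians) of community c. Regions
    in the same community are perfectly phase-locked; between communities
    the planted coherence is cos of the offset difference.
    """

    memberships: list[np.ndarray]
    offsets: list[np.ndarray]
    dwell_mean: int = DEFAULT_DWELL
    dwell_distribution: str = "geometric"

    def __post_init__(self) -> None:
        if len(self.memberships) != len(self.offsets):
            raise ValueError("memberships and offsets must have one entry per regime")
        if self.n_regimes < 1:
            raise ValueError("need at least one regime")
        if self.dwell_mean < 2:
            raise ValueError(f"dwell_mean must be >= 2, got {self.dwell_mean}")
        if self.dwell_distribution not in ("fixed", "geometric"):
            raise ValueError(f"unknown dwell_distribution {self.dwell_distribution!r}")
        n = len(self.memberships[0])
        for r, (m, o) in enumerate(zip(self.memberships, self.offsets)):
            m = np.asarray(m, dtype=int)
            if len(m) != n:
                raise ValueError("all regimes must label the same region set")
            if m.min() < 0 or m.max() >= len(o):
                raise ValueError(f"regime {r}: community label outside offset table")
            self.memberships[r] = m
            self.offsets[r] = np.asarray(o, dtype=float)

    @property
    def n_regimes(self) -> int:
        return len(self.memberships)

    @property
    def n_regions(self) -> int:
        return len(self.memberships[0])

    @classmethod
    def random(
        cls,
        n_regions: int,
        n_regimes: int = 3,
        n_communities: int = 4,
        dwell_mean: int = DEFAULT_DWELL,
        dwell_distribution: str = "geometric",
        rng: np.random.Generator | None = None,
    ) -> "RegimeSpec":
        """Random balanced community partitions with uniform phase offsets."""
        rng = np.random.default_rng() if rng is None else rng
        memberships, offsets = [], []
        for _ in range(n_regimes):
            labels = np.repeat(np.arange(n_communities), -(-n_regions // n_communities))
            labels = labels[:n_regions]
            rng.shuffle(labels)
            memberships.append(labels)
            offsets.append(rng.uniform(0.0, 2 * np.pi, size=n_communities))
        return cls(
            memberships=memberships,
            offsets=offsets,
            dwell_mean=dwell_mean,
            dwell_distribution=dwell_distribution,
        )


def _state_sequence(spec: RegimeSpec, t: int, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(t, dtype=int)
    pos = 0
    current = int(rng.integers(spec.n_regimes))
    while pos < t:
        if spec.dwell_distribution == "fixed":
            dwell = spec.dwell_mean
        else:
            dwell = int(rng.geometric(1.0 / spec.dwell_mean))
        dwell = max(dwell, 1)
        states[pos : pos + dwell] = current
        pos += dwell
        if spec.n_regimes > 1:
            nxt = int(rng.integers(spec.n_regimes - 1))
            current = nxt if nxt < current else nxt + 1
    return states


def generate_regime_bold(
    spec: RegimeSpec,
    n_regions: int | None = None,
    n_timepoints: int = DEFAULT_T["rest"],
    tr_seconds: float = DEFAULT_TR,
    oscillation_hz: float = DEFAULT_OSC_HZ,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "synthetic",
    condition: str = "synthetic",
) -> tuple[BoldTimeSeries, np.ndarray]:
    """Regime-switching sinusoidal BOLD plus the hidden state sequence.

    Region r's signal is sin(2 pi f TR t + offset of r's community under the
    regime active at t) + Gaussian noise. The shared carrier makes regime
    transitions phase-continuous; only relative phases step at a switch.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_regions if n_regions is None else n_regions
    if n != spec.n_regions:
        raise ValueError(
            f"spec describes {spec.n_regions} regions but n_regions={n}"
        )
    if n < 4:
        raise ValueError(f"need at least 4 regions, got {n}")
    if oscillation_hz >= 1.0 / (2.0 * tr_seconds):
        raise ValueError(
            f"oscillation_hz={oscillation_hz} at or above Nyquist "
            f"({1.0 / (2.0 * tr_seconds):.4g} Hz for TR={tr_seconds}s)"
        )
    states = _state_sequence(spec, n_timepoints, rng)
    carrier = 2.0 * np.pi * oscillation_hz * tr_seconds * np.arange(n_timepoints)
    offset_per_region = np.empty((n, n_timepoints))
    for r in range(spec.n_regimes):
        mask = states == r
        if mask.any():
            offset_per_region[:, mask] = spec.offsets[r][spec.memberships[r]][:, None]
    signal = np.sin(carrier[None, :] + offset_per_region)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    ts = BoldTimeSeries(
        values=signal,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        condition=condition,
    )
    return ts, states


def generate_ar_series(
    coefficients,
    constant: float = 0.0,
    noise_sd: float = 1.0,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a stationary AR(p) series, discarding a 10x-order burn-in."""
    coefficients = np.atleast_1d(np.asarray(coefficients, dtype=float))
    p = len(coefficients)
    if p and np.any(coefficients != 0.0):
        companion = np.zeros((p, p))
        companion[0, :] = coefficients
        if p > 1:
            companion[1:, :-1] = np.eye(p - 1)
        radius = np.max(np.abs(np.linalg.eigvals(companion)))
        if radius >= 1.0:
            raise ValueError(
                f"coefficients define a nonstationary process "
                f"(companion spectral radius {radius:.4f} >= 1)"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = 10 * max(p, 1)
    total = n + burn
    eps = rng.normal(0.0, noise_sd, size=total)
    x = np.zeros(total)
    for t in range(total):
        acc = constant + eps[t]
        for i in range(min(p, t)):
            acc += coefficients[i] * x[t - 1 - i]
        x[t] = acc
    return x[burn:]


@dataclass
class SyntheticCohortSpec:
    """Recipe for a synthetic lifespan cohort.

    ``dwell_by_condition`` maps a condition name to either a fixed mean
    dwell time (samples) or a callable age -> dwell, which is how group
    orderings (longer task dwells) and lifespan U-shapes are planted.
    """

    n_subjects: int = 20
    age_range: tuple[float, float] = (18.0, 88.0)
    conditions: tuple[str, ...] = ("rest", "smt")
    dwell_by_condition: Mapping[str, int | Callable[[float], int]] = field(
        default_factory=lambda: {"rest": DEFAULT_DWELL, "smt": 4 * DEFAULT_DWELL}
    )
    n_regions: int = DEFAULT_N
    n_timepoints: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_T))
    tr_seconds: float = DEFAULT_TR
    oscillation_hz: float = DEFAULT_OSC_HZ
    noise_sd: float = DEFAULT_NOISE_SD
    n_regimes: int = 3
    n_communities: int = 4
    dwell_distribution: str = "geometric"
    seed: int = 0


def _dwell_for(spec: SyntheticCohortSpec, condition: str, age: float) -> int:
    rule = spec.dwell_by_condition[condition]
    dwell = rule(age) if callable(rule) else rule
    return max(int(round(dwell)), 2)


def generate_cohort(
    spec: SyntheticCohortSpec, outdir: str | Path | None = None, overwrite: bool = False
) -> tuple[SubjectTable, dict[tuple[str, str], BoldTimeSeries]]:
    """Generate a synthetic cohort; optionally write per-subject CSVs.

    Returns the subject table and an in-memory mapping
    (subject_id, condition) -> BoldTimeSeries. With ``outdir`` set, each
    series is written as a regions x time CSV and the manifest as
    ``subjects.csv``; the table's ``path`` column then points at the files.
    """
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        if outdir.exists() and any(outdir.iterdir()) and not overwrite:
            raise FileExistsError(
                f"output directory {outdir} is not empty (pass overwrite=True)"
            )
        outdir.mkdir(parents=True, exist_ok=True)
    lo, hi = spec.age_range
    ages = np.sort(rng.uniform(lo, hi, size=spec.n_subjects))
    rows = []
    series: dict[tuple[str, str], BoldTimeSeries] = {}
    for i, age in enumerate(ages):
        sid = f"sub{i + 1:04d}"
        for cond in spec.conditions:
            regime = RegimeSpec.random(
                spec.n_regions,
                n_regimes=spec.n_regimes,
                n_communities=spec.n_communities,
                dwell_mean=_dwell_for(spec, cond, age),
                dwell_distribution=spec.dwell_distribution,
                rng=rng,
            )
            t = spec.n_timepoints.get(cond, DEFAULT_T["rest"])
            ts, states = generate_regime_bold(
                regime,
                n_timepoints=t,
                tr_seconds=spec.tr_seconds,
                oscillation_hz=spec.oscillation_hz,
                noise_sd=spec.noise_sd,
                seed=rng,
                subject_id=sid,
                condition=cond if cond in ("rest", "movie", "smt") else "synthetic",
            )
            path = ""
            if outdir is not None:
                path = str(outdir / f"{sid}_{cond}.csv")
                np.savetxt(path, ts.values, delimiter=",", fmt="%.10g")
                np.savetxt(
                    outdir / f"{sid}_{cond}_states.csv", states[:, None],
                    delimiter=",", fmt="%d",
                )
            series[(sid, cond)] = ts
            rows.append(
                {"subject_id": sid, "age_years": float(age), "condition": cond, "path": path}
            )
    frame = pd.DataFrame(rows)
    if outdir is not None:
        frame.to_csv(outdir / "subjects.csv", index=False)
    return SubjectTable(frame), series
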