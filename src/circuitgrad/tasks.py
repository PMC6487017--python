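"""Synthetic task generators: the design objectives a circuit is trained on.

Each generator returns a :class:`TrainingSet` of (input signal, desired
output) pairs.  Static-input tasks (ultrasensitive switch, French-flag
stripe) present a grid of constant morphogen levels and ask for a 0/1
endpoint response; the duration detector presents single rectangular pulses
and asks for irreversible activation after sufficiently long ones; the
oscillator presents zero input and a full cosine target trajectory; the
robust counter presents stochastic trains of rectangular pulses with varying
number, amplitude, duration and gap, and asks for an endpoint equal to the
pulse count.  All generators are pure functions of their arguments and seed.

Input routing follows the convention that gene 1 receives the external
input and the last gene is read out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuits import InputSignal


@dataclass
class TrainingSet:
    """A collection of (input signal, desired output) pairs.

    ``target_mode`` is ``endpoint`` (desired output is the final readout) or
    ``trajectory`` (the desired output is a full time course, described by
    the cost parameters in ``metadata``).
    """

    cases: list[tuple[InputSignal, float | None]]
    target_mode: str = "endpoint"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.cases:
            raise ValueError("a TrainingSet needs at least one case")
        if self.target_mode not in ("endpoint", "trajectory"):
            raise ValueError(f"unknown target_mode {self.target_mode!r}")
        durations = {sig.duration for sig, _ in self.cases}
        if len(durations) != 1:
            raise ValueError("all cases must share one simulation duration")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def duration(self) -> float:
        return self.cases[0][0].duration

    def signals(self) -> list[InputSignal]:
        return [sig for sig, _ in self.cases]

    def targets(self) -> np.ndarray:
        return np.array([t if t is not None else np.nan for _, t in self.cases])

    def to_csv(self, outdir, dt: float = 0.01) -> None:
        """One CSV per case (time, input) plus a manifest with the targets."""
        import os

        os.makedirs(outdir, exist_ok=True)
        n_steps = int(round(self.duration / dt))
        t = np.arange(n_steps) * dt
        lines = ["case,file,target"]
        for idx, (sig, target) in enumerate(self.cases):
            fname = f"case_{idx:03d}.csv"
            vals = sig.sample_on_grid(n_steps, dt)
            np.savetxt(
                os.path.join(outdir, fname),
                np.column_stack([t, vals]),
                delimiter=",",
                header="time,input",
                comments="",
            )
            lines.append(f"{idx},{fname},{'' if target is None else target}")
        with open(os.path.join(outdir, "manifest.csv"), "w") as fh:
            fh.write("\n".join(lines) + "\n")


def make_switch_task(
    x_grid: Sequence[float] | None = None,
    x_star: float = 0.5,
    duration: float = 10.0,
) -> TrainingSet:
    """Ultrasensitive switch: target 1 for input >= x_star, else 0."""
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 11)
    x_grid = np.asarray(x_grid, dtype=float)
    if not (x_grid.min() < x_star <= x_grid.max()):
        raise ValueError("x_grid must span both sides of x_star")
    cases = [
        (InputSignal(mode="static", level=float(x), duration=duration),
         1.0 if x >= x_star else 0.0)
        for x in x_grid
    ]
    return TrainingSet(cases, "endpoint",
                       {"task": "switch", "x_star": x_star})


def make_french_flag_task(
    x_grid: Sequence[float] | None = None,
    band: tuple[float, float] = (0.3, 0.7),
    duration: float = 10.0,
) -> TrainingSet:
    """Stripe (French-flag) task: target 1 for inputs inside ``band``."""
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 11)
    x_grid = np.asarray(x_grid, dtype=float)
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy x_lo < x_hi")
    tol = 1e-9  # band edges are inclusive up to grid round-off
    cases = [
        (InputSignal(mode="static", level=float(x), duration=duration),
         1.0 if lo - tol <= x <= hi + tol else 0.0)
        for x in x_grid
    ]
    return TrainingSet(cases, "endpoint",
                       {"task": "french_flag", "band": (lo, hi)})


def make_duration_task(
    durations: Sequence[float] | None = None,
    amplitude: float = 1.0,
    critical_duration: float = 2.0,
    evaluation_delay: float = 4.0,
) -> TrainingSet:
    """Duration detector: one pulse per case; target 1 iff it outlasts the
    critical duration (strict >), judged after the input has been withdrawn."""
    if durations is None:
        durations = np.geomspace(0.5, 8.0, 8)
    durations = np.asarray(durations, dtype=float)
    T = float(durations.max() + evaluation_delay)
    cases = [
        (InputSignal(mode="time_series", pulses=[(0.0, float(d), amplitude)],
                     duration=T),
         1.0 if d > critical_duration else 0.0)
        for d in durations
    ]
    return TrainingSet(cases, "endpoint",
                       {"task": "duration_detector",
                        "critical_duration": critical_duration})


def make_oscillator_task(
    A_osc: float = 1.0, omega: float = 0.5, duration: float = 40.0
) -> TrainingSet:
    """Self-sustained oscillation: zero input, target A_osc cos(omega t).

    The duration must cover at least three periods; initial conditions (and
    decay rates) are the natural learnable groups so the phase can be fitted.
    """
    if duration * omega < 3 * 2 * np.pi:
        raise ValueError("duration must cover at least three periods")
    cases = [(InputSignal(mode="zero", duration=duration), None)]
    return TrainingSet(cases, "trajectory",
                       {"task": "oscillator", "A_osc": A_osc, "omega": omega,
                        "learn_k": True, "learn_y0": True})


@dataclass
class PulseEnsembleConfig:
    """Distribution of stochastic pulse trains for the counter task."""

    count_range: tuple[int, int] = (1, 5)
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    duration_range: tuple[float, float] = (0.5, 1.5)
    gap_range: tuple[float, float] = (1.0, 3.0)
    n_cases: int = 40
    seed: int = 0

    def __post_init__(self):
        for name in ("amplitude_range", "duration_range", "gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive interval")
        lo, hi = self.count_range
        if lo < 1 or hi < lo:
            raise ValueError("count_range must be a positive integer interval")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")

    def max_train_length(self) -> float:
        n = self.count_range[1]
        return n * (self.duration_range[1] + self.gap_range[1])


def make_counter_task(
    config: PulseEnsembleConfig, total_duration: float = 30.0
) -> TrainingSet:
    """Robust pulse counter: trains of rectangular pulses, endpoint target =
    pulse count.  Reproducible per seed; rejects windows too short to pack
    the maximal draw."""
    if config.max_train_length() > total_duration:
        raise ValueError(
            f"pulse trains of up to {config.max_train_length():.2f} time units "
            f"cannot fit in a window of {total_duration}"
        )
    rng = np.random.default_rng(config.seed)
    cases = []
    for _ in range(config.n_cases):
        count = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
        t = float(rng.uniform(*config.gap_range))
        pulses = []
        for _p in range(count):
            dur = float(rng.uniform(*config.duration_range))
            amp = float(rng.uniform(*config.amplitude_range))
            pulses.append((t, dur, amp))
            t += dur + float(rng.uniform(*config.gap_range))
        # leading gap shifts the train; drop it if the tail would overflow
        if pulses[-1][0] + pulses[-1][1] > total_duration:
            shift = pulses[0][0]
            pulses = [(s - shift, d, a) for s, d, a in pulses]
        cases.append(
            (InputSignal(mode="time_series", pulses=pulses, duration=total_duration),
             float(count))
        )
    return TrainingSet(cases, "endpoint",
                       {"task": "counter", "seed": config.seed,
                        "learn_k": True})


def naive_integrator_count(
    signal: InputSignal, a0: float = 1.0, d0: float = 1.0, dt: float = 0.01
) -> float:
    """Analog count estimate by integrating the input: (int I dt) / (a0 d0).

    Exact for a train of reference pulses (amplitude a0, duration d0) and
    biased in proportion to amplitude/duration variability — the failure
    mode the learned counter is meant to avoid.
    """
    if a0 <= 0 or d0 <= 0:
        raise ValueError("reference amplitude and duration must be positive")
    return signal.integral(dt) / (a0 * d0)
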