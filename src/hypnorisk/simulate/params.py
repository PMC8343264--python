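"""Parameter containers for the synthetic sleep-seizure cohort generator.

Defaults describe a refractory focal-epilepsy cohort followed for months
under ambulatory intracranial EEG: long habitual sleep (roughly 9.5 h per
night plus naps), cyclical NREM/REM architecture whose cycles shorten and
whose REM share grows across the night, frequent brief arousals (WASO),
telemetry dropouts, and a day-level seizure process driven by a logistic
model with patient-specific intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import ParameterError

# Stage-proportion trajectories across cycles 1..5. Deep sleep (N3)
# concentrates early in the night, REM grows toward morning, N2 fills the
# remainder -- mirroring conventional adult sleep architecture.
_DEFAULT_TRAJECTORIES = {
    "N1": (0.06, 0.08, 0.09, 0.11, 0.12),
    "N2": (0.49, 0.49, 0.51, 0.51, 0.48),
    "N3": (0.35, 0.28, 0.20, 0.12, 0.08),
    "REM": (0.10, 0.15, 0.20, 0.26, 0.32),
}


@dataclass
class SleepArchitectureParams:
    """Night-level sleep architecture of one synthetic patient.

    Clock times are hours of day in [0, 24); durations are hours.
    """

    mean_sleep_onset_clock_time: float = 23.0
    onset_jitter_sd: float = 0.75
    night_sleep_duration_mean: float = 9.5
    night_sleep_duration_sd: float = 1.0
    nap_rate_per_day: float = 0.6
    nap_duration_range: tuple[float, float] = (0.25, 1.75)
    n_cycles: int = 5
    cycle1_duration: float = 1.9
    cycle_duration_decay: float = 0.85
    stage_trajectories: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_TRAJECTORIES.items()}
    )
    waso_fraction: float = 0.10
    dropout_rate: float = 0.03
    artifact_rate: float = 0.01

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        lo, hi = self.nap_duration_range
        if not (0 < lo < hi):
            raise ParameterError("nap_duration_range must satisfy 0 < lo < hi")
        if hi >= 2.0:
            raise ParameterError("naps must be shorter than 2 h by definition")
        if self.cycle1_duration <= 0 or self.cycle_duration_decay <= 0:
            raise ParameterError("cycle durations must be strictly positive")
        if self.n_cycles < 1:
            raise ParameterError("need at least one sleep cycle")
        traj = self.stage_trajectories
        if set(traj) != {"N1", "N2", "N3", "REM"}:
            raise ParameterError("stage_trajectories must cover N1, N2, N3, REM")
        mat = np.array([traj[s] for s in ("N1", "N2", "N3", "REM")], dtype=float)
        if mat.shape[1] != self.n_cycles:
            raise ParameterError(
                f"each trajectory needs {self.n_cycles} per-cycle proportions"
            )
        if np.any(mat < 0) or np.any(mat > 1):
            raise ParameterError("stage proportions must lie in [0, 1]")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
            raise ParameterError("per-cycle stage proportions must sum to 1")
        for name in ("waso_fraction", "dropout_rate", "artifact_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ParameterError(f"{name} must lie in [0, 1)")

    def cycle_proportions(self) -> np.ndarray:
        """(n_cycles, 4) array of N1/N2/N3/REM proportions per cycle."""
        t = self.stage_trajectories
        return np.column_stack([t["N1"], t["N2"], t["N3"], t["REM"]]).astype(float)


@dataclass
class SeizureRiskParams:
    """Day-level seizure-generating model.

    Seizure days are drawn from ``logit(p) = b0_i + log(or_decreased) I(dec)
    + log(or_increased) I(inc)`` with patient intercepts
    ``b0_i ~ N(baseline_log_odds, random_intercept_sd^2)``. Within a seizure
    day, event times are placed into sleep-wake states according to
    ``state_placement_weights``. ``postseizure_effects`` shift the next
    day's sleep (additively) after wake-seizure and sleep-seizure days.
    """

    baseline_log_odds: float = -0.85
    random_intercept_sd: float = 0.5
    or_decreased: float = 0.92
    or_increased: float = 0.73
    state_placement_weights: dict[str, float] = field(
        default_factory=lambda: {
            "WAKE": 0.35,
            "N1": 0.15,
            "N2": 0.20,
            "N3": 0.10,
            "REM": 0.10,
            "WASO": 0.10,
        }
    )
    postseizure_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "wake_sz": {"duration_h": 0.7, "waso_prop": 0.0, "rem_prop": 0.0},
            "sleep_sz": {"duration_h": 1.2, "waso_prop": 0.04, "rem_prop": -0.04},
        }
    )
    seizure_duration_log_mean: float = np.log(60.0)  # seconds
    seizure_duration_log_sd: float = 0.5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.or_decreased <= 0 or self.or_increased <= 0:
            raise ParameterError("generating odds ratios must be positive")
        if self.random_intercept_sd < 0:
            raise ParameterError("random_intercept_sd must be nonnegative")
        w = np.array(list(self.state_placement_weights.values()), dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ParameterError(
                "state placement weights must be nonnegative and not all zero"
            )


# Relative band-power targets (delta, theta, alpha, low beta, high beta)
# per state: alpha-dominant wake, theta-dominant N1/REM, delta-dominant
# deep sleep. Values are relative shares over the five scoring bands.
_DEFAULT_PROFILES = {
    "WAKE": (0.15, 0.20, 0.30, 0.15, 0.20),
    "N1": (0.25, 0.35, 0.20, 0.10, 0.10),
    "N2": (0.45, 0.25, 0.15, 0.10, 0.05),
    "N3": (0.70, 0.15, 0.08, 0.04, 0.03),
    "REM": (0.20, 0.40, 0.20, 0.10, 0.10),
}


@dataclass
class SignalModel:
    """Spectral shape of the synthetic one-channel EEG-like signal.

    Each state's segment is coloured Gaussian noise whose power spectrum is
    piecewise-constant over the five scoring bands (relative shares from
    ``band_profiles``) plus a broadband noise floor.
    """

    sampling_rate: float = 128.0
    band_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_PROFILES.items()}
    )
    amplitude_scale: float = 50.0  # RMS amplitude, arbitrary units
    noise_floor: float = 0.05  # broadband relative power

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate < 40.0:
            raise ParameterError(
                "sampling_rate must be at least twice the highest band edge (>= 40 Hz)"
            )
        for state, prof in self.band_profiles.items():
            p = np.asarray(prof, dtype=float)
            if p.size != 5 or np.any(p < 0):
                raise ParameterError(
                    f"profile for {state} must be 5 nonnegative relative powers"
                )
        if self.noise_floor < 0:
            raise ParameterError("noise_floor must be nonnegative")
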