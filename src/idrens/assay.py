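"""Wet-lab assay analytics with synthetic-data generators.

Two stages: luminescence-plate quantification (mixing arithmetic, replicate
statistics, one-way ANOVA against a control) and plasmon-resonance trace
processing (baseline-subtracted transition windows, post-switch drift).
The generators are synthetic stand-ins whose statistical structure mirrors
the measured contrasts; they are not instrument models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Concentration arithmetic


def molar_concentration(mass_conc_mg_ml: float, molecular_weight_kda: float,
                        v_sample_ul: float, v_reagent_ul: float = 0.0) -> float:
    """Final molar concentration in uM after diluting a protein solution
    with a reagent volume.

    (mass_conc / MW) gives mM for mg/ml over kDa; scaled by the dilution
    factor v_sample / (v_sample + v_reagent) and converted to uM.
    """
    if mass_conc_mg_ml <= 0 or molecular_weight_kda <= 0 or v_sample_ul <= 0:
        raise ValueError("mass concentration, molecular weight and sample volume must be positive")
    if v_reagent_ul < 0:
        raise ValueError("reagent volume must be non-negative")
    millimolar = mass_conc_mg_ml / molecular_weight_kda
    dilution = v_sample_ul / (v_sample_ul + v_reagent_ul)
    return millimolar * 1000.0 * dilution


def aliquot_amount(volume_ul: float, conc_um: float) -> float:
    """Amount of substance (nmol) in a pipetted aliquot; unrounded.

    Round to 2 decimals for display (e.g. 8 ul of 42 uM -> 0.34 nmol).
    """
    if volume_ul < 0 or conc_um < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_ul * conc_um * 1e-3


# ---------------------------------------------------------------------------
# Luminescence plate


@dataclass
class LuminescencePlate:
    """Per-sample replicate intensities (arbitrary luminescence units)."""

    intensities: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for sample, values in self.intensities.items():
            arr = np.asarray(values, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative intensity for sample {sample!r}")
            clean[sample] = arr
        self.intensities = clean
        if not self.balanced:
            warnings.warn("unbalanced replicate counts across samples", stacklevel=2)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities)

    @property
    def balanced(self) -> bool:
        counts = {len(v) for v in self.intensities.values()}
        return len(counts) <= 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": s, "replicate": k + 1, "intensity": v}
            for s, values in self.intensities.items()
            for k, v in enumerate(values)
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "LuminescencePlate":
        df = pd.read_csv(path)
        groups = {
            str(s): g.sort_values("replicate")["intensity"].to_numpy()
            for s, g in df.groupby("sample", sort=False)
        }
        return cls(groups)


def summarize_plate(plate: LuminescencePlate) -> pd.DataFrame:
    """Per-sample mean and SEM (sd / sqrt(n)); SEM is NaN (flagged with a
    warning) for single-replicate samples."""
    rows = []
    for sample, values in plate.intensities.items():
        n = len(values)
        if n < 2:
            warnings.warn(f"sample {sample!r}: SEM undefined for a single replicate",
                          stacklevel=2)
            sem = float("nan")
        else:
            sem = float(np.std(values, ddof=1) / np.sqrt(n))
        rows.append({"sample": sample, "mean": float(np.mean(values)),
                     "sem": sem, "n": n})
    return pd.DataFrame(rows).set_index("sample")


def _two_group_anova(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups (equivalent to t-test, F = t^2),
    with explicit zero-within-variance conventions."""
    ss_within = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    if ss_within == 0.0:
        if a.mean() == b.mean():
            return float("nan"), 1.0  # indistinguishable, flagged via p = 1
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def anova_vs_control(plate: LuminescencePlate, control_label: str,
                     alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
    """Pairwise sample-vs-control one-way ANOVA (two-group) per sample.

    Returns F, p and the significance flag (p < alpha) for every non-control
    sample.  ``bonferroni=True`` divides alpha by the number of comparisons;
    the default applies no multiple-testing correction.
    """
    if control_label not in plate.intensities:
        raise ValueError(f"control {control_label!r} not on the plate")
    others = [s for s in plate.samples if s != control_label]
    if not others:
        raise ValueError("need at least one non-control sample")
    control = plate.intensities[control_label]
    threshold = alpha / len(others) if bonferroni else alpha
    rows = []
    for sample in others:
        f, p = _two_group_anova(plate.intensities[sample], control)
        rows.append({"sample": sample, "F": f, "p": p,
                     "significant": bool(p < threshold)})
    return pd.DataFrame(rows).set_index("sample")


def anova_global(plate: LuminescencePlate) -> tuple[float, float]:
    """k-group one-way ANOVA over all samples on the plate."""
    f, p = stats.f_oneway(*plate.intensities.values())
    return float(f), float(p)


#: Synthetic plate means (arbitrary units).  Free parameters chosen only to
#: reproduce the qualitative ordering GFP << impaired mutants < WT-like.
DEFAULT_EFFECT_PROFILE: Mapping[str, float] = {
    "GFP": 5.0,
    "WT": 100.0,
    "D42A": 100.0,
    "E44A": 55.0,
    "D49A": 100.0,
    "E50A": 55.0,
    "E51A": 100.0,
    "EE50AA": 55.0,
    "E53A": 100.0,
    "R55A": 55.0,
    "D56A": 100.0,
}

DEFAULT_PLATE_NOISE_SD = 6.0


def simulate_plate(effect_profile: Mapping[str, float] | None = None,
                   noise_sd: float = DEFAULT_PLATE_NOISE_SD,
                   n_rep: int = 3, seed: int = 0) -> LuminescencePlate:
    """Gaussian replicates around per-sample means, truncated at 0;
    seed-reproducible via a Philox stream."""
    profile = dict(effect_profile) if effect_profile is not None else dict(DEFAULT_EFFECT_PROFILE)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    data = {
        sample: np.maximum(0.0, mean + noise_sd * rng.standard_normal(n_rep))
        for sample, mean in profile.items()
    }
    return LuminescencePlate(data)


# ---------------------------------------------------------------------------
# Plasmon-resonance traces

PRE_SWITCH_S = 100
POST_SWITCH_S = 300
WINDOW_S = PRE_SWITCH_S + POST_SWITCH_S

#: Slope (nm/s) below which a post-switch window is labeled "decaying".
DECAY_SLOPE_THRESHOLD = -2e-4

NPS_SCENARIOS = ("Mms6", "Mms6MM", "protein_free")

TRANSITION_LABELS = ("buffer_to_protein", "water_to_iron", "iron_to_water")


@dataclass
class NPSTrace:
    """1 Hz plasmon-peak wavelength series with labeled solution switches."""

    time: np.ndarray
    wavelength: np.ndarray
    transitions: Mapping[str, float]
    scenario: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        if self.time.shape != self.wavelength.shape:
            raise ValueError("time and wavelength must have equal length")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, 1.0):
            raise ValueError("trace must be uniformly sampled at 1 Hz")
        for label, t in self.transitions.items():
            if not (self.time[0] <= t <= self.time[-1]):
                raise ValueError(f"transition {label!r} at {t} outside trace range")

    def write_csv(self, path: str | Path) -> tuple[Path, Path]:
        path = Path(path)
        pd.DataFrame({"time_s": self.time, "wavelength_nm": self.wavelength}
                     ).to_csv(path, index=False)
        sidecar = path.with_suffix(".transitions.json")
        sidecar.write_text(json.dumps(
            {"scenario": self.scenario, "transitions": dict(self.transitions)},
            indent=2))
        return path, sidecar

    @classmethod
    def read_csv(cls, path: str | Path) -> "NPSTrace":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".transitions.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            time=df["time_s"].to_numpy(),
            wavelength=df["wavelength_nm"].to_numpy(),
            transitions=meta.get("transitions", {}),
            scenario=meta.get("scenario", ""),
        )


@dataclass
class TransitionWindow:
    """Baseline-subtracted 400 s window around one solution switch."""

    time_rel: np.ndarray   # seconds relative to the switch, [-100, 299]
    dlambda: np.ndarray    # nm, baseline-subtracted
    baseline: float        # nm, mean over the 100 s pre-switch segment
    t_switch: float
    label: str = ""

    def __len__(self) -> int:
        return len(self.time_rel)

    @property
    def pre_switch(self) -> np.ndarray:
        return self.dlambda[self.time_rel < 0]

    @property
    def post_switch(self) -> np.ndarray:
        return self.dlambda[self.time_rel >= 0]

    def plateau(self, last_s: int = 100) -> float:
        """Mean d-lambda over the final ``last_s`` seconds of the window."""
        return float(self.dlambda[-last_s:].mean())


def transition_window(trace: NPSTrace, t_switch: float, label: str = "") -> TransitionWindow:
    """Extract the 400 s window (100 s before, 300 s after ``t_switch``) and
    subtract the pre-switch mean as baseline."""
    start = t_switch - PRE_SWITCH_S
    idx = np.searchsorted(trace.time, start)
    if not np.isclose(trace.time[idx] if idx < len(trace.time) else np.nan, start):
        raise ValueError(f"window start {start}s not on the trace grid")
    if idx + WINDOW_S > len(trace.time):
        raise ValueError("window exceeds trace bounds")
    seg_t = trace.time[idx:idx + WINDOW_S]
    seg_l = trace.wavelength[idx:idx + WINDOW_S]
    baseline = float(seg_l[:PRE_SWITCH_S].mean())
    return TransitionWindow(
        time_rel=seg_t - t_switch,
        dlambda=seg_l - baseline,
        baseline=baseline,
        t_switch=float(t_switch),
        label=label,
    )


def post_switch_drift(win: TransitionWindow, fit_last_s: int = 200
                      ) -> tuple[float, bool]:
    """Least-squares slope (nm/s) of d-lambda over the final ``fit_last_s``
    seconds of the window, and whether it labels the window 'decaying'."""
    t = win.time_rel[-fit_last_s:]
    y = win.dlambda[-fit_last_s:]
    slope = float(np.polyfit(t, y, 1)[0])
    return slope, slope < DECAY_SLOPE_THRESHOLD


@dataclass(frozen=True)
class NPSScenarioParams:
    """Step amplitudes (nm) and kinetics (s) of one synthetic scenario."""

    protein_shift: float
    iron_shift: float
    iron_decay_amp: float
    iron_decay_tau: float
    water_shift: float
    rise_tau: float = 30.0


#: Amplitudes chosen to mirror the qualitative measured contrasts: both
#: proteins adsorb alike; the iron shift is small for both proteins (with a
#: slow decay for the triple mutant only) and near-zero protein-free; the
#: post-iron water shift is large except for the triple mutant.
NPS_SCENARIO_PARAMS: Mapping[str, NPSScenarioParams] = {
    "Mms6": NPSScenarioParams(2.0, 0.4, 0.0, 250.0, 4.0),
    "Mms6MM": NPSScenarioParams(2.0, 0.5, 0.5, 250.0, 0.15),
    "protein_free": NPSScenarioParams(0.0, 0.05, 0.0, 250.0, 4.0),
}

DEFAULT_NPS_NOISE_SD = 0.02
NPS_BASE_WAVELENGTH = 600.0
NPS_TRACE_LENGTH_S = 2000
NPS_TRANSITION_TIMES: Mapping[str, float] = {
    "buffer_to_protein": 300.0,
    "water_to_iron": 900.0,
    "iron_to_water": 1500.0,
}


def simulate_nps_trace(scenario: str, seed: int = 0,
                       noise_sd: float = DEFAULT_NPS_NOISE_SD) -> NPSTrace:
    """Piecewise synthetic sensorgram with the three labeled transitions.

    Each switch adds a saturating-exponential step; the iron step of the
    triple-mutant scenario additionally decays back over time.
    """
    if scenario not in NPS_SCENARIO_PARAMS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {', '.join(NPS_SCENARIOS)}")
    p = NPS_SCENARIO_PARAMS[scenario]
    t = np.arange(NPS_TRACE_LENGTH_S, dtype=float)
    lam = np.full_like(t, NPS_BASE_WAVELENGTH)

    def step(t0: float, amplitude: float) -> np.ndarray:
        dt = np.maximum(t - t0, 0.0)
        return np.where(t >= t0, amplitude * (1.0 - np.exp(-dt / p.rise_tau)), 0.0)

    times = NPS_TRANSITION_TIMES
    lam += step(times["buffer_to_protein"], p.protein_shift)
    lam += step(times["water_to_iron"], p.iron_shift)
    if p.iron_decay_amp:
        dt = np.maximum(t - times["water_to_iron"], 0.0)
        lam -= np.where(t >= times["water_to_iron"],
                        p.iron_decay_amp * (1.0 - np.exp(-dt / p.iron_decay_tau)),
                        0.0)
    lam += step(times["iron_to_water"], p.water_shift)
    if noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        lam = lam + noise_sd * rng.standard_normal(len(t))
    return NPSTrace(time=t, wavelength=lam, transitions=dict(times),
                    scenario=scenario)


def analyze_trace(trace: NPSTrace) -> pd.DataFrame:
    """Window features (plateau, drift, decay flag) for every labeled switch."""
    rows = []
    for label, t_switch in trace.transitions.items():
        win = transition_window(trace, t_switch, label=label)
        slope, decaying = post_switch_drift(win)
        rows.append({
            "transition": label,
            "t_switch": t_switch,
            "baseline_nm": win.baseline,
            "plateau_nm": win.plateau(),
            "drift_nm_per_s": slope,
            "decaying": decaying,
        })
    return pd.DataFrame(rows).set_index("transition")
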