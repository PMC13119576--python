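"""Synthetic CoP-like signals and cohorts with known ground truth.

The generators produce quiet-standing-like center-of-pressure recordings
whose dynamical properties are controlled analytically:

* long-range correlation via spectral synthesis with a prescribed DFA
  exponent,
* bounded two-regime diffusion via an Ornstein-Uhlenbeck (OU) process with
  known mean-square-displacement curve, and
* adjustable regularity via a sinusoidal variance fraction.

A cohort generator layers between-subject parameter heterogeneity, a
faller/non-faller label with an adjustable age confound, and optional group
effects injected into chosen sway features by perturbing the signal
parameters that drive them.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from copsway.core import CONDITIONS, CoPTrial, ParticipantRecord

__all__ = [
    "SynthSignalParams",
    "SynthCohortParams",
    "gen_colored_noise",
    "gen_ou_walk",
    "gen_cop_trial",
    "gen_cohort",
    "EFFECT_MECHANISMS",
]


@dataclass
class SynthSignalParams:
    """Parameters of one synthetic CoP trial.

    The signal is a variance-weighted mix of a stochastic component
    (OU walk + colored/white noise) and an optional sinusoid:

    ``periodic_fraction`` is the proportion of total variance contributed by
    the sinusoid; ``alpha_target`` sets the DFA exponent of the noise
    component (``None`` for plain white noise); ``ou_sigma``/``ou_tau`` are
    the stationary SD (cm) and relaxation time (s) of the OU component;
    ``noise_sd`` scales the noise component (cm).
    """

    n_samples: int = 6000
    fs: float = 100.0
    alpha_target: Optional[float] = None
    periodic_fraction: float = 0.0
    ou_sigma: float = 0.35
    ou_tau: float = 1.0
    noise_sd: float = 0.06
    periodic_freq: float = 0.3  # Hz, sway-band oscillation used for regularity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0.0 <= self.periodic_fraction <= 1.0:
            raise ValueError("periodic_fraction must lie in [0, 1]")
        if self.ou_tau <= 0:
            raise ValueError("ou_tau must be positive")
        if self.ou_sigma < 0 or self.noise_sd < 0:
            raise ValueError("ou_sigma and noise_sd must be non-negative")


@dataclass
class SynthCohortParams:
    """Parameters of a synthetic faller / non-faller cohort.

    ``confound_strength`` shifts the faller age distribution by that many
    age-SDs, creating measurable confounding for the propensity-score stage.
    ``effect_features`` is a list of ``(feature_name, standardized_effect)``
    pairs; each named feature is pushed apart between groups by roughly the
    stated number of between-subject feature SDs (positive = higher in
    fallers), realized by perturbing the generator parameter that drives it.
    """

    n_fallers: int
    n_nonfallers: int
    confound_strength: float = 0.0
    effect_features: Sequence[Tuple[str, float]] = field(default_factory=list)
    trials_per_condition: int = 3
    n_samples: int = 6000
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fallers < 1 or self.n_nonfallers < 1:
            raise ValueError("group counts must be >= 1")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        for name, size in self.effect_features:
            if not np.isfinite(size):
                raise ValueError(f"effect size for {name!r} must be finite")


def gen_colored_noise(alpha_target: float, n_samples: int, seed) -> np.ndarray:
    """Zero-mean, unit-SD noise with a prescribed DFA scaling exponent.

    Spectral synthesis: the power spectrum is proportional to
    ``f**(-beta)`` with ``beta = 2 * alpha_target - 1``, realized with
    complex-Gaussian Fourier coefficients (random phases).  ``alpha = 0.5``
    gives white noise, ``alpha = 1.0`` 1/f noise, ``alpha = 1.5`` Brownian-like
    noise.
    """
    if not 0.2 <= alpha_target <= 1.8:
        raise ValueError(f"alpha_target={alpha_target} outside supported range [0.2, 1.8]")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    beta = 2.0 * alpha_target - 1.0
    freqs = np.fft.rfftfreq(n_samples)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    coeff[0] = 0.0  # zero mean
    x = np.fft.irfft(coeff, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def gen_ou_walk(
    ou_sigma: float, ou_tau: float, n_samples: int, fs: float, seed
) -> np.ndarray:
    """Two independent Ornstein-Uhlenbeck channels, shape ``(n_samples, 2)``.

    Exact discretization with stationary initialization: each channel has
    stationary SD ``ou_sigma`` (cm) and relaxation time ``ou_tau`` (s).  The
    planar mean-square displacement is
    ``MSD(dt) = 4 * ou_sigma**2 * (1 - exp(-dt / ou_tau))``,
    i.e. short-lag slope ``4 * ou_sigma**2 / ou_tau`` and a long-lag plateau
    at ``4 * ou_sigma**2``.
    """
    if ou_tau <= 0:
        raise ValueError("ou_tau must be positive")
    if ou_sigma < 0:
        raise ValueError("ou_sigma must be non-negative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if ou_tau < 5.0 / fs:
        raise ValueError(f"ou_tau={ou_tau} too short: need ou_tau >= 5/fs = {5.0 / fs}")
    rng = np.random.default_rng(seed)
    if ou_sigma == 0.0:
        return np.zeros((n_samples, 2))
    rho = math.exp(-1.0 / (fs * ou_tau))
    innov_sd = ou_sigma * math.sqrt(1.0 - rho * rho)
    out = np.empty((n_samples, 2))
    for ch in range(2):
        x0 = rng.normal(0.0, ou_sigma)
        eps = rng.normal(0.0, innov_sd, size=n_samples - 1)
        # AR(1) recursion via lfilter, seeded with the stationary start
        x = sps.lfilter([1.0], [1.0, -rho], eps, zi=np.array([rho * x0]))[0]
        out[:, ch] = np.concatenate([[x0], x])
    return out


def _trial_child_seeds(seed) -> np.ndarray:
    """Four reproducible child seeds (OU, noise AP, noise ML, phases)."""
    return np.random.SeedSequence(seed).generate_state(4)


def gen_cop_trial(
    params: SynthSignalParams,
    participant_id: str = "synthetic",
    condition: str = "EO_firm",
    trial_index: int = 1,
) -> CoPTrial:
    """Synthesize one two-channel CoP-like trial.

    The stochastic component is ``OU walk + noise_sd * noise`` per channel
    (the noise is colored to ``alpha_target`` if set, else white); the
    periodic component is a sinusoid at ``periodic_freq`` Hz with random
    phase per channel, scaled so that the total variance budget is split
    ``(1 - periodic_fraction) : periodic_fraction``.  Deterministic given
    ``params.seed``.
    """
    p = params
    ou_seed, na_seed, nm_seed, ph_seed = _trial_child_seeds(p.seed)

    stoch = gen_ou_walk(p.ou_sigma, p.ou_tau, p.n_samples, p.fs, ou_seed)
    for ch, nseed in ((0, na_seed), (1, nm_seed)):
        if p.noise_sd > 0:
            if p.alpha_target is not None:
                noise = gen_colored_noise(p.alpha_target, p.n_samples, nseed)
            else:
                noise = np.random.default_rng(nseed).standard_normal(p.n_samples)
            stoch[:, ch] = stoch[:, ch] + p.noise_sd * noise

    target_sd = math.sqrt(p.ou_sigma**2 + p.noise_sd**2)
    t = np.arange(p.n_samples) / p.fs
    phases = np.random.default_rng(ph_seed).uniform(0.0, 2.0 * np.pi, size=2)
    amp = math.sqrt(2.0) * target_sd  # sinusoid of this amplitude has SD target_sd
    w = 2.0 * np.pi * p.periodic_freq
    sin_ap = amp * np.sin(w * t + phases[0])
    sin_ml = amp * np.sin(w * t + phases[1])

    a = math.sqrt(1.0 - p.periodic_fraction)
    b = math.sqrt(p.periodic_fraction)
    cop_ap = a * stoch[:, 0] + b * sin_ap
    cop_ml = a * stoch[:, 1] + b * sin_ml
    return CoPTrial(
        participant_id=participant_id,
        condition=condition,
        trial_index=trial_index,
        fs=p.fs,
        cop_ap=cop_ap,
        cop_ml=cop_ml,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Between-subject population distribution of signal parameters.
#: Log-normal parameters are given as (log-median, log-SD); normal ones as
#: (mean, SD, low-clip, high-clip).
_POP_LOGNORMAL = {
    "ou_sigma": (math.log(0.35), 0.25),
    "ou_tau": (math.log(1.0), 0.20),
    "noise_sd": (math.log(0.06), 0.30),
}
_POP_NORMAL = {
    "alpha_target": (1.0, 0.08, 0.6, 1.4),
    "periodic_fraction": (0.15, 0.06, 0.0, 0.5),
}

#: Eyes-closed condition amplifies sway relative to eyes-open.
_EC_MULTIPLIERS = {"ou_sigma": 1.3, "noise_sd": 1.2}

#: Mechanism used to inject a standardized group effect into each supported
#: feature: feature name -> (signal parameter, gain).  The faller group's
#: parameter is shifted by ``effect * gain`` parameter-SDs; gains were
#: calibrated empirically (see docs/methods.md) so that the realized shift in
#: the extracted feature is approximately ``effect`` feature-SDs.
EFFECT_MECHANISMS = {
    "velo": ("ou_sigma", 1.22),
    "velo_ap": ("ou_sigma", 1.22),
    "velo_ml": ("ou_sigma", 1.23),
    "velo_sd_ap": ("ou_sigma", 1.22),
    "velo_sd_ml": ("ou_sigma", 1.23),
    "area": ("ou_sigma", 1.04),
    "mfreq_ap": ("noise_sd", 2.87),
    "mfreq_ml": ("noise_sd", 2.07),
    "mp3": ("ou_sigma", -1.01),
    "mt3": ("periodic_fraction", 3.97),
    "md3": ("ou_sigma", 1.01),
    "fd": ("noise_sd", 2.92),
    "alpha_ap": ("ou_tau", 1.99),
    "alpha_ml": ("ou_tau", 2.03),
    "sda_ds": ("ou_sigma", 1.05),
    "sda_dl": ("ou_tau", 3.92),
    "sda_crit": ("ou_tau", 1.86),
    "sda_crid": ("ou_sigma", 1.04),
    "mse1_ap": ("noise_sd", 2.75),
    "mse1_ml": ("noise_sd", 2.11),
    "mse10_ap": ("ou_tau", -1.70),
    "mse10_ml": ("ou_tau", -1.67),
    "mse40_ap": ("ou_tau", -4.27),
    "mse40_ml": ("ou_tau", -3.07),
    "det_ap": ("noise_sd", -2.35),
    "det_ml": ("noise_sd", -1.95),
    "lam_ap": ("noise_sd", -2.28),
    "lam_ml": ("noise_sd", -1.94),
}

_AGE_MEAN = 72.0
_AGE_SD = 6.5


def _draw_subject_params(rng: np.random.Generator) -> dict:
    out = {}
    for name, (mu, lsd) in _POP_LOGNORMAL.items():
        out[name] = math.exp(rng.normal(mu, lsd))
    for name, (mean, sd, lo, hi) in _POP_NORMAL.items():
        out[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return out


def _apply_effects(params: dict, effects: Sequence[Tuple[str, float]]) -> dict:
    out = dict(params)
    for name, size in effects:
        if name not in EFFECT_MECHANISMS:
            raise ValueError(
                f"unknown effect feature {name!r}; supported features: "
                f"{sorted(EFFECT_MECHANISMS)}"
            )
        pname, gain = EFFECT_MECHANISMS[name]
        shift = size * gain
        if pname in _POP_LOGNORMAL:
            lsd = _POP_LOGNORMAL[pname][1]
            out[pname] = out[pname] * math.exp(shift * lsd)
        else:
            mean, sd, lo, hi = _POP_NORMAL[pname]
            out[pname] = float(np.clip(out[pname] + shift * sd, lo, hi))
    return out


def gen_cohort(params: SynthCohortParams) -> Tuple[List[ParticipantRecord], List[CoPTrial]]:
    """Generate a synthetic faller/non-faller cohort with CoP trials.

    Each subject gets the eight propensity-model covariates plus a 12-month
    fall count; fallers' ages are shifted by ``confound_strength`` age-SDs
    and their signal parameters are perturbed per ``effect_features``.
    Every subject receives ``trials_per_condition`` trials in each of the
    eyes-open and eyes-closed firm-surface conditions.  Seeding is
    counter-based per (group, subject, condition, trial), so enlarging the
    cohort never reshuffles existing subjects.
    """
    p = params
    # validate effect feature names up front
    _apply_effects(_draw_subject_params(np.random.default_rng(0)), p.effect_features)

    records: List[ParticipantRecord] = []
    trials: List[CoPTrial] = []
    for group, n_group in ((1, p.n_fallers), (0, p.n_nonfallers)):
        for j in range(n_group):
            ss = np.random.SeedSequence(p.seed, spawn_key=(group, j))
            rng = np.random.default_rng(ss)
            pid = f"{'F' if group else 'N'}{j + 1:04d}"

            age_mean = _AGE_MEAN + (p.confound_strength * _AGE_SD if group else 0.0)
            age = max(60.0, rng.normal(age_mean, _AGE_SD))
            # mild age links for medication count and illness keep the
            # covariate table realistic without adding direct group effects
            meds = int(rng.poisson(max(0.2, 1.5 + 0.05 * (age - 70.0))))
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    age=round(age, 1),
                    sex=int(rng.random() < 0.3),  # 1 = male, ~30% as in the source data
                    bmi=round(float(np.clip(rng.normal(25.5, 2.9), 16, 42)), 1),
                    adl=int(rng.random() < 0.6),
                    illness=int(rng.random() < min(0.9, 0.3 + 0.01 * (age - 70.0))),
                    n_medications=meds,
                    disability=int(rng.random() < 0.2),
                    orthosis=int(rng.random() < 0.1),
                    falls12m=int(rng.choice([1, 2, 3], p=[0.8, 0.15, 0.05])) if group else 0,
                )
            )

            subj_params = _draw_subject_params(rng)
            if group:
                subj_params = _apply_effects(subj_params, p.effect_features)

            for ci, cond in enumerate(CONDITIONS):
                cond_params = dict(subj_params)
                if cond == "EC_firm":
                    for k, mult in _EC_MULTIPLIERS.items():
                        cond_params[k] = cond_params[k] * mult
                for ti in range(p.trials_per_condition):
                    tseed = np.random.SeedSequence(
                        p.seed, spawn_key=(group, j, ci, ti)
                    ).generate_state(1)[0]
                    sp = SynthSignalParams(
                        n_samples=p.n_samples,
                        fs=p.fs,
                        alpha_target=cond_params["alpha_target"],
                        periodic_fraction=cond_params["periodic_fraction"],
                        ou_sigma=cond_params["ou_sigma"],
                        ou_tau=cond_params["ou_tau"],
                        noise_sd=cond_params["noise_sd"],
                        seed=int(tseed),
                    )
                    trials.append(
                        gen_cop_trial(sp, participant_id=pid, condition=cond, trial_index=ti + 1)
                    )
    return records, trials
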