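"""Synthetic subject cohorts with known injected effects.

Every downstream analysis stage (learning-curve classification, CP statistics,
ERP measurement) can be validated against ground truth by generating subjects
from parameterized archetypes:

* **trial logs** — per-trial correctness is Bernoulli(p(t)) with a logistic
  learning curve p(t) = 0.5 + (a − 0.5) / (1 + exp(−(t − t0)/s)), so chance
  performance rises to asymptote ``a`` around trial ``t0``; reaction times are
  lognormal with a declining mean for subjects who learn.
* **dissimilarity ratings** — pre-phase ratings are the archetype's base mean
  plus Gaussian noise, rounded and clipped to the 1–9 scale; post-phase
  ratings additionally carry the injected between-category separation
  (``sigma_b``) and signed within-category change (``sigma_w``).
* **EEG epochs** — 500 Hz epochs spanning −1000…+2000 ms around stimulus
  onset on a 10-channel montage. Each trial is Gaussian noise plus two
  components: a negative Gaussian bump centered at 185 ms on the occipital
  cluster (the N1) and a positive slow wave centered at 700 ms on the parietal
  cluster (the LPC). After the subject's learning point the N1 is attenuated
  and the LPC amplified by the profile's injected changes. Artifact trials
  (>100 µV excursions) are injected at the profile's artifact rate.

Default effect magnitudes emulate the observed regimes of the study the
generator stands in for (learner between-category change ≈ +1.8 rating units,
N1 attenuation ≈ +1.1 µV, LPC boost ≈ +0.5 µV); they are emulation targets
carried as ground-truth labels, not empirical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .behavior import RatingTable, TrialLog
from .erp import EpochArray
from .stimuli import RatingPairSet, TrialSchedule

__all__ = [
    "SubjectProfile",
    "CohortBundle",
    "ARCHETYPES",
    "learning_curve",
    "gen_trial_log",
    "gen_ratings",
    "gen_epochs",
    "gen_cohort",
    "template_window_mean",
]

DEFAULT_CHANNELS = ("Iz", "Oz", "O1", "O2", "POz", "Pz", "P1", "P2", "CPz", "Fz")
OCCIPITAL = ("Iz", "Oz", "O1", "O2", "POz")
PARIETAL = ("Pz", "P1", "P2", "CPz")

N1_CENTER_S = 0.185
N1_SIGMA_S = 0.025
LPC_CENTER_S = 0.700
LPC_SIGMA_S = 0.080


def learning_curve(t, t0: float, s: float, a: float):
    """Logistic accuracy curve from chance (0.5) to asymptote ``a``."""
    return 0.5 + (a - 0.5) / (1.0 + np.exp(-(np.asarray(t, float) - t0) / s))


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one synthetic subject."""

    archetype: str               # Learner | Immediate | Borderline | NonLearner
    t0: float                    # learning onset trial
    steepness: float             # logistic slope (trials)
    asymptote: float             # asymptotic accuracy, in [0.5, 1]
    rt_base: float = 1.1         # pre-learning median RT (s)
    rt_decline: float = 0.3      # RT drop at asymptote (s)
    rt_sigma: float = 0.25       # lognormal shape
    base_between: float = 5.0    # pre-phase mean rating, between pairs
    base_within: float = 4.2     # pre-phase mean rating, within pairs
    sigma_b: float = 0.0         # injected between-category change
    sigma_w: float = 0.0         # injected within-category change (signed)
    rating_noise: float = 1.0    # rating noise SD (rating units)
    n1_pre: float = -4.0         # N1 peak amplitude before learning (µV)
    n1_change: float = 0.0       # N1 change after learning (µV; + = attenuated)
    lpc_pre: float = 2.0         # LPC peak amplitude before learning (µV)
    lpc_change: float = 0.0      # LPC change after learning (µV)
    eeg_noise_sd: float = 10.0   # white-noise SD per sample (µV)
    artifact_rate: float = 0.0   # probability a trial carries a >100 µV spike

    def __post_init__(self):
        if not 0.5 <= self.asymptote <= 1.0:
            raise ValueError("asymptote must lie in [0.5, 1]")
        if self.archetype == "NonLearner" and self.asymptote >= 0.8:
            raise ValueError("NonLearner asymptote must stay below 0.8")
        if self.archetype == "Immediate" and self.accuracy_at(1) < 0.8:
            raise ValueError("Immediate profiles must start at >= 80% accuracy")

    def accuracy_at(self, trial) -> np.ndarray:
        return learning_curve(
            np.asarray(trial, dtype=float), self.t0, self.steepness, self.asymptote
        )


#: Archetype parameter presets; effect magnitudes mirror the learner and
#: non-learner regimes the generator emulates.
ARCHETYPES = {
    "Learner": SubjectProfile(
        archetype="Learner", t0=150.0, steepness=15.0, asymptote=0.96,
        base_between=5.04, base_within=4.01, sigma_b=1.8, sigma_w=-0.43,
        n1_change=1.1, lpc_change=0.5, artifact_rate=0.06,
    ),
    "Immediate": SubjectProfile(
        archetype="Immediate", t0=-50.0, steepness=10.0, asymptote=0.95,
        base_between=5.04, base_within=4.01, sigma_b=1.8, sigma_w=-0.43,
        n1_change=1.1, lpc_change=0.5, artifact_rate=0.06,
    ),
    "Borderline": SubjectProfile(
        archetype="Borderline", t0=120.0, steepness=20.0, asymptote=0.78,
        base_between=4.9, base_within=4.3, sigma_b=0.9, sigma_w=0.1,
        artifact_rate=0.06,
    ),
    "NonLearner": SubjectProfile(
        archetype="NonLearner", t0=200.0, steepness=30.0, asymptote=0.55,
        base_between=4.87, base_within=4.55, sigma_b=0.776, sigma_w=0.376,
        artifact_rate=0.06,
    ),
}


def gen_trial_log(
    profile: SubjectProfile,
    n_trials: int = 400,
    seed: int = 0,
    schedule: TrialSchedule | None = None,
    subject_id: str = "synth",
) -> TrialLog:
    """Simulate one subject's categorization trial log."""
    rng = substream(seed, "trial-log")
    t = np.arange(1, n_trials + 1)
    p = profile.accuracy_at(t)
    correct = rng.random(n_trials) < p
    if schedule is not None:
        if len(schedule) != n_trials:
            raise ValueError("schedule length must equal n_trials")
        stim_ids = list(schedule.order)
        categories = [sid[0] for sid in stim_ids]
    else:
        categories = np.where(rng.random(n_trials) < 0.5, "K", "L").tolist()
        stim_ids = [f"{c}{i:03d}" for i, c in enumerate(categories)]
    flip = {"K": "L", "L": "K"}
    responses = [c if ok else flip[c] for c, ok in zip(categories, correct)]
    # RT declines along the same logistic time course as accuracy
    progress = (p - 0.5) / max(profile.asymptote - 0.5, 1e-9)
    median_rt = np.maximum(profile.rt_base - profile.rt_decline * progress, 0.25)
    rt = np.exp(rng.normal(np.log(median_rt), profile.rt_sigma))
    return TrialLog(
        subject_id=subject_id,
        trials=pd.DataFrame(
            {
                "trial": t,
                "stimulus_id": stim_ids,
                "category": categories,
                "response": responses,
                "correct": correct.astype(int),
                "rt": rt,
            }
        ),
    )


def gen_ratings(
    profile: SubjectProfile,
    pairs: RatingPairSet,
    seed: int = 0,
    subject_id: str = "synth",
) -> RatingTable:
    """Simulate pre/post dissimilarity ratings with the profile's injected effects."""
    rng = substream(seed, "ratings")
    rows = []
    for i, ptype in enumerate(pairs.pair_types):
        base = profile.base_between if ptype == "between" else profile.base_within
        effect = profile.sigma_b if ptype == "between" else profile.sigma_w
        for phase, mean in (("pre", base), ("post", base + effect)):
            raw = mean + rng.normal(0.0, profile.rating_noise)
            rows.append(
                {
                    "pair": i,
                    "pair_type": ptype,
                    "phase": phase,
                    "rating": int(np.clip(round(raw), 1, 9)),
                }
            )
    return RatingTable(subject_id=subject_id, ratings=pd.DataFrame(rows))


def _gauss(times: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / sigma) ** 2)


def template_window_mean(
    center_s: float,
    sigma_s: float,
    window_s: tuple,
    sfreq: float = 500.0,
    tmin: float = -1.0,
) -> float:
    """Window mean of a unit Gaussian component under the pipeline's sampling.

    Closed form for the attenuation factor relating a component's *peak*
    amplitude to its *window-mean* measurement: the average of
    exp(−(t−c)²/2σ²) over the half-open sample window, which converges to
    σ√(π/2)·[erf(·)−erf(·)]/(t1−t0) as the sampling rate grows.
    """
    i0 = int(round((window_s[0] - tmin) * sfreq))
    i1 = int(round((window_s[1] - tmin) * sfreq))
    t = tmin + np.arange(i0, i1) / sfreq
    return float(_gauss(t, center_s, sigma_s).mean())


def gen_epochs(
    profile: SubjectProfile,
    n_trials: int = 400,
    learning_point: int | None = None,
    seed: int = 0,
    subject_id: str = "synth",
    sfreq: float = 500.0,
    tmin: float = -1.0,
    tmax: float = 2.0,
    ch_names: tuple = DEFAULT_CHANNELS,
) -> EpochArray:
    """Simulate stimulus-locked epochs with N1/LPC templates plus noise.

    ``learning_point`` is the 1-based trial from which the after-learning
    component amplitudes apply; ``None`` means the pre-learning amplitudes
    hold throughout (e.g., a non-learner with no injected change).
    """
    rng = substream(seed, "epochs")
    n_samples = int(round((tmax - tmin) * sfreq))
    times = tmin + np.arange(n_samples) / sfreq
    n_ch = len(ch_names)
    occ = np.array([ch in OCCIPITAL for ch in ch_names])
    par = np.array([ch in PARIETAL for ch in ch_names])
    n1_t = _gauss(times, N1_CENTER_S, N1_SIGMA_S)
    lpc_t = _gauss(times, LPC_CENTER_S, LPC_SIGMA_S)

    after = np.zeros(n_trials, dtype=bool)
    if learning_point is not None:
        after[learning_point - 1 :] = True

    data = rng.normal(0.0, profile.eeg_noise_sd, size=(n_ch, n_samples, n_trials))
    n1_amp = np.where(after, profile.n1_pre + profile.n1_change, profile.n1_pre)
    lpc_amp = np.where(after, profile.lpc_pre + profile.lpc_change, profile.lpc_pre)
    data[occ] += n1_t[None, :, None] * n1_amp[None, None, :]
    data[par] += lpc_t[None, :, None] * lpc_amp[None, None, :]

    artifact = rng.random(n_trials) < profile.artifact_rate
    for tr in np.flatnonzero(artifact):
        ch = rng.integers(n_ch)
        s0 = rng.integers(n_samples - 50)
        data[ch, s0 : s0 + 50, tr] += rng.choice([-1.0, 1.0]) * rng.uniform(150.0, 300.0)

    meta = pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "phase": np.where(after, "after", "before"),
            "artifact": artifact,
        }
    )
    return EpochArray(
        subject_id=subject_id, data=data, ch_names=tuple(ch_names),
        sfreq=sfreq, tmin=tmin, tmax=tmax, metadata=meta,
    )


@dataclass(frozen=True)
class CohortBundle:
    """A cohort's profiles, logs and ratings; epochs are generated on demand."""

    profiles: tuple
    logs: tuple
    ratings: tuple
    pair_set: RatingPairSet | None
    seed: int
    n_trials: int = 400

    def __len__(self) -> int:
        return len(self.profiles)

    def epochs_for(self, i: int, learning_point: int | None = None, **kw) -> EpochArray:
        """Generate subject i's epochs (deferred: they are memory-heavy)."""
        profile = self.profiles[i]
        if learning_point is None and profile.archetype in ("Learner", "Immediate"):
            learning_point = max(int(round(profile.t0)), 1)
        return gen_epochs(
            profile,
            n_trials=self.n_trials,
            learning_point=learning_point,
            seed=int(substream(self.seed, "cohort-epochs", i).integers(2**31 - 1)),
            subject_id=self.logs[i].subject_id,
            **kw,
        )


def _jitter_profile(profile: SubjectProfile, rng, spread: float) -> SubjectProfile:
    """Draw a subject-level profile around the archetype means."""
    if spread <= 0:
        return profile
    a = float(np.clip(profile.asymptote + rng.normal(0, 0.02 * spread),
                      0.5, 0.995))
    if profile.archetype == "NonLearner":
        a = min(a, 0.79)
    return replace(
        profile,
        t0=profile.t0 + rng.normal(0, 30.0 * spread),
        asymptote=a,
        sigma_b=profile.sigma_b + rng.normal(0, 0.3 * spread),
        sigma_w=profile.sigma_w + rng.normal(0, 0.3 * spread),
        n1_change=profile.n1_change + rng.normal(0, 0.2 * spread),
        lpc_change=profile.lpc_change + rng.normal(0, 0.1 * spread),
    )


def gen_cohort(
    n_subjects: int,
    mix: dict | None = None,
    seed: int = 0,
    pairs: RatingPairSet | None = None,
    n_trials: int = 400,
    profile_spread: float = 1.0,
) -> CohortBundle:
    """Generate a cohort of subjects with archetype proportions ``mix``.

    ``mix`` maps archetype names to proportions summing to 1 (default: the
    learner/non-learner/borderline split of roughly two thirds, a quarter and
    a tenth seen in behavioural cohorts of this kind). Subject counts are the
    largest-remainder rounding of the proportions. ``profile_spread`` scales
    between-subject jitter around the archetype means (0 = identical subjects,
    used for exact parameter-recovery checks).
    """
    if mix is None:
        mix = {"Learner": 0.65, "NonLearner": 0.25, "Borderline": 0.10}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    # largest-remainder apportionment
    quotas = {k: v * n_subjects for k, v in mix.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n_subjects - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1

    profiles, logs, ratings = [], [], []
    i = 0
    for archetype in sorted(counts):
        for _ in range(counts[archetype]):
            rng = substream(seed, "cohort-profile", i)
            profile = _jitter_profile(ARCHETYPES[archetype], rng, profile_spread)
            sid = f"S{i:03d}"
            log_seed = int(substream(seed, "cohort-log", i).integers(2**31 - 1))
            logs.append(
                gen_trial_log(profile, n_trials=n_trials, seed=log_seed, subject_id=sid)
            )
            if pairs is not None:
                rat_seed = int(substream(seed, "cohort-rat", i).integers(2**31 - 1))
                ratings.append(gen_ratings(profile, pairs, seed=rat_seed, subject_id=sid))
            profiles.append(profile)
            i += 1
    return CohortBundle(
        profiles=tuple(profiles),
        logs=tuple(logs),
        ratings=tuple(ratings),
        pair_set=pairs,
        seed=seed,
        n_trials=n_trials,
    )
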