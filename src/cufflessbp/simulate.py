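"""Synthetic paired-ECG/PPG cohort simulator with known ground truth.

The generator emulates the study conditions the pipeline was designed for:
participants whose systolic pressure and pulse transit time obey
``SBP = c / PTT`` with a participant-level stiffness coefficient c drawn
from one of five disjoint, ordered class ranges (class 1 highest, class
proportions 1:1:3:3:2); sessions structured reference - device record -
reference with dual-observer auscultatory readings rounded to the nearest
2 mmHg; and the four waveform artifact classes the exclusion rules screen
for. Every hidden truth (class, coefficient, per-beat R/onset times,
session BP) is carried on the generated objects so downstream stages can
be tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError, QuotaError
from .types import (ARTIFACT_LABELS, ParticipantProfile, RawRecord,
                    ReferenceMeasurement, SessionRecord)

# Default per-class generator parameters. Coefficient ranges (mmHg*ms) are
# disjoint and ordered, class 1 highest, so SBP x PTT recovers the class
# exactly. BP setpoint means step down with the class so the cohort covers
# the high/normal/low strata the distribution audit requires; diastolic-wave
# morphology and age shift with the class so the waveform itself carries
# group information.
DEFAULT_CLASS_WEIGHTS = (1, 1, 3, 3, 2)
DEFAULT_COEFF_RANGES = {
    1: (44000.0, 50000.0),
    2: (38000.0, 43000.0),
    3: (30000.0, 37000.0),
    4: (23000.0, 29000.0),
    5: (17000.0, 22000.0),
}
CLASS_SBP_MEAN = {1: 170.0, 2: 152.0, 3: 125.0, 4: 110.0, 5: 94.0}
CLASS_SBP_SD = {1: 6.0, 2: 5.0, 3: 9.0, 4: 7.0, 5: 5.0}
CLASS_AGE_MEAN = {1: 72.0, 2: 64.0, 3: 55.0, 4: 45.0, 5: 35.0}
CLASS_DIA_AMP = {1: 0.55, 2: 0.45, 3: 0.35, 4: 0.25, 5: 0.15}
CLASS_DIA_DELAY = {1: 0.30, 2: 0.27, 3: 0.24, 4: 0.21, 5: 0.18}

# ECG morphology: five Gaussian components (amplitude, center offset from R
# in s, width in s). P and T offsets scale with the RR interval; Q/R/S are
# fixed-width. T amplitude = 0.45 of R so the 0.7 R/T threshold is exercised.
_ECG_COMPONENTS = (
    ("P", 0.12, -0.22, 0.030, True),
    ("Q", -0.08, -0.035, 0.012, False),
    ("R", 1.00, 0.0, 0.016, False),
    ("S", -0.12, 0.035, 0.014, False),
    ("T", 0.45, 0.31, 0.060, True),
)

_SYS_SIGMA = 0.045   # systolic pulse component width (s)
_DIA_SIGMA = 0.075   # diastolic component width (s)


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int = 84
    sessions_per_participant: int = 3
    n_extra_sessions: int = 8          # spread one extra session over the first k
    class_weights: tuple = DEFAULT_CLASS_WEIGHTS
    coeff_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COEFF_RANGES))
    duration_s: float = 12.0
    hr_mean: float = 70.0
    hr_sd: float = 8.0
    session_sbp_sd: float = 3.0        # within-participant session-to-session
    prepost_drift_sd: float = 1.5      # BP drift between reference phases
    observer_noise_sd: float = 1.5     # per observer, before 2-mmHg rounding
    ecg_noise_sd: float = 0.01
    pulse_noise_sd: float = 0.005
    baseline_wander_amp: float = 0.04
    powerline_amp: float = 0.4
    powerline_hz: float = 50.0
    # engineered-violation fractions (for exclusion-harness testing)
    frac_observer_disagreement: float = 0.0
    frac_prepost_sbp: float = 0.0
    frac_prepost_dbp: float = 0.0
    frac_short_participant: float = 0.0
    artifact_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.class_weights) != 5 or any(w <= 0 for w in self.class_weights):
            raise ConfigurationError("class_weights must be five positive numbers")
        if set(self.coeff_ranges) != {1, 2, 3, 4, 5}:
            raise ConfigurationError("coeff_ranges must cover classes 1..5")
        prev_low = math.inf
        for cls in (1, 2, 3, 4, 5):
            lo, hi = self.coeff_ranges[cls]
            if not (0 < lo < hi):
                raise ConfigurationError(f"class {cls} range must satisfy 0 < lo < hi")
            if hi >= prev_low:
                raise ConfigurationError(
                    "class coefficient ranges must be disjoint and ordered "
                    "(class 1 highest)")
            prev_low = lo
        if self.sessions_per_participant < 3:
            raise ConfigurationError("need at least three sessions per participant")
        self.n_extra_sessions = min(self.n_extra_sessions, self.n_participants)


def _sample_class(rng: np.random.Generator, weights) -> int:
    p = np.asarray(weights, dtype=float)
    return int(rng.choice(np.arange(1, 6), p=p / p.sum()))


def generate_participant(config: CohortConfig, rng_seed: int, *,
                         stiffness_class: int | None = None,
                         sex: str | None = None,
                         participant_id: str | None = None) -> ParticipantProfile:
    """Draw one participant profile; deterministic for a fixed seed.

    With ``stiffness_class=None`` the class is sampled from the configured
    1:1:3:3:2 weights (cohort generation passes exact assignments instead).
    """
    rng = np.random.default_rng(rng_seed)
    cls = stiffness_class if stiffness_class is not None \
        else _sample_class(rng, config.class_weights)
    lo, hi = config.coeff_ranges[cls]
    coeff = float(rng.uniform(lo, hi))
    if sex is None:
        sex = "female" if rng.random() < 0.5 else "male"
    sbp0 = float(np.clip(rng.normal(CLASS_SBP_MEAN[cls], CLASS_SBP_SD[cls]), 85, 200))
    ratio = float(rng.uniform(0.55, 0.75))
    dbp0 = ratio * sbp0
    age = float(np.clip(rng.normal(CLASS_AGE_MEAN[cls], 7.0), 18, 92))
    height = float(rng.normal(158.0 if sex == "female" else 171.0, 6.0))
    bmi = float(rng.normal(23.0, 2.5))
    weight = round(bmi * (height / 100.0) ** 2, 1)
    return ParticipantProfile(
        participant_id=participant_id or f"P{rng_seed % 10 ** 8:08d}",
        age=round(age, 1), sex=sex, weight=weight, height=round(height, 1),
        stiffness_class=cls, bp_setpoint_sbp=round(sbp0, 1),
        bp_setpoint_dbp=round(dbp0, 1), ptt_coefficient=round(coeff, 1),
        dbp_ratio=ratio,
        dia_amplitude=float(np.clip(rng.normal(CLASS_DIA_AMP[cls], 0.04), 0.05, 0.7)),
        dia_delay_s=float(np.clip(rng.normal(CLASS_DIA_DELAY[cls], 0.01), 0.12, 0.36)),
    )


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def quantize(x: np.ndarray, bits: int, full_scale: float) -> tuple[np.ndarray, bool]:
    """Mid-rise uniform quantization over [-full_scale/2, full_scale/2)."""
    levels = 2 ** bits
    delta = full_scale / levels
    q = np.floor(x / delta)
    clipped = bool(np.any(q < -levels // 2) or np.any(q > levels // 2 - 1))
    q = np.clip(q, -levels // 2, levels // 2 - 1)
    return (q + 0.5) * delta, clipped


def synthesize_record(profile: ParticipantProfile, sbp: float, dbp: float,
                      hr: float, duration: float, rng_seed: int,
                      artifact_labels: frozenset | set = frozenset(),
                      config: CohortConfig | None = None,
                      run_config: RunConfig | None = None) -> RawRecord:
    """Synthesize one paired ECG/pulse record with embedded ground truth.

    The pulse onset (maximum-upstroke point of the systolic component)
    trails each R peak by PTT = ptt_coefficient / sbp milliseconds plus a
    zero-mean per-beat jitter bounded by 2 ms.
    """
    config = config or CohortConfig()
    run_config = run_config or RunConfig()
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s (beat-averaging window)")
    if not sbp > dbp:
        raise ValueError("require sbp > dbp")
    if not 30.0 <= hr <= 180.0:
        raise ValueError("hr must lie in [30, 180] bpm")
    bad = set(artifact_labels) - set(ARTIFACT_LABELS)
    if bad:
        raise ValueError(f"unknown artifact labels: {sorted(bad)}")

    rng = np.random.default_rng(rng_seed)
    fs = run_config.sampling_rate
    n = int(round(fs * duration))
    t = np.arange(n) / fs

    ptt_ms = profile.ptt_coefficient / sbp
    rr = 60.0 / hr

    # beat train with RR jitter
    r_times = []
    tcur = 0.45 * rr + 0.1
    while tcur < duration - 0.6 * rr:
        r_times.append(tcur)
        tcur += rr * (1.0 + rng.normal(0.0, 0.02))
    r_times = np.array(r_times)

    ecg = np.zeros(n)
    pulse = np.zeros(n)
    onset_times = np.empty_like(r_times)
    for i, rt in enumerate(r_times):
        for _name, amp, off, sigma, scaled in _ECG_COMPONENTS:
            center = rt + (off * rr / 0.857 if scaled else off)
            ecg += amp * _gauss(t, center, sigma)
        jitter = float(np.clip(rng.normal(0.0, 0.8), -2.0, 2.0))  # ms
        onset = rt + (ptt_ms + jitter) / 1000.0
        onset_times[i] = onset
        amp_fluct = 1.0 + rng.normal(0.0, 0.05)
        # systolic component: max upstroke of a Gaussian is one sigma before
        # its center, so the center sits at onset + sigma
        sys_center = onset + _SYS_SIGMA
        pulse += amp_fluct * _gauss(t, sys_center, _SYS_SIGMA)
        pulse += amp_fluct * profile.dia_amplitude * _gauss(
            t, sys_center + profile.dia_delay_s, _DIA_SIGMA)

    phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
    ecg = ecg + config.baseline_wander_amp * np.sin(2 * np.pi * 0.18 * t + phase1)
    pulse = pulse + config.baseline_wander_amp * np.sin(2 * np.pi * 0.15 * t + phase2)
    ecg = ecg + rng.normal(0.0, config.ecg_noise_sd, n)
    pulse = pulse + rng.normal(0.0, config.pulse_noise_sd, n)

    labels = frozenset(artifact_labels)
    if "unclear_crest" in labels:
        # no discernible QRS train: a slow respiratory-scale hump whose
        # residual after the detection band-pass still dominates the noise
        ecg = 1.0 * np.sin(2 * np.pi * 0.15 * t + phase1) \
            + rng.normal(0.0, 0.001, n)
    if "powerline_noise" in labels:
        pl = config.powerline_amp * np.sin(2 * np.pi * config.powerline_hz * t)
        ecg = ecg + pl
        pulse = pulse + 0.5 * pl
    if "wavelet_error_trigger" in labels:
        pulse = np.zeros(n)
    if "low_amplitude" in labels:
        ecg = ecg * 0.01
        pulse = pulse * 0.01

    ecg, clip1 = quantize(ecg, run_config.resolution_bits, run_config.full_scale)
    pulse, clip2 = quantize(pulse, run_config.resolution_bits, run_config.full_scale)

    truth = {
        "r_indices": np.round(r_times * fs).astype(int),
        "onset_indices": np.round(onset_times * fs).astype(int),
        "ptt_ms": ptt_ms,
        "sbp": sbp, "dbp": dbp, "hr": hr,
    }
    return RawRecord(ecg=ecg, pulse=pulse, sampling_rate=fs,
                     resolution_bits=run_config.resolution_bits,
                     duration=duration, artifact_labels=labels,
                     clipped=clip1 or clip2, truth=truth)


def _round2(x: float) -> int:
    """Round to the nearest 2 mmHg (auscultatory recording convention)."""
    return int(2 * round(x / 2.0))


def _reference(rng: np.random.Generator, sbp: float, dbp: float,
               noise_sd: float, force_sbp_gap: float | None = None
               ) -> ReferenceMeasurement:
    o1s = _round2(sbp + rng.normal(0, noise_sd))
    o1d = _round2(dbp + rng.normal(0, noise_sd))
    if force_sbp_gap is not None:
        o2s = o1s + _round2(force_sbp_gap)
        o2d = _round2(dbp + rng.normal(0, noise_sd))
    else:
        o2s = _round2(sbp + rng.normal(0, noise_sd))
        o2d = _round2(dbp + rng.normal(0, noise_sd))
    return ReferenceMeasurement(obs1_sbp=o1s, obs1_dbp=o1d,
                                obs2_sbp=o2s, obs2_dbp=o2d)


def _exact_class_counts(n: int, weights) -> list[int]:
    """Largest-remainder apportionment of n participants to the five classes."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for idx in np.argsort(-rem)[: n - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def generate_cohort(config: CohortConfig, rng_seed: int,
                    run_config: RunConfig | None = None,
                    check_quotas: bool | None = None) -> list[SessionRecord]:
    """Generate the full synthetic cohort as a flat, participant-grouped list.

    Classes are apportioned exactly at the configured 1:1:3:3:2 weights and
    sexes alternate, so the distribution quotas hold by construction; the
    audit is still run (unless engineered violations are requested) and a
    failure raises :class:`QuotaError`.
    """
    run_config = run_config or RunConfig()
    has_violations = any((config.frac_observer_disagreement,
                          config.frac_prepost_sbp, config.frac_prepost_dbp,
                          config.frac_short_participant,
                          config.artifact_fraction))
    last_err: QuotaError | None = None
    for attempt in range(5):
        sessions = _generate_cohort_once(config, (rng_seed, attempt),
                                         run_config)
        if check_quotas is None:
            # the quota table is meaningful only at the protocol's scale
            do_check = not has_violations and len(sessions) >= 255
        else:
            do_check = check_quotas
        if not do_check:
            return sessions
        try:
            _verify_quotas(sessions)
            return sessions
        except QuotaError as err:   # redraw the cohort deterministically
            last_err = err
    raise last_err


def _generate_cohort_once(config: CohortConfig, entropy,
                          run_config: RunConfig) -> list[SessionRecord]:
    ss = np.random.SeedSequence(entropy)
    rng = np.random.default_rng(ss.spawn(1)[0])

    counts = _exact_class_counts(config.n_participants, config.class_weights)
    classes = np.repeat(np.arange(1, 6), counts)
    classes = classes[rng.permutation(config.n_participants)]

    violate = {"obs": set(), "prepost_sbp": set(), "prepost_dbp": set()}
    short_participants: set[int] = set()
    if config.frac_short_participant > 0:
        k = int(round(config.frac_short_participant * config.n_participants))
        short_participants = set(
            rng.choice(config.n_participants, size=k, replace=False).tolist())

    sessions: list[SessionRecord] = []
    child_seeds = ss.spawn(config.n_participants)
    for pi in range(config.n_participants):
        pid = f"P{pi:03d}"
        pss = child_seeds[pi]
        prng = np.random.default_rng(pss.spawn(1)[0])
        profile = generate_participant(
            config, int(pss.generate_state(1)[0] % 2 ** 31),
            stiffness_class=int(classes[pi]),
            sex="female" if pi % 2 == 0 else "male",
            participant_id=pid)
        n_sessions = config.sessions_per_participant + (
            1 if pi < config.n_extra_sessions else 0)
        if pi in short_participants:
            n_sessions = 2
        for si in range(n_sessions):
            seed_rec = int(pss.generate_state(2)[1] % 2 ** 28) + si
            sbp_true = float(profile.bp_setpoint_sbp
                             + prng.normal(0, config.session_sbp_sd))
            dbp_true = float(profile.dbp_ratio * sbp_true + prng.normal(0, 1.5))
            dbp_true = min(dbp_true, sbp_true - 20.0)
            hr = float(np.clip(prng.normal(config.hr_mean, config.hr_sd), 45, 110))

            violations: set[str] = set()
            if pi in short_participants:
                violations.add("short_participant")
            obs_gap = None
            if prng.random() < config.frac_observer_disagreement:
                obs_gap = 6.0
                violations.add("observer_disagreement")
            sbp_b = sbp_true + prng.normal(0, config.prepost_drift_sd)
            dbp_b = dbp_true + prng.normal(0, config.prepost_drift_sd)
            sbp_a = sbp_true + prng.normal(0, config.prepost_drift_sd)
            dbp_a = dbp_true + prng.normal(0, config.prepost_drift_sd)
            if prng.random() < config.frac_prepost_sbp:
                sbp_a = sbp_b + 14.0
                violations.add("prepost_sbp")
            if prng.random() < config.frac_prepost_dbp:
                # 10 mmHg: drift must survive the even-mmHg recording grid
                dbp_a = dbp_b + 10.0
                violations.add("prepost_dbp")

            labels: set[str] = set()
            if prng.random() < config.artifact_fraction:
                labels.add(ARTIFACT_LABELS[int(prng.integers(0, 4))])
                violations.add("artifact")

            record = synthesize_record(profile, sbp_true, dbp_true, hr,
                                       config.duration_s, seed_rec,
                                       artifact_labels=labels, config=config,
                                       run_config=run_config)
            record.truth["violations"] = frozenset(violations)
            ref_b = _reference(prng, sbp_b, dbp_b, config.observer_noise_sd,
                               force_sbp_gap=obs_gap)
            ref_a = _reference(prng, sbp_a, dbp_a, config.observer_noise_sd)
            sessions.append(SessionRecord(
                participant_id=pid, session_id=f"{pid}S{si:02d}",
                ref_before=ref_b, device_record=record, ref_after=ref_a,
                true_sbp=sbp_true, true_dbp=dbp_true,
                true_ptt=profile.ptt_coefficient / sbp_true, true_hr=hr))
        for s in sessions[-n_sessions:]:
            s.device_record.truth["profile"] = profile
    return sessions


def _verify_quotas(sessions: list[SessionRecord]) -> None:
    from .protocol import DEFAULT_QUOTAS, audit_distribution, merge_observers
    rows = []
    for s in sessions:
        ref = merge_observers(s.ref_before)
        if not ref.valid:
            continue
        rows.append({"participant_id": s.participant_id, "sex": _sex_of(s),
                     "sbp": ref.merged_sbp, "dbp": ref.merged_dbp})
    import pandas as pd
    audit = audit_distribution(pd.DataFrame(rows), DEFAULT_QUOTAS)
    failed = audit.loc[~audit["passed"], "name"].tolist()
    if failed:
        raise QuotaError(f"cohort fails distribution quotas: {failed}")


def _sex_of(session: SessionRecord) -> str:
    profile = session.device_record.truth.get("profile")
    return profile.sex if profile is not None else "unknown"


def cohort_profiles(sessions: list[SessionRecord]) -> dict[str, ParticipantProfile]:
    """participant_id -> hidden profile (ground truth; test use only)."""
    out = {}
    for s in sessions:
        out[s.participant_id] = s.device_record.truth["profile"]
    return out
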