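"""Seeded synthetic intraoperative records with known ground truth.

The generator produces everything a downstream stage consumes — a 1 Hz
mean-arterial-pressure (MAP) trajectory, pulse-derived features (HR,
perfusion index PI, dicrotic-notch relative amplitude NRA) coupled to
MAP through the Ohm-Poiseuille model, beat-resolved PPG/ECG waveforms
at 125 Hz, and intermittent noisy cuff readings — so that every
pipeline stage is testable without any real cohort.

What the generator emulates, and how:

* MAP follows an Ornstein-Uhlenbeck (mean-reverting) process around a
  patient baseline with superimposed raised-cosine hypotension dips,
  clipped to the 40-160 mmHg operating range.
* Each patient carries slightly different mechanistic parameters
  (log-jitter on alpha, Gaussian offset on delta) and a slow "coupling
  drift" residual, so that pulse features alone do not determine MAP
  across patients and cuff calibration carries genuine information.
  Both effects vanish when ``feature_noise_sd`` is zero, making the
  mechanistic coupling exactly invertible in the noise-free setting.
* HR and PI are drawn as smooth stochastic processes; NRA is solved
  pointwise from the mechanistic identity, guaranteeing consistency.
* Cuff readings equal the concurrent arterial MAP plus Gaussian noise
  (mu = 0, sigma = 3.1 mmHg by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .mechanistic import MechanisticParams, mechanistic_predict
from .records import Channel, CuffEvent, PhysioRecord, WAVEFORM_FS

__all__ = [
    "SimParams",
    "GroundTruth",
    "SimFeatures",
    "ArtifactSpec",
    "simulate_map_trajectory",
    "simulate_latent_features",
    "synthesize_waveforms",
    "synthesize_cuff",
    "generate_record",
    "inject_artifacts",
    "DEFAULT_MECH_PARAMS",
]

#: Default ground-truth coupling.  With HR ~ 75 bpm, PI ~ 3 % and
#: NRA ~ 0.45 these place MAP near 80 mmHg and keep the pointwise NRA
#: solution inside (0, 1) across the 50-150 mmHg operating range.
DEFAULT_MECH_PARAMS = MechanisticParams(alpha=3.3, beta=0.2, beta_prime=0.1, delta=20.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic patient record.

    Units: seconds, mmHg, events/hour; rates in Hz.  The one-hour
    minimum record length and the 125 Hz waveform rate are fixed
    inclusion conventions of the study design.
    """

    duration_s: int = 3600
    map_baseline: float = 80.0  # mmHg
    map_reversion_rate: float = 1.0 / 300.0  # 1/s
    map_volatility: float = 0.5  # mmHg / sqrt(s)
    #: smoothing scale of the trajectory; arterial MAP has no appreciable
    #: sample-to-sample roughness at 1 Hz
    map_smooth_s: float = 4.0
    episode_rate: float = 2.0  # hypotension episodes / hour
    episode_depth: float = 10.0  # mmHg
    episode_duration_s: float = 300.0
    #: slow vasomotor (Mayer-wave-like) oscillation: amplitude expressed
    #: per unit volatility so a zero-volatility series stays constant
    mayer_amp_per_volatility: float = 3.0
    mayer_period_s: float = 30.0
    #: soft bound (in stationary sds) on OU excursions from baseline;
    #: emulates clinical intervention against sustained extremes
    map_excursion_bound_sd: float = 1.8
    cuff_interval_s: int = 300
    cuff_noise_mu: float = 0.0
    cuff_noise_sigma: float = 3.1
    true_mech_params: MechanisticParams = DEFAULT_MECH_PARAMS
    feature_noise_sd: float = 1.0  # mmHg-equivalent per sample
    #: stationary sd of the slow coupling-drift residual, expressed as a
    #: multiple of feature_noise_sd (0 when feature_noise_sd is 0)
    drift_noise_ratio: float = 3.0
    drift_tau_s: float = 600.0
    #: inter-patient variability of the mechanistic coupling: delta gets
    #: an independent Gaussian offset plus a component tracking the
    #: patient's resting baseline (keeping the NRA inversion in range)
    patient_delta_sd: float = 6.0  # mmHg, independent part
    patient_delta_baseline_coupling: float = 0.5
    patient_alpha_jitter: float = 0.10  # lognormal sd of alpha
    #: inter-patient spread of the resting MAP baseline (the cohorts'
    #: across-patient MAP dispersion is well above the within-record one)
    patient_baseline_sd: float = 10.0  # mmHg, clipped to [66, 105]
    waveform_fs: int = WAVEFORM_FS
    derived_fs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 3600:
            raise ValueError(
                f"duration_s={self.duration_s}: records shorter than one hour "
                "(3600 s) are excluded by the study's inclusion rule"
            )
        if self.cuff_interval_s <= 0:
            raise ValueError("cuff_interval_s must be positive")
        if self.cuff_noise_sigma < 0:
            raise ValueError("cuff_noise_sigma must be non-negative")
        if self.waveform_fs != WAVEFORM_FS:
            raise ValueError(f"waveform_fs must be {WAVEFORM_FS} Hz")


@dataclass
class GroundTruth:
    """Latent truth retained alongside a generated record."""

    map_1hz: np.ndarray
    beat_times: np.ndarray
    hr_latent: np.ndarray
    pi_latent: np.ndarray
    nra_latent: np.ndarray
    true_mech_params: MechanisticParams
    drift: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")


@dataclass
class SimFeatures:
    """Observed (noisy) and latent pulse-derived features at 1 Hz."""

    hr: np.ndarray
    pi: np.ndarray
    nra: np.ndarray
    hr_latent: np.ndarray
    pi_latent: np.ndarray
    nra_latent: np.ndarray
    #: MAP series exactly consistent with the latent features and the
    #: true parameters (differs from the requested MAP only where the
    #: NRA solution had to be clipped into (0, 1))
    map_consistent: np.ndarray

    def __iter__(self):
        return iter((self.hr, self.pi, self.nra))


def _ou_series(
    n: int,
    tau_s: float,
    stationary_sd: float,
    rng: np.random.Generator,
    start_at_stationary: bool = True,
) -> np.ndarray:
    """Zero-mean Ornstein-Uhlenbeck path at 1 Hz via its exact AR(1) form."""
    if stationary_sd == 0 or n == 0:
        return np.zeros(n)
    phi = float(np.exp(-1.0 / tau_s))
    eps_sd = stationary_sd * np.sqrt(1.0 - phi * phi)
    x0 = rng.normal(0.0, stationary_sd) if start_at_stationary else 0.0
    eps = rng.normal(0.0, eps_sd, size=n - 1)
    out = np.empty(n)
    out[0] = x0
    if n > 1:
        out[1:] = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])[0]
    return out


def simulate_map_trajectory(params: SimParams, seed=None) -> np.ndarray:
    """Simulate a 1 Hz intraoperative MAP trajectory.

    Mean-reverting (OU) dynamics around ``map_baseline`` with
    Poisson-arriving raised-cosine hypotension dips, clipped to the
    40-160 mmHg range.  A given (params, seed) pair always yields the
    identical series.
    """
    if params.duration_s <= 0:
        raise ValueError("duration_s must be positive to simulate a trajectory")
    rng = _as_rng(params.seed if seed is None else seed)
    n = int(params.duration_s)
    theta = params.map_reversion_rate
    if theta > 0:
        stat_sd = params.map_volatility / np.sqrt(2.0 * theta)
        tau = 1.0 / theta
    else:
        stat_sd = 0.0
        tau = np.inf
    dev = _ou_series(n, tau, stat_sd, rng)
    if params.map_excursion_bound_sd > 0 and stat_sd > 0:
        bound = params.map_excursion_bound_sd * stat_sd
        dev = bound * np.tanh(dev / bound)
    series = params.map_baseline + dev

    t = np.arange(n, dtype=np.float64)
    # phase drawn here to keep the stream layout stable
    mayer_amp = params.mayer_amp_per_volatility * params.map_volatility
    mayer_phase = rng.uniform(0.0, 2.0 * np.pi)

    n_episodes = rng.poisson(params.episode_rate * n / 3600.0) if params.episode_rate > 0 else 0
    # dips scale with the patient's pressure reserve above 50 mmHg, so
    # low-baseline patients have proportionally shallower episodes
    reserve = float(np.clip((params.map_baseline - 54.0) / 34.0, 0.0, 1.0))
    for _ in range(n_episodes):
        t0 = rng.uniform(0, n)
        dur = params.episode_duration_s * rng.uniform(0.5, 1.5)
        depth = params.episode_depth * rng.uniform(0.5, 1.5) * reserve
        inside = (t >= t0) & (t < t0 + dur)
        series[inside] -= depth * np.sin(np.pi * (t[inside] - t0) / dur) ** 2
    if params.map_smooth_s > 0:
        series = gaussian_filter1d(series, params.map_smooth_s, mode="nearest")
    if mayer_amp > 0:
        # added after smoothing: the oscillation is smooth by construction
        # and guarantees a floor on within-segment variability
        series = series + mayer_amp * np.sin(
            2.0 * np.pi * t / params.mayer_period_s + mayer_phase
        )
    return np.clip(series, 40.0, 160.0)


def simulate_latent_features(
    map_1hz: np.ndarray,
    true_mech_params: MechanisticParams,
    feature_noise_sd: float,
    seed=None,
    map_offset: np.ndarray | None = None,
    max_invalid_fraction: float = 0.05,
) -> SimFeatures:
    """Draw (HR, PI, NRA) at 1 Hz consistent with a MAP series.

    HR and PI are smooth free processes; NRA is solved pointwise from
    the mechanistic identity, so with ``feature_noise_sd=0`` the forward
    model applied to the latent features reproduces ``map_consistent``
    exactly.  Observation noise is allocated across the three features
    in proportion to their local sensitivities so that the induced MAP
    residual has standard deviation ~ ``feature_noise_sd`` mmHg.

    ``map_offset`` (optional, same length) is subtracted from the MAP
    series before inversion; :func:`generate_record` uses it to inject
    the slow coupling-drift residual.
    """
    rng = _as_rng(seed)
    map_1hz = np.asarray(map_1hz, dtype=np.float64)
    n = map_1hz.size
    p = true_mech_params
    if p.alpha <= 0:
        raise ValueError("true alpha must be positive to invert the coupling")
    if np.any(map_1hz <= 0) or np.any(map_1hz >= 200):
        raise ValueError("MAP values must lie in (0, 200) mmHg")

    target = map_1hz if map_offset is None else map_1hz - np.asarray(map_offset)

    # smooth latent HR and PI processes
    hr = 75.0 + _ou_series(n, 120.0, 8.0, rng)
    hr = gaussian_filter1d(hr, 5.0, mode="nearest")
    hr = np.clip(hr, 45.0, 135.0)
    log_pi = np.log(3.0) + _ou_series(n, 180.0, 0.25, rng)
    pi = np.clip(np.exp(gaussian_filter1d(log_pi, 5.0, mode="nearest")), 0.3, 15.0)

    log_term = np.log1p(1.0 / pi)
    denom = p.alpha * (log_term + p.beta) * hr
    if np.any(np.abs(denom) < 1e-9):
        raise ValueError("degenerate coupling: alpha*(ln(1+1/PI)+beta)*HR vanishes")
    nra = (target - p.delta) / denom - p.beta_prime
    invalid = (nra <= 0.0) | (nra >= 1.0)
    if invalid.mean() > max_invalid_fraction:
        raise ValueError(
            f"no NRA solution in (0,1) for {invalid.mean():.1%} of samples "
            f"(> {max_invalid_fraction:.0%}); parameters are inconsistent with "
            "the requested MAP range"
        )
    nra = np.clip(nra, 0.005, 0.995)
    map_consistent, _ = mechanistic_predict(hr, pi, nra, p)

    if feature_noise_sd > 0:
        # local sensitivities of MAP to each feature
        d_hr = p.alpha * (log_term + p.beta) * (nra + p.beta_prime)
        d_pi = -p.alpha * (nra + p.beta_prime) * hr / (pi * (pi + 1.0))
        d_nra = p.alpha * (log_term + p.beta) * hr
        budget = feature_noise_sd / np.sqrt(3.0)
        hr_obs = hr + rng.normal(0.0, 1.0, n) * budget / np.abs(d_hr)
        pi_obs = pi + rng.normal(0.0, 1.0, n) * budget / np.abs(d_pi)
        nra_obs = nra + rng.normal(0.0, 1.0, n) * budget / np.abs(d_nra)
        hr_obs = np.clip(hr_obs, 40.0, 140.0)
        pi_obs = np.clip(pi_obs, 0.11, 20.0)
        nra_obs = np.clip(nra_obs, 0.001, 1.0)
    else:
        hr_obs, pi_obs, nra_obs = hr.copy(), pi.copy(), nra.copy()

    return SimFeatures(hr_obs, pi_obs, nra_obs, hr, pi, nra, map_consistent)


# ---------------------------------------------------------------------------
# Beat-resolved waveform synthesis
# ---------------------------------------------------------------------------

# pulse-template phase landmarks (fractions of the beat period)
_PHI_PEAK = 0.25
_PHI_NOTCH = 0.55
_PHI_BUMP = 0.70


def _pulse_template(phi: np.ndarray, nra: float) -> np.ndarray:
    """Two-lobe pulse shape in [0, 1]: systolic lobe, dicrotic notch at
    relative height ``nra``, small dicrotic lobe, decay to the foot."""
    s = np.empty_like(phi)
    bump = nra + 0.12 * (1.0 - nra)
    m = phi < _PHI_PEAK
    s[m] = 0.5 * (1.0 - np.cos(np.pi * phi[m] / _PHI_PEAK))
    m = (phi >= _PHI_PEAK) & (phi < _PHI_NOTCH)
    s[m] = nra + (1.0 - nra) * 0.5 * (
        1.0 + np.cos(np.pi * (phi[m] - _PHI_PEAK) / (_PHI_NOTCH - _PHI_PEAK))
    )
    m = (phi >= _PHI_NOTCH) & (phi < _PHI_BUMP)
    s[m] = nra + (bump - nra) * 0.5 * (
        1.0 - np.cos(np.pi * (phi[m] - _PHI_NOTCH) / (_PHI_BUMP - _PHI_NOTCH))
    )
    m = phi >= _PHI_BUMP
    s[m] = bump * 0.5 * (1.0 + np.cos(np.pi * (phi[m] - _PHI_BUMP) / (1.0 - _PHI_BUMP)))
    return s


def synthesize_waveforms(
    hr_1hz: np.ndarray,
    pi_1hz: np.ndarray,
    nra_1hz: np.ndarray,
    seed=None,
    fs: int = WAVEFORM_FS,
    ppg_dc: float = 1.0,
    ecg_noise_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize beat-by-beat PPG and ECG at 125 Hz from 1 Hz features.

    Each beat places one pulse template on a DC baseline with its AC
    amplitude chosen so that 100 x (peak - foot) / beat-mean equals the
    target PI, and its notch at relative height NRA.  The ECG carries a
    unit R-spike at each beat onset plus low-amplitude noise.  Returns
    ``(ppg, ecg, beat_times)``.
    """
    rng = _as_rng(seed)
    hr_1hz = np.asarray(hr_1hz, dtype=np.float64)
    pi_1hz = np.asarray(pi_1hz, dtype=np.float64)
    nra_1hz = np.asarray(nra_1hz, dtype=np.float64)
    if not (hr_1hz.size == pi_1hz.size == nra_1hz.size):
        raise ValueError("feature series must share the same 1 Hz grid")
    if np.any(hr_1hz <= 0):
        raise ValueError("HR must be positive everywhere to place beats")
    n_s = hr_1hz.size
    total = n_s * fs
    ppg = np.full(total, ppg_dc)
    ecg = rng.normal(0.0, ecg_noise_sd, total)

    beat_times = []
    t = 0.0
    while t < n_s:
        sec = min(int(t), n_s - 1)
        period = 60.0 / hr_1hz[sec]
        i0 = int(round(t * fs))
        i1 = min(int(round((t + period) * fs)), total)
        if i1 - i0 >= 4:
            phi = np.arange(i1 - i0, dtype=np.float64) / (period * fs)
            s = _pulse_template(np.minimum(phi, 1.0), float(nra_1hz[sec]))
            pi_target = pi_1hz[sec]
            amp = pi_target * ppg_dc / (100.0 - pi_target * s.mean())
            ppg[i0:i1] = ppg_dc + amp * s
            ecg[i0] += 1.0
            if i0 + 1 < total:
                ecg[i0 + 1] += 0.4
            beat_times.append(t)
        t += period
    return ppg, ecg, np.asarray(beat_times)


def synthesize_cuff(
    map_1hz: np.ndarray,
    cuff_interval_s: int,
    mu: float = 0.0,
    sigma: float = 3.1,
    seed=None,
) -> list[CuffEvent]:
    """Place cuff events at t = 0, interval, 2*interval, ... <= duration.

    Each reading equals the concurrent arterial MAP plus N(mu, sigma^2)
    noise (the additive error model of oscillometric readings relative
    to the arterial line).
    """
    if cuff_interval_s <= 0:
        raise ValueError("cuff interval must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = _as_rng(seed)
    map_1hz = np.asarray(map_1hz, dtype=np.float64)
    n = map_1hz.size
    times = np.arange(0, n + 1, int(cuff_interval_s))
    events = []
    for t in times:
        base = map_1hz[min(int(t), n - 1)]
        value = base + (rng.normal(mu, sigma) if sigma > 0 else mu)
        events.append(CuffEvent(float(t), float(np.clip(value, 20.0, 250.0))))
    return events


def generate_record(params: SimParams) -> tuple[PhysioRecord, GroundTruth]:
    """Generate one complete synthetic patient record plus its truth.

    Component generators draw from independent child streams of
    ``params.seed``, so e.g. changing the cuff interval leaves the MAP
    trajectory and features bitwise unchanged (which makes calibration-
    distance sweeps exactly paired).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_map, rng_patient, rng_drift, rng_feat, rng_wave, rng_cuff = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    base = params.true_mech_params
    drift_sd = params.drift_noise_ratio * params.feature_noise_sd
    n = int(params.duration_s)
    drift = _ou_series(n, params.drift_tau_s, drift_sd, rng_drift)

    # patient-level draws in the tails can make the NRA inversion
    # infeasible for the realized trajectory; redraw the patient (same
    # dedicated stream, so the whole procedure stays a pure function of
    # the seed) rather than fail record generation
    feats = None
    for _attempt in range(20):
        alpha_p = base.alpha * float(
            np.exp(rng_patient.normal(0.0, params.patient_alpha_jitter))
        )
        baseline_p = params.map_baseline + float(
            rng_patient.normal(0.0, params.patient_baseline_sd)
        )
        baseline_p = float(np.clip(baseline_p, 66.0, 105.0))
        delta_p = (
            base.delta
            + params.patient_delta_baseline_coupling * (baseline_p - params.map_baseline)
            + float(rng_patient.normal(0.0, params.patient_delta_sd))
        )
        patient_params = MechanisticParams(alpha_p, base.beta, base.beta_prime, delta_p)
        map_raw = simulate_map_trajectory(replace(params, map_baseline=baseline_p), rng_map)
        try:
            feats = simulate_latent_features(
                map_raw,
                patient_params,
                params.feature_noise_sd,
                rng_feat,
                map_offset=drift,
            )
            break
        except ValueError:
            continue
    if feats is None:
        raise ValueError(
            "could not draw a patient with a feasible feature coupling for "
            f"seed {params.seed}; parameters are inconsistent with the MAP range"
        )
    # reference MAP kept exactly consistent with the latent coupling
    map_ref = feats.map_consistent + drift

    ppg, ecg, beat_times = synthesize_waveforms(
        feats.hr, feats.pi, feats.nra, rng_wave, fs=params.waveform_fs
    )
    cuffs = synthesize_cuff(
        map_ref, params.cuff_interval_s, params.cuff_noise_mu,
        params.cuff_noise_sigma, rng_cuff,
    )

    record = PhysioRecord(
        patient_id=f"synthetic-{params.seed:06d}",
        ppg=Channel.complete(ppg, params.waveform_fs),
        ecg=Channel.complete(ecg, params.waveform_fs),
        hr=Channel.complete(feats.hr, params.derived_fs),
        pi=Channel.complete(feats.pi, params.derived_fs),
        nra=Channel.complete(feats.nra, params.derived_fs),
        map_ref=Channel.complete(map_ref, params.derived_fs),
        cuff_events=cuffs,
        metadata={"device": "synthetic", "seed": params.seed},
    )
    truth = GroundTruth(
        map_1hz=map_ref,
        beat_times=beat_times,
        hr_latent=feats.hr_latent,
        pi_latent=feats.pi_latent,
        nra_latent=feats.nra_latent,
        true_mech_params=patient_params,
        drift=drift,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Artifact injection for quality-control testing
# ---------------------------------------------------------------------------

_ARTIFACT_KINDS = ("missing_run", "flatline", "level_shift", "spike_train")


@dataclass(frozen=True)
class ArtifactSpec:
    """One corruption to apply to a record channel.

    kind: missing_run | flatline | level_shift | spike_train.
    ``edge`` applies to level_shift: "hard" steps in instantaneously,
    "smooth" ramps in with a raised cosine over ``ramp_s`` seconds.
    """

    kind: str
    channel: str
    start_s: float
    length_s: float
    magnitude: float = 0.0
    edge: str = "hard"
    ramp_s: float = 60.0
    spike_period_s: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.length_s <= 0:
            raise ValueError("artifact length must be positive")


def inject_artifacts(
    record: PhysioRecord,
    artifact_spec: ArtifactSpec | list[ArtifactSpec],
    seed=None,
) -> PhysioRecord:
    """Return a copy of *record* with artifacts applied.

    Samples outside artifact windows are bitwise unchanged; an empty
    spec list returns an identical copy.  Missing samples are encoded
    in the channel's explicit missing mask.
    """
    specs = artifact_spec if isinstance(artifact_spec, list) else [artifact_spec]
    out = record.copy()
    for spec in specs:
        channels = out.channels()
        if spec.channel not in channels:
            raise ValueError(f"unknown channel {spec.channel!r}")
        ch = channels[spec.channel]
        fs = ch.fs
        i0 = int(round(spec.start_s * fs))
        i1 = int(round((spec.start_s + spec.length_s) * fs))
        if i0 < 0 or i1 > len(ch):
            raise ValueError(
                f"artifact window [{spec.start_s}, {spec.start_s + spec.length_s}) s "
                "falls outside the record"
            )
        if spec.kind == "missing_run":
            ch.missing[i0:i1] = True
        elif spec.kind == "flatline":
            ch.values[i0:i1] = ch.values[i0]
        elif spec.kind == "level_shift":
            if spec.edge == "smooth":
                ramp = max(1, int(round(spec.ramp_s * fs)))
                win = np.full(i1 - i0, spec.magnitude)
                k = min(ramp, i1 - i0)
                win[:k] = spec.magnitude * 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / ramp))
                ch.values[i0:i1] += win
            else:
                ch.values[i0:i1] += spec.magnitude
        elif spec.kind == "spike_train":
            step = max(1, int(round(spec.spike_period_s * fs)))
            ch.values[i0:i1:step] += spec.magnitude
    return out
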