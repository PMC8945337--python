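"""Synthetic multi-modal physiological cohort generator.

Emulates the study design the analysis pipeline expects: a cohort of
subjects, each recorded for ~50 min at a configurable sampling rate in two
conditions — after a caffeine oral film and after a placebo film — across
three modalities (ECG, electrodermal activity, respiration).

The caffeine effect is modelled pharmacokinetically as a two-compartment
Bateman absorption–elimination profile: a *free* fraction that absorbs
quickly plus a *microencapsulated* fraction that absorbs slowly, both
eliminated at a common first-order rate. The resulting dimensionless
effect curve e(t) modulates each modality:

* **ECG** — instantaneous heart rate is raised by a fractional gain
  ``alpha_ecg``; beats are synthesized as a fixed sum of five Gaussian
  bumps (P, Q, R, S, T) placed on the RR grid, with Gaussian RR jitter
  (``hrv_sd``) and additive white measurement noise. Window energy is then
  essentially proportional to the local beat rate.
* **EDA** — a tonic conductance level (slow random walk around
  ``eda_tonic``, raised slightly by ``beta_eda_tonic``·e) plus phasic
  skin-conductance responses: an inhomogeneous Bernoulli/Poisson event
  stream at rate ``scr_rate``·(1 + ``gamma_scr``·e) convolved with a
  biexponential (fast-rise, slow-decay) kernel, SCR amplitudes scaled by
  (1 + ``beta_eda_tonic``·e). Conductance is clipped at zero. Optionally a
  high-amplitude electrode-removal artifact is added to the final 5 min.
* **Respiration** — a quasi-sinusoid whose instantaneous frequency is
  ``resp_rate``·(1 + ``delta_resp``·e)/60 Hz, with a weak amplitude
  coupling (half the frequency gain), slow amplitude-modulation noise and
  comparatively strong additive noise — deliberately the least
  discriminable modality.

Default gains are chosen so the between-condition energy separation orders
ECG > EDA > respiration; they are generator dials, not physiological
claims.

Reproducibility: one master seed; every record draws from its own
``numpy.random.SeedSequence(master_seed, spawn_key=(subject_index,
stream))`` PCG64 stream, where ``stream`` 0 is the subject-parameter draw
and streams 1–6 enumerate condition × modality. Adding a subject therefore
never perturbs existing subjects, and identical config + seed reproduces
the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import signal as sps

from .io import SignalRecord

# ---------------------------------------------------------------------------
# Tunable generator constants (documented in docs/methods.md)
# ---------------------------------------------------------------------------

#: |ka - ke| below this switches the Bateman function to its ka -> ke limit.
BATEMAN_RATE_TOL = 1e-12

#: Reference effect scale: gains are fractional changes at effect = 1.
MAX_EFFECT_NORM = 1.0

#: Per-modality scaling of the effect curve (ECG strongest, RF weakest).
DEFAULT_MODALITY_SCALING = {"ECG": 1.0, "EDA": 0.6, "RF": 0.3}

ECG_NOISE_SD = 0.03  # mV, additive white measurement noise
EDA_NOISE_SD = 0.01  # microsiemens
EDA_DRIFT_SD = 0.3  # microsiemens, total tonic random-walk sd over a session
SCR_AMP_MEDIAN = 0.5  # microsiemens, median SCR amplitude
SCR_AMP_SIGMA = 0.4  # lognormal sigma of SCR amplitudes
SCR_RISE_S = 0.7  # biexponential kernel rise time constant
SCR_DECAY_S = 3.0  # and decay time constant
RESP_NOISE_SD = 0.35  # a.u., additive measurement noise
RESP_AM_DEPTH = 0.25  # slow amplitude-modulation depth
RESP_AM_TAU_S = 30.0  # correlation time of the amplitude modulation
ARTIFACT_NOISE_SD = 3.0  # microsiemens, electrode-removal burst in final 5 min
ARTIFACT_DURATION_MIN = 5.0

#: PQRST template: (offset from R in s, Gaussian width in s, amplitude in mV)
ECG_WAVES = (
    (-0.200, 0.045, 0.12),  # P
    (-0.035, 0.012, -0.14),  # Q
    (0.000, 0.018, 1.00),  # R
    (0.035, 0.014, -0.22),  # S
    (0.280, 0.070, 0.32),  # T
)

Seed = int | SeedSequence


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PKProfile:
    """Two-compartment Bateman release profile (free + encapsulated caffeine).

    Doses are in arbitrary effect units; rates in 1/min; ``lag`` (min) is
    the delay between film intake and the start of absorption. A placebo is
    represented by both doses equal to zero.
    """

    dose_free: float = 1.0
    dose_encapsulated: float = 1.0
    ka_free: float = 1.0
    ka_encapsulated: float = 0.02
    ke: float = 0.01
    lag: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka_free", "ka_encapsulated", "ke"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.ka_free <= self.ka_encapsulated:
            raise ValueError("ka_free must exceed ka_encapsulated (free absorbs faster)")
        if self.dose_free < 0 or self.dose_encapsulated < 0:
            raise ValueError("doses must be nonnegative")
        if self.lag < 0:
            raise ValueError("lag must be nonnegative")

    def scaled(self, factor: float) -> "PKProfile":
        """Copy with both doses multiplied by ``factor``."""
        return replace(
            self,
            dose_free=self.dose_free * factor,
            dose_encapsulated=self.dose_encapsulated * factor,
        )


PLACEBO_PK = PKProfile(dose_free=0.0, dose_encapsulated=0.0)


@dataclass
class SubjectParams:
    """Per-subject physiological baselines and effect sensitivities."""

    subject_id: str
    hr_baseline: float = 70.0  # beats/min
    hrv_sd: float = 40.0  # ms, Gaussian RR jitter
    eda_tonic: float = 5.0  # microsiemens
    scr_rate: float = 4.0  # events/min
    resp_rate: float = 15.0  # breaths/min
    effect_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_GAINS)
    )

    def __post_init__(self) -> None:
        if not 40.0 <= self.hr_baseline <= 200.0:
            raise ValueError(f"hr_baseline {self.hr_baseline} outside [40, 200] bpm")
        if not 6.0 <= self.resp_rate <= 30.0:
            raise ValueError(f"resp_rate {self.resp_rate} outside [6, 30] breaths/min")
        if self.eda_tonic < 0 or self.scr_rate < 0 or self.hrv_sd < 0:
            raise ValueError("eda_tonic, scr_rate and hrv_sd must be nonnegative")
        if any(v < 0 for v in self.effect_gains.values()):
            raise ValueError("effect gains must be nonnegative")


#: Dimensionless fractional gains at effect = MAX_EFFECT_NORM.
DEFAULT_EFFECT_GAINS = {
    "alpha_ecg": 0.15,  # fractional heart-rate increase
    "beta_eda_tonic": 0.08,  # fractional tonic-level and SCR-amplitude increase
    "gamma_scr": 0.4,  # fractional SCR-rate increase
    "delta_resp": 0.05,  # fractional breathing-rate increase
}


@dataclass
class CohortConfig:
    """Synthetic-study configuration: cohort size, recording and PK settings.

    ``duration_min`` is the analyzed post-intake span; each recording
    additionally starts with ``baseline_min`` of pre-intake baseline, as in
    the study protocol (film intake follows a baseline task). Amplitude
    normalization downstream runs over the whole recording while energy
    profiles are computed on the post-intake span, so the baseline anchors
    the per-record energy scale without contributing effect.
    """

    n_subjects: int = 13
    duration_min: float = 50.0
    baseline_min: float = 15.0
    fs: float = 1000.0
    pk: PKProfile = field(default_factory=PKProfile)
    modality_effect_scaling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_SCALING)
    )
    artifact_final_segment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.duration_min < 10.0:
            raise ValueError("duration_min must be at least 10 min")
        if self.baseline_min < 0:
            raise ValueError("baseline_min must be nonnegative")
        if self.fs < 60.0:
            raise ValueError("fs must be at least 60 Hz (2 x highest filter cutoff)")


# ---------------------------------------------------------------------------
# Pharmacokinetic effect model
# ---------------------------------------------------------------------------


def bateman_concentration(
    t: np.ndarray | float, dose: float, ka: float, ke: float
) -> np.ndarray | float:
    """Bateman absorption–elimination curve at time ``t`` (minutes).

    C(t) = dose * ka/(ka-ke) * (exp(-ke t) - exp(-ka t)); when
    |ka - ke| < BATEMAN_RATE_TOL the analytic limit dose * ka * t * exp(-ka t)
    is used. The result is nonnegative for t >= 0.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("rate constants ka and ke must be strictly positive")
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    if abs(ka - ke) < BATEMAN_RATE_TOL:
        out = dose * ka * t_arr * np.exp(-ka * t_arr)
    else:
        out = dose * ka / (ka - ke) * (np.exp(-ke * t_arr) - np.exp(-ka * t_arr))
    out = np.maximum(out, 0.0)  # guard against -0.0 / rounding at t ~ 0
    return float(out) if np.isscalar(t) else out


def bateman_tmax(ka: float, ke: float) -> float:
    """Closed-form peak time ln(ka/ke)/(ka-ke) of the Bateman curve (min)."""
    if abs(ka - ke) < BATEMAN_RATE_TOL:
        return 1.0 / ka
    return float(np.log(ka / ke) / (ka - ke))


def effect_profile(t_grid: np.ndarray, pk: PKProfile) -> np.ndarray:
    """Dimensionless caffeine-effect curve on a time grid (minutes).

    Sum of the free and encapsulated Bateman compartments, shifted by the
    absorption lag; identically zero before the lag and for a placebo
    profile (both doses zero).
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be nonnegative")
    if t_grid.size > 1 and np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted ascending")
    tau = np.maximum(t_grid - pk.lag, 0.0)
    effect = bateman_concentration(tau, pk.dose_free, pk.ka_free, pk.ke)
    effect = effect + bateman_concentration(
        tau, pk.dose_encapsulated, pk.ka_encapsulated, pk.ke
    )
    return np.where(t_grid < pk.lag, 0.0, effect)


# ---------------------------------------------------------------------------
# Per-modality simulators
# ---------------------------------------------------------------------------


def _check_grid(duration_min: float, fs: float, effect: np.ndarray) -> int:
    n_float = duration_min * 60.0 * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-6:
        raise ValueError(
            f"duration {duration_min} min at fs {fs} Hz is not a whole sample count"
        )
    if effect.shape != (n,):
        raise ValueError(
            f"effect array length {effect.shape} does not match the "
            f"{n}-sample duration grid"
        )
    return n


def simulate_ecg(
    duration_min: float,
    fs: float,
    subject: SubjectParams,
    effect: np.ndarray,
    seed: Seed,
    *,
    condition: str = "placebo",
    noise_sd: float = ECG_NOISE_SD,
    max_effect_norm: float = MAX_EFFECT_NORM,
) -> SignalRecord:
    """Template-based PQRST ECG with effect-modulated heart rate.

    Beat centers are quantized to the sample grid (an error of at most half
    a sample period, irrelevant to windowed energy).
    """
    effect = np.asarray(effect, dtype=np.float64)
    n = _check_grid(duration_min, fs, effect)
    rng = default_rng(seed)
    alpha = subject.effect_gains["alpha_ecg"]
    hr_t = subject.hr_baseline * (1.0 + alpha * effect / max_effect_norm)

    # one fixed PQRST template, placed at every beat center
    half_s = max(abs(o) + 4.0 * w for o, w, _ in ECG_WAVES)
    rel = np.arange(-int(np.ceil(half_s * fs)), int(np.ceil(half_s * fs)) + 1)
    t_rel = rel / fs
    template = np.zeros_like(t_rel)
    for offset, width, amp in ECG_WAVES:
        template += amp * np.exp(-0.5 * ((t_rel - offset) / width) ** 2)

    x = np.zeros(n)
    duration_s = n / fs
    jitter_sd_s = subject.hrv_sd / 1000.0
    t = float(rng.uniform(0.0, 60.0 / subject.hr_baseline))
    while t < duration_s:
        center = int(round(t * fs))
        lo, hi = center + rel[0], center + rel[-1] + 1
        a, b = max(lo, 0), min(hi, n)
        if a < b:
            x[a:b] += template[a - lo : b - lo]
        rr = 60.0 / hr_t[min(center, n - 1)]
        if jitter_sd_s > 0:
            rr += float(rng.normal(0.0, jitter_sd_s))
        t += max(rr, 0.25)  # refractory floor
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return SignalRecord(x, fs, "ECG", subject.subject_id, condition)


def _scr_kernel(fs: float) -> np.ndarray:
    """Biexponential SCR kernel (fast rise, slow decay), peak-normalized."""
    t = np.arange(0.0, 8.0 * SCR_DECAY_S, 1.0 / fs)
    k = np.exp(-t / SCR_DECAY_S) - np.exp(-t / SCR_RISE_S)
    return k / k.max()


def simulate_eda(
    duration_min: float,
    fs: float,
    subject: SubjectParams,
    effect: np.ndarray,
    seed: Seed,
    *,
    condition: str = "placebo",
    noise_sd: float = EDA_NOISE_SD,
    drift_sd: float = EDA_DRIFT_SD,
    artifact_final_segment: bool = False,
    max_effect_norm: float = MAX_EFFECT_NORM,
    return_events: bool = False,
) -> SignalRecord | tuple[SignalRecord, np.ndarray]:
    """Tonic + phasic skin conductance with effect-modulated SCR activity.

    With ``return_events`` the sample indices of the SCR events are
    returned alongside the record (useful for rate diagnostics).
    """
    effect = np.asarray(effect, dtype=np.float64)
    n = _check_grid(duration_min, fs, effect)
    rng = default_rng(seed)
    e = effect / max_effect_norm
    beta = subject.effect_gains["beta_eda_tonic"]
    gamma = subject.effect_gains["gamma_scr"]

    tonic = subject.eda_tonic * (1.0 + beta * e)
    if drift_sd > 0:
        tonic = tonic + np.cumsum(rng.normal(0.0, drift_sd / np.sqrt(n), n))

    # inhomogeneous event stream: per-sample Bernoulli with p = rate/fs.
    # A shared uniform array makes the realized event set monotone in rate.
    rate_per_sample = subject.scr_rate / 60.0 / fs * (1.0 + gamma * e)
    events = np.flatnonzero(rng.random(n) < rate_per_sample)
    phasic = np.zeros(n)
    if events.size:
        amps = rng.lognormal(np.log(SCR_AMP_MEDIAN), SCR_AMP_SIGMA, events.size)
        amps = amps * (1.0 + beta * e[events])
        impulses = np.zeros(n)
        np.add.at(impulses, events, amps)
        kernel = _scr_kernel(fs)
        phasic = sps.fftconvolve(impulses, kernel)[:n]

    x = tonic + phasic
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    if artifact_final_segment:
        m = min(n, int(round(ARTIFACT_DURATION_MIN * 60.0 * fs)))
        x[-m:] = x[-m:] + rng.normal(0.0, ARTIFACT_NOISE_SD, m)
    x = np.maximum(x, 0.0)  # conductance cannot be negative
    record = SignalRecord(x, fs, "EDA", subject.subject_id, condition)
    return (record, events) if return_events else record


def simulate_resp(
    duration_min: float,
    fs: float,
    subject: SubjectParams,
    effect: np.ndarray,
    seed: Seed,
    *,
    condition: str = "placebo",
    noise_sd: float = RESP_NOISE_SD,
    am_depth: float = RESP_AM_DEPTH,
    max_effect_norm: float = MAX_EFFECT_NORM,
) -> SignalRecord:
    """Quasi-sinusoidal respiration with effect-modulated breathing rate.

    The effect raises the instantaneous frequency by ``delta_resp``·e and
    the amplitude by half that gain — a weak, noise-dominated energy
    signature, matching respiration's role as the least discriminable
    modality.
    """
    effect = np.asarray(effect, dtype=np.float64)
    n = _check_grid(duration_min, fs, effect)
    rng = default_rng(seed)
    e = effect / max_effect_norm
    delta = subject.effect_gains["delta_resp"]

    f_inst = subject.resp_rate * (1.0 + delta * e) / 60.0  # Hz
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs

    amplitude = 1.0 + 0.5 * delta * e
    if am_depth > 0:
        # slow AM noise: white noise on a 1 s grid, smoothed over RESP_AM_TAU_S
        coarse = rng.normal(0.0, 1.0, max(int(np.ceil(n / fs)) + 2, 4))
        win = int(RESP_AM_TAU_S)
        smooth = np.convolve(coarse, np.ones(win) / win, mode="same")
        slow = np.interp(np.arange(n) / fs, np.arange(coarse.size), smooth)
        amplitude = amplitude * np.maximum(1.0 + am_depth * slow * np.sqrt(win), 0.2)

    x = amplitude * np.sin(phase)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return SignalRecord(x, fs, "RF", subject.subject_id, condition)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_MODALITIES = ("ECG", "EDA", "RF")
_CONDITIONS = ("caffeine", "placebo")


def draw_subject_params(rng: np.random.Generator, subject_id: str) -> SubjectParams:
    """Draw one subject's baselines from the documented cohort priors."""
    gains = {
        k: v * float(np.exp(rng.normal(0.0, 0.15)))
        for k, v in DEFAULT_EFFECT_GAINS.items()
    }
    return SubjectParams(
        subject_id=subject_id,
        hr_baseline=float(np.clip(rng.normal(70.0, 7.0), 50.0, 90.0)),
        hrv_sd=float(np.clip(rng.normal(40.0, 12.0), 10.0, 80.0)),
        eda_tonic=float(np.clip(rng.normal(5.0, 1.5), 1.0, 12.0)),
        scr_rate=float(np.clip(rng.normal(4.0, 1.0), 0.5, 8.0)),
        resp_rate=float(np.clip(rng.normal(15.0, 2.0), 9.0, 22.0)),
        effect_gains=gains,
    )


def _record_seed(master_seed: int, subject_index: int, stream: int) -> SeedSequence:
    # stream 0: subject params; 1..6: condition x modality simulators
    return SeedSequence(master_seed, spawn_key=(subject_index, stream))


def generate_cohort(config: CohortConfig) -> list[SignalRecord]:
    """Simulate the full cohort: n_subjects × 3 modalities × 2 conditions.

    The caffeine condition uses ``config.pk``; the placebo condition uses a
    zero-dose profile through the identical generation path.
    """
    total_min = config.baseline_min + config.duration_min
    n = int(round(total_min * 60.0 * config.fs))
    t_min = np.arange(n) / config.fs / 60.0
    # effect clock starts at film intake, i.e. after the baseline phase
    t_post_intake = np.maximum(t_min - config.baseline_min, 0.0)
    simulators = {"ECG": simulate_ecg, "EDA": simulate_eda, "RF": simulate_resp}

    records: list[SignalRecord] = []
    for i in range(config.n_subjects):
        subject = draw_subject_params(
            default_rng(_record_seed(config.seed, i, 0)), f"S{i + 1:02d}"
        )
        for ci, condition in enumerate(_CONDITIONS):
            pk = config.pk if condition == "caffeine" else PLACEBO_PK
            effect = effect_profile(t_post_intake, pk)
            if config.baseline_min > 0:
                effect[t_min < config.baseline_min] = 0.0
            for mi, modality in enumerate(_MODALITIES):
                eff_mod = effect * config.modality_effect_scaling[modality]
                seed = _record_seed(config.seed, i, 1 + ci * 3 + mi)
                kwargs = {"condition": condition}
                if modality == "EDA":
                    kwargs["artifact_final_segment"] = config.artifact_final_segment
                records.append(
                    simulators[modality](
                        total_min, config.fs, subject, eff_mod, seed, **kwargs
                    )
                )
    return records


def write_cohort(records: list[SignalRecord], out_dir, format: str = "csv") -> list:
    """Persist a cohort as one file per record (``<subject>_<modality>_<condition>``)."""
    from pathlib import Path

    from .io import write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "edf" if format == "edf" else "csv"
    paths = []
    for rec in records:
        name = f"{rec.subject_id}_{rec.modality}_{rec.condition}.{ext}"
        paths.append(write_recording(rec, out_dir / name, format=format))
    return paths
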