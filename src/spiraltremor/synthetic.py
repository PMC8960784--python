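"""Seeded synthetic spiral-drawing cohorts.

No raw recordings are distributed with the package, so every downstream
stage is exercised against synthetic sessions whose group-level feature
statistics emulate the published cohort: 18 controls and 17 ET subjects
(6 ET-0, 5 ET+1, 6 ET+2), with per-site mean PSD ratios, task times and
FTM severity scores matching the printed group means and SDs.

Signal model
------------
*Pen*: an Archimedes spiral r = a*theta traversed at constant angular rate
over the drawing duration, plus seeded band-limited (0.4–3.2 Hz) positional
wobble emulating voluntary speed fluctuations, with pen-up lead/trail
segments (pressure 0) before and after the drawing.

*Accelerometer*: voluntary component = second finite difference of the pen
trajectory mapped into the 3-D sensor frame (energy below 4 Hz), plus an
amplitude-modulated tremor sinusoid at a per-subject frequency inside the
4–12 Hz tremor band distributed across axes by a fixed unit orientation
vector, plus white noise, plus a constant gravity offset on one axis.

Per-subject feature targets (PSD ratio per site, task time) are drawn from
moment-matched truncated normals, and the injected tremor amplitude is
calibrated per site so the ratio *extracted by the analysis pipeline* hits
the drawn target.  Clinical FTM scores are drawn consistent with the
published bivariate severity model plus its residual scatter.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import signal as sps
from scipy import stats as sstats

from .errors import AliasingError, InvalidParameterError
from .features import highpass, psd_ratio, vector_magnitude
from .ingest import (
    GROUP_LABELS,
    SITES,
    AccelTrace,
    ClinicalRecord,
    PenTrace,
    segment_task,
    slice_accel,
    write_accel_csv,
    write_pen_csv,
)
from .stats import FTM_MAX, PUBLISHED_MODEL, predict_ftm

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"

#: Gravitational acceleration, m/s^2, added to the sensor z axis.
GRAVITY = 9.81

#: Fixed unit vectors mapping pen-plane accelerations and the tremor axis
#: into the sensor frame (tablet tilted relative to the sensor mounting).
_E1 = np.array([0.94, 0.0, 0.341])
_E1 = _E1 / np.linalg.norm(_E1)
_E2 = np.array([0.0, 0.94, 0.341])
_E2 = _E2 / np.linalg.norm(_E2)
_TREMOR_AXIS = np.array([0.45, 0.40, 0.80])
_TREMOR_AXIS = _TREMOR_AXIS / np.linalg.norm(_TREMOR_AXIS)

#: Minimum synthetic task time (s); shorter drawings cannot support the
#: 2 s spectral-estimation floor with margin.
MIN_TASK_TIME = 4.0

#: Residual SD (FTM points) of the published severity model, used when
#: drawing clinical scores consistent with it.
FTM_RESIDUAL_SD = 8.158

#: SD (FTM points) of per-rater scoring noise around the subject's latent
#: severity; chosen so blinded raters agree at r^2 around 0.95.
RATER_SD = 2.0


def _rng(seed: "SeedLike") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Group parameters (defaults reproduce the published cohort structure)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Target feature statistics for one phenotype group.

    ``mean_ratio_per_site`` / ``sd_ratio_per_site`` are ordered (S1, S2, S3):
    hand dorsum, mid-forearm, upper arm.  ``mean_ftm``/``sd_ftm`` are kept as
    reference statistics of the emulated cohort; generated clinical scores
    are drawn from the severity model rather than from these moments.
    """

    group_label: str
    n_subjects: int
    mean_ratio_per_site: tuple[float, float, float]
    sd_ratio_per_site: tuple[float, float, float]
    mean_task_time: float
    sd_task_time: float
    mean_ftm: float | None = None
    sd_ftm: float = 0.0

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise InvalidParameterError(f"unknown group label {self.group_label!r}")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if any(m < 0 for m in self.mean_ratio_per_site) or self.mean_task_time < 0:
            raise InvalidParameterError("group means must be non-negative")
        if any(s < 0 for s in self.sd_ratio_per_site) or self.sd_task_time < 0:
            raise InvalidParameterError("group SDs must be non-negative")


def default_group_params() -> list[GroupParams]:
    """The emulated cohort: 18 controls, 6 ET-0, 5 ET+1, 6 ET+2 with the
    published per-site PSD-ratio, task-time and FTM group statistics."""
    return [
        GroupParams(
            "control", 18, (0.55, 0.79, 0.81), (0.37, 1.12, 0.60), 12.64, 5.53
        ),
        GroupParams(
            "ET0", 6, (2.15, 2.84, 0.88), (1.66, 2.42, 1.14), 20.53, 14.23, 16.0, 9.2
        ),
        GroupParams(
            "ET1plus", 5, (3.90, 5.16, 0.97), (2.59, 5.59, 0.95), 19.82, 8.04, 20.4, 3.8
        ),
        GroupParams(
            "ET2plus", 6, (4.74, 6.96, 2.09), (1.82, 6.24, 2.59), 26.92, 14.95, 36.25, 12.24
        ),
    ]


@dataclass(frozen=True)
class TremorSpec:
    """Physical parameters of one synthetic tremor signal."""

    tremor_freq: float
    tremor_amplitude: float
    am_depth: float = 0.3
    am_rate: float = 0.5
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if not (4.0 < self.tremor_freq < 12.0):
            raise InvalidParameterError(
                "tremor_freq must lie strictly inside the 4-12 Hz tremor band"
            )
        if self.tremor_amplitude < 0:
            raise InvalidParameterError("tremor_amplitude must be >= 0")
        if not (0 <= self.am_depth < 1):
            raise InvalidParameterError("am_depth must lie in [0, 1)")
        if not (0 <= self.am_rate < 1):
            raise InvalidParameterError("am_rate must be < 1 Hz")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    """One generated session: pen trace, three accel traces, clinical record.

    ``targets`` records the drawn per-subject feature targets (psd_ratio per
    site, task_time, latent ftm) that the traces were calibrated to."""

    subject_id: str
    group_label: str
    pen: PenTrace
    accel_by_site: dict[str, AccelTrace]
    clinical: ClinicalRecord
    targets: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Moment-matched truncated normal
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=256)
def _matched_loc(mean: float, sd: float, lower: float) -> float:
    """Location parameter mu such that a normal(mu, sd) truncated below at
    ``lower`` has mean ``mean``.

    Printed group SDs exceed the means for several cells, so a plain normal
    would generate impossible negatives and naive truncation would bias the
    realised group means upward; matching the truncated mean keeps the
    generator centred on the configured value.
    """
    if mean <= lower:
        raise InvalidParameterError(
            f"target mean {mean} must exceed the truncation bound {lower}"
        )

    def gap(mu: float) -> float:
        a = (lower - mu) / sd
        return float(sstats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)) - mean

    lo = mean - 12.0 * sd
    hi = mean  # truncation only raises the mean, so gap(mean) >= 0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10 * max(1.0, sd)))


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float = 0.0,
    size=None,
):
    """Draw from a lower-truncated normal whose *truncated* mean equals ``mean``."""
    if sd == 0:
        if mean < lower:
            raise InvalidParameterError("degenerate draw below the truncation bound")
        return mean if size is None else np.full(size, mean)
    mu = _matched_loc(float(mean), float(sd), float(lower))
    a = (lower - mu) / sd
    draw = sstats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=size, random_state=rng)
    return float(draw) if size is None else draw


# ---------------------------------------------------------------------------
# Pen synthesis
# ---------------------------------------------------------------------------


def synth_spiral_pen(
    duration_drawing: float,
    n_turns: int = 3,
    fs_pen: float = 100.0,
    lead_pen_up: float = 1.0,
    seed: "SeedLike" = None,
    *,
    trail_pen_up: float | None = None,
    r_max_mm: float = 60.0,
    wobble_rms_mm: float = 1.0,
    wobble_band: tuple[float, float] = (0.4, 3.2),
) -> PenTrace:
    """Synthesize a spiral-drawing pen stream.

    The pen traverses an Archimedes spiral r = a*theta at constant angular
    rate for ``duration_drawing`` seconds (pressure > 0 exactly there), held
    stationary with pressure 0 for ``lead_pen_up`` seconds before and
    ``trail_pen_up`` (default: same) seconds after.  Band-limited positional
    wobble (RMS ``wobble_rms_mm``) emulates voluntary speed fluctuation in
    the 0.5-4 Hz band; it is cosine-ramped at both ends so the unwrapped
    spiral angle stays well defined near the origin.
    """
    if duration_drawing <= 0:
        raise InvalidParameterError("duration_drawing must be positive")
    if n_turns < 1:
        raise InvalidParameterError("n_turns must be >= 1")
    if fs_pen <= 0:
        raise InvalidParameterError("fs_pen must be positive")
    if lead_pen_up < 0:
        raise InvalidParameterError("lead_pen_up must be >= 0")
    if trail_pen_up is None:
        trail_pen_up = lead_pen_up
    rng = _rng(seed)

    n_down = int(round(duration_drawing * fs_pen))
    if n_down < 2:
        raise InvalidParameterError("drawing interval shorter than 2 pen samples")
    n_lead = int(round(lead_pen_up * fs_pen))
    n_trail = int(round(trail_pen_up * fs_pen))

    theta = np.linspace(0.0, 2.0 * np.pi * n_turns, n_down)
    a = r_max_mm / (2.0 * np.pi * n_turns)
    r = a * theta
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    if wobble_rms_mm > 0 and n_down > 30:
        f_hi = min(wobble_band[1], 0.45 * fs_pen)
        sos = sps.butter(2, (wobble_band[0], f_hi), btype="bandpass", fs=fs_pen, output="sos")
        raw = rng.standard_normal((n_down, 2))
        try:
            wob = sps.sosfiltfilt(sos, raw, axis=0)
        except ValueError:
            wob = np.zeros_like(raw)
        rms = wob.std(axis=0)
        rms[rms == 0] = 1.0
        wob = wob / rms * wobble_rms_mm
        # ramp the wobble in/out so angle unwrapping near r = 0 stays clean
        ramp_s = max(0.5, min(2.0, 0.2 * duration_drawing))
        n_ramp = min(int(round(ramp_s * fs_pen)), n_down // 2)
        window = np.ones(n_down)
        if n_ramp > 0:
            edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            window[:n_ramp] = edge
            window[-n_ramp:] = edge[::-1]
        wob *= window[:, None]
        x = x + wob[:, 0]
        y = y + wob[:, 1]

    # smooth, strictly positive pen pressure during drawing
    phase = rng.uniform(0, 2 * np.pi)
    pressure_down = 0.6 + 0.15 * np.sin(
        2 * np.pi * 0.2 * np.arange(n_down) / fs_pen + phase
    )

    x_all = np.concatenate([np.full(n_lead, x[0]), x, np.full(n_trail, x[-1])])
    y_all = np.concatenate([np.full(n_lead, y[0]), y, np.full(n_trail, y[-1])])
    p_all = np.concatenate([np.zeros(n_lead), pressure_down, np.zeros(n_trail)])
    n = x_all.size
    t = np.arange(n) / fs_pen
    return PenTrace(t=t, x=x_all, y=y_all, pressure=p_all, fs=fs_pen)


# ---------------------------------------------------------------------------
# Accelerometer synthesis
# ---------------------------------------------------------------------------


@dataclass
class _AccelComponents:
    """Cached building blocks of one accel trace; tremor amplitude enters
    only in :func:`_assemble`, so amplitude calibration is cheap."""

    t: np.ndarray
    voluntary: np.ndarray  # (n, 3)
    tremor_wave: np.ndarray  # (n,), unit amplitude, AM applied
    noise: np.ndarray  # (n, 3)
    fs: float
    site: str


def _accel_components(
    pen: PenTrace,
    spec: TremorSpec,
    fs: float,
    seed: "SeedLike",
    site: str,
    smooth_cutoff: float = 3.5,
) -> _AccelComponents:
    if fs <= 2.0 * spec.tremor_freq:
        raise AliasingError(
            f"fs={fs} Hz cannot represent a {spec.tremor_freq} Hz tremor"
        )
    if len(pen) < 2:
        raise InvalidParameterError("pen trace too short")
    rng = _rng(seed)

    span = float(pen.t[-1] - pen.t[0])
    n = int(np.floor(span * fs)) + 1
    t = pen.t[0] + np.arange(n) / fs

    # voluntary: second finite difference of the (interpolated) pen path,
    # mm -> m, optionally smoothed below the tremor band
    xp = np.interp(t, pen.t, pen.x) / 1000.0
    yp = np.interp(t, pen.t, pen.y) / 1000.0
    dt = 1.0 / fs
    ax_p = np.gradient(np.gradient(xp, dt), dt)
    ay_p = np.gradient(np.gradient(yp, dt), dt)
    if smooth_cutoff and smooth_cutoff < fs / 2:
        sos = sps.butter(4, smooth_cutoff, btype="lowpass", fs=fs, output="sos")
        try:
            ax_p = sps.sosfiltfilt(sos, ax_p)
            ay_p = sps.sosfiltfilt(sos, ay_p)
        except ValueError:
            pass
    voluntary = np.outer(ax_p, _E1) + np.outer(ay_p, _E2)

    phase_am = rng.uniform(0, 2 * np.pi)
    phase_tremor = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate * t + phase_am)
    tremor_wave = envelope * np.sin(2 * np.pi * spec.tremor_freq * t + phase_tremor)

    noise = rng.normal(0.0, spec.noise_sd, size=(n, 3)) if spec.noise_sd > 0 else np.zeros((n, 3))
    return _AccelComponents(t=t, voluntary=voluntary, tremor_wave=tremor_wave, noise=noise, fs=fs, site=site)


def _assemble(comp: _AccelComponents, amplitude: float) -> AccelTrace:
    acc = comp.voluntary + amplitude * np.outer(comp.tremor_wave, _TREMOR_AXIS) + comp.noise
    acc = acc.copy()
    acc[:, 2] += GRAVITY
    return AccelTrace(
        t=comp.t, ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2], site=comp.site, fs=comp.fs
    )


def synth_accel(
    pen: PenTrace,
    spec: TremorSpec,
    site_gain: float = 1.0,
    fs: float = 148.1,
    seed: "SeedLike" = None,
    *,
    site: str = "S2",
    smooth_cutoff: float = 3.5,
) -> AccelTrace:
    """Synthesize one accelerometer trace covering the pen-trace time span.

    The tremor sinusoid amplitude is ``spec.tremor_amplitude * site_gain``,
    so one subject-level tremor drives all three sites with site-specific
    gain.  Identical ``seed`` and parameters give bit-identical traces.
    """
    if site_gain <= 0:
        raise InvalidParameterError("site_gain must be positive")
    comp = _accel_components(pen, spec, fs, seed, site, smooth_cutoff=smooth_cutoff)
    return _assemble(comp, spec.tremor_amplitude * site_gain)


# ---------------------------------------------------------------------------
# Amplitude calibration
# ---------------------------------------------------------------------------


def calibrate_amplitude(target_ratio: float, voluntary, tremor_freq: float) -> float:
    """Tremor-sinusoid amplitude A whose addition to ``voluntary`` yields the
    target band-power ratio.

    Uses the band-power inversion A^2/2 = target * P_low - P_high, where
    P_low / P_high are the voluntary signal's band powers (a sinusoid of
    amplitude A contributes variance A^2/2, essentially all of it inside the
    tremor band for 4 < f < 12 Hz).
    """
    if target_ratio < 0:
        raise InvalidParameterError("target_ratio must be non-negative")
    if not (4.0 <= tremor_freq <= 12.0):
        raise InvalidParameterError("tremor_freq must lie in the 4-12 Hz band")
    if target_ratio == 0:
        return 0.0
    sig = voluntary if voluntary.filtered else highpass(voluntary)
    powers = psd_ratio(sig)  # raises if the low band is empty
    needed = target_ratio * powers.p_low - powers.p_high
    if needed <= 0:
        return 0.0
    return float(np.sqrt(2.0 * needed))


def _measured_ratio(comp: _AccelComponents, amplitude: float, window) -> float:
    trace = _assemble(comp, amplitude)
    segment = slice_accel(trace, window)
    return psd_ratio(highpass(vector_magnitude(segment))).ratio


def _calibrated_amplitude(
    comp: _AccelComponents,
    spec: TremorSpec,
    target: float,
    window,
    tol: float = 0.02,
    max_iter: int = 3,
) -> float:
    """Amplitude such that the pipeline-extracted ratio hits ``target``.

    The extracted ratio is r(A) = r0 + k*A^2 to excellent approximation
    (tremor power adds only to the high band), so a closed-form guess plus
    one or two secant corrections converges.
    Returns 0 when the target is below the tremor-free baseline r0.
    """
    r0 = _measured_ratio(comp, 0.0, window)
    if target <= r0:
        return 0.0
    # closed-form initial guess: project the tremor axis onto gravity (the
    # magnitude of g + a is g + a_z to first order) and fold in the AM power
    segment = slice_accel(_assemble(comp, 0.0), window)
    p_low0 = psd_ratio(highpass(vector_magnitude(segment))).p_low
    proj = abs(_TREMOR_AXIS[2])
    am_factor = 1.0 + 0.5 * spec.am_depth**2
    amp = float(np.sqrt(2.0 * (target - r0) * p_low0 / (proj**2 * am_factor)))
    for _ in range(max_iter):
        r = _measured_ratio(comp, amp, window)
        if abs(r - target) <= tol * target:
            break
        if r <= r0:
            break
        amp *= float(np.sqrt((target - r0) / (r - r0)))
    return amp


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def make_cohort(
    params: Sequence[GroupParams] | None = None,
    seed: "SeedLike" = 0,
    *,
    fs_accel: float = 148.1,
    fs_pen: float = 100.0,
    lead_pen_up: float = 1.0,
    n_turns: int = 3,
    tremor_freq_range: tuple[float, float] = (4.5, 11.5),
    am_depth: float = 0.3,
    am_rate: float = 0.5,
    noise_sd: float = 0.005,
    ftm_residual_sd: float = FTM_RESIDUAL_SD,
    rater_sd: float = RATER_SD,
) -> list[SyntheticSubject]:
    """Generate a full synthetic cohort (default: the emulated 35-subject study).

    Per subject: feature targets (task time; PSD ratio per site) are drawn
    from moment-matched truncated normals of the group's configured moments;
    a pen trace of that task time and three accel traces are generated with
    the per-site tremor amplitude calibrated so the extracted ratio hits the
    drawn target; clinical FTM is drawn from the published severity model
    applied to the drawn targets plus Gaussian residual, scored by two
    synthetic raters, and clipped to the FTM scale.  Tremor frequency is
    drawn uniformly inside the tremor band, away from its edges, once per
    subject.  Identical seed and parameters regenerate the cohort
    bit-identically.
    """
    if params is None:
        params = default_group_params()
    if len(params) == 0:
        raise InvalidParameterError("at least one group is required")
    ss = np.random.SeedSequence(
        seed if isinstance(seed, (int, np.integer)) else None
    ) if not isinstance(seed, np.random.SeedSequence) else seed
    if isinstance(seed, np.random.Generator):
        raise InvalidParameterError("make_cohort requires an int or SeedSequence seed")
    total = sum(g.n_subjects for g in params)
    children = ss.spawn(total)

    subjects: list[SyntheticSubject] = []
    idx = 0
    for group in params:
        for k in range(group.n_subjects):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            subject_id = f"{group.group_label}_{k + 1:02d}"

            task_time = float(
                truncated_normal(
                    rng, group.mean_task_time, group.sd_task_time, lower=MIN_TASK_TIME
                )
            )
            rho_targets = {
                site: float(
                    truncated_normal(
                        rng,
                        group.mean_ratio_per_site[i],
                        group.sd_ratio_per_site[i],
                        lower=0.0,
                    )
                )
                for i, site in enumerate(SITES)
            }
            tremor_freq = float(rng.uniform(*tremor_freq_range))

            pen_seed, *site_seeds = child.spawn(1 + len(SITES))
            pen = synth_spiral_pen(
                task_time,
                n_turns=n_turns,
                fs_pen=fs_pen,
                lead_pen_up=lead_pen_up,
                seed=pen_seed,
            )
            window = segment_task(pen)

            spec0 = TremorSpec(
                tremor_freq=tremor_freq,
                tremor_amplitude=0.0,
                am_depth=am_depth,
                am_rate=am_rate,
                noise_sd=noise_sd,
            )
            accel_by_site: dict[str, AccelTrace] = {}
            for site, site_seed in zip(SITES, site_seeds):
                comp = _accel_components(pen, spec0, fs_accel, site_seed, site)
                amp = _calibrated_amplitude(comp, spec0, rho_targets[site], window)
                accel_by_site[site] = _assemble(comp, amp)

            if group.group_label == "control":
                clinical = ClinicalRecord(subject_id, group.group_label)
                ftm_true = None
            else:
                ftm_true = predict_ftm(
                    PUBLISHED_MODEL, task_time, rho_targets["S2"]
                ) + rng.normal(0.0, ftm_residual_sd)
                ftm_true = float(np.clip(ftm_true, 0.0, FTM_MAX))
                r1, r2 = np.clip(
                    ftm_true + rng.normal(0.0, rater_sd, size=2), 0.0, FTM_MAX
                )
                clinical = ClinicalRecord(
                    subject_id, group.group_label, float(r1), float(r2)
                )

            subjects.append(
                SyntheticSubject(
                    subject_id=subject_id,
                    group_label=group.group_label,
                    pen=pen,
                    accel_by_site=accel_by_site,
                    clinical=clinical,
                    targets={
                        "task_time": task_time,
                        "psd_ratio": rho_targets,
                        "tremor_freq": tremor_freq,
                        "ftm_true": ftm_true,
                    },
                )
            )
    return subjects


def cohort_clinical_frame(subjects: Sequence[SyntheticSubject]) -> pd.DataFrame:
    """The clinical table (one row per subject) as written to cohort.csv."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group_label for s in subjects],
            "ftm_rater1": [s.clinical.ftm_rater1 for s in subjects],
            "ftm_rater2": [s.clinical.ftm_rater2 for s in subjects],
        }
    )


def write_cohort(subjects: Sequence[SyntheticSubject], outdir: str | Path) -> Path:
    """Write per-subject pen/accel CSVs plus the cohort clinical table.

    Layout: ``<id>_pen.csv`` (t, x, y, pressure), ``<id>_accel_<site>.csv``
    (t, ax, ay, az) and ``cohort.csv`` (subject_id, group, ftm_rater1,
    ftm_rater2).  Output is byte-stable for a fixed cohort.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_pen_csv(s.pen, outdir / f"{s.subject_id}_pen.csv")
        for site, trace in s.accel_by_site.items():
            write_accel_csv(trace, outdir / f"{s.subject_id}_accel_{site}.csv")
    cohort_clinical_frame(subjects).to_csv(
        outdir / "cohort.csv", index=False, float_format="%.10g"
    )
    return outdir
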