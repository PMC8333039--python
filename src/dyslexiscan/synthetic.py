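"""Synthetic labelled reading-trace cohorts.

The generator emulates the morphology of gaze x-coordinates recorded
while a child reads a short multi-line text:

* a low-risk (LR) trace is a near-ideal saw-tooth — one almost-linear
  left-to-right sweep per text line, ended by an instantaneous return
  sweep to the start of the next line, so the noiseless trace has
  exactly as many teeth as the text has lines;
* a high-risk (HR) trace is the same saw-tooth slowed down on average
  and disrupted by regressions: sudden backward jumps within a line
  followed by a forward re-read at normal speed.

Defaults mirror the study stimulus: 8 lines of on average 4.6 words,
sampled at 100 Hz.  Per-line sweep durations are log-normal (positive,
right-skewed); the group difference enters as a multiplicative slowdown
on HR line durations, so the reading-time distributions overlap — being
slow does not by itself make a reader high-risk.

Two control modes matter for experiments:

* *time-matched* (``hr_time_compensation=True`` with slowdown 1): HR
  line durations are shrunk by the expected re-reading overhead, so HR
  and LR traces have equal expected length but different shapes — used
  to show the spectrum carries information beyond reading time;
* *speed-only* (:func:`simulate_speed_dilated_cohort`): both classes
  share one generative process at a reference length and HR traces are
  pure time dilations of their reference waveform, so the classes
  differ in nothing but reading speed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import CohortManifest, Recording, manifest_from_cohort
from .errors import ValidationError
from .preprocess import dct_resample


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the package's study conditions."""

    n_lines: int = 8
    sample_rate_hz: float = 100.0
    words_per_line_mean: float = 4.6
    lr_line_duration_s: tuple[float, float] = (2.2, 0.55)  # (mean, sd), seconds
    hr_slowdown_factor: float = 1.5
    regression_rate_per_line: float = 1.5  # HR only; LR traces have none
    regression_span_frac: float = 0.3
    fixation_jitter_sd: float = 4.0
    eye_noise_sd: float = 1.5
    x_range: tuple[float, float] = (100.0, 900.0)
    tail_duration_s: float = 0.0  # optional non-reading tail after the last line
    hr_time_compensation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValidationError("n_lines must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.lr_line_duration_s[0] <= 0 or self.lr_line_duration_s[1] < 0:
            raise ValidationError("line duration mean must be > 0 and sd >= 0")
        if not 0.0 <= self.regression_span_frac <= 1.0:
            raise ValidationError("regression_span_frac must be in [0, 1]")
        if self.hr_slowdown_factor < 1.0:
            raise ValidationError("hr_slowdown_factor must be >= 1")
        if self.regression_rate_per_line < 0:
            raise ValidationError("regression_rate_per_line must be >= 0")
        if self.x_range[1] <= self.x_range[0]:
            raise ValidationError("x_range must satisfy x_end > x_start")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal samples parameterised by their distribution mean and sd."""
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _line_sweep(
    x_start: float,
    x_end: float,
    n_base: int,
    regression_positions: np.ndarray,
    span: float,
) -> np.ndarray:
    """One line's x-trajectory at constant forward speed.

    The sweep advances by ``width / n_base`` per sample; each regression
    jumps the gaze back by ``span`` (clipped at the line start) when it
    is first passed, after which reading resumes forward.  The final
    sample sits exactly at ``x_end`` (the tooth tip).
    """
    width = x_end - x_start
    step = width / n_base
    segments = []
    cur = x_start
    for p in np.sort(regression_positions):
        if p <= cur:
            continue
        n_seg = max(1, int(round((p - cur) / step)))
        segments.append(cur + step * np.arange(n_seg))
        cur = max(x_start, p - span)
    n_seg = max(1, int(round((x_end - cur) / step)))
    segments.append(cur + step * np.arange(n_seg))
    segments.append(np.array([x_end]))
    return np.concatenate(segments)


def simulate_trace(label: str, cfg: SimConfig, rng: np.random.Generator) -> Recording:
    """Generate one subject's :class:`Recording` (subject_id left generic)."""
    if label not in ("HR", "LR"):
        raise ValidationError(f"label must be 'HR' or 'LR', got {label!r}")
    x_start, x_end = cfg.x_range
    width = x_end - x_start
    span = cfg.regression_span_frac * width

    words = np.maximum(1, rng.poisson(cfg.words_per_line_mean, cfg.n_lines))
    mean_s, sd_s = cfg.lr_line_duration_s
    line_means = mean_s * words / cfg.words_per_line_mean
    line_sds = sd_s * line_means / mean_s
    if label == "HR":
        line_means = line_means * cfg.hr_slowdown_factor
        line_sds = line_sds * cfg.hr_slowdown_factor
        if cfg.hr_time_compensation:
            # remove the expected re-reading overhead so group lengths match
            comp = 1.0 + cfg.regression_rate_per_line * cfg.regression_span_frac
            line_means = line_means / comp
            line_sds = line_sds / comp
    durations = np.array(
        [_lognormal(rng, m, s, 1)[0] for m, s in zip(line_means, line_sds)]
    )

    rate = cfg.regression_rate_per_line if label == "HR" else 0.0
    lines = []
    for d in durations:
        n_base = max(2, int(round(d * cfg.sample_rate_hz)))
        k = rng.poisson(rate) if rate > 0 else 0
        positions = rng.uniform(x_start, x_end, k) if k else np.empty(0)
        lines.append(_line_sweep(x_start, x_end, n_base, positions, span))
    x = np.concatenate(lines)
    line_idx = np.repeat(np.arange(cfg.n_lines), [len(ln) for ln in lines])

    if cfg.fixation_jitter_sd > 0:
        x = x + rng.normal(0.0, cfg.fixation_jitter_sd, len(x))
    reading_end = len(x)

    if cfg.tail_duration_s > 0:
        n_tail = int(round(cfg.tail_duration_s * cfg.sample_rate_hz))
        wander = np.cumsum(rng.normal(0.0, width / 200.0, n_tail))
        x = np.concatenate([x, (x_start + x_end) / 2.0 + wander])
        line_idx = np.concatenate([line_idx, np.full(n_tail, cfg.n_lines - 1)])

    def eye_noise() -> np.ndarray:
        if cfg.eye_noise_sd > 0:
            return rng.normal(0.0, cfg.eye_noise_sd, len(x))
        return np.zeros(len(x))

    return Recording(
        subject_id=f"{label}-sim",
        label=label,
        lx=x + eye_noise(),
        rx=x + eye_noise(),
        ly=line_idx.astype(float),
        ry=line_idx.astype(float),
        reading_end_index=reading_end,
        sample_rate_hz=cfg.sample_rate_hz,
    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject stream independent of generation order
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _make_ids(n_hr: int, n_lr: int) -> list[tuple[str, str]]:
    out = [(f"HR{i:03d}", "HR") for i in range(1, n_hr + 1)]
    out += [(f"LR{i:03d}", "LR") for i in range(1, n_lr + 1)]
    return out


def simulate_cohort(
    n_hr: int, n_lr: int, cfg: SimConfig
) -> tuple[list[Recording], CohortManifest]:
    """Generate a labelled cohort, reproducible under ``cfg.seed``."""
    if n_hr < 1 or n_lr < 1:
        raise ValidationError("need at least one subject per class")
    cohort = []
    for index, (sid, label) in enumerate(_make_ids(n_hr, n_lr)):
        rec = simulate_trace(label, cfg, _subject_rng(cfg.seed, index))
        rec.subject_id = sid
        cohort.append(rec)
    return cohort, manifest_from_cohort(cohort)


def simulate_speed_dilated_cohort(
    n_hr: int, n_lr: int, cfg: SimConfig
) -> tuple[list[Recording], CohortManifest]:
    """Cohort whose classes differ in reading speed and nothing else.

    Every subject's waveform (noise included) is drawn from the same
    LR-morphology process at a reference length; HR subjects are then
    dilated in time by ``cfg.hr_slowdown_factor`` using the cosine-domain
    resampler, i.e. the identical waveform played out more slowly.
    Time-free representations of such a cohort carry no class
    information by construction; length-aware ones (zero padding,
    reading time) separate it easily.
    """
    if n_hr < 1 or n_lr < 1:
        raise ValidationError("need at least one subject per class")
    base_cfg = replace(cfg, regression_rate_per_line=0.0, hr_slowdown_factor=1.0)
    cohort = []
    for index, (sid, label) in enumerate(_make_ids(n_hr, n_lr)):
        rec = simulate_trace("LR", base_cfg, _subject_rng(cfg.seed, index))
        factor = cfg.hr_slowdown_factor if label == "HR" else 1.0
        m = max(rec.n_samples, int(round(rec.n_samples * factor)))
        lx = dct_resample(rec.lx, m) if m > rec.n_samples else rec.lx.copy()
        rx = dct_resample(rec.rx, m) if m > rec.n_samples else rec.rx.copy()
        cohort.append(
            Recording(
                subject_id=sid,
                label=label,
                lx=lx,
                rx=rx,
                ly=None,
                ry=None,
                reading_end_index=m,
                sample_rate_hz=cfg.sample_rate_hz,
            )
        )
    return cohort, manifest_from_cohort(cohort)


def count_teeth(x: np.ndarray, drop_frac: float = 0.5) -> int:
    """Count saw-tooth cycles: large downward resets, plus a final tooth
    if the trace ends near the line end (the last line has no return)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0
    rng_x = x.max() - x.min()
    if rng_x == 0:
        return 0
    drops = int(np.sum(np.diff(x) < -drop_frac * rng_x))
    if x[-1] - x.min() > drop_frac * rng_x:
        drops += 1
    return drops
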