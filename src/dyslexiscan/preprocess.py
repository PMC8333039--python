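"""Signal pre-processing and the four fixed-length representations.

The classifier needs fixed-length inputs, while reading traces vary in
length with reading speed.  Two length-normalisation routes are provided,
each in a time-domain and a magnitude-spectrum flavour:

``TIME_ZEROPAD``
    the trimmed x-trace padded with trailing zeros to the cohort target
    length ``N`` (the number of padded zeros implicitly encodes reading
    time);
``SPEC_ZEROPAD``
    magnitude spectrum of the zero-padded trace;
``TIME_INTERP``
    the trace resampled to length ``N`` with harmonic (cosine-basis)
    interpolation, which removes reading-time information and keeps only
    the waveform shape, optionally rescaled by the length ratio ``M/N``;
``SPEC_INTERP``
    magnitude spectrum of the interpolated trace.

Spectra exclude the DC bin (it encodes only the horizontal text centre)
and keep the non-redundant first half, bins ``1 .. floor(N/2)``.

The resampler works in the domain of the orthonormal cosine transform:
a signal of length ``M`` is analysed into ``M`` cosine coefficients,
the coefficient vector is zero-extended to the target length ``N``, and
the result is synthesised with the length-``N`` DCT-III basis

    U[k, n] = sqrt(2/N) * c_n * cos(pi * (2k+1) * n / (2N)),

with ``c_0 = 1/sqrt(2)`` and ``c_n = 1`` otherwise, which makes ``U``
orthonormal.  A final ``sqrt(N/M)`` amplitude renormalisation makes the
operation shape-preserving (a constant maps to the same constant), i.e.
a pure time dilation of the underlying waveform.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import dct, idct

from .datamodel import PreparedSignal, Recording
from .errors import ValidationError


class Branch(str, enum.Enum):
    """The four representation branches."""

    TIME_ZEROPAD = "TIME_ZEROPAD"
    SPEC_ZEROPAD = "SPEC_ZEROPAD"
    TIME_INTERP = "TIME_INTERP"
    SPEC_INTERP = "SPEC_INTERP"

    @property
    def is_spectral(self) -> bool:
        return self in (Branch.SPEC_ZEROPAD, Branch.SPEC_INTERP)

    @property
    def is_interpolated(self) -> bool:
        return self in (Branch.TIME_INTERP, Branch.SPEC_INTERP)


#: Recognised amplitude-correction modes for the interpolated branches.
ENERGY_CORRECTIONS = ("ratio", "sqrt_ratio", "none")


@dataclass
class Dct3Basis:
    """Explicit DCT-III synthesis basis (rows: samples k, columns: harmonics n)."""

    N: int
    U: np.ndarray
    c: np.ndarray

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Reconstruct a length-``N`` signal from cosine coefficients."""
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.N,):
            raise ValidationError(f"expected {self.N} coefficients, got {coeffs.shape}")
        return self.U @ coeffs


@dataclass
class Representation:
    """A fixed-length feature vector for one subject under one branch."""

    subject_id: str
    label: str
    branch: Branch
    values: np.ndarray
    target_length: int
    original_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (
            self.target_length // 2
            if Branch(self.branch).is_spectral
            else self.target_length
        )
        if len(self.values) != expected:
            raise ValidationError(
                f"branch {self.branch} expects length {expected}, "
                f"got {len(self.values)}"
            )


def average_eyes(rec: Recording) -> np.ndarray:
    """Element-wise mean of the left- and right-eye x-traces.

    There is no evidence the two eyes scan differently in at-risk readers,
    and averaging halves noise without losing the reading pattern.
    """
    if len(rec.lx) != len(rec.rx):
        raise ValidationError("lx and rx must have equal length")
    return (rec.lx + rec.rx) / 2.0


def trim_to_reading(x: np.ndarray, reading_end_index: int) -> np.ndarray:
    """Keep only the active reading part, ``x[0:reading_end_index]``."""
    x = np.asarray(x, dtype=float)
    if not 0 < reading_end_index <= len(x):
        raise ValidationError(
            f"reading_end_index={reading_end_index} out of range (0, {len(x)}]"
        )
    return x[:reading_end_index].copy()


def prepare_signal(rec: Recording) -> PreparedSignal:
    """Average the eyes and trim to active reading (y-traces are dropped)."""
    x = trim_to_reading(average_eyes(rec), rec.reading_end_index)
    return PreparedSignal(
        subject_id=rec.subject_id,
        label=rec.label,
        x=x,
        original_length=rec.reading_end_index,
        sample_rate_hz=rec.sample_rate_hz,
    )


def zero_pad(x: np.ndarray, N: int) -> np.ndarray:
    """Extend ``x`` to length ``N`` with trailing zeros (bit-exact prefix)."""
    x = np.asarray(x, dtype=float)
    M = len(x)
    if N < M:
        raise ValidationError(f"target length N={N} < signal length M={M}")
    out = np.zeros(N, dtype=float)
    out[:M] = x
    return out


def dct3_basis(N: int) -> Dct3Basis:
    """Build the orthonormal DCT-III basis matrix of size ``N`` x ``N``."""
    if N < 1:
        raise ValidationError("basis size N must be >= 1")
    k = np.arange(N)[:, None]  # sample index
    n = np.arange(N)[None, :]  # harmonic index
    c = np.ones(N)
    c[0] = 1.0 / np.sqrt(2.0)
    U = np.sqrt(2.0 / N) * c[None, :] * np.cos(np.pi * (2 * k + 1) * n / (2 * N))
    return Dct3Basis(N=N, U=U, c=c)


def cosine_analysis(x: np.ndarray) -> np.ndarray:
    """Orthonormal cosine analysis coefficients of ``x`` (Parseval-exact)."""
    return dct(np.asarray(x, dtype=float), type=2, norm="ortho")


def dct_resample(x: np.ndarray, N: int, allow_downsample: bool = False) -> np.ndarray:
    """Resample ``x`` (length ``M``) to length ``N`` in the cosine domain.

    Upsampling zero-extends the analysis coefficients; downsampling (only
    with ``allow_downsample=True``) truncates them.  The ``sqrt(N/M)``
    renormalisation preserves amplitude, so a constant signal of value
    ``a`` maps to a constant of value ``a`` and ``N == M`` is the
    identity.
    """
    x = np.asarray(x, dtype=float)
    M = len(x)
    if M < 2:
        raise ValidationError("signal must have at least 2 samples")
    if N < 2:
        raise ValidationError("target length must be >= 2")
    if N < M and not allow_downsample:
        raise ValidationError(f"target length N={N} < signal length M={M}")
    if N == M:
        return x.copy()
    coeffs = cosine_analysis(x)
    if N > M:
        coeffs = np.concatenate([coeffs, np.zeros(N - M)])
    else:
        coeffs = coeffs[:N]
    return idct(coeffs, type=2, norm="ortho") * np.sqrt(N / M)


def energy_correct(
    x_resampled: np.ndarray, M: int, N: int | None = None, mode: str = "ratio"
) -> np.ndarray:
    """Rescale a resampled signal by the original/modified length ratio.

    ``mode='ratio'`` multiplies by ``M/N`` (the default, the literal
    length ratio), ``'sqrt_ratio'`` by ``sqrt(M/N)`` (exact energy
    preservation for an orthonormal resampler), ``'none'`` leaves the
    amplitude-preserving resampler output untouched.  Note that any
    length-dependent rescaling re-injects reading-time information into
    the otherwise time-free interpolated representation (see the methods
    note).
    """
    x_resampled = np.asarray(x_resampled, dtype=float)
    if N is None:
        N = len(x_resampled)
    if not 1 <= M:
        raise ValidationError("original length M must be >= 1")
    if mode not in ENERGY_CORRECTIONS:
        raise ValidationError(
            f"unknown energy correction {mode!r}; expected one of {ENERGY_CORRECTIONS}"
        )
    if mode == "none":
        return x_resampled.copy()
    r = M / N
    if mode == "sqrt_ratio":
        r = np.sqrt(r)
    return x_resampled * r


def magnitude_spectrum(x: np.ndarray) -> np.ndarray:
    """|DFT| at bins ``1 .. floor(N/2)`` (DC excluded, Nyquist kept for even N).

    The DC bin carries only the horizontal centre of the text on screen,
    and the second half of the spectrum of a real signal is the mirror
    image of the first, so both are dropped.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    if N < 2:
        raise ValidationError("signal must have at least 2 samples")
    return np.abs(np.fft.rfft(x))[1 : N // 2 + 1]


def build_representation(
    sig: PreparedSignal,
    branch: Branch | str,
    N: int,
    energy_correction: str = "ratio",
) -> Representation:
    """Dispatch a prepared signal through one of the four branches.

    ``N`` is the cohort target length (the slowest reader's trimmed
    length).  For the interpolated branches a signal longer than ``N``
    (possible when ``N`` was fixed on training data only) is resampled
    down by coefficient truncation; the zero-padding branches reject it.
    """
    try:
        branch = Branch(branch)
    except ValueError as exc:
        raise ValidationError(f"unknown branch {branch!r}") from exc
    M = sig.original_length
    if branch.is_interpolated:
        y = dct_resample(sig.x, N, allow_downsample=True)
        y = energy_correct(y, M=M, N=N, mode=energy_correction)
    else:
        y = zero_pad(sig.x, N)
    if branch.is_spectral:
        y = magnitude_spectrum(y)
    return Representation(
        subject_id=sig.subject_id,
        label=sig.label,
        branch=branch,
        values=y,
        target_length=N,
        original_length=M,
    )


def representation_length(branch: Branch | str, N: int) -> int:
    """Feature-vector length of *branch* at cohort target length ``N``."""
    return N // 2 if Branch(branch).is_spectral else N


def build_cohort_representations(
    signals: list[PreparedSignal],
    branch: Branch | str,
    N: int | None = None,
    energy_correction: str = "ratio",
) -> list[Representation]:
    """Represent every signal; ``N`` defaults to the slowest reader's length."""
    if not signals:
        raise ValidationError("no signals given")
    if N is None:
        N = max(s.original_length for s in signals)
    return [build_representation(s, branch, N, energy_correction) for s in signals]


def write_representations(reps: list[Representation], directory: str) -> str:
    """Persist one branch's representations: a matrix ``.npy`` + sidecar CSV."""
    if not reps:
        raise ValidationError("no representations to write")
    branches = {Branch(r.branch) for r in reps}
    if len(branches) != 1:
        raise ValidationError("all representations must share one branch")
    branch = branches.pop()
    os.makedirs(directory, exist_ok=True)
    mat = np.vstack([r.values for r in reps])
    np.save(os.path.join(directory, f"{branch.value}.npy"), mat)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reps],
            "label": [r.label for r in reps],
            "original_length": [r.original_length for r in reps],
            "branch": [branch.value] * len(reps),
            "target_length": [r.target_length for r in reps],
        }
    ).to_csv(os.path.join(directory, f"{branch.value}.csv"), index=False)
    return os.path.join(directory, f"{branch.value}.npy")
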