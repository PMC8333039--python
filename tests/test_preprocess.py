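import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyslexiscan import (
    Branch,
    PreparedSignal,
    ValidationError,
    build_representation,
    dct3_basis,
    dct_resample,
    energy_correct,
    magnitude_spectrum,
    zero_pad,
)
from dyslexiscan.preprocess import cosine_analysis, representation_length

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# cosine basis and resampling


@pytest.mark.parametrize("N", [1, 2, 3, 4, 8, 16, 33, 64])
def test_dct3_basis_orthonormal(N):
    """U @ U.T == identity within 1e-10 for every basis size."""
    b = dct3_basis(N)
    assert np.abs(b.U @ b.U.T - np.eye(N)).max() < 1e-10


def test_dct3_basis_forced_values():
    assert dct3_basis(1).U[0, 0] == pytest.approx(1.0)
    # sqrt(2/2) * 1 * cos(pi/4)
    assert dct3_basis(2).U[0, 1] == pytest.approx(0.7071067811865476, abs=1e-15)


def test_dct3_basis_rejects_bad_size():
    with pytest.raises(ValidationError):
        dct3_basis(0)


def test_resample_agrees_with_explicit_basis_synthesis(rng):
    """The fast transform path equals direct synthesis with the basis matrix."""
    x = rng.normal(size=9)
    N = 17
    coeffs = np.concatenate([cosine_analysis(x), np.zeros(N - len(x))])
    direct = dct3_basis(N).synthesize(coeffs) * np.sqrt(N / len(x))
    np.testing.assert_allclose(dct_resample(x, N), direct, atol=1e-10)


def test_resample_constant_preservation():
    np.testing.assert_allclose(
        dct_resample(np.full(3, 5.0), 6), np.full(6, 5.0), atol=1e-10
    )


@given(st.integers(2, 40))
def test_resample_identity_at_equal_length(n):
    x = np.random.default_rng(n).normal(size=n)
    np.testing.assert_allclose(dct_resample(x, n), x, atol=1e-10)


def test_resample_single_mode_oracle():
    """A pure first-harmonic input resamples to the stretched first harmonic.

    Up to the amplitude renormalisation, only one analysis coefficient is
    active, so the output must be that one basis function of the longer
    basis evaluated densely.
    """
    M, N = 8, 16
    k = np.arange(M)
    x = np.cos(np.pi * (2 * k + 1) * 1 / (2 * M))
    coeff = cosine_analysis(x)
    assert np.abs(coeff[2:]).max() < 1e-12  # single active mode (n=1)
    kN = np.arange(N)
    expected = np.cos(np.pi * (2 * kN + 1) * 1 / (2 * N))  # same harmonic, stretched
    out = dct_resample(x, N)
    # compare shape: normalise both to unit maximum amplitude
    np.testing.assert_allclose(
        out / np.abs(out).max(), expected / np.abs(expected).max(), atol=1e-10
    )


def test_resample_rejects_shrink_without_flag(rng):
    with pytest.raises(ValidationError):
        dct_resample(rng.normal(size=10), 5)
    out = dct_resample(np.full(10, 3.0), 5, allow_downsample=True)
    np.testing.assert_allclose(out, np.full(5, 3.0), atol=1e-10)


@given(st.integers(2, 30), st.integers(0, 2**31 - 1))
def test_parseval_for_cosine_analysis(n, seed):
    x = np.random.default_rng(seed).normal(size=n)
    c = cosine_analysis(x)
    assert np.sum(c**2) == pytest.approx(np.sum(x**2), abs=1e-10)


# ---------------------------------------------------------------------------
# zero padding, energy correction, magnitude spectrum


@given(st.integers(1, 20), st.integers(0, 10))
def test_zero_pad_prefix_bitexact_and_zero_tail(m, extra):
    x = np.random.default_rng(m * 31 + extra).normal(size=m)
    out = zero_pad(x, m + extra)
    assert (out[:m] == x).all()
    assert (out[m:] == 0).all()


def test_zero_pad_rejects_shrink():
    with pytest.raises(ValidationError):
        zero_pad(np.ones(5), 4)


def test_energy_correct_ratio_modes():
    x = np.full(6, 5.0)
    np.testing.assert_allclose(energy_correct(x, M=3), np.full(6, 2.5))
    np.testing.assert_allclose(energy_correct(x, M=6), x)
    np.testing.assert_allclose(energy_correct(np.zeros(6), M=3), np.zeros(6))
    np.testing.assert_allclose(
        energy_correct(x, M=3, mode="sqrt_ratio"), np.full(6, 5.0 / np.sqrt(2))
    )
    np.testing.assert_allclose(energy_correct(x, M=3, mode="none"), x)
    with pytest.raises(ValidationError):
        energy_correct(x, M=3, mode="bogus")


def test_magnitude_spectrum_impulse():
    # |DFT| of a unit impulse is flat; DC excluded leaves bins 1..2
    np.testing.assert_allclose(magnitude_spectrum([1, 0, 0, 0]), [1.0, 1.0])


def test_magnitude_spectrum_constant_is_zero():
    np.testing.assert_allclose(magnitude_spectrum(np.full(4, 3.3)), [0.0, 0.0])


@given(st.integers(2, 50), st.integers(0, 2**31 - 1))
def test_magnitude_spectrum_against_full_dft(n, seed):
    """Conjugate symmetry: kept bins equal the magnitudes at mirrored bins N-k,
    and the ell-1 bound |X_k| <= sum|x| holds."""
    x = np.random.default_rng(seed).normal(size=n)
    spec = magnitude_spectrum(x)
    full = np.abs(np.fft.fft(x))
    assert len(spec) == n // 2
    np.testing.assert_allclose(spec, full[1 : n // 2 + 1], atol=1e-10)
    mirrored = full[[n - k for k in range(1, n // 2 + 1)]]
    np.testing.assert_allclose(spec, mirrored, atol=1e-8)
    assert spec.max() <= np.abs(x).sum() + 1e-10


def test_magnitude_spectrum_circular_shift_invariance(rng):
    x = rng.normal(size=32)
    np.testing.assert_allclose(
        magnitude_spectrum(x), magnitude_spectrum(np.roll(x, 7)), atol=1e-10
    )


# ---------------------------------------------------------------------------
# representation dispatch


def _sig(x, sid="S", label="LR"):
    x = np.asarray(x, dtype=float)
    return PreparedSignal(subject_id=sid, label=label, x=x, original_length=len(x))


def test_time_zeropad_dispatch():
    rep = build_representation(_sig([1.0, 2.0, 3.0]), Branch.TIME_ZEROPAD, N=5)
    np.testing.assert_array_equal(rep.values, [1, 2, 3, 0, 0])
    assert rep.original_length == 3


@pytest.mark.parametrize("branch", list(Branch))
def test_representation_lengths_and_nonnegativity(branch, rng):
    sig = _sig(rng.normal(size=37) + 300.0)
    rep = build_representation(sig, branch, N=100)
    assert len(rep.values) == representation_length(branch, 100)
    if branch.is_spectral:
        assert (rep.values >= 0).all()


def test_unknown_branch_rejected(rng):
    with pytest.raises(ValidationError):
        build_representation(_sig(rng.normal(size=10)), "TIME_BOGUS", N=20)


def test_interp_branch_matches_pure_time_dilation(rng):
    """Two signals that are the same waveform at different reading speeds
    map to the same interpolated representation (amplitude rescaling off)."""
    base = rng.normal(size=40).cumsum() + 500.0
    slow = dct_resample(base, 60)  # the same waveform read more slowly
    N = 90
    r1 = build_representation(_sig(base), Branch.TIME_INTERP, N, energy_correction="none")
    r2 = build_representation(_sig(slow), Branch.TIME_INTERP, N, energy_correction="none")
    np.testing.assert_allclose(r1.values, r2.values, atol=1e-6)
    s1 = build_representation(_sig(base), Branch.SPEC_INTERP, N, energy_correction="none")
    s2 = build_representation(_sig(slow), Branch.SPEC_INTERP, N, energy_correction="none")
    np.testing.assert_allclose(s1.values, s2.values, atol=1e-6)
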