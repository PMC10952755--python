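"""Shared fixtures: the liver-protocol pulse, slice geometry and ratio LUT
are session-scoped because the Bloch LUT build is the single most expensive
shared ingredient."""

import numpy as np
import pytest

from b1dam.bloch import SliceSelection, TissueParams
from b1dam.lut import build_ratio_lut
from b1dam.pulses import make_hws_pulse


@pytest.fixture(scope="session")
def pulse():
    """The 3.2 ms Hamming-windowed sinc with 0.55 ms FWHM."""
    return make_hws_pulse(duration=3.2, fwhm_target=0.55, n_samples=512)


@pytest.fixture(scope="session")
def slice_sel():
    """2.54 kHz/cm slice-select, 8 mm slice, half-moment refocusing,
    201-point grid over +/-0.5 cm."""
    return SliceSelection(gradient=2.54)


@pytest.fixture(scope="session")
def tissue():
    return TissueParams(t1=900.0, t2=30.0)


@pytest.fixture(scope="session")
def lut(pulse, slice_sel, tissue):
    """On-resonance slice-profile ratio LUT at TE 11 ms."""
    return build_ratio_lut(pulse, slice_sel, te=11.0, tissue=tissue)


@pytest.fixture(scope="session")
def te():
    return 11.0


def isochromat_spgr(t1, t2, fa, tr, inc_deg, n_tr=1000, n_spins=2000):
    """Independent brute-force steady-state SPGR oracle: an ensemble of
    spins uniformly dephased by the gradient spoiler each TR, driven by the
    same quadratic RF phase schedule; signal is the post-RF complex mean."""
    theta = 2 * np.pi * np.arange(n_spins) / n_spins
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    a = np.radians(fa)
    mxy = np.zeros(n_spins, complex)
    mz = np.ones(n_spins)
    sig = 0.0
    for k in range(n_tr):
        phi = np.radians(0.5 * k * (k + 1) * inc_deg)
        c, s = np.cos(phi), np.sin(phi)
        mx, my = mxy.real, mxy.imag
        x = c * mx + s * my
        y = -s * mx + c * my
        y2 = y * np.cos(a) - mz * np.sin(a)
        z2 = y * np.sin(a) + mz * np.cos(a)
        mx = c * x - s * y2
        my = s * x + c * y2
        sig = np.abs(np.mean(mx + 1j * my))
        mxy = (mx + 1j * my) * e2 * np.exp(1j * theta)
        mz = 1.0 + (z2 - 1.0) * e1
    return sig
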