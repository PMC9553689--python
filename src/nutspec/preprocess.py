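"""Spectral pretreatment: Savitzky-Golay smoothing/derivatives and SNV.

Both operators act scan-wise on a :class:`~nutspec.containers.SpectraSet` and
return a new set on the same wavelength grid. The default calibration chain is
smoothing followed by the standard normal variate transform; the two address
different artefacts (high-frequency noise vs. per-scan baseline/scatter).
"""

from __future__ import annotations

from math import factorial

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectraSet


def _edge_rows(window: int, polyorder: int, deriv: int, step: float, left: bool) -> list[tuple[slice, np.ndarray]]:
    """Projection rows for the edge points, fit on truncated windows.

    For an edge point i the window is clipped to the available grid instead of
    padding with fabricated values; the local polynomial is refit on the
    truncated window (widened to polyorder+1 points when the clip leaves too
    few) and its `deriv`-th derivative evaluated at the point itself.
    """
    half = window // 2
    rows = []
    fact = float(factorial(deriv))
    for i in range(half):
        lo, hi = (0, max(i + half + 1, polyorder + 1)) if left else (-max(half + i + 1, polyorder + 1), None)
        idx = slice(lo, hi)
        # abscissae relative to the evaluation point, in grid-step units
        n_pts = (hi - lo) if hi is not None else -lo
        if left:
            x = (np.arange(n_pts) - i) * step
        else:
            x = (np.arange(n_pts) - (n_pts - 1 - i)) * step
        V = np.vander(x, polyorder + 1, increasing=True)
        proj = np.linalg.pinv(V)[deriv] * fact
        rows.append((idx, proj))
    return rows


def savitzky_golay(
    spectra: SpectraSet,
    window: int = 11,
    polyorder: int = 2,
    deriv_order: int = 0,
) -> SpectraSet:
    """Local polynomial least-squares smoothing / differentiation.

    ``deriv_order=0`` returns the smoothed spectrum; ``deriv_order=1`` the
    first derivative in absorbance per nm (scaled by the grid step). Edges are
    handled by refitting the polynomial on truncated windows rather than by
    padding.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if deriv_order < 0 or deriv_order > polyorder:
        raise ValueError("require 0 <= deriv_order <= polyorder")
    p = spectra.wavelengths.size
    if window > p:
        raise ValueError(f"window ({window}) exceeds number of wavelengths ({p})")
    step = spectra.step if p > 1 else 1.0
    Y = spectra.absorbance
    out = savgol_filter(Y, window, polyorder, deriv=deriv_order, delta=step, axis=1, mode="interp")
    half = window // 2
    for i, (idx, proj) in enumerate(_edge_rows(window, polyorder, deriv_order, step, left=True)):
        out[:, i] = Y[:, idx] @ proj
    for i, (idx, proj) in enumerate(_edge_rows(window, polyorder, deriv_order, step, left=False)):
        out[:, p - 1 - i] = Y[:, idx] @ proj
    return spectra.with_absorbance(out)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate transform: per-scan centre to mean 0, scale to sd 1.

    The sd uses the sample (n-1) convention. SNV removes per-scan additive
    baseline offsets and multiplicative scatter — it is invariant to any
    positive-slope affine transform of a scan. A constant scan has no scatter
    information to normalise and is rejected.
    """
    Y = spectra.absorbance
    mean = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        names = [spectra.sample_ids[i] for i in zero]
        raise ValueError(f"constant scan(s) cannot be SNV-transformed: {names}")
    return spectra.with_absorbance((Y - mean) / sd)


_PRETREATMENTS = {
    "sg": savitzky_golay,
    "savgol": savitzky_golay,
    "snv": snv,
}


def apply_chain(spectra: SpectraSet, chain: str | list[str]) -> SpectraSet:
    """Apply a comma-separated (or listed) pretreatment chain, e.g. ``"sg,snv"``.

    Savitzky-Golay steps accept ``sg:window:polyorder:deriv`` overrides.
    """
    steps = chain.split(",") if isinstance(chain, str) else list(chain)
    out = spectra
    for raw in steps:
        name, *args = raw.strip().split(":")
        if not name:
            continue
        if name not in _PRETREATMENTS:
            raise ValueError(f"unknown pretreatment {name!r}; known: {sorted(set(_PRETREATMENTS))}")
        if name in ("sg", "savgol"):
            w, po, d = (int(a) for a in args) if args else (11, 2, 0)
            out = savitzky_golay(out, window=w, polyorder=po, deriv_order=d)
        else:
            out = snv(out)
    return out
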