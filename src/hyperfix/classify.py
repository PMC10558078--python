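"""Amplifier/suppressor classification against the Moran baseline.

A structure is a suppressor of selection if the mutant fixation
probability sits below the Moran process value for every r > 1 and above
it for every r < 1 (an amplifier reverses both signs).  The comparison is
only meaningful if the curve passes the neutral anchor x_i(1) = i/N;
majority-rule (model 2) dynamics generally fail it, in which case the
structure is neither an amplifier nor a suppressor (``not_comparable``
here, reported alongside the conventional "neither" wording).

Sign calls must separate structure from noise.  A grid point is *signed*
only when |x(r) - x_Moran(r)| exceeds (a) an absolute floor above the
linear-solver noise, (b) a relative tolerance against the magnitude of the
curves (fixation probabilities decay like r^{-N} for r < 1, far below any
absolute tolerance at large N), and (c) for simulated curves, the ~95%
interval half-width.  Unsigned points carry no evidence either way; a
verdict requires every signed point to be consistent and at least one
signed point to exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import moran_fixation
from .curves import FixationCurve

__all__ = ["Verdict", "classify_selection"]

_ABS_FLOOR = 1e-11  # below this, differences are linear-solver noise


@dataclass(frozen=True)
class Verdict:
    """Classification of a fixation curve against the Moran baseline."""

    classification: str  # amplifier | suppressor | equivalent | neither | not_comparable
    r_values: np.ndarray
    delta: np.ndarray  # x(r) - x_moran(r)
    signs: np.ndarray  # +1 / -1 where resolved beyond tolerance, 0 otherwise
    tol: float
    anchor_gap: float  # |x(1) - i/N|
    baseline: str
    annotation: str = ""


def classify_selection(
    curve: FixationCurve, N: int | None = None, tol: float = 1e-9
) -> Verdict:
    """Classify a fixation curve as amplifier/suppressor/equivalent/neither.

    The grid must contain r = 1 and at least three points on each side of
    it.  ``tol`` is the relative tolerance for sign calls and the absolute
    tolerance for the r = 1 anchor on exact curves; simulated curves use
    their confidence intervals instead.
    """
    N = N if N is not None else curve.N
    r = np.asarray(curve.r_values, dtype=float)
    x = np.asarray(curve.x, dtype=float)
    at_one = np.isclose(r, 1.0, rtol=0.0, atol=1e-12)
    if not at_one.any():
        raise ValueError("the r grid must contain r = 1")
    if (r < 1).sum() < 3 or (r > 1).sum() < 3:
        raise ValueError("need at least 3 grid points on each side of r = 1")

    i = curve.i
    moran = np.array([moran_fixation(N, rv, i) for rv in r])
    delta = x - moran
    anchor_gap = float(np.abs(delta[at_one]).max())
    baseline = f"Moran(N={N}, i={i})"

    threshold = np.maximum(_ABS_FLOOR, tol * np.maximum(np.abs(x), np.abs(moran)))
    if curve.stderr is not None:
        half = 1.96 * np.asarray(curve.stderr, dtype=float)
        threshold = np.maximum(threshold, half)
        anchor_ok = anchor_gap <= max(float(half[at_one].max()), tol)
    else:
        anchor_ok = anchor_gap <= tol
    signed = np.abs(delta) > threshold
    signs = np.where(signed, np.sign(delta), 0).astype(int)

    def verdict(name: str, note: str = "") -> Verdict:
        return Verdict(
            classification=name, r_values=r, delta=delta, signs=signs,
            tol=tol, anchor_gap=anchor_gap, baseline=baseline, annotation=note,
        )

    if not anchor_ok:
        return verdict(
            "not_comparable",
            "x(1) deviates from i/N, so the amplifier/suppressor dichotomy "
            "does not apply (neither amplifier nor suppressor)",
        )

    above, below = r > 1, r < 1
    if not signed[above | below].any():
        note = "equivalent within sampling noise" if curve.stderr is not None else ""
        return verdict("equivalent", note)
    sup_ok = (signs[above] <= 0).all() and (signs[below] >= 0).all()
    amp_ok = (signs[above] >= 0).all() and (signs[below] <= 0).all()
    unresolved = int((~signed[above | below]).sum())
    note = f"{unresolved} grid points unresolved beyond tolerance" if unresolved else ""
    if sup_ok and not amp_ok:
        return verdict("suppressor", note)
    if amp_ok and not sup_ok:
        return verdict("amplifier", note)
    return verdict("neither")
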