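"""PAT-to-systolic-BP calibration via the Bramwell-Hill relation.

Once the collapse parameters (a, c) of the brachial artery are known, the
Bramwell-Hill equation maps transmural pressure to pulse wave velocity.  For
each beat in a segment between two cuff inflations, the measured change in
pulse arrival time converts to a PWV through

    PWV = 1 / ( dPAT/L + 1/PWV(P_sys_ref) )

with L the heart-to-finger path (~1 m) and ``P_sys_ref`` the systemic
systolic pressure at the calibrating inflation; inverting the tabulated
PWV(Ptm) curve then yields a beat-to-beat systolic pressure estimate.  The
pre-ejection period is assumed constant over the segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .collapse import CollapseParams, pwv

__all__ = ["Calibration", "build_calibration", "estimate_systolic", "accuracy_flag"]


@dataclass(frozen=True)
class Calibration:
    """Tabulated monotone PWV(Ptm) branch plus the calibration anchor."""

    ptm_grid: np.ndarray  # mmHg, 1 mmHg spacing
    pwv_grid: np.ndarray  # m/s, strictly increasing
    p_sys_ref: float  # mmHg
    path_length: float = 1.0  # m

    @property
    def pwv_ref(self) -> float:
        """PWV at the reference systolic pressure (m/s)."""
        return float(np.interp(self.p_sys_ref, self.ptm_grid, self.pwv_grid))


def build_calibration(col: CollapseParams, p_sys_ref: float,
                      ptm_min: float = 50.0, ptm_max: float = 200.0,
                      step: float = 1.0) -> Calibration:
    """Tabulate PWV(Ptm) on a 1 mmHg grid over the monotone high-pressure branch.

    Above ~50 mmHg transmural pressure the Bramwell-Hill PWV is monotone
    (approximately linear) in Ptm for physiologic collapse parameters, which
    makes the table invertible.  The area scale d cancels in the PWV, so the
    calibration needs only (a, c).  Raises if the curve is not strictly
    increasing over the requested range or if ``p_sys_ref`` falls outside it.
    """
    if not (ptm_min <= p_sys_ref <= ptm_max):
        raise ValueError(f"build_calibration: p_sys_ref={p_sys_ref} outside "
                         f"[{ptm_min}, {ptm_max}] mmHg")
    grid = np.arange(ptm_min, ptm_max + step / 2, step)
    v = np.asarray(pwv(grid, col))
    dv = np.diff(v)
    if np.any(dv <= 0):
        bad = grid[:-1][dv <= 0]
        raise ValueError("build_calibration: PWV(Ptm) not strictly increasing "
                         f"over [{bad.min():.0f}, {bad.max():.0f}] mmHg")
    return Calibration(ptm_grid=grid, pwv_grid=v, p_sys_ref=float(p_sys_ref))


def estimate_systolic(pat_series: np.ndarray, cal: Calibration,
                      *, ref_beats: int = 10) -> np.ndarray:
    """Beat-to-beat systolic pressure estimate from a PAT series (mmHg).

    The reference PAT is the median of the first ``ref_beats`` beats of the
    segment; each beat's dPAT maps to a PWV and then, through the inverted
    calibration table, to a transmural (= systolic) pressure.  Beats whose
    implied PWV leaves the calibrated range are returned as ``nan``
    (unestimable) rather than extrapolated.  The constant-PEP assumption is
    recorded in the docstring contract: any PEP drift aliases into the
    estimate.
    """
    pat = np.asarray(pat_series, dtype=float)
    head = pat[:ref_beats]
    if not np.isfinite(head).any():
        raise ValueError("estimate_systolic: no finite PAT values in reference window")
    ref = float(np.nanmedian(head))
    dpat = pat - ref
    inv_v = dpat / cal.path_length + 1.0 / cal.pwv_ref
    est = np.full(pat.shape, np.nan)
    ok = np.isfinite(inv_v) & (inv_v > 0)
    v = 1.0 / inv_v[ok]
    in_range = (v >= cal.pwv_grid[0]) & (v <= cal.pwv_grid[-1])
    # invert the monotone table: Ptm as a function of PWV
    ptm = np.full(v.shape, np.nan)
    ptm[in_range] = np.interp(v[in_range], cal.pwv_grid, cal.ptm_grid)
    est[ok] = ptm
    return est


def accuracy_flag(est: np.ndarray, truth: np.ndarray, t: np.ndarray,
                  *, err_thresh: float = 10.0,
                  dur_thresh: float = 60.0) -> bool:
    """Segment-level accuracy criterion: ``True`` means accurate.

    The estimate is inaccurate when its absolute error exceeds 10 mmHg
    continuously for longer than one minute.  Beats with no estimate are
    treated as erroneous samples (a gap that long is a failure too).
    Segments shorter than the duration threshold are accurate by default,
    with a warning.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    t = np.asarray(t, dtype=float)
    if t[-1] - t[0] < dur_thresh:
        warnings.warn("accuracy_flag: segment shorter than the duration "
                      "threshold; accurate by default")
        return True
    bad = ~(np.abs(est - truth) <= err_thresh)  # nan-safe: nan counts as bad
    run_start = None
    for i, flag in enumerate(bad):
        if flag and run_start is None:
            run_start = t[i]
        elif not flag and run_start is not None:
            run_start = None
        if run_start is not None and t[i] - run_start > dur_thresh:
            return False
    return True
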