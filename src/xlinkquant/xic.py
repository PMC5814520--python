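"""MS1-filtering quantitation: extracted ion chromatograms, peak picking,
retention-time alignment and match-between-runs.

For each cross-linking feature the first three isotope peaks (M, M+1, M+2)
of its precursor are traced across the MS1 spectra of every run within a
narrow m/z tolerance (default +/-0.055), the summed-isotope trace is
integrated between automatically chosen peak boundaries, and runs without
an identification are quantified at the aligned retention time of runs that
have one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .chem import isotope_mzs
from .linearize import LinearForm
from .mzml_io import MS1Run
from .ssl_io import FeatureKey

log = logging.getLogger(__name__)

DEFAULT_MZ_TOLERANCE = 0.055     # half-window, m/z
DEFAULT_N_ISOTOPES = 3
DEFAULT_BOUNDARY_FRACTION = 0.01  # of (smoothed) apex intensity
DEFAULT_SEARCH_WINDOW = 2.0       # minutes around the seed RT
INSTRUMENT_MZ_RANGE = (400.0, 1600.0)


@dataclass
class XICTrace:
    """Per-isotope extracted ion chromatograms of one feature in one run."""

    key: FeatureKey
    run_id: str
    rts: np.ndarray                  # minutes, shared by all isotopes
    intensities: np.ndarray          # shape (n_isotopes, n_spectra)
    quantifiable: bool = True        # False iff precursor outside m/z range

    @property
    def summed(self) -> np.ndarray:
        return self.intensities.sum(axis=0)


@dataclass
class PeakResult:
    """Integrated peak of one feature in one run."""

    run_id: str
    key: FeatureKey
    rt_start: float
    rt_apex: float
    rt_end: float
    area: float
    found: bool                   # a peak was located in the trace
    from_identification: bool = True  # False = match between runs
    noise_area: float = 0.0       # noise-floor-equivalent area estimate

    @property
    def quantified(self) -> bool:
        """Area above the run's noise-floor estimate."""
        return self.found and self.area > self.noise_area


def extract_xic(run: MS1Run, lf: LinearForm,
                tolerance: float = DEFAULT_MZ_TOLERANCE,
                n_isotopes: int = DEFAULT_N_ISOTOPES,
                rt_window: tuple[float, float] | None = None,
                key: FeatureKey | None = None) -> XICTrace:
    """Extract per-isotope XICs of a linear form's precursor from one run.

    For each isotope k the per-spectrum intensity is the sum of all centroid
    intensities within ``tolerance`` of the isotope m/z.  A precursor outside
    the instrument acquisition range is flagged unquantifiable (all-zero
    trace), not an error.
    """
    key = key or FeatureKey("", lf.charge, lf.residue_pair)
    mzs = np.asarray(isotope_mzs(lf.precursor_mz, lf.charge, n_isotopes))
    lo, hi = INSTRUMENT_MZ_RANGE
    if not lo <= lf.precursor_mz <= hi:
        log.warning("precursor m/z %.3f outside instrument range %s; "
                    "feature %s flagged unquantifiable",
                    lf.precursor_mz, INSTRUMENT_MZ_RANGE, key)
        return XICTrace(key, run.run_id, run.rts.copy(),
                        np.zeros((n_isotopes, len(run))), quantifiable=False)

    if rt_window is not None:
        mask = (run.rts >= rt_window[0]) & (run.rts <= rt_window[1])
        idx = np.nonzero(mask)[0]
    else:
        idx = np.arange(len(run))
    rts = run.rts[idx]
    out = np.zeros((n_isotopes, len(idx)))
    los, his = mzs - tolerance, mzs + tolerance
    for col, i in enumerate(idx):
        mz, inten = run.spectra[i]
        if len(mz) == 0:
            continue
        left = np.searchsorted(mz, los, side="left")
        right = np.searchsorted(mz, his, side="right")
        for k in range(n_isotopes):
            if right[k] > left[k]:
                out[k, col] = inten[left[k]:right[k]].sum()
    return XICTrace(key, run.run_id, rts, out)


def _smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    if len(y) < width:
        return y.copy()
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def estimate_noise_area(summed: np.ndarray, rt_start: float,
                        rt_end: float) -> float:
    """Noise-floor-equivalent area: median of the bottom decile of the
    positive summed-trace intensities times the peak width.  Positive values
    only — centroided MS1 traces are mostly exact zeros, which carry no
    information about the noise level."""
    positive = summed[summed > 0]
    if len(positive) == 0:
        return 0.0
    n_low = max(1, len(positive) // 10)
    floor = float(np.median(np.sort(positive)[:n_low]))
    return floor * max(rt_end - rt_start, 0.0)


def pick_peak(trace: XICTrace, rt_seed: float,
              boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
              search_window: float = DEFAULT_SEARCH_WINDOW,
              from_identification: bool = True) -> PeakResult:
    """Locate and integrate the chromatographic peak nearest ``rt_seed``.

    The apex is the local maximum of the 5-point-smoothed summed-isotope
    trace nearest the seed within the search window.  Boundaries extend
    outward until the smoothed intensity drops below
    ``boundary_fraction * apex`` or starts rising again (a valley); the area
    is the trapezoidal integral of the raw summed trace between them.
    """
    summed = trace.summed
    n = len(summed)
    zero = PeakResult(trace.run_id, trace.key, rt_seed, rt_seed, rt_seed,
                      0.0, found=False,
                      from_identification=from_identification)
    if n == 0 or not trace.quantifiable or not np.any(summed > 0):
        return zero

    sm = _smooth(summed)
    in_window = np.abs(trace.rts - rt_seed) <= search_window
    if not np.any(in_window & (sm > 0)):
        return zero

    # local maxima of the smoothed trace (plateau-tolerant at edges)
    interior = np.zeros(n, dtype=bool)
    if n >= 3:
        interior[1:-1] = (sm[1:-1] >= sm[:-2]) & (sm[1:-1] >= sm[2:])
    interior[0] = n == 1 or (n > 1 and sm[0] >= sm[1])
    interior[-1] = n > 1 and sm[-1] >= sm[-2]
    cand = np.nonzero(interior & in_window & (sm > 0))[0]
    if len(cand) == 0:
        return zero
    # ignore candidates far below the strongest one in the window (noise
    # blips sitting nearer the seed than the real peak), then take the
    # candidate nearest the seed
    cand = cand[sm[cand] >= 0.05 * sm[cand].max()]
    apex = int(cand[np.argmin(np.abs(trace.rts[cand] - rt_seed))])

    cutoff = boundary_fraction * sm[apex]
    left = apex
    while left > 0 and sm[left - 1] > cutoff and sm[left - 1] <= sm[left]:
        left -= 1
    right = apex
    while right < n - 1 and sm[right + 1] > cutoff and sm[right + 1] <= sm[right]:
        right += 1

    area = float(np.trapezoid(summed[left:right + 1],
                              trace.rts[left:right + 1]))
    rt_start, rt_end = float(trace.rts[left]), float(trace.rts[right])
    return PeakResult(trace.run_id, trace.key, rt_start,
                      float(trace.rts[apex]), rt_end, area, found=True,
                      from_identification=from_identification,
                      noise_area=estimate_noise_area(summed, rt_start, rt_end))


# -- retention-time alignment ------------------------------------------------

@dataclass
class RTAlignment:
    """Per-run monotone linear mappings onto a reference run's RT axis."""

    reference: str
    slopes: dict[str, float] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)

    def to_reference(self, run_id: str, rt: float) -> float:
        return self.slopes.get(run_id, 1.0) * rt + self.intercepts.get(run_id, 0.0)

    def from_reference(self, run_id: str, rt: float) -> float:
        a = self.slopes.get(run_id, 1.0)
        b = self.intercepts.get(run_id, 0.0)
        return (rt - b) / a


def align_rt(apex_by_run: Mapping[str, Mapping[FeatureKey, float]],
             min_anchors: int = 3) -> RTAlignment:
    """Robust linear RT alignment from anchor-feature apex times.

    ``apex_by_run[run_id][key]`` is the apex RT of an anchor feature
    (identified in that run).  The run with the most anchors is the
    reference; each other run is mapped by a Theil-Sen fit of reference apex
    vs own apex over shared anchors.  Runs with fewer than ``min_anchors``
    shared anchors keep the identity mapping (warned).
    """
    if not apex_by_run:
        raise ValueError("no runs to align")
    reference = max(apex_by_run, key=lambda r: len(apex_by_run[r]))
    aln = RTAlignment(reference=reference)
    ref_apexes = apex_by_run[reference]
    for run_id, apexes in apex_by_run.items():
        if run_id == reference:
            continue
        shared = sorted(set(apexes) & set(ref_apexes),
                        key=lambda k: apexes[k])
        if len(shared) < min_anchors:
            log.warning("run %s: only %d shared anchors (< %d); "
                        "identity RT mapping used", run_id, len(shared),
                        min_anchors)
            continue
        x = np.array([apexes[k] for k in shared])
        y = np.array([ref_apexes[k] for k in shared])
        if len(shared) == min_anchors or np.ptp(x) < 1e-9:
            slope, intercept = 1.0, float(np.median(y - x))
        else:
            res = theilslopes(y, x)
            slope, intercept = float(res[0]), float(res[1])
            if slope <= 0:  # degenerate fit; fall back to a pure shift
                slope, intercept = 1.0, float(np.median(y - x))
        aln.slopes[run_id] = slope
        aln.intercepts[run_id] = intercept
    return aln


# -- cross-run quantitation --------------------------------------------------

def quantify_feature_across_runs(
        lf: LinearForm, key: FeatureKey, runs: Sequence[MS1Run],
        id_rts: Mapping[str, float],
        alignment: RTAlignment | None = None,
        tolerance: float = DEFAULT_MZ_TOLERANCE,
        n_isotopes: int = DEFAULT_N_ISOTOPES,
        search_window: float = DEFAULT_SEARCH_WINDOW) -> list[PeakResult]:
    """Quantify one feature in every run (match between runs).

    ``id_rts`` maps run ids to the identification RT seed for runs where the
    feature was identified; other runs are seeded with the aligned median
    apex RT of the identified runs.
    """
    if not id_rts:
        raise ValueError(f"feature {key} identified in no run")
    results: list[PeakResult] = []
    detected: dict[str, PeakResult] = {}
    for run in runs:
        if run.run_id in id_rts:
            trace = extract_xic(run, lf, tolerance, n_isotopes, key=key)
            detected[run.run_id] = pick_peak(
                trace, id_rts[run.run_id], search_window=search_window,
                from_identification=True)

    aln = alignment or RTAlignment(reference=runs[0].run_id)
    ref_apexes = [aln.to_reference(r, p.rt_apex)
                  for r, p in detected.items() if p.found]
    median_ref_rt = float(np.median(ref_apexes)) if ref_apexes else float(
        np.median(list(id_rts.values())))

    for run in runs:
        if run.run_id in detected:
            results.append(detected[run.run_id])
            continue
        seed = aln.from_reference(run.run_id, median_ref_rt)
        trace = extract_xic(run, lf, tolerance, n_isotopes, key=key)
        results.append(pick_peak(trace, seed, search_window=search_window,
                                 from_identification=False))
    return results


def quantify_all(features: Mapping[FeatureKey, LinearForm],
                 runs: Sequence[MS1Run],
                 id_rts: Mapping[FeatureKey, Mapping[str, float]],
                 tolerance: float = DEFAULT_MZ_TOLERANCE,
                 n_isotopes: int = DEFAULT_N_ISOTOPES,
                 search_window: float = DEFAULT_SEARCH_WINDOW,
                 align: bool = True) -> pd.DataFrame:
    """Quantify every feature in every run; returns the quantitation table.

    Anchors for RT alignment are features identified in at least two runs.
    Columns: feature, run, rt_start, rt_apex, rt_end, area, found, matched,
    quantified.
    """
    apex_by_run: dict[str, dict[FeatureKey, float]] = {
        r.run_id: {} for r in runs}
    if align and len(runs) > 1:
        for key, lf in features.items():
            seeds = id_rts.get(key, {})
            if len(seeds) < 2:
                continue
            for run in runs:
                if run.run_id in seeds:
                    trace = extract_xic(run, lf, tolerance, n_isotopes,
                                        key=key)
                    peak = pick_peak(trace, seeds[run.run_id],
                                     search_window=search_window)
                    if peak.found:
                        apex_by_run[run.run_id][key] = peak.rt_apex
    alignment = align_rt(apex_by_run) if align and len(runs) > 1 else None

    rows = []
    for key, lf in features.items():
        for p in quantify_feature_across_runs(
                lf, key, runs, id_rts.get(key, {}), alignment,
                tolerance, n_isotopes, search_window):
            rows.append({
                "feature": str(key), "run": p.run_id,
                "rt_start": p.rt_start, "rt_apex": p.rt_apex,
                "rt_end": p.rt_end, "area": p.area, "found": p.found,
                "matched": not p.from_identification,
                "quantified": p.quantified,
            })
    return pd.DataFrame(rows)


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    """One row per (feature, run): key, apex, boundaries, area, flags."""
    table.to_csv(path, index=False)
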