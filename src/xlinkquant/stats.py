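"""Reproducibility statistics over quantified cross-linking features.

Feature areas aggregate to residue-pair records: the CV of a residue pair is
the median CV of its member features across replicas.  The module also
implements the reporting filters (co-elution ambiguity, complete
quantitation), identification saturation curves, replica observation
frequencies, overlap counts and CV-vs-intensity binning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ssl_io import FeatureKey

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class ResiduePairRecord:
    """A unique protein residue pair and its quantitation evidence."""

    protein_id: str
    residues: tuple[int, int]          # (i, j), i <= j
    features: list[FeatureKey] = field(default_factory=list)
    ca_distance: float | None = None   # Angstrom
    pair_cv: float | None = None       # percent
    median_area: float | None = None

    def __post_init__(self) -> None:
        i, j = self.residues
        if i > j:
            self.residues = (j, i)


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean.

    Sample (n-1) standard deviation; undefined (raises) for fewer than two
    values or non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatsError(f"CV undefined for {arr.size} value(s)")
    mean = arr.mean()
    if mean <= 0:
        raise StatsError(f"CV undefined for non-positive mean {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def residue_pair_cv(feature_cvs: Sequence[float]) -> float:
    """Pair-level CV: median of the member features' CVs (midpoint rule)."""
    if len(feature_cvs) == 0:
        raise StatsError("residue pair has no member feature CVs")
    return float(np.median(feature_cvs))


def feature_cv_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-feature CV (%) and median area across runs from a quantitation
    table (columns feature, run, area).  Features with non-positive mean
    area get NaN CV."""
    rows = []
    for key, grp in quant.groupby("feature", sort=False):
        areas = grp["area"].to_numpy(dtype=float)
        try:
            cv = cv_percent(areas)
        except StatsError:
            cv = math.nan
        rows.append({"feature": key, "cv": cv,
                     "median_area": float(np.median(areas)),
                     "n_runs": len(areas),
                     "n_quantified": int(grp["quantified"].sum())})
    return pd.DataFrame(rows)


# -- reporting filters -------------------------------------------------------

def filter_coeluting_alternatives(
        pairs: Sequence[ResiduePairRecord], quant: pd.DataFrame,
        feature_meta: Mapping[str, tuple[str, int, tuple[int, int]]],
) -> tuple[list[ResiduePairRecord], list[ResiduePairRecord]]:
    """Drop residue pairs with LC-unresolved alternative linkage sites.

    ``feature_meta[feature] = (plain linear sequence, charge, residue pair)``.
    A pair is removed when any of its features shares (sequence, charge)
    with a feature of a *different* residue pair and their integrated peak
    boundaries overlap in any run — the two linkage variants are then not
    fully separated in the LC dimension and neither can be quantified
    unambiguously.
    """
    bounds: dict[str, dict[str, tuple[float, float]]] = {}
    for row in quant.itertuples():
        if row.found:
            bounds.setdefault(row.feature, {})[row.run] = (row.rt_start,
                                                           row.rt_end)

    by_seq_charge: dict[tuple[str, int], list[str]] = {}
    for feat, (seq, charge, _pair) in feature_meta.items():
        by_seq_charge.setdefault((seq, charge), []).append(feat)

    ambiguous_pairs: set[tuple[int, int]] = set()
    for feats in by_seq_charge.values():
        for fa, fb in combinations(feats, 2):
            if feature_meta[fa][2] == feature_meta[fb][2]:
                continue  # same residue pair: not an alternative
            ba, bb = bounds.get(fa, {}), bounds.get(fb, {})
            for run in set(ba) & set(bb):
                (s1, e1), (s2, e2) = ba[run], bb[run]
                if s1 <= e2 and s2 <= e1:  # boundary overlap in this run
                    ambiguous_pairs.add(feature_meta[fa][2])
                    ambiguous_pairs.add(feature_meta[fb][2])
                    break

    retained = [p for p in pairs if p.residues not in ambiguous_pairs]
    removed = [p for p in pairs if p.residues in ambiguous_pairs]
    return retained, removed


def filter_complete_quant(
        pairs: Sequence[ResiduePairRecord], quant: pd.DataFrame,
        n_runs: int) -> tuple[list[ResiduePairRecord],
                              list[ResiduePairRecord]]:
    """Keep pairs whose every member feature is quantified (area above the
    noise floor) in all ``n_runs`` replicas."""
    ok_features = {
        feat for feat, grp in quant.groupby("feature", sort=False)
        if len(grp) == n_runs and bool(grp["quantified"].all())
    }
    retained, removed = [], []
    for p in pairs:
        if p.features and all(str(f) in ok_features for f in p.features):
            retained.append(p)
        else:
            removed.append(p)
    return retained, removed


# -- replica-set statistics --------------------------------------------------

def saturation_curve(per_run_sets: Sequence[set], k: int,
                     max_exhaustive: int = 10, n_mc: int = 2000,
                     seed: int = 0) -> float:
    """Mean number of unique residue pairs found in ``k`` runs.

    Exhaustive over all C(n, k) subsets for n <= ``max_exhaustive``; seeded
    Monte Carlo above that.
    """
    n = len(per_run_sets)
    if not 1 <= k <= n:
        raise StatsError(f"k={k} out of range 1..{n}")
    if n <= max_exhaustive:
        sizes = [len(set().union(*combo))
                 for combo in combinations(per_run_sets, k)]
    else:
        rng = np.random.default_rng(seed)
        sizes = []
        for _ in range(n_mc):
            idx = rng.choice(n, size=k, replace=False)
            sizes.append(len(set().union(*(per_run_sets[i] for i in idx))))
    return float(np.mean(sizes))


def saturation_table(per_run_sets: Sequence[set], **kwargs) -> pd.DataFrame:
    """Saturation curve for k = 1..n as a table (k, mean_unique_pairs)."""
    n = len(per_run_sets)
    return pd.DataFrame({
        "k": np.arange(1, n + 1),
        "mean_unique_pairs": [saturation_curve(per_run_sets, k, **kwargs)
                              for k in range(1, n + 1)],
    })


def observation_frequency(per_run_sets: Sequence[set]) -> dict[int, int]:
    """Histogram: number of unique pairs observed in exactly m of n runs.

    Total histogram mass equals the size of the union over runs.
    """
    if len(per_run_sets) < 1:
        raise StatsError("need at least one run")
    counts: dict = {}
    for s in per_run_sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    hist = {m: 0 for m in range(1, len(per_run_sets) + 1)}
    for m in counts.values():
        hist[m] += 1
    return hist


def overlap_counts(set1: set, set2: set) -> tuple[int, int, int]:
    """Venn partition sizes (only in 1, shared, only in 2)."""
    shared = set1 & set2
    return (len(set1) - len(shared), len(shared), len(set2) - len(shared))


def cv_by_intensity_bins(pairs: Sequence[ResiduePairRecord],
                         bin_width: float = 1.0) -> pd.DataFrame:
    """Median pair CV per log2(median peak area) bin.

    Pairs lacking a CV or with non-positive area are excluded (logged);
    empty bins are omitted.  Columns: bin_left, n_pairs, median_cv.
    """
    usable = []
    for p in pairs:
        if (p.pair_cv is None or p.median_area is None
                or not p.median_area > 0 or math.isnan(p.pair_cv)):
            log.info("pair %s excluded from intensity binning", p.residues)
            continue
        usable.append((math.log2(p.median_area), p.pair_cv))
    if not usable:
        return pd.DataFrame(columns=["bin_left", "n_pairs", "median_cv"])
    log_areas = np.array([u[0] for u in usable])
    cvs = np.array([u[1] for u in usable])
    bins = np.floor(log_areas / bin_width).astype(int)
    rows = []
    for b in sorted(set(bins)):
        mask = bins == b
        rows.append({"bin_left": b * bin_width, "n_pairs": int(mask.sum()),
                     "median_cv": float(np.median(cvs[mask]))})
    return pd.DataFrame(rows)


# -- experiment-level aggregation --------------------------------------------

def build_pair_records(features: Mapping[FeatureKey, tuple[int, int]],
                       fcv: pd.DataFrame,
                       protein_id: str = "protein") -> list[ResiduePairRecord]:
    """Group features (key -> residue pair) into ResiduePairRecords with
    pair CV (median of member CVs) and median area (median of member
    median areas)."""
    by_pair: dict[tuple[int, int], list[FeatureKey]] = {}
    for key, pair in features.items():
        i, j = pair
        by_pair.setdefault((min(i, j), max(i, j)), []).append(key)
    cv_of = dict(zip(fcv["feature"], fcv["cv"]))
    area_of = dict(zip(fcv["feature"], fcv["median_area"]))
    records = []
    for pair, keys in by_pair.items():
        cvs = [cv_of[str(k)] for k in keys
               if str(k) in cv_of and not math.isnan(cv_of[str(k)])]
        areas = [area_of[str(k)] for k in keys if str(k) in area_of]
        rec = ResiduePairRecord(protein_id, pair, features=list(keys))
        if cvs:
            rec.pair_cv = residue_pair_cv(cvs)
        else:
            log.info("pair %s has no defined member CVs; excluded from CV "
                     "summaries", pair)
        if areas:
            rec.median_area = float(np.median(areas))
        records.append(rec)
    return records


def experiment_cv_summary(pairs: Sequence[ResiduePairRecord]) -> dict:
    """Median and mean pair CV (%) over pairs with a defined CV."""
    cvs = [p.pair_cv for p in pairs
           if p.pair_cv is not None and not math.isnan(p.pair_cv)]
    if not cvs:
        return {"n_pairs": 0, "median_cv": math.nan, "mean_cv": math.nan}
    return {"n_pairs": len(cvs),
            "median_cv": round(float(np.median(cvs)), 1),
            "mean_cv": round(float(np.mean(cvs)), 1)}
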