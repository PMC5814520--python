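"""End-to-end orchestration: PSM table -> linear forms -> spectral-library
input -> structure validation -> MS1 quantitation -> reproducibility report.

Stage order mirrors the quantitation workflow: identifications are
linearized and written as .ssl; decoy matches and residue pairs beyond the
Calpha distance limit are excluded; the surviving features are quantified
across all runs (match between runs); LC-unresolved alternative linkage
sites and incompletely quantified pairs are filtered; the remainder yields
per-pair CVs, saturation curves, observation frequencies and CV-vs-intensity
bins.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import linearize as lin
from . import ssl_io, stats, structure, xic
from .mzml_io import MS1Run, read_mzml

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run-level configuration; defaults are the standard acquisition and
    filtering settings (m/z tolerance 0.055, 3 isotope peaks, precursor
    charges 3-7, 30 A distance limit)."""

    psm_table: str
    mzml_files: list[str] = field(default_factory=list)
    pdb: str | None = None
    chain: str = "A"
    output_dir: str = "xlinkquant_out"
    tolerance: float = xic.DEFAULT_MZ_TOLERANCE
    n_isotopes: int = xic.DEFAULT_N_ISOTOPES
    charge_min: int = 3
    charge_max: int = 7
    distance_threshold: float = structure.DEFAULT_DISTANCE_THRESHOLD
    numbering_offset: int = 0     # sequence -> structure residue numbering
    search_window: float = xic.DEFAULT_SEARCH_WINDOW
    experiment: str = "experiment"
    seed: int = 0


def _load_runs(cfg: PipelineConfig) -> list[MS1Run]:
    runs = []
    for path in cfg.mzml_files:
        if not Path(path).exists():
            raise PipelineError("load_runs", f"mzML file not found: {path}")
        runs.append(read_mzml(path))
    if not runs:
        raise PipelineError("load_runs", "no mzML files supplied")
    return runs


def run_pipeline(cfg: PipelineConfig,
                 runs: list[MS1Run] | None = None,
                 psms: list[lin.CrossLinkPSM] | None = None) -> dict:
    """Execute the full workflow; returns the report dict (also written to
    ``output_dir`` together with all tables and the resolved config).

    ``runs``/``psms`` may be supplied directly (e.g. straight from the
    synthetic generator) to bypass file loading.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": {}, "warnings": []}

    def stage(name):
        log.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    # -- identifications ----------------------------------------------------
    s = stage("identifications")
    if psms is None:
        try:
            psms = lin.read_psm_table(cfg.psm_table)
        except Exception as e:
            raise PipelineError("identifications", str(e)) from e
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    all_pairs = {p.residue_pair for p in targets}
    s["n_psms"] = len(psms)
    s["n_decoy_psms"] = len(decoys)
    s["n_unique_pairs_incl_decoys"] = len(
        {(p.residue_pair, p.is_decoy) for p in psms})
    s["n_unique_pairs"] = len(all_pairs)
    pair_flags = [d for _, d in sorted(
        {(p.residue_pair, p.is_decoy) for p in psms})]
    s["decoy_fdr"] = structure.decoy_fdr(pair_flags)

    # -- linearization + spectral-library input -----------------------------
    s = stage("linearize")
    forms = {}
    for p in psms:
        lf = lin.to_linear_form(p)
        delta = lin.verify_mass_equivalence(lf, p)
        if delta >= lin.MASS_EQUIVALENCE_TOL:
            raise PipelineError(
                "linearize", f"mass equivalence violated ({delta:.2e} Da) "
                f"for scan {p.scan} in {p.run_id}")
        forms[id(p)] = lf
    records = [ssl_io.record_from_psm(p, f"{p.run_id}.mzML") for p in psms]
    ssl_path = out / "library.ssl"
    ssl_io.write_ssl(records, ssl_path)
    s["n_ssl_records"] = len(records)
    s["ssl_file"] = str(ssl_path)

    # -- structure validation ------------------------------------------------
    s = stage("structure")
    pair_records = [stats.ResiduePairRecord("target", pair)
                    for pair in sorted(all_pairs)]
    model = None
    if cfg.pdb and Path(cfg.pdb).exists():
        model = structure.load_ca_coords(cfg.pdb, cfg.chain)
        if cfg.numbering_offset:
            model.ca_coords = {r + cfg.numbering_offset: c
                               for r, c in model.ca_coords.items()}
    elif cfg.pdb:
        msg = f"PDB file {cfg.pdb} not found; structure stage skipped"
        log.warning(msg)
        report["warnings"].append(msg)
    retained_pairs, removed_pairs = structure.distance_filter(
        pair_records, model, cfg.distance_threshold)
    structure.write_distance_table(pair_records, out / "distances.csv")
    s["n_pairs_in"] = len(pair_records)
    s["n_removed_distance"] = len(removed_pairs)
    s["n_retained"] = len(retained_pairs)
    s["n_decoy_pairs_excluded"] = len({p.residue_pair for p in decoys})
    retained_set = {p.residues for p in retained_pairs}

    # -- quantitation --------------------------------------------------------
    s = stage("quantify")
    if runs is None:
        runs = _load_runs(cfg)
    run_rts = {r.run_id: r.rts for r in runs}
    features: dict[ssl_io.FeatureKey, lin.LinearForm] = {}
    id_rts: dict[ssl_io.FeatureKey, dict[str, float]] = {}
    feature_meta: dict[str, tuple[str, int, tuple[int, int]]] = {}
    n_out_of_charge = 0
    for p in targets:
        if not cfg.charge_min <= p.charge <= cfg.charge_max:
            n_out_of_charge += 1
            continue
        if p.residue_pair not in retained_set:
            continue
        key = ssl_io.feature_key(p)
        lf = forms[id(p)]
        features.setdefault(key, lf)
        feature_meta[str(key)] = (lf.sequence, lf.charge, lf.residue_pair)
        rts = run_rts.get(p.run_id)
        if rts is None or not 1 <= p.scan <= len(rts):
            continue
        id_rts.setdefault(key, {})[p.run_id] = float(rts[p.scan - 1])
    features = {k: v for k, v in features.items() if id_rts.get(k)}
    quant = xic.quantify_all(features, runs, id_rts,
                             tolerance=cfg.tolerance,
                             n_isotopes=cfg.n_isotopes,
                             search_window=cfg.search_window)
    xic.write_quant_table(quant, out / "quantitation.csv")
    s["n_features"] = len(features)
    s["n_psms_out_of_charge_range"] = n_out_of_charge
    s["n_rows"] = len(quant)
    s["n_matched_rows"] = int(quant["matched"].sum()) if len(quant) else 0

    # -- statistics ----------------------------------------------------------
    s = stage("stats")
    fcv = stats.feature_cv_table(quant)
    fcv.to_csv(out / "feature_cv.csv", index=False)
    feat_pairs = {k: k.link_sites for k in features}
    pairs = stats.build_pair_records(feat_pairs, fcv)
    if model is not None:
        structure.annotate_distances(pairs, model)
    s["n_pairs_quantifiable"] = len(pairs)

    pairs_lc, removed_lc = stats.filter_coeluting_alternatives(
        pairs, quant, feature_meta)
    s["n_removed_coelution"] = len(removed_lc)
    pairs_cq, removed_cq = stats.filter_complete_quant(
        pairs_lc, quant, n_runs=len(runs))
    s["n_removed_incomplete"] = len(removed_cq)
    s["n_quantified_pairs"] = len(pairs_cq)
    s["cv_summary"] = stats.experiment_cv_summary(pairs_cq)

    pair_rows = [{"residue_i": p.residues[0], "residue_j": p.residues[1],
                  "n_features": len(p.features),
                  "pair_cv": p.pair_cv, "median_area": p.median_area,
                  "ca_distance": p.ca_distance} for p in pairs_cq]
    pd.DataFrame(pair_rows).to_csv(out / "pair_cv.csv", index=False)

    per_run_sets = []
    for run in runs:
        per_run_sets.append({p.residue_pair for p in targets
                             if p.run_id == run.run_id
                             and p.residue_pair in retained_set})
    sat = stats.saturation_table(per_run_sets, seed=cfg.seed)
    sat.to_csv(out / "saturation.csv", index=False)
    freq = stats.observation_frequency(per_run_sets)
    pd.DataFrame({"n_replicas": list(freq), "n_pairs": list(freq.values())}
                 ).to_csv(out / "observation_frequency.csv", index=False)
    bins = stats.cv_by_intensity_bins(pairs_cq)
    bins.to_csv(out / "cv_by_intensity.csv", index=False)
    s["saturation_k1"] = float(sat["mean_unique_pairs"].iloc[0])
    s["saturation_kn"] = float(sat["mean_unique_pairs"].iloc[-1])
    s["observation_frequency"] = freq

    # counts must shrink monotonically along the pipeline
    report["stage_counts"] = {
        "identified_pairs": report["stages"]["identifications"]["n_unique_pairs"],
        "distance_passed": report["stages"]["structure"]["n_retained"],
        "quantifiable": s["n_pairs_quantifiable"],
        "ambiguity_passed": s["n_pairs_quantifiable"] - s["n_removed_coelution"],
        "complete_quantified": s["n_quantified_pairs"],
    }
    report["runtime_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
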