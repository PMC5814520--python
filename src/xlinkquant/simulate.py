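"""Self-contained synthetic QCLMS worlds for testing and validation.

Generates a random protein, its BS3-cross-linked tryptic peptide pairs with
known ground-truth peak areas, replicate MS1 acquisitions (centroided, 3 s
cycle) with controlled between-replica noise, the matching PSM table an
identification engine would emit, and a toy PDB — so the whole pipeline is
exercisable without any external data.

Two replica designs are emulated: *injection* replicas (repeated injections
of one pooled sample; low multiplicative noise, default CV 14%, small RT
jitter) and *reaction* replicas (parallel cross-linking reactions; higher
noise, default CV 32%, larger RT jitter).  Between-replica variation is
log-normal multiplicative with sigma chosen so the population CV equals the
target; isotope envelope abundances follow a crude mass-dependent heuristic
(adequate because quantitation sums isotopes; deliberately non-physical).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import get_modification, mz_from_mass, C13_SPACING
from .linearize import (CrossLinkPSM, crosslinked_mass, to_linear_form,
                        write_psm_table)
from .mzml_io import MS1Run, write_mzml
from .ssl_io import FeatureKey, feature_key

AA_ALPHABET = "ACDEFGHILMNPQSTVWY"  # K/R appended separately as cleavage sites


class SimulationError(ValueError):
    pass


# -- in-silico digestion -----------------------------------------------------

@dataclass(frozen=True)
class TrypticPeptide:
    start: int      # 1-based position of the first residue in the protein
    sequence: str
    missed: int     # number of missed cleavage sites


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cleaves (K/R not before P)."""
    return [i + 1 for i, ch in enumerate(sequence)
            if ch in "KR" and (i + 1 == len(sequence)
                               or sequence[i + 1] != "P")]


def digest(protein: str, max_missed: int = 4, min_len: int = 6,
           max_len: int = 60) -> list[TrypticPeptide]:
    """All tryptic peptides with 0..max_missed missed cleavages.

    Cleavage after K/R except before P; peptides outside the length bounds
    are dropped.
    """
    if not protein:
        raise SimulationError("empty protein sequence")
    bounds = [0] + cleavage_sites(protein)
    if bounds[-1] != len(protein):
        bounds.append(len(protein))
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            seq = protein[bounds[a]:bounds[b]]
            if min_len <= len(seq) <= max_len:
                peptides.append(TrypticPeptide(bounds[a] + 1, seq, b - a - 1))
    return peptides


# -- simulation parameters and truth -----------------------------------------

@dataclass
class SimulationParams:
    """Study conditions of one synthetic replicate experiment."""

    n_pairs: int = 55
    n_runs: int = 10
    experiment: str = "injection"        # "injection" | "reaction"
    cv_target: float | None = None       # fraction; default 0.14 / 0.32
    rt_jitter_sd: float | None = None    # minutes; default 0.1 / 0.3
    protein_length: int = 360
    gradient_min: float = 20.0
    cycle_time_s: float = 3.0
    peak_sigma_min: float = 0.15
    area_log10_lo: float = 5.0
    area_log10_hi: float = 8.0
    id_prob: float = 0.7                 # per-run identification probability
    n_coeluting: int = 1                 # planted LC-unresolved site variants
    n_separated_alt: int = 1             # planted LC-resolved site variants
    n_absent: int = 1                    # features absent from one run
    n_decoys: int = 3
    n_violating: int = 4                 # pairs planted beyond 30 A
    second_charge_prob: float = 0.3
    intensity_dependent_cv: bool = False
    cv_lo: float = 0.05                  # used when intensity_dependent_cv
    cv_hi: float = 0.40
    noise_floor: float = 5.0
    noise_peaks_per_spectrum: int = 10
    max_missed: int = 4
    run_shift_max: float = 0.4           # per-run constant RT offset bound

    def resolved_cv(self) -> float:
        if self.cv_target is not None:
            return self.cv_target
        return 0.14 if self.experiment == "injection" else 0.32

    def resolved_jitter(self) -> float:
        if self.rt_jitter_sd is not None:
            return self.rt_jitter_sd
        return 0.1 if self.experiment == "injection" else 0.3


@dataclass
class SyntheticFeature:
    """Ground truth of one cross-linking feature."""

    index: int
    psm_template: CrossLinkPSM      # run/scan fields unused in the template
    charge: int
    mono_mz: float
    base_rt: float                  # minutes
    base_area: float                # summed-isotope area, intensity*min
    cv: float                       # target fractional CV of this feature
    areas: np.ndarray = field(default=None)      # per-run true areas
    apex_rts: np.ndarray = field(default=None)   # per-run apex RTs
    identified_runs: list[int] = field(default_factory=list)
    role: str = "normal"  # normal|coelute|separated_alt|absent

    @property
    def key(self) -> FeatureKey:
        return feature_key(self.psm_template)

    @property
    def residue_pair(self) -> tuple[int, int]:
        return self.psm_template.residue_pair


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and check one synthetic world."""

    params: SimulationParams
    seed: int
    protein: str
    features: list[SyntheticFeature]
    decoy_psms: list[CrossLinkPSM]
    run_ids: list[str]
    run_shifts: np.ndarray
    ca_coords: np.ndarray           # (protein_length, 3)
    pair_distances: dict[tuple[int, int], float]
    violating_pairs: set[tuple[int, int]]

    def isotope_ratios(self, mass: float) -> tuple[float, float]:
        r1 = min(0.0005 * mass, 1.2)
        r2 = min(0.5 * (0.0005 * mass) ** 2, 1.0)
        return r1, r2

    def target_pairs(self) -> set[tuple[int, int]]:
        return {f.residue_pair for f in self.features}

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "params": asdict(self.params),
            "protein": self.protein,
            "run_ids": self.run_ids,
            "features": [{
                "index": f.index, "key": str(f.key), "charge": f.charge,
                "mono_mz": f.mono_mz, "base_rt": f.base_rt,
                "base_area": f.base_area, "cv": f.cv, "role": f.role,
                "residue_pair": list(f.residue_pair),
                "areas": [float(a) for a in f.areas],
                "apex_rts": [float(t) for t in f.apex_rts],
                "identified_runs": f.identified_runs,
            } for f in self.features],
            "violating_pairs": sorted(map(list, self.violating_pairs)),
            "pair_distances": {f"{i}-{j}": d for (i, j), d
                               in sorted(self.pair_distances.items())},
        }


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein built from short tryptic blocks ending in K/R, with
    C/M/S/T/Y sprinkled in so fixed/variable mods and link sites occur."""
    out: list[str] = []
    while len(out) < length - 1:
        block = rng.integers(5, 12)
        out.extend(rng.choice(list(AA_ALPHABET), size=block))
        out.append("K" if rng.random() < 0.7 else "R")
    return "".join(out[:length - 1]) + "K"


def _pick_charge(mass: float, extra: bool, rng: np.random.Generator
                 ) -> list[int]:
    """Smallest charge 3..7 putting the precursor in m/z 400-1600; possibly
    one additional adjacent charge state."""
    charges = [z for z in range(3, 8) if 400.0 <= mz_from_mass(mass, z) <= 1600.0]
    if not charges:
        return []
    picked = [charges[0]]
    if extra and len(charges) > 1:
        picked.append(charges[1])
    return picked


def _default_mods(pep: str, rng: np.random.Generator):
    mods = []
    for i, ch in enumerate(pep, start=1):
        if ch == "C":
            mods.append((i, get_modification("cm")))
        elif ch == "M" and rng.random() < 0.3:
            mods.append((i, get_modification("ox")))
    return tuple(mods)


def _link_sites(pep: str) -> list[int]:
    # exclude the C-terminal K/R: a cross-linked K blocks cleavage there
    return [i for i, ch in enumerate(pep[:-1], start=1) if ch in "KSTY"]


def build_truth(params: SimulationParams, seed: int) -> SyntheticTruth:
    """Deterministically build the ground truth of one synthetic world.

    The world always contains at least one pair of LC-unresolved
    alternative-linkage features (exercises the co-elution filter) and at
    least one feature absent from one run (exercises the complete-
    quantitation filter), as long as the corresponding counts are > 0.
    """
    rng = np.random.default_rng(seed)
    protein = _random_protein(rng, params.protein_length)
    peptides = [p for p in digest(protein, params.max_missed)
                if p.missed <= 2 and _link_sites(p.sequence)]
    if len(peptides) < 4:
        raise SimulationError("protein too short for cross-link generation")
    n_linkable = len({p.start + s - 1 for p in peptides
                      for s in _link_sites(p.sequence)})
    if params.n_pairs > n_linkable * (n_linkable - 1) // 2:
        raise SimulationError(
            f"requested {params.n_pairs} residue pairs but only "
            f"{n_linkable} cross-linkable positions exist")

    sigma_grid = 0.25  # minimal m/z separation between distinct features
    used_mz: list[float] = []
    used_pairs: set[tuple[int, int]] = set()
    features: list[SyntheticFeature] = []

    def mz_clear(mz: float, z: int) -> bool:
        iso = [mz + k * C13_SPACING / z for k in range(3)]
        return all(abs(m - u) > sigma_grid for m in iso for u in used_mz)

    def register(mz: float, z: int) -> None:
        used_mz.extend(mz + k * C13_SPACING / z for k in range(3))

    def make_psm(pa: TrypticPeptide, pb: TrypticPeptide, sa: int, sb: int,
                 charge: int, mods_a, mods_b) -> CrossLinkPSM:
        return CrossLinkPSM(
            run_id="", scan=0, charge=charge,
            pep_a=pa.sequence, pep_b=pb.sequence, site_a=sa, site_b=sb,
            prot_pos_a=pa.start + sa - 1, prot_pos_b=pb.start + sb - 1,
            mods_a=mods_a, mods_b=mods_b,
            score=float(rng.uniform(5, 25)))

    def new_feature(psm: CrossLinkPSM, charge: int, base_rt: float,
                    role: str) -> SyntheticFeature:
        lf = to_linear_form(psm)
        return SyntheticFeature(
            index=len(features), psm_template=psm, charge=charge,
            mono_mz=mz_from_mass(lf.neutral_mass, charge),
            base_rt=base_rt,
            base_area=float(10 ** rng.uniform(params.area_log10_lo,
                                              params.area_log10_hi)),
            cv=0.0, role=role)

    n_wanted = params.n_pairs
    attempts = 0
    while len(used_pairs) < n_wanted:
        attempts += 1
        if attempts > 200 * n_wanted:
            raise SimulationError(
                f"could not place {n_wanted} residue pairs; protein has too "
                "few cross-linkable sites for the requested world")
        ia, ib = rng.integers(0, len(peptides), size=2)
        pa, pb = peptides[ia], peptides[ib]
        if pa.sequence == pb.sequence:
            continue
        sa = int(rng.choice(_link_sites(pa.sequence)))
        sb = int(rng.choice(_link_sites(pb.sequence)))
        pair = tuple(sorted((pa.start + sa - 1, pb.start + sb - 1)))
        if pair in used_pairs:
            continue
        mods_a = _default_mods(pa.sequence, rng)
        mods_b = _default_mods(pb.sequence, rng)
        try:
            psm = make_psm(pa, pb, sa, sb, 3, mods_a, mods_b)
        except ValueError:
            continue
        mass = crosslinked_mass(psm)
        charges = _pick_charge(mass, rng.random() < params.second_charge_prob,
                               rng)
        if not charges or not all(
                mz_clear(mz_from_mass(mass, z), z) for z in charges):
            continue
        used_pairs.add(pair)
        base_rt = float(rng.uniform(2.0, params.gradient_min - 2.0))
        for z in charges:
            psm_z = make_psm(pa, pb, sa, sb, z, mods_a, mods_b)
            feat = new_feature(psm_z, z, base_rt, "normal")
            register(feat.mono_mz, z)
            features.append(feat)

    # planted alternative-linkage variants: same peptide pair and charge,
    # different link site -> identical m/z, distinguishable only by RT
    def plant_alternatives(n: int, rt_gap: float, role: str) -> None:
        planted = 0
        for feat in list(features):
            if planted >= n:
                break
            if feat.role != "normal":
                continue
            t = feat.psm_template
            pa_sites = [s for s in _link_sites(t.pep_a) if s != t.site_a]
            if not pa_sites:
                continue
            sa2 = int(pa_sites[0])
            pair2 = tuple(sorted((t.prot_pos_a + sa2 - t.site_a,
                                  t.prot_pos_b)))
            if pair2 in used_pairs or pair2[0] == pair2[1]:
                continue
            psm2 = CrossLinkPSM(
                run_id="", scan=0, charge=t.charge, pep_a=t.pep_a,
                pep_b=t.pep_b, site_a=sa2, site_b=t.site_b,
                prot_pos_a=t.prot_pos_a + sa2 - t.site_a,
                prot_pos_b=t.prot_pos_b, mods_a=t.mods_a, mods_b=t.mods_b,
                score=float(rng.uniform(5, 25)))
            rt2 = feat.base_rt + rt_gap
            if not 1.0 <= rt2 <= params.gradient_min - 1.0:
                continue
            feat.role = role
            f2 = new_feature(psm2, t.charge, rt2, role)
            f2.base_area = feat.base_area * float(rng.uniform(0.5, 2.0))
            used_pairs.add(pair2)
            features.append(f2)
            planted += 1
        if planted < n:
            raise SimulationError(f"could not plant {n} {role} variants")

    if params.n_coeluting:
        plant_alternatives(params.n_coeluting, 0.05, "coelute")
    if params.n_separated_alt:
        plant_alternatives(params.n_separated_alt, 3.0, "separated_alt")

    # per-feature CV targets
    cv0 = params.resolved_cv()
    log_areas = np.log10([f.base_area for f in features])
    for f, la in zip(features, log_areas):
        if params.intensity_dependent_cv:
            frac = (la - params.area_log10_lo) / max(
                params.area_log10_hi - params.area_log10_lo, 1e-9)
            f.cv = params.cv_hi - (params.cv_hi - params.cv_lo) * float(
                np.clip(frac, 0.0, 1.0))
        else:
            f.cv = cv0

    # per-run truth: areas (log-normal multiplicative) and apex RTs
    n_runs = params.n_runs
    run_ids = [f"{params.experiment}_{i + 1:02d}" for i in range(n_runs)]
    run_shifts = rng.uniform(-params.run_shift_max, params.run_shift_max,
                             size=n_runs)
    jitter = params.resolved_jitter()
    for f in features:
        sigma = math.sqrt(math.log(1.0 + f.cv ** 2))
        mult = np.exp(rng.normal(0.0, sigma, size=n_runs)) if sigma > 0 \
            else np.ones(n_runs)
        f.areas = f.base_area * mult
        f.apex_rts = np.clip(
            f.base_rt + run_shifts + rng.normal(0.0, jitter, size=n_runs),
            0.5, params.gradient_min - 0.5)

    # absent features: zero area in one run; keep clear of pairs involved
    # in the planted LC-ambiguity scenarios so each filter has its own
    # unambiguous victim
    planted_pairs = {f.residue_pair for f in features if f.role != "normal"}
    candidates = [f for f in features if f.role == "normal"
                  and f.residue_pair not in planted_pairs]
    for f in candidates[:params.n_absent]:
        f.role = "absent"
        f.areas[n_runs // 2] = 0.0

    # identification schedule (>= 1 run each, Bernoulli otherwise)
    for f in features:
        ids = [r for r in range(n_runs)
               if rng.random() < params.id_prob and f.areas[r] > 0]
        if not ids:
            present = [r for r in range(n_runs) if f.areas[r] > 0]
            ids = [int(rng.choice(present))]
        f.identified_runs = ids

    # decoy PSMs from the reversed protein
    decoy_psms: list[CrossLinkPSM] = []
    rev = protein[::-1]
    rev_peps = [p for p in digest(rev, params.max_missed)
                if p.missed <= 2 and _link_sites(p.sequence)]
    while len(decoy_psms) < params.n_decoys and len(rev_peps) >= 2:
        ia, ib = rng.integers(0, len(rev_peps), size=2)
        pa, pb = rev_peps[ia], rev_peps[ib]
        if pa.sequence == pb.sequence:
            continue
        sa = int(rng.choice(_link_sites(pa.sequence)))
        sb = int(rng.choice(_link_sites(pb.sequence)))
        psm = CrossLinkPSM(
            run_id=run_ids[int(rng.integers(0, n_runs))],
            scan=int(rng.integers(1, 50)), charge=3,
            pep_a=pa.sequence, pep_b=pb.sequence, site_a=sa, site_b=sb,
            prot_pos_a=pa.start + sa - 1, prot_pos_b=pb.start + sb - 1,
            score=float(rng.uniform(1, 6)), is_decoy=True)
        decoy_psms.append(psm)

    # toy structure: compact coordinate cloud; designated violating pairs
    # get one residue displaced beyond the distance limit
    L = len(protein)
    coords = rng.normal(0.0, 7.0, size=(L, 3))
    coords *= (12.0 / np.maximum(np.linalg.norm(coords, axis=1),
                                 1e-9))[:, None] * rng.uniform(
        0.3, 1.0, size=L)[:, None]
    pair_list = sorted(used_pairs)
    viol_idx = rng.choice(len(pair_list),
                          size=min(params.n_violating, len(pair_list)),
                          replace=False)
    for vi in viol_idx:
        i, j = pair_list[vi]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[j - 1] = coords[i - 1] + direction * rng.uniform(33.0, 45.0)
    distances = {p: float(np.linalg.norm(coords[p[0] - 1] - coords[p[1] - 1]))
                 for p in pair_list}
    violating = {p for p, d in distances.items() if d >= 30.0}

    return SyntheticTruth(
        params=params, seed=seed, protein=protein, features=features,
        decoy_psms=decoy_psms, run_ids=run_ids, run_shifts=run_shifts,
        ca_coords=coords, pair_distances=distances, violating_pairs=violating)


# -- rendering ---------------------------------------------------------------

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def render_pdb(truth: SyntheticTruth, chain: str = "A") -> str:
    """Calpha-only PDB text of the toy structure."""
    lines = []
    for i, (ch, xyz) in enumerate(zip(truth.protein, truth.ca_coords),
                                  start=1):
        x, y, z = xyz
        lines.append(
            f"ATOM  {i:5d}  CA  {_ONE_TO_THREE[ch]:>3s} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f" C")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _scan_grid(params: SimulationParams) -> np.ndarray:
    cycle = params.cycle_time_s / 60.0
    n = int(params.gradient_min / cycle)
    return (np.arange(n) + 0.5) * cycle


def render_run(truth: SyntheticTruth, run_index: int) -> MS1Run:
    """Render one replica as a centroided MS1 run.

    Each present feature elutes as a Gaussian (apex, sigma from the truth)
    times a 3-peak isotope envelope at its charge's m/z; a uniform random
    noise floor is added to every spectrum.
    """
    params = truth.params
    rng = np.random.default_rng((truth.seed + 1) * 10_000 + run_index)
    rts = _scan_grid(params)
    sigma = params.peak_sigma_min
    mz_acc: list[list[float]] = [[] for _ in rts]
    int_acc: list[list[float]] = [[] for _ in rts]

    for f in truth.features:
        area = f.areas[run_index]
        if area <= 0:
            continue
        apex = f.apex_rts[run_index]
        r1, r2 = truth.isotope_ratios(
            f.mono_mz * f.charge)  # ~neutral mass scale
        envelope = np.array([1.0, r1, r2])
        a_mono = area / envelope.sum()
        amp = a_mono / (sigma * math.sqrt(2.0 * math.pi))
        lo = np.searchsorted(rts, apex - 4 * sigma)
        hi = np.searchsorted(rts, apex + 4 * sigma)
        gauss = amp * np.exp(-0.5 * ((rts[lo:hi] - apex) / sigma) ** 2)
        iso_mz = [f.mono_mz + k * C13_SPACING / f.charge for k in range(3)]
        for s, g in zip(range(lo, hi), gauss):
            for k in range(3):
                mz_acc[s].append(iso_mz[k])
                int_acc[s].append(g * envelope[k])

    spectra = []
    for s in range(len(rts)):
        n_noise = params.noise_peaks_per_spectrum
        if n_noise:
            mz_acc[s].extend(rng.uniform(400.0, 1600.0, size=n_noise))
            int_acc[s].extend(params.noise_floor *
                              rng.uniform(0.5, 1.5, size=n_noise))
        mz = np.asarray(mz_acc[s])
        inten = np.asarray(int_acc[s])
        order = np.argsort(mz, kind="stable")
        spectra.append((mz[order], inten[order]))
    return MS1Run(run_id=truth.run_ids[run_index], rts=rts, spectra=spectra)


def psm_rows(truth: SyntheticTruth) -> list[CrossLinkPSM]:
    """The PSM table an identification engine would emit: one row per
    (feature, identified run), plus the decoy matches."""
    from dataclasses import replace
    cycle = truth.params.cycle_time_s / 60.0
    rows = []
    for f in truth.features:
        for r in f.identified_runs:
            scan = int(np.clip(round(f.apex_rts[r] / cycle - 0.5) + 1,
                               1, int(truth.params.gradient_min / cycle)))
            rows.append(replace(f.psm_template, run_id=truth.run_ids[r],
                                scan=scan))
    rows.extend(truth.decoy_psms)
    return rows


@dataclass
class RenderedWorld:
    truth: SyntheticTruth
    runs: list[MS1Run]
    psms: list[CrossLinkPSM]
    pdb_text: str


def render_runs(truth: SyntheticTruth,
                outdir: str | Path | None = None) -> RenderedWorld:
    """Render all replicas (and optionally write mzML / PSM table / toy PDB /
    truth JSON to ``outdir``)."""
    runs = [render_run(truth, i) for i in range(truth.params.n_runs)]
    world = RenderedWorld(truth=truth, runs=runs, psms=psm_rows(truth),
                          pdb_text=render_pdb(truth))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for run in runs:
            write_mzml(run, outdir / f"{run.run_id}.mzML")
        write_psm_table(world.psms, outdir / "psms.tsv")
        (outdir / "structure.pdb").write_text(world.pdb_text)
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_json(), indent=1))
    return world
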