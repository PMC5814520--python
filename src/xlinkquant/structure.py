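"""Validate cross-links against a crystal structure.

BS3 bridges residues up to roughly 25-30 A apart (Calpha-Calpha), so
identified residue pairs whose Calpha distance in a reference structure is
>= 30 A are treated as likely false and excluded before quantitation, along
with decoy matches.  A random-pair distance baseline and a decoy-based FDR
complete the quality assessment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .stats import ResiduePairRecord

log = logging.getLogger(__name__)

DEFAULT_DISTANCE_THRESHOLD = 30.0  # Angstrom
#: BS3 reacts with lysine, serine, threonine, tyrosine and protein N-termini.
LINKABLE = frozenset("KSTY")


class StructureError(ValueError):
    pass


@dataclass
class StructureModel:
    """Calpha coordinates of one chain, indexed by residue number."""

    chain_id: str
    ca_coords: dict[int, np.ndarray] = field(default_factory=dict)
    #: residue number -> one-letter code where known (for linkable-site picks)
    residue_names: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ca_coords)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def load_ca_coords(pdb_file: str | Path, chain: str = "A") -> StructureModel:
    """Load one Calpha coordinate per residue of ``chain`` from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered).  Residues without a CA atom are omitted with
    a log message.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(pdb_file))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain not in chains:
        raise StructureError(
            f"chain {chain!r} not in {pdb_file}; available: "
            f"{sorted(chains)}")
    out = StructureModel(chain_id=chain)
    for residue in chains[chain]:
        if residue.id[0].strip():
            continue  # heteroatoms / waters
        resnum = residue.id[1]
        if "CA" not in residue:
            log.info("residue %s %d has no CA atom; omitted",
                     residue.get_resname(), resnum)
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            alts = atom.disordered_get_list()
            atom = max(alts, key=lambda a: a.get_occupancy() or 0.0)
        out.ca_coords[resnum] = np.asarray(atom.get_coord(), dtype=float)
        name = _THREE_TO_ONE.get(residue.get_resname().upper())
        if name:
            out.residue_names[resnum] = name
    return out


def ca_distance(model: StructureModel, i: int, j: int) -> float | None:
    """Euclidean Calpha-Calpha distance (A); None if either is unresolved."""
    a = model.ca_coords.get(i)
    b = model.ca_coords.get(j)
    if a is None or b is None:
        return None
    return float(np.linalg.norm(a - b))


def annotate_distances(pairs: Sequence[ResiduePairRecord],
                       model: StructureModel) -> None:
    """Attach Calpha distances to residue-pair records in place."""
    for p in pairs:
        p.ca_distance = ca_distance(model, *p.residues)


def distance_filter(
        pairs: Sequence[ResiduePairRecord], model: StructureModel | None,
        threshold: float = DEFAULT_DISTANCE_THRESHOLD,
        decoy_pairs: Iterable[tuple[int, int]] = (),
) -> tuple[list[ResiduePairRecord], list[ResiduePairRecord]]:
    """Remove pairs measured at >= ``threshold`` A, and all decoy pairs.

    Pairs whose distance cannot be measured (unresolved residue or no
    structure) are retained — they cannot be falsified — and logged.
    """
    decoys = {(min(i, j), max(i, j)) for i, j in decoy_pairs}
    retained, removed = [], []
    for p in pairs:
        d = ca_distance(model, *p.residues) if model is not None else None
        p.ca_distance = d
        if p.residues in decoys:
            removed.append(p)
            continue
        if d is None:
            if model is not None:
                log.info("pair %s unresolved in structure; retained",
                         p.residues)
            retained.append(p)
        elif d >= threshold:
            removed.append(p)
        else:
            retained.append(p)
    return retained, removed


def linkable_residues(model: StructureModel,
                      n_terminus: int | None = None) -> list[int]:
    """Residue numbers BS3 can react with (K/S/T/Y plus the N-terminus)."""
    out = {num for num, name in model.residue_names.items()
           if name in LINKABLE}
    if n_terminus is not None and n_terminus in model.ca_coords:
        out.add(n_terminus)
    return sorted(out)


def random_distance_distribution(model: StructureModel,
                                 linkable: Sequence[int],
                                 n_samples: int, seed: int) -> np.ndarray:
    """Distances of uniformly sampled unordered linkable-residue pairs.

    Sampling is without replacement within a draw (two distinct residues)
    and with replacement across draws; reproducible under ``seed``.
    """
    resolved = [r for r in linkable if r in model.ca_coords]
    if len(resolved) < 2:
        raise StructureError("need at least two resolved linkable residues")
    rng = np.random.default_rng(seed)
    out = np.empty(n_samples)
    for s in range(n_samples):
        i, j = rng.choice(len(resolved), size=2, replace=False)
        out[s] = ca_distance(model, resolved[i], resolved[j])
    return out


def decoy_fdr(flags: Sequence[bool]) -> dict:
    """Decoy-based FDR over a match list: 100 * n_decoy / n_total.

    Returns the percentage together with both counts so the reader can apply
    an alternative estimator to the same numbers.
    """
    n = len(flags)
    if n == 0:
        raise StructureError("FDR undefined for an empty match list")
    n_decoy = int(sum(bool(f) for f in flags))
    return {"n_decoy": n_decoy, "n_total": n,
            "fdr_percent": 100.0 * n_decoy / n}


def write_distance_table(pairs: Sequence[ResiduePairRecord],
                         path: str | Path) -> None:
    """Annotated cross-link table with a Calpha distance column."""
    import pandas as pd
    rows = [{"residue_i": p.residues[0], "residue_j": p.residues[1],
             "ca_distance": (round(p.ca_distance, 2)
                             if p.ca_distance is not None else ""),
             "n_features": len(p.features)} for p in pairs]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pseudobonds(pairs: Sequence[ResiduePairRecord], chain: str,
                      path: str | Path) -> None:
    """Pseudo-bond list for structure viewers (ChimeraX dialect)."""
    with open(path, "w") as fh:
        for p in pairs:
            i, j = p.residues
            fh.write(f"/{chain}:{i}@CA /{chain}:{j}@CA\n")
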