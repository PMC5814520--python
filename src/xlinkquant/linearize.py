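"""Convert cross-linked peptide pairs into mass-equivalent linear forms.

A BS3 cross-link between peptides A and B is represented as the single
sequence ``first + "K" + second`` where the inserted lysine carries the
``K_xlink`` modification (+27.98368 Da).  The arithmetic closes because

    inserted K residue + K_xlink delta - water = BS3 spacer (C8H10O2),

so the linear form has exactly the neutral mass of the cross-linked species
and can be handled by any tool built for linear peptides.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chem import (ChemError, Modification, get_modification, mz_from_mass,
                   peptide_mass, BS3_SPACER_MASS)

#: Residues BS3 can react with (plus protein N-termini).
LINKABLE_RESIDUES = frozenset("KSTY")

MASS_EQUIVALENCE_TOL = 1e-4  # Da


class LinearizeError(ValueError):
    pass


ModList = Sequence[tuple[int, Modification]]


@dataclass(frozen=True)
class CrossLinkPSM:
    """One identified cross-linked peptide spectrum match."""

    run_id: str
    scan: int
    charge: int
    pep_a: str
    pep_b: str
    site_a: int  # 1-based link position within pep_a
    site_b: int
    prot_pos_a: int  # 1-based residue index of the linked residue in the protein
    prot_pos_b: int
    mods_a: tuple[tuple[int, Modification], ...] = ()
    mods_b: tuple[tuple[int, Modification], ...] = ()
    score: float = 0.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        for pep, site, label in ((self.pep_a, self.site_a, "a"),
                                 (self.pep_b, self.site_b, "b")):
            if not pep:
                raise LinearizeError(f"peptide {label} is empty")
            if not 1 <= site <= len(pep):
                raise LinearizeError(
                    f"link site {site} outside peptide {label} ({pep})")
            if pep[site - 1] not in LINKABLE_RESIDUES and site != 1:
                raise LinearizeError(
                    f"link site {site} in peptide {label} ({pep}) is "
                    f"{pep[site - 1]}, not a cross-linkable residue")

    @property
    def residue_pair(self) -> tuple[int, int]:
        """Canonical (min, max) protein residue pair of this cross-link."""
        i, j = self.prot_pos_a, self.prot_pos_b
        return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class LinearForm:
    """Mass-equivalent linear representation of a cross-linked peptide pair."""

    sequence: str
    kxlink_position: int  # 1-based index of the inserted K
    mods: tuple[tuple[int, Modification], ...]
    neutral_mass: float
    charge: int
    precursor_mz: float
    link_sites: tuple[int, int] = (0, 0)  # within linear sequence, 1-based
    residue_pair: tuple[int, int] = (0, 0)  # protein coordinates, canonical
    is_decoy: bool = False


def crosslinked_mass(psm: CrossLinkPSM) -> float:
    """Neutral mass of the cross-linked species: both peptides + BS3 spacer."""
    return (peptide_mass(psm.pep_a, psm.mods_a)
            + peptide_mass(psm.pep_b, psm.mods_b)
            + BS3_SPACER_MASS)


def _canonical_order(psm: CrossLinkPSM) -> CrossLinkPSM:
    """Put the lexicographically smaller peptide first; ties broken by the
    smaller link site.  A deterministic order makes identical cross-links
    from different runs collapse to one quantitation feature."""
    key_a = (psm.pep_a, psm.site_a, psm.prot_pos_a)
    key_b = (psm.pep_b, psm.site_b, psm.prot_pos_b)
    if key_b < key_a:
        return replace(psm,
                       pep_a=psm.pep_b, pep_b=psm.pep_a,
                       site_a=psm.site_b, site_b=psm.site_a,
                       prot_pos_a=psm.prot_pos_b, prot_pos_b=psm.prot_pos_a,
                       mods_a=psm.mods_b, mods_b=psm.mods_a)
    return psm


def to_linear_form(psm: CrossLinkPSM) -> LinearForm:
    """Build the linear form ``first + K + second`` of a cross-link PSM.

    Modification positions of the first peptide are kept; the inserted K sits
    at ``len(first) + 1`` and carries K_xlink; positions within the second
    peptide shift by ``len(first) + 1``.  An N-terminal modification of the
    second peptide is re-mapped onto its first residue (that terminus no
    longer exists in the concatenated sequence).
    """
    p = _canonical_order(psm)
    first, second = p.pep_a, p.pep_b
    offset = len(first) + 1
    sequence = first + "K" + second

    mods: list[tuple[int, Modification]] = [(pos, m) for pos, m in p.mods_a]
    mods.append((offset, get_modification("K_xlink")))
    for pos, m in p.mods_b:
        mods.append((offset + pos if pos >= 1 else offset + 1, m))

    seen: set[int] = set()
    for pos, _ in mods:
        if pos != 0 and pos in seen:
            raise LinearizeError(
                f"modification position collision at {pos} after remapping "
                f"({sequence}); malformed input")
        seen.add(pos)

    mods.sort(key=lambda pm: pm[0])
    mass = peptide_mass(sequence, mods)
    return LinearForm(
        sequence=sequence,
        kxlink_position=offset,
        mods=tuple(mods),
        neutral_mass=mass,
        charge=p.charge,
        precursor_mz=mz_from_mass(mass, p.charge),
        link_sites=(p.site_a, offset + p.site_b),
        residue_pair=p.residue_pair,
        is_decoy=p.is_decoy,
    )


def verify_mass_equivalence(lf: LinearForm, psm: CrossLinkPSM) -> float:
    """Absolute difference between the linear-form mass and the cross-linked
    mass of the source PSM.  The pipeline asserts this is < 1e-4 Da."""
    return abs(lf.neutral_mass - crosslinked_mass(psm))


# -- PSM table I/O -----------------------------------------------------------

PSM_COLUMNS = ["run", "scan", "charge", "PepSeq1", "PepSeq2", "LinkPos1",
               "LinkPos2", "Protein1Pos", "Protein2Pos", "Mods1", "Mods2",
               "score", "decoy"]


def _format_mods(mods: ModList) -> str:
    return ";".join(f"{pos}:{m.name}" for pos, m in mods)


def _parse_mods(text: str) -> tuple[tuple[int, Modification], ...]:
    if not text or (isinstance(text, float) and pd.isna(text)):
        return ()
    out = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        pos_s, _, name = item.partition(":")
        out.append((int(pos_s), get_modification(name)))
    return tuple(out)


def write_psm_table(psms: Sequence[CrossLinkPSM], path: str | Path,
                    sep: str = "\t") -> None:
    rows = []
    for p in psms:
        rows.append({
            "run": p.run_id, "scan": p.scan, "charge": p.charge,
            "PepSeq1": p.pep_a, "PepSeq2": p.pep_b,
            "LinkPos1": p.site_a, "LinkPos2": p.site_b,
            "Protein1Pos": p.prot_pos_a, "Protein2Pos": p.prot_pos_b,
            "Mods1": _format_mods(p.mods_a), "Mods2": _format_mods(p.mods_b),
            "score": p.score, "decoy": int(p.is_decoy),
        })
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep=sep, index=False,
                                                   float_format="%.17g")


def read_psm_table(path: str | Path) -> list[CrossLinkPSM]:
    """Read a delimited PSM table (tab or comma, auto-detected)."""
    text = Path(path).read_text()
    dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters="\t,")
    df = pd.read_csv(io.StringIO(text), sep=dialect.delimiter,
                     keep_default_na=False, float_precision="round_trip")
    missing = [c for c in PSM_COLUMNS if c not in df.columns and
               c not in ("Mods1", "Mods2", "score", "decoy")]
    if missing:
        raise LinearizeError(f"PSM table missing required columns: {missing}")
    psms = []
    for _, r in df.iterrows():
        psms.append(CrossLinkPSM(
            run_id=str(r["run"]), scan=int(r["scan"]), charge=int(r["charge"]),
            pep_a=str(r["PepSeq1"]), pep_b=str(r["PepSeq2"]),
            site_a=int(r["LinkPos1"]), site_b=int(r["LinkPos2"]),
            prot_pos_a=int(r["Protein1Pos"]), prot_pos_b=int(r["Protein2Pos"]),
            mods_a=_parse_mods(r.get("Mods1", "")),
            mods_b=_parse_mods(r.get("Mods2", "")),
            score=float(r.get("score", 0.0) or 0.0),
            is_decoy=bool(int(r.get("decoy", 0) or 0)),
        ))
    return psms
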