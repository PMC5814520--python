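"""Monoisotopic mass arithmetic for peptides, BS3 modifications and isotope envelopes.

All masses are monoisotopic daltons. The package targets high-resolution
Orbitrap data; average masses are deliberately unsupported. Residue masses are
fixed in code at 5-decimal precision so downstream tests are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

# -- elemental monoisotopic masses (Da) --------------------------------------
MASS_H = 1.00782503
MASS_C = 12.0
MASS_N = 14.00307401
MASS_O = 15.99491462
MASS_S = 31.97207117

PROTON_MASS = 1.007276
WATER_MASS = 18.010565
NH3_MASS = 17.02654911
C13_SPACING = 1.003355  # C13 - C12

#: Monoisotopic residue (i.e. amino-acid-minus-water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: BS3 spacer, C8H10O2 — what remains bridging the two peptides once both
#: NHS esters have reacted.
BS3_SPACER_MASS = 8 * MASS_C + 10 * MASS_H + 2 * MASS_O


class ChemError(ValueError):
    """Raised for invalid residues, positions or charges."""


@dataclass(frozen=True)
class Modification:
    """A named mass modification.

    ``targets`` holds single-letter residue codes; ``n_term`` marks a
    modification that may sit on the peptide N-terminus (position 0).
    """

    name: str
    delta_mass: float
    targets: frozenset[str] = field(default_factory=frozenset)
    n_term: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.name}({self.delta_mass:+.5f})"


def _std_mods() -> dict[str, Modification]:
    spacer = BS3_SPACER_MASS
    return {
        m.name: m
        for m in (
            # fixed / variable search modifications
            Modification("cm", 2 * MASS_C + 3 * MASS_H + MASS_N + MASS_O,
                         frozenset("C")),  # carbamidomethyl, +57.02146
            Modification("ox", MASS_O, frozenset("M")),  # oxidation, +15.99491
            # BS3-derived modifications.  The bridge mass in a linearized
            # cross-link lives on one inserted lysine: spacer minus the
            # lysine residue that the insertion itself adds, plus the water
            # the extra residue removes from the chain sum.
            Modification("K_xlink",
                         spacer - RESIDUE_MASSES["K"] + WATER_MASS,
                         frozenset("K")),  # +27.98368
            Modification("bs3oh", spacer + WATER_MASS,
                         frozenset("KSTY"), n_term=True),  # hydrolyzed, +156.07864
            Modification("bs3nh2", spacer + NH3_MASS,
                         frozenset("KSTY"), n_term=True),  # aminated, +155.09463
            Modification("bs3loop", spacer,
                         frozenset("KSTY"), n_term=True),  # loop-link, +138.06808
        )
    }


#: Default modification registry.  Users may register further cross-linker
#: chemistries via :func:`register_modification`.
MODIFICATIONS: dict[str, Modification] = _std_mods()


def register_modification(mod: Modification) -> None:
    """Add (or replace) a modification in the global registry."""
    MODIFICATIONS[mod.name] = mod


def get_modification(name: str) -> Modification:
    try:
        return MODIFICATIONS[name]
    except KeyError:
        raise ChemError(f"unknown modification {name!r}") from None


def peptide_mass(sequence: str,
                 mods: Sequence[tuple[int, Modification]] = ()) -> float:
    """Neutral monoisotopic mass of a (modified) linear peptide.

    Parameters
    ----------
    sequence
        Residue string using single-letter codes.
    mods
        ``(position, Modification)`` pairs; positions are 1-based within the
        peptide, 0 denotes the N-terminus.
    """
    if not sequence:
        raise ChemError("empty peptide sequence")
    mass = WATER_MASS
    for ch in sequence:
        try:
            mass += RESIDUE_MASSES[ch]
        except KeyError:
            raise ChemError(f"unknown residue code {ch!r}") from None
    for pos, mod in mods:
        if not 0 <= pos <= len(sequence):
            raise ChemError(
                f"modification position {pos} out of range for "
                f"peptide of length {len(sequence)}")
        mass += mod.delta_mass
    return mass


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass at positive charge ``z`` (proton adducts)."""
    if z < 1:
        raise ChemError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def isotope_mz(mono_mz: float, z: int, k: int, max_isotopes: int = 3) -> float:
    """m/z of the k-th isotope peak (k = 0 is the monoisotopic peak).

    The envelope is limited to ``max_isotopes`` peaks (default 3: M, M+1,
    M+2), matching MS1-filtering practice on Orbitrap data.
    """
    if z < 1:
        raise ChemError(f"charge must be >= 1, got {z}")
    if not 0 <= k < max_isotopes:
        raise ChemError(
            f"isotope index {k} outside supported envelope 0..{max_isotopes - 1}")
    return mono_mz + k * C13_SPACING / z


def isotope_mzs(mono_mz: float, z: int, n: int = 3) -> list[float]:
    """The first ``n`` isotope m/z values of a precursor."""
    return [isotope_mz(mono_mz, z, k, max_isotopes=n) for k in range(n)]


def modification_table(mods: Iterable[Modification] | None = None) -> str:
    """Render the registry as a small TSV config table (name, delta, targets)."""
    rows = ["name\tdelta_mass\ttargets\tn_term"]
    for m in (mods if mods is not None else MODIFICATIONS.values()):
        rows.append(f"{m.name}\t{m.delta_mass:.5f}\t"
                    f"{''.join(sorted(m.targets))}\t{int(m.n_term)}")
    return "\n".join(rows) + "\n"
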