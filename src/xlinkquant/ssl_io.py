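"""Read/write .ssl spectrum-sequence-list files and canonical feature keys.

The .ssl dialect is the tab-separated BiblioSpec input: one row per PSM with
columns ``file  scan  charge  sequence  score-type  score``.  Modified
sequences carry signed bracketed mass deltas with 5 decimal places directly
after the modified residue, e.g. ``AKK[+27.98368]GGR``; an N-terminal
modification is a leading bracket before the first residue.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem import WATER_MASS, RESIDUE_MASSES, ChemError
from .linearize import CrossLinkPSM, LinearForm, to_linear_form

SSL_HEADER = ["file", "scan", "charge", "sequence", "score-type", "score"]
DEFAULT_SCORE_TYPE = "UNKNOWN"

_MOD_RE = re.compile(r"\[([+-]\d+(?:\.\d+)?)\]")


class SSLError(ValueError):
    pass


@dataclass(frozen=True)
class SSLRecord:
    file: str
    scan: int
    charge: int
    sequence: str  # modified-sequence text
    score_type: str = DEFAULT_SCORE_TYPE
    score: float = 0.0


def render_mod_sequence(lf: LinearForm) -> str:
    """Linear sequence with bracketed 5-decimal mass deltas after each
    modified residue (position 0 renders as a leading bracket)."""
    by_pos: dict[int, float] = {}
    for pos, mod in lf.mods:
        by_pos[pos] = by_pos.get(pos, 0.0) + mod.delta_mass
    out = []
    if 0 in by_pos:
        out.append(f"[{by_pos[0]:+.5f}]")
    for i, ch in enumerate(lf.sequence, start=1):
        out.append(ch)
        if i in by_pos:
            out.append(f"[{by_pos[i]:+.5f}]")
    return "".join(out)


def parse_mod_sequence(text: str) -> tuple[str, list[tuple[int, float]]]:
    """Split a modified-sequence string into (plain sequence, [(pos, delta)]).

    Positions are 1-based; a leading bracket maps to position 0.
    """
    seq: list[str] = []
    deltas: list[tuple[int, float]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            m = _MOD_RE.match(text, i)
            if not m:
                raise SSLError(f"malformed bracketed modification in {text!r}")
            deltas.append((len(seq), float(m.group(1))))
            i = m.end()
        else:
            if not ch.isalpha() or ch.upper() not in RESIDUE_MASSES:
                raise SSLError(f"unexpected character {ch!r} in sequence {text!r}")
            seq.append(ch.upper())
            i += 1
    return "".join(seq), deltas


def mod_sequence_mass(text: str) -> float:
    """Neutral mass implied by a modified-sequence string."""
    seq, deltas = parse_mod_sequence(text)
    if not seq:
        raise SSLError(f"no residues in sequence {text!r}")
    try:
        mass = WATER_MASS + sum(RESIDUE_MASSES[c] for c in seq)
    except KeyError as e:  # pragma: no cover - guarded in parse
        raise SSLError(f"unknown residue {e} in {text!r}") from None
    return mass + sum(d for _, d in deltas)


def record_from_psm(psm: CrossLinkPSM, mzml_file: str,
                    score_type: str = DEFAULT_SCORE_TYPE) -> SSLRecord:
    lf = to_linear_form(psm)
    return SSLRecord(file=mzml_file, scan=psm.scan, charge=psm.charge,
                     sequence=render_mod_sequence(lf),
                     score_type=score_type, score=psm.score)


def write_ssl(records: Sequence[SSLRecord], path: str | Path) -> None:
    """Write records as tab-separated .ssl with the standard header.

    One row per PSM — no deduplication at this layer; a spectral library
    entry exists for every identified spectrum of every feature.
    """
    if not records:
        raise SSLError("no records to write")
    for r in records:
        if not 1 <= r.charge <= 9:
            raise SSLError(f"charge {r.charge} outside 1..9 in record "
                           f"scan={r.scan}")
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(SSL_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.file}\t{r.scan}\t{r.charge}\t{r.sequence}\t"
                     f"{r.score_type}\t{r.score!r}\n")


def read_ssl(path: str | Path) -> list[SSLRecord]:
    """Parse an .ssl file (tab or comma separated; extra columns ignored)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SSLError(f"{path}: empty file")
    dialect = csv.Sniffer().sniff(lines[0], delimiters="\t,")
    rows = list(csv.DictReader(io.StringIO(text), delimiter=dialect.delimiter))
    header = rows[0].keys() if rows else csv.DictReader(
        io.StringIO(text), delimiter=dialect.delimiter).fieldnames or []
    for col in SSL_HEADER:
        if col not in header:
            raise SSLError(f"{path}: missing required column {col!r}")
    records = []
    for lineno, row in enumerate(rows, start=2):
        try:
            scan = int(row["scan"])
            charge = int(row["charge"])
            score = float(row["score"])
        except (TypeError, ValueError) as e:
            raise SSLError(f"{path}: line {lineno}: {e}") from None
        parse_mod_sequence(row["sequence"])  # validates, raises with context
        records.append(SSLRecord(file=row["file"], scan=scan, charge=charge,
                                 sequence=row["sequence"],
                                 score_type=row["score-type"], score=score))
    return records


# -- feature keys ------------------------------------------------------------

@dataclass(frozen=True, order=True)
class FeatureKey:
    """Canonical identity of a cross-linking feature.

    A feature is a unique combination of linearized (modified) peptide
    sequence, charge state and linkage sites; records sharing a key are the
    same quantitation unit across runs.
    """

    mod_sequence: str
    charge: int
    link_sites: tuple[int, int]

    def __str__(self) -> str:
        i, j = self.link_sites
        return f"{self.mod_sequence}/{self.charge}@{i}-{j}"


def feature_key(obj: CrossLinkPSM | LinearForm | SSLRecord) -> FeatureKey:
    """Canonical, peptide-order-invariant key of a PSM / linear form / record.

    For .ssl records (which do not carry protein coordinates) the linkage
    component is empty; keys from records are comparable among records only.
    """
    if isinstance(obj, CrossLinkPSM):
        obj = to_linear_form(obj)
    if isinstance(obj, LinearForm):
        return FeatureKey(render_mod_sequence(obj), obj.charge,
                          obj.residue_pair)
    if isinstance(obj, SSLRecord):
        return FeatureKey(obj.sequence, obj.charge, (0, 0))
    raise TypeError(f"cannot build a feature key from {type(obj).__name__}")


def group_by_feature(psms: Iterable[CrossLinkPSM]
                     ) -> dict[FeatureKey, list[CrossLinkPSM]]:
    """Partition PSMs by feature key (insertion-ordered)."""
    groups: dict[FeatureKey, list[CrossLinkPSM]] = {}
    for p in psms:
        groups.setdefault(feature_key(p), []).append(p)
    return groups
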