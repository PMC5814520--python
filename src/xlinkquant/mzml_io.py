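"""Minimal MS1 mzML reading and writing.

Reading consumes centroided MS1 spectra only; profile-mode data is rejected
(this package quantifies centroided data).  The reader is namespace-aware,
handles 32-/64-bit float binary arrays with zlib or no compression, and
converts scan start times to minutes.  Writing emits a small, standard
MS1-only mzML (64-bit, uncompressed, base64) so synthetic runs round-trip
through the same file format real acquisitions arrive in.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree


class MzmlError(ValueError):
    pass


@dataclass
class MS1Run:
    """One LC-MS run reduced to its centroided MS1 spectra.

    ``rts`` are retention times in minutes, strictly increasing; ``spectra``
    holds per-spectrum ``(mz, intensity)`` float arrays with mz sorted.
    """

    run_id: str
    rts: np.ndarray
    spectra: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        if len(self.rts) != len(self.spectra):
            raise MzmlError("rts and spectra length mismatch")
        if len(self.rts) > 1 and not np.all(np.diff(self.rts) > 0):
            raise MzmlError("retention times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rts)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


_SPECTRUM_TEMPLATE = """\
   <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
     </scan>
    </scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{mz_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{int_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""


def write_mzml(run: MS1Run, path: str | Path) -> None:
    """Write an MS1Run as MS1-only centroid mzML (scan numbers are 1-based)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <cvList count="2">\n'
        '  <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '  <cv id="UO" fullName="UNIT-ONTOLOGY" URI="http://ontologies.berkeleybop.org/uo.obo"/>\n'
        ' </cvList>\n'
        f' <run id="{escape(run.run_id)}">\n'
        f'  <spectrumList count="{len(run)}">\n'
    ]
    for i, (rt, (mz, inten)) in enumerate(zip(run.rts, run.spectra)):
        mz_b64, int_b64 = _b64(mz), _b64(inten)
        parts.append(_SPECTRUM_TEMPLATE.format(
            index=i, scan=i + 1, n=len(mz), rt=rt,
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64))
    parts.append('  </spectrumList>\n </run>\n</mzML>\n')
    Path(path).write_text("".join(parts))


# accessions used while reading
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _localname(el) -> str:
    return etree.QName(el).localname


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values) where kind is
    'mz', 'intensity' or None."""
    dtype = "<f8"
    compressed = False
    kind = None
    payload = b""
    for child in bda.iter():
        name = _localname(child)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def _parse_spectrum(el, path) -> tuple[float, np.ndarray, np.ndarray] | None:
    """Return (rt_minutes, mz, intensity) for an MS1 spectrum, else None."""
    ms_level = None
    rt = None
    mz = inten = None
    for child in el.iter():
        name = _localname(child)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value"))
            elif acc == _ACC_PROFILE:
                raise MzmlError(
                    f"{path}: profile-mode spectra are not supported; "
                    "centroid the data first")
            elif acc == _ACC_SCAN_START:
                rt = float(child.get("value"))
                if child.get("unitName", "").lower() == "second":
                    rt /= 60.0
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if ms_level != 1:
        return None
    if rt is None or mz is None or inten is None:
        raise MzmlError(f"{path}: spectrum missing scan time or arrays")
    return rt, mz, inten


def read_mzml(path: str | Path, run_id: str | None = None) -> MS1Run:
    """Read the MS1 spectra of an mzML file into an :class:`MS1Run`."""
    rts: list[float] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    for _, el in etree.iterparse(str(path), events=("end",),
                                 tag="{*}spectrum"):
        parsed = _parse_spectrum(el, path)
        el.clear(keep_tail=True)
        if parsed is None:
            continue
        rt, mz, inten = parsed
        order = np.argsort(mz, kind="stable")
        rts.append(rt)
        spectra.append((mz[order], inten[order]))
    return MS1Run(run_id=run_id or Path(path).stem, rts=np.asarray(rts),
                  spectra=spectra)
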