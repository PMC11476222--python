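"""mzML reading and writing for centroided MS1 runs.

The reader is a compact, dependency-free mzML parser (stdlib XML +
base64/zlib + numpy): it streams ``<spectrum>`` elements from plain or
indexed mzML, keeps MS1 scans, decodes 32/64-bit float arrays with or
without zlib compression, converts scan start times to minutes, and
rejects profile-mode spectra — the whole pipeline operates on detected
(centroided) ion m/z values.

The writer emits plain mzML with uncompressed 64-bit arrays and the
controlled-vocabulary terms readers need to decode them.  It exists for
the synthetic-fixture module, so simulated runs exercise the same file
format as instrument exports.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np

from .xic import SpectrumRun

__all__ = ["read_mzml", "write_mzml", "ProfileModeError"]

_NS = "{http://psi.hupo.org/ms/mzml}"


class ProfileModeError(ValueError):
    """Raised when an mzML file contains profile-mode MS1 spectra."""


def _cv_accessions(elem: ET.Element) -> dict[str, str]:
    """accession -> value for all cvParams directly under ``elem``."""
    return {
        cv.get("accession", ""): cv.get("value", "")
        for cv in elem.findall(f"{_NS}cvParam")
    }


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values) where kind is
    'mz', 'intensity', or None for other array types."""
    acc = _cv_accessions(bda)
    if "MS:1000514" in acc:
        kind = "mz"
    elif "MS:1000515" in acc:
        kind = "intensity"
    else:
        kind = None
    binary = bda.find(f"{_NS}binary")
    raw = base64.b64decode((binary.text or "") if binary is not None else "")
    if "MS:1000574" in acc:  # zlib compression
        raw = zlib.decompress(raw)
    if "MS:1000521" in acc:  # 32-bit float
        dtype = "<f4"
    else:  # MS:1000523 64-bit float (default when unstated)
        dtype = "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _scan_start_minutes(spectrum: ET.Element, path: str) -> float:
    for scan in spectrum.iter(f"{_NS}scan"):
        for cv in scan.findall(f"{_NS}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value", "nan"))
                unit = (cv.get("unitName") or cv.get("unitAccession") or "")
                if "second" in unit or unit == "UO:0000010":
                    rt /= 60.0
                return rt
    raise ValueError(f"{path}: spectrum without a scan start time")


def read_mzml(path: str | Path) -> SpectrumRun:
    """Read centroided MS1 spectra from a (plain or indexed) mzML file."""
    spectra: list[tuple[float, np.ndarray, np.ndarray]] = []
    polarity = "negative"
    path = str(path)
    for _, elem in ET.iterparse(path, events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        acc = _cv_accessions(elem)
        ms_level = int(acc.get("MS:1000511", "1") or "1")
        if ms_level != 1:
            elem.clear()
            continue
        if "MS:1000128" in acc:  # profile spectrum
            raise ProfileModeError(
                f"{path}: spectrum {elem.get('id')!r} is profile-mode; "
                "centroid the data before extraction"
            )
        if "MS:1000130" in acc:  # positive scan
            polarity = "positive"
        rt = _scan_start_minutes(elem, path)
        mz = inten = None
        for bda in elem.iter(f"{_NS}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz is None or inten is None:
            raise ValueError(
                f"{path}: spectrum {elem.get('id')!r} lacks m/z or "
                "intensity arrays"
            )
        spectra.append((rt, mz, inten))
        elem.clear()
    if not spectra:
        raise ValueError(f"{path}: no MS1 spectra found")
    return SpectrumRun(spectra=spectra, polarity=polarity,
                       metadata={"source": path})


def _b64(arr: np.ndarray) -> str:
    raw = struct.pack(f"<{len(arr)}d", *map(float, arr))
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", extra: str = "") -> str:
    return (f'<cvParam cvRef="MS" accession="{accession}" '
            f'name={quoteattr(name)} value={quoteattr(value)}{extra}/>')


def write_mzml(run: SpectrumRun, path: str | Path) -> None:
    """Write a SpectrumRun as plain mzML (centroided MS1, uncompressed
    64-bit float arrays, scan start times in minutes)."""
    pol_acc, pol_name = (
        ("MS:1000129", "negative scan")
        if run.polarity == "negative"
        else ("MS:1000130", "positive scan")
    )
    lines: list[str] = []
    w = lines.append
    w('<?xml version="1.0" encoding="utf-8"?>')
    w('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">')
    w('<cvList count="2">')
    w('<cv id="MS" fullName="Proteomics Standards Initiative Mass '
      'Spectrometry Ontology" URI="https://raw.githubusercontent.com/'
      'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>')
    w('<cv id="UO" fullName="Unit Ontology" '
      'URI="http://ontologies.berkeleybop.org/uo.obo"/>')
    w('</cvList>')
    w('<fileDescription><fileContent>')
    w(_cv("MS:1000579", "MS1 spectrum"))
    w(_cv("MS:1000127", "centroid spectrum"))
    w('</fileContent></fileDescription>')
    w('<softwareList count="1">'
      '<software id="gangliotk" version="0"/></softwareList>')
    w('<instrumentConfigurationList count="1">'
      '<instrumentConfiguration id="IC1"/>'
      '</instrumentConfigurationList>')
    w('<dataProcessingList count="1"><dataProcessing id="dp1">'
      '<processingMethod order="1" softwareRef="gangliotk">'
      + _cv("MS:1000544", "Conversion to mzML")
      + '</processingMethod></dataProcessing></dataProcessingList>')
    w('<run id="run1" defaultInstrumentConfigurationRef="IC1">')
    w(f'<spectrumList count="{len(run)}" defaultDataProcessingRef="dp1">')
    for i, (rt, mz, inten) in enumerate(run.spectra):
        w(f'<spectrum index="{i}" id="scan={i + 1}" '
          f'defaultArrayLength="{len(mz)}">')
        w(_cv("MS:1000511", "ms level", "1"))
        w(_cv("MS:1000579", "MS1 spectrum"))
        w(_cv("MS:1000127", "centroid spectrum"))
        w(_cv(pol_acc, pol_name))
        w('<scanList count="1">')
        w(_cv("MS:1000795", "no combination"))
        w('<scan>')
        w(_cv("MS:1000016", "scan start time", f"{rt:.10g}",
              ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'))
        w('</scan></scanList>')
        w('<binaryDataArrayList count="2">')
        for arr, acc, name, unit in (
            (mz, "MS:1000514", "m/z array",
             ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'),
            (inten, "MS:1000515", "intensity array",
             ' unitCvRef="MS" unitAccession="MS:1000131" '
             'unitName="number of detector counts"'),
        ):
            enc = _b64(arr)
            w(f'<binaryDataArray encodedLength="{len(enc)}">')
            w(_cv("MS:1000523", "64-bit float"))
            w(_cv("MS:1000576", "no compression"))
            w(_cv(acc, name, "", unit))
            w(f'<binary>{enc}</binary>')
            w('</binaryDataArray>')
        w('</binaryDataArrayList>')
        w('</spectrum>')
    w('</spectrumList></run></mzML>')
    text = "\n".join(lines)
    ET.fromstring(text)  # well-formedness check before touching disk
    Path(path).write_text(text)
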