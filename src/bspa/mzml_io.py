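"""mzML reading and writing for centroided MS1 runs.

This module implements the subset of mzML 1.1 that LC-MS reaction
monitoring produces and consumes: centroided MS1 spectra with base64-encoded
32/64-bit float arrays (plain or zlib-compressed), retention times in
seconds or minutes, and spectrum-level ms-level/centroid/profile metadata.
The writer emits plain (non-indexed) mzML with 64-bit uncompressed arrays,
chosen so written files round-trip bit-exactly.  Chromatogram lists, MSn
precursor hierarchies and vendor extensions are out of scope.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

__all__ = ["RawSpectrum", "iter_spectra", "write_mzml"]

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xsi:schemaLocation="http://psi.hupo.org/ms/mzml http://psidev.info/files/ms/mzML/xsd/mzML1.1.0.xsd" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" version="4.1.0" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" version="releases/2020-03-10" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="bspa" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="bspa synthetic campaign generator"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="bspa">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode("ascii")


def _binary_array(array: np.ndarray, kind_accession: str, kind_name: str, unit: str) -> str:
    data = _encode(array)
    return f"""            <binaryDataArray encodedLength="{len(data)}">
              <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
              <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
              <cvParam cvRef="MS" accession="{kind_accession}" name="{kind_name}" value=""{unit}/>
              <binary>{data}</binary>
            </binaryDataArray>
"""


def write_mzml(path: str | Path, run_id: str, scans) -> None:
    """Write centroided MS1 scans to ``path``.

    ``scans`` is an iterable of objects with ``rt`` (seconds), ``mz`` and
    ``intensity`` array attributes and an integer ``ms_level``.
    """
    scans = list(scans)
    parts = [_HEADER]
    parts.append(
        f'  <run id="{escape(run_id, {chr(34): "&quot;"})}" defaultInstrumentConfigurationRef="IC1">\n'
        f'    <spectrumList count="{len(scans)}" defaultDataProcessingRef="DP1">\n'
    )
    for index, scan in enumerate(scans):
        mz = np.asarray(scan.mz, dtype=float)
        intensity = np.asarray(scan.intensity, dtype=float)
        parts.append(
            f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{mz.size}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
"""
        )
        parts.append(_binary_array(
            mz, "MS:1000514", "m/z array",
            ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'))
        parts.append(_binary_array(
            intensity, "MS:1000515", "intensity array",
            ' unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'))
        parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    Path(path).write_text("".join(parts))


# ---------------------------------------------------------------------------
# reading

@dataclass
class RawSpectrum:
    """One decoded spectrum: arrays plus the cv metadata the QC layer needs."""

    id: str
    ms_level: int
    rt_seconds: float | None
    mz: np.ndarray
    intensity: np.ndarray
    is_profile: bool = False


class MzmlParseError(ValueError):
    """The file is not well-formed mzML of the supported subset."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_ACCESSION_DTYPE = {
    "MS:1000523": np.dtype("<f8"),  # 64-bit float
    "MS:1000521": np.dtype("<f4"),  # 32-bit float
}


def _decode_binary(elem, default_length: int) -> tuple[str | None, np.ndarray]:
    """(array kind accession, decoded values) of one binaryDataArray."""
    dtype = None
    compressed = False
    kind = None
    text = ""
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc in _ACCESSION_DTYPE:
                dtype = _ACCESSION_DTYPE[acc]
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
            elif acc in ("MS:1000514", "MS:1000515"):  # m/z | intensity array
                kind = acc
        elif tag == "binary":
            text = child.text or ""
    if dtype is None:
        raise MzmlParseError("binaryDataArray without a supported float precision")
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if default_length and values.size != default_length:
        raise MzmlParseError(
            f"binary array length {values.size} != defaultArrayLength {default_length}")
    return kind, values


def _parse_spectrum(elem) -> RawSpectrum:
    ms_level = 1
    rt = None
    is_profile = False
    mz = intensity = None
    default_length = int(elem.get("defaultArrayLength", 0))
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "1"))
            elif acc == "MS:1000128":
                is_profile = True
            elif acc == "MS:1000016":
                value = float(child.get("value", "nan"))
                unit = child.get("unitName", "second")
                rt = value * 60.0 if unit.startswith("min") else value
        elif tag == "binaryDataArray":
            kind, values = _decode_binary(child, default_length)
            if kind == "MS:1000514":
                mz = values
            elif kind == "MS:1000515":
                intensity = values
    if mz is None or intensity is None:
        raise MzmlParseError(
            f"spectrum {elem.get('id')!r}: missing m/z or intensity array")
    return RawSpectrum(id=elem.get("id", ""), ms_level=ms_level, rt_seconds=rt,
                       mz=mz, intensity=intensity, is_profile=is_profile)


def iter_spectra(path: str | Path):
    """Stream the spectra of an mzML file as :class:`RawSpectrum` objects.

    Works for plain and indexed mzML (the index wrapper is ignored).
    Raises :class:`MzmlParseError` on malformed XML or unsupported
    encodings.
    """
    path = Path(path)
    try:
        context = ElementTree.iterparse(str(path), events=("end",))
        found = False
        for _event, elem in context:
            if _local(elem.tag) == "spectrum":
                found = True
                yield _parse_spectrum(elem)
                elem.clear()
        if not found:
            raise MzmlParseError(f"{path}: no spectra found")
    except ElementTree.ParseError as exc:
        raise MzmlParseError(f"{path}: malformed XML: {exc}") from exc
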