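"""Centroid-MS1 mzML reading and writing.

Self-contained mzML 1.1 support for the subset the pipeline needs:
positive-mode centroided MS1 spectra with 32/64-bit float arrays,
uncompressed or zlib-compressed.  Profile-mode scans are rejected — the
trace builder assumes centroided data.  The writer emits minimal but
standards-conforming files (64-bit little-endian, no compression) so
the simulator's runs round-trip through any mzML-aware tool.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np

from .features import CentroidSpectrum


class MzmlFormatError(ValueError):
    """Malformed or unsupported mzML content."""


def _encode(array: np.ndarray) -> str:
    data = np.asarray(array, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="ligandfish" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="ligandfish"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="ligandfish">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.10g}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
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


def write_mzml(path: str | Path, run: list[CentroidSpectrum], run_id: str = "run") -> None:
    """Write one centroided MS1 run to an mzML file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_HEADER)
        fh.write(
            f'  <run id="{escape(run_id)}" '
            'defaultInstrumentConfigurationRef="IC1">\n'
            f'    <spectrumList count="{len(run)}" defaultDataProcessingRef="DP1">\n'
        )
        for i, spec in enumerate(run):
            mz_b64 = _encode(spec.mz)
            int_b64 = _encode(spec.intensity)
            fh.write(
                _SPECTRUM.format(
                    index=i,
                    scan=i + 1,
                    n=len(spec),
                    rt=spec.retention_time,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write("    </spectrumList>\n  </run>\n</mzML>\n")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem: ET.Element) -> tuple[np.ndarray, str | None]:
    dtype = "<f8"
    compressed = False
    kind = None
    text = ""
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64), kind


def _parse_spectrum(elem: ET.Element, path: Path, index: int) -> CentroidSpectrum | None:
    ms_level = None
    is_profile = False
    rt = None
    rt_unit = "minute"
    arrays: dict[str, np.ndarray] = {}
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "0"))
            elif acc == "MS:1000128":
                is_profile = True
            elif acc == "MS:1000016":
                rt = float(child.get("value", "nan"))
                rt_unit = child.get("unitName", "minute")
        elif name == "binaryDataArray":
            arr, kind = _decode_binary_array(child)
            if kind:
                arrays[kind] = arr
    if ms_level is not None and ms_level != 1:
        return None
    if is_profile:
        raise MzmlFormatError(
            f"{path.name} spectrum index {index}: profile-mode spectrum; "
            "centroid the data first"
        )
    if rt is None or "mz" not in arrays or "intensity" not in arrays:
        raise MzmlFormatError(
            f"{path.name} spectrum index {index}: missing scan time or data arrays"
        )
    if rt_unit in ("second", "seconds"):
        rt /= 60.0
    mz, inten = arrays["mz"], arrays["intensity"]
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size > 1:  # guard against coincident m/z values
        dup = np.diff(mz) <= 0
        if dup.any():
            keep = np.concatenate(([True], ~dup))
            grp = np.cumsum(keep) - 1
            inten = np.bincount(grp, weights=inten)
            mz = mz[keep]
    return CentroidSpectrum(rt, mz, inten)


def read_mzml(path: str | Path) -> list[CentroidSpectrum]:
    """Read centroided MS1 spectra from an mzML file, sorted by RT."""
    path = Path(path)
    spectra: list[CentroidSpectrum] = []
    index = 0
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) != "spectrum":
                continue
            spec = _parse_spectrum(elem, path, index)
            if spec is not None:
                spectra.append(spec)
            index += 1
            elem.clear()
    except MzmlFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise MzmlFormatError(
            f"cannot parse mzML file {path} (spectrum index {index}): {exc}"
        ) from exc
    spectra.sort(key=lambda s: s.retention_time)
    return spectra


def read_msruns(paths: dict[str, str | Path]) -> dict[str, list[CentroidSpectrum]]:
    """Read several runs, mapping run id -> spectra list."""
    return {run_id: read_mzml(p) for run_id, p in paths.items()}


def write_msruns(
    runs: dict[str, list[CentroidSpectrum]], directory: str | Path
) -> dict[str, Path]:
    """Write every run as ``<directory>/<run_id>.mzML``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for run_id, run in runs.items():
        p = directory / f"{run_id}.mzML"
        write_mzml(p, run, run_id=run_id)
        out[run_id] = p
    return out


def discover_runs(directory: str | Path) -> dict[str, Path]:
    """Map run ids to mzML paths in a directory (``sample_1.mzML`` ...)."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.mzML")) + sorted(directory.glob("*.mzml"))
    if not paths:
        raise FileNotFoundError(
            f"no mzML files in {directory}; expected files named like "
            "sample_1.mzML / control_1.mzML for n replicate pairs"
        )
    return {p.stem: p for p in paths}
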