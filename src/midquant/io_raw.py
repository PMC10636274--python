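"""Vendor-agnostic raw MS file parsing.

mzML 1.1 and mzXML 3.x are parsed with a compact streaming reader
(stdlib ElementTree) that covers the encodings these files use in
practice: base64 binary arrays with zlib or no compression, 32- and
64-bit floats in either byte order, CV-param retention-time units,
centroid/profile flags and MS2 precursor selection. ANDI-MS netCDF (the
ASTM E2077/E1947 layout with ``scan_acquisition_time``, ``scan_index``,
``mass_values`` and ``intensity_values`` variables) goes through
``scipy.io.netcdf_file``. All three produce the same in-memory scan model
with retention times in seconds.

The module also carries minimal mzML/mzXML/netCDF *writers*. These exist so
that synthetic runs with known ground truth can be materialized as real
files and pushed through the full reading path; they emit a small,
standards-conforming subset (64-bit arrays, zlib or no compression) and are
not general-purpose exporters.
"""

from __future__ import annotations

import base64
import re
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io

from .errors import ParseError, UnsupportedFormatError


@dataclass
class Scan:
    """One mass spectrum: centroided or profile m/z-intensity pairs at one RT."""

    rt: float  # seconds
    ms_level: int
    mz_values: np.ndarray
    intensities: np.ndarray
    precursor_mz: float | None = None
    precursor_window: float | None = None  # isolation half-width, Th
    polarity: str = "unknown"  # "positive" | "negative" | "unknown"
    centroided: bool = True

    def __post_init__(self):
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise ParseError("m/z and intensity arrays differ in length")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            order = np.argsort(self.mz_values, kind="stable")
            self.mz_values = self.mz_values[order]
            self.intensities = self.intensities[order]
        if np.any(self.intensities < 0):
            raise ParseError("negative intensities")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ParseError("MS2 scan without precursor m/z")


@dataclass
class RawRun:
    scans: list[Scan]
    source_path: str = ""
    instrument_hint: str = "unknown"  # "low_res" | "high_res" | "unknown"

    def __post_init__(self):
        if not self.scans:
            raise ParseError(f"no scans in {self.source_path or 'run'}")
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.rt)


# -------------------------------------------------------------- reading ---

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".mzxml":
        return "mzxml"
    if suffix in (".cdf", ".nc"):
        return "cdf"
    head = path.read_bytes()[:512]
    if head.startswith(b"CDF"):
        return "cdf"
    lowered = head.lower()
    if b"<mzxml" in lowered or b"mzxml" in lowered:
        return "mzxml"
    if b"<mzml" in lowered or b"<indexedmzml" in lowered:
        return "mzml"
    raise UnsupportedFormatError(f"cannot determine format of {path}")


def infer_centroided(mz: np.ndarray, intensities: np.ndarray) -> bool:
    """Heuristic profile-vs-centroid call when file metadata is silent.

    A scan is treated as profile when more than half of consecutive m/z
    spacings are below 0.01 Th and nonzero intensities form contiguous runs
    of at least 5 points; anything else is treated as centroided.
    """
    if mz.size < 10:
        return True
    spacings = np.diff(mz)
    if np.mean(spacings < 0.01) <= 0.5:
        return True
    nonzero = intensities > 0
    best_run = run = 0
    for flag in nonzero:
        run = run + 1 if flag else 0
        best_run = max(best_run, run)
    return best_run < 5


_ISO_DURATION = re.compile(
    r"^-?P?T?(?:(\d+(?:\.\d+)?)H)?(?:(\d+(?:\.\d+)?)M)?(?:(\d+(?:\.\d+)?)S)?$"
)


def _rt_text_to_seconds(text: str, unit: str | None = None) -> float:
    """Retention time to seconds: CV-param units honored, ISO-8601 durations
    ("PT1.5S") parsed, bare numbers assumed seconds unless told minutes."""
    text = text.strip()
    if text.upper().startswith(("P", "-P", "T", "PT")) and not _is_number(text):
        m = _ISO_DURATION.match(text.upper().lstrip("-").replace("PT", "T", 1))
        if not m or not any(m.groups()):
            raise ParseError(f"unparseable retention time {text!r}")
        h, mi, s = (float(g) if g else 0.0 for g in m.groups())
        return 3600.0 * h + 60.0 * mi + s
    value = float(text)
    if unit in ("minute", "min", "minutes"):
        return value * 60.0
    if unit in ("hour", "hours"):
        return value * 3600.0
    return value


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def _local(tag: str) -> str:
    return tag.rpartition("}")[2]


def _iter_local(elem, name: str):
    for child in elem.iter():
        if _local(child.tag) == name:
            yield child


def _cv_accessions(elem) -> dict[str, ET.Element]:
    return {
        c.get("accession"): c
        for c in elem
        if _local(c.tag) == "cvParam" and c.get("accession")
    }


def _decode_mzml_array(array_elem) -> np.ndarray:
    params = {}
    binary_text = ""
    for child in array_elem:
        name = _local(child.tag)
        if name == "cvParam":
            params[child.get("accession")] = child
        elif name == "binary":
            binary_text = child.text or ""
    dtype = "<f8" if "MS:1000523" in params else "<f4"
    raw = base64.b64decode(binary_text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _scan_from_mzml_elem(elem, index: int) -> Scan:
    params = _cv_accessions(elem)
    ms_level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
    if "MS:1000127" in params:
        centroided = True
    elif "MS:1000128" in params:
        centroided = False
    else:
        centroided = None
    polarity = (
        "positive" if "MS:1000130" in params
        else "negative" if "MS:1000129" in params
        else "unknown"
    )
    rt = None
    for scan_elem in _iter_local(elem, "scan"):
        scan_params = _cv_accessions(scan_elem)
        if "MS:1000016" in scan_params:
            p = scan_params["MS:1000016"]
            rt = _rt_text_to_seconds(p.get("value"), p.get("unitName"))
            break
    if rt is None:
        raise ParseError(f"scan index {index}: missing scan start time")
    precursor_mz = None
    precursor_window = None
    for prec in _iter_local(elem, "precursor"):
        for window_elem in _iter_local(prec, "isolationWindow"):
            wp = _cv_accessions(window_elem)
            offsets = [
                float(wp[a].get("value"))
                for a in ("MS:1000828", "MS:1000829")
                if a in wp
            ]
            if offsets:
                precursor_window = sum(offsets) / len(offsets)
        for ion in _iter_local(prec, "selectedIon"):
            ip = _cv_accessions(ion)
            if "MS:1000744" in ip:
                precursor_mz = float(ip["MS:1000744"].get("value"))
        break
    mz = intensity = None
    for array_elem in _iter_local(elem, "binaryDataArray"):
        arr_params = _cv_accessions(array_elem)
        values = _decode_mzml_array(array_elem)
        if "MS:1000514" in arr_params:
            mz = values
        elif "MS:1000515" in arr_params:
            intensity = values
    if mz is None or intensity is None:
        raise ParseError(f"scan index {index}: missing m/z or intensity array")
    if centroided is None:
        centroided = infer_centroided(mz, intensity)
    return Scan(
        rt=rt,
        ms_level=ms_level,
        mz_values=mz,
        intensities=intensity,
        precursor_mz=precursor_mz,
        precursor_window=precursor_window,
        polarity=polarity,
        centroided=centroided,
    )


def _read_mzml(path: Path) -> list[Scan]:
    scans = []
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "spectrum":
                try:
                    scans.append(_scan_from_mzml_elem(elem, len(scans)))
                except ParseError:
                    raise
                except Exception as exc:
                    raise ParseError(
                        f"failed to parse scan index {len(scans)}: {exc}"
                    ) from exc
                elem.clear()
    except ET.ParseError as exc:
        raise ParseError(f"malformed mzML in {path}: {exc}") from exc
    return scans


def _decode_mzxml_peaks(peaks_elem) -> tuple[np.ndarray, np.ndarray]:
    precision = peaks_elem.get("precision", "32")
    byte_order = peaks_elem.get("byteOrder", "network")
    compression = peaks_elem.get("compressionType", "none")
    endian = ">" if byte_order in ("network", "big") else "<"
    dtype = f"{endian}f{8 if precision == '64' else 4}"
    raw = base64.b64decode(peaks_elem.text or "")
    if compression == "zlib":
        raw = zlib.decompress(raw)
    pairs = np.frombuffer(raw, dtype=dtype).astype(float)
    return pairs[0::2], pairs[1::2]


def _scan_from_mzxml_elem(elem, index: int) -> Scan:
    rt_text = elem.get("retentionTime")
    if rt_text is None:
        raise ParseError(f"scan index {index}: missing retentionTime")
    rt = _rt_text_to_seconds(rt_text)
    ms_level = int(elem.get("msLevel", "1"))
    polarity = {"+": "positive", "-": "negative"}.get(
        elem.get("polarity"), "unknown"
    )
    precursor_mz = None
    precursor_window = None
    mz = intensity = None
    for child in elem:
        name = _local(child.tag)
        if name == "precursorMz":
            precursor_mz = float(child.text)
            if child.get("windowWideness"):
                precursor_window = float(child.get("windowWideness")) / 2.0
        elif name == "peaks":
            mz, intensity = _decode_mzxml_peaks(child)
    if mz is None:
        raise ParseError(f"scan index {index}: missing peaks element")
    centroid_attr = elem.get("centroided")
    centroided = (
        bool(int(centroid_attr)) if centroid_attr is not None
        else infer_centroided(mz, intensity)
    )
    return Scan(
        rt=rt,
        ms_level=ms_level,
        mz_values=mz,
        intensities=intensity,
        precursor_mz=precursor_mz,
        precursor_window=precursor_window,
        polarity=polarity,
        centroided=centroided,
    )


def _read_mzxml(path: Path) -> list[Scan]:
    scans = []
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "scan":
                try:
                    scans.append(_scan_from_mzxml_elem(elem, len(scans)))
                except ParseError:
                    raise
                except Exception as exc:
                    raise ParseError(
                        f"failed to parse scan index {len(scans)}: {exc}"
                    ) from exc
                elem.clear()
    except ET.ParseError as exc:
        raise ParseError(f"malformed mzXML in {path}: {exc}") from exc
    scans.sort(key=lambda s: s.rt)
    return scans


_ANDI_REQUIRED = ("scan_acquisition_time", "scan_index", "mass_values",
                  "intensity_values")


def _read_cdf(path: Path) -> list[Scan]:
    with scipy.io.netcdf_file(str(path), mmap=False) as nc:
        missing = [v for v in _ANDI_REQUIRED if v not in nc.variables]
        if missing:
            raise UnsupportedFormatError(
                f"{path} is netCDF but not ANDI-MS: missing variables {missing}"
            )
        times = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=float)
        index = np.asarray(nc.variables["scan_index"][:], dtype=int)
        mass = np.asarray(nc.variables["mass_values"][:], dtype=float)
        inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
    scans = []
    boundaries = list(index) + [mass.size]
    for i, rt in enumerate(times):
        lo, hi = boundaries[i], boundaries[i + 1]
        if lo > hi or hi > mass.size:
            raise ParseError(f"failed to parse scan index {i}: bad scan_index")
        mz = mass[lo:hi]
        intensity = np.clip(inten[lo:hi], 0, None)
        scans.append(
            Scan(
                rt=float(rt),
                ms_level=1,  # ANDI-MS carries no MS-level dimension
                mz_values=mz,
                intensities=intensity,
                centroided=infer_centroided(mz, intensity),
            )
        )
    return scans


_READERS = {"mzml": _read_mzml, "mzxml": _read_mzxml, "cdf": _read_cdf}


def read_run(path, format_hint: str | None = None) -> RawRun:
    """Parse an mzML, mzXML or ANDI-MS netCDF file into a :class:`RawRun`.

    The format is taken from *format_hint* if given, otherwise detected
    from the file extension or magic bytes. Retention times are converted
    to seconds regardless of source units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or _sniff_format(path)).lower().lstrip(".")
    if fmt not in _READERS:
        raise UnsupportedFormatError(f"unsupported format {fmt!r}")
    try:
        scans = _READERS[fmt](path)
    except (ParseError, UnsupportedFormatError):
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if not scans:
        raise ParseError(f"no scans in {path}")
    return RawRun(scans=scans, source_path=str(path))


# ----------------------------------------------------------- centroiding ---

def centroid_profile_scan(scan: Scan) -> Scan:
    """Reduce a profile scan to centroids.

    Each local intensity maximum above zero becomes one peak. Its m/z is the
    intensity-weighted centroid of the contiguous profile points assigned to
    it (split at local minima between adjacent maxima and at zeros); its
    intensity is the apex intensity.
    """
    mz, y = scan.mz_values, scan.intensities
    n = y.size
    peaks_mz, peaks_int = [], []
    i = 0
    while i < n:
        if y[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and y[j + 1] > 0:
            j += 1
        # segment [i, j] of strictly positive intensity; split at local minima
        seg_start = i
        k = i
        while k <= j:
            # advance to local maximum
            while k < j and y[k + 1] >= y[k]:
                k += 1
            apex = k
            # descend to local minimum / segment end
            while k < j and y[k + 1] <= y[k]:
                k += 1
            seg_end = k if k == j else k  # minimum belongs to left peak
            weights = y[seg_start:seg_end + 1]
            peaks_mz.append(float(np.average(mz[seg_start:seg_end + 1],
                                             weights=weights)))
            peaks_int.append(float(y[apex]))
            seg_start = seg_end + 1
            k = seg_end + 1
        i = j + 1
    return Scan(
        rt=scan.rt,
        ms_level=scan.ms_level,
        mz_values=np.array(peaks_mz),
        intensities=np.array(peaks_int),
        precursor_mz=scan.precursor_mz,
        precursor_window=scan.precursor_window,
        polarity=scan.polarity,
        centroided=True,
    )


# -------------------------------------------------------------- writing ---

def _b64_doubles(values: np.ndarray, compress: bool = True) -> tuple[str, int]:
    raw = np.asarray(values, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw)
    encoded = base64.b64encode(raw).decode("ascii")
    return encoded, len(encoded)


def write_mzml(run: RawRun, path) -> None:
    """Write *run* as mzML 1.1 with zlib-compressed 64-bit arrays."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <cvList count="2">',
        '    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '    <cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent'
        '.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        '  </cvList>',
        '  <fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>'
        '</fileContent></fileDescription>',
        f'  <run id="run" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(run.scans)}" '
        'defaultDataProcessingRef="DP1">',
    ]
    for i, scan in enumerate(run.scans):
        mz_b64, _ = _b64_doubles(scan.mz_values)
        int_b64, _ = _b64_doubles(scan.intensities)
        mode_param = (
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
            if scan.centroided
            else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>'
        )
        polarity_param = {
            "positive": '<cvParam cvRef="MS" accession="MS:1000130" '
                        'name="positive scan"/>',
            "negative": '<cvParam cvRef="MS" accession="MS:1000129" '
                        'name="negative scan"/>',
        }.get(scan.polarity, "")
        lines.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{scan.mz_values.size}">'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{scan.ms_level}"/>'
        )
        lines.append("        " + mode_param + polarity_param)
        lines.append(
            '        <scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" '
            'unitName="second"/></scan></scanList>'
        )
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            half = scan.precursor_window if scan.precursor_window is not None else 1.0
            lines.append(
                '        <precursorList count="1"><precursor>'
                "<isolationWindow>"
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{scan.precursor_mz!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{half!r}"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{half!r}"/>'
                "</isolationWindow>"
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{scan.precursor_mz!r}"/>'
                "</selectedIon></selectedIonList>"
                "<activation/></precursor></precursorList>"
            )
        for name, accession, b64 in (
            ("m/z array", "MS:1000514", _b64_doubles(scan.mz_values)[0]),
            ("intensity array", "MS:1000515", _b64_doubles(scan.intensities)[0]),
        ):
            lines.append(
                '        <binaryDataArrayList count="2">'
                if name == "m/z array"
                else ""
            )
            lines.append(
                f'          <binaryDataArray encodedLength="{len(b64)}">'
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
                '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
                f'<cvParam cvRef="MS" accession="{accession}" name="{name}"/>'
                f"<binary>{b64}</binary></binaryDataArray>"
            )
        lines.append("        </binaryDataArrayList>")
        lines.append("      </spectrum>")
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(line for line in lines if line != ""))


def write_mzxml(run: RawRun, path) -> None:
    """Write *run* as a minimal mzXML 3.2 file (uncompressed 64-bit peaks)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f'  <msRun scanCount="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans):
        # interleaved (m/z, intensity) pairs, network (big-endian) byte order
        pairs = np.empty(scan.mz_values.size * 2)
        pairs[0::2] = scan.mz_values
        pairs[1::2] = scan.intensities
        b64 = base64.b64encode(
            np.asarray(pairs, dtype=">f8").tobytes()
        ).decode("ascii")
        polarity_attr = {"positive": ' polarity="+"', "negative": ' polarity="-"'}
        attrs = (
            f'num="{i + 1}" msLevel="{scan.ms_level}" '
            f'peaksCount="{scan.mz_values.size}" '
            f'retentionTime="PT{scan.rt!r}S" '
            f'centroided="{1 if scan.centroided else 0}"'
            + polarity_attr.get(scan.polarity, "")
        )
        lines.append(f"    <scan {attrs}>")
        if scan.ms_level == 2 and scan.precursor_mz is not None:
            width = (
                2.0 * scan.precursor_window
                if scan.precursor_window is not None
                else 2.0
            )
            lines.append(
                f'      <precursorMz windowWideness="{width!r}">'
                f"{scan.precursor_mz!r}</precursorMz>"
            )
        lines.append(
            f'      <peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{b64}</peaks>'
        )
        lines.append("    </scan>")
    lines += ["  </msRun>", "</mzXML>", ""]
    Path(path).write_text("\n".join(lines))


def write_cdf(run: RawRun, path) -> None:
    """Write *run* as ANDI-MS netCDF (MS1 scans only; netCDF-3 classic)."""
    ms1 = [s for s in run.scans if s.ms_level == 1]
    if not ms1:
        raise ParseError("ANDI-MS export requires MS1 scans")
    index, mass, inten = [], [], []
    for scan in ms1:
        index.append(len(mass))
        mass.extend(scan.mz_values.tolist())
        inten.extend(scan.intensities.tolist())
    with scipy.io.netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", len(ms1))
        nc.createDimension("point_number", len(mass))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = np.array([s.rt for s in ms1])
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.array(index, dtype=np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = np.array(mass)
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = np.array(inten)
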