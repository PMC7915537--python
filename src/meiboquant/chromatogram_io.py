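"""Readers and writers for centroided scan data and curve tables.

The internal scan format is a plain CSV with one row per centroid
(``scan_index,rt_min,mz,intensity``); a scan with no centroids is kept
as a single row with empty m/z and intensity fields so that empty scans
survive a round trip.  Centroided mzML is supported through pyteomics
for reading; writing produces minimal uncompressed 64-bit mzML.
"""

from __future__ import annotations

import base64
import io
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanSet", "read_scans", "write_scans", "read_curve", "write_curve"]

_CSV_HEADER = "scan_index,rt_min,mz,intensity"


@dataclass
class ScanSet:
    """Time-ordered centroided spectra.

    rts are minutes, strictly increasing; each scan's m/z array is
    sorted ascending and paired with an equal-length intensity array.
    """

    rts: np.ndarray
    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rts = np.asarray(self.rts, dtype=float)
        if len(self.mz_arrays) != len(self.rts) or len(self.intensity_arrays) != len(self.rts):
            raise ValueError("scan arrays must have one entry per retention time")
        if len(self.rts) > 1 and not np.all(np.diff(self.rts) > 0):
            order = np.argsort(self.rts, kind="stable")
            if len(np.unique(self.rts)) != len(self.rts):
                raise ValueError("duplicate scan retention times")
            self.rts = self.rts[order]
            self.mz_arrays = [self.mz_arrays[i] for i in order]
            self.intensity_arrays = [self.intensity_arrays[i] for i in order]
        fixed_mz, fixed_int = [], []
        for mz, inten in zip(self.mz_arrays, self.intensity_arrays):
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError("m/z and intensity arrays differ in length")
            if mz.size and not np.all(np.diff(mz) >= 0):
                order = np.argsort(mz, kind="stable")
                mz, inten = mz[order], inten[order]
            fixed_mz.append(mz)
            fixed_int.append(inten)
        self.mz_arrays, self.intensity_arrays = fixed_mz, fixed_int

    def __len__(self) -> int:
        return len(self.rts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScanSet):
            return NotImplemented
        return (
            np.array_equal(self.rts, other.rts)
            and all(np.array_equal(a, b) for a, b in zip(self.mz_arrays, other.mz_arrays))
            and all(np.array_equal(a, b) for a, b in zip(self.intensity_arrays, other.intensity_arrays))
        )


def write_scans(scans: ScanSet, path, format: str = "internal_csv") -> None:
    if format == "internal_csv":
        _write_csv(scans, path)
    elif format == "mzml":
        _write_mzml(scans, path)
    else:
        raise ValueError(f"unsupported scan format {format!r}")


def read_scans(path, format: str = "internal_csv") -> ScanSet:
    if format == "internal_csv":
        return _read_csv(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported scan format {format!r}")


# ---------------------------------------------------------------------------
# internal CSV

def _write_csv(scans: ScanSet, path) -> None:
    buf = io.StringIO()
    for key in sorted(scans.metadata):
        buf.write(f"# {key}={scans.metadata[key]}\n")
    buf.write(_CSV_HEADER + "\n")
    for i, (rt, mz, inten) in enumerate(zip(scans.rts, scans.mz_arrays, scans.intensity_arrays)):
        if mz.size == 0:
            buf.write(f"{i},{rt:.6f},,\n")
            continue
        for m, h in zip(mz, inten):
            buf.write(f"{i},{rt:.6f},{m:.5f},{h:.3f}\n")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


def _read_csv(path) -> ScanSet:
    metadata: dict = {}
    rows_by_scan: dict[int, tuple[float, list, list]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            text = line[1:].strip()
            if "=" in text:
                key, _, value = text.partition("=")
                metadata[key.strip()] = value.strip()
            continue
        body.append((lineno, line))
    if not body:
        raise ValueError(f"{path}: empty scan file")
    header_lineno, header = body[0]
    if header.strip() != _CSV_HEADER:
        raise ValueError(f"{path}:{header_lineno}: expected header {_CSV_HEADER!r}")
    if len(body) == 1:
        raise ValueError(f"{path}: no scan rows")
    for lineno, line in body[1:]:
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        try:
            idx = int(parts[0])
            rt = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
        entry = rows_by_scan.setdefault(idx, (rt, [], []))
        if parts[2] == "" and parts[3] == "":
            continue  # explicit empty-scan record
        try:
            entry[1].append(float(parts[2]))
            entry[2].append(float(parts[3]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    indices = sorted(rows_by_scan)
    rts = np.array([rows_by_scan[i][0] for i in indices])
    mzs = [np.array(rows_by_scan[i][1]) for i in indices]
    intens = [np.array(rows_by_scan[i][2]) for i in indices]
    return ScanSet(rts, mzs, intens, metadata)


# ---------------------------------------------------------------------------
# mzML (centroid spectra, uncompressed 64-bit)

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def _write_mzml(scans: ScanSet, path) -> None:
    from lxml import etree

    NS = "http://psi.hupo.org/ms/mzml"
    E = lambda tag, **attrs: etree.SubElement(parent_stack[-1], f"{{{NS}}}{tag}", **attrs)

    root = etree.Element(f"{{{NS}}}mzML", version="1.1.0")
    parent_stack = [root]

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
        if unit:
            attrs.update(unitCvRef="UO", unitAccession=unit[0], unitName=unit[1])
        etree.SubElement(parent, f"{{{NS}}}cvParam", **attrs)

    cvlist = etree.SubElement(root, f"{{{NS}}}cvList", count="2")
    etree.SubElement(cvlist, f"{{{NS}}}cv", id="MS", fullName="PSI-MS", URI="")
    etree.SubElement(cvlist, f"{{{NS}}}cv", id="UO", fullName="UO", URI="")
    run = etree.SubElement(root, f"{{{NS}}}run", id="run1")
    speclist = etree.SubElement(run, f"{{{NS}}}spectrumList",
                                count=str(len(scans)), defaultDataProcessingRef="dp1")
    for i, (rt, mz, inten) in enumerate(zip(scans.rts, scans.mz_arrays, scans.intensity_arrays)):
        spec = etree.SubElement(speclist, f"{{{NS}}}spectrum", index=str(i),
                                id=f"scan={i}", defaultArrayLength=str(mz.size))
        cv(spec, "MS:1000127", "centroid spectrum")
        cv(spec, "MS:1000511", "ms level", "1")
        slist = etree.SubElement(spec, f"{{{NS}}}scanList", count="1")
        scan = etree.SubElement(slist, f"{{{NS}}}scan")
        cv(scan, "MS:1000016", "scan start time", f"{rt:.6f}",
           unit=("UO:0000031", "minute"))
        bal = etree.SubElement(spec, f"{{{NS}}}binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (inten, "MS:1000515", "intensity array", ("MS:1000131", "number of detector counts")),
        ):
            encoded = _b64(arr)
            bda = etree.SubElement(bal, f"{{{NS}}}binaryDataArray",
                                   encodedLength=str(len(encoded)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name, unit=unit)
            binary = etree.SubElement(bda, f"{{{NS}}}binary")
            binary.text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary(bda) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.findall("{*}cvParam")}
    text = bda.findtext("{*}binary") or ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in accessions:
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path) -> ScanSet:
    """Minimal reader for centroided mzML (MS1 spectra, 32/64-bit
    float arrays, optional zlib compression)."""
    from lxml import etree

    rts, mzs, intens = [], [], []
    for _, spec in etree.iterparse(str(path), tag="{*}spectrum"):
        accessions = {cv.get("accession") for cv in spec.findall("{*}cvParam")}
        if _ACC_PROFILE in accessions:
            raise ValueError("profile-mode spectra are not supported; centroid first")
        rt = None
        for cv in spec.iter("{*}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        if rt is None:
            raise ValueError(f"{path}: spectrum {spec.get('id')} lacks a scan start time")
        mz = inten = None
        for bda in spec.iter("{*}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.findall("{*}cvParam")}
            if _ACC_MZ_ARRAY in accs:
                mz = _decode_binary(bda)
            elif _ACC_INTENSITY_ARRAY in accs:
                inten = _decode_binary(bda)
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum {spec.get('id')} lacks data arrays")
        rts.append(rt)
        mzs.append(mz)
        intens.append(inten)
        spec.clear()
    if not rts:
        raise ValueError(f"{path}: no spectra found")
    return ScanSet(np.array(rts), mzs, intens)


# ---------------------------------------------------------------------------
# two-column curve tables (temperature_K, value)

def write_curve(temperature_k: np.ndarray, values: np.ndarray, path,
                value_name: str = "birefringence") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"temperature_K,{value_name}\n")
        for t, v in zip(temperature_k, values):
            fh.write(f"{t:.4f},{v:.6f}\n")


def read_curve(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.size == 0:
        raise ValueError(f"{path}: empty curve file")
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1]
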