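"""Reading and writing MS/MS spectra (MGF and mzML) and tabular artifacts.

MGF and mzML parsing is delegated to pyteomics; a minimal mzML *writer* is
provided in-package because pyteomics has no serializer.  Retention times
are normalized to minutes everywhere.
"""

from __future__ import annotations

import base64
import logging
import struct
import warnings
import zlib
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union
from xml.etree import ElementTree as ET

import numpy as np
from pyteomics import mgf as _mgf

from .formula import ElementalFormula
from .model import FragmentPeak, IonSpectrum, KnownCompoundRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class SpectrumIOError(ValueError):
    """Raised for malformed spectrum files."""


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: PathLike) -> List[IonSpectrum]:
    """Read an MGF file into :class:`IonSpectrum` objects.

    Polarity is inferred from the sign of the CHARGE field (defaulting to
    '+'); RTINSECONDS is converted to minutes.  Blocks without PEPMASS are
    skipped with a warning; malformed blocks raise an error naming the
    block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    spectra: List[IonSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, block in enumerate(reader):
            try:
                params = block.get("params", {})
                if "pepmass" not in params:
                    logger.warning("MGF block %d lacks PEPMASS; skipped", idx)
                    continue
                pepmass = params["pepmass"]
                precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list))
                                  else pepmass)
                polarity = "+"
                charge = params.get("charge")
                if charge:
                    ch = charge[0] if isinstance(charge, (tuple, list)) else charge
                    if int(ch) < 0:
                        polarity = "-"
                rt = params.get("rtinseconds")
                rt_min = float(rt) / 60.0 if rt is not None else None
                title = str(params.get("title", f"spectrum_{idx}"))
                peaks = [
                    FragmentPeak(mz=float(m), intensity=float(i))
                    for m, i in zip(block["m/z array"], block["intensity array"])
                ]
                spectra.append(
                    IonSpectrum(
                        id=title,
                        precursor_mz=precursor,
                        polarity=polarity,
                        retention_time=rt_min,
                        peaks=peaks,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise SpectrumIOError(
                    f"malformed MGF block {idx} in {path}: {exc}"
                ) from exc
    return spectra


def write_mgf(spectra: Iterable[IonSpectrum], path: PathLike) -> None:
    """Write spectra to MGF (TITLE/PEPMASS/CHARGE/RTINSECONDS dialect)."""
    entries = []
    for s in spectra:
        params = {
            "title": s.id,
            "pepmass": s.precursor_mz,
            "charge": "1+" if s.polarity == "+" else "1-",
        }
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time * 60.0
        entries.append(
            {
                "params": params,
                "m/z array": np.array([p.mz for p in s.peaks]),
                "intensity array": np.array([p.intensity for p in s.peaks]),
            }
        )
    _mgf.write(entries, str(path), write_charges=True)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _decode_binary(bda: ET.Element, ns: str) -> List[float]:
    accessions = {cv.get("accession") for cv in bda.iter(f"{{{ns}}}cvParam")}
    node = bda.find(f"{{{ns}}}binary")
    if node is None or not (node.text or "").strip():
        return []
    raw = base64.b64decode(node.text.strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    fmt = "f" if "MS:1000521" in accessions else "d"  # 32- vs 64-bit float
    width = 4 if fmt == "f" else 8
    return list(struct.unpack("<%d%s" % (len(raw) // width, fmt), raw))


def read_mzml(path: PathLike) -> List[IonSpectrum]:
    """Read MS2 scans from a centroided mzML file.

    A self-contained PSI-mzML reader (64/32-bit float arrays, zlib or
    uncompressed).  MS1 scans are ignored; profile-mode spectra raise an
    error advising centroiding.  Returns an empty list (with a warning)
    if the file holds no MS2 scans.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ns = "http://psi.hupo.org/ms/mzml"
    spectra: List[IonSpectrum] = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if elem.tag != f"{{{ns}}}spectrum":
            continue
        params = {cv.get("accession"): cv
                  for cv in elem.iter(f"{{{ns}}}cvParam")}
        level = params.get("MS:1000511")
        if level is None or level.get("value") != "2":
            elem.clear()
            continue
        if "MS:1000128" in params:
            raise SpectrumIOError(
                f"{path}: profile-mode spectrum {elem.get('id')}; "
                "centroid the data before reading"
            )
        polarity = "-" if "MS:1000129" in params else "+"
        sel = params.get("MS:1000744")
        if sel is None:
            logger.warning("mzML scan %s lacks precursor m/z; skipped",
                           elem.get("id"))
            elem.clear()
            continue
        precursor = float(sel.get("value"))
        rt = None
        start = params.get("MS:1000016")
        if start is not None:
            rt = float(start.get("value"))
            if start.get("unitName") == "second":
                rt /= 60.0
        mz_arr: List[float] = []
        int_arr: List[float] = []
        for bda in elem.iter(f"{{{ns}}}binaryDataArray"):
            accs = {cv.get("accession")
                    for cv in bda.iter(f"{{{ns}}}cvParam")}
            if "MS:1000514" in accs:
                mz_arr = _decode_binary(bda, ns)
            elif "MS:1000515" in accs:
                int_arr = _decode_binary(bda, ns)
        if len(int_arr) != len(mz_arr):
            int_arr = [0.0] * len(mz_arr)
        spectra.append(
            IonSpectrum(
                id=str(elem.get("id", f"scan={len(spectra)}")),
                precursor_mz=precursor,
                polarity=polarity,
                retention_time=rt,
                peaks=[FragmentPeak(m, i)
                       for m, i in zip(mz_arr, int_arr)],
            )
        )
        elem.clear()
    if not spectra:
        warnings.warn(f"{path}: no MS2 scans found")
    return spectra


def _b64_doubles(values: Sequence[float]) -> str:
    raw = struct.pack("<%dd" % len(values), *values)
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_mzml(spectra: Iterable[IonSpectrum], path: PathLike) -> None:
    """Write a minimal but standards-conformant mzML file of MS2 scans.

    Arrays are 64-bit little-endian, zlib-compressed, as pyteomics expects.
    Intended for round-tripping and small test files, not for vendor-scale
    data.
    """
    spectra = list(spectra)
    ns = "http://psi.hupo.org/ms/mzml"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}mzML", version="1.1.0")
    ET.SubElement(root, f"{{{ns}}}cvList", count="1")
    run = None
    filedesc = ET.SubElement(root, f"{{{ns}}}fileDescription")
    fc = ET.SubElement(filedesc, f"{{{ns}}}fileContent")
    _cv(fc, "MS:1000580", "MSn spectrum")
    run = ET.SubElement(root, f"{{{ns}}}run", id="run1")
    slist = ET.SubElement(run, f"{{{ns}}}spectrumList",
                          count=str(len(spectra)))
    for i, s in enumerate(spectra):
        sp = ET.SubElement(
            slist, f"{{{ns}}}spectrum",
            index=str(i), id=f"scan={i}",
            defaultArrayLength=str(len(s.peaks)),
        )
        _cv(sp, "MS:1000511", "ms level", value="2")
        _cv(sp, "MS:1000580", "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        if s.polarity == "+":
            _cv(sp, "MS:1000130", "positive scan")
        else:
            _cv(sp, "MS:1000129", "negative scan")
        if s.retention_time is not None:
            sl = ET.SubElement(sp, f"{{{ns}}}scanList", count="1")
            _cv(sl, "MS:1000795", "no combination")
            scan = ET.SubElement(sl, f"{{{ns}}}scan")
            _cv(scan, "MS:1000016", "scan start time",
                value=repr(float(s.retention_time)),
                unit=("UO:0000031", "minute"))
        plist = ET.SubElement(sp, f"{{{ns}}}precursorList", count="1")
        prec = ET.SubElement(plist, f"{{{ns}}}precursor")
        silist = ET.SubElement(prec, f"{{{ns}}}selectedIonList", count="1")
        si = ET.SubElement(silist, f"{{{ns}}}selectedIon")
        _cv(si, "MS:1000744", "selected ion m/z",
            value=repr(float(s.precursor_mz)),
            unit=("MS:1000040", "m/z"))
        bal = ET.SubElement(sp, f"{{{ns}}}binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", [p.mz for p in s.peaks]),
            ("MS:1000515", "intensity array", [p.intensity for p in s.peaks]),
        ):
            payload = _b64_doubles(values)
            bda = ET.SubElement(bal, f"{{{ns}}}binaryDataArray",
                                encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000574", "zlib compression")
            _cv(bda, accession, name)
            ET.SubElement(bda, f"{{{ns}}}binary").text = payload
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


def _cv(parent: ET.Element, accession: str, name: str,
        value: Optional[str] = None, unit: Optional[tuple] = None) -> None:
    ns = "http://psi.hupo.org/ms/mzml"
    attrs = {"cvRef": "MS", "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = value
    else:
        attrs["value"] = ""
    if unit is not None:
        attrs["unitAccession"], attrs["unitName"] = unit
        attrs["unitCvRef"] = "UO" if unit[0].startswith("UO") else "MS"
    ET.SubElement(parent, f"{{{ns}}}cvParam", attrs)


# ---------------------------------------------------------------------------
# Registry TSV
# ---------------------------------------------------------------------------

def write_registry_tsv(records: Iterable[KnownCompoundRecord],
                       path: PathLike) -> None:
    lines = ["id\tname\tformula\tgroup\tsource\tpolarity"]
    for r in records:
        lines.append("\t".join(
            [r.id, r.name, r.formula.hill(), r.group, r.source, r.polarity]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_registry_tsv(path: PathLike) -> List[KnownCompoundRecord]:
    rows = Path(path).read_text().strip().splitlines()
    header = rows[0].split("\t")
    out = []
    for line in rows[1:]:
        d = dict(zip(header, line.split("\t")))
        out.append(
            KnownCompoundRecord(
                id=d["id"], name=d["name"],
                formula=ElementalFormula.parse(d["formula"]),
                group=d["group"], source=d.get("source", ""),
                polarity=d.get("polarity", "+"),
            )
        )
    return out


# Re-export the in-study fixture loader at this module's surface.
from .fixture import paper_fixture  # noqa: E402,F401
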