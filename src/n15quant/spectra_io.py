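"""In-memory LC-MS run model, mzML reading/writing, and result tables.

Both directions of mzML 1.1 are handled with a compact lxml layer: the
reader streams ``<spectrum>`` elements (plain or indexed documents, gzip
accepted, 32/64-bit float arrays, zlib or uncompressed) and the writer
emits minimal plain mzML (64-bit, uncompressed, base64 binary arrays).
Write/read identity is covered by tests.
"""

from __future__ import annotations

import base64
import gzip
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class MS1Spectrum:
    """A centroided survey scan; peak arrays are kept mz-sorted."""

    scan_id: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass
class MS2Spectrum:
    """A fragmentation spectrum with its selected precursor."""

    scan_id: int
    retention_time: float  # minutes
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class Run:
    ms1: list[MS1Spectrum]
    ms2: list[MS2Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ms1 = sorted(self.ms1, key=lambda s: s.retention_time)
        self.ms2 = sorted(self.ms2, key=lambda s: (s.retention_time, s.scan_id))


def centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a profile trace to centroids: local maxima with a 3-point
    intensity-weighted m/z.  A convenience only; centroided input is
    recommended."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) < 3:
        keep = intensity > 0
        return mz[keep], intensity[keep]
    is_max = (intensity[1:-1] >= intensity[:-2]) & (intensity[1:-1] > intensity[2:]) & (
        intensity[1:-1] > 0
    )
    idx = np.nonzero(is_max)[0] + 1
    out_mz = np.empty(len(idx))
    out_int = np.empty(len(idx))
    for j, i in enumerate(idx):
        sl = slice(i - 1, i + 2)
        w = intensity[sl]
        out_mz[j] = float(np.average(mz[sl], weights=w))
        out_int[j] = float(w.sum())
    return out_mz, out_int


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# cv accessions understood by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_PROFILE = "MS:1000128"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"


def _cv_params(element) -> dict[str, dict]:
    out = {}
    for cv in element.iter(_MZML_NS + "cvParam"):
        out[cv.get("accession")] = dict(cv.attrib)
    return out


def _decode_array(bda) -> tuple[str | None, np.ndarray]:
    accs = _cv_params(bda)
    binary = bda.find(_MZML_NS + "binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accs else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if _ACC_MZ_ARRAY in accs:
        return "mz", values
    if _ACC_INT_ARRAY in accs:
        return "intensity", values
    return None, values


def _parse_spectrum(element, index: int):
    params = _cv_params(element)
    level = int(params.get(_ACC_MS_LEVEL, {}).get("value", 1))
    rt = 0.0
    scan_el = element.find(
        f"{_MZML_NS}scanList/{_MZML_NS}scan"
    )
    if scan_el is not None:
        sp = _cv_params(scan_el)
        if _ACC_SCAN_START in sp:
            rt = float(sp[_ACC_SCAN_START]["value"])
            if sp[_ACC_SCAN_START].get("unitName", "minute").startswith("second"):
                rt /= 60.0
    arrays: dict[str, np.ndarray] = {}
    for bda in element.iter(_MZML_NS + "binaryDataArray"):
        kind, values = _decode_array(bda)
        if kind:
            arrays[kind] = values
    mz = arrays.get("mz", np.empty(0))
    inten = arrays.get("intensity", np.empty(0))
    n = min(len(mz), len(inten))
    mz, inten = mz[:n], inten[:n]
    try:
        scan_id = int(str(element.get("id", index)).rsplit("=", 1)[-1])
    except ValueError:
        scan_id = index
    if level == 1:
        if _ACC_PROFILE in params:
            mz, inten = centroid_profile(mz, inten)
        return MS1Spectrum(scan_id, rt, mz, inten)
    ion = element.find(
        f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
        f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
    )
    if ion is None:
        raise ValueError(f"MS{level} scan {scan_id} lacks a selected precursor ion")
    ip = _cv_params(ion)
    if _ACC_SELECTED_MZ not in ip:
        raise ValueError(f"MS{level} scan {scan_id} lacks a precursor m/z")
    pmz = float(ip[_ACC_SELECTED_MZ]["value"])
    charge = ip.get(_ACC_CHARGE)
    return MS2Spectrum(
        scan_id, rt, pmz,
        int(charge["value"]) if charge is not None else None,
        mz, inten,
    )


def read_run(path: str | Path) -> Run:
    """Parse an mzML file (plain or indexed; gzip accepted) into a
    :class:`Run`.  Profile MS1 scans are centroided; scans are sorted by
    retention time."""
    opener = gzip.open if str(path).endswith(".gz") else open
    ms1: list[MS1Spectrum] = []
    ms2: list[MS2Spectrum] = []
    try:
        with opener(str(path), "rb") as handle:
            for i, (_, element) in enumerate(
                etree.iterparse(handle, tag=_MZML_NS + "spectrum")
            ):
                spec = _parse_spectrum(element, i)
                (ms1 if isinstance(spec, MS1Spectrum) else ms2).append(spec)
                element.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: not a readable mzML document ({exc})") from exc
    if not ms1:
        raise ValueError(f"{path}: run contains no MS1 scans")
    return Run(ms1=ms1, ms2=ms2, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# mzML writing

_NS = "http://psi.hupo.org/ms/mzml"


def _encode(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    ).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **unit) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(unit)
    etree.SubElement(parent, "cvParam", **attrs)


def _binary_list(parent, mz: np.ndarray, intensity: np.ndarray) -> None:
    bdal = etree.SubElement(parent, "binaryDataArrayList", count="2")
    for accession, name, values in (
        ("MS:1000514", "m/z array", mz),
        ("MS:1000515", "intensity array", intensity),
    ):
        payload = _encode(values)
        bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
        _cv(bda, "MS:1000523", "64-bit float")
        _cv(bda, "MS:1000576", "no compression")
        _cv(bda, accession, name)
        etree.SubElement(bda, "binary").text = payload


def write_mzml(run: Run, path: str | Path) -> None:
    """Serialise a run as plain (non-indexed) mzML 1.1."""
    root = etree.Element(
        "mzML", xmlns=_NS, version="1.1.0", id="n15quant_run"
    )
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology", URI="http://ontologies.berkeleybop.org/uo.obo"
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")

    slist = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(slist, "software", id="n15quant", version="0.1.0")
    iclist = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(iclist, "instrumentConfiguration", id="IC1")
    dplist = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dplist, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="0", softwareRef="n15quant")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    spectra: list[tuple[float, int, object]] = []
    for s in run.ms1:
        spectra.append((s.retention_time, s.scan_id, s))
    for s in run.ms2:
        spectra.append((s.retention_time, s.scan_id, s))
    spectra.sort(key=lambda t: (t[0], t[1]))

    runel = etree.SubElement(
        root, "run", id="run1", defaultInstrumentConfigurationRef="IC1"
    )
    sl = etree.SubElement(
        runel, "spectrumList", count=str(len(spectra)), defaultDataProcessingRef="DP1"
    )
    for index, (rt, scan_id, s) in enumerate(spectra):
        spec = etree.SubElement(
            sl,
            "spectrum",
            index=str(index),
            id=f"scan={scan_id}",
            defaultArrayLength=str(len(s.mz)),
        )
        is_ms2 = isinstance(s, MS2Spectrum)
        _cv(spec, "MS:1000511", "ms level", "2" if is_ms2 else "1")
        _cv(spec, "MS:1000580" if is_ms2 else "MS:1000579",
            "MSn spectrum" if is_ms2 else "MS1 spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scl = etree.SubElement(spec, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan = etree.SubElement(scl, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", repr(float(rt)),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        if is_ms2:
            plist = etree.SubElement(spec, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            sil = etree.SubElement(prec, "selectedIonList", count="1")
            ion = etree.SubElement(sil, "selectedIon")
            _cv(ion, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            if s.precursor_charge is not None:
                _cv(ion, "MS:1000041", "charge state", str(int(s.precursor_charge)))
        _binary_list(spec, s.mz, s.intensity)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Result tables

PAIRS_COLUMNS = [
    "light_mz", "heavy_mz", "charge", "nitrogen_count",
    "rt_start", "rt_end", "light_area", "heavy_area", "log2_ratio",
]
PSMS_COLUMNS = [
    "scan", "sequence", "label", "charge", "score", "q_value", "decoy",
]
PEPTIDES_COLUMNS = [
    "sequence", "charges", "median_log2_ratio", "n_measurements", "cv_percent",
]
PROTEINS_COLUMNS = [
    "protein", "n_distinct_peptides", "median_log2_ratio", "cv_percent",
]


def _ordered(df: pd.DataFrame | None, columns: list[str], sort_by: list[str]) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame(columns=columns)
    out = df.reindex(columns=columns)
    return out.sort_values(sort_by, kind="mergesort").reset_index(drop=True)


def write_results(
    pairs: pd.DataFrame | None,
    psms: pd.DataFrame | None,
    peptide_table: pd.DataFrame | None,
    protein_table: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four canonical TSVs with fixed headers and deterministic
    row order; identical inputs produce byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "pairs.tsv": _ordered(pairs, PAIRS_COLUMNS, ["light_mz", "charge"]),
        "psms.tsv": _ordered(psms, PSMS_COLUMNS, ["scan", "sequence"]),
        "peptides.tsv": _ordered(peptide_table, PEPTIDES_COLUMNS, ["sequence"]),
        "proteins.tsv": _ordered(protein_table, PROTEINS_COLUMNS, ["protein"]),
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        paths[name] = p
    return paths
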