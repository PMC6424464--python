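"""LC-MS run data model and readers/writers.

Centroided-only model: a :class:`Run` holds MS1 scans (retention time +
peak list) and MS2 spectra.  Supported formats are a centroided subset of
mzML (read via pyteomics, written by a small deterministic writer), MGF
(MS2 only) and plain CSV peak tables.  Retention times are minutes.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PeakList",
    "MS2Spectrum",
    "Run",
    "Chromatogram",
    "Feature",
    "read_run",
    "write_run",
    "extract_xic",
    "integrate_area",
]


@dataclass
class PeakList:
    """Parallel centroided m/z and intensity arrays, m/z strictly increasing."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size

    @classmethod
    def from_pairs(cls, pairs) -> "PeakList":
        """Build from (m/z, intensity) pairs, sorting and merging duplicates."""
        if not pairs:
            return cls(np.empty(0), np.empty(0))
        arr = np.asarray(sorted(pairs), dtype=float)
        mz, inv = np.unique(arr[:, 0], return_inverse=True)
        inten = np.zeros_like(mz)
        np.add.at(inten, inv, arr[:, 1])
        return cls(mz, inten)


@dataclass
class MS2Spectrum:
    precursor_mz: float
    precursor_charge: int
    rt: float
    peaks: PeakList
    scan_id: str | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be > 0")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")


@dataclass
class Run:
    """An LC-MS run: ordered MS1 scans and an MS2 spectrum collection."""

    ms1: list[tuple[float, PeakList]] = field(default_factory=list)
    ms2: list[MS2Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [rt for rt, _ in self.ms1]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("MS1 scan retention times must be non-decreasing")

    @property
    def ms1_rts(self) -> np.ndarray:
        return np.array([rt for rt, _ in self.ms1])


@dataclass
class Chromatogram:
    """Extracted-ion chromatogram of a narrow m/z window."""

    rt: np.ndarray
    intensity: np.ndarray
    target_mz: float
    tol_ppm: float
    charge: int | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity series must have equal length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) < 0):
            raise ValueError("rt series must be non-decreasing")

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class Feature:
    """An MS1 ion feature: apex, bounds and integrated area of one species."""

    mz: float
    charge: int
    rt_apex: float
    rt_start: float
    rt_end: float
    area: float
    apex_intensity: float = 0.0

    def __post_init__(self) -> None:
        if not self.rt_start <= self.rt_apex <= self.rt_end:
            raise ValueError("feature rt bounds must contain the apex")
        if self.area < 0:
            raise ValueError("feature area must be non-negative")


# ---------------------------------------------------------------------------
# mzML writing (centroided subset; 64-bit float, no compression)

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession: str, name: str, value: str = "", **units):
    from lxml import etree

    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if units:
        attrs.update(
            unitCvRef="UO",
            unitAccession=units["unit_accession"],
            unitName=units["unit_name"],
        )
    return etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def _binary_array(parent, data: np.ndarray, kind: str):
    from lxml import etree

    payload = base64.b64encode(np.asarray(data, dtype="<f8").tobytes()).decode("ascii")
    bda = etree.SubElement(
        parent, f"{{{_MZML_NS}}}binaryDataArray", {"encodedLength": str(len(payload))}
    )
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(bda, "MS:1000514", "m/z array", unit_accession="MS:1000040", unit_name="m/z")
    else:
        _cv(
            bda,
            "MS:1000515",
            "intensity array",
            unit_accession="MS:1000131",
            unit_name="number of detector counts",
        )
    etree.SubElement(bda, f"{{{_MZML_NS}}}binary").text = payload
    return bda


def _write_mzml(run: Run, path: Path) -> None:
    from lxml import etree

    E = lambda parent, tag, **attrs: etree.SubElement(  # noqa: E731
        parent, f"{{{_MZML_NS}}}{tag}", {k: str(v) for k, v in attrs.items()}
    )
    root = etree.Element(f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"}, nsmap={None: _MZML_NS})
    cvlist = E(root, "cvList", count=2)
    E(
        cvlist,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    E(cvlist, "cv", id="UO", fullName="Unit Ontology", URI="http://ontologies.berkeleybop.org/uo.obo")
    runel = E(root, "run", id=run.metadata.get("run_id", "run"))

    # interleave MS1 and MS2 in retention-time order (stable: MS1 first on ties)
    entries: list[tuple[float, int, object]] = [
        (rt, 1, (rt, peaks)) for rt, peaks in run.ms1
    ] + [(s.rt, 2, s) for s in run.ms2]
    entries.sort(key=lambda e: (e[0], e[1]))

    slist = E(runel, "spectrumList", count=len(entries))
    for index, (rt, level, obj) in enumerate(entries):
        if level == 1:
            rt, peaks = obj
            scan_id = f"scan={index + 1}"
        else:
            peaks = obj.peaks
            scan_id = obj.scan_id or f"scan={index + 1}"
        spec = E(
            slist,
            "spectrum",
            index=index,
            id=scan_id,
            defaultArrayLength=len(peaks),
        )
        _cv(spec, "MS:1000511", "ms level", str(level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scanlist = E(spec, "scanList", count=1)
        _cv(scanlist, "MS:1000795", "no combination")
        scan = E(scanlist, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(float(rt)),
            unit_accession="UO:0000031",
            unit_name="minute",
        )
        if level == 2:
            plist = E(spec, "precursorList", count=1)
            prec = E(plist, "precursor")
            silist = E(prec, "selectedIonList", count=1)
            si = E(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(float(obj.precursor_mz)),
                unit_accession="MS:1000040", unit_name="m/z")
            _cv(si, "MS:1000041", "charge state", str(obj.precursor_charge))
        balist = E(spec, "binaryDataArrayList", count=2)
        _binary_array(balist, peaks.mz, "mz")
        _binary_array(balist, peaks.intensity, "intensity")

    path.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    )


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit float, raw or zlib."""
    import zlib

    accessions = {
        cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")
    }
    text = bda.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> Run:
    from lxml import etree

    ms1: list[tuple[float, PeakList]] = []
    ms2: list[MS2Spectrum] = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzML {path}: {exc}") from exc
    for spec in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in spec.iter(f"{{{_MZML_NS}}}cvParam")
        }
        level = int(params.get("MS:1000511", 1))
        rt = float(params.get("MS:1000016", 0.0))
        scan = spec.find(f".//{{{_MZML_NS}}}scan")
        if scan is not None:
            for cv in scan.iter(f"{{{_MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "second":
                        rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
            key = "mz" if "MS:1000514" in accs else "intensity"
            arrays[key] = _decode_binary_array(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(
                f"mzML spectrum {spec.get('id')!r} lacks m/z or intensity arrays"
            )
        peaks = PeakList(arrays["mz"], arrays["intensity"])
        if level == 1:
            ms1.append((rt, peaks))
        else:
            pmz, pz = 0.0, 1
            ion = spec.find(f".//{{{_MZML_NS}}}selectedIon")
            if ion is not None:
                for cv in ion.iter(f"{{{_MZML_NS}}}cvParam"):
                    if cv.get("accession") == "MS:1000744":
                        pmz = float(cv.get("value"))
                    elif cv.get("accession") == "MS:1000041":
                        pz = int(cv.get("value"))
            ms2.append(MS2Spectrum(pmz, pz, rt, peaks, scan_id=spec.get("id")))
    ms1.sort(key=lambda e: e[0])
    return Run(ms1, ms2, {"source": str(path), "format": "mzml"})


# ---------------------------------------------------------------------------
# MGF (MS2 only)


def _write_mgf(run: Run, path: Path) -> None:
    from pyteomics import mgf

    spectra = [
        {
            "m/z array": s.peaks.mz,
            "intensity array": s.peaks.intensity,
            "params": {
                "title": s.scan_id or f"spectrum={i}",
                "pepmass": (s.precursor_mz, None),
                "charge": [s.precursor_charge],
                "rtinseconds": s.rt * 60.0,
            },
        }
        for i, s in enumerate(run.ms2)
    ]
    mgf.write(spectra, output=str(path), file_mode="w")


def _read_mgf(path: Path) -> Run:
    from pyteomics import mgf

    ms2 = []
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = params.get("charge")
            ms2.append(
                MS2Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=int(charge[0]) if charge else 1,
                    rt=float(params.get("rtinseconds", 0.0)) / 60.0,
                    peaks=PeakList(spec["m/z array"], spec["intensity array"]),
                    scan_id=params.get("title"),
                )
            )
    return Run([], ms2, {"source": str(path), "format": "mgf"})


# ---------------------------------------------------------------------------
# CSV peak tables

_CSV_COLUMNS = ["scan", "ms_level", "rt_min", "precursor_mz", "precursor_z", "mz", "intensity"]


def _write_csv(run: Run, path: Path) -> None:
    import pandas as pd

    rows = []
    entries = [(rt, 1, None, None, peaks) for rt, peaks in run.ms1] + [
        (s.rt, 2, s.precursor_mz, s.precursor_charge, s.peaks) for s in run.ms2
    ]
    entries.sort(key=lambda e: (e[0], e[1]))
    for scan, (rt, level, pmz, pz, peaks) in enumerate(entries, start=1):
        for mz, inten in zip(peaks.mz, peaks.intensity):
            rows.append((scan, level, rt, pmz, pz, mz, inten))
        if len(peaks) == 0:  # keep empty scans
            rows.append((scan, level, rt, pmz, pz, np.nan, np.nan))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _read_csv(path: Path) -> Run:
    import pandas as pd

    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CSV peak table missing columns: {sorted(missing)}")
    ms1, ms2 = [], []
    for scan, group in df.groupby("scan", sort=True):
        level = int(group["ms_level"].iloc[0])
        rt = float(group["rt_min"].iloc[0])
        real = group.dropna(subset=["mz"])
        peaks = PeakList.from_pairs(list(zip(real["mz"], real["intensity"])))
        if level == 1:
            ms1.append((rt, peaks))
        else:
            ms2.append(
                MS2Spectrum(
                    precursor_mz=float(group["precursor_mz"].iloc[0]),
                    precursor_charge=int(group["precursor_z"].iloc[0]),
                    rt=rt,
                    peaks=peaks,
                    scan_id=f"scan={scan}",
                )
            )
    ms1.sort(key=lambda e: e[0])
    return Run(ms1, ms2, {"source": str(path), "format": "csv"})


_FORMATS = {
    "mzml": (_read_mzml, _write_mzml),
    "mgf": (_read_mgf, _write_mgf),
    "csv": (_read_csv, _write_csv),
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown run format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return fmt


def read_run(path, fmt: str | None = None) -> Run:
    """Read an LC-MS run from mzML, MGF or a CSV peak table."""
    path = Path(path)
    return _FORMATS[_infer_format(path, fmt)][0](path)


def write_run(run: Run, path, fmt: str | None = None) -> None:
    """Write a run; ``read_run(write_run(...))`` round-trips all used fields."""
    path = Path(path)
    _FORMATS[_infer_format(path, fmt)][1](run, path)


# ---------------------------------------------------------------------------
# XIC extraction and integration


def extract_xic(
    run: Run,
    target_mz: float,
    tol_ppm: float,
    rt_window: tuple[float, float] | None = None,
    charge: int | None = None,
) -> Chromatogram:
    """Per-MS1-scan summed intensity within ±tol_ppm of ``target_mz``.

    Scans with no matching peak contribute zero; an empty run yields an
    empty chromatogram.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    lo = target_mz * (1 - tol_ppm * 1e-6)
    hi = target_mz * (1 + tol_ppm * 1e-6)
    rts, intensities = [], []
    for rt, peaks in run.ms1:
        if rt_window is not None and not rt_window[0] <= rt <= rt_window[1]:
            continue
        i, j = np.searchsorted(peaks.mz, [lo, hi])
        rts.append(rt)
        intensities.append(float(peaks.intensity[i:j].sum()))
    return Chromatogram(np.array(rts), np.array(intensities), target_mz, tol_ppm, charge)


def integrate_area(c: Chromatogram, baseline_percentile: float = 10.0) -> float:
    """Trapezoidal area of the baseline-subtracted chromatogram.

    The baseline is the given percentile of the window's intensities
    (constant); subtracted intensities are clipped at zero.
    """
    if len(c) == 0:
        return 0.0
    baseline = np.percentile(c.intensity, baseline_percentile)
    corrected = np.clip(c.intensity - baseline, 0.0, None)
    return float(np.trapezoid(corrected, c.rt))
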