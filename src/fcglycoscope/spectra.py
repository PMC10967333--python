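"""Spectrum/Run containers, MGF read-write, minimal mzML read, peak matching.

MGF is the canonical interchange format here. Because the pipeline also
consumes MS1-only runs (the 18O deglycosylation experiment), the MGF dialect
carries an ``MSLEVEL`` header per block; MS1 blocks have no PEPMASS. Parsing
and serialisation go through :mod:`pyteomics.mgf`; unknown block headers are
preserved in :attr:`Spectrum.extra` and round-tripped.

mzML support is read-only and limited to centroided spectra; profile-mode
data raise an explicit unsupported-feature error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Spectrum",
    "Run",
    "PeakMatch",
    "MGFError",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "match_peak",
]


class MGFError(ValueError):
    """Raised for malformed or contract-violating MGF content."""


@dataclass
class Spectrum:
    """One centroided scan: parallel m/z (strictly increasing) and intensity
    arrays, plus a precursor descriptor for MS2."""

    scan_id: str
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    rt: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be parallel 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"scan {self.scan_id}: m/z not strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")
        if self.ms_level not in (1, 2):
            raise ValueError(f"scan {self.scan_id}: ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"scan {self.scan_id}: MS2 requires a precursor m/z")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class Run:
    """An ordered collection of scans with unique scan ids."""

    spectra: list[Spectrum]
    source: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scan ids in run")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def by_id(self, scan_id: str) -> Spectrum:
        for s in self.spectra:
            if s.scan_id == scan_id:
                return s
        raise KeyError(scan_id)


# ---------------------------------------------------------------------------
# MGF

_KNOWN_PARAMS = {"title", "pepmass", "charge", "rtinseconds", "mslevel"}


def read_mgf(path: str | Path) -> Run:
    """Read an MGF file into a :class:`Run`.

    Blocks must carry PEPMASS unless marked ``MSLEVEL=1``; violations raise
    :class:`MGFError` naming the offending block.
    """
    from pyteomics import mgf as _mgf

    spectra = []
    with _mgf.read(str(path), convert_arrays=1, use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"index={i}"))
            ms_level = int(params["mslevel"]) if "mslevel" in params else None
            pepmass = params.get("pepmass")
            if pepmass is None:
                if ms_level is None or ms_level == 2:
                    raise MGFError(
                        f"{path}: block {i} ({title}): missing PEPMASS in an "
                        "MS2 block"
                    )
                precursor_mz = None
            else:
                precursor_mz = float(pepmass[0]) if isinstance(pepmass, tuple) else float(pepmass)
            if ms_level is None:
                ms_level = 2
            charge = params.get("charge")
            if charge is not None and len(charge):
                charge = int(charge[0])
            else:
                charge = None
            rt = params.get("rtinseconds")
            rt = float(rt) if rt is not None else None
            extra = {k: v for k, v in params.items() if k not in _KNOWN_PARAMS}
            order = np.argsort(entry["m/z array"], kind="stable")
            spectra.append(
                Spectrum(
                    scan_id=title,
                    ms_level=ms_level,
                    mz=entry["m/z array"][order],
                    intensity=entry["intensity array"][order],
                    precursor_mz=precursor_mz,
                    precursor_charge=charge,
                    rt=rt,
                    extra=dict(extra),
                )
            )
    return Run(spectra, source=str(path))


def write_mgf(run: Run, path: str | Path) -> None:
    """Serialise a run to MGF (deterministic: fixed formats and key order)."""
    from pyteomics import mgf as _mgf

    entries = []
    for s in run.spectra:
        params: dict = {"title": s.scan_id, "mslevel": s.ms_level}
        if s.rt is not None:
            params["rtinseconds"] = f"{s.rt:.3f}"
        if s.ms_level == 2:
            params["pepmass"] = f"{s.precursor_mz:.5f}"
            if s.precursor_charge is not None:
                params["charge"] = s.precursor_charge
        params.update(s.extra)
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as fh:
        _mgf.write(
            entries,
            output=fh,
            key_order=("title", "mslevel", "rtinseconds", "pepmass", "charge"),
            fragment_format="{:.5f} {:.6g}",
        )


# ---------------------------------------------------------------------------
# mzML (read-only subset)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions of the supported mzML subset
_CV_MS_LEVEL = "MS:1000511"
_CV_PROFILE = "MS:1000128"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE = "MS:1000041"
_CV_SCAN_START = "MS:1000016"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


def _decode_binary_array(bda, scan_id: str) -> tuple[str | None, np.ndarray]:
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in bda.iter(_MZML_NS + "cvParam")
    }
    if _CV_F64 in accessions:
        dtype = "<f8"
    elif _CV_F32 in accessions:
        dtype = "<f4"
    else:
        raise ValueError(
            f"scan {scan_id}: unsupported mzML binary encoding (only 32/64-bit "
            "float are supported)"
        )
    node = bda.find(_MZML_NS + "binary")
    raw = base64.b64decode(node.text or "")
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    elif _CV_NO_COMPRESSION not in accessions:
        raise ValueError(
            f"scan {scan_id}: unsupported mzML compression (only zlib or none)"
        )
    values = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    kind = None
    if _CV_MZ_ARRAY in accessions:
        kind = "mz"
    elif _CV_INTENSITY_ARRAY in accessions:
        kind = "intensity"
    return kind, values


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file (binary 64/32-bit float, zlib or none).

    Only the centroided-spectrum subset is supported; profile-mode spectra
    and exotic encodings raise an explicit unsupported-feature error.
    """
    from lxml import etree

    spectra = []
    for _event, elem in etree.iterparse(str(path), tag=_MZML_NS + "spectrum"):
        scan_id = elem.get("id", f"index={elem.get('index')}")
        params = {
            cv.get("accession"): cv
            for cv in elem.iter(_MZML_NS + "cvParam")
        }
        if _CV_PROFILE in params:
            raise ValueError(
                f"{path}: profile-mode spectrum {scan_id}; only centroided "
                "mzML is supported"
            )
        ms_level = int(params[_CV_MS_LEVEL].get("value")) if _CV_MS_LEVEL in params else 1
        precursor_mz = None
        precursor_charge = None
        if _CV_SELECTED_MZ in params:
            precursor_mz = float(params[_CV_SELECTED_MZ].get("value"))
        if _CV_CHARGE in params:
            precursor_charge = int(params[_CV_CHARGE].get("value"))
        rt = None
        if _CV_SCAN_START in params:
            cv = params[_CV_SCAN_START]
            rt = float(cv.get("value"))
            if cv.get("unitName") == "minute":
                rt *= 60.0
        mz = inten = None
        for bda in elem.iter(_MZML_NS + "binaryDataArray"):
            kind, values = _decode_binary_array(bda, scan_id)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz is None or inten is None:
            raise ValueError(f"{path}: scan {scan_id}: missing m/z or intensity array")
        order = np.argsort(mz, kind="stable")
        spectra.append(
            Spectrum(
                scan_id=str(scan_id),
                ms_level=ms_level,
                mz=mz[order],
                intensity=inten[order],
                precursor_mz=precursor_mz,
                precursor_charge=precursor_charge,
                rt=rt,
            )
        )
        elem.clear()
    return Run(spectra, source=str(path))


# ---------------------------------------------------------------------------
# peak matching


@dataclass(frozen=True)
class PeakMatch:
    index: int
    mz: float
    intensity: float
    ppm: float


def match_peak(spectrum: Spectrum, target_mz: float, tol_ppm: float) -> PeakMatch | None:
    """Most intense peak within *tol_ppm* of *target_mz* (ties: smaller |ppm|).

    The window is relative to the target, so matching commutes with a uniform
    m/z rescaling of spectrum and target.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = target_mz * tol_ppm * 1e-6
    lo = int(np.searchsorted(spectrum.mz, target_mz - half, side="left"))
    hi = int(np.searchsorted(spectrum.mz, target_mz + half, side="right"))
    if lo == hi:
        return None
    best = None
    for i in range(lo, hi):
        ppm = (spectrum.mz[i] - target_mz) / target_mz * 1e6
        cand = (-spectrum.intensity[i], abs(ppm), i)
        if best is None or cand < best[0]:
            best = (cand, i, ppm)
    _, i, ppm = best
    return PeakMatch(i, float(spectrum.mz[i]), float(spectrum.intensity[i]), float(ppm))
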