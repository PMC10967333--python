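"""Seeded synthetic MGF runs with ground truth.

Two kinds of runs are generated, emulating the acquisition that produced the
study data:

* glyco search runs — per sampled glycopeptide, an MS1 scan carrying its
  isotope envelope at charges 2/3 (heights proportional to the preset
  glycoform weight) followed by an HCD MS2 scan with oxonium, Y-series,
  b/y and site-localising glyco-b/y ions, plus noise peaks and bare-peptide
  decoy precursors;

* 18O deglycosylation runs — MS1-only scans mixing the unlabeled Asn-peptide
  envelope with the +2.98826 Da Asp(18O) envelope at a configurable occupancy
  fraction, with the 97%-purity light-water leakage emitted at +0.98402 Da.

Peaks are centroided: Gaussian m/z jitter (sigma 2 ppm by default), log-normal
peak-height noise, and a centroider that cannot separate peaks closer than
2x FWHM at the configured MS1 resolving power (120,000 @ m/z 200, scaled as
1/sqrt(m/z)) — this is what folds the unlabeled M+3 isotopologue into the
labeled monoisotopic peak in the occupancy runs. MS2 fragment peaks are
emitted at their exact (jittered) positions.

The two platform presets encode the published profiles: HCA-N (tobacco) has
13 glycoforms dominated by G0 with ~1% fucosylation and an occupied fraction
of 0.491; HCA_mRNA (vaginal-cell mRNA expression) has 11 fairly evenly
distributed glycoforms led by G0F/G1F/G2F, including G2S1F and monoHexNAc,
with occupancy 0.960. Compositions named in the study text anchor each
preset; the remaining filler glycoforms and all weights are documented
package constants, not literature claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_CONSTANTS,
    GlycanComposition,
    Glycopeptide,
    Peptide,
    glycopeptide_mz,
    peptide_mass,
    peptide_mz,
)
from .gpsm import theoretical_fragments
from .glycans import default_library
from .quant import NEUTRON, isotope_envelope
from .spectra import Run, Spectrum

__all__ = [
    "PlatformPreset",
    "SynthConfig",
    "PRESETS",
    "generate_glyco_run",
    "generate_deglyco_run",
    "synthetic_heavy_chain",
    "synthetic_light_chain",
    "default_proteins",
    "merge_centroids",
    "peak_fwhm",
]


@dataclass(frozen=True)
class PlatformPreset:
    """Glycoform weight profile + site occupancy for one expression platform."""

    name: str
    weights: tuple[tuple[GlycanComposition, float], ...]
    occupancy: float

    def __post_init__(self) -> None:
        total = sum(w for _c, w in self.weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"preset {self.name}: weights sum to {total}, not 1")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"preset {self.name}: occupancy outside [0, 1]")
        comps = [c for c, _w in self.weights]
        if len(set(comps)) != len(comps):
            raise ValueError(f"preset {self.name}: duplicate compositions")
        if any(w < 0 for _c, w in self.weights):
            raise ValueError(f"preset {self.name}: negative weight")

    @property
    def n_glycoforms(self) -> int:
        return len(self.weights)


def _build_presets() -> dict[str, PlatformPreset]:
    lib = default_library()
    g = lib.shorthand_to_composition
    c = GlycanComposition
    hca_n = (
        (g("G0"), 0.40),
        (g("Man5"), 0.09),
        (g("Man6"), 0.06),
        (g("Man7"), 0.05),
        (g("Man8"), 0.04),
        (g("Man9"), 0.03),
        (c(hexnac=3, hex=5), 0.07),
        (c(hexnac=3, hex=6), 0.05),
        (g("G1"), 0.08),
        (g("G2"), 0.05),
        (c(hexnac=3, hex=3), 0.04),
        (g("G0F"), 0.01),
        (g("monoHexNAc"), 0.03),
    )
    hca_mrna = (
        (g("G0F"), 0.16),
        (g("G1F"), 0.15),
        (g("G2F"), 0.14),
        (g("G0"), 0.08),
        (g("G1"), 0.08),
        (g("G2S1F"), 0.08),
        (g("Man5"), 0.07),
        (g("Man6"), 0.05),
        (c(hexnac=3, hex=5), 0.06),
        (c(hexnac=3, hex=5, fuc=1), 0.06),
        (g("monoHexNAc"), 0.07),
    )
    return {
        "hca-n": PlatformPreset("hca-n", hca_n, occupancy=0.491),
        "hca-mrna": PlatformPreset("hca-mrna", hca_mrna, occupancy=0.960),
    }


PRESETS: dict[str, PlatformPreset] = _build_presets()


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    preset: PlatformPreset
    seed: int = 0
    peptide: str = "EEQYNSTYR"
    peptide_start: int = 293
    site: int = 5
    charges: tuple[int, ...] = (2, 3)
    charge_weights: tuple[float, ...] = (0.7, 0.3)
    resolving_power: float = 120000.0  # @ m/z 200, FWHM scaled as 1/sqrt(m/z)
    min_separation_fwhm: float = 2.0
    envelope_peaks: int = 6
    n_repeats: int = 3  # MS2 spectra per glycoform
    n_ms1_scans: int = 8  # deglyco runs
    noise_peaks_ms1: int = 40
    noise_peaks_ms2: int = 60
    noise_intensity: float = 0.01  # noise-peak intensity scale, x base_intensity
    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 2.0
    n_decoys: int = 2
    label_purity: float = 0.97
    base_intensity: float = 1.0e6
    rt_start: float = 60.0
    rt_step: float = 2.0
    ms1_range: tuple[float, float] = (370.0, 2000.0)
    ms2_range: tuple[float, float] = (100.0, 2000.0)

    def __post_init__(self) -> None:
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if len(self.charges) != len(self.charge_weights):
            raise ValueError("charges and charge_weights must be parallel")

    @property
    def peptide_obj(self) -> Peptide:
        return Peptide(self.peptide, start=self.peptide_start, sequon_sites=(self.site,))


def peak_fwhm(mz: float, resolving_power_200: float) -> float:
    """FWHM at *mz* for a resolving power quoted at m/z 200 (orbitrap-like
    1/sqrt(m/z) scaling)."""
    return mz ** 1.5 / (resolving_power_200 * math.sqrt(200.0))


def merge_centroids(
    mz: np.ndarray,
    intensity: np.ndarray,
    resolving_power_200: float,
    min_separation_fwhm: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks the centroider cannot separate.

    Peaks whose gap to the previous peak is below
    ``min_separation_fwhm * FWHM`` coalesce into one intensity-weighted
    centroid with summed height.
    """
    order = np.argsort(mz, kind="stable")
    mz, intensity = np.asarray(mz, float)[order], np.asarray(intensity, float)[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    i = 0
    n = len(mz)
    while i < n:
        j = i + 1
        while j < n and mz[j] - mz[j - 1] < min_separation_fwhm * peak_fwhm(
            mz[j - 1], resolving_power_200
        ):
            j += 1
        w = intensity[i:j]
        out_mz.append(float(np.average(mz[i:j], weights=w)) if w.sum() > 0 else float(mz[i]))
        out_int.append(float(w.sum()))
        i = j
    return np.asarray(out_mz), np.asarray(out_int)


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _jitter(rng: np.random.Generator, mz: float, ppm_sigma: float) -> float:
    if ppm_sigma <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)


def _noise_peaks(
    rng: np.random.Generator, n: int, mz_range: tuple[float, float], scale: float
) -> tuple[np.ndarray, np.ndarray]:
    if n <= 0 or scale <= 0:
        return np.empty(0), np.empty(0)
    mz = rng.uniform(mz_range[0], mz_range[1], size=n)
    inten = rng.exponential(scale, size=n)
    return mz, inten


def _finalize(
    mz: list[float],
    inten: list[float],
    rng: np.random.Generator,
    cfg: SynthConfig,
    ms_level: int,
) -> tuple[np.ndarray, np.ndarray]:
    mz_arr = np.asarray(mz, float)
    int_arr = np.asarray(inten, float)
    if ms_level == 1:
        mz_arr, int_arr = merge_centroids(
            mz_arr, int_arr, cfg.resolving_power, cfg.min_separation_fwhm
        )
        nmz, nint = _noise_peaks(
            rng, cfg.noise_peaks_ms1, cfg.ms1_range, cfg.noise_intensity * cfg.base_intensity
        )
    else:
        # MS2 fragments are kept at their exact jittered positions; only
        # coincident duplicates collapse.
        mz_arr, int_arr = merge_centroids(mz_arr, int_arr, 1e12, 1.0)
        nmz, nint = _noise_peaks(
            rng, cfg.noise_peaks_ms2, cfg.ms2_range, cfg.noise_intensity * cfg.base_intensity
        )
    mz_arr = np.concatenate([mz_arr, nmz])
    int_arr = np.concatenate([int_arr, nint])
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # drop pathological exact ties introduced by noise draws
    keep = np.concatenate([[True], np.diff(mz_arr) > 1e-9])
    return mz_arr[keep], int_arr[keep]


def _envelope_rows(
    mono_mz: float,
    envelope: np.ndarray,
    height: float,
    charge: int,
    rng: np.random.Generator,
    cfg: SynthConfig,
) -> tuple[list[float], list[float]]:
    mzs, ints = [], []
    for k, rel in enumerate(envelope):
        if rel * height <= 0:
            continue
        mzs.append(_jitter(rng, mono_mz + k * NEUTRON / charge, cfg.mz_jitter_ppm))
        ints.append(rel * height)
    return mzs, ints


_FRAGMENT_SCALE = {"B": 0.30, "Y": 0.10, "b": 0.05, "y": 0.05}


def generate_glyco_run(config: SynthConfig) -> tuple[Run, pd.DataFrame]:
    """Generate a glycopeptide search run and its ground-truth table.

    Each glycoform yields ``n_repeats`` MS1+MS2 scan pairs; MS1 envelope
    heights carry the preset weight (times log-normal noise), so profiling
    the run recovers the preset profile. Decoy events are bare-peptide
    MS1+MS2 pairs with no carbohydrate signal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pep = cfg.peptide_obj
    scans: list[Spectrum] = []
    truth_rows = []
    scan_no = 0

    def next_id(level: int) -> str:
        nonlocal scan_no
        scan_no += 1
        return f"scan={scan_no:04d}"

    def rt() -> float:
        return cfg.rt_start + len(scans) * cfg.rt_step

    events: list[tuple[GlycanComposition | None, float]] = []
    for comp, w in cfg.preset.weights:
        events += [(comp, w)] * cfg.n_repeats
    events += [(None, 0.0)] * cfg.n_decoys

    for comp, weight in events:
        gp = Glycopeptide(pep, cfg.site, comp) if comp is not None else Glycopeptide(pep, None)
        envelope = isotope_envelope(gp if comp is not None else pep, cfg.envelope_peaks)
        # --- MS1 scan
        mzs: list[float] = []
        ints: list[float] = []
        height_scale = weight if comp is not None else 0.2
        for z, cw in zip(cfg.charges, cfg.charge_weights):
            mono = glycopeptide_mz(gp, z) if comp is not None else peptide_mz(pep, z)
            h = cfg.base_intensity * height_scale * cw * _lognormal(rng, cfg.intensity_cv)
            m, i = _envelope_rows(mono, envelope, h, z, rng, cfg)
            mzs += m
            ints += i
        ms1_rt = rt()
        mz_arr, int_arr = _finalize(mzs, ints, rng, cfg, ms_level=1)
        scans.append(Spectrum(next_id(1), 1, mz_arr, int_arr, rt=ms1_rt))

        # --- MS2 scan
        zi = int(rng.choice(len(cfg.charges), p=np.asarray(cfg.charge_weights)))
        z = cfg.charges[zi]
        prec_mz = glycopeptide_mz(gp, z) if comp is not None else peptide_mz(pep, z)
        mzs, ints = [], []
        for frag in theoretical_fragments(gp, charges=(1, 2)):
            scale = _FRAGMENT_SCALE[frag.series]
            if frag.series in ("b", "y") and not frag.remnant.is_empty:
                scale = 0.03
            mzs.append(_jitter(rng, frag.mz, cfg.mz_jitter_ppm))
            ints.append(cfg.base_intensity * scale * _lognormal(rng, cfg.intensity_cv))
        ms2_rt = rt()
        mz_arr, int_arr = _finalize(mzs, ints, rng, cfg, ms_level=2)
        sid = next_id(2)
        scans.append(
            Spectrum(
                sid, 2, mz_arr, int_arr,
                precursor_mz=_jitter(rng, prec_mz, cfg.mz_jitter_ppm),
                precursor_charge=z,
                rt=ms2_rt,
            )
        )
        truth_rows.append(
            {
                "scan_id": sid,
                "peptide": pep.sequence,
                "protein_site": pep.start + cfg.site - 1 if comp is not None else -1,
                "composition": str(comp) if comp is not None else "none",
                "weight": weight,
                "charge": z,
                "is_decoy": comp is None,
            }
        )

    run = Run(
        scans,
        metadata={
            "preset": cfg.preset.name,
            "true_occupancy": cfg.preset.occupancy,
            "seed": cfg.seed,
        },
    )
    return run, pd.DataFrame(truth_rows)


def generate_deglyco_run(config: SynthConfig) -> tuple[Run, float]:
    """Generate an MS1-only 18O PNGase-F run at the preset occupancy.

    Each scan mixes three species of the target peptide: unlabeled Asn form
    (fraction 1-theta), Asp+18O (theta x purity, +2.98826 Da) and the
    light-water leakage Asp form (theta x (1-purity), +0.98402 Da).
    """
    cfg = config
    theta = cfg.preset.occupancy
    rng = np.random.default_rng(cfg.seed)
    pep = cfg.peptide_obj
    consts = DEFAULT_CONSTANTS
    neutral = peptide_mass(pep)
    env_asn = isotope_envelope(pep, cfg.envelope_peaks)
    env_asp = isotope_envelope(
        pep.with_mods(((cfg.site, "deamidation"),)), cfg.envelope_peaks
    )
    shift_label = consts.modifications["deamidation_18O"]
    shift_deam = consts.modifications["deamidation"]

    scans: list[Spectrum] = []
    for s in range(cfg.n_ms1_scans):
        mzs: list[float] = []
        ints: list[float] = []
        for z, cw in zip(cfg.charges, cfg.charge_weights):
            base = cfg.base_intensity * cw
            species = (
                (0.0, env_asn, base * (1.0 - theta)),
                (shift_label, env_asp, base * theta * cfg.label_purity),
                (shift_deam, env_asp, base * theta * (1.0 - cfg.label_purity)),
            )
            for shift, env, height in species:
                if height <= 0:
                    continue
                mono = (neutral + shift + z * consts.proton) / z
                m, i = _envelope_rows(
                    mono, env, height * _lognormal(rng, cfg.intensity_cv), z, rng, cfg
                )
                mzs += m
                ints += i
        mz_arr, int_arr = _finalize(mzs, ints, rng, cfg, ms_level=1)
        scans.append(
            Spectrum(
                f"scan={s + 1:04d}", 1, mz_arr, int_arr,
                rt=cfg.rt_start + s * cfg.rt_step,
            )
        )
    run = Run(
        scans,
        metadata={"preset": cfg.preset.name, "true_occupancy": theta, "seed": cfg.seed},
    )
    return run, theta


# ---------------------------------------------------------------------------
# synthetic protein fixtures

_HC_BLOCK = "ASTLVGPKSEQALGVTFSDR"
_LC_BLOCK = "GSVDTALQKPEAVLGSTFKR"


def synthetic_heavy_chain() -> str:
    """Synthetic 450-residue heavy-chain stand-in (documented placeholder).

    The real heavy-chain sequence is not published; this placeholder keeps
    exactly what the pipeline exercises: the universal IgG1 CH2 tryptic
    context EEQYNSTYR at positions 293-301 (sequon N297) and a second sequon
    at N71, embedded in a repeating glycine-free scaffold with regular
    Glu-C/trypsin sites and no other Asn.
    """
    seq = list((_HC_BLOCK * 23)[:450])
    seq[70:73] = "NGS"  # sequon at N71
    seq[291] = "K"  # tryptic site ahead of the CH2 context
    seq[292:301] = "EEQYNSTYR"  # sequon at N297
    return "".join(seq)


def synthetic_light_chain() -> str:
    """Synthetic 214-residue light-chain stand-in with no sequon."""
    return (_LC_BLOCK * 11)[:214]


def default_proteins() -> list[tuple[str, str]]:
    return [
        ("synthetic_heavy_chain (placeholder scaffold; CH2 context at 293-301)",
         synthetic_heavy_chain()),
        ("synthetic_light_chain (placeholder scaffold; no sequon)",
         synthetic_light_chain()),
    ]
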