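"""Isotope envelopes, glycoform profiling and 18O occupancy quantification."""

import dataclasses

import numpy as np
import pytest

from fcglycoscope.chem import DEFAULT_CONSTANTS, GlycanComposition, Glycopeptide, Peptide, peptide_composition, peptide_mass
from fcglycoscope.gpsm import search
from fcglycoscope.quant import (
    _ELEMENT_ISOTOPES,
    glycoform_profile,
    isotope_envelope,
    occupancy_18O,
)
from fcglycoscope.spectra import Run, Spectrum
from fcglycoscope.synth import PRESETS, PlatformPreset, SynthConfig, generate_deglyco_run

PEP = Peptide("EEQYNSTYR", start=293, sequon_sites=(5,))


def naive_envelope(comp, n):
    """Independent oracle: atom-by-atom sequential convolution in pure Python."""
    dist = [1.0]
    for el, count in comp.items():
        iso = list(_ELEMENT_ISOTOPES[el])
        for _ in range(count):
            out = [0.0] * min(n, len(dist) + len(iso) - 1)
            for i, a in enumerate(dist):
                for j, b in enumerate(iso):
                    if i + j < len(out):
                        out[i + j] += a * b
            dist = out
    m = max(dist)
    return [x / m for x in dist]


class TestIsotopeEnvelope:
    def test_glycine_m1_ratio(self):
        env = isotope_envelope("G", n_peaks=3)
        assert env[1] / env[0] == pytest.approx(0.025, abs=0.005)

    def test_single_peak(self):
        assert list(isotope_envelope("G", n_peaks=1)) == [1.0]

    def test_against_polynomial_oracle(self):
        comp = peptide_composition("EEQYNSTYR")
        env = isotope_envelope("EEQYNSTYR", n_peaks=5)
        oracle = naive_envelope(comp, 5)
        assert np.allclose(env, oracle, atol=1e-3)
        assert env[3] / env[0] == pytest.approx(oracle[3] / oracle[0], abs=1e-3)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            isotope_envelope("AZ")

    def test_n_peaks_validation(self):
        with pytest.raises(ValueError):
            isotope_envelope("G", n_peaks=0)


def _ms1_with(heights, charges=(2,), constants=DEFAULT_CONSTANTS):
    """Build MS1 scans holding unlabeled / labeled monoisotopic peaks only."""
    neutral = peptide_mass(PEP)
    shift = constants.modifications["deamidation_18O"]
    peaks = []
    for z in charges:
        if heights.get("un", 0) > 0:
            peaks.append(((neutral + z * constants.proton) / z, heights["un"]))
        if heights.get("lab", 0) > 0:
            peaks.append(((neutral + shift + z * constants.proton) / z, heights["lab"]))
    peaks.sort()
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return Run([Spectrum("s1", 1, mz, inten)])


class TestOccupancy:
    def test_symmetric_heights_give_half(self):
        res = occupancy_18O(_ms1_with({"un": 100.0, "lab": 100.0}), PEP, correct_isotope=False)
        assert res.occupied == pytest.approx(0.5)

    def test_all_labeled_gives_one(self):
        res = occupancy_18O(_ms1_with({"lab": 50.0}), PEP, correct_isotope=False)
        assert res.occupied == pytest.approx(1.0)

    def test_no_peaks_not_quantifiable(self):
        res = occupancy_18O(_ms1_with({}), PEP)
        assert not res.quantifiable
        assert res.occupied is None

    def test_intensity_scaling_invariance(self):
        run, _ = generate_deglyco_run(SynthConfig(preset=PRESETS["hca-n"], seed=5))
        r1 = occupancy_18O(run, PEP)
        scaled = Run(
            [
                Spectrum(s.scan_id, 1, s.mz, s.intensity * 777.0, rt=s.rt)
                for s in run.spectra
            ]
        )
        r2 = occupancy_18O(scaled, PEP)
        assert r1.occupied == pytest.approx(r2.occupied, abs=1e-12)

    def test_isotope_interference_correction(self):
        """At true occupancy 0 the corrected estimate is ~0; switching the
        correction off strictly inflates it (the unlabeled M+3 leaks into
        the labeled window)."""
        preset = PlatformPreset("zero", PRESETS["hca-n"].weights, occupancy=0.0)
        run, _ = generate_deglyco_run(SynthConfig(preset=preset, seed=2))
        # 25 ppm window: wide enough that the merged M+3 centroid is seen
        on = occupancy_18O(run, PEP, tol_ppm=25.0, correct_isotope=True)
        off = occupancy_18O(run, PEP, tol_ppm=25.0, correct_isotope=False)
        assert on.occupied <= 0.01
        assert off.occupied > on.occupied

    @pytest.mark.parametrize("theta", [0.1, 0.25, 0.491, 0.75, 0.96])
    def test_parameter_recovery_curve(self, theta):
        """Absolute bias of the mean estimate <= 0.02 at default noise."""
        preset = PlatformPreset("x", PRESETS["hca-n"].weights, occupancy=theta)
        ests = []
        for seed in range(1, 9):
            run, _ = generate_deglyco_run(SynthConfig(preset=preset, seed=seed))
            ests.append(occupancy_18O(run, PEP).occupied)
        assert abs(float(np.mean(ests)) - theta) <= 0.02


class TestProfile:
    def test_single_composition_fraction_one(self, noiseless_run_truth, proteins, library):
        run, truth = noiseless_run_truth
        gpsms = [g for g in search(run, proteins, library) if g.glycopeptide.site]
        g0 = [g for g in gpsms if str(g.glycopeptide.glycan) == "HexNAc4Hex3"]
        prof = glycoform_profile(g0, run)
        assert prof.n_glycoforms == 1
        assert list(prof.fractions.values()) == [1.0]

    def test_fractions_sum_to_one(self, mrna_run_truth, mrna_gpsms):
        run, _ = mrna_run_truth
        prof = glycoform_profile([g for g in mrna_gpsms if g.glycopeptide.site], run)
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_recovers_generator_weights(self, mrna_run_truth, mrna_gpsms):
        """Recovered fractions within +-0.05 of the generating weights."""
        run, _ = mrna_run_truth
        prof = glycoform_profile([g for g in mrna_gpsms if g.glycopeptide.site], run)
        weights = {c: w for c, w in PRESETS["hca-mrna"].weights}
        assert set(prof.fractions) == set(weights)
        for comp, frac in prof.fractions.items():
            assert frac == pytest.approx(weights[comp], abs=0.05)

    def test_removal_renormalizes_proportionally(self, mrna_run_truth, mrna_gpsms):
        run, _ = mrna_run_truth
        glyco = [g for g in mrna_gpsms if g.glycopeptide.site]
        full = glycoform_profile(glyco, run)
        drop = next(iter(full.fractions))
        reduced = glycoform_profile(
            [g for g in glyco if g.glycopeptide.glycan != drop], run
        )
        scale = 1.0 - full.fractions[drop]
        for comp, frac in reduced.fractions.items():
            assert frac == pytest.approx(full.fractions[comp] / scale, rel=1e-6)

    def test_empty_gpsm_list_no_crash(self, mrna_run_truth):
        run, _ = mrna_run_truth
        prof = glycoform_profile([], run)
        assert prof.fractions == {}
        assert prof.n_glycoforms == 0

    def test_mixed_sites_rejected(self, mrna_gpsms):
        from fcglycoscope.gpsm import GPSM

        other_pep = Peptide("NGTK", start=71, sequon_sites=(1,))
        alien = GPSM(
            scan_id="alien",
            glycopeptide=Glycopeptide(other_pep, 1, GlycanComposition(hexnac=2, hex=3)),
            score=50.0, precursor_mz=None, precursor_charge=None,
            precursor_ppm=None, matched_fragments=(), site_localized=False,
        )
        with pytest.raises(ValueError, match="sites"):
            glycoform_profile([g for g in mrna_gpsms if g.glycopeptide.site] + [alien], Run([]))
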