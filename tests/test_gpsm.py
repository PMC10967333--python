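"""Candidate generation, fragment prediction, scoring and search."""

import dataclasses

import numpy as np
import pytest

from fcglycoscope.chem import GlycanComposition, Glycopeptide, Peptide
from fcglycoscope.glycans import default_library
from fcglycoscope.gpsm import (
    SearchConfig,
    expand_variable_mods,
    generate_candidates,
    score_gpsm,
    search,
    theoretical_fragments,
    y_remnant_path,
)
from fcglycoscope.spectra import Run, Spectrum
from fcglycoscope.synth import PRESETS, SynthConfig, default_proteins, generate_glyco_run

PEP = Peptide("EEQYNSTYR", start=293, sequon_sites=(5,))
G0 = GlycanComposition(hexnac=4, hex=3)


def synthetic_ms2(gp, charge=2, intensity=100.0):
    from fcglycoscope.chem import glycopeptide_mz

    frags = theoretical_fragments(gp, charges=(1, 2))
    mz = np.asarray(sorted({round(f.mz, 6) for f in frags}))
    return Spectrum(
        "s", 2, mz, np.full(len(mz), intensity),
        precursor_mz=glycopeptide_mz(gp, charge), precursor_charge=charge,
    )


class TestCandidates:
    def test_reference_precursor_yields_g0_candidate(self, library):
        cands = generate_candidates(1244.4976, 2, [PEP], library)
        assert any(
            c.glycan == G0 and c.site == 5 and c.peptide.sequence == "EEQYNSTYR"
            for c in cands
        )

    def test_bare_peptide_candidate(self, library):
        cands = generate_candidates(595.2596, 2, [PEP], library)
        assert len(cands) == 1
        assert cands[0].site is None and cands[0].glycan.is_empty

    def test_far_precursor_empty(self, library):
        assert generate_candidates(700.0, 2, [PEP], library) == []

    def test_peptide_without_sequon_only_bare(self, library):
        pep = Peptide("LVTK")
        cands = generate_candidates(460.3130, 1, [pep], library, tol_ppm=50)
        assert all(c.glycan.is_empty for c in cands)


class TestFragments:
    def test_y5_plus_hexnac_present(self):
        gp = Glycopeptide(PEP, 5, G0)
        labels = {f.label for f in theoretical_fragments(gp)}
        assert "y5+HexNAc1" in labels
        assert "b5+HexNAc1" in labels

    def test_y0_is_bare_peptide(self):
        gp = Glycopeptide(PEP, 5, G0)
        y0 = [f for f in theoretical_fragments(gp) if f.series == "Y" and f.index == 0 and f.charge == 1]
        assert y0[0].mz == pytest.approx(1189.5120, abs=5e-4)

    def test_single_residue_no_backbone_ions(self):
        frags = theoretical_fragments(Glycopeptide(Peptide("N", sequon_sites=()), None))
        assert not [f for f in frags if f.series in ("b", "y")]

    def test_remnant_path_truncation(self):
        path = y_remnant_path(GlycanComposition(hexnac=4, hex=5, fuc=1, neuac=1), depth=8)
        assert len(path) == 8
        # chitobiose core first
        assert path[0] == GlycanComposition(hexnac=1)
        assert path[1] == GlycanComposition(hexnac=2)
        assert path[2] == GlycanComposition(hexnac=2, hex=1)


class TestScoring:
    def test_true_match_scores_high_and_localizes(self):
        gp = Glycopeptide(PEP, 5, G0)
        g = score_gpsm(synthetic_ms2(gp), gp)
        assert g.score >= 90
        assert g.site_localized

    def test_wrong_glycan_scores_lower(self):
        gp = Glycopeptide(PEP, 5, G0)
        spec = synthetic_ms2(gp)
        wrong = Glycopeptide(PEP, 5, GlycanComposition(hexnac=4, hex=4))
        assert score_gpsm(spec, wrong).score < score_gpsm(spec, gp).score

    def test_empty_spectrum_scores_zero(self):
        gp = Glycopeptide(PEP, 5, G0)
        empty = Spectrum("s", 2, np.array([]), np.array([]), precursor_mz=1244.5, precursor_charge=2)
        assert score_gpsm(empty, gp).score == 0.0

    def test_score_invariant_to_intensity_rescaling(self):
        gp = Glycopeptide(PEP, 5, G0)
        s1 = synthetic_ms2(gp, intensity=10.0)
        s2 = Spectrum("s", 2, s1.mz, s1.intensity * 1234.5, precursor_mz=s1.precursor_mz, precursor_charge=2)
        assert score_gpsm(s1, gp).score == score_gpsm(s2, gp).score

    def test_matched_fragments_reverify(self, mrna_gpsms):
        """Every reported matched fragment re-verifies within tolerance."""
        for g in mrna_gpsms:
            for frag, obs_mz, _inten in g.matched_fragments:
                assert abs(obs_mz - frag.mz) / frag.mz * 1e6 <= 20.0


class TestSearch:
    def test_noiseless_identification_is_perfect(self, noiseless_run_truth, proteins, library):
        run, truth = noiseless_run_truth
        gpsms = search(run, proteins, library)
        truth_map = {r["scan_id"]: r["composition"] for _i, r in truth.iterrows()}
        assert len(gpsms) == len(truth)
        for g in gpsms:
            assert str(g.glycopeptide.glycan) == truth_map[g.scan_id]
            assert g.glycopeptide.protein_site == 297

    def test_default_noise_identification_above_95(self, mrna_run_truth, mrna_gpsms):
        _run, truth = mrna_run_truth
        truth_map = {
            r["scan_id"]: r["composition"] for _i, r in truth.iterrows() if not r["is_decoy"]
        }
        correct = sum(
            1 for g in mrna_gpsms if str(g.glycopeptide.glycan) == truth_map.get(g.scan_id)
        )
        assert correct / len(truth_map) >= 0.95

    def test_peptide_only_run_gives_no_gpsms(self, proteins, library):
        cfg = dataclasses.replace(
            SynthConfig(preset=PRESETS["hca-n"], seed=3),
            n_repeats=0, n_decoys=4,
        )
        run, truth = generate_glyco_run(cfg)
        assert truth["is_decoy"].all()
        assert search(run, proteins, library) == []

    def test_precursor_error_within_tolerance(self, mrna_gpsms):
        assert all(abs(g.precursor_ppm) <= 10.0 for g in mrna_gpsms)

    def test_ambiguous_site_tie_break_deterministic(self, library):
        """Two sequons with identical backbone evidence: the documented
        tie-break (smaller site) is chosen, stably across reruns."""
        pep = Peptide("NGSNGTK", sequon_sites=(1, 4))
        comp = GlycanComposition(hexnac=2, hex=3)
        gp = Glycopeptide(pep, 1, comp)
        spec = synthetic_ms2(gp)
        a = score_gpsm(spec, gp)
        b = score_gpsm(spec, Glycopeptide(pep, 4, comp))
        assert a.score >= b.score  # site-1 evidence includes the early glyco-b ions
        cands = generate_candidates(spec.precursor_mz, 2, [pep], library)
        assert {c.site for c in cands if not c.glycan.is_empty} == {1, 4}

    def test_search_is_deterministic(self, mrna_run_truth, proteins, library):
        run, _ = mrna_run_truth
        r1 = search(run, proteins, library)
        r2 = search(run, proteins, library)
        assert [(g.scan_id, str(g.glycopeptide.glycan), g.score) for g in r1] == [
            (g.scan_id, str(g.glycopeptide.glycan), g.score) for g in r2
        ]


def test_expand_variable_mods():
    pep = Peptide("MAMK", start=1)
    variants = expand_variable_mods([pep], max_oxidations=2)
    mod_sets = {v.mods for v in variants}
    assert () in mod_sets
    assert ((1, "oxidation"),) in mod_sets
    assert ((1, "oxidation"), (3, "oxidation")) in mod_sets
    assert ((1, "acetyl"),) in mod_sets  # protein N-terminus
    internal = Peptide("MAMK", start=50)
    assert all(
        "acetyl" not in {n for _p, n in v.mods} for v in expand_variable_mods([internal])
    )
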