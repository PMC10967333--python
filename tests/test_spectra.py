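"""Spectrum containers, MGF round-tripping and ppm peak matching."""

import numpy as np
import pytest

from fcglycoscope.spectra import MGFError, Run, Spectrum, match_peak, read_mgf, write_mgf


def random_run(rng, n_spectra):
    spectra = []
    for i in range(n_spectra):
        n = rng.integers(1, 40)
        mz = np.sort(rng.uniform(100, 2000, n))
        mz = mz[np.concatenate([[True], np.diff(mz) > 1e-6])]
        inten = rng.uniform(1, 1e6, len(mz))
        ms_level = int(rng.integers(1, 3))
        spectra.append(
            Spectrum(
                f"scan={i}",
                ms_level,
                mz,
                inten,
                precursor_mz=float(rng.uniform(300, 1500)) if ms_level == 2 else None,
                precursor_charge=int(rng.integers(1, 4)) if ms_level == 2 else None,
                rt=float(i),
            )
        )
    return Run(spectra)


def test_mgf_roundtrip_random_runs(tmp_path):
    """Write-then-read preserves structure, peaks to 1e-4 m/z, 0.1% intensity."""
    rng = np.random.default_rng(1)
    run = random_run(rng, 200)
    path = tmp_path / "rt.mgf"
    write_mgf(run, path)
    back = read_mgf(path)
    assert len(back) == len(run)
    for a, b in zip(run.spectra, back.spectra):
        assert a.scan_id == b.scan_id
        assert a.ms_level == b.ms_level
        assert np.allclose(a.mz, b.mz, atol=1e-4)
        assert np.allclose(a.intensity, b.intensity, rtol=1e-3)
        if a.ms_level == 2:
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            assert b.precursor_charge == a.precursor_charge
        assert b.rt == pytest.approx(a.rt, abs=1e-3)


def test_mgf_roundtrip_idempotent(tmp_path):
    rng = np.random.default_rng(2)
    run = random_run(rng, 20)
    p1, p2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
    write_mgf(run, p1)
    write_mgf(read_mgf(p1), p2)
    assert p1.read_text() == p2.read_text()


def test_unknown_headers_preserved(tmp_path):
    run = Run(
        [
            Spectrum(
                "s1", 2, np.array([100.0, 200.0]), np.array([1.0, 2.0]),
                precursor_mz=500.0, precursor_charge=2,
                extra={"custom_tag": "hello"},
            )
        ]
    )
    path = tmp_path / "x.mgf"
    write_mgf(run, path)
    back = read_mgf(path)
    assert back.spectra[0].extra.get("custom_tag") == "hello"


def test_empty_file_empty_run(tmp_path):
    path = tmp_path / "empty.mgf"
    path.write_text("")
    assert len(read_mgf(path)) == 0


def test_missing_pepmass_ms2_is_error(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text("BEGIN IONS\nTITLE=s1\n100.0 1.0\nEND IONS\n")
    with pytest.raises(MGFError, match="PEPMASS"):
        read_mgf(path)


def test_ms1_block_without_pepmass_ok(tmp_path):
    path = tmp_path / "ms1.mgf"
    path.write_text("BEGIN IONS\nTITLE=s1\nMSLEVEL=1\n100.0 1.0\nEND IONS\n")
    run = read_mgf(path)
    assert run.spectra[0].ms_level == 1
    assert run.spectra[0].precursor_mz is None


def test_spectrum_validation():
    with pytest.raises(ValueError, match="increasing"):
        Spectrum("s", 1, np.array([2.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="negative"):
        Spectrum("s", 1, np.array([1.0, 2.0]), np.array([1.0, -1.0]))
    with pytest.raises(ValueError, match="precursor"):
        Spectrum("s", 2, np.array([1.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="duplicate"):
        Run([Spectrum("s", 1, np.array([1.0]), np.array([1.0]))] * 2)


def _spec(mz, inten):
    return Spectrum("s", 1, np.asarray(mz, float), np.asarray(inten, float))


def test_match_peak_boundaries():
    target = 204.0867
    assert match_peak(_spec([target], [1.0]), target, 15.0) is not None
    # just inside / just outside the 15 ppm edge
    assert match_peak(_spec([target * (1 + 14.99e-6)], [1.0]), target, 15.0) is not None
    assert match_peak(_spec([target * (1 + 15.01e-6)], [1.0]), target, 15.0) is None
    # the spec'd boundary case: 204.0898 is ~15.2 ppm high
    assert match_peak(_spec([204.0898], [1.0]), target, 15.0) is None


def test_match_peak_tie_by_intensity_then_ppm():
    target = 500.0
    near, far = 500.001, 499.998
    m = match_peak(_spec(sorted([near, far]), [5.0, 5.0][:: 1]), target, 10.0)
    # equal intensities: smaller |ppm| wins
    assert m.mz == pytest.approx(near)
    m = match_peak(_spec([499.998, 500.001], [9.0, 1.0]), target, 10.0)
    assert m.mz == pytest.approx(499.998)  # more intense wins


def test_match_peak_rescaling_symmetry():
    mz = [400.0, 500.0, 600.0]
    s = _spec(mz, [1.0, 2.0, 3.0])
    m1 = match_peak(s, 500.0005, 5.0)
    s2 = _spec([x * 1.5 for x in mz], [1.0, 2.0, 3.0])
    m2 = match_peak(s2, 500.0005 * 1.5, 5.0)
    assert (m1 is None) == (m2 is None)
    assert m1.index == m2.index


# ---------------------------------------------------------------------------
# mzML subset


def _mzml_doc(spectra, compress=False):
    """Build a minimal mzML document (synthetic fixture) for the reader."""
    import base64
    import struct
    import zlib

    def b64(values):
        raw = struct.pack(f"<{len(values)}d", *values)
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        if compress
        else '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
    )
    blocks = []
    for i, s in enumerate(spectra):
        prec = ""
        if s["ms_level"] == 2:
            prec = f"""<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
            <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s['precursor_mz']}"/>
            <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s['charge']}"/>
            </selectedIon></selectedIonList></precursor></precursorList>"""
        mode = (
            '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
            if s.get("profile")
            else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        )
        blocks.append(f"""<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s['mz'])}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s['ms_level']}"/>
        {mode}
        <scanList count="1"><scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s['rt_min']}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
        </scan></scanList>
        {prec}
        <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="0">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        {comp_cv}
        <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
        <binary>{b64(s['mz'])}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="0">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        {comp_cv}
        <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
        <binary>{b64(s['intensity'])}</binary>
        </binaryDataArray>
        </binaryDataArrayList>
        </spectrum>""")
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0"><run id="r">'
        f'<spectrumList count="{len(blocks)}">{"".join(blocks)}</spectrumList>'
        "</run></mzML>"
    )


@pytest.mark.parametrize("compress", [False, True])
def test_read_mzml_subset(tmp_path, compress):
    from fcglycoscope.spectra import read_mzml

    doc = _mzml_doc(
        [
            {"ms_level": 1, "mz": [100.0, 204.0867, 500.5], "intensity": [10.0, 50.0, 5.0], "rt_min": 1.5},
            {"ms_level": 2, "mz": [204.0867], "intensity": [99.0], "rt_min": 1.6,
             "precursor_mz": 1244.4976, "charge": 2},
        ],
        compress=compress,
    )
    path = tmp_path / "mini.mzML"
    path.write_text(doc)
    run = read_mzml(path)
    assert len(run) == 2
    ms1, ms2_ = run.spectra
    assert ms1.ms_level == 1
    assert np.allclose(ms1.mz, [100.0, 204.0867, 500.5])
    assert ms1.rt == pytest.approx(90.0)  # minutes converted to seconds
    assert ms2_.precursor_mz == pytest.approx(1244.4976)
    assert ms2_.precursor_charge == 2


def test_read_mzml_profile_rejected(tmp_path):
    from fcglycoscope.spectra import read_mzml

    doc = _mzml_doc(
        [{"ms_level": 1, "mz": [100.0], "intensity": [1.0], "rt_min": 0.0, "profile": True}]
    )
    path = tmp_path / "prof.mzML"
    path.write_text(doc)
    with pytest.raises(ValueError, match="profile"):
        read_mzml(path)


def test_mzml_to_mgf_conversion(tmp_path):
    from fcglycoscope.spectra import read_mgf, read_mzml, write_mgf

    doc = _mzml_doc(
        [{"ms_level": 2, "mz": [204.0867, 366.1396], "intensity": [5.0, 2.0],
          "rt_min": 2.0, "precursor_mz": 1244.4976, "charge": 2}]
    )
    src = tmp_path / "conv.mzML"
    src.write_text(doc)
    out = tmp_path / "conv.mgf"
    write_mgf(read_mzml(src), out)
    back = read_mgf(out)
    assert back.spectra[0].precursor_mz == pytest.approx(1244.4976, abs=1e-4)
    assert np.allclose(back.spectra[0].mz, [204.0867, 366.1396], atol=1e-4)
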