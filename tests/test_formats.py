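"""Legacy SAS file formats: .dat, .out, .fit/.fir and PDB round trips."""

import io

import numpy as np
import pytest

from sascifio.formats import (
    Atom,
    AtomicModel,
    FormatError,
    ModelFit,
    ScatteringCurve,
    read_dat,
    read_fitfile,
    read_out,
    read_pdb,
    write_dat,
    write_fitfile,
    write_out,
    write_pdb,
)
from sascifio.synth import SphereTruth, make_bead_model, make_curve, make_distribution, make_fit


@pytest.fixture(scope="module")
def curve():
    return make_curve(SphereTruth(), n_points=50)


@pytest.fixture(scope="module")
def dist(curve):
    return make_distribution(SphereTruth(), curve)


class TestDat:
    def test_metadata_and_points(self):
        c = read_dat("Sample: lysozyme\n0.01 100.0 1.0\n0.02 99.0 1.1\n")
        assert c.metadata == {"Sample": "lysozyme"}
        assert len(c) == 2
        np.testing.assert_allclose(c.err, [1.0, 1.1])

    def test_two_columns_mean_no_errors(self):
        c = read_dat("0.01 100.0\n0.02 99.0\n")
        assert c.err is None

    def test_trailing_text_warns(self):
        with pytest.warns(UserWarning, match="trailing"):
            c = read_dat("0.01 100.0 1.0\nDetector saturated\n")
        assert len(c) == 1

    def test_too_few_columns_rejected(self):
        with pytest.raises(FormatError):
            read_dat("header only\nanother line\n")

    def test_non_monotone_s_rejected(self):
        with pytest.raises(FormatError, match="increasing"):
            read_dat("0.02 1.0 0.1\n0.01 2.0 0.1\n")

    def test_roundtrip(self, curve):
        back = read_dat(write_dat(curve))
        np.testing.assert_allclose(back.s, curve.s, rtol=1e-6)
        np.testing.assert_allclose(back.I, curve.I, rtol=1e-6)
        np.testing.assert_allclose(back.err, curve.err, rtol=1e-6)
        assert back.metadata == curve.metadata

    def test_three_column_contract(self, curve):
        bare = ScatteringCurve(curve.s, curve.I)  # no errors
        rows = [l.split() for l in write_dat(bare).splitlines() if l[:1] != ""]
        data_rows = [r for r in rows if len(r) and r[0][0].isdigit() or
                     (len(r) and r[0].lstrip("+-")[0].isdigit())]
        assert all(len(r) == 3 for r in data_rows)
        two_col = write_dat(bare, three_columns=False)
        assert all(len(l.split()) == 2 for l in two_col.splitlines())

    def test_single_point_curve(self):
        text = write_dat(ScatteringCurve([0.1], [5.0]))
        assert len(text.splitlines()) == 1


class TestOut:
    def test_endpoints_and_parameters(self, dist):
        back = read_out(write_out(dist))
        assert back.r[0] == 0.0
        assert back.r[-1] == pytest.approx(back.Dmax, rel=1e-6)
        assert back.Rg == pytest.approx(dist.Rg, rel=1e-6)
        assert back.I0 == pytest.approx(dist.I0, rel=1e-6)

    def test_row_counts_split_extrapolated(self, dist):
        text = write_out(dist)
        n_exp = int(np.sum(~np.isnan(dist.fit_iexp)))
        n_ext = int(np.sum(np.isnan(dist.fit_iexp)))
        def numeric(parts):
            try:
                [float(p) for p in parts]
                return bool(parts)
            except ValueError:
                return False

        rows = [l.split() for l in text.splitlines()]
        assert sum(1 for r in rows if numeric(r) and len(r) == 5) == n_exp
        assert sum(1 for r in rows if numeric(r) and len(r) == 2) == n_ext
        back = read_out(text)
        assert len(back.fit_s) == n_exp + n_ext

    def test_roundtrip_tables(self, dist):
        back = read_out(write_out(dist))
        np.testing.assert_allclose(back.p, dist.p, rtol=1e-6)
        np.testing.assert_allclose(back.perr, dist.perr, rtol=1e-6)
        np.testing.assert_allclose(back.fit_s, dist.fit_s, rtol=1e-6)
        np.testing.assert_allclose(back.fit_iext, dist.fit_iext, rtol=1e-6)
        exp = ~np.isnan(dist.fit_iexp)
        np.testing.assert_allclose(back.fit_iexp[exp], dist.fit_iexp[exp], rtol=1e-6)
        assert np.isnan(back.fit_iexp[~exp]).all()

    def test_missing_real_space_section_rejected(self, dist):
        text = write_out(dist)
        keep = [l for l in text.splitlines() if len(l.split()) != 3]
        with pytest.raises(FormatError, match="real-space"):
            read_out("\n".join(keep))


class TestFitFiles:
    def test_fir_has_four_columns(self, curve):
        fit = make_fit(SphereTruth(), curve)
        text = write_fitfile(fit, "fir")
        rows = [l.split() for l in text.splitlines() if not l.startswith("#")]
        assert all(len(r) == 4 for r in rows)
        back = read_fitfile(text)
        assert back.err is not None
        np.testing.assert_allclose(back.err, fit.err, rtol=1e-6)

    def test_fit_has_three_columns(self, curve):
        fit = make_fit(SphereTruth(), curve)
        text = write_fitfile(fit, "fit")
        rows = [l.split() for l in text.splitlines() if not l.startswith("#")]
        assert all(len(r) == 3 for r in rows)
        assert read_fitfile(text).err is None

    def test_chi2_header_parsed(self):
        fit = read_fitfile("Chi^2: 1.23\n0.1 1.0 1.1\n0.2 0.9 0.8\n")
        assert fit.chi2_reduced == 1.23

    def test_chi2_emitted_iff_set(self, curve):
        fit = make_fit(SphereTruth(), curve)
        assert "Chi^2" in write_fitfile(fit)
        fit.chi2_reduced = None
        assert "Chi^2" not in write_fitfile(fit)

    def test_roundtrip_with_statistics(self, curve):
        fit = make_fit(SphereTruth(), curve)
        fit.cormap_p = 0.31
        back = read_fitfile(write_fitfile(fit, "fit"), "fit")
        np.testing.assert_allclose(back.Ifit, fit.Ifit, rtol=1e-6)
        assert back.chi2_reduced == pytest.approx(fit.chi2_reduced, rel=1e-6)
        assert back.cormap_p == pytest.approx(0.31)

    def test_dialect_mismatch_rejected(self):
        with pytest.raises(FormatError, match="dialect"):
            read_fitfile("0.1 1.0 1.1\n", "fir")
        with pytest.raises(FormatError, match="column"):
            read_fitfile("0.1 1 2 3\n0.2 1 2\n")


class TestPdb:
    def test_single_atom_coordinates(self):
        line = ("ATOM      1  CA  DUM A   1       1.000   2.000   3.000"
                "  1.00 20.00           C")
        model = read_pdb(line)
        assert len(model) == 1
        a = model.atoms[0]
        assert (a.x, a.y, a.z) == (1.0, 2.0, 3.0)
        assert a.res_name == "DUM" and a.chain_id == "A"

    def test_roundtrip_to_three_decimals(self):
        truth = SphereTruth()
        model = make_bead_model(truth, n_beads=50)
        back = read_pdb(write_pdb(model))
        assert len(back) == 50
        np.testing.assert_allclose(back.coordinates(), model.coordinates(),
                                   atol=5e-4)
        assert all(a.res_name == "DUM" for a in back.atoms)

    def test_other_records_ignored(self):
        text = ("HEADER    SYNTHETIC\nREMARK   1\n"
                "ATOM      1  CA  DUM A   1       0.000   0.000   0.000\nEND\n")
        assert len(read_pdb(text)) == 1

    def test_bad_coordinate_names_line(self):
        text = "ATOM      1  CA  DUM A   1       x.000   0.000   0.000"
        with pytest.raises(FormatError, match="line 1"):
            read_pdb(text)

    def test_biotite_reads_our_output(self):
        """Independent PDB oracle: biotite parses identical coordinates."""
        pdb = pytest.importorskip("biotite.structure.io.pdb")
        model = make_bead_model(SphereTruth(), n_beads=30)
        pdb_file = pdb.PDBFile.read(io.StringIO(write_pdb(model)))
        coords = pdb_file.get_structure(model=1).coord
        np.testing.assert_allclose(coords, model.coordinates(), atol=5e-4)
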