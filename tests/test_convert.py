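"""Converters: insert/extract round trips, re-binning, conflict policy."""

import numpy as np
import pytest

from sascifio.cif import CifFile, parse_cif, write_cif
from sascifio.convert import (
    ConflictError,
    ConversionContext,
    cif2all,
    cif2dat,
    cif2fit,
    cif2out,
    cif2pdb,
    cif2sub,
    collect,
    dat2cif,
    fit2cif,
    out2cif,
    pdb2cif,
    read_flat_config,
    rebin_to_grid,
)
from sascifio.formats import (
    ModelFit,
    ScatteringCurve,
    read_dat,
    read_fitfile,
    read_out,
    read_pdb,
)
from sascifio.model import EntryError, validate
from sascifio.synth import (
    SphereTruth,
    generate_entry,
    make_bead_model,
    make_curve,
    make_distribution,
    make_fit,
    sphere_intensity,
)


@pytest.fixture()
def curve():
    return make_curve(SphereTruth(), n_points=60)


@pytest.fixture()
def filled(curve):
    """CifFile with curve, distribution, one model and one fit."""
    truth = SphereTruth()
    file = CifFile()
    dat2cif(curve, file)
    out2cif(make_distribution(truth, curve), file)
    pdb2cif(make_bead_model(truth, n_beads=40), file)
    fit2cif(make_fit(truth, curve), file)
    return file


class TestDatConverters:
    def test_two_point_curve_makes_two_rows(self):
        file = dat2cif(ScatteringCurve([0.01, 0.02], [10.0, 9.0]), CifFile())
        assert file.blocks[0]["sas_scan_intensity"].n_rows == 2

    def test_metadata_routes_to_sample_category(self):
        c = ScatteringCurve([0.01, 0.02], [1.0, 0.9],
                            metadata={"Concentration": "4.0"})
        file = dat2cif(c, CifFile())
        assert file.blocks[0]["sas_sample"].scalar("specimen_concentration") == "4.0"

    def test_momentum_transfer_range_items(self, curve):
        file = dat2cif(curve, CifFile())
        scan = file.blocks[0]["sas_scan"]
        assert float(scan.scalar("momentum_transfer_min")) == pytest.approx(
            curve.s[0], rel=1e-6)
        assert float(scan.scalar("momentum_transfer_max")) == pytest.approx(
            curve.s[-1], rel=1e-6)

    def test_roundtrip(self, curve):
        (back,) = cif2dat(dat2cif(curve, CifFile()))
        np.testing.assert_allclose(back.s, curve.s, rtol=1e-6)
        np.testing.assert_allclose(back.I, curve.I, rtol=1e-6)
        np.testing.assert_allclose(back.err, curve.err, rtol=1e-6)
        assert back.metadata == curve.metadata

    def test_two_main_blocks_give_two_curves(self, curve):
        file = dat2cif(curve, CifFile())
        c2 = ScatteringCurve([0.05, 0.06], [4.0, 3.0])
        dat2cif(c2, file, ConversionContext(block="MAIN2"))
        curves = cif2dat(file)
        assert len(curves) == 2

    def test_placeholder_errors_mean_absent(self, curve):
        bare = ScatteringCurve(curve.s, curve.I)
        (back,) = cif2dat(dat2cif(bare, CifFile()))
        assert back.err is None

    def test_conflict_policy(self, curve):
        file = dat2cif(curve, CifFile())
        with pytest.raises(ConflictError):
            dat2cif(curve, file)
        again = dat2cif(curve, file, ConversionContext(overwrite="replace"))
        assert write_cif(again) == write_cif(dat2cif(curve, CifFile()))

    def test_empty_file_warns(self):
        with pytest.warns(UserWarning):
            assert cif2dat(CifFile()) == []


class TestRebin:
    def test_identity_grid(self):
        s = np.linspace(0.0, 1.0, 11)
        I = np.cos(s)
        np.testing.assert_array_equal(rebin_to_grid(s, I, s), I)

    def test_exact_on_affine(self):
        src = np.linspace(0.0, 2.0, 9)
        dst = np.sort(np.random.default_rng(0).uniform(0.0, 2.0, 25))
        I = 3.5 * src - 1.25
        np.testing.assert_allclose(rebin_to_grid(src, I, dst), 3.5 * dst - 1.25,
                                   rtol=0, atol=1e-14)

    def test_outside_range_marked_absent(self):
        out = rebin_to_grid([1.0, 2.0], [1.0, 2.0], [0.5, 1.5, 2.5])
        assert np.isnan(out[0]) and np.isnan(out[2]) and out[1] == 1.5

    def test_too_few_source_points(self):
        with pytest.raises(ValueError, match="two source"):
            rebin_to_grid([1.0], [1.0], [1.0])

    def test_sphere_coarse_grid_within_half_percent(self):
        """Re-binned regularized curve vs direct analytic evaluation.

        The sphere intensity crosses zero inside the fitted range, so the
        deviation is normalized by the curve scale I(0) — a pointwise
        relative bound is singular at the zeros for any interpolant.
        """
        truth = SphereTruth()
        fine = np.linspace(0.01, 0.30, 200)
        coarse = fine[::2]
        rebinned = rebin_to_grid(coarse,
                                 sphere_intensity(truth.R, truth.I0, coarse),
                                 fine)
        direct = sphere_intensity(truth.R, truth.I0, fine)
        ok = ~np.isnan(rebinned)
        assert np.abs(rebinned[ok] - direct[ok]).max() / truth.I0 < 0.005

    def test_subset_destination_is_exact(self):
        """Source spacing ≤ destination spacing: dst nodes hit src nodes."""
        truth = SphereTruth()
        fine = np.linspace(0.01, 0.30, 200)
        coarse = fine[::2]
        rebinned = rebin_to_grid(fine,
                                 sphere_intensity(truth.R, truth.I0, fine),
                                 coarse)
        np.testing.assert_array_equal(
            rebinned, sphere_intensity(truth.R, truth.I0, coarse))


class TestOutConverters:
    def test_three_categories_written(self, curve):
        file = out2cif(make_distribution(SphereTruth(), curve), CifFile())
        block = file.blocks[0]
        for name in ("sas_p_of_r", "sas_p_of_r_extrapolated_intensity",
                     "sas_p_of_r_details"):
            assert block.get(name) is not None

    def test_row_count_and_dmax_preserved(self, curve):
        dist = make_distribution(SphereTruth(), curve)
        file = out2cif(dist, CifFile())
        block = file.blocks[0]
        assert block["sas_p_of_r"].n_rows == len(dist.r)
        assert float(block["sas_p_of_r_details"].scalar("dmax")) == pytest.approx(
            dist.Dmax, rel=1e-6)

    def test_reconstruction_matches_experimental_grid(self, curve):
        dist = make_distribution(SphereTruth(), curve)
        file = dat2cif(curve, CifFile())
        out2cif(dist, file)
        back = cif2out(file)
        exp = back.experimental
        np.testing.assert_allclose(back.fit_s[exp], curve.s, rtol=1e-6)
        np.testing.assert_allclose(back.p, dist.p, rtol=1e-6)

    def test_coarse_stored_fit_covers_every_experimental_point(self, curve):
        dist = make_distribution(SphereTruth(), curve, rebin_factor=2)
        file = dat2cif(curve, CifFile())
        out2cif(dist, file)
        back = cif2out(file)
        exp = back.experimental
        in_overlap = curve.s <= dist.fit_s[-1] + 1e-12
        assert exp.sum() == in_overlap.sum()
        assert not np.isnan(back.fit_ireg[exp]).any()

    def test_absent_distribution_rejected(self, curve):
        with pytest.raises(EntryError, match="sas_p_of_R"):
            cif2out(dat2cif(curve, CifFile()))


class TestModelConverters:
    def test_one_atom_roundtrip(self):
        model = read_pdb(
            "ATOM      1  CA  DUM A   1       1.000   2.000   3.000"
            "  1.00 20.00           C")
        file = pdb2cif(model, CifFile())
        (text,) = cif2pdb(file)
        back = read_pdb(text)
        np.testing.assert_allclose(back.coordinates(), [[1.0, 2.0, 3.0]],
                                   atol=5e-4)

    def test_two_models_two_files(self, tmp_path):
        truth = SphereTruth()
        file = CifFile()
        pdb2cif(make_bead_model(truth, n_beads=10), file)
        pdb2cif(make_bead_model(truth, n_beads=20), file)
        texts = cif2pdb(file, tmp_path)
        assert len(texts) == 2
        assert sorted(p.name for p in tmp_path.iterdir()) == [
            "model1.pdb", "model2.pdb"]

    def test_bead_radius_survives(self):
        model = make_bead_model(SphereTruth(), n_beads=10)
        file = pdb2cif(model, CifFile())
        assert float(file.blocks[0]["sas_model"].scalar("bead_radius")) == \
            pytest.approx(model.bead_radius, rel=1e-6)


class TestFitConverters:
    def test_fir_errors_not_stored_in_fit_block(self, curve, filled):
        fit_block = next(b for b in filled.blocks if b.name == "FIT")
        assert "error" not in fit_block["sas_model_fitting"].item_names
        # but recoverable from MAIN when extracting the .fir dialect
        (text,) = cif2fit(filled, dialect="fir")
        back = read_fitfile(text, "fir")
        np.testing.assert_allclose(back.err, curve.err, rtol=1e-6)

    def test_chi2_roundtrip(self, curve):
        truth = SphereTruth()
        file = CifFile()
        dat2cif(curve, file)
        pdb2cif(make_bead_model(truth, n_beads=5), file)
        fit = make_fit(truth, curve)
        fit.chi2_reduced = 1.00
        fit2cif(fit, file)
        (text,) = cif2fit(file)
        assert read_fitfile(text).chi2_reduced == pytest.approx(1.00)

    def test_two_fits_two_files(self, curve, tmp_path):
        truth = SphereTruth()
        file = dat2cif(curve, CifFile())
        for _ in range(2):
            pdb2cif(make_bead_model(truth, n_beads=5), file)
        fit2cif(make_fit(truth, curve, model_id=1), file)
        fit2cif(make_fit(truth, curve, model_id=2), file)
        assert len(cif2fit(file, tmp_path)) == 2
        assert len(list(tmp_path.glob("*.fit"))) == 2

    def test_unknown_model_link_rejected(self, curve):
        file = dat2cif(curve, CifFile())
        with pytest.raises(EntryError, match="unknown model"):
            fit2cif(make_fit(SphereTruth(), curve, model_id=3), file)

    def test_unlinked_fit_warns(self, curve):
        file = dat2cif(curve, CifFile())
        with pytest.warns(UserWarning, match="model link"):
            fit2cif(make_fit(SphereTruth(), curve), file)


class TestSub:
    def test_sample_name_line_present(self, filled):
        pairs = cif2sub(filled)
        assert pairs.get("sample_name") == "Synthetic sphere R=50 A"

    def test_no_citation_no_citation_lines(self, filled):
        assert not any(k.startswith("citation") for k in cif2sub(filled))

    def test_count_matches_populated_scalars(self, filled):
        pairs = cif2sub(filled)
        expected = 0
        for block in filled.blocks:
            for cat in block.categories:
                if cat.is_loop:
                    continue
                for item in cat.item_names:
                    if item != "id" and cat.scalar(item) is not None:
                        expected += 1
        assert len(pairs) == expected


class TestCollectAndAll:
    def test_collect_builds_main_model_fit(self, file_set):
        file = collect(file_set.dat, file_set.out, file_set.models,
                       file_set.config)
        assert [b.name for b in file.blocks] == ["MAIN", "MODEL", "FIT"]
        assert not [f for f in validate(file) if f.severity == "error"]

    def test_config_only_beam_metadata(self, file_set):
        file = collect(file_set.dat,
                       config={"beam_beamline_name": "TEST-BEAM"})
        assert file.blocks[0]["sas_beam"].scalar("beamline_name") == "TEST-BEAM"

    def test_missing_dat_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            collect(tmp_path / "nope.dat")

    def test_cif2all_manifest_and_outdir(self, file_set, tmp_path):
        file = collect(file_set.dat, file_set.out, file_set.models,
                       file_set.config)
        out_dir = tmp_path / "nested" / "products"  # created on demand
        manifest = cif2all(file, out_dir)
        assert out_dir.is_dir()
        kinds = sorted(m.kind for m in manifest)
        assert kinds == ["dat", "fit", "out", "pdb", "sub"]
        assert all(m.ok for m in manifest)

    def test_curve_only_entry_yields_dat_and_sub(self, file_set, tmp_path):
        file = collect(file_set.dat)
        manifest = cif2all(file, tmp_path / "x")
        assert sorted(m.kind for m in manifest) == ["dat", "sub"]

    def test_collect_then_cif2all_reproduces_inputs(self, file_set, tmp_path):
        """Entry-level round trip: the regenerated file set matches."""
        file = collect(file_set.dat, file_set.out, file_set.models,
                       file_set.config)
        manifest = {m.kind: m.path for m in cif2all(file, tmp_path / "re")}
        assert manifest["dat"].read_text() == file_set.dat.read_text()
        d_in = read_out(file_set.out.read_text())
        d_out = read_out(manifest["out"].read_text())
        np.testing.assert_allclose(d_out.p, d_in.p, rtol=1e-6)
        np.testing.assert_allclose(d_out.fit_s, d_in.fit_s, rtol=1e-6)
        m_in = read_pdb(file_set.models[0][0].read_text())
        m_out = read_pdb(manifest["pdb"].read_text())
        np.testing.assert_allclose(m_out.coordinates(), m_in.coordinates(),
                                   atol=5e-4)
        f_in = read_fitfile(file_set.models[0][1].read_text())
        f_out = read_fitfile(manifest["fit"].read_text())
        np.testing.assert_allclose(f_out.Ifit, f_in.Ifit, rtol=1e-6)
        cfg = read_flat_config(file_set.config.read_text())
        sub = read_flat_config(manifest["sub"].read_text())
        assert all(sub.get(k) == v for k, v in cfg.items())

    def test_inserts_do_not_touch_other_blocks(self, curve):
        truth = SphereTruth()
        file = dat2cif(curve, CifFile())
        before = write_cif(CifFile([file.blocks[0]]))
        pdb2cif(make_bead_model(truth, n_beads=5), file)
        fit2cif(make_fit(truth, curve), file)
        assert write_cif(CifFile([file.blocks[0]])) == before
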