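import math

import numpy as np
import pytest

from xlinkquant.linearize import to_linear_form
from xlinkquant.mzml_io import MS1Run, MzmlError, read_mzml, write_mzml
from xlinkquant.ssl_io import FeatureKey, feature_key
from xlinkquant.xic import (RTAlignment, XICTrace, align_rt, extract_xic,
                            pick_peak, quantify_feature_across_runs)

from test_linearize import make_psm

KEY = FeatureKey("AKKGK", 3, (1, 2))


def single_peak_run(mz_values, intensities, rts=None):
    rts = np.asarray(rts if rts is not None else
                     np.arange(len(mz_values)) * 0.05 + 0.05)
    spectra = []
    for mzs, ints in zip(mz_values, intensities):
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        order = np.argsort(mzs)
        spectra.append((mzs[order], ints[order]))
    return MS1Run("r1", rts, spectra)


def gaussian_trace(amp=1e5, sigma=0.1, apex=5.0, span=4.0, dt=0.02,
                   key=KEY):
    rts = np.arange(apex - span, apex + span + dt / 2, dt)
    y = amp * np.exp(-0.5 * ((rts - apex) / sigma) ** 2)
    return XICTrace(key, "r1", rts, y[None, :].repeat(1, axis=0))


class TestMzmlRoundTrip:
    def test_write_read_identity(self, tmp_path):
        run = single_peak_run([[500.0, 600.5], [501.0], []],
                              [[10.0, 20.0], [5.0], []])
        path = tmp_path / "r.mzML"
        write_mzml(run, path)
        back = read_mzml(path)
        assert np.allclose(back.rts, run.rts)
        for (m1, i1), (m2, i2) in zip(back.spectra, run.spectra):
            assert np.array_equal(m1, m2) and np.array_equal(i1, i2)

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "profile.mzML"
        text = write_and_patch_profile(path)
        with pytest.raises(MzmlError, match="profile"):
            read_mzml(path)

    def test_seconds_unit_converted(self, tmp_path):
        run = single_peak_run([[500.0]], [[1.0]], rts=[2.0])
        path = tmp_path / "r.mzML"
        write_mzml(run, path)
        patched = path.read_text().replace(
            'value="2.000000" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"',
            'value="120.0" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"')
        path.write_text(patched)
        assert read_mzml(path).rts[0] == pytest.approx(2.0)


def write_and_patch_profile(path):
    run = single_peak_run([[500.0]], [[1.0]])
    write_mzml(run, path)
    text = path.read_text().replace(
        'accession="MS:1000127" name="centroid spectrum"',
        'accession="MS:1000128" name="profile spectrum"')
    path.write_text(text)
    return text


class TestExtractXic:
    def setup_method(self):
        self.lf = to_linear_form(make_psm())  # mono m/z ~ 187? -> adjust
        # use a PSM whose precursor lands inside the instrument range
        self.lf = to_linear_form(make_psm(
            pep_a="GKGGHHWWK", pep_b="AKHHWWGGK", site_a=2, site_b=2))
        assert 400 <= self.lf.precursor_mz <= 1600

    def test_single_centroid_hits_only_isotope_zero(self):
        run = single_peak_run([[self.lf.precursor_mz]], [[100.0]])
        tr = extract_xic(run, self.lf)
        assert tr.intensities[0, 0] == 100.0
        assert tr.intensities[1:, 0].sum() == 0.0

    def test_tolerance_boundary_excludes_at_0p056(self):
        run = single_peak_run([[self.lf.precursor_mz + 0.056]], [[100.0]])
        tr = extract_xic(run, self.lf, tolerance=0.055)
        assert tr.summed.sum() == 0.0

    def test_two_centroids_in_window_summed(self):
        mz = self.lf.precursor_mz
        run = single_peak_run([[mz - 0.01, mz + 0.01]], [[40.0, 60.0]])
        tr = extract_xic(run, self.lf)
        assert tr.intensities[0, 0] == 100.0

    def test_out_of_range_precursor_flagged(self):
        lf = to_linear_form(make_psm(charge=7))  # tiny peptides -> m/z < 400
        assert lf.precursor_mz < 400
        run = single_peak_run([[lf.precursor_mz]], [[50.0]])
        tr = extract_xic(run, lf)
        assert not tr.quantifiable
        assert tr.summed.sum() == 0.0

    def test_tolerance_monotonicity(self):
        mz = self.lf.precursor_mz
        rng = np.random.default_rng(2)
        mzs = mz + rng.uniform(-0.2, 0.2, size=50)
        ints = rng.uniform(1, 100, size=50)
        run = single_peak_run([mzs], [ints])
        narrow = extract_xic(run, self.lf, tolerance=0.055)
        wide = extract_xic(run, self.lf, tolerance=0.1)
        assert np.all(wide.intensities >= narrow.intensities)


class TestPickPeak:
    def test_gaussian_area_matches_closed_form(self):
        amp, sigma = 2.5e5, 0.12
        tr = gaussian_trace(amp=amp, sigma=sigma)
        peak = pick_peak(tr, rt_seed=5.0)
        analytic = amp * sigma * math.sqrt(2 * math.pi)
        assert peak.found
        assert peak.area == pytest.approx(analytic, rel=0.01)
        assert peak.rt_start < peak.rt_apex < peak.rt_end

    def test_seed_selects_nearer_of_two_separated_peaks(self):
        dt = 0.02
        rts = np.arange(0, 12, dt)
        y = (1e5 * np.exp(-0.5 * ((rts - 3.0) / 0.1) ** 2)
             + 2e5 * np.exp(-0.5 * ((rts - 9.0) / 0.1) ** 2))
        tr = XICTrace(KEY, "r1", rts, y[None, :])
        peak = pick_peak(tr, rt_seed=8.8)
        assert abs(peak.rt_apex - 9.0) < 0.05
        # only the second gaussian integrated (brute-force expectation)
        assert peak.area == pytest.approx(2e5 * 0.1 * math.sqrt(2 * math.pi),
                                          rel=0.01)

    def test_flat_zero_trace(self):
        rts = np.arange(0, 2, 0.05)
        tr = XICTrace(KEY, "r1", rts, np.zeros((3, len(rts))))
        peak = pick_peak(tr, rt_seed=1.0)
        assert peak.area == 0.0 and not peak.found

    def test_area_linearity_in_intensity(self):
        tr = gaussian_trace()
        scaled = XICTrace(KEY, "r1", tr.rts, 3.0 * tr.intensities)
        a1 = pick_peak(tr, 5.0).area
        a3 = pick_peak(scaled, 5.0).area
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_summed_area_equals_sum_of_isotope_areas(self):
        # trapezoid additivity over identical boundaries is exact
        rts = np.arange(0, 4, 0.02)
        rng = np.random.default_rng(0)
        iso = np.stack([a * np.exp(-0.5 * ((rts - 2.0) / 0.1) ** 2)
                        for a in (1e5, 8e4, 3e4)])
        tr = XICTrace(KEY, "r1", rts, iso)
        peak = pick_peak(tr, 2.0)
        i0 = np.searchsorted(rts, peak.rt_start)
        i1 = np.searchsorted(rts, peak.rt_end) + 1
        per_iso = sum(np.trapezoid(iso[k, i0:i1], rts[i0:i1])
                      for k in range(3))
        assert peak.area == pytest.approx(per_iso, rel=1e-12)


class TestAlignRt:
    def _apexes(self, rng, n_anchors, shift):
        base = dict(enumerate(np.sort(rng.uniform(2, 18, size=n_anchors))))
        ref = {FeatureKey(f"P{i}", 3, (i, i + 1)): t
               for i, t in base.items()}
        other = {k: t + shift for k, t in ref.items()}
        return ref, other

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(1)
        # the shifted run elutes 0.5 min early, so mapping onto the
        # reference axis must add the 0.5 min back
        ref, other = self._apexes(rng, 20, shift=-0.5)
        aln = align_rt({"ref": ref, "shifted": other})
        assert aln.reference == "ref"
        mapped = aln.to_reference("shifted", 10.0)
        assert mapped == pytest.approx(10.5, abs=0.05)

    def test_single_run_identity(self):
        aln = align_rt({"only": {KEY: 5.0}})
        assert aln.to_reference("only", 7.3) == 7.3

    def test_zero_offset_runs_near_identity(self):
        rng = np.random.default_rng(4)
        ref, other = self._apexes(rng, 15, shift=0.0)
        aln = align_rt({"a": ref, "b": other})
        run = "a" if aln.reference == "b" else "b"
        assert aln.to_reference(run, 10.0) == pytest.approx(10.0, abs=0.05)

    def test_too_few_anchors_identity_mapping(self):
        aln = align_rt({"a": {KEY: 5.0}, "b": {KEY: 6.0}})
        run = "a" if aln.reference == "b" else "b"
        assert aln.to_reference(run, 5.0) == 5.0

    def test_inverse_mapping(self):
        aln = RTAlignment("ref", {"r": 1.02}, {"r": 0.3})
        rt = 12.3
        assert aln.from_reference("r", aln.to_reference("r", rt)) == \
            pytest.approx(rt, abs=1e-12)


class TestMatchBetweenRuns:
    def test_feature_identified_in_subset_quantified_everywhere(
            self, noiseless_world):
        truth = noiseless_world.truth
        runs = noiseless_world.runs
        # a feature whose m/z is unique (the planted LC-ambiguity variants
        # deliberately share theirs)
        feat = next(f for f in truth.features if f.role == "normal")
        lf = to_linear_form(feat.psm_template)
        key = feature_key(feat.psm_template)
        # pretend it was identified only in run 0
        id_rts = {runs[0].run_id: float(feat.apex_rts[0])}
        results = quantify_feature_across_runs(lf, key, runs, id_rts)
        assert len(results) == len(runs)
        assert all(r.found for r in results)
        assert sum(not r.from_identification for r in results) == len(runs) - 1
        for r, true_area in zip(results, feat.areas):
            assert r.area == pytest.approx(true_area, rel=0.02)

    def test_single_run_single_result(self, noiseless_world):
        truth = noiseless_world.truth
        feat = truth.features[1]
        lf = to_linear_form(feat.psm_template)
        key = feature_key(feat.psm_template)
        runs = noiseless_world.runs[:1]
        out = quantify_feature_across_runs(
            lf, key, runs, {runs[0].run_id: float(feat.apex_rts[0])})
        assert len(out) == 1 and out[0].found
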