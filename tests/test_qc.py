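"""TIC construction, peak finding, ion matching and verdict logic."""

import numpy as np
import pytest

from bspa.chem import ProductTarget
from bspa.qc import (
    ChromatogramRun,
    IterationReport,
    MzmlError,
    ProfileModeError,
    QCConfig,
    QCVerdict,
    SpectrumScan,
    TICPeak,
    assign_verdict,
    compute_tic,
    find_tic_peaks,
    match_expected,
    peak_spectrum,
    read_run,
    reconcile,
    round_half_up,
    summarize,
)

from conftest import make_run

MINIMAL_MZML = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="tiny">
    <spectrumList count="4">
      <spectrum index="0" id="scan=1" defaultArrayLength="2">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="0.5" unitName="minute"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="24">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>AAAAAABAeUAAAAAAAMB5QA==</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="24">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>AAAAAAAAJEAAAAAAAAA0QA==</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
      <spectrum index="1" id="scan=2" defaultArrayLength="0">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="31.0" unitName="second"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary></binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary></binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
      <spectrum index="2" id="scan=3" defaultArrayLength="1">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="35.0" unitName="second"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="12">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>AAAAAABAeUA=</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="12">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>AAAAAAAAPkA=</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
      <spectrum index="3" id="scan=4" defaultArrayLength="1">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="40.0" unitName="second"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="12">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>AAAAAABAeUA=</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="12">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>AAAAAAAAPkA=</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
"""


class TestReadRun:
    def test_ms1_scans_loaded_ms2_ignored_minutes_converted(self, tmp_path):
        path = tmp_path / "tiny.mzML"
        path.write_text(MINIMAL_MZML)
        run = read_run(path)
        assert len(run.scans) == 3  # MS2 scan dropped
        assert run.scans[0].rt == pytest.approx(30.0)  # 0.5 min -> seconds
        assert run.scans[0].mz.tolist() == [404.0, 412.0]
        assert run.scans[0].intensity.tolist() == [10.0, 20.0]

    def test_profile_mode_rejected_unless_flagged(self, tmp_path):
        text = MINIMAL_MZML.replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"')
        path = tmp_path / "profile.mzML"
        path.write_text(text)
        with pytest.raises(ProfileModeError):
            read_run(path)
        run = read_run(path, assume_centroided=True)
        assert len(run.scans) == 3

    def test_malformed_xml_is_typed_error(self, tmp_path):
        path = tmp_path / "broken.mzML"
        path.write_text("<mzML><run></mzML>")
        with pytest.raises(MzmlError):
            read_run(path)


class TestComputeTic:
    def test_sums_each_scan(self):
        scan = SpectrumScan(rt=0.0, mz=np.array([100.0, 200.0, 300.0]),
                            intensity=np.array([10.0, 20.0, 30.0]))
        run = ChromatogramRun(sample_id="x", scans=(scan,))
        rt, tic = compute_tic(run)
        assert tic.tolist() == [60.0]

    def test_zero_intensities_zero_tic(self):
        run = make_run([0, 0, 0, 0])
        _, tic = compute_tic(run)
        assert tic.tolist() == [0.0] * 4

    def test_tic_conservation(self):
        run = make_run([3, 1, 4, 1, 5, 9, 2, 6])
        _, tic = compute_tic(run)
        total = sum(float(s.intensity.sum()) for s in run.scans)
        assert tic.sum() == total


class TestFindTicPeaks:
    def test_flat_trace_no_peaks(self, qc_config):
        assert find_tic_peaks(np.full(20, 7.0), qc_config) == []

    def test_single_gaussian_single_peak_at_apex(self, qc_config, gaussian_tic):
        peaks = find_tic_peaks(gaussian_tic, qc_config)
        assert len(peaks) == 1
        assert peaks[0].apex_index == 30
        assert peaks[0].left_index <= 30 < peaks[0].right_index

    def test_two_separated_gaussians(self, qc_config):
        x = np.arange(100, dtype=float)
        tic = (1e5 * np.exp(-((x - 25) ** 2) / 18.0)
               + 1e5 * np.exp(-((x - 75) ** 2) / 18.0))
        peaks = find_tic_peaks(tic, qc_config)
        assert [p.apex_index for p in peaks] == [25, 75]

    def test_prominence_monotonicity(self, qc_config):
        rng = np.random.default_rng(42)
        tic = np.abs(rng.normal(1e4, 4e3, 200)) + 1e5 * np.exp(
            -((np.arange(200) - 90.0) ** 2) / 50.0)
        strict = {p.apex_index
                  for p in find_tic_peaks(tic, QCConfig(min_prominence_fraction=0.2))}
        loose = {p.apex_index
                 for p in find_tic_peaks(tic, QCConfig(min_prominence_fraction=0.02))}
        assert strict <= loose


class TestPeakSpectrum:
    def test_single_scan_window_unchanged(self, qc_config):
        run = make_run([5.0])
        peak = TICPeak(apex_rt=0, apex_index=0, prominence=5, left_index=0, right_index=1)
        mz, inten = peak_spectrum(run, peak, qc_config)
        assert mz.tolist() == [200.0] and inten.tolist() == [5.0]

    def test_aligned_scans_sum_elementwise(self, qc_config):
        scans = tuple(
            SpectrumScan(rt=float(i), mz=np.array([100.0, 200.0]),
                         intensity=np.array([1.0 + i, 10.0]))
            for i in range(2)
        )
        run = ChromatogramRun(sample_id="x", scans=scans)
        peak = TICPeak(apex_rt=0, apex_index=0, prominence=1, left_index=0, right_index=2)
        mz, inten = peak_spectrum(run, peak, qc_config)
        assert mz.tolist() == [100.0, 200.0]
        assert inten.tolist() == [3.0, 20.0]

    def test_apex_mode_returns_apex_scan(self):
        config = QCConfig(spectrum_aggregation="apex")
        scans = tuple(
            SpectrumScan(rt=float(i), mz=np.array([100.0 + i]),
                         intensity=np.array([float(i + 1)]))
            for i in range(3)
        )
        run = ChromatogramRun(sample_id="x", scans=scans)
        peak = TICPeak(apex_rt=1, apex_index=1, prominence=1, left_index=0, right_index=3)
        mz, _ = peak_spectrum(run, peak, config)
        assert mz.tolist() == [101.0]


def _target(mono=100.0):
    return ProductTarget(id="T", smiles="", formula="C5", mono_mass=mono, avg_mass=mono,
                         expected_ions=(("[M+H]+", mono + 1.007276, 1),))


class TestMatchExpected:
    def test_exact_hit_is_rank_one(self, qc_config):
        spectrum = (np.array([101.0073]), np.array([1000.0]))
        matches = match_expected(spectrum, [_target()], qc_config)
        assert len(matches) == 1
        match = matches[0]
        assert match.rank == 1 and match.most_prominent and match.within_tol

    def test_outside_tolerance_no_match(self):
        config = QCConfig(mz_tolerance=0.0001)
        spectrum = (np.array([101.10]), np.array([1000.0]))
        assert match_expected(spectrum, [_target()], config) == []

    def test_decoy_base_peak_gives_rank_two(self, qc_config):
        spectrum = (np.array([101.0073, 350.0]), np.array([1000.0, 2000.0]))
        matches = match_expected(spectrum, [_target()], qc_config)
        assert matches[0].rank == 2 and not matches[0].most_prominent

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(90, 110, 60))
        inten = rng.uniform(1, 100, 60)
        targets = [_target(m) for m in (99.5, 100.0, 101.5)]
        seen = set()
        for tol in (0.01, 0.1, 0.3, 1.0):
            got = {(m.target_id, m.adduct)
                   for m in match_expected((mz, inten), targets, QCConfig(mz_tolerance=tol))}
            assert seen <= got
            seen = got

    def test_intensity_floor_filters_weak_signals(self, qc_config):
        spectrum = (np.array([101.0073]), np.array([50.0]))
        assert match_expected(spectrum, [_target()], qc_config, intensity_floor=100.0) == []


class TestVerdict:
    def test_no_peaks_fails(self, qc_config):
        verdict = assign_verdict("s", [], [], qc_config)
        assert verdict.status == "fail" and verdict.confidence == ""

    def test_rank_one_match_is_prominent_success(self, qc_config):
        peak = TICPeak(apex_rt=0, apex_index=0, prominence=1, left_index=0, right_index=1)
        match = match_expected((np.array([101.0073]), np.array([10.0])),
                               [_target()], qc_config)
        verdict = assign_verdict("s", [peak], [match], qc_config)
        assert (verdict.status, verdict.confidence) == ("success", "prominent")

    def test_low_rank_match_is_minor_success(self, qc_config):
        # matched but not most prominent: flagged, still a success
        peak = TICPeak(apex_rt=0, apex_index=0, prominence=1, left_index=0, right_index=1)
        spectrum = (np.array([101.0073, 300.0, 400.0]),
                    np.array([10.0, 50.0, 90.0]))
        match = match_expected(spectrum, [_target()], qc_config)
        verdict = assign_verdict("s", [peak], [match], qc_config)
        assert (verdict.status, verdict.confidence) == ("success", "minor")


class TestReconcile:
    @pytest.mark.parametrize("status, label, expected", [
        ("success", "yes", "TP"),
        ("fail", "no", "TN"),
        ("success", "no", "FP"),
        ("fail", "yes", "FN"),
    ])
    def test_confusion_categories(self, status, label, expected):
        verdict = QCVerdict(sample_id="s", status=status, confidence="", matches=())
        assert reconcile(verdict, label) == expected

    def test_missing_label_is_error(self):
        verdict = QCVerdict(sample_id="s", status="fail", confidence="", matches=())
        with pytest.raises(ValueError):
            reconcile(verdict)


class TestSummarize:
    def test_single_iteration_totals_equal_row(self):
        row = IterationReport(iteration="1", n_samples=10, match_pct=80.0,
                              tp=3, fn=1, fp=1, tp_plus_tn_pct=80.0,
                              fn_pct=10.0, fp_pct=10.0)
        summary = summarize([row])
        assert summary.match_pct_total == 80
        assert summary.tp_total == 3 and summary.fn_total == 1 and summary.fp_total == 1

    def test_totals_are_means_of_percentages_not_pooled(self):
        rows = [
            IterationReport(iteration="a", n_samples=10, match_pct=100.0,
                            tp_plus_tn_pct=100.0, fn_pct=0.0, fp_pct=0.0),
            IterationReport(iteration="b", n_samples=1000, match_pct=50.0,
                            tp_plus_tn_pct=50.0, fn_pct=25.0, fp_pct=25.0),
        ]
        summary = summarize(rows)
        assert summary.match_pct_total == 75  # mean, not sample-weighted
        assert summary.n_samples_total == 1010

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize([])


def test_round_half_up_at_the_printed_precision():
    assert round_half_up(82.954) == 83
    assert round_half_up(90.8) == 91
    assert round_half_up(2.5) == 3  # half goes up, unlike banker's rounding
    assert round_half_up(2.25, 1) == 2.3
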