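"""EIC extraction, peak calling, verdict logic, UpSet counts, and
match-between-runs classification."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from xlpasef.chem_core import isotope_mz
from xlpasef.im_library import MobilityLibraryEntry
from xlpasef.irt_align import IrtModel
from xlpasef.validation import (
    Eic,
    MS1PeakSource,
    _decide_verdict,
    call_peak,
    extract_eic,
    match_between_runs,
    upset_counts,
    validate_precursor,
)
from xlpasef.xsm_results import XsmSet

from test_xsm_results import xsm


def planted_source(
    run_id="r1",
    mz=668.3944,
    rt_center=20.0,
    im=0.82,
    abundance=1000.0,
    z=3,
    ratios=(1.0, 0.85, 0.5),
    sigma=0.06,
    step=0.02,
):
    """Gaussian isotope triplet on a shared scan grid, plus silence elsewhere."""
    grid = np.arange(rt_center - 0.2, rt_center + 0.2 + step / 2, step)
    rows = {"rt_min": [], "mz": [], "intensity": [], "inv_k0": []}
    total = 0.0
    for k, ratio in enumerate(ratios):
        mz_k = isotope_mz(mz, z, k)
        for rt in grid:
            inten = abundance * ratio * np.exp(-0.5 * ((rt - rt_center) / sigma) ** 2)
            rows["rt_min"].append(rt)
            rows["mz"].append(mz_k)
            rows["intensity"].append(inten)
            rows["inv_k0"].append(im)
            if k == 0:
                total += inten
    return MS1PeakSource(run_id, pd.DataFrame(rows)), total


class TestExtractEic:
    def test_ppm_half_window_arithmetic(self):
        # 10 ppm of 668.3944 Th is a 0.006684 Th half-window: a peak just
        # inside is captured, just outside is not
        inside = 668.3944 + 0.00667
        outside = 668.3944 + 0.00670
        source = MS1PeakSource("r", pd.DataFrame({
            "rt_min": [1.0, 2.0], "mz": [inside, outside],
            "intensity": [5.0, 7.0], "inv_k0": [0.8, 0.8],
        }))
        eic = extract_eic(source, 668.3944, ppm=10)
        assert eic.intensity.tolist() == [5.0]

    def test_empty_window_gives_empty_trace(self):
        source = MS1PeakSource("r", pd.DataFrame({
            "rt_min": [1.0], "mz": [500.0], "intensity": [5.0], "inv_k0": [0.8],
        }))
        eic = extract_eic(source, 900.0, ppm=10)
        assert len(eic.rt) == 0

    def test_planted_peak_total_recovered(self):
        source, planted_total = planted_source()
        eic = extract_eic(
            source, 668.3944, ppm=10, rt_window=(19.0, 21.0),
            im_center=0.82, im_halfwidth=0.025,
        )
        assert eic.intensity.sum() == pytest.approx(planted_total, rel=1e-6)

    def test_mobility_window_excludes(self):
        source, _ = planted_source(im=0.95)
        eic = extract_eic(
            source, 668.3944, ppm=10, im_center=0.82, im_halfwidth=0.025
        )
        assert len(eic.rt) == 0

    def test_linearity(self):
        source, _ = planted_source()
        doubled = MS1PeakSource(
            "r1", source._table.assign(intensity=source._table.intensity * 2)
        )
        e1 = extract_eic(source, 668.3944, ppm=10)
        e2 = extract_eic(doubled, 668.3944, ppm=10)
        assert np.allclose(e2.intensity, 2 * e1.intensity)

    def test_bad_ppm_rejected(self):
        source, _ = planted_source()
        with pytest.raises(ValueError):
            extract_eic(source, 668.0, ppm=0)


def triplet_from_source(source, mz=668.3944, z=3, **kw):
    return [
        extract_eic(source, isotope_mz(mz, z, k), ppm=10, isotope=k, **kw)
        for k in range(3)
    ]


class TestCallPeak:
    def test_planted_triplet_detected_at_apex(self):
        source, _ = planted_source(rt_center=20.0)
        peak = call_peak(triplet_from_source(source))
        assert peak.detected
        assert peak.apex_rt == pytest.approx(20.0, abs=0.02 + 1e-9)
        assert peak.coelution > 0.99
        assert peak.sn >= 3

    def test_monoisotope_only_fails_coelution(self):
        source, _ = planted_source(ratios=(1.0, 0.0, 0.0))
        peak = call_peak(triplet_from_source(source))
        assert peak.coelution < 0.8
        assert not peak.detected

    def test_flat_zero_traces_not_detected(self):
        empty = [
            Eic("p", k, "r", np.array([]), np.array([]), 10.0, (0.0, 1.0))
            for k in range(3)
        ]
        peak = call_peak(empty)
        assert not peak.detected and peak.sn == 0.0

    def test_boundaries_bracket_apex(self):
        source, _ = planted_source()
        peak = call_peak(triplet_from_source(source))
        assert peak.boundaries[0] <= peak.apex_rt <= peak.boundaries[1]


class TestVerdictLogic:
    @pytest.mark.parametrize(
        "passes_fdr,control,all_replicates",
        list(product([True, False], repeat=3)),
    )
    def test_three_criterion_conjunction(self, passes_fdr, control, all_replicates):
        """validated iff q passes AND all replicates detected AND no control."""
        n_rep = 4
        count = n_rep if all_replicates else 2
        verdict = _decide_verdict(
            q_value=0.03 if passes_fdr else 0.10,
            alpha=0.05,
            control_detected=control,
            replicate_count=count,
            n_replicates=n_rep,
        )
        if passes_fdr and all_replicates and not control:
            assert verdict == "validated"
        else:
            assert verdict != "validated"
        # precedence: fdr > control > replicates
        if not passes_fdr:
            assert verdict == "rejected_fdr"
        elif control:
            assert verdict == "rejected_control"
        elif not all_replicates:
            assert verdict == "rejected_replicates"

    def test_zero_detections_is_not_detected(self):
        assert _decide_verdict(0.01, 0.05, False, 0, 4) == "not_detected"


@pytest.fixture
def scenario():
    """Four replicates with a planted precursor, one silent control."""
    mz, z, im, irt = 668.3944, 3, 0.82, 62.5
    model = IrtModel(run_id="", slope=2.5, intercept=-20.0,
                     residual_sd=0.1, n_standards=10)
    rt = (irt - model.intercept) / model.slope
    reps = {}
    models = {}
    for i in range(4):
        run = f"rep{i+1}"
        reps[run], _ = planted_source(run_id=run, rt_center=rt, im=im, mz=mz)
        models[run] = IrtModel(run_id=run, slope=2.5, intercept=-20.0,
                               residual_sd=0.1, n_standards=10)
    silent = MS1PeakSource("ctrl", pd.DataFrame(
        {"rt_min": [1.0], "mz": [400.0], "intensity": [1.0], "inv_k0": [1.0]}
    ))
    models["ctrl"] = IrtModel(run_id="ctrl", slope=2.5, intercept=-20.0,
                              residual_sd=0.1, n_standards=10)
    entry = MobilityLibraryEntry(
        precursor="KQTALVELLK@1--KFWGK@1/3", charge=z, mean_inv_k0=im,
        inv_k0_range=(im, im), n_observations=4, window_width=0.05,
    )
    return dict(mz=mz, z=z, irt=irt, reps=reps,
                controls={"ctrl": silent}, models=models, entry=entry, rt=rt)


class TestValidatePrecursor:
    def test_full_detection_validates(self, scenario):
        s = scenario
        rec = validate_precursor(
            key=s["entry"].precursor, mono_mz=s["mz"], charge=s["z"],
            q_value=0.03, consensus_irt=s["irt"],
            replicate_sources=s["reps"], control_sources=s["controls"],
            library_entry=s["entry"], irt_models=s["models"],
        )
        assert rec.verdict == "validated"
        assert rec.replicate_detection_count == 4
        assert not rec.negative_control_detected

    def test_control_peak_rejects(self, scenario):
        s = scenario
        contaminated, _ = planted_source(run_id="ctrl", rt_center=s["rt"], im=0.82)
        rec = validate_precursor(
            key=s["entry"].precursor, mono_mz=s["mz"], charge=s["z"],
            q_value=0.03, consensus_irt=s["irt"],
            replicate_sources=s["reps"],
            control_sources={"ctrl": contaminated},
            library_entry=s["entry"], irt_models=s["models"],
        )
        assert rec.verdict == "rejected_control"

    def test_high_q_rejected_regardless_of_detection(self, scenario):
        s = scenario
        rec = validate_precursor(
            key=s["entry"].precursor, mono_mz=s["mz"], charge=s["z"],
            q_value=0.10, consensus_irt=s["irt"],
            replicate_sources=s["reps"], control_sources=s["controls"],
            library_entry=s["entry"], irt_models=s["models"],
        )
        assert rec.verdict == "rejected_fdr"
        assert rec.replicate_detection_count == 4

    def test_missing_library_entry_not_detected(self, scenario):
        s = scenario
        rec = validate_precursor(
            key="x", mono_mz=s["mz"], charge=s["z"], q_value=0.01,
            consensus_irt=s["irt"], replicate_sources=s["reps"],
            control_sources=s["controls"], library_entry=None,
            irt_models=s["models"],
        )
        assert rec.verdict == "not_detected"


def oracle_upset(id_sets):
    names = list(id_sets)
    out = {}
    for element in set().union(*map(set, id_sets.values())):
        combo = tuple(n for n in names if element in set(id_sets[n]))
        out[combo] = out.get(combo, 0) + 1
    return out


class TestUpset:
    def test_two_set_example(self):
        counts = upset_counts({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert counts == {("A",): 1, ("B",): 1, ("A", "B"): 2}

    def test_identical_sets_all_in_full_intersection(self):
        counts = upset_counts({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert counts == {("A", "B", "C"): 2}

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(1)
        sets = {
            f"S{i}": set(rng.choice(200, size=rng.integers(20, 120), replace=False))
            for i in range(4)
        }
        counts = upset_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_matches_per_element_bruteforce(self):
        rng = np.random.default_rng(2)
        sets = {
            f"S{i}": set(rng.choice(200, size=100, replace=False))
            for i in range(4)
        }
        assert upset_counts(sets) == oracle_upset(sets)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            upset_counts({})


class TestMatchBetweenRuns:
    def make_record(self, key, detected_runs, all_runs):
        from xlpasef.validation import ValidationRecord

        rec = ValidationRecord(precursor=key, q_value=0.01)
        rec.per_run_detected = {r: r in detected_runs for r in all_runs}
        return rec

    def test_single_xsm_with_peaks_everywhere(self):
        runs = [f"rep{i}" for i in range(1, 5)]
        record = self.make_record(_key_of("KQTALVELLK"), set(runs), runs)
        xsms = XsmSet(records=[xsm(scan="s1", run="rep4")])
        df = match_between_runs([record], xsms, runs)
        assert (df["status"] == "xsm_and_peak").sum() == 1
        assert (df["status"] == "peak_only").sum() == 3

    def test_xsms_everywhere_no_transfer(self):
        runs = ["rep1", "rep2"]
        record = self.make_record(_key_of("KQTALVELLK"), set(runs), runs)
        xsms = XsmSet(records=[xsm(scan="s1", run="rep1"), xsm(scan="s2", run="rep2")])
        df = match_between_runs([record], xsms, runs)
        assert (df["status"] == "peak_only").sum() == 0
        assert df.attrs["fraction_xsm_all_replicates"] == 1.0

    def test_planted_split_fractions(self):
        """Cohort with a planted 40%/60% split of full-XSM vs partial-XSM."""
        runs = [f"rep{i}" for i in range(1, 5)]
        records, xsm_records = [], []
        for i in range(10):
            key_pep = f"{'A' * (i + 2)}K"
            full = i < 4  # 40% have XSMs in every replicate
            xsm_in = runs if full else runs[:1]
            for j, run in enumerate(xsm_in):
                xsm_records.append(
                    xsm(scan=f"p{i}r{j}", run=run, pep_a=key_pep)
                )
            records.append(
                self.make_record(
                    _key_of(key_pep), set(runs), runs
                )
            )
        xsms = XsmSet(records=xsm_records)
        df = match_between_runs(records, xsms, runs)
        assert df.attrs["fraction_xsm_all_replicates"] == pytest.approx(0.4)
        assert df.attrs["fraction_rescued"] == pytest.approx(0.6)


def _key_of(pep_a):
    from xlpasef.xsm_results import precursor_key

    return precursor_key(pep_a, 1, "KFWGK", 1, 3)
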