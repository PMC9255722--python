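"""Study pipeline: per-subject runs, summaries, paired comparison, I/O."""

import numpy as np
import pandas as pd
import pytest

from glottimetry import (
    BreathingKinematics,
    GlottisShape,
    SceneParams,
    StudyConfig,
    SubjectResult,
    compare_agents,
    generate_crossover_study,
    generate_recording,
    load_supplementary_results,
    run_study,
    run_subject,
    summarize_by_stage,
    summarize_group,
    synthetic_reference_results,
    write_results,
)
from glottimetry.study import EmptyGroupError, PairingError, SchemaError


def make_result(subject_id, agent, al_diff, stage=1, al_min=20.0, sex="female"):
    return SubjectResult(subject_id=subject_id, sex=sex, stage=stage, agent=agent,
                         al_max=al_min + al_diff, al_min=al_min)


class TestRunSubject:
    def test_rendered_recording_recovers_ground_truth_motion(
        self, default_shape, default_kin, default_scene
    ):
        rec = generate_recording(default_shape, default_kin, default_scene,
                                 duration_s=32, fps=15, seed=4)
        measured = run_subject(rec, subject_id="d1", agent="propofol-like")
        truth = run_subject(rec, use_ground_truth=True)
        assert not measured.flagged
        assert measured.al_diff == pytest.approx(truth.al_diff, rel=0.10)
        assert measured.n_cycles >= 5

    def test_deterministic(self, small_shape, small_scene):
        rec = generate_recording(small_shape, BreathingKinematics(), small_scene,
                                 duration_s=30, fps=10, seed=8)
        r1 = run_subject(rec, subject_id="d1")
        r2 = run_subject(rec, subject_id="d1")
        assert r1 == r2

    def test_constant_glottis_flagged(self, default_shape, default_scene):
        kin = BreathingKinematics(amplitude_frac=0.0)
        rec = generate_recording(default_shape, kin, default_scene,
                                 duration_s=30, fps=10, seed=0, render=False)
        res = run_subject(rec, subject_id="d1")
        assert res.flagged
        assert res.flag_reason == "no detectable motion"

    def test_recording_roundtrip_through_disk(self, tmp_path, small_shape, small_scene):
        from glottimetry import save_recording

        rec = generate_recording(small_shape, BreathingKinematics(), small_scene,
                                 duration_s=30, fps=10, seed=3)
        save_recording(rec, tmp_path / "rec")
        from_disk = run_subject(tmp_path / "rec", subject_id="d1")
        in_memory = run_subject(rec, subject_id="d1")
        assert from_disk.al_max == pytest.approx(in_memory.al_max)
        assert from_disk.al_min == pytest.approx(in_memory.al_min)


class TestSummaries:
    def test_two_values(self):
        grp = [make_result("a", "propofol", 0.0, al_min=3.0),
               make_result("b", "propofol", 0.0, al_min=5.0)]
        s = summarize_group(grp, "al_min")
        assert s.mean == pytest.approx(4.0)
        assert s.sd == pytest.approx(1.4142, rel=1e-3)
        assert s.min == 3.0 and s.max == 5.0

    def test_single_value_has_no_sd(self):
        s = summarize_group([make_result("a", "propofol", 0.0, al_min=7.0)], "al_min")
        assert s.mean == 7.0 and s.n == 1
        assert np.isnan(s.sd)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            summarize_group([], "al_diff")

    def test_ci_uses_t_distribution(self):
        vals = [10.0, 12.0, 14.0, 16.0, 18.0]
        grp = [make_result(f"s{i}", "p", 0.0, al_min=v) for i, v in enumerate(vals)]
        s = summarize_group(grp, "al_min")
        # t(4, 0.975) = 2.776
        half = 2.7764 * s.sd / np.sqrt(5)
        assert s.ci95_low == pytest.approx(s.mean - half, rel=1e-3)
        assert s.ci95_high == pytest.approx(s.mean + half, rel=1e-3)

    def test_stage_summaries_of_simulated_study(self):
        recs, manifest = generate_crossover_study(StudyConfig(), seed=2, render=False)
        results = run_study(recs, manifest, use_ground_truth=True)
        cells = summarize_by_stage(results)
        assert len(cells) == 4
        assert all(cell["n"] == 5 for cell in cells.values())


class TestCompareAgents:
    def test_identical_outcomes_give_null_result(self):
        results = []
        for i in range(6):
            results.append(make_result(f"s{i}", "propofol", 20.0, stage=1))
            results.append(make_result(f"s{i}", "alfaxalone", 20.0, stage=2))
        cmp_res = compare_agents(results)
        assert cmp_res.mean_difference == 0.0
        assert cmp_res.wilcoxon_pvalue == 1.0

    def test_variability_ratio_from_group_means(self):
        results = []
        for i in range(10):
            results.append(make_result(f"s{i}", "propofol", 31.0, stage=1))
            results.append(make_result(f"s{i}", "alfaxalone", 13.0, stage=2))
        cmp_res = compare_agents(results)
        assert cmp_res.agent_order == ("propofol", "alfaxalone")
        assert cmp_res.variability_ratio == pytest.approx(13 / 31, rel=1e-6)

    def test_unpaired_subject_rejected(self):
        results = [make_result("s1", "propofol", 30.0),
                   make_result("s1", "alfaxalone", 10.0),
                   make_result("s2", "propofol", 25.0)]
        with pytest.raises(PairingError, match="s2"):
            compare_agents(results)


class TestSupplementaryIO:
    def test_well_formed_table(self, tmp_path):
        path = write_results(synthetic_reference_results(), tmp_path / "t.csv")
        loaded = load_supplementary_results(path)
        assert len(loaded) == 20

    def test_missing_agent_column(self, tmp_path):
        df = pd.DataFrame({"subject_id": ["a"], "stage": [1],
                           "al_max": [50.0], "al_min": [20.0]})
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="agent"):
            load_supplementary_results(p)

    def test_round_trip_identity(self, tmp_path):
        original = synthetic_reference_results()
        path = write_results(original, tmp_path / "t.csv")
        loaded = load_supplementary_results(path)
        for a, b in zip(original, sorted(loaded, key=lambda r: (r.subject_id, r.stage))):
            assert a.subject_id == b.subject_id
            assert a.stage == b.stage and a.agent == b.agent
            assert a.al_max == pytest.approx(b.al_max)
            assert a.al_min == pytest.approx(b.al_min)

    def test_column_map(self, tmp_path):
        df = pd.DataFrame({"dog": ["a", "a"], "period": [1, 2],
                           "drug": ["propofol", "alfaxalone"],
                           "maxAL": [50.0, 30.0], "minAL": [20.0, 15.0]})
        p = tmp_path / "mapped.csv"
        df.to_csv(p, index=False)
        loaded = load_supplementary_results(
            p, column_map={"subject_id": "dog", "stage": "period",
                           "agent": "drug", "al_max": "maxAL", "al_min": "minAL"})
        assert loaded[0].al_diff == pytest.approx(30.0)


class TestReferenceTable:
    """The synthetic per-dog stand-in reproduces the published summaries."""

    def test_crossover_balance(self):
        res = synthetic_reference_results()
        df = pd.DataFrame([(r.subject_id, r.stage, r.agent) for r in res],
                          columns=["subject", "stage", "agent"])
        assert df.groupby("subject").agent.nunique().eq(2).all()
        assert df[df.stage == 1].agent.value_counts().eq(5).all()

    def test_stage_cells_match_published_integers(self):
        cells = summarize_by_stage(synthetic_reference_results())
        expected = {
            (1, "propofol"): {"al_max": (84, 32), "al_min": (48, 20), "al_diff": (37, 17)},
            (1, "alfaxalone"): {"al_max": (36, 9), "al_min": (21, 7), "al_diff": (16, 8)},
            (2, "propofol"): {"al_max": (55, 29), "al_min": (30, 11), "al_diff": (26, 24)},
            (2, "alfaxalone"): {"al_max": (44, 19), "al_min": (34, 10), "al_diff": (9, 10)},
        }
        sexes = {(1, "propofol"): (3, 2), (1, "alfaxalone"): (2, 3),
                 (2, "propofol"): (2, 3), (2, "alfaxalone"): (3, 2)}
        for key, endpoints in expected.items():
            for ep, (mean, sd) in endpoints.items():
                assert round(cells[key][ep].mean) == mean, (key, ep)
                assert round(cells[key][ep].sd) == sd, (key, ep)
            f, m = sexes[key]
            assert cells[key]["sex_counts"] == {"female": f, "male": m}


def test_directionality_of_simulated_effect():
    """Shrinking the gap between agent presets shrinks the paired difference."""
    from glottimetry import ALFAXALONE_LIKE, PROPOFOL_LIKE, AgentProfile

    means = []
    for amp in (ALFAXALONE_LIKE.amplitude_scale, 0.85, PROPOFOL_LIKE.amplitude_scale):
        alf = AgentProfile("alfaxalone-like", amplitude_scale=amp,
                           baseline_scale=ALFAXALONE_LIKE.baseline_scale)
        cfg = StudyConfig(agent_first_half=alf)
        recs, manifest = generate_crossover_study(cfg, seed=7, render=False)
        results = run_study(recs, manifest, use_ground_truth=True)
        cmp_res = compare_agents(results)
        means.append(cmp_res.mean_difference)
    assert means[0] > means[1] > means[2] > 0 or (means[0] > means[1] > means[2])
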