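"""Design selection: argmax rules, exact set cover, Ward2 clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crtlead.campaign import ResponseMatrix
from crtlead.eikonal import ConductionParameters
from crtlead.leads import ELECTRODE_LETTERS, enumerate_lead_designs
from crtlead.optimization import (
    cohort_optimal,
    cross_cohort_evaluate,
    greedy_design_cover,
    hac_cluster,
    minimal_design_cover,
    patient_optimal,
)


def matrix_from_rows(rows):
    recs = pd.DataFrame(rows)
    base = pd.DataFrame(
        [{"cohort": c, "subject": s, "tat_ms": 100.0, "at090_ms": 100.0}
         for c, s in recs[["cohort", "subject"]].drop_duplicates().itertuples(index=False)]
    )
    return ResponseMatrix(records=recs, baselines=base, params=ConductionParameters())


def full_grid(best: dict, veins=("LA",), base=5.0):
    """Synthetic records: every config at ``base`` %, each subject's listed
    best configs at higher values."""
    rows = []
    configs = [
        "".join(c) for k in (1, 2) for c in itertools.combinations(ELECTRODE_LETTERS, k)
    ]
    for subject, (cfg_best, val) in best.items():
        for vein in veins:
            for cfg in configs:
                rows.append(
                    {
                        "cohort": "HF",
                        "subject": subject,
                        "vein": vein,
                        "config": cfg,
                        "at090_red_pct": val if cfg == cfg_best else base,
                        "at090_red_ms": 0.0,
                        "tat_ms": 0.0,
                        "at090_ms": 0.0,
                        "tat_red_ms": 0.0,
                        "tat_red_pct": 0.0,
                    }
                )
    return matrix_from_rows(rows)


class TestPatientOptimal:
    def test_unique_argmax(self):
        m = full_grid({"S1": ("cd", 20.0)})
        assert patient_optimal(m, "S1") == ("LA", "cd", 20.0)

    def test_tie_breaks_lexicographic(self):
        m = full_grid({"S1": ("zz", 0.0)})  # no real best: all tie at 5.0
        vein, cfg, val = patient_optimal(m, "S1")
        assert (vein, cfg, val) == ("LA", "a", 5.0)

    def test_matches_brute_force_scan(self, tiny_campaign):
        for subject in tiny_campaign.records["subject"].unique():
            vein, cfg, val = patient_optimal(tiny_campaign, subject)
            g = tiny_campaign.records.query("subject == @subject")
            assert val == pytest.approx(g["at090_red_pct"].max())
            best_rows = g[g["at090_red_pct"] >= val - 1e-12]
            assert cfg == min(best_rows["config"])

    def test_missing_subject_raises(self, tiny_campaign):
        with pytest.raises(ValueError):
            patient_optimal(tiny_campaign, "nobody")


def brute_force_cover_size(targets, designs):
    for size in range(1, 8):
        for combo in itertools.combinations(designs, size):
            if all(any(d.contains(t) for d in combo) for t in targets):
                return size
    raise AssertionError("no cover found")


class TestMinimalCover:
    def test_single_config_cover(self):
        cover = minimal_design_cover(["ah"])
        assert len(cover) == 1
        assert cover[0].contains("ah")
        assert cover[0].name == "abch"  # lexicographic completion

    def test_known_five_subject_case(self):
        targets = ["a", "ah", "cd", "ch", "dh"]
        cover = minimal_design_cover(targets)
        assert len(cover) == brute_force_cover_size(
            targets, enumerate_lead_designs()
        )

    def test_exact_cover_matches_brute_force_on_random_instances(self):
        designs = enumerate_lead_designs()
        configs = [
            "".join(c)
            for k in (1, 2)
            for c in itertools.combinations(ELECTRODE_LETTERS, k)
        ]
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_subj = rng.integers(1, 13)
            targets = list(rng.choice(configs, size=n_subj, replace=True))
            cover = minimal_design_cover(targets)
            assert len(cover) == brute_force_cover_size(set(targets), designs)
            assert all(any(d.contains(t) for d in cover) for t in set(targets))

    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(7)
        configs = [
            "".join(c)
            for k in (1, 2)
            for c in itertools.combinations(ELECTRODE_LETTERS, k)
        ]
        for _ in range(20):
            targets = list(rng.choice(configs, size=rng.integers(2, 10), replace=True))
            assert len(greedy_design_cover(targets)) >= len(
                minimal_design_cover(targets)
            )


class TestCohortOptimal:
    def test_all_subjects_best_at_ah(self):
        m = full_grid({f"S{i}": ("ah", 20.0) for i in range(4)})
        sel = cohort_optimal(m, "HF")
        assert len(sel.chosen_designs) == 1
        assert set("ah") <= set(sel.chosen_designs[0].electrodes)
        assert sel.primary_design.name == "abch"

    def test_coverage_and_invariants(self, tiny_campaign):
        sel = cohort_optimal(tiny_campaign)
        designs = enumerate_lead_designs()
        for s, (_, cfg, _) in sel.per_subject_best.items():
            assert any(d.contains(cfg) for d in sel.chosen_designs)
        # primary covers at least as many subjects as any other design
        best_cov = len(sel.coverage[sel.primary_design.name])
        for d in designs:
            n = sum(
                1
                for s, (_, cfg, _) in sel.per_subject_best.items()
                if d.contains(cfg)
            )
            assert n <= best_cov

    def test_empty_cohort_raises(self, tiny_campaign):
        with pytest.raises(ValueError):
            cohort_optimal(tiny_campaign, "XX")


class TestCrossCohort:
    def test_containment_gives_patient_optimal(self):
        m = full_grid({"S1": ("ah", 20.0), "S2": ("bh", 15.0)})
        d = next(x for x in enumerate_lead_designs() if x.name == "abgh")
        vals = cross_cohort_evaluate(m, d, "HF")
        assert vals["S1"] == 20.0 and vals["S2"] == 15.0

    def test_restricted_maximization_bounded(self, tiny_campaign):
        designs = enumerate_lead_designs()
        for d in (designs[0], designs[33], designs[-1]):
            vals = cross_cohort_evaluate(tiny_campaign, d)
            for s, v in vals.items():
                assert v <= patient_optimal(tiny_campaign, s)[2] + 1e-9

    def test_matches_direct_scan(self, tiny_campaign):
        d = next(x for x in enumerate_lead_designs() if x.name == "acdh")
        vals = cross_cohort_evaluate(tiny_campaign, d)
        recs = tiny_campaign.records
        for s, v in vals.items():
            g = recs[recs["subject"] == s]
            vein = patient_optimal(tiny_campaign, s)[0]
            gg = g[(g["vein"] == vein) & (g["config"].isin(d.admissible_configurations()))]
            assert v == pytest.approx(gg["at090_red_pct"].max())

    def test_personalisation_dominance(self, tiny_campaign):
        designs = enumerate_lead_designs()
        per_subject = [
            patient_optimal(tiny_campaign, s)[2]
            for s in tiny_campaign.records["subject"].unique()
        ]
        for d in designs[::17]:
            vals = cross_cohort_evaluate(tiny_campaign, d)
            assert vals.mean() <= np.mean(per_subject) + 1e-9


def ward2_lance_williams(X):
    """Independent Ward.D2 reference: Lance-Williams recurrence on
    Euclidean distances (squared internally), naive O(n^3)."""
    n = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    active = {i: (1, i) for i in range(n)}  # id -> (size, linkage index)
    next_id = n
    d2 = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    for _ in range(n - 1):
        (i, j), val = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active[i][0], active[j][0]
        merges.append((active[i][1], active[j][1], np.sqrt(val), si + sj))
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            sk = active[k][0]
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dik, djk = d2[a], d2[b]
            dij = val
            dnew = (
                (si + sk) * dik + (sj + sk) * djk - sk * dij
            ) / (si + sj + sk)
            del d2[a], d2[b]
            d2[(k, new)] = dnew
        del d2[(i, j)]
        del active[i], active[j]
        active[new] = (si + sj, new)
    return merges


class TestWardClustering:
    def test_identical_rows_merge_first_at_zero(self):
        rows = []
        data = {"S1": [1.0, 2.0], "S2": [1.0, 2.0], "S3": [9.0, 9.0]}
        for s, (va, vb) in data.items():
            rows += [
                dict(cohort="HF", subject=s, vein="LA", config="a",
                     at090_red_pct=va, at090_red_ms=0, tat_ms=0, at090_ms=0,
                     tat_red_ms=0, tat_red_pct=0),
                dict(cohort="HF", subject=s, vein="LA", config="b",
                     at090_red_pct=vb, at090_red_ms=0, tat_ms=0, at090_ms=0,
                     tat_red_ms=0, tat_red_pct=0),
            ]
        m = matrix_from_rows(rows)
        res = hac_cluster(m, vein="LA", k_values=(2,))
        assert res.merge_tree[0, 2] == 0.0
        assert set(res.merge_tree[0, :2].astype(int)) == {0, 1}
        labels = res.labels_at_k[2]
        assert labels[0] == labels[1] != labels[2]

    def test_merge_tree_matches_lance_williams_on_five_points(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        rows = []
        for i in range(5):
            for j in range(4):
                rows.append(
                    dict(cohort="HF", subject=f"S{i}", vein="LA", config=f"c{j}",
                         at090_red_pct=X[i, j], at090_red_ms=0, tat_ms=0,
                         at090_ms=0, tat_red_ms=0, tat_red_pct=0)
                )
        m = matrix_from_rows(rows)
        res = hac_cluster(m, vein="LA")
        ref = ward2_lance_williams(X)
        got_heights = res.merge_tree[:, 2]
        ref_heights = [r[2] for r in ref]
        assert np.allclose(got_heights, ref_heights)
        got_sizes = res.merge_tree[:, 3].astype(int).tolist()
        assert got_sizes == [r[3] for r in ref]

    def test_heights_non_decreasing(self, tiny_campaign):
        res = hac_cluster(tiny_campaign, axis="configurations", vein="LA")
        h = res.merge_tree[:, 2]
        assert (np.diff(h) >= -1e-9).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        def build(order):
            rows = []
            for i in order:
                for j in range(3):
                    rows.append(
                        dict(cohort="HF", subject=f"S{i}", vein="LA",
                             config=f"c{j}", at090_red_pct=X[i, j],
                             at090_red_ms=0, tat_ms=0, at090_ms=0,
                             tat_red_ms=0, tat_red_pct=0)
                    )
            return matrix_from_rows(rows)
        a = hac_cluster(build(range(6)), vein="LA", k_values=(3,))
        b = hac_cluster(build([3, 1, 0, 5, 2, 4]), vein="LA", k_values=(3,))
        # pivot sorts subjects, so both see the same matrix
        assert np.allclose(a.merge_tree, b.merge_tree)

    def test_too_few_items_raises(self):
        m = full_grid({"S1": ("ah", 10.0)})
        with pytest.raises(ValueError):
            hac_cluster(m, vein="LA")
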