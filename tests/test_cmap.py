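import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flipmoa import (
    SimConfig,
    jaccard,
    make_signature,
    mimic_drugs,
    mimicry_scores,
    simulate_all,
    target_enrichment,
)
from flipmoa.flip import FlipSet
from flipmoa.io import DrugProfile, DrugProfileLibrary, DrugTargetTable


class TestMakeSignature:
    def test_top_and_bottom_flanks(self):
        scores = pd.Series({"a": 5.0, "b": 4.0, "c": 3.0, "d": -4.0, "e": -5.0})
        sig = make_signature(scores, n_sig=2)
        assert set(sig.up) == {"a", "b"}
        assert set(sig.down) == {"d", "e"}

    def test_all_equal_scores_use_lexicographic_blocks(self):
        scores = pd.Series(1.0, index=["d", "b", "a", "c", "e", "f"])
        sig = make_signature(scores, n_sig=2)
        assert sig.down == ["a", "b"]
        assert sig.up == ["e", "f"]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            make_signature(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}), n_sig=2)

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=1000), index=[f"g{i:04d}" for i in range(1000)])
        sig = make_signature(scores, n_sig=100)
        order = sorted(scores.index, key=lambda g: (scores[g], g))
        assert sig.down == order[:100]
        assert sig.up == order[-100:]


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_and_empty(self):
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 0.0

    def test_one_third(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    @given(
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0


def tiny_library(n_genes=30, n_sig=5):
    rng = np.random.default_rng(3)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    up_down = genes[:n_sig]
    down_up = genes[n_sig : 2 * n_sig]
    fs = FlipSet(up_down, down_up, [], [])
    profiles = {}
    # perfect mimic: down flank = up_down, up flank = down_up
    scores = pd.Series(0.0, index=genes)
    scores[up_down] = -10.0 - np.arange(n_sig)
    scores[down_up] = 10.0 + np.arange(n_sig)
    scores[genes[2 * n_sig :]] = rng.normal(0, 0.1, n_genes - 2 * n_sig)
    profiles["MIMIC_P"] = DrugProfile("MIMIC", scores, True, True)
    n_noise = n_genes - 2 * n_sig
    for i in range(12):
        # symmetric spread keeps the zero-scored flip genes out of both flanks
        noise = rng.permutation(
            np.concatenate([np.linspace(1, 2, n_noise // 2), -np.linspace(1, 2, n_noise - n_noise // 2)])
        )
        sc = pd.Series(0.0, index=genes)
        sc[genes[2 * n_sig :]] = noise
        if i < 11:
            sc[up_down[0]] = -10.0  # one concordant hit: weak positive jaccard
        profiles[f"D{i:02d}_P"] = DrugProfile(f"D{i:02d}", sc, True, True)
    profiles["BAD_P"] = DrugProfile("BAD", scores * 0.9, False, True)  # filtered out
    return fs, DrugProfileLibrary(profiles, genes)


class TestMimicry:
    def test_perfect_mimic_scores_one_and_tops_library(self):
        fs, lib = tiny_library()
        mim = mimicry_scores(fs, lib, n_sig=5)
        assert mim.at["MIMIC_P", "jaccard"] == pytest.approx(1.0)
        assert mim.index[0] == "MIMIC_P"
        assert bool(mim.at["MIMIC_P", "in_top_decile"])

    def test_filtered_profiles_never_scored(self):
        fs, lib = tiny_library()
        mim = mimicry_scores(fs, lib, n_sig=5)
        assert "BAD_P" not in mim.index

    def test_orthogonal_profile_scores_zero(self):
        # with >= 10 positive-scoring profiles, a zero-overlap profile
        # can never be pulled into the top decile by threshold ties
        fs, lib = tiny_library()
        mim = mimicry_scores(fs, lib, n_sig=5)
        assert (mim["jaccard"] > 0).sum() >= 10
        assert mim.at["D11_P", "jaccard"] == 0.0
        assert not bool(mim.at["D11_P", "in_top_decile"])

    def test_decile_size_up_to_ties(self, bundle, flipset):
        mim = mimicry_scores(flipset, bundle["library"])
        n = len(mim)
        m = math.ceil(0.1 * n)
        flagged = int(mim["in_top_decile"].sum())
        threshold = mim["jaccard"].sort_values(ascending=False).iloc[m - 1]
        ties = int((mim["jaccard"] == threshold).sum())
        assert m <= flagged <= m + ties

    def test_pooled_mode_ignores_direction(self):
        fs, lib = tiny_library()
        anti = lib.profiles["MIMIC_P"].scores * -1  # reversed drug
        lib.profiles["ANTI_P"] = DrugProfile("ANTI", anti, True, True)
        mim = mimicry_scores(fs, lib, mode="pooled", n_sig=5)
        assert mim.at["ANTI_P", "jaccard"] == mim.at["MIMIC_P", "jaccard"]
        directional = mimicry_scores(fs, lib, mode="directional", n_sig=5)
        assert directional.at["ANTI_P", "jaccard"] == 0.0

    def test_empty_retained_library_rejected(self):
        fs, lib = tiny_library()
        for p in lib.profiles.values():
            p.quality = False
        with pytest.raises(ValueError, match="quality"):
            mimicry_scores(fs, lib, n_sig=5)


def _mim_frame(mimics, others):
    rows = []
    for i, d in enumerate(mimics):
        rows.append((f"{d}_P", d, 0.9 - i * 0.01, True))
    for i, d in enumerate(others):
        rows.append((f"{d}_P", d, 0.1 - i * 0.001, False))
    df = pd.DataFrame(rows, columns=["profile_id", "drug_id", "jaccard", "in_top_decile"])
    return df.set_index("profile_id")


class TestTargetEnrichment:
    def test_exclusive_target_is_extremal(self):
        mimics = [f"M{i}" for i in range(5)]
        others = [f"O{i}" for i in range(45)]
        mim = _mim_frame(mimics, others)
        rows = [(d, "T_HIT", "KEGG") for d in mimics]
        rows += [(d, "T_BG", "KEGG") for d in mimics[:2] + others[:20]]
        tab = DrugTargetTable(pd.DataFrame(rows, columns=["drug_id", "target_id", "source_db"]))
        res = target_enrichment(mim, tab)
        assert res.at["T_HIT", "ef"] == pytest.approx(50 / 5)  # (5/5)/(5/50)
        assert res["p"].idxmin() == "T_HIT"

    def test_unannotated_target_skipped(self):
        mim = _mim_frame(["M0"], ["O0"])
        tab = DrugTargetTable(
            pd.DataFrame([("ZZZ", "T_NONE", "KEGG")], columns=["drug_id", "target_id", "source_db"])
        )
        res = target_enrichment(mim, tab)
        assert "T_NONE" not in res.index

    def test_random_annotation_has_unit_mean_ef(self):
        rng = np.random.default_rng(11)
        mimics = [f"M{i}" for i in range(10)]
        others = [f"O{i}" for i in range(90)]
        mim = _mim_frame(mimics, others)
        efs = []
        for _ in range(50):
            rows = [
                (d, "T", "KEGG")
                for d in mimics + others
                if rng.random() < 0.3
            ]
            tab = DrugTargetTable(pd.DataFrame(rows, columns=["drug_id", "target_id", "source_db"]))
            res = target_enrichment(mim, tab)
            if "T" in res.index:
                efs.append(res.at["T", "ef"])
        assert np.mean(efs) == pytest.approx(1.0, abs=0.15)

    def test_shuffling_drug_ids_breaks_planted_enrichment(self, bundle, flipset):
        gt = bundle["ground_truth"]
        mim = mimicry_scores(flipset, bundle["library"])
        res = target_enrichment(mim, bundle["targets"])
        planted = gt.planted_targets[0]
        assert res.index[0] == planted
        rng = np.random.default_rng(1)
        shuffled = bundle["targets"].rows.copy()
        shuffled["drug_id"] = rng.permutation(shuffled["drug_id"].to_numpy())
        res2 = target_enrichment(mim, DrugTargetTable(shuffled))
        assert res2.at[planted, "p"] > res.at[planted, "p"]
        assert res2.at[planted, "ef"] < res.at[planted, "ef"]


def test_planted_mimics_reach_top_decile(bundle, flipset):
    gt = bundle["ground_truth"]
    mim = mimicry_scores(flipset, bundle["library"])
    drugs = mimic_drugs(mim)
    assert set(gt.planted_mimic_drugs) <= drugs
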