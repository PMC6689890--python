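"""Library scoring, prefiltering, diverse/analog selection, k-medoids."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pcmscreen.descriptors import circular_fingerprint, molecular_weight
from pcmscreen.io_standardize import CompoundRecord, Source, merge_datasets
from pcmscreen.labeling import LabelingScheme, binarize
from pcmscreen.model import train
from pcmscreen.screening import (
    _tanimoto_distance_matrix,
    build_selection_report,
    hit_rate_percent,
    kmedoids,
    prefilter,
    score_library,
    select_analogs,
    select_diverse,
)


class TestHitRate:
    def test_rounds_half_up(self):
        assert hit_rate_percent(15, 40) == 38  # 37.5 rounds up
        assert hit_rate_percent(15, 37) == 41
        assert hit_rate_percent(1, 8) == 13   # 12.5 rounds up

    def test_rejects_empty_denominator(self):
        with pytest.raises(ValueError):
            hit_rate_percent(1, 0)


def _toy_scores():
    # 30 hand-set (probability, MW) pairs covering both boundaries
    rows = []
    probs = [0.85, 0.80, 0.79, 0.95, 0.50, 0.10, 0.80, 0.85, 1.00, 0.75] * 3
    mws = (
        [310.0, 300.0, 400.0, 301.0, 500.0, 350.0, 299.9, 300.1, 300.0, 330.0]
        + [250.0, 305.0, 310.0, 320.0, 330.0, 340.0, 350.0, 360.0, 370.0, 380.0]
        + [300.0] * 10
    )
    for i, (p, mw) in enumerate(zip(probs, mws)):
        rows.append({"compound_id": f"L{i:02d}", "probability": p, "mw": mw})
    return pd.DataFrame(rows)


class TestPrefilter:
    def test_hand_counted_survivors_with_boundaries(self):
        table = _toy_scores()
        survivors = prefilter(table, p_cut=0.8, mw_cut=300.0)
        expected = [
            r["compound_id"]
            for _, r in table.iterrows()
            if r["probability"] >= 0.8 and r["mw"] > 300.0
        ]
        assert survivors == expected
        # boundary checks: p = 0.8 kept, MW = 300 removed
        assert "L01" not in survivors  # p 0.80 but MW exactly 300
        assert "L03" in survivors      # p 0.95, MW 301
        assert "L02" not in survivors  # MW 400 but p 0.79

    def test_monotone_in_probability_cut(self):
        table = _toy_scores()
        strict = set(prefilter(table, p_cut=0.8))
        loose = set(prefilter(table, p_cut=0.5))
        assert strict <= loose


def _fp_set(smiles_list):
    return {
        f"c{i:02d}": circular_fingerprint(s) for i, s in enumerate(smiles_list)
    }


CHEMOTYPE_A = [  # sulfonamide anilines: one tight island
    "O=S(=O)(N)c1ccc(N)cc1",
    "O=S(=O)(N)c1ccc(NC)cc1",
    "O=S(=O)(NC)c1ccc(N)cc1",
    "O=S(=O)(N)c1ccc(NCC)cc1",
]
CHEMOTYPE_B = [  # polyol sugars: another island
    "OCC1OC(O)C(O)C(O)C1O",
    "OCC1OC(OC)C(O)C(O)C1O",
    "OCC1OC(OCC)C(O)C(O)C1O",
    "OCC1OC(O)C(O)C(N)C1O",
]


class TestSelectDiverse:
    def test_returns_all_when_k_exceeds_survivors(self):
        fps = _fp_set(CHEMOTYPE_A + CHEMOTYPE_B)
        assert select_diverse(fps, k=40, seed=0) == sorted(fps)

    def test_k1_matches_brute_force_medoid(self):
        smiles = CHEMOTYPE_A + CHEMOTYPE_B + ["CCO", "c1ccncc1", "CCCCCCCC"]
        fps = _fp_set(smiles)
        ids = sorted(fps)
        dist = _tanimoto_distance_matrix(np.vstack([fps[i] for i in ids]))
        brute = ids[int(np.argmin(dist.sum(axis=1)))]
        assert select_diverse(fps, k=1, seed=0) == [brute]

    def test_two_islands_one_medoid_each(self):
        fps = _fp_set(CHEMOTYPE_A + CHEMOTYPE_B)
        picks = select_diverse(fps, k=2, seed=0)
        island_a = {f"c{i:02d}" for i in range(4)}
        island_b = {f"c{i:02d}" for i in range(4, 8)}
        assert len(set(picks) & island_a) == 1
        assert len(set(picks) & island_b) == 1

    def test_deterministic_for_fixed_seed(self):
        smiles = CHEMOTYPE_A + CHEMOTYPE_B + ["CCO", "CCN", "CCC", "c1ccccc1"]
        fps = _fp_set(smiles)
        assert select_diverse(fps, k=3, seed=5) == select_diverse(fps, k=3, seed=5)

    def test_diverse_picks_spread_wider_than_random(self):
        # on a survivor-like population (predicted actives sharing the
        # planted motif), medoids average a lower pairwise similarity than
        # equal-size random samples, over 10 seeds
        from rdkit import Chem

        from pcmscreen.synthetic import GeneratorConfig, generate_library

        lib = generate_library(GeneratorConfig(seed=7, n_library=400))
        motif = Chem.MolFromSmarts("S(=O)(=O)N")
        survivors = [
            c for c in lib
            if Chem.MolFromSmiles(c.structure).HasSubstructMatch(motif)
        ]
        fps = {c.compound_id: circular_fingerprint(c.structure) for c in survivors}

        def avg_sim(ids):
            sims = []
            for a, b in itertools.combinations(ids, 2):
                fa, fb = fps[a] > 0, fps[b] > 0
                union = np.sum(fa | fb)
                sims.append(np.sum(fa & fb) / union if union else 0.0)
            return float(np.mean(sims))

        medoid_sims, random_sims = [], []
        for seed in range(10):
            medoid_sims.append(avg_sim(select_diverse(fps, k=6, seed=seed)))
            rng = np.random.default_rng(seed)
            random_sims.append(
                avg_sim(list(rng.choice(sorted(fps), size=6, replace=False)))
            )
        assert np.mean(medoid_sims) <= np.mean(random_sims)


class TestKmedoids:
    def test_k_equals_n_is_identity(self):
        fps = _fp_set(CHEMOTYPE_A)
        dist = _tanimoto_distance_matrix(
            np.vstack([fps[i] for i in sorted(fps)])
        )
        medoids, labels = kmedoids(dist, k=len(fps), seed=0)
        assert medoids == list(range(len(fps)))
        assert labels.tolist() == list(range(len(fps)))

    def test_assignments_partition(self):
        fps = _fp_set(CHEMOTYPE_A + CHEMOTYPE_B + ["CCO", "CCCC"])
        dist = _tanimoto_distance_matrix(
            np.vstack([fps[i] for i in sorted(fps)])
        )
        medoids, labels = kmedoids(dist, k=3, seed=1)
        assert len(labels) == len(fps)
        assert set(labels.tolist()) == set(range(3))


class TestSelectAnalogs:
    def test_reference_among_survivors_ranked_first(self):
        fps = _fp_set(CHEMOTYPE_A)
        ref = CompoundRecord("ref", CHEMOTYPE_A[0], Source.IN_HOUSE)
        picks = select_analogs(ref, fps, n=2)
        assert picks[0] == "c00"  # identical structure, Tanimoto 1

    def test_requesting_more_than_survivors_returns_all(self):
        fps = _fp_set(CHEMOTYPE_A[:3])
        ref = CompoundRecord("ref", CHEMOTYPE_A[0], Source.IN_HOUSE)
        assert len(select_analogs(ref, fps, n=10)) == 3

    def test_dissimilar_survivors_still_returned(self):
        fps = _fp_set(["CCCCCCCC", "CCOCC", "CCCCN"])
        ref = CompoundRecord("ref", "OCC1OC(O)C(O)C(O)C1O", Source.IN_HOUSE)
        picks = select_analogs(ref, fps, n=3)
        assert len(picks) == 3

    def test_ties_broken_lexicographically(self):
        # duplicate structures tie at similarity 1.0
        fps = {
            "b_dup": circular_fingerprint(CHEMOTYPE_A[0]),
            "a_dup": circular_fingerprint(CHEMOTYPE_A[0]),
        }
        ref = CompoundRecord("ref", CHEMOTYPE_A[0], Source.IN_HOUSE)
        assert select_analogs(ref, fps, n=2) == ["a_dup", "b_dup"]


@pytest.fixture(scope="module")
def trained_setup(small_study):
    from pcmscreen.descriptors import assemble_matrix
    from pcmscreen.synthetic import generate_library

    config, public, inhouse, panel = small_study
    merged = merge_datasets(public, inhouse)
    scheme = LabelingScheme(8.5, 70.0)
    matrix = assemble_matrix(
        merged.compounds, merged.activities, panel,
        labeling=lambda r: binarize(r, scheme),
    )
    ensemble = train(matrix, n_trees=100, seed=0)
    library = generate_library(config)
    return ensemble, panel, library, merged


class TestScoreLibraryAndReport:
    def test_probability_per_library_compound(self, trained_setup):
        ensemble, panel, library, _ = trained_setup
        scored, n_failed = score_library(ensemble, library, panel, "T1")
        assert len(scored) == len(library)
        assert n_failed == 0
        assert scored["probability"].between(0, 1).all()

    def test_training_active_scores_high(self, trained_setup):
        ensemble, panel, library, merged = trained_setup
        actives = [
            r for r in merged.activities
            if r.target_id == "T1" and r.dialect.value == "percent_control"
            and r.value < 40.0
        ]
        by_id = {c.compound_id: c for c in merged.compounds}
        probe = [by_id[actives[0].compound_id]]
        scored, _ = score_library(ensemble, probe, panel, "T1")
        assert scored["probability"].iloc[0] >= 0.5

    def test_empty_library(self, trained_setup):
        ensemble, panel, _, _ = trained_setup
        scored, n_failed = score_library(ensemble, [], panel, "T1")
        assert scored.empty and n_failed == 0

    def test_unscorable_structures_counted_not_fatal(self, trained_setup):
        ensemble, panel, library, _ = trained_setup
        bad = CompoundRecord("bad", "this_is_not_smiles((", Source.LIBRARY)
        scored, n_failed = score_library(
            ensemble, [bad] + list(library[:3]), panel, "T1"
        )
        assert n_failed == 1 and len(scored) == 3

    def test_selection_report_bookkeeping(self, trained_setup):
        # diverse picks come from survivors; analog picks never overlap them
        ensemble, panel, library, merged = trained_setup
        scored, _ = score_library(ensemble, library, panel, "T1")
        refs = [
            (CompoundRecord("refA", CHEMOTYPE_A[0], Source.IN_HOUSE), 3),
            (CompoundRecord("refB", CHEMOTYPE_B[0], Source.IN_HOUSE), 2),
        ]
        report = build_selection_report(
            scored, library, refs, k_diverse=5, p_cut=0.5, mw_cut=250.0, seed=0
        )
        survivors = set(prefilter(report.table, 0.5, 250.0))
        assert set(report.diverse_picks) <= survivors
        for picks in report.analog_picks.values():
            assert not set(picks) & set(report.diverse_picks)
            assert set(picks) <= survivors
        assert len(report.all_picks) == len(set(report.all_picks))
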