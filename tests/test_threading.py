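import itertools

import numpy as np
import pytest

from conthread import (
    FeatureWeights,
    Query,
    Template,
    ThreadingConfig,
    align,
    build_model,
    filter_homologs,
    final_score,
    pair_score,
    rank_templates,
    sequence_identity,
    zscores,
)
from conthread.contact_io import FeatureTrack
from conthread.threading import similarity_matrix
from conthread.synthetic import (
    gen_features,
    gen_structure,
    native_contact_map,
    perturb_template,
)


def random_features(L, rng):
    prof = rng.dirichlet(np.ones(20), size=L)
    prof2 = rng.dirichlet(np.ones(20), size=L)
    return FeatureTrack(
        ss=rng.choice(list("HEC"), size=L),
        sa=rng.random(L),
        phi=rng.uniform(-180, 180, L),
        psi=rng.uniform(-180, 180, L),
        seq_profile=prof,
        struct_profile=prof2,
        hydro=rng.uniform(-4.5, 4.5, L),
    )


def brute_force_global(S, gap_open, gap_ext):
    """Enumerate every global alignment path (moves D/U/L) and score it
    with affine gap penalties: first gapped position costs gap_open,
    each further one gap_ext."""
    n, m = S.shape
    best = -np.inf
    stack = [(0, 0, 0.0, None)]
    while stack:
        i, j, score, last = stack.pop()
        if i == n and j == m:
            best = max(best, score)
            continue
        if i < n and j < m:
            stack.append((i + 1, j + 1, score + S[i, j], "D"))
        if i < n:
            pen = gap_ext if last == "U" else gap_open
            stack.append((i + 1, j, score + pen, "U"))
        if j < m:
            pen = gap_ext if last == "L" else gap_open
            stack.append((i, j + 1, score + pen, "L"))
    return best


class TestPairScore:
    def test_identical_rows_reach_channel_maximum(self, rng):
        f = random_features(5, rng)
        w = FeatureWeights()
        s = pair_score(f, 2, f, 2, w)
        # ss/sa/torsion/hydro all reach their per-channel maximum of 1
        profile_part = float(f.seq_profile[2] @ f.seq_profile[2]
                             + f.struct_profile[2] @ f.struct_profile[2])
        assert s == pytest.approx(profile_part + 4.0)

    def test_ss_mismatch_contributes_zero(self, rng):
        f = random_features(4, rng)
        g = random_features(4, rng)
        f.ss[1] = "H"
        g.ss[2] = "E"
        w_only_ss = FeatureWeights(prof=0, struct_prof=0, ss=1, sa=0,
                                   torsion=0, hydro=0)
        assert pair_score(f, 1, g, 2, w_only_ss) == 0.0

    def test_torsion_extreme(self, rng):
        f = random_features(4, rng)
        g = random_features(4, rng)
        f.phi[1], g.phi[2] = 0.0, 180.0
        f.psi[1], g.psi[2] = 0.0, 0.0
        w = FeatureWeights(prof=0, struct_prof=0, ss=0, sa=0, torsion=1, hydro=0)
        # (cos(180) + cos(0)) / 2 == 0
        assert pair_score(f, 1, g, 2, w) == pytest.approx(0.0)

    def test_matrix_matches_scalar(self, rng):
        q = random_features(6, rng)
        t = random_features(5, rng)
        S = similarity_matrix(q, t)
        for i in range(6):
            for j in range(5):
                assert S[i, j] == pytest.approx(pair_score(q, i, t, j))


class TestAlign:
    def test_self_alignment_identity(self, features80):
        a = align(features80, features80)
        assert a.gaps == 0
        assert all(q == t for q, t in a.pairs)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n, m = rng.integers(2, 7, size=2)
        q = random_features(int(n), rng)
        t = random_features(int(m), rng)
        S = similarity_matrix(q, t)
        a = align(q, t, gap_open=-2.0, gap_ext=-0.4)
        assert a.raw_score == pytest.approx(
            brute_force_global(S, -2.0, -0.4), abs=1e-9)

    def test_infinite_gap_cost_forces_diagonal(self, rng):
        q = random_features(6, rng)
        t = random_features(6, rng)
        a = align(q, t, gap_open=-1e18, gap_ext=-1e18)
        assert a.pairs == tuple((i, i) for i in range(1, 7))


class TestZScores:
    def test_hand_computed_population_sd(self):
        z = zscores([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(z, [-1.22474487, 0.0, 1.22474487])

    def test_degenerate_dispersion(self):
        with pytest.warns(UserWarning):
            z = zscores([2.0, 2.0, 2.0], [1, 1, 1])
        np.testing.assert_array_equal(z, [0, 0, 0])

    def test_location_invariance(self, rng):
        raws = rng.random(8).tolist()
        shifted = [r + 5.0 for r in raws]
        np.testing.assert_allclose(zscores(raws, [1] * 8),
                                   zscores(shifted, [1] * 8), atol=1e-12)


class TestFinalScore:
    def test_direct_sum(self):
        assert final_score(0.0, 1.0, w_cmo=2.0) == 2.0

    def test_zero_weight_reduces_to_z(self):
        assert final_score(1.37, 0.8, w_cmo=0.0) == 1.37

    def test_absent_cmo(self):
        assert final_score(-0.5, None) == -0.5

    def test_cmo_out_of_range(self):
        with pytest.raises(ValueError):
            final_score(0.0, 1.2)


class TestSequenceIdentityAndHomologs:
    def test_identical_sequence_removed(self, structure80, features80):
        twin = Template(id="twin", structure=structure80, features=features80)
        assert filter_homologs([twin], structure80.sequence) == []

    def test_remote_homolog_kept(self, structure80, features80):
        remote = perturb_template(structure80, 1.0, 0.0, seed=5,
                                  target_identity=0.25)
        ident = sequence_identity(structure80.sequence, remote.sequence)
        assert abs(ident - 25.0) <= 5.0
        t = Template(id="r", structure=remote, features=features80)
        assert filter_homologs([t], structure80.sequence) == [t]

    def test_empty_library(self):
        assert filter_homologs([], "ACDEF") == []


class TestBuildModel:
    def test_identity_copy(self, structure80, features80):
        from conthread.threading import Alignment
        a = Alignment(pairs=tuple((i, i) for i in range(1, 81)),
                      raw_score=0.0, gaps=0)
        model = build_model(80, structure80, a,
                            query_sequence=structure80.sequence)
        np.testing.assert_allclose(model.ca, structure80.ca)

    def test_partial_alignment_places_exact_count(self, structure80):
        from conthread.threading import Alignment
        a = Alignment(pairs=tuple((i, i) for i in range(1, 11)),
                      raw_score=0.0, gaps=0)
        model = build_model(50, structure80, a)
        assert model.placed_mask.sum() == 10

    def test_empty_alignment_warns(self, structure80):
        from conthread.threading import Alignment
        with pytest.warns(UserWarning):
            model = build_model(10, structure80,
                                Alignment(pairs=(), raw_score=0.0, gaps=10))
        assert model.placed_mask.sum() == 0


def small_library(query, n_decoys=4, shuffle=0.3):
    lib = [Template(
        id="twin", structure=query,
        features=gen_features(query, seed=77))]
    for d in range(n_decoys):
        s = gen_structure(len(query), seed=800 + d)
        s = perturb_template(s, 1.0, shuffle, seed=810 + d, template_id=f"dec{d}")
        lib.append(Template(id=f"dec{d}", structure=s,
                            features=gen_features(s, seed=820 + d)))
    return lib


class TestRankTemplates:
    def test_self_recognition_pure_mode(self, structure80):
        """With the homolog filter off and the unperturbed query present,
        pure threading ranks it first."""
        lib = small_library(structure80)
        q = Query(id="q", sequence=structure80.sequence,
                  features=gen_features(structure80, seed=77))
        result = rank_templates(q, lib, "pure")
        assert result.best == "twin"

    def test_assisted_with_zero_weight_equals_pure(self, structure80):
        lib = small_library(structure80)
        feats = gen_features(structure80, seed=77)
        pmap = native_contact_map(structure80)
        cfg = ThreadingConfig(w_cmo=0.0)
        pure = rank_templates(
            Query(id="q", sequence=structure80.sequence, features=feats),
            lib, "pure", cfg)
        assisted = rank_templates(
            Query(id="q", sequence=structure80.sequence, features=feats,
                  predicted_map=pmap), lib, "assisted", cfg)
        assert [s.template_id for s in assisted.ranking] == \
            [s.template_id for s in pure.ranking]
        assert [s.final for s in assisted.ranking] == \
            [s.final for s in pure.ranking]
        np.testing.assert_array_equal(
            np.nan_to_num(assisted.model.ca), np.nan_to_num(pure.model.ca))

    def test_assisted_requires_map(self, structure80):
        lib = small_library(structure80)
        q = Query(id="q", sequence=structure80.sequence,
                  features=gen_features(structure80, seed=77))
        with pytest.raises(ValueError):
            rank_templates(q, lib, "assisted")

    def test_empty_library_rejected(self, structure80):
        q = Query(id="q", sequence=structure80.sequence,
                  features=gen_features(structure80, seed=77))
        with pytest.raises(ValueError, match="no templates"):
            rank_templates(q, [], "pure")
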