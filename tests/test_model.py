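import numpy as np
import pytest

from pindex import (
    HomoeologTriple,
    PIndexModel,
    RetentionProfile,
    classify,
    classify_event_table,
    pairwise_matrix,
    pindex_multi,
    pindex_pair,
    pindex_recursive,
    pindex_selfref,
    profile_from_masks,
    read_event_fixture,
    simulate_losses,
)
from pindex.fixtures import random_retention_profile

from naive import naive_pindex


def _profile(rates_by_chrom, M=100):
    rates = {c: np.asarray(A, dtype=float) for c, A in rates_by_chrom.items()}
    return RetentionProfile(
        rates=rates,
        window_gene_counts={
            c: np.full(A.shape[1], M, dtype=int) for c, A in rates.items()
        },
        M=M,
    )


class TestPairIndex:
    def test_hand_traced_one_sided_loss(self):
        # windows: informative (+), uninformative, informative (+), informative (+)
        prof = _profile({"c1": [[1.0, 0.9, 0.8, 0.7], [0.5, 0.9, 0.4, 0.35]]})
        res = pindex_pair(prof, tau=0.05)
        row = res.per_chromosome.iloc[0]
        assert row["n_informative"] == 3
        assert row["term"] == pytest.approx(1.0)
        assert res.pindex == pytest.approx(1.0)

    def test_identical_subgenomes_undefined(self):
        prof = _profile({"c1": [[0.8, 0.6, 0.7], [0.8, 0.6, 0.7]]})
        res = pindex_pair(prof)
        assert res.status == "undefined" and res.pindex == 0.0

    def test_symmetric_cancellation(self):
        prof = _profile({"c1": [[0.8, 0.4, 0.8, 0.4], [0.4, 0.8, 0.4, 0.8]]})
        assert pindex_pair(prof).pindex == pytest.approx(0.0)

    def test_wrong_track_count_rejected(self, rng):
        prof = _profile({"c1": rng.random((3, 8))})
        with pytest.raises(ValueError, match="pindex_multi"):
            pindex_pair(prof)

    def test_raw_weight_scheme_uses_total_windows(self):
        # c1: 2 of 4 windows informative; c2: 2 of 2 informative
        prof = _profile(
            {
                "c1": [[0.9, 0.6, 0.6, 0.9], [0.5, 0.6, 0.6, 0.5]],
                "c2": [[0.9, 0.9], [0.5, 0.5]],
            }
        )
        informative = pindex_pair(prof, weight_scheme="informative")
        raw = pindex_pair(prof, weight_scheme="raw")
        wi = informative.per_chromosome.set_index("chromosome")["weight"]
        wr = raw.per_chromosome.set_index("chromosome")["weight"]
        assert wi["c1"] == pytest.approx(0.5) and wi["c2"] == pytest.approx(0.5)
        assert wr["c1"] == pytest.approx(4 / 6) and wr["c2"] == pytest.approx(2 / 6)


class TestMultiIndex:
    def test_hand_traced_three_tracks(self):
        prof = _profile({"c1": [[1.0, 1.0], [0.5, 0.5], [0.2, 0.2]]})
        res = pindex_multi(prof, tau=0.05)
        # 3 pairs x 2 windows, all informative, all signs aligned per pair
        assert res.per_chromosome.iloc[0]["term"] == pytest.approx(1.0)
        assert res.pindex == pytest.approx(1.0)

    def test_identical_tracks_undefined(self):
        prof = _profile({"c1": [[0.6, 0.7], [0.6, 0.7], [0.6, 0.7]]})
        assert pindex_multi(prof).status == "undefined"

    def test_reduces_to_pair_for_two_tracks(self, rng):
        for _ in range(30):
            prof = random_retention_profile(
                rng, S=2, n_chromosomes=(1, 6), n_windows=(5, 20)
            )
            assert pindex_multi(prof).pindex == pytest.approx(
                pindex_pair(prof).pindex, abs=1e-12
            )

    def test_empty_pair_set_rejected(self, rng):
        prof = _profile({"c1": rng.random((3, 5))})
        with pytest.raises(ValueError, match="pair_set"):
            pindex_multi(prof, pair_set=[])

    def test_printed_denominator_never_smaller(self, rng):
        """The literal published denominator N*C(S,2) - delta(N) over-normalizes."""
        for _ in range(20):
            prof = random_retention_profile(
                rng, S=3, n_chromosomes=(1, 4), n_windows=(5, 20)
            )
            default = pindex_multi(prof).pindex
            printed = pindex_multi(prof, denominator_scheme="printed").pindex
            assert printed <= default + 1e-12


class TestAgainstNaiveOracle:
    @pytest.mark.parametrize("S", [2, 3])
    def test_matches_direct_formula(self, S):
        rng = np.random.default_rng(2024 + S)
        checked = 0
        for _ in range(500):
            prof = random_retention_profile(
                rng, S=S, n_chromosomes=(1, 8), n_windows=(5, 30)
            )
            expected = naive_pindex(
                {c: A.tolist() for c, A in prof.rates.items()}
            )
            res = pindex_multi(prof) if S > 2 else pindex_pair(prof)
            if expected is None:
                assert res.status == "undefined"
            else:
                assert res.pindex == pytest.approx(expected, abs=1e-12)
                checked += 1
        assert checked > 400  # nearly all random profiles are informative

    def test_matches_under_alternative_schemes(self, rng):
        for _ in range(100):
            prof = random_retention_profile(
                rng, S=3, n_chromosomes=(1, 5), n_windows=(5, 20)
            )
            for kwargs in (
                {"weight_scheme": "raw"},
                {"denominator_scheme": "printed"},
                {"pair_norm": "S"},
            ):
                expected = naive_pindex(
                    {c: A.tolist() for c, A in prof.rates.items()}, **kwargs
                )
                got = pindex_multi(prof, **kwargs)
                if expected is None:
                    assert got.status == "undefined"
                else:
                    assert got.pindex == pytest.approx(expected, abs=1e-12)


class TestInvariants:
    def test_range_and_weight_conservation(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            S = int(rng.integers(2, 4))
            prof = random_retention_profile(rng, S=S)
            res = pindex_multi(prof)
            assert 0.0 <= res.pindex <= 1.0
            if res.status == "ok":
                assert res.per_chromosome["weight"].sum() == pytest.approx(
                    1.0, abs=1e-12
                )
                assert res.per_chromosome["term"].between(0, 1).all()

    def test_label_swap_symmetry(self, rng):
        for _ in range(50):
            prof = random_retention_profile(rng, S=2, n_chromosomes=(1, 6))
            swapped = prof.subset_tracks((1, 0))
            assert pindex_pair(prof).pindex == pytest.approx(
                pindex_pair(swapped).pindex, abs=1e-12
            )

    def test_mean_index_monotone_in_planted_retention_gap(self):
        """More biased fractionation gives a larger index on average."""
        gaps = [0.0, 0.1, 0.2, 0.3]
        means = []
        for gap in gaps:
            vals = []
            for seed in range(1, 51):
                rng = np.random.default_rng(seed)
                masks = {
                    f"c{c}": np.vstack(
                        [
                            simulate_losses(1000, 0.6 + gap / 2, 0.5, rng),
                            simulate_losses(1000, 0.6 - gap / 2, 0.5, rng),
                        ]
                    )
                    for c in range(4)
                }
                vals.append(pindex_pair(profile_from_masks(masks, M=100)).pindex)
            means.append(np.mean(vals))
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestSelfReference:
    def test_identical_homoeologs_undefined(self, rng):
        keep = rng.random(400) < 0.7
        copy = rng.random(400) < 0.6
        triple = HomoeologTriple(np.vstack([keep, copy, copy]))
        res = pindex_selfref([triple], M=10)
        assert res.status == "undefined"

    def test_reference_losses_are_skipped(self):
        # the reference copy lost slots 0..9: they must contribute to no window
        presence = np.ones((3, 30), dtype=bool)
        presence[0, :10] = False
        presence[1, 10:20] = False  # divergence only on reference-retained slots
        res = pindex_selfref([HomoeologTriple(presence)], M=10)
        assert int(res.per_chromosome["N"].sum()) == 2  # 20 retained slots / M=10

    def test_rotation_spread_small_under_homogeneous_loss(self):
        rng = np.random.default_rng(11)
        triples = [
            HomoeologTriple(
                np.vstack([simulate_losses(2500, 0.6, 0.5, rng) for _ in range(3)]),
                label=f"t{t}",
            )
            for t in range(10)
        ]
        out = pindex_selfref(triples, M=100, rotate=True)
        vals = [r.pindex for r in out.per_reference]
        assert all(r.status == "ok" for r in out.per_reference)
        assert max(vals) - min(vals) < 0.1
        assert out.mean_pindex == pytest.approx(np.mean(vals))

    def test_requires_triples(self):
        with pytest.raises(TypeError):
            pindex_selfref([np.ones((3, 10), bool)])
        with pytest.raises(ValueError):
            HomoeologTriple(np.ones((2, 10), bool))


class TestRecursiveEvents:
    def test_biased_old_round_balanced_young_round(self):
        rng = np.random.default_rng(4)
        masks = {
            f"c{c}": np.vstack(
                [
                    simulate_losses(2000, r, 0.5, rng)
                    for r in (0.75, 0.75, 0.45, 0.45)
                ]
            )
            for c in range(6)
        }
        alpha, beta = pindex_recursive(profile_from_masks(masks, M=100))
        assert beta.pindex > 0.3 > alpha.pindex

    def test_identical_within_pairs_consistent_across(self):
        a = np.tile([True, True, True, False], 50)
        b = np.tile([True, False, False, False], 50)
        masks = {"c1": np.vstack([a, a, b, b])}
        alpha, beta = pindex_recursive(profile_from_masks(masks, M=10))
        assert alpha.status == "undefined"
        assert beta.pindex == pytest.approx(1.0)

    def test_all_tracks_identical_both_undefined(self):
        a = np.tile([True, True, False], 100)
        alpha, beta = pindex_recursive(profile_from_masks({"c1": np.vstack([a] * 4)}, M=10))
        assert alpha.status == "undefined" and beta.status == "undefined"

    def test_invalid_pairing_rejected(self, rng):
        prof = profile_from_masks({"c1": rng.random((4, 200)) < 0.6}, M=100)
        with pytest.raises(ValueError, match="partition"):
            pindex_recursive(prof, pairing=((0, 1), (1, 3)))
        with pytest.raises(ValueError, match="4-track"):
            pindex_recursive(prof.subset_tracks((0, 1)))


class TestPairwiseMatrix:
    def test_symmetry_zero_diagonal_and_simple_grouping(self, rng):
        same = rng.random(600) < 0.7
        diverged = rng.random(600) < 0.4
        prof = profile_from_masks(
            {"c1": np.vstack([same, same.copy(), diverged])}, M=100
        )
        dm = pairwise_matrix(prof)
        np.testing.assert_allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert dm.groups == [[0, 1], [2]]

    def test_planted_two_plus_three_structure_recovered(self):
        rng = np.random.default_rng(8)
        targets = (0.75, 0.75, 0.45, 0.45, 0.45)
        masks = {
            f"c{c}": np.vstack([simulate_losses(1500, r, 0.5, rng) for r in targets])
            for c in range(5)
        }
        dm = pairwise_matrix(profile_from_masks(masks, M=100))
        assert dm.groups == [[0, 1], [2, 3, 4]]
        assert dm.integrated_between > max(
            w for w in dm.integrated_within if not np.isnan(w)
        )

    def test_needs_at_least_three_tracks(self, rng):
        prof = profile_from_masks({"c1": rng.random((2, 300)) < 0.5}, M=100)
        with pytest.raises(ValueError, match="S >= 3"):
            pairwise_matrix(prof)


class TestClassification:
    @pytest.mark.parametrize(
        "values, verdict",
        [([0.17], "auto"), ([0.70], "allo"), ([0.30], "auto"), ([0.31], "allo")],
    )
    def test_threshold_rule(self, values, verdict):
        assert classify(values).verdict == verdict

    def test_event_mean_used(self):
        res = classify([0.2, 0.5], label="mixed")
        assert res.event_pindex == pytest.approx(0.35)
        assert res.verdict == "allo"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify([1.2])
        with pytest.raises(ValueError):
            classify([])

    def test_published_event_table_summary(self):
        table = classify_event_table(read_event_fixture())
        assert len(table) == 24
        assert (table["verdict"] == "allo").sum() == 21
        assert table.attrs["percent_allo"] == pytest.approx(87.5)
        assert sorted(table.loc[table["verdict"] == "auto", "event_number"]) == [
            9,
            11,
            12,
        ]
        # printed Auto labels coincide with the threshold rule's verdicts
        labeled = table[table["printed_nature"] != "unlabeled"]
        assert (
            labeled["verdict"] == labeled["printed_nature"].str.lower()
        ).all()

    def test_extreme_threshold(self):
        table = classify_event_table(read_event_fixture(), threshold=0.9)
        assert table.attrs["percent_allo"] == 0.0
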