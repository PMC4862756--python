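"""Profile scoring, Gumbel E-values, HMMER ingestion, dual classification."""

import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from hybridnet.domains import (
    DomainHit,
    GumbelCalibration,
    apply_family_thresholds,
    build_profile,
    calibrate_gumbel,
    classify_dual,
    evalue,
    fit_gumbel_moments,
    max_window_score,
    read_domtblout,
    scan_proteome,
    write_domtblout,
)
from hybridnet.simulate import AMINO_ACIDS, make_family_spec, simulate_proteome


class TestBuildProfile:
    def test_even_split_column_log_odds(self):
        # 50/50 between two residues, uniform background 1/20, tiny
        # pseudocount: log-odds -> ln(0.5 * 20) = ln 10 at each residue
        profile = build_profile(["AC", "AD"], pseudocount=1e-9)
        ia, ic, id_ = (AMINO_ACIDS.index(a) for a in "ACD")
        assert profile.log_odds[0, ia] == pytest.approx(math.log(20), abs=1e-6)
        assert profile.log_odds[1, ic] == pytest.approx(math.log(10), abs=1e-6)
        assert profile.log_odds[1, id_] == pytest.approx(math.log(10), abs=1e-6)

    def test_huge_pseudocount_flattens_to_zero(self):
        profile = build_profile(["ACDE"], pseudocount=1e9)
        assert np.abs(profile.log_odds).max() < 1e-6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["AC", "ACD"])

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["AC"], pseudocount=0.0)


class TestMaxWindowScore:
    def test_embedded_exemplar_scores_consensus_sum(self):
        spec = make_family_spec("f", length=20, n_exemplars=1, seed=1)
        profile = build_profile(spec.exemplars)
        protein = "GG" + spec.exemplars[0] + "HH"
        expected = profile.log_odds.max(axis=1).sum()
        assert max_window_score(protein, profile) == pytest.approx(expected)

    def test_protein_equal_to_profile_has_one_placement(self):
        profile = build_profile(["ACDEF"])
        assert max_window_score("ACDEF", profile) == pytest.approx(
            profile.log_odds.max(axis=1).sum()
        )

    def test_shorter_protein_rejected(self):
        profile = build_profile(["ACDEF"])
        with pytest.raises(ValueError):
            max_window_score("AC", profile)

    def test_matches_brute_force_placements(self):
        rng = np.random.default_rng(0)
        letters = list(AMINO_ACIDS)
        for _ in range(200):
            m = rng.integers(1, 11)
            n = rng.integers(m, 51)
            exemplars = ["".join(rng.choice(letters, size=m)) for _ in range(rng.integers(1, 4))]
            profile = build_profile(exemplars)
            protein = "".join(rng.choice(letters, size=n))
            aa = {a: i for i, a in enumerate(AMINO_ACIDS)}
            brute = max(
                sum(profile.log_odds[p, aa[protein[s + p]]] for p in range(m))
                for s in range(n - m + 1)
            )
            assert max_window_score(protein, profile) == pytest.approx(brute)

    def test_random_background_scores_below_consensus(self):
        rng = np.random.default_rng(1)
        spec = make_family_spec("f", length=30, seed=2)
        profile = build_profile(spec.exemplars)
        consensus = profile.consensus_score()
        for _ in range(100):
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=60))
            assert max_window_score(protein, profile) < consensus


class TestGumbel:
    def test_moment_fit_recovers_known_parameters(self):
        # true Gumbel(10, 2) draws from scipy (the independent sampler)
        draws = gumbel_r.rvs(loc=10.0, scale=2.0, size=10_000, random_state=5)
        mu, beta = fit_gumbel_moments(draws)
        assert mu == pytest.approx(10.0, abs=0.1)
        assert beta == pytest.approx(2.0, abs=0.1)

    def test_fitted_location_sits_at_gumbel_tail_quantile(self):
        # by the Gumbel CDF, P(S >= mu) = 1 - exp(-1) ~ 0.632: check the
        # fitted mu against fresh draws from the true distribution
        train = gumbel_r.rvs(loc=4.0, scale=1.5, size=5000, random_state=7)
        mu, beta = fit_gumbel_moments(train)
        fresh = gumbel_r.rvs(loc=4.0, scale=1.5, size=5000, random_state=8)
        frac = np.mean(fresh >= mu)
        expect = 1 - math.exp(-1)
        se = math.sqrt(expect * (1 - expect) / 5000)
        assert abs(frac - expect) < 4 * se

    def test_calibration_runs_on_profile_scores(self):
        profile = build_profile(make_family_spec("f", length=12, seed=3).exemplars)
        cal = calibrate_gumbel(profile, n_random=200, length=60, seed=4)
        assert cal.beta > 0
        assert cal.n_calibration == 200

    def test_evalue_closed_form_at_mu(self):
        cal = GumbelCalibration(mu=10.0, beta=2.0, n_calibration=100, calib_length=50)
        assert evalue(10.0, cal, 1) == pytest.approx(1 - math.exp(-1))

    def test_evalue_limits_and_linearity(self):
        cal = GumbelCalibration(mu=10.0, beta=2.0, n_calibration=100, calib_length=50)
        assert evalue(1e6, cal, 100) == pytest.approx(0.0, abs=1e-12)
        small = evalue(30.0, cal, 1)
        assert evalue(30.0, cal, 2) == pytest.approx(2 * small, rel=1e-6)
        # monotone non-increasing everywhere, strictly decreasing on the
        # informative range (the deep left tail saturates at N in floats)
        scores = np.linspace(0, 40, 50)
        evs = [evalue(s, cal, 10) for s in scores]
        assert all(a >= b for a, b in zip(evs, evs[1:]))
        informative = [evalue(s, cal, 10) for s in np.linspace(10, 40, 30)]
        assert all(a > b for a, b in zip(informative, informative[1:]))

    def test_zero_variance_rejected(self):
        profile = build_profile(["AAAA"], pseudocount=1e-9)
        # degenerate profile where every random sequence scores identically
        # cannot be calibrated
        with pytest.raises(ValueError):
            calibrate_gumbel(
                profile.__class__(
                    name="flat",
                    log_odds=np.zeros_like(profile.log_odds),
                    background=profile.background,
                    pseudocount=1.0,
                ),
                n_random=100,
                length=10,
                seed=0,
            )


class TestDomtblout:
    HEADER = "# target name accession tlen query name accession qlen E-value score bias # of c-Evalue i-Evalue score bias from to from to from to acc description\n"

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "empty.domtblout"
        path.write_text("# nothing here\n#\n")
        assert read_domtblout(path) == []

    def test_single_row_fixture(self, tmp_path):
        path = tmp_path / "one.domtblout"
        row = (
            "SPPG_03925 - 410 KilA-N PF04383.13 110 3e-14 45.1 0.1 "
            "1 1 2.1e-16 1e-12 40.2 0.1 5 100 30 140 25 150 0.93 G1/S factor\n"
        )
        path.write_text(self.HEADER + row)
        (hit,) = read_domtblout(path)
        assert hit.protein_id == "SPPG_03925"
        assert hit.family == "KilA-N"
        assert hit.evalue == pytest.approx(1e-12)  # best-domain i-Evalue
        assert hit.score == pytest.approx(40.2)

    def test_malformed_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "bad.domtblout"
        path.write_text(self.HEADER + "too few fields\n")
        with pytest.warns(UserWarning, match="malformed"):
            assert read_domtblout(path) == []

    def test_round_trip(self, tmp_path):
        hits = [
            DomainHit("p1", "E2F_DP", 80.0, 1e-20),
            DomainHit("p2", "KilA_N", 12.5, 3e-07),
            DomainHit("p3", "E2F_DP", 2.0, 0.5),
        ]
        path = tmp_path / "rt.domtblout"
        write_domtblout(hits, path)
        back = read_domtblout(path)
        assert [(h.protein_id, h.family) for h in back] == [
            (h.protein_id, h.family) for h in hits
        ]
        for orig, parsed in zip(hits, back):
            assert parsed.evalue == pytest.approx(orig.evalue, rel=1e-2)


class TestClassifyDual:
    def test_high_tier_single_family(self):
        hits = [DomainHit("p", "E2F_DP", 50.0, 1e-12), DomainHit("p", "KilA_N", 1.0, 1.0)]
        (c,) = classify_dual(hits, "E2F_DP", "KilA_N")
        assert c.label == "E2F_DP"
        assert c.tier_a == "high"
        assert c.tier_b == "none"

    def test_marginal_tier_flagged_for_validation(self):
        hits = [DomainHit("p", "KilA_N", 20.0, 1e-07)]
        (c,) = classify_dual(hits, "E2F_DP", "KilA_N")
        assert c.label == "KilA_N"
        assert c.tier_b == "marginal"

    def test_neither_family_significant(self):
        hits = [
            DomainHit("p", "E2F_DP", 5.0, 1e-3),
            DomainHit("p", "KilA_N", 5.0, 1e-3),
        ]
        (c,) = classify_dual(hits, "E2F_DP", "KilA_N")
        assert c.label == "none"

    def test_both_families_flagged_never_assigned(self):
        hits = [
            DomainHit("p", "E2F_DP", 50.0, 1e-12),
            DomainHit("p", "KilA_N", 40.0, 1e-8),
        ]
        (c,) = classify_dual(hits, "E2F_DP", "KilA_N")
        assert c.label == "both_flagged"

    def test_row_order_invariant(self):
        hits = [
            DomainHit("p1", "E2F_DP", 50.0, 1e-12),
            DomainHit("p2", "KilA_N", 40.0, 1e-11),
            DomainHit("p1", "E2F_DP", 10.0, 1e-2),
        ]
        fwd = classify_dual(hits, "E2F_DP", "KilA_N")
        rev = classify_dual(hits[::-1], "E2F_DP", "KilA_N")
        assert fwd == rev

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            classify_dual([], "A", "B", marginal=1e-10, high=1e-5)


class TestFamilyThresholds:
    def test_cyclin_counted_at_its_threshold(self):
        hits = [DomainHit("p1", "CDC_cyclin", 90.0, 1e-25, genome="g1")]
        counts = apply_family_thresholds(hits)
        assert counts == {"g1": {"CDC_cyclin": 1}}

    def test_whi5_threshold_boundary(self):
        hits = [
            DomainHit("p1", "WHI5", 10.0, 1e-4, genome="g1"),  # above 1e-5: out
            DomainHit("p2", "WHI5", 20.0, 1e-6, genome="g1"),  # below: in
        ]
        counts = apply_family_thresholds(hits)
        assert counts == {"g1": {"WHI5": 1}}

    def test_empty_hit_table(self):
        assert apply_family_thresholds([]) == {}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="Mystery"):
            apply_family_thresholds([DomainHit("p", "Mystery", 1.0, 1e-30)])

    def test_distinct_proteins_counted_once(self):
        hits = [
            DomainHit("p1", "CDK", 90.0, 1e-25, genome="g1"),
            DomainHit("p1", "CDK", 85.0, 1e-22, genome="g1"),
            DomainHit("p2", "CDK", 80.0, 1e-21, genome="g1"),
        ]
        assert apply_family_thresholds(hits) == {"g1": {"CDK": 2}}


class TestScanProteome:
    def test_family_members_recovered_at_high_tier(self):
        sa = make_family_spec("E2F_DP", seed=11)
        sb = make_family_spec("KilA_N", seed=99)
        proteome = simulate_proteome(sa, sb, n_a=8, n_b=8, n_bg=15, seed=0)
        hits = scan_proteome(
            proteome.proteins, build_profile(sa.exemplars, name="E2F_DP"), seed=1
        ) + scan_proteome(
            proteome.proteins, build_profile(sb.exemplars, name="KilA_N"), seed=2
        )
        classes = {c.protein_id: c for c in classify_dual(hits, "E2F_DP", "KilA_N")}
        for pid, truth in proteome.truth_labels.items():
            c = classes[pid]
            if truth == "familyA":
                assert c.label == "E2F_DP" and c.tier_a == "high"
            elif truth == "familyB":
                assert c.label == "KilA_N" and c.tier_b == "high"
            else:
                assert c.label == "none"
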