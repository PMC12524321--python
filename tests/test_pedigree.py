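import datetime

import numpy as np
import pandas as pd
import pytest

from autozyg.pedigree import (Pedigree, PedigreeRecord, build_a_matrix, f_ped,
                              generation_metrics, trace_ancestors,
                              validate_pedigree)

from oracles import mc_relationship


def rows(*tuples):
    return pd.DataFrame(
        [dict(zip(("id", "sire", "dam", "sex", "birth_date"), t))
         for t in tuples])


class TestValidation:
    def test_self_parent_severed(self):
        ped, report = validate_pedigree(rows(("a", "a", "0", "m", "")))
        assert ped["a"].sire_id == ""
        assert report.counts["self-parent"] == 1

    def test_identical_duplicate_kept_once(self):
        ped, report = validate_pedigree(
            rows(("a", "0", "0", "m", ""), ("a", "0", "0", "m", "")))
        assert len(ped) == 1
        assert report.counts["duplicate"] == 1

    def test_conflicting_duplicate_keeps_first(self):
        ped, report = validate_pedigree(
            rows(("s", "0", "0", "m", ""), ("t", "0", "0", "m", ""),
                 ("a", "s", "0", "f", ""), ("a", "t", "0", "f", "")))
        assert ped["a"].sire_id == "s"
        assert report.counts["duplicate"] == 1

    def test_parental_sex_mismatch_flagged_not_severed(self):
        # dam recorded with sex male: flagged, link kept
        ped, report = validate_pedigree(
            rows(("d", "0", "0", "m", ""), ("s", "0", "0", "m", ""),
                 ("x", "s", "d", "f", ""), ("y", "0", "0", "f", ""),
                 ("z", "s", "y", "m", "")))
        assert ped["x"].dam_id == "d"
        assert report.counts["parental-sex-mismatch"] == 1

    def test_sire_equals_dam_severed(self):
        ped, report = validate_pedigree(
            rows(("p", "0", "0", "u", ""), ("a", "p", "p", "m", "")))
        assert ped["a"].sire_id == "p" and ped["a"].dam_id == ""
        assert report.counts["sire-equals-dam"] == 1

    def test_implausible_parental_age_severed(self):
        ped, report = validate_pedigree(
            rows(("p", "0", "0", "m", "2000-01-01"),
                 ("a", "p", "0", "f", "2000-06-01")))
        assert ped["a"].sire_id == ""
        assert report.counts["implausible-parental-age"] == 1

    def test_invalid_sex_and_bad_date_logged(self):
        _, report = validate_pedigree(rows(("a", "0", "0", "q", "not-a-date")))
        assert report.counts["invalid-sex"] == 1
        assert report.counts["bad-birth-date"] == 1

    def test_cycle_severed_and_logged(self):
        ped, report = validate_pedigree(
            rows(("a", "b", "0", "m", ""), ("b", "a", "0", "m", "")))
        assert "cycle" in report.counts
        assert len(ped) == 2

    def test_severing_never_increases_f_ped(self):
        base = rows(("f1", "0", "0", "m", ""), ("f2", "0", "0", "f", ""),
                    ("s", "f1", "f2", "m", ""), ("d", "f1", "f2", "f", ""),
                    ("x", "s", "d", "m", ""))
        ped, _ = validate_pedigree(base)
        f_before = build_a_matrix(ped).loc("x", "x") - 1
        # same pedigree with the dam link made invalid by parental age
        severed = base.copy()
        severed.loc[severed["id"] == "d", "birth_date"] = "2020-01-01"
        severed.loc[severed["id"] == "x", "birth_date"] = "2020-06-01"
        ped2, _ = validate_pedigree(severed)
        f_after = build_a_matrix(ped2).loc("x", "x") - 1
        assert f_after <= f_before


class TestTracing:
    @staticmethod
    def chain(n):
        """n-deep single-parent chain: c0 <- c1 <- ... (c_{n} is founder)."""
        recs = [("c%d" % n, "0", "0", "m", "")]
        for i in range(n - 1, -1, -1):
            recs.append((f"c{i}", f"c{i+1}", "0", "m", ""))
        ped, _ = validate_pedigree(rows(*recs))
        return ped

    def test_founder_any_horizon(self):
        ped = self.chain(0)
        assert len(trace_ancestors(ped, "c0", 99)) == 1

    def test_horizon_one_keeps_parents_only(self):
        ped, _ = validate_pedigree(
            rows(("g1", "0", "0", "m", ""), ("g2", "0", "0", "f", ""),
                 ("p", "g1", "g2", "m", ""), ("q", "0", "0", "f", ""),
                 ("x", "p", "q", "m", "")))
        sub = trace_ancestors(ped, "x", 1)
        assert sorted(sub.ids) == ["p", "q", "x"]
        assert sub["p"].sire_id == ""  # horizon cut

    def test_six_deep_chain_horizon_five(self):
        ped = self.chain(6)
        sub = trace_ancestors(ped, "c0", 5)
        assert "c5" in sub and "c6" not in sub

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError):
            trace_ancestors(self.chain(1), "nope", 2)


class TestGenerationMetrics:
    def test_founder(self):
        ped = TestTracing.chain(0)
        assert generation_metrics(ped, "c0") == (0, 0)

    def test_both_parents_founders(self):
        ped, _ = validate_pedigree(
            rows(("s", "0", "0", "m", ""), ("d", "0", "0", "f", ""),
                 ("x", "s", "d", "m", "")))
        assert generation_metrics(ped, "x") == (1, 1)

    def test_one_deep_side_unknown_dam(self):
        # sire known to 2 generations, dam unknown: depth 2, complete 0
        ped, _ = validate_pedigree(
            rows(("g", "0", "0", "m", ""), ("s", "g", "0", "m", ""),
                 ("x", "s", "0", "f", "")))
        assert generation_metrics(ped, "x") == (2, 0)

    def test_complete_never_exceeds_depth(self, mixed_cohort):
        _, ped, *_ = mixed_cohort
        for aid in ped.ids:
            depth, complete = generation_metrics(ped, aid)
            assert complete <= depth


def pedigree_from_parents(parents):
    recs = []
    for i, (s, d) in enumerate(parents):
        recs.append(PedigreeRecord(
            f"i{i}", f"i{s}" if s >= 0 else "", f"i{d}" if d >= 0 else ""))
    return Pedigree(recs)


class TestAMatrix:
    def test_classic_identities(self):
        # full sibs -> offspring F = 0.25; parent-offspring 0.25; half sib 0.125
        ped = pedigree_from_parents(
            [(-1, -1), (-1, -1), (0, 1), (0, 1), (2, 3),   # full-sib child i4
             (0, 2),                                       # parent-offspring i5
             (-1, -1), (0, 6), (2, 7)])                    # half-sib child i8
        A = build_a_matrix(ped)
        assert A.loc("i4", "i4") == pytest.approx(1.25)
        assert A.loc("i5", "i5") == pytest.approx(1.25)
        assert A.loc("i8", "i8") == pytest.approx(1.125)
        assert A.loc("i0", "i0") == 1.0

    def test_matches_gene_dropping_monte_carlo(self):
        rng = np.random.default_rng(42)
        from oracles import random_pedigree_parents
        parents = random_pedigree_parents(15, rng)
        Amat = build_a_matrix(pedigree_from_parents(parents))
        order = [Amat.ids.index(f"i{k}") for k in range(len(parents))]
        A = Amat.values[np.ix_(order, order)]
        A_hat, se = mc_relationship(parents, 40_000, rng)
        z = np.abs(A - A_hat) / np.maximum(se, 1e-9)
        ok = (np.abs(A - A_hat) < 1e-12) | (z < 3.5)
        assert ok.all()

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(5)
        from oracles import random_pedigree_parents
        A = build_a_matrix(
            pedigree_from_parents(random_pedigree_parents(20, rng))).values
        assert np.allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() > -1e-9


class TestFPed:
    def test_values_and_completeness_filter(self):
        ped = pedigree_from_parents([(-1, -1), (-1, -1), (0, 1), (0, 1),
                                     (2, 3)])
        A = build_a_matrix(ped)
        f = f_ped(A, ped, min_complete_generations=0)
        assert f["i0"] == 0.0
        assert f["i4"] == pytest.approx(0.25)
        # i4 has 2 complete generations; threshold 5 masks it
        f5 = f_ped(A, ped, min_complete_generations=5)
        assert np.isnan(f5["i4"])

    def test_invariant_to_record_order(self):
        recs = [PedigreeRecord("x", "s", "d"), PedigreeRecord("s", "g", ""),
                PedigreeRecord("d", "g", ""), PedigreeRecord("g", "", "")]
        f1 = f_ped(build_a_matrix(Pedigree(recs)), Pedigree(recs),
                   min_complete_generations=0)
        rev = list(reversed(recs))
        f2 = f_ped(build_a_matrix(Pedigree(rev)), Pedigree(rev),
                   min_complete_generations=0)
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())
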