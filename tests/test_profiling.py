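import itertools
import math

import numpy as np
import pytest

from tepselect.hpv import HPVCall
from tepselect.profiling import (
    annotate_hpv_strata,
    identify_tep,
    length_distribution,
    prevalence_filter,
    saturation_estimate,
    stratify_by_hpv,
)
from tepselect.records import BenignReference, Ligandome


def lig(sample_id, peptides):
    return Ligandome(sample_id=sample_id, class_i_peptides=set(peptides))


def benign(peptides=(), hla_class="I"):
    return BenignReference(
        peptides_by_class={"I": set(), "II": set(), hla_class: set(peptides)},
        tissue_index={p: {"tonsil"} for p in peptides},
        n_samples={"I": 1, "II": 1},
    )


PEPTIDES = [f"{aa}AAAAAAAA" for aa in "ACDEFGHIKLMN"]  # 12 distinct 9-mers


class TestIdentifyTep:
    def test_empty_benign_everything_is_tep(self):
        ligs = [lig("s1", PEPTIDES[:4]), lig("s2", PEPTIDES[2:6])]
        teps = identify_tep(ligs, benign(), "I")
        assert {t.sequence for t in teps} == set(PEPTIDES[:6])

    def test_tumour_subset_of_benign_gives_zero_tep(self):
        ligs = [lig("s1", PEPTIDES[:4])]
        assert identify_tep(ligs, benign(PEPTIDES[:6]), "I") == []

    def test_matches_set_difference_oracle(self):
        """5 toy samples, 12 peptides, 4 planted in benign."""
        rng = np.random.default_rng(3)
        sample_sets = [set(rng.choice(PEPTIDES, 5, replace=False)) for _ in range(5)]
        planted = set(PEPTIDES[:4])
        teps = identify_tep([lig(f"s{i}", s) for i, s in enumerate(sample_sets)],
                            benign(planted), "I")
        oracle = set().union(*sample_sets) - planted
        assert {t.sequence for t in teps} == oracle
        for t in teps:
            n = sum(t.sequence in s for s in sample_sets)
            assert t.n_positive_samples == n
            assert t.prevalence_pct == pytest.approx(100.0 * n / 5)

    def test_tep_never_intersects_benign(self, small_cohort):
        from tepselect.records import apply_identification_filters, ligandomes_from_records

        ligs = list(ligandomes_from_records(
            apply_identification_filters(small_cohort.records)).values())
        for cls in ("I", "II"):
            teps = identify_tep(ligs, small_cohort.benign, cls, ligands_only=False)
            assert not {t.sequence for t in teps} & small_cohort.benign.peptides_by_class[cls]

    def test_il_collapse_option(self):
        ligs = [lig("s1", ["ILILILILI"])]
        # benign holds the I→L collapsed twin: exact matching keeps the TEP,
        # collapsed matching removes it
        ref = benign(["LLLLLLLLL"])
        assert len(identify_tep(ligs, ref, "I")) == 1
        assert identify_tep(ligs, ref, "I", collapse_il=True) == []


class TestPrevalence:
    def test_three_of_forty_is_7_5_pct(self):
        ligs = [
            lig(f"s{i}", [PEPTIDES[0]] if i < 3 else [f"AA{i:02d}".replace("0", "G").replace("1", "H")
                                                      .replace("2", "K").replace("3", "L")
                                                      .replace("4", "M").replace("5", "N")
                                                      .replace("6", "P").replace("7", "Q")
                                                      .replace("8", "R").replace("9", "S") + "AAAAA"])
            for i in range(40)
        ]
        teps = identify_tep(ligs, benign(), "I")
        by_seq = {t.sequence: t for t in teps}
        assert by_seq[PEPTIDES[0]].prevalence_pct == pytest.approx(7.5)
        kept = prevalence_filter(teps, min_samples=3)
        assert [t.sequence for t in kept] == [PEPTIDES[0]]

    def test_min_samples_one_is_identity(self):
        ligs = [lig("s1", PEPTIDES[:3])]
        teps = identify_tep(ligs, benign(), "I")
        assert prevalence_filter(teps, 1) == teps

    def test_all_below_threshold_empty(self):
        ligs = [lig("s1", PEPTIDES[:2]), lig("s2", PEPTIDES[:2])]
        teps = identify_tep(ligs, benign(), "I")
        assert prevalence_filter(teps, 3) == []

    def test_prevalence_invariant_under_sample_order(self):
        ligs = [lig(f"s{i}", PEPTIDES[i : i + 3]) for i in range(5)]
        a = identify_tep(ligs, benign(), "I")
        b = identify_tep(ligs[::-1], benign(), "I")
        assert a == b


def call(pid, status):
    return HPVCall(patient_id=pid, status=status,
                   hpv_type="HPV-16" if status == "positive" else None)


class TestStratifyByHpv:
    def test_all_positive(self):
        ligs = [lig("s1", PEPTIDES[:3]), lig("s2", PEPTIDES[1:4])]
        calls = {"s1": call("s1", "positive"), "s2": call("s2", "positive")}
        pos, neg, shared = stratify_by_hpv(ligs, calls, "I")
        assert neg == set() and shared == set()
        assert pos == set(PEPTIDES[:4])

    def test_shared_peptide(self):
        ligs = [lig("s1", [PEPTIDES[0]]), lig("s2", [PEPTIDES[0]])]
        calls = {"s1": call("s1", "positive"), "s2": call("s2", "negative")}
        pos, neg, shared = stratify_by_hpv(ligs, calls, "I")
        assert shared == {PEPTIDES[0]} and pos == set() and neg == set()

    def test_partition_covers_union(self):
        rng = np.random.default_rng(5)
        ligs = [lig(f"s{i}", rng.choice(PEPTIDES, 4, replace=False)) for i in range(6)]
        calls = {f"s{i}": call(f"s{i}", "positive" if i % 2 else "negative") for i in range(6)}
        pos, neg, shared = stratify_by_hpv(ligs, calls, "I")
        union = set().union(*(l.class_i_peptides for l in ligs))
        assert pos | neg | shared == union
        assert len(pos) + len(neg) + len(shared) == len(union)

    def test_missing_call_raises(self):
        with pytest.raises(ValueError, match="s1"):
            stratify_by_hpv([lig("s1", PEPTIDES[:1])], {}, "I")

    def test_annotate_strata(self):
        ligs = [lig("s1", [PEPTIDES[0]]), lig("s2", [PEPTIDES[1]])]
        calls = {"s1": call("s1", "positive"), "s2": call("s2", "negative")}
        teps = identify_tep(ligs, benign(), "I")
        annotated = annotate_hpv_strata(teps, stratify_by_hpv(ligs, calls, "I"))
        strata = {t.sequence: t.hpv_stratum for t in annotated}
        assert strata == {PEPTIDES[0]: "hpv_pos_only", PEPTIDES[1]: "hpv_neg_only"}


class TestLengthDistribution:
    def test_all_same_length(self):
        assert length_distribution([lig("s1", PEPTIDES[:3])], "I") == {9: 1.0}

    def test_hand_counted_fractions(self):
        peptides = ["AAAAAAAA", "CCCCCCCCC", "DDDDDDDDD", "EEEEEEEEEE"]
        dist = length_distribution([lig("s1", peptides)], "I")
        assert dist == {8: 0.25, 9: 0.5, 10: 0.25}

    def test_sums_to_one(self, small_cohort):
        from tepselect.records import apply_identification_filters, ligandomes_from_records

        ligs = list(ligandomes_from_records(
            apply_identification_filters(small_cohort.records)).values())
        for cls in ("I", "II"):
            dist = length_distribution(ligs, cls, ligands_only=False)
            assert math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9)


class TestSaturation:
    def proteins(self, mapping):
        return {p: {f"PR{i}"} for p, i in mapping.items()}

    def test_identical_samples_fully_saturated(self):
        ligs = [lig(f"s{i}", PEPTIDES[:4]) for i in range(5)]
        res = saturation_estimate(ligs, "I", self.proteins({p: i for i, p in enumerate(PEPTIDES[:4])}))
        assert np.allclose(res.curve, res.curve[0])
        assert res.pct_attained == pytest.approx(100.0, abs=1e-6)

    def test_disjoint_samples_far_from_saturation(self):
        ligs = [lig(f"s{i}", [PEPTIDES[i]]) for i in range(6)]
        res = saturation_estimate(ligs, "I", self.proteins({p: i for i, p in enumerate(PEPTIDES)}))
        # linear accumulation: the fitted asymptote exceeds what was seen
        assert res.est_max_proteins > res.n_observed * 1.3
        assert res.pct_attained < 80.0

    def test_curve_equals_full_permutation_average(self):
        """5-sample toy: the reported curve equals the average over all 5!
        orderings computed independently here."""
        rng = np.random.default_rng(9)
        sets = [set(rng.choice(PEPTIDES, 4, replace=False)) for _ in range(5)]
        ligs = [lig(f"s{i}", s) for i, s in enumerate(sets)]
        prot = {p: {f"PR_{p}"} for p in PEPTIDES}
        res = saturation_estimate(ligs, "I", prot)
        expected = np.zeros(5)
        for order in itertools.permutations(range(5)):
            seen = set()
            for i, idx in enumerate(order):
                seen |= {f"PR_{p}" for p in sets[idx]}
                expected[i] += len(seen)
        expected /= math.factorial(5)
        assert np.allclose(res.curve, expected)

    def test_curve_monotone_nondecreasing(self, small_cohort):
        from tepselect.records import apply_identification_filters, ligandomes_from_records

        ligs = list(ligandomes_from_records(
            apply_identification_filters(small_cohort.records)).values())
        res = saturation_estimate(ligs, "I", small_cohort.source_proteins, ligands_only=False)
        assert (np.diff(res.curve) >= -1e-9).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            saturation_estimate([lig("s1", PEPTIDES[:2])] * 2, "I", {})
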