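"""Consensus calling, tool/lab filters and pathogenicity labeling."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tp53hit.variant_filtering import (
    ConsensusVariant,
    RawCall,
    UnknownCallerError,
    VariantAnnotation,
    VariantParseError,
    consensus,
    filter_variants,
    final_retention,
    lab_thresholds,
    label_pathogenicity,
    normalize_and_key,
    tool_filter,
)


def make_call(caller, *, vaf=0.2, depth=500, quality=60.0, flags=("PASS",),
              pos=7577120, ref="C", alt="T", sample="s1"):
    return RawCall(
        caller=caller, chromosome="chr17", position=pos, ref=ref, alt=alt,
        vaf=vaf, depth=depth, quality=quality, filter_flags=frozenset(flags),
        sample_id=sample,
    )


PATHOGENIC_ANN = VariantAnnotation(
    consequence="nonsense", clinvar_status="pathogenic",
    cosmic_present=True, insilico_support="strong", population_freq=0.0,
)


class TestNormalizeAndKey:
    def test_shared_prefix_trim(self):
        key = normalize_and_key("chr17", 100, "CA", "CT")
        assert (key.position, key.ref, key.alt) == (101, "A", "T")

    def test_identical_snv_same_key(self):
        k1 = normalize_and_key("chr17", 7577120, "C", "T")
        k2 = normalize_and_key("chr17", 7577120, "C", "T")
        assert k1 == k2

    def test_equivalent_deletion_representations(self):
        # oracle: both spell "delete one T from the TT run after A"
        k1 = normalize_and_key("chr17", 100, "ATT", "AT")
        k2 = normalize_and_key("chr17", 101, "TT", "T")
        assert k1 == k2

    @pytest.mark.parametrize("ref, alt", [("", "A"), ("A", ""), ("AN", "A"), ("A", "A")])
    def test_malformed_alleles(self, ref, alt):
        with pytest.raises(VariantParseError):
            normalize_and_key("chr17", 100, ref, alt)

    @given(
        core=st.tuples(
            st.sampled_from(["A", "C", "G", "T"]),
            st.sampled_from(["A", "C", "G", "T"]),
        ).filter(lambda t: t[0] != t[1]),
        prefix=st.text(alphabet="ACGT", max_size=4),
        suffix=st.text(alphabet="ACGT", max_size=4),
        pos=st.integers(1, 10**6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_padding_invariance(self, core, prefix, suffix, pos):
        """Shared flanking context never changes the normalized key."""
        ref, alt = core
        bare = normalize_and_key("chr17", pos, ref, alt)
        padded = normalize_and_key(
            "chr17", pos - len(prefix), prefix + ref + suffix, prefix + alt + suffix
        )
        assert bare == padded


class TestToolFilter:
    @pytest.mark.parametrize(
        "call, expected",
        [
            (make_call("shearwater", quality=31), True),
            (make_call("shearwater", quality=30), False),
            (make_call("mutect2", flags=("PASS", "germline_risk")), False),
            (make_call("mutect2", flags=("PASS",)), True),
            (make_call("sophia", flags=("PASS",)), True),
            (make_call("sophia", flags=("noise",)), False),
        ],
    )
    def test_rules(self, call, expected):
        assert tool_filter(call) is expected

    def test_unknown_caller(self):
        with pytest.raises(UnknownCallerError):
            make_call("varscan")


class TestConsensus:
    def test_two_of_three_survives(self):
        out = consensus([make_call("mutect2"), make_call("sophia")])
        assert len(out) == 1
        assert out[0].verdict("consensus_2of3") is True
        assert out[0].supporting_callers == {"mutect2", "sophia"}

    def test_single_caller_dropped(self):
        out = consensus([make_call("shearwater", quality=50)])
        assert out[0].verdict("consensus_2of3") is False

    def test_median_vaf(self):
        out = consensus(
            [
                make_call("mutect2", vaf=0.10),
                make_call("sophia", vaf=0.12),
                make_call("shearwater", vaf=0.20, quality=50),
            ]
        )
        assert out[0].vaf == pytest.approx(0.12)

    def test_failing_caller_does_not_count(self):
        out = consensus(
            [make_call("mutect2"), make_call("shearwater", quality=10)]
        )
        assert out[0].verdict("consensus_2of3") is False


class TestLabThresholds:
    @pytest.mark.parametrize(
        "depth, vaf, expected",
        [(251, 0.051, True), (250, 0.10, False), (1000, 0.05, False)],
    )
    def test_strict_bounds(self, depth, vaf, expected):
        cv = ConsensusVariant(
            key=None, supporting_callers=frozenset(), vaf=vaf, depth=depth
        )
        assert lab_thresholds(cv) is expected


class TestLabelPathogenicity:
    @pytest.mark.parametrize(
        "ann, expected",
        [
            # rule 1: loss of function regardless of databases
            (VariantAnnotation("nonsense"), "pathogenic"),
            (VariantAnnotation("missense"), "pathogenic"),
            (VariantAnnotation("frameshift"), "pathogenic"),
            # rule 2: database + strong in-silico
            (
                VariantAnnotation(
                    "splice", clinvar_status="pathogenic", insilico_support="strong"
                ),
                "pathogenic",
            ),
            (
                VariantAnnotation(
                    "splice", clinvar_status="pathogenic", insilico_support="weak"
                ),
                "vus",
            ),
            (VariantAnnotation("synonymous"), "vus"),
            (VariantAnnotation("other", clinvar_status="benign"), "benign"),
        ],
    )
    def test_rules(self, ann, expected):
        assert label_pathogenicity(ann) == expected

    def test_missing_annotation(self):
        with pytest.raises(KeyError):
            label_pathogenicity(None)


class TestFinalRetention:
    def _cv(self, pathogenicity="pathogenic"):
        return ConsensusVariant(
            key=None, supporting_callers=frozenset({"mutect2", "sophia"}),
            vaf=0.2, depth=600, pathogenicity=pathogenicity,
        )

    def test_common_variant_dropped(self):
        ann = VariantAnnotation("missense", cosmic_present=True, population_freq=0.02)
        assert final_retention(self._cv(), ann) is False

    def test_confirmed_rare_retained(self):
        ann = VariantAnnotation("nonsense", cosmic_present=True, population_freq=0.0)
        assert final_retention(self._cv(), ann) is True

    def test_lof_without_database_dropped(self):
        ann = VariantAnnotation("nonsense")  # absent from ClinVar and COSMIC
        assert final_retention(self._cv(), ann) is False
        assert final_retention(self._cv(), ann, db_confirm=False) is True


class TestCascadeOracle:
    def test_retention_equals_brute_force_boolean_rule(self):
        """Pipeline retention equals direct evaluation of the stated rule
        over all caller-pass combinations x lab outcomes x annotations."""
        caller_subsets = [
            set(c) for r in range(4)
            for c in itertools.combinations(["mutect2", "sophia", "shearwater"], r)
        ]
        lab_cases = [(600, 0.2, True), (250, 0.2, False), (600, 0.05, False)]
        annotations = [
            PATHOGENIC_ANN,  # pathogenic + confirmed
            VariantAnnotation("nonsense"),  # pathogenic, unconfirmed
            VariantAnnotation("synonymous"),  # vus
            VariantAnnotation("other", clinvar_status="benign"),  # benign
            VariantAnnotation("missense", cosmic_present=True, population_freq=0.05),
        ]
        for passing, (depth, vaf, lab_ok), ann in itertools.product(
            caller_subsets, lab_cases, annotations
        ):
            calls = []
            for caller in ("mutect2", "sophia", "shearwater"):
                ok = caller in passing
                calls.append(
                    make_call(
                        caller,
                        vaf=vaf,
                        depth=depth,
                        quality=60.0 if ok else 10.0,
                        flags=("PASS",) if ok or caller == "shearwater" else ("fail",),
                    )
                )
            [result] = filter_variants(calls, {calls[0].key: ann})
            label = label_pathogenicity(ann)
            expected = (
                len(passing) >= 2
                and lab_ok
                and label == "pathogenic"
                and ann.population_freq <= 0.01
                and (
                    ann.clinvar_status in ("pathogenic", "likely_pathogenic")
                    or ann.cosmic_present
                )
            )
            assert result.retained == expected, (passing, depth, vaf, ann)

    def test_order_independence(self, rng):
        calls = [
            make_call("mutect2", vaf=0.1),
            make_call("sophia", vaf=0.15),
            make_call("shearwater", vaf=0.12, quality=45),
            make_call("mutect2", pos=7578406, ref="G", alt="A"),
        ]
        ann = {c.key: PATHOGENIC_ANN for c in calls}
        baseline = {
            (v.key, v.retained, v.vaf)
            for v in filter_variants(calls, ann)
        }
        for _ in range(5):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            shuffled = {
                (v.key, v.retained, v.vaf)
                for v in filter_variants(perm, ann)
            }
            assert shuffled == baseline

    def test_adding_passing_caller_monotone(self):
        base = [make_call("mutect2")]
        ann = {base[0].key: PATHOGENIC_ANN}
        [before] = filter_variants(base, ann)
        [after] = filter_variants(base + [make_call("sophia")], ann)
        assert not before.retained and after.retained
        [more] = filter_variants(
            base + [make_call("sophia"), make_call("shearwater", quality=50)], ann
        )
        assert more.retained  # a third caller never un-retains

    def test_blacklist_excludes_matched_normal_artifacts(self):
        calls = [make_call("mutect2"), make_call("sophia")]
        ann = {calls[0].key: PATHOGENIC_ANN}
        [kept] = filter_variants(calls, ann)
        assert kept.retained
        [dropped] = filter_variants(calls, ann, blacklist={calls[0].key})
        assert not dropped.retained
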