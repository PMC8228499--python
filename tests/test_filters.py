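"""VAF arithmetic, the one-sided somatic Fisher test, and the filter chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from liquidbx.filters import (
    AnnotatedVariant,
    FilterConfig,
    Reason,
    apply_filter_chain,
    compute_vaf,
    decompose_multiallelic,
    somatic_fisher_test,
)


def make_variant(**kw) -> AnnotatedVariant:
    """A variant passing every per-variant rule unless overridden."""
    defaults = dict(
        chrom="chr1", pos=1000, ref="A", alt="T", gene="TP53",
        func_class="nonsynonymous_snv",
        tumor_alt_fwd=20, tumor_alt_rev=20, tumor_ref_fwd=80, tumor_ref_rev=80,
        normal_alt=0, normal_ref=200, depth=200, vaf=0.2,
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestComputeVaf:
    @pytest.mark.parametrize("alt,depth,expected", [
        (0, 100, 0.0),
        (5, 50, 0.1),
        (37, 200, 0.185),
        (0, 0, 0.0),
    ])
    def test_values(self, alt, depth, expected):
        assert compute_vaf(alt, depth) == pytest.approx(expected)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf(11, 10)


def brute_force_tail(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric tail by explicit enumeration over more-extreme tables
    (fixed margins, tumor-alt increasing)."""
    n_tumor, n_alt, total = a + b, a + c, a + b + c + d

    def log_comb(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_comb(total, n_tumor)
    p = 0.0
    for k in range(a, min(n_tumor, n_alt) + 1):
        if n_tumor - k > total - n_alt:
            continue
        p += math.exp(
            log_comb(n_alt, k) + log_comb(total - n_alt, n_tumor - k) - denom
        )
    return p


class TestSomaticFisher:
    def test_no_enrichment_balanced(self):
        p = somatic_fisher_test(10, 90, 10, 90)
        assert p == pytest.approx(brute_force_tail(10, 90, 10, 90), rel=1e-12)
        assert p >= 0.5

    def test_no_alt_anywhere(self):
        assert somatic_fisher_test(0, 100, 0, 100) == pytest.approx(1.0)

    def test_clear_enrichment_passes_threshold(self):
        p = somatic_fisher_test(30, 170, 0, 200)
        assert p == pytest.approx(brute_force_tail(30, 170, 0, 200), rel=1e-9)
        assert p < 0.05

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            somatic_fisher_test(0, 0, 0, 0)

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scipy_one_sided(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = somatic_fisher_test(a, b, c, d)
        _, scipy_p = fisher_exact([[a, b], [c, d]], alternative="greater")
        assert ours == pytest.approx(scipy_p, rel=1e-9, abs=1e-12)


class TestFilterChain:
    def run_one(self, variant, n_fill=9, config=None):
        # fill patients keep the carrier fraction below the recurrence cutoff
        cohort = {"p0": [variant]}
        for i in range(n_fill):
            cohort[f"fill{i}"] = []
        return apply_filter_chain(cohort, config)["p0"][0]

    def test_passing_variant_kept(self):
        out = self.run_one(make_variant())
        assert out.kept and out.reason_codes == [] and out.error is None

    @pytest.mark.parametrize("override,reason", [
        (dict(func_class="synonymous_snv"), Reason.FUNC_CLASS),
        (dict(func_class="nonframeshift_indel"), Reason.FUNC_CLASS),
        (dict(tumor_alt_fwd=40, tumor_alt_rev=0), Reason.STRAND),
        (dict(tumor_alt_fwd=1, tumor_alt_rev=0, vaf=0.2), Reason.SUPPORT),
        (dict(depth=150), Reason.DEPTH),
        (dict(vaf=0.05), Reason.VAF),
        (dict(normal_alt=40, normal_ref=160), Reason.SOMATIC_P),
        (dict(dbsnp_id="rs123"), Reason.DBSNP),
    ])
    def test_single_rule_failures(self, override, reason):
        out = self.run_one(make_variant(**override))
        assert not out.kept
        assert reason in out.reason_codes

    def test_all_failures_recorded_no_short_circuit(self):
        v = make_variant(func_class="synonymous_snv", depth=100, vaf=0.05,
                         dbsnp_id="rs1")
        out = self.run_one(v)
        assert set(out.reason_codes) >= {
            Reason.FUNC_CLASS, Reason.DEPTH, Reason.VAF, Reason.DBSNP}

    def test_cosmic_exempts_dbsnp(self):
        out = self.run_one(make_variant(dbsnp_id="rs1", cosmic_id="COSM1"))
        assert out.kept

    def test_somatic_p_computed_from_counts_when_unset(self):
        # explicit somatic_p overrides count-based computation
        out = self.run_one(make_variant(somatic_p=0.2))
        assert Reason.SOMATIC_P in out.reason_codes

    def test_missing_inputs_yield_error_outcome(self):
        v = make_variant(tumor_alt_fwd=None, tumor_alt_rev=None)
        out = self.run_one(v)
        assert not out.kept and out.error is not None

    def test_recurrence_rule(self):
        key_fields = dict(chrom="chr2", pos=555, ref="G", alt="C", gene="KRAS")
        cohort = {}
        for i in range(10):
            variants = [make_variant()] if i >= 4 else [make_variant(**key_fields)]
            cohort[f"p{i}"] = variants
        out = apply_filter_chain(cohort)
        # 4/10 carriers > 30% -> removed in every carrier
        for i in range(4):
            o = out[f"p{i}"][0]
            assert not o.kept and o.reason_codes == [Reason.RECURRENT_NON_COSMIC]
        # the unrelated variant (6/10 carriers, also recurrent) is removed too
        assert not out["p5"][0].kept

    def test_recurrence_boundary_is_strict(self):
        # exactly 30% of 10 patients is NOT "more than 30%"
        cohort = {f"p{i}": [make_variant(pos=77)] if i < 3 else []
                  for i in range(10)}
        out = apply_filter_chain(cohort)
        assert all(o.kept for o in out["p0"])

    def test_recurrent_with_cosmic_kept(self):
        cohort = {f"p{i}": [make_variant(pos=88, cosmic_id="COSM9")]
                  for i in range(10)}
        out = apply_filter_chain(cohort)
        assert all(out[p][0].kept for p in cohort)

    def test_recurrence_counts_patient_once_despite_duplicates(self):
        # 3 carriers, one with a duplicate record: still 30%, not >30%
        cohort = {
            "p0": [make_variant(pos=99), make_variant(pos=99)],
            "p1": [make_variant(pos=99)],
            "p2": [make_variant(pos=99)],
        }
        cohort.update({f"p{i}": [] for i in range(3, 10)})
        out = apply_filter_chain(cohort)
        assert all(o.kept for o in out["p0"])


class TestMonotonicity:
    """Relaxing any single threshold never rejects a previously kept variant."""

    @given(
        alt_f=st.integers(0, 60), alt_r=st.integers(0, 60),
        ref_f=st.integers(0, 200), ref_r=st.integers(0, 200),
        normal_alt=st.integers(0, 30),
        dbsnp=st.booleans(), cosmic=st.booleans(),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_relaxed_config_keeps_superset(self, alt_f, alt_r, ref_f, ref_r,
                                           normal_alt, dbsnp, cosmic):
        depth = alt_f + alt_r + ref_f + ref_r
        if depth == 0:
            return
        v = AnnotatedVariant(
            chrom="chr1", pos=5, ref="A", alt="T", gene="TP53",
            func_class="nonsynonymous_snv",
            tumor_alt_fwd=alt_f, tumor_alt_rev=alt_r,
            tumor_ref_fwd=ref_f, tumor_ref_rev=ref_r,
            normal_alt=normal_alt, normal_ref=300,
            depth=depth, vaf=(alt_f + alt_r) / depth,
            dbsnp_id="rs1" if dbsnp else None,
            cosmic_id="COSM1" if cosmic else None,
        )
        strict = FilterConfig()
        relaxed = FilterConfig(min_supporting_reads=1, min_depth=50,
                               min_vaf=0.01, max_somatic_p=0.5,
                               recurrence_fraction=0.9)
        kept_strict = apply_filter_chain({"p": [v]}, strict)["p"][0].kept
        kept_relaxed = apply_filter_chain({"p": [v]}, relaxed)["p"][0].kept
        assert not kept_strict or kept_relaxed

    def test_cosmic_never_rejected_for_germline_reasons(self):
        v = make_variant(dbsnp_id="rs5", cosmic_id="COSM5")
        cohort = {f"p{i}": [make_variant(dbsnp_id="rs5", cosmic_id="COSM5")]
                  for i in range(10)}
        out = apply_filter_chain(cohort)
        for outs in out.values():
            for o in outs:
                assert Reason.DBSNP not in o.reason_codes
                assert Reason.RECURRENT_NON_COSMIC not in o.reason_codes


def test_multiallelic_decomposition():
    parts = decompose_multiallelic(
        "chr3", 42, "A", ["T", "G"],
        gene="KRAS", func_class="nonsynonymous_snv",
    )
    assert [p.alt for p in parts] == ["T", "G"]
    assert all(p.pos == 42 and p.ref == "A" for p in parts)
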