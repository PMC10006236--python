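"""Cascade filters: score classes, eQTL risk alleles, PWM impacts,
chromatin domains, and stage bookkeeping."""

import itertools

import numpy as np
import pytest

from cisreg import regulatory_cascade as rc
from cisreg import synthetic_data as sd
from cisreg.config import SimConfig
from cisreg.errors import InvalidAnnotationError, InvalidMotifError


class TestRegulomeRank:
    def test_total_order(self):
        ranks = [rc.regulome_rank(c) for c in rc.REGULOME_ORDER]
        assert ranks == sorted(ranks)
        assert rc.regulome_rank("1a") == 1

    @pytest.mark.parametrize("cls,kept", [
        ("1a", True), ("2b", True), ("4", True), ("5", False), ("6", False),
    ])
    def test_keep_rule(self, cls, kept):
        assert rc.regulome_keep(cls) is kept

    def test_unknown_class(self):
        with pytest.raises(InvalidAnnotationError):
            rc.regulome_rank("7")


def _ann(**kw):
    base = dict(rsid="rs1", gene="g", ref="C", alt="G")
    base.update(kw)
    return rc.SnvAnnotation(**base)


class TestEqtlRiskAllele:
    def test_negative_beta_with_down_gene_names_effect_allele(self):
        # a variant lowering expression of a gene that is itself lowered
        # in tumours: the effect allele is the risk allele
        ann = _ann(eqtl=[rc.EqtlEntry("Lung", "G", -0.39, 2.5e-28)])
        ok, allele = rc.eqtl_filter_and_risk_allele(ann, "down")
        assert ok and allele == "G"

    def test_positive_beta_with_up_gene(self):
        ann = _ann(ref="A", alt="T",
                   eqtl=[rc.EqtlEntry("Lung", "T", 0.5, 0.001)])
        ok, allele = rc.eqtl_filter_and_risk_allele(ann, "up")
        assert ok and allele == "T"

    def test_sign_mismatch_flips_to_other_allele(self):
        ann = _ann(eqtl=[rc.EqtlEntry("Lung", "G", 0.4, 0.001)])
        ok, allele = rc.eqtl_filter_and_risk_allele(ann, "down")
        assert ok and allele == "C"

    def test_conflicting_entries_ambiguous_and_dropped(self):
        ann = _ann(eqtl=[rc.EqtlEntry("Lung", "G", 0.3, 0.01),
                         rc.EqtlEntry("Lung", "G", -0.3, 0.01)])
        ok, allele = rc.eqtl_filter_and_risk_allele(ann, "down")
        assert not ok and allele == "ambiguous"

    def test_no_significant_entry_fails(self):
        ann = _ann(eqtl=[rc.EqtlEntry("Lung", "G", -0.3, 0.2)])
        assert rc.eqtl_filter_and_risk_allele(ann, "down") == (False, None)

    def test_other_tissue_ignored(self):
        ann = _ann(eqtl=[rc.EqtlEntry("Liver", "G", -0.3, 1e-10)])
        assert rc.eqtl_filter_and_risk_allele(ann, "down")[0] is False


def _consensus_pwm(motif):
    pwm = np.zeros((len(motif), 4))
    for i, b in enumerate(motif):
        pwm[i, "ACGT".index(b)] = 1.0
    return pwm


class TestPwmImpact:
    def test_uniform_pwm_is_neutral(self):
        pwm = np.full((4, 4), 0.25)
        imp = rc.pwm_impact_score("AAACATAA", "A", "G", pwm, snv_index=4)
        assert imp.score_ref == imp.score_alt
        assert imp.direction == "none"

    def test_consensus_completion_exact_p(self):
        # alt completes the 4-mer consensus: only 1 of 4^4 background
        # sequences reaches the perfect score
        pwm = _consensus_pwm("ACGT")
        imp = rc.pwm_impact_score("AAACATAA", "A", "G", pwm, snv_index=4)
        assert imp.p_impact == pytest.approx(0.25 ** 4, abs=0)
        assert imp.score_alt > imp.score_ref

    def test_consensus_destruction_is_loss(self):
        # long consensus so the match p-value clears the 0.001 cut
        motif = "ACGTACGT"
        pwm = _consensus_pwm(motif)
        ctx = "A" + motif + "A"  # SNV index 5 = the second 'A' of motif
        imp = rc.pwm_impact_score(ctx, ref="A", alt="C", pwm=pwm,
                                  snv_index=5)
        assert imp.direction == "loss"
        assert imp.p_impact == pytest.approx(0.25 ** 8, abs=0)

    def test_gain_direction_with_significant_match(self):
        motif = "ACGTACGT"
        pwm = _consensus_pwm(motif)
        ctx = "ACGTCCGTA"  # index 4 C -> A restores the consensus
        imp = rc.pwm_impact_score(ctx, ref="C", alt="A", pwm=pwm,
                                  snv_index=4)
        assert imp.direction == "gain"

    def test_zero_column_pwm_rejected(self):
        pwm = np.zeros((3, 4))
        with pytest.raises(InvalidMotifError):
            rc.pwm_impact_score("AAAA", "A", "C", pwm)

    @pytest.mark.parametrize("length,seed", [(3, 0), (4, 1), (5, 2), (6, 3)])
    def test_tail_probability_equals_brute_force(self, length, seed):
        # the DP over the discretized score grid must agree exactly with
        # enumeration of all 4^L sequences
        rng = np.random.default_rng(seed)
        pwm = rng.dirichlet(np.ones(4) * 0.4, size=length)
        bg = np.full(4, 0.25)
        q = rc._int_logodds(pwm, bg, 0.01)
        sentinel = np.iinfo(np.int64).min
        scores = []
        for seq in itertools.product(range(4), repeat=length):
            vals = [q[i, b] for i, b in enumerate(seq)]
            scores.append(None if sentinel in vals else sum(vals))
        for thr in (-500, -50, 0, 60, 400):
            brute = sum(0.25 ** length for s in scores
                        if s is not None and s >= thr)
            assert rc.score_distribution_tail(q, bg, thr) == \
                pytest.approx(brute, abs=1e-12)


class TestChromatinDomains:
    @pytest.mark.parametrize("label,expected", [
        ("Active TSS", "promoter"),
        ("Promoter Upstream of TSS", "promoter"),
        ("Promoter Downstream of TSS 1", "promoter"),
        ("Active Enhancer 1", "enhancer"),
        ("Primary H3K27ac possible Enhancer", "enhancer"),
        ("Weak Enhancer 2", "enhancer"),
        ("Quiescent", "repressed_or_insulator"),
        ("Heterochromatin", "repressed_or_insulator"),
        ("Primary DNase site", "repressed_or_insulator"),
    ])
    def test_classification(self, label, expected):
        assert rc.chromatin_domain_class(label) == expected

    def test_total_on_vocabulary(self):
        for label in rc.CHROMATIN_STATES:
            assert rc.chromatin_domain_class(label) in (
                "enhancer", "promoter", "repressed_or_insulator")

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            rc.chromatin_domain_class("Super Enhancer Deluxe!")


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(seed=13)
    tables = sd.gen_dhs_and_snvs(cfg)
    in_dhs = set(tables.snvs.loc[tables.snvs.fail_stage != "dhs", "rsid"])
    anns = rc.annotations_from_frame(tables.snvs, in_dhs_rsids=in_dhs)
    directions = {g: "down" for g in sd.gene_annotation(cfg).gene}
    return rc.run_cascade(anns, directions)


class TestRunCascade:
    def test_counts_non_increasing_and_nested(self, planted):
        state = planted.state
        counts = [state.counts[s] for s in state.stage_names]
        assert counts == sorted(counts, reverse=True)
        state.check_nested()  # raises on violation

    def test_exactly_planted_survive_eqtl_stage(self, planted):
        assert planted.state.counts["eqtl"] == 22
        survivors = {a.rsid for a in planted.survivors}
        assert survivors == {f"rs{900000 + i}" for i in range(22)}

    def test_promoter_shortlist_size(self, planted):
        assert sorted(planted.shortlist) == ["rs900000", "rs900001",
                                             "rs900002"]

    def test_risk_alleles_set_on_survivors(self, planted):
        for a in planted.survivors:
            assert a.risk_allele in (a.ref, a.alt)

    def test_all_null_annotations_shrink_to_zero(self):
        anns = [rc.SnvAnnotation(rsid=f"rs{i}", gene="g", ref="A", alt="G",
                                 pop_freq={"P": 0.2})
                for i in range(30)]
        res = rc.run_cascade(anns, {"g": "down"})
        assert res.state.counts["dhs"] == 0
        assert res.shortlist == set()


def test_bh_fdr_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.uniform(size=40)
    ours = rc.bh_fdr(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref)
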