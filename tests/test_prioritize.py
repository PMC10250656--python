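import itertools

import numpy as np
import pytest

from dytburden.classify import classify, effective_maf
from dytburden.exceptions import ValidationError
from dytburden.io import ExonicFunction as EF
from dytburden.io import Status
from dytburden.panel import GenePanel, Inheritance, PanelGene
from dytburden.prioritize import (
    AcmgClass,
    Model,
    acmg_classify,
    ad_candidates,
    ar_candidates,
    classify_findings,
    control_screen,
    load_acmg_config,
    predictor_support,
)

from conftest import make_annotation, make_cohort

PANEL = GenePanel(
    genes=[
        PanelGene("TH", Inheritance.AR),
        PanelGene("ANO3", Inheritance.AD),
        PanelGene("ADCY5", Inheritance.BOTH),
    ]
)


def _random_cohort(rng, n_samples, n_variants):
    genes = ["TH", "ANO3", "ADCY5", "OFFPANEL"]
    anns = []
    for j in range(n_variants):
        func = rng.choice([EF.MISSENSE, EF.STOPGAIN, EF.SYNONYMOUS], p=[0.6, 0.2, 0.2])
        anns.append(
            make_annotation(
                vid=f"chr1:{100 + j}:A:G",
                gene=str(rng.choice(genes)),
                func=func,
                reve=float(rng.uniform(0, 1)) if func is EF.MISSENSE else None,
                maf=(float(rng.choice([0.0, 0.0005, 0.002, 0.02])), None),
            )
        )
    dos = rng.choice([0.0, 1.0, 2.0, np.nan], size=(n_samples, n_variants),
                     p=[0.55, 0.25, 0.15, 0.05])
    n_cases = max(1, n_samples // 2)
    return make_cohort(dos, anns, n_cases=n_cases)


def _oracle_ar(cohort, panel):
    """Exhaustive enumeration of recessive findings."""
    out = set()
    rec_genes = {g.symbol for g in panel.recessive_genes()}
    for i, s in enumerate(cohort.samples):
        if s.status is not Status.CASE:
            continue
        for gene in rec_genes:
            qualifying = [
                j
                for j, v in enumerate(cohort.variants)
                if v.id in cohort.annotations
                and cohort.annotations[v.id].gene == gene
                and classify(cohort.annotations[v.id]).is_deleterious
                and effective_maf(cohort.annotations[v.id]) < 0.01
            ]
            for j in qualifying:
                if cohort.dosages[i, j] == 2.0:
                    out.add((s.sample_id, gene, "AR_hom", (cohort.variants[j].id,)))
            hets = [j for j in qualifying if cohort.dosages[i, j] == 1.0]
            for a, b in itertools.combinations(hets, 2):
                pair = tuple(sorted((cohort.variants[a].id, cohort.variants[b].id)))
                out.add((s.sample_id, gene, "AR_comphet", pair))
    return out


class TestArCandidates:
    def test_matches_exhaustive_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            cohort = _random_cohort(rng, int(rng.integers(4, 20)), int(rng.integers(5, 30)))
            got = {
                (f.sample_id, f.gene, f.model.value, tuple(sorted(f.variant_ids)))
                for f in ar_candidates(cohort, PANEL)
            }
            assert got == _oracle_ar(cohort, PANEL)

    def test_single_het_deleterious_yields_no_finding(self):
        ann = make_annotation(vid="chr1:100:A:G", gene="TH", reve=0.9, maf=(0.0, None))
        cohort = make_cohort([[1.0]], [ann])
        assert ar_candidates(cohort, PANEL) == []

    def test_three_hets_yield_three_pairs(self):
        anns = [
            make_annotation(vid=f"chr1:{100+j}:A:G", gene="TH", reve=0.9, maf=(0.0, None))
            for j in range(3)
        ]
        cohort = make_cohort([[1.0, 1.0, 1.0]], anns)
        findings = ar_candidates(cohort, PANEL)
        assert len(findings) == 3
        assert all(f.model is Model.AR_COMPHET for f in findings)

    def test_missing_dosage_is_non_carrier(self):
        ann = make_annotation(vid="chr1:100:A:G", gene="TH", reve=0.9, maf=(0.0, None))
        cohort = make_cohort([[np.nan], [2.0]], [ann])
        findings = ar_candidates(cohort, PANEL)
        assert [f.sample_id for f in findings] == ["S001"]


class TestAdCandidates:
    def test_stricter_maf_threshold_applies(self):
        # het deleterious at MAF 0.0021 passes the recessive filter but not
        # the dominant one
        ann = make_annotation(vid="chr1:100:A:G", gene="ANO3", reve=0.9, maf=(0.0021, 0.0012))
        cohort = make_cohort([[1.0]], [ann])
        assert ad_candidates(cohort, PANEL) == []

    def test_homozygote_not_reported_under_dominant_model(self):
        ann = make_annotation(vid="chr1:100:A:G", gene="ANO3", reve=0.9, maf=(0.0, None))
        cohort = make_cohort([[2.0]], [ann])
        assert ad_candidates(cohort, PANEL) == []

    def test_dual_inheritance_gene_screened_under_both_models(self):
        anns = [
            make_annotation(vid=f"chr1:{100+j}:A:G", gene="ADCY5", reve=0.9, maf=(0.0, None))
            for j in range(2)
        ]
        cohort = make_cohort([[1.0, 1.0]], anns)
        ar = ar_candidates(cohort, PANEL)
        ad = ad_candidates(cohort, PANEL)
        assert [f.model for f in ar] == [Model.AR_COMPHET]
        assert sorted(f.variant_ids[0] for f in ad) == [a.variant_id for a in anns]

    def test_no_finding_violates_its_maf_threshold_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            cohort = _random_cohort(rng, 12, 25)
            for f in ar_candidates(cohort, PANEL):
                assert all(
                    effective_maf(cohort.annotations[v]) < 0.01 for v in f.variant_ids
                )
            for f in ad_candidates(cohort, PANEL):
                assert effective_maf(cohort.annotations[f.variant_ids[0]]) < 0.001


class TestControlScreen:
    def _ad_finding_cohort(self, control_dosage):
        ann = make_annotation(vid="chr1:100:A:G", gene="ANO3", reve=0.9, maf=(0.0, None))
        cohort = make_cohort([[1.0], [control_dosage]], [ann], n_cases=1)
        findings = ad_candidates(cohort, PANEL)
        return control_screen(findings, cohort)

    def test_dominant_finding_screened_on_any_control_carrier(self):
        (f,) = self._ad_finding_cohort(1.0)
        assert f.screened_out and f.screen_reason == "control carrier"

    def test_dominant_finding_retained_without_control_carrier(self):
        (f,) = self._ad_finding_cohort(0.0)
        assert not f.screened_out

    def test_recessive_hom_retained_when_controls_are_het_only(self):
        ann = make_annotation(vid="chr1:100:A:G", gene="TH", reve=0.9, maf=(0.001, None))
        cohort = make_cohort([[2.0], [1.0]], [ann], n_cases=1)
        (f,) = control_screen(ar_candidates(cohort, PANEL), cohort)
        assert not f.screened_out
        cohort2 = make_cohort([[2.0], [2.0]], [ann], n_cases=1)
        (f2,) = control_screen(ar_candidates(cohort2, PANEL), cohort2)
        assert f2.screened_out and f2.screen_reason == "control biallelic"

    def test_comphet_screened_only_by_biallelic_control(self):
        anns = [
            make_annotation(vid=f"chr1:{100+j}:A:G", gene="TH", reve=0.9, maf=(0.0, None))
            for j in range(2)
        ]
        # control carries one member only: retained
        cohort = make_cohort([[1.0, 1.0], [1.0, 0.0]], anns, n_cases=1)
        (f,) = control_screen(ar_candidates(cohort, PANEL), cohort)
        assert not f.screened_out
        # control carries both members: screened
        cohort2 = make_cohort([[1.0, 1.0], [1.0, 1.0]], anns, n_cases=1)
        (f2,) = control_screen(ar_candidates(cohort2, PANEL), cohort2)
        assert f2.screened_out

    def test_no_controls_retains_everything(self):
        ann = make_annotation(vid="chr1:100:A:G", gene="ANO3", reve=0.9, maf=(0.0, None))
        cohort = make_cohort([[1.0]], [ann])
        (f,) = control_screen(ad_candidates(cohort, PANEL), cohort)
        assert not f.screened_out

    def test_screening_is_monotone_in_control_carriers(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cohort = _random_cohort(rng, 14, 20)
            findings = ar_candidates(cohort, PANEL) + ad_candidates(cohort, PANEL)
            base = control_screen([f for f in findings], cohort)
            screened_before = {id(f) for f in base if f.screened_out}
            # add a carrier of everything to the controls
            more = cohort.dosages.copy()
            more[-1, :] = 2.0
            cohort2 = make_cohort(
                more,
                list(cohort.annotations.values()),
                n_cases=sum(s.status is Status.CASE for s in cohort.samples),
            )
            for f in findings:
                f.screened_out, f.screen_reason = False, None
            after = control_screen(findings, cohort2)
            assert screened_before <= {id(f) for f in after if f.screened_out}


class TestPredictorSupport:
    def test_all_seven_damaging(self):
        calls = {k: "damaging" for k in
                 ("SIFT", "LRT", "MutationAssessor", "PolyPhen2-HVAR",
                  "PolyPhen2-HDIV", "MutationTaster")}
        ann = make_annotation(cadd=29.6, calls=calls)
        assert predictor_support(ann) == 7

    def test_all_missing_counts_zero(self):
        assert predictor_support(make_annotation()) == 0

    def test_cadd_threshold_is_configurable(self):
        calls = {k: "tolerated" for k in ("SIFT", "LRT")}
        ann = make_annotation(cadd=29.6, calls=calls)
        assert predictor_support(ann) == 1
        assert predictor_support(ann, cadd_damaging_min=30.0) == 0


class TestAcmg:
    def test_unknown_evidence_code_in_config_rejected(self, tmp_path):
        bad = tmp_path / "acmg.yaml"
        bad.write_text(
            "evidence:\n  PVS1: {rule: lof}\ncombining:\n  P:\n    - codes: [PVS9]\n"
        )
        with pytest.raises(ValidationError, match="PVS9"):
            load_acmg_config(bad)

    def test_unknown_rule_kind_rejected(self, tmp_path):
        bad = tmp_path / "acmg.yaml"
        bad.write_text("evidence:\n  PVS1: {rule: sorcery}\ncombining: {}\n")
        with pytest.raises(ValidationError, match="sorcery"):
            load_acmg_config(bad)

    def test_lof_allowlist_restricts_pvs1(self, table2_cohort, default_panel, tmp_path):
        cfg_text = (
            "evidence:\n"
            "  PVS1: {rule: lof, gene_allowlist: [TOR1A]}\n"
            "  PM2: {rule: absent}\n"
            "combining:\n  P:\n    - codes: [PVS1, PM2]\n"
        )
        p = tmp_path / "acmg.yaml"
        p.write_text(cfg_text)
        cfg = load_acmg_config(p)
        findings = ad_candidates(table2_cohort, default_panel)
        stopgain = next(f for f in findings if f.variant_ids == ["chr11:26621198:G:A"])
        assert acmg_classify(stopgain, table2_cohort, cfg) is AcmgClass.US

    def test_classification_is_order_independent(self, table2_cohort, default_panel):
        findings = ad_candidates(table2_cohort, default_panel)
        control_screen(findings, table2_cohort)
        fwd = [f.acmg for f in classify_findings(list(findings), table2_cohort)]
        for f in findings:
            f.acmg = None
        rev = list(reversed(
            [f.acmg for f in classify_findings(list(reversed(findings)), table2_cohort)]
        ))
        assert fwd == rev

    def test_novel_missense_stays_uncertain_under_recessive_model(
        self, table1_cohort, default_panel
    ):
        findings = ar_candidates(table1_cohort, default_panel)
        control_screen(findings, table1_cohort)
        classify_findings(findings, table1_cohort)
        comphet = [f for f in findings if not f.screened_out and f.model is Model.AR_COMPHET]
        assert comphet and all(f.acmg is AcmgClass.US for f in comphet)
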