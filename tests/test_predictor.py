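"""The four-condition rule-application engine."""

import itertools

import pytest

from pirsite import fixtures, matchio, profilehmm
from pirsite.matchio import SignatureMatch, TargetProtein
from pirsite.predictor import (PredictionResources, PredictorConfig,
                               ResourceError, check_scope, check_trigger,
                               evaluate_feature_group, map_template_position,
                               predict)
from pirsite.rulestore import TaxonomicScope


def bundle_proteins(bundle):
    proteins = matchio.parse_interproscan_xml(bundle.xml)
    matchio.attach_lineages(proteins, organism_map=bundle.organism_map)
    return proteins


def ft_keys(annotations):
    return {(a.protein_id, a.feature_key, a.target_from, a.target_to)
            for a in annotations if a.annotation_class == "FT"}


class TestTrigger:
    def rule(self, default_bundle):
        return default_bundle.rule

    def test_signature_accession_match(self, default_bundle):
        prot = TargetProtein("X", "MKT", matches=[
            SignatureMatch(default_bundle.spec.signature, locations=[(1, 3)])])
        assert check_trigger(prot, default_bundle.rule)

    def test_no_matches(self, default_bundle):
        assert not check_trigger(TargetProtein("X", "MKT"),
                                 default_bundle.rule)

    def test_interpro_accession_also_triggers(self, default_bundle):
        prot = TargetProtein("X", "MKT", matches=[
            SignatureMatch("PF00000",
                           interpro_accession=default_bundle.spec.signature)])
        assert check_trigger(prot, default_bundle.rule)


class TestScope:
    def test_include_hit(self):
        scope = TaxonomicScope(frozenset({"Eukaryota"}))
        assert check_scope(["Eukaryota", "Chordata"], scope)

    def test_include_miss(self):
        scope = TaxonomicScope(frozenset({"Eukaryota"}))
        assert not check_scope(["Bacteria"], scope)

    def test_exclusion_takes_precedence(self):
        scope = TaxonomicScope(frozenset({"Eukaryota"}), frozenset({"Fungi"}))
        assert not check_scope(["Eukaryota", "Fungi"], scope)

    def test_truth_table_enumeration(self):
        # oracle: (lineage ∩ include != ∅) and (lineage ∩ exclude == ∅)
        taxa = ["A", "B", "C"]
        scope = TaxonomicScope(frozenset({"A"}), frozenset({"B"}))
        for r in range(len(taxa) + 1):
            for lineage in itertools.combinations(taxa, r):
                expected = ("A" in lineage) and ("B" not in lineage)
                assert check_scope(list(lineage), scope) == expected, lineage

    def test_case_insensitive(self):
        scope = TaxonomicScope(frozenset({"Eukaryota"}))
        assert check_scope(["eukaryota"], scope)

    def test_missing_lineage_policy(self):
        scope = TaxonomicScope(frozenset({"Eukaryota"}))
        assert not check_scope(None, scope, require_scope=True)
        assert check_scope(None, scope, require_scope=False)
        assert check_scope(None, None)  # unscoped rules apply everywhere


@pytest.fixture(scope="module")
def site_hmm():
    # 8 conserved columns; enough signal to pin the alignment
    return profilehmm.build_profile(["ACDEFGHI"] * 5 + ["ACDEWGHI"],
                                    hmm_id="map8")


class TestPositionMapping:

    def test_identity_mapping(self, site_hmm):
        tpl = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        tgt = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        for pos in range(1, 9):
            assert map_template_position(tpl, tgt, pos) == pos

    def test_flanked_target_shifts_mapping(self, site_hmm):
        tpl = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        tgt = profilehmm.viterbi_align(site_hmm, "WWWACDEFGHI")
        assert map_template_position(tpl, tgt, 5) == 8

    def test_internal_insertion_shifts_downstream_positions(self, site_hmm):
        tpl = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        tgt = profilehmm.viterbi_align(site_hmm, "ACDEPPPFGHI")
        # independent expectation: pairwise alignment through the profile
        # puts target F (pos 8) at node 5, 3 residues downstream of template
        assert map_template_position(tpl, tgt, 5) == 8
        assert map_template_position(tpl, tgt, 2) == 2

    def test_deletion_at_site_node_unmapped(self, site_hmm):
        tpl = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        tgt = profilehmm.viterbi_align(site_hmm, "ACDEGHI")  # F deleted
        assert map_template_position(tpl, tgt, 5) is None
        assert map_template_position(tpl, tgt, 8) == 7

    def test_position_outside_template_alignment(self, site_hmm):
        tpl = profilehmm.viterbi_align(site_hmm, "ACDEFGHIKLM")  # KLM flank
        tgt = profilehmm.viterbi_align(site_hmm, "ACDEFGHI")
        assert map_template_position(tpl, tgt, 10) is None


class TestFeatureGroup:
    def test_conserved_site_annotated(self, clean_bundle):
        [prot] = [p for p in bundle_proteins(clean_bundle)
                  if p.protein_id == "TGT0001"]
        rule = clean_bundle.rule
        group = rule.feature_groups[0]
        tpl_aln = profilehmm.viterbi_align(clean_bundle.srhmm,
                                           clean_bundle.template_seq)
        anns, rejs = evaluate_feature_group(prot, rule, group,
                                            clean_bundle.srhmm, tpl_aln)
        assert rejs == []
        [ann] = anns
        assert ann.feature_key == "METAL"
        site = clean_bundle.spec.sites[0]
        assert ann.target_from == ann.target_to == site.position
        assert prot.sequence[ann.target_from - 1] == site.residue

    def test_glu_for_his_is_residue_mismatch(self, default_bundle):
        negatives = [m.member_id for m in default_bundle.members
                     if m.is_negative]
        prot = [p for p in bundle_proteins(default_bundle)
                if p.protein_id == negatives[0]][0]
        rule = default_bundle.rule
        tpl_aln = profilehmm.viterbi_align(default_bundle.srhmm,
                                           default_bundle.template_seq)
        anns, rejs = evaluate_feature_group(
            prot, rule, rule.feature_groups[0], default_bundle.srhmm, tpl_aln)
        assert anns == []
        assert [r.stage for r in rejs] == ["residue_mismatch"]

    def test_evalue_gate(self, default_bundle, rng):
        # a random sequence passes the trigger but not the SRHMM gate
        noise = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        prot = TargetProtein("NOISE1", noise, matches=[
            SignatureMatch(default_bundle.spec.signature,
                           locations=[(1, 80)])])
        rule = default_bundle.rule
        tpl_aln = profilehmm.viterbi_align(default_bundle.srhmm,
                                           default_bundle.template_seq)
        anns, rejs = evaluate_feature_group(
            prot, rule, rule.feature_groups[0], default_bundle.srhmm, tpl_aln)
        assert anns == []
        assert [r.stage for r in rejs] == ["srhmm_evalue"]


class TestPredict:
    def test_clean_family_counts(self, clean_bundle):
        # 5 conserved members, one rule with 1 FT + 1 KW + 1 CC
        anns, _ = predict(bundle_proteins(clean_bundle), [clean_bundle.rule],
                          fixtures.bundle_resources(clean_bundle))
        by_class = {}
        for a in anns:
            by_class.setdefault(a.annotation_class, []).append(a)
        assert len(by_class["FT"]) == 5
        assert len(by_class["KW"]) == 5
        assert len(by_class["CC"]) == 5
        assert ft_keys(anns) == clean_bundle.expected_annotation_keys()

    def test_zero_rules(self, clean_bundle):
        anns, rejs = predict(bundle_proteins(clean_bundle), [],
                             PredictionResources())
        assert anns == [] and rejs == []

    def test_scope_gate_isolation(self, clean_bundle):
        perturbed = fixtures.perturb_lineages(clean_bundle, 0.4, seed=5)
        anns, rejs = predict(bundle_proteins(perturbed), [perturbed.rule],
                             fixtures.bundle_resources(perturbed))
        out_ids = {m.member_id for m in perturbed.members
                   if tuple(m.lineage) ==
                   tuple(perturbed.spec.out_of_scope_lineage)}
        assert len(out_ids) == 2  # round(0.4 * 5)
        for pid in out_ids:
            stages = {r.stage for r in rejs if r.protein_id == pid}
            assert stages == {"scope"}
            assert not any(a.protein_id == pid for a in anns)
        assert ft_keys(anns) == perturbed.expected_annotation_keys()

    def test_trigger_failure_never_reaches_later_stages(self, clean_bundle):
        proteins = bundle_proteins(clean_bundle)
        for p in proteins:
            p.matches = []  # no signatures at all
        anns, rejs = predict(proteins, [clean_bundle.rule],
                             fixtures.bundle_resources(clean_bundle))
        assert anns == []
        assert {r.stage for r in rejs} == {"trigger"}

    def test_monotone_evalue_gate(self, default_bundle):
        proteins = bundle_proteins(default_bundle)
        resources = fixtures.bundle_resources(default_bundle)
        counts = []
        for cutoff in (1.0, 1e-4, 1e-30, 1e-200):
            anns, _ = predict(proteins, [default_bundle.rule], resources,
                              PredictorConfig(evalue_cutoff_override=cutoff))
            counts.append(len(anns))
        assert counts == sorted(counts, reverse=True)

    def test_soundness_recheckable_post_hoc(self, default_bundle):
        proteins = bundle_proteins(default_bundle)
        anns, _ = predict(proteins, [default_bundle.rule],
                          fixtures.bundle_resources(default_bundle))
        seqs = {p.protein_id: p.sequence for p in proteins}
        allowed = {ft.feature_key: ft.allowed_residues
                   for g in default_bundle.rule.feature_groups
                   for ft in g.features}
        for ann in anns:
            if ann.annotation_class != "FT":
                continue
            groups = allowed[ann.feature_key]
            assert seqs[ann.protein_id][ann.target_from - 1] in groups[0]
            assert seqs[ann.protein_id][ann.target_to - 1] in groups[-1]

    def test_kw_cc_require_at_least_one_ft(self, default_bundle):
        anns, _ = predict(bundle_proteins(default_bundle),
                          [default_bundle.rule],
                          fixtures.bundle_resources(default_bundle))
        ft_proteins = {a.protein_id for a in anns
                       if a.annotation_class == "FT"}
        other_proteins = {a.protein_id for a in anns
                          if a.annotation_class in ("KW", "CC")}
        assert other_proteins <= ft_proteins
        negatives = {m.member_id for m in default_bundle.members
                     if m.is_negative}
        assert not (other_proteins & negatives)

    def test_output_deterministically_ordered(self, default_bundle):
        proteins = bundle_proteins(default_bundle)
        resources = fixtures.bundle_resources(default_bundle)
        a1, _ = predict(proteins, [default_bundle.rule], resources)
        a2, _ = predict(list(reversed(proteins)), [default_bundle.rule],
                        resources)
        assert a1 == a2
        assert a1 == sorted(a1, key=lambda a: a.sort_key)

    def test_unresolvable_resources_fail_before_prediction(self, clean_bundle):
        with pytest.raises(ResourceError, match="SRHMM"):
            predict(bundle_proteins(clean_bundle), [clean_bundle.rule],
                    PredictionResources(templates={
                        clean_bundle.spec.template_accession:
                        clean_bundle.template_seq}))

    def test_uncalibrated_srhmm_rejected(self, clean_bundle):
        import copy

        res = fixtures.bundle_resources(clean_bundle)
        hmm = copy.deepcopy(res.hmms[clean_bundle.srhmm.hmm_id])
        hmm.calibration = None
        res.hmms[hmm.hmm_id] = hmm
        with pytest.raises(ResourceError, match="calibrated"):
            predict(bundle_proteins(clean_bundle), [clean_bundle.rule], res)
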