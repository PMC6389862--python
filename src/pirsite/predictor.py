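"""The rule-application engine.

For every (target protein, rule) pair, four conditions are evaluated in
order:

1. *trigger* — the target must carry the rule's family signature (PIRSF or
   InterPro accession) among its InterProScan matches;
2. *scope* — the target organism's lineage must fall inside the rule's
   taxonomic scope (exclusion beats inclusion; rules without a scope block
   apply everywhere);
3. *SRHMM e-value* — the target must align to the feature group's
   site-specific profile HMM with an e-value at or below the gate
   (default 1e-4);
4. *site residue* — the target and the curated template are both aligned to
   the SRHMM; a feature is propagated only when every checked template
   position maps through match states to a target position whose residue is
   among the allowed amino acids.

Keywords and comments attach once per (protein, rule) pair when at least one
feature annotation was emitted.  Rejections at each stage are recorded, so
the gates are independently observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .matchio import TargetProtein
from .profilehmm import HmmAlignment, ProfileHMM, score_to_evalue, viterbi_align
from .rulestore import FEATURE_KEYS, FeatureGroup, SiteRule

REJECTION_STAGES = ("trigger", "scope", "srhmm_evalue",
                    "position_unmapped", "residue_mismatch")

_CLASS_RANK = {"FT": 0, "KW": 1, "CC": 2}


class ResourceError(ValueError):
    """A rule references an SRHMM or template that cannot be resolved."""


@dataclass
class PredictorConfig:
    evalue_cutoff_override: float | None = None
    require_scope: bool = True    # skip scoped rules when lineage missing
    dedupe: bool = True
    keep_trigger_rejections: bool = True

    def __post_init__(self):
        if self.evalue_cutoff_override is not None \
                and not self.evalue_cutoff_override > 0:
            raise ValueError("e-value cutoff override must be positive")


@dataclass(frozen=True)
class PredictedAnnotation:
    protein_id: str
    rule_id: str
    annotation_class: str  # FT | KW | CC
    nucleotide_id: str | None = None
    feature_key: str | None = None
    target_from: int | None = None
    target_to: int | None = None
    description: str = ""
    evidence: str = ""

    def __post_init__(self):
        if self.annotation_class not in _CLASS_RANK:
            raise ValueError(f"bad annotation class {self.annotation_class!r}")
        if self.annotation_class == "FT":
            if self.feature_key not in FEATURE_KEYS:
                raise ValueError(f"bad feature key {self.feature_key!r}")
            if not (self.target_from and self.target_to
                    and 1 <= self.target_from <= self.target_to):
                raise ValueError(
                    f"bad feature coordinates "
                    f"{self.target_from}..{self.target_to}")

    @property
    def sort_key(self):
        return (self.protein_id, self.rule_id,
                _CLASS_RANK[self.annotation_class],
                self.target_from or 0, self.target_to or 0,
                self.feature_key or "", self.description)

    @property
    def dedupe_key(self):
        return (self.protein_id, self.annotation_class, self.feature_key,
                self.target_from, self.target_to, self.description)


@dataclass(frozen=True)
class RejectionRecord:
    protein_id: str
    rule_id: str
    stage: str
    detail: str = ""

    def __post_init__(self):
        if self.stage not in REJECTION_STAGES:
            raise ValueError(f"unknown rejection stage {self.stage!r}")


@dataclass
class PredictionResources:
    """SRHMMs and template sequences the rules refer to."""

    hmms: dict[str, ProfileHMM] = field(default_factory=dict)
    templates: dict[str, str] = field(default_factory=dict)

    def check(self, rules: list[SiteRule]) -> None:
        missing = []
        for rule in rules:
            if rule.template_accession not in self.templates:
                missing.append(
                    f"{rule.rule_id}: template {rule.template_accession!r}")
            for group in rule.feature_groups:
                if group.srhmm_id not in self.hmms:
                    missing.append(
                        f"{rule.rule_id}: SRHMM {group.srhmm_id!r}")
                elif self.hmms[group.srhmm_id].calibration is None:
                    missing.append(
                        f"{rule.rule_id}: SRHMM {group.srhmm_id!r} is not "
                        "calibrated")
        if missing:
            raise ResourceError("unresolvable resources: " + "; ".join(missing))


def check_trigger(protein: TargetProtein, rule: SiteRule) -> bool:
    """True iff any signature or InterPro accession equals the rule trigger."""
    for m in protein.matches:
        if m.signature_accession == rule.trigger:
            return True
        if m.interpro_accession and m.interpro_accession == rule.trigger:
            return True
    return False


def check_scope(lineage: list[str] | None, scope, *,
                require_scope: bool = True) -> bool:
    """Taxonomic scope gate; case-insensitive, exclusion takes precedence."""
    if scope is None:
        return True
    if lineage is None:
        return not require_scope
    names = {t.lower() for t in lineage}
    if names & {t.lower() for t in scope.exclude}:
        return False
    return bool(names & {t.lower() for t in scope.include})


def map_template_position(template_aln: HmmAlignment,
                          target_aln: HmmAlignment,
                          template_pos: int) -> int | None:
    """Map a 1-based template position to the target through the profile.

    Finds the match node the template position aligns to, then the target
    position aligned to the same node.  Returns None when the template
    position is unaligned or sits in an insert state, or when the target
    path passes that node with a delete.
    """
    located = template_aln.node_of_position(template_pos)
    if located is None:
        return None
    kind, node = located
    if kind != "M":
        return None  # curation drift: template site on an insert state
    return target_aln.match_position(node)


def evaluate_feature_group(protein: TargetProtein, rule: SiteRule,
                           group: FeatureGroup, srhmm: ProfileHMM,
                           template_aln: HmmAlignment,
                           config: PredictorConfig | None = None,
                           target_aln: HmmAlignment | None = None,
                           ) -> tuple[list[PredictedAnnotation],
                                      list[RejectionRecord]]:
    """Apply one feature group (conditions 3 and 4) to one target protein.

    ``template_aln`` is the template's alignment to the SRHMM (computed once
    per rule/SRHMM and cached by :func:`predict`).  Returns the emitted
    feature annotations and any rejection records.
    """
    config = config or PredictorConfig()
    cutoff = (config.evalue_cutoff_override
              if config.evalue_cutoff_override is not None
              else group.evalue_cutoff)
    if target_aln is None:
        target_aln = viterbi_align(srhmm, protein.sequence,
                                   sequence_id=protein.protein_id)
    evalue = score_to_evalue(target_aln.bit_score, srhmm.calibration)
    if evalue > cutoff:
        return [], [RejectionRecord(
            protein.protein_id, rule.rule_id, "srhmm_evalue",
            f"group {group.group_id}: e-value {evalue:.3g} > {cutoff:g}")]

    annotations: list[PredictedAnnotation] = []
    rejections: list[RejectionRecord] = []
    for ft in group.features:
        mapped: list[int | None] = [
            map_template_position(template_aln, target_aln, pos)
            for pos in ft.checked_positions]
        if any(p is None for p in mapped) or \
                (len(mapped) == 2 and mapped[0] > mapped[1]):
            rejections.append(RejectionRecord(
                protein.protein_id, rule.rule_id, "position_unmapped",
                f"group {group.group_id} {ft.feature_key} "
                f"{ft.template_from}..{ft.template_to}: template position "
                "does not map to the target"))
            continue
        residues = [protein.sequence[p - 1] for p in mapped]
        bad = [(pos, res) for pos, res, allowed
               in zip(mapped, residues, ft.allowed_residues)
               if res not in allowed]
        if bad:
            detail = ", ".join(
                f"target {pos} has {res!r}" for pos, res in bad)
            rejections.append(RejectionRecord(
                protein.protein_id, rule.rule_id, "residue_mismatch",
                f"group {group.group_id} {ft.feature_key} "
                f"{ft.template_from}..{ft.template_to}: {detail}"))
            continue
        annotations.append(PredictedAnnotation(
            protein_id=protein.protein_id,
            nucleotide_id=protein.nucleotide_id,
            rule_id=rule.rule_id,
            annotation_class="FT",
            feature_key=ft.feature_key,
            target_from=mapped[0],
            target_to=mapped[-1],
            description=ft.description,
            evidence=ft.evidence))
    return annotations, rejections


def predict(proteins: list[TargetProtein], rules: list[SiteRule],
            resources: PredictionResources,
            config: PredictorConfig | None = None,
            ) -> tuple[list[PredictedAnnotation], list[RejectionRecord]]:
    """Apply every rule to every target protein.

    Conditions are checked in order (trigger, scope, per-group SRHMM
    e-value, residue identity); keywords and comments attach once per
    (protein, rule) pair iff at least one feature annotation was emitted.
    Output is deduplicated and deterministically ordered by
    (protein_id, rule_id, class, target_from).
    """
    config = config or PredictorConfig()
    resources.check(rules)

    template_cache: dict[tuple[str, str], HmmAlignment] = {}

    def template_alignment(rule: SiteRule, group: FeatureGroup) -> HmmAlignment:
        key = (group.srhmm_id, rule.template_accession)
        if key not in template_cache:
            template_cache[key] = viterbi_align(
                resources.hmms[group.srhmm_id],
                resources.templates[rule.template_accession],
                sequence_id=rule.template_accession)
        return template_cache[key]

    annotations: list[PredictedAnnotation] = []
    rejections: list[RejectionRecord] = []

    for protein in proteins:
        if not protein.sequence:
            raise ResourceError(
                f"protein {protein.protein_id} has no sequence; supply a "
                "side FASTA")
        target_cache: dict[str, HmmAlignment] = {}
        for rule in rules:
            if not check_trigger(protein, rule):
                if config.keep_trigger_rejections:
                    rejections.append(RejectionRecord(
                        protein.protein_id, rule.rule_id, "trigger",
                        f"no match for trigger {rule.trigger}"))
                continue
            if not check_scope(protein.lineage, rule.scope,
                               require_scope=config.require_scope):
                rejections.append(RejectionRecord(
                    protein.protein_id, rule.rule_id, "scope",
                    "organism lineage outside the rule's taxonomic scope"
                    if protein.lineage is not None
                    else "no lineage supplied for a scoped rule"))
                continue
            pair_fts: list[PredictedAnnotation] = []
            for group in rule.feature_groups:
                srhmm = resources.hmms[group.srhmm_id]
                if group.srhmm_id not in target_cache:
                    target_cache[group.srhmm_id] = viterbi_align(
                        srhmm, protein.sequence,
                        sequence_id=protein.protein_id)
                fts, rejs = evaluate_feature_group(
                    protein, rule, group, srhmm,
                    template_alignment(rule, group), config,
                    target_aln=target_cache[group.srhmm_id])
                pair_fts.extend(fts)
                rejections.extend(rejs)
            annotations.extend(pair_fts)
            if pair_fts:
                for kw in rule.keywords:
                    annotations.append(PredictedAnnotation(
                        protein_id=protein.protein_id,
                        nucleotide_id=protein.nucleotide_id,
                        rule_id=rule.rule_id, annotation_class="KW",
                        description=kw))
                for cc in rule.comments:
                    annotations.append(PredictedAnnotation(
                        protein_id=protein.protein_id,
                        nucleotide_id=protein.nucleotide_id,
                        rule_id=rule.rule_id, annotation_class="CC",
                        description=cc))

    if config.dedupe:
        seen = set()
        unique = []
        for ann in annotations:
            if ann.dedupe_key not in seen:
                seen.add(ann.dedupe_key)
                unique.append(ann)
        annotations = unique
    annotations.sort(key=lambda a: a.sort_key)
    return annotations, rejections
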