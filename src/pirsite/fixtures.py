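"""Seeded synthetic protein families with planted functional sites.

The generator emulates the curation inputs of a site rule: a template
protein with experimentally characterized residues, family members derived
from it by point mutations and short indels (never touching the planted
sites, except in members designated as negatives, whose site residue is
mutated outside the allowed set), the true multiple alignment, the rule
flat file, the site-specific profile HMM built and calibrated from the
alignment, the members' family-signature matches as InterProScan XML, and
reference annotations.  A ground-truth table records exactly which
(member, site) pairs must be annotated and why the others must be rejected,
so the whole prediction pipeline is testable end to end with no downloads.

Everything is a pure function of the spec's seed: the same spec yields a
byte-identical bundle.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace

import numpy as np

from . import profilehmm, rulestore
from .matchio import write_fasta
from .profilehmm import ProfileHMM, build_profile, calibrate, extract_site_blocks
from .rulestore import (AMINO_ACIDS, FeatureGroup, FeatureTemplate, SiteRule,
                        TaxonomicScope, serialize_rule)

IPS5_NS = "http://www.ebi.ac.uk/interpro/resources/schemas/interproscan5"


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    """One planted site: a conserved residue at a template position."""

    position: int                  # 1-based on the template
    residue: str
    feature_key: str = "METAL"
    description: str = "Iron (heme axial ligand)"
    evidence: str = "ECO:0000256"


@dataclass
class FamilySpec:
    seed: int = 0
    template_length: int = 120
    n_members: int = 8
    sites: tuple[SiteSpec, ...] = (SiteSpec(position=60, residue="H"),)
    mutation_rate: float = 0.05
    indel_rate: float = 0.02
    negative_fraction: float = 0.0
    flank: int = 10
    lineage: tuple[str, ...] = ("Eukaryota", "Metazoa", "Chordata")
    out_of_scope_lineage: tuple[str, ...] = ("Bacteria",)
    scope_include: tuple[str, ...] = ("Eukaryota",)
    scope_exclude: tuple[str, ...] = ()
    signature: str = "PIRSF900001"
    interpro: str = "IPR900001"
    rule_id: str = "PIRSR900001-1"
    template_accession: str = "TPL001"
    keywords: tuple[str, ...] = ("Heme",)
    comments: tuple[str, ...] = ("-!- COFACTOR: Binds 1 heme group.",)
    calibration_n: int = 100

    def validate(self) -> None:
        if self.template_length < 10:
            raise GenerationError("template too short")
        if self.n_members < 1:
            raise GenerationError("need at least one member")
        for rate in (self.mutation_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise GenerationError("rates must lie in [0, 1)")
        if not 0 <= self.negative_fraction <= 1:
            raise GenerationError("negative fraction must lie in [0, 1]")
        if not self.sites:
            raise GenerationError("at least one site required")
        for s in self.sites:
            if not 1 <= s.position <= self.template_length:
                raise GenerationError(
                    f"site position {s.position} outside template")
            if len(s.residue) != 1 or s.residue not in AMINO_ACIDS:
                raise GenerationError(
                    f"site residue must be one standard amino acid, "
                    f"got {s.residue!r}")
        if len({s.position for s in self.sites}) != len(self.sites):
            raise GenerationError("duplicate site positions")


@dataclass(frozen=True)
class GroundTruthEntry:
    member_id: str
    feature_key: str
    template_pos: int           # 1-based
    member_pos: int | None      # 1-based, None when not annotatable
    outcome: str                # annotated | residue_mismatch | scope


@dataclass
class MemberRecord:
    member_id: str
    sequence: str
    lineage: tuple[str, ...]
    is_negative: bool
    site_map: dict[int, int]    # template pos (1-based) -> member pos


@dataclass
class FamilyBundle:
    spec: FamilySpec
    template_seq: str
    members: list[MemberRecord]
    msa: list[tuple[str, str]]
    rule: SiteRule
    rule_text: str
    srhmm: ProfileHMM
    template_fasta: str
    member_fasta: str
    xml: str
    reference_rows: list[tuple]
    ground_truth: list[GroundTruthEntry]

    @property
    def organism_map(self) -> dict[str, list[str]]:
        return {m.member_id: list(m.lineage) for m in self.members}

    def expected_annotation_keys(self) -> set[tuple[str, str, int, int]]:
        """(protein, key, from, to) set the predictor must reproduce."""
        return {(e.member_id, e.feature_key, e.member_pos, e.member_pos)
                for e in self.ground_truth if e.outcome == "annotated"}

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "template.fasta").write_text(self.template_fasta)
        (out / "members.fasta").write_text(self.member_fasta)
        (out / "msa.afa").write_text(
            "".join(f">{sid}\n{row}\n" for sid, row in self.msa))
        (out / "rules.uru").write_text(self.rule_text)
        hmm_dir = out / "hmms"
        hmm_dir.mkdir(exist_ok=True)
        (hmm_dir / f"{self.srhmm.hmm_id}.hmm").write_text(
            profilehmm.write_profile(self.srhmm))
        (out / "interproscan.xml").write_text(self.xml)
        from .evaluation import write_reference_tsv

        (out / "reference.tsv").write_text(
            write_reference_tsv(self.reference_rows))
        (out / "organisms.tsv").write_text("".join(
            f"{m.member_id}\t{'; '.join(m.lineage)}\n" for m in self.members))
        (out / "ground_truth.tsv").write_text("".join(
            f"{e.member_id}\t{e.feature_key}\t{e.template_pos}\t"
            f"{e.member_pos if e.member_pos is not None else '.'}\t"
            f"{e.outcome}\n" for e in self.ground_truth))


def _random_sequence(rng, length: int) -> list[str]:
    aas = list(AMINO_ACIDS)
    return [aas[i] for i in rng.integers(0, 20, size=length)]


def _other_residue(rng, residue: str) -> str:
    alternatives = [a for a in AMINO_ACIDS if a != residue]
    return alternatives[rng.integers(0, len(alternatives))]


def _geometric_capped(rng, p: float = 0.5, cap: int = 3) -> int:
    return min(int(rng.geometric(p)), cap)


def generate_family(spec: FamilySpec) -> FamilyBundle:
    """Generate one internally consistent family bundle from a seeded spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.template_length
    site_pos0 = {s.position - 1: s for s in spec.sites}

    template = _random_sequence(rng, L)
    for p0, site in site_pos0.items():
        template[p0] = site.residue
    template_seq = "".join(template)

    n_neg = int(round(spec.negative_fraction * spec.n_members))
    negatives = set(rng.choice(spec.n_members, size=n_neg, replace=False)
                    ) if n_neg else set()

    members: list[MemberRecord] = []
    edits = []  # (sub, deleted, ins) per member, template coordinates
    for m in range(spec.n_members):
        is_neg = m in negatives
        sub: dict[int, str] = {}
        deleted: set[int] = set()
        ins: dict[int, str] = {}
        for i in range(L):
            if i in site_pos0:
                if is_neg:
                    sub[i] = _other_residue(rng, site_pos0[i].residue)
            elif rng.random() < spec.mutation_rate:
                sub[i] = _other_residue(rng, template[i])
        for i in range(L):
            if rng.random() < spec.indel_rate:
                g = _geometric_capped(rng)
                if rng.random() < 0.5:
                    # deletion, never removing a planted site position
                    for j in range(i, min(i + g, L)):
                        if j in site_pos0:
                            break
                        deleted.add(j)
                else:
                    ins[i] = "".join(_random_sequence(rng, g))
        seq_chars: list[str] = []
        site_map: dict[int, int] = {}
        for i in range(L):
            if i not in deleted:
                seq_chars.append(sub.get(i, template[i]))
                if i in site_pos0:
                    site_map[i + 1] = len(seq_chars)
            if i in ins:
                seq_chars.extend(ins[i])
        members.append(MemberRecord(
            member_id=f"TGT{m + 1:04d}",
            sequence="".join(seq_chars),
            lineage=spec.lineage,
            is_negative=is_neg,
            site_map=site_map))
        edits.append((sub, deleted, ins))

    # true alignment: one column per template position, plus insertion
    # blocks sized to the longest insertion at each position
    maxins = [0] * L
    for _sub, _deleted, ins in edits:
        for i, text in ins.items():
            maxins[i] = max(maxins[i], len(text))
    msa: list[tuple[str, str]] = []
    tpl_row = []
    for i in range(L):
        tpl_row.append(template[i])
        tpl_row.append("-" * maxins[i])
    msa.append((spec.template_accession, "".join(tpl_row)))
    for m, (sub, deleted, ins) in enumerate(edits):
        row = []
        for i in range(L):
            row.append("-" if i in deleted else sub.get(i, template[i]))
            text = ins.get(i, "")
            row.append(text + "-" * (maxins[i] - len(text)))
        msa.append((members[m].member_id, "".join(row)))

    msa_col_of_pos = {}
    col = 0
    for i in range(L):
        msa_col_of_pos[i] = col
        col += 1 + maxins[i]
    site_cols = {msa_col_of_pos[p0] for p0 in site_pos0}

    sub_rows, _block_spec = extract_site_blocks(
        [row for _sid, row in msa], site_cols, spec.flank)
    srhmm = build_profile(sub_rows, gap_threshold=0.5, pseudocount_weight=1.0,
                          hmm_id=spec.rule_id)
    srhmm.calibration = calibrate(
        srhmm, n=spec.calibration_n,
        seed=(spec.seed * 9973 + 17) % (2 ** 31))

    features = tuple(
        FeatureTemplate(
            feature_key=s.feature_key,
            template_from=s.position, template_to=s.position,
            allowed_residues=(frozenset(s.residue),),
            description=s.description, evidence=s.evidence)
        for s in sorted(spec.sites, key=lambda s: s.position))
    rule = SiteRule(
        rule_id=spec.rule_id,
        trigger=spec.signature,
        template_accession=spec.template_accession,
        feature_groups=(FeatureGroup(group_id=1, srhmm_id=spec.rule_id,
                                     features=features),),
        scope=TaxonomicScope(frozenset(spec.scope_include),
                             frozenset(spec.scope_exclude)),
        keywords=spec.keywords,
        comments=spec.comments)
    rule_text = serialize_rule(rule)

    xml = _interproscan_xml(members, spec)

    reference_rows = []
    ground_truth = []
    for member in members:
        for s in sorted(spec.sites, key=lambda s: s.position):
            pos = member.site_map[s.position]
            if member.is_negative:
                ground_truth.append(GroundTruthEntry(
                    member.member_id, s.feature_key, s.position, None,
                    "residue_mismatch"))
            else:
                reference_rows.append((member.member_id, s.feature_key,
                                       pos, pos, s.description))
                ground_truth.append(GroundTruthEntry(
                    member.member_id, s.feature_key, s.position, pos,
                    "annotated"))

    return FamilyBundle(
        spec=spec,
        template_seq=template_seq,
        members=members,
        msa=msa,
        rule=rule,
        rule_text=rule_text,
        srhmm=srhmm,
        template_fasta=write_fasta({spec.template_accession: template_seq}),
        member_fasta=write_fasta(
            {m.member_id: m.sequence for m in members}),
        xml=xml,
        reference_rows=reference_rows,
        ground_truth=ground_truth)


def _interproscan_xml(members, spec: FamilySpec) -> str:
    root = ET.Element("protein-matches", {"xmlns": IPS5_NS})
    for member in members:
        prot = ET.SubElement(root, "protein")
        seq_el = ET.SubElement(prot, "sequence")
        seq_el.text = member.sequence
        ET.SubElement(prot, "xref", {"id": member.member_id,
                                     "name": member.member_id})
        matches = ET.SubElement(prot, "matches")
        match = ET.SubElement(matches, "hmmer3-match")
        sig = ET.SubElement(match, "signature", {"ac": spec.signature,
                                                 "name": "synthetic family"})
        ET.SubElement(sig, "entry", {"ac": spec.interpro,
                                     "type": "FAMILY"})
        locs = ET.SubElement(match, "locations")
        ET.SubElement(locs, "hmmer3-location",
                      {"start": "1", "end": str(len(member.sequence))})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def perturb_lineages(bundle: FamilyBundle, out_of_scope_fraction: float,
                     seed: int) -> FamilyBundle:
    """Move a fraction of members outside the rule's taxonomic scope.

    Exactly ``round(fraction * n)`` members (seeded choice, no replacement)
    are reassigned the spec's out-of-scope lineage; the ground truth is
    updated to expect a scope rejection for each of them.
    """
    if not 0 <= out_of_scope_fraction <= 1:
        raise GenerationError("fraction must lie in [0, 1]")
    new = copy.deepcopy(bundle)
    n = len(new.members)
    k = int(round(out_of_scope_fraction * n))
    if k == 0:
        return new
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False))
    moved_ids = set()
    for idx in chosen:
        member = new.members[idx]
        member.lineage = tuple(new.spec.out_of_scope_lineage)
        moved_ids.add(member.member_id)
    new.ground_truth = [
        replace(e, member_pos=None, outcome="scope")
        if e.member_id in moved_ids else e
        for e in new.ground_truth]
    return new


def random_rule(rng, index: int = 1) -> SiteRule:
    """One structurally valid random rule (for round-trip exercising)."""
    keys = sorted(rulestore.FEATURE_KEYS)
    aas = list(AMINO_ACIDS)

    def _residue_group():
        k = int(rng.integers(1, 4))
        return frozenset(rng.choice(aas, size=k, replace=False))

    def _text(n):
        alphabet = list("abcdefghij XYZ()-;\"',.")
        return "".join(rng.choice(alphabet, size=n)).strip() or "site"

    groups = []
    for gid in range(1, int(rng.integers(1, 4)) + 1):
        features = []
        for _ in range(int(rng.integers(1, 4))):
            key = keys[int(rng.integers(0, len(keys)))]
            start = int(rng.integers(1, 200))
            if rng.random() < 0.5:
                stop, residues = start, (_residue_group(),)
            else:
                stop = start + int(rng.integers(1, 30))
                residues = (_residue_group(), _residue_group())
            features.append(FeatureTemplate(
                feature_key=key, template_from=start, template_to=stop,
                allowed_residues=residues,
                description=_text(int(rng.integers(1, 25))),
                evidence="ECO:%07d" % int(rng.integers(0, 10 ** 7))
                if rng.random() < 0.8 else ""))
        groups.append(FeatureGroup(
            group_id=gid, srhmm_id=f"PIRSR{index:06d}-{gid}",
            evalue_cutoff=float(10.0 ** -rng.integers(2, 9)),
            features=tuple(features)))
    taxa = ["Eukaryota", "Bacteria", "Archaea", "Metazoa", "Fungi",
            "Viridiplantae", "Chordata"]
    scope = None
    if rng.random() < 0.7:
        include = set(rng.choice(taxa, size=int(rng.integers(1, 3)),
                                 replace=False))
        exclude = set(t for t in rng.choice(taxa, size=int(rng.integers(0, 2)),
                                            replace=False)
                      if t not in include)
        scope = TaxonomicScope(frozenset(include), frozenset(exclude))
    return SiteRule(
        rule_id=f"PIRSR{index:06d}-1",
        trigger=f"PIRSF{int(rng.integers(0, 10**6)):06d}",
        template_accession="P%05d" % int(rng.integers(0, 10 ** 5)),
        feature_groups=tuple(groups),
        scope=scope,
        keywords=tuple(_text(int(rng.integers(3, 12)))
                       for _ in range(int(rng.integers(0, 3)))),
        comments=tuple("-!- " + _text(int(rng.integers(5, 40)))
                       for _ in range(int(rng.integers(0, 3)))))


def random_annotations(rng, n_proteins: int = 4, max_per_protein: int = 4
                       ) -> tuple[list, dict[str, int]]:
    """A random annotation set plus protein lengths (for writer exercising)."""
    from .predictor import PredictedAnnotation

    keys = sorted(rulestore.FEATURE_KEYS)
    annotations = []
    lengths: dict[str, int] = {}
    for p in range(n_proteins):
        pid = f"PROT{p + 1:03d}"
        length = int(rng.integers(80, 400))
        lengths[pid] = length
        nid = f"contig{p}" if rng.random() < 0.5 else None
        for _ in range(int(rng.integers(1, max_per_protein + 1))):
            rule_id = f"PIRSR{int(rng.integers(1, 6)):06d}-1"
            cls = ["FT", "FT", "FT", "KW", "CC"][int(rng.integers(0, 5))]
            if cls == "FT":
                start = int(rng.integers(1, length))
                stop = min(length, start + int(rng.integers(0, 20)))
                annotations.append(PredictedAnnotation(
                    protein_id=pid, nucleotide_id=nid, rule_id=rule_id,
                    annotation_class="FT",
                    feature_key=keys[int(rng.integers(0, len(keys)))],
                    target_from=start, target_to=stop,
                    description="desc; with=special,chars%"
                    if rng.random() < 0.3 else "plain site",
                    evidence="ECO:0000256"))
            else:
                annotations.append(PredictedAnnotation(
                    protein_id=pid, nucleotide_id=nid, rule_id=rule_id,
                    annotation_class=cls,
                    description="Keyword A" if cls == "KW"
                    else "-!- COFACTOR: something."))
    return annotations, lengths


def bundle_resources(bundle: FamilyBundle):
    """PredictionResources view of one bundle (SRHMM + template sequence)."""
    from .predictor import PredictionResources

    return PredictionResources(
        hmms={bundle.srhmm.hmm_id: bundle.srhmm},
        templates={bundle.spec.template_accession: bundle.template_seq})
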