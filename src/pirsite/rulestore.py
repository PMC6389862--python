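"""Site rules (PIRSRs): data model, flat-file parser, serializer, validator.

A site rule couples a family trigger signature, an optional taxonomic scope,
and one or more *feature groups*.  Each group names a site-specific profile
HMM (SRHMM), an e-value gate, and a set of feature templates: positions on a
curated template protein whose functional-site annotations are propagated to
a target when the target's aligned residues carry the required amino acids.

Rules are stored in a documented dialect of the UniRule flat-file format
(``.uru``).  A record looks like::

    ID   PIRSR000178-1
    TR   PIRSF000178
    TPL  P69054
    KW   Heme
    CC   -!- COFACTOR: Binds 2 heme groups per dimer.
    Scope
      include: Eukaryota
      exclude: Fungi
    end scope
    Case 1
      SRHMM   PIRSR000178-1
      Evalue  1e-04
      FT   METAL   70   70   H   "Iron (heme axial ligand)"   ECO:0000256
    end case
    //

FT columns are: feature key, 1-based from, 1-based to, residue condition,
quoted description, evidence tag.  The residue condition lists the allowed
amino acids at each checked position: one letter group for single-residue
sites, two groups joined by ``-`` for range features (checked at the
endpoints), e.g. ``C-C`` for a disulfide bond or ``HQ-E`` for alternatives.
``.`` stands for an empty description or evidence.  The ``Evalue`` line may
be omitted; the gate then defaults to 1e-4.  Unknown line types are kept as
opaque extension lines and reported as warnings, never errors.

Coordinates in rule files are 1-based inclusive (UniProt FT convention).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The 16 controlled feature keys supported for site annotation.
FEATURE_KEYS = frozenset({
    "ACT_SITE", "BINDING", "CARBOHYD", "CHAIN", "CROSSLNK", "DISULFID",
    "DNA_BIND", "LIPID", "METAL", "MOD_RES", "MOTIF", "NP_BIND",
    "PROPEP", "REGION", "SITE", "ZN_FING",
})

DEFAULT_EVALUE_CUTOFF = 1e-4


class RuleError(ValueError):
    """Invariant violation in a rule object."""


class RuleParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None,
                 rule_id: str | None = None):
        loc = []
        if rule_id:
            loc.append(f"rule {rule_id}")
        if line_no is not None:
            loc.append(f"line {line_no}")
        prefix = f"[{', '.join(loc)}] " if loc else ""
        super().__init__(prefix + message)
        self.line_no = line_no
        self.rule_id = rule_id


class RuleFormatWarning(UserWarning):
    """Non-fatal oddity in a rule file (e.g. an unknown line type)."""


@dataclass(frozen=True)
class TaxonomicScope:
    """Kingdom/sub-taxon branch a rule may fire in; exclusion wins."""

    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.include:
            raise RuleError("scope include set must be non-empty")
        low_inc = {t.lower() for t in self.include}
        low_exc = {t.lower() for t in self.exclude}
        if low_inc & low_exc:
            raise RuleError("scope include and exclude sets overlap")


@dataclass(frozen=True)
class FeatureTemplate:
    """One propagatable feature on the template protein.

    ``allowed_residues`` holds one frozenset per checked position: a single
    set when ``template_from == template_to``, two sets (one per endpoint)
    for range features.
    """

    feature_key: str
    template_from: int
    template_to: int
    allowed_residues: tuple[frozenset[str], ...]
    description: str = ""
    evidence: str = ""

    def __post_init__(self):
        if self.feature_key not in FEATURE_KEYS:
            raise RuleError(f"unknown feature key {self.feature_key!r}")
        if not (1 <= self.template_from <= self.template_to):
            raise RuleError(
                f"bad feature positions {self.template_from}..{self.template_to}")
        n_checked = 1 if self.template_from == self.template_to else 2
        if len(self.allowed_residues) != n_checked:
            raise RuleError(
                f"{self.feature_key}: expected {n_checked} residue group(s), "
                f"got {len(self.allowed_residues)}")
        for group in self.allowed_residues:
            if not group:
                raise RuleError("empty allowed-residue set")
            bad = set(group) - set(AMINO_ACIDS)
            if bad:
                raise RuleError(f"non-standard residues in condition: {sorted(bad)}")

    @property
    def checked_positions(self) -> tuple[int, ...]:
        """Template positions whose aligned target residues are checked."""
        if self.template_from == self.template_to:
            return (self.template_from,)
        return (self.template_from, self.template_to)


@dataclass(frozen=True)
class FeatureGroup:
    """A Case block: one SRHMM, its e-value gate, and its feature templates."""

    group_id: int
    srhmm_id: str
    features: tuple[FeatureTemplate, ...]
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF

    def __post_init__(self):
        if not self.srhmm_id:
            raise RuleError("feature group lacks an SRHMM id")
        if not self.features:
            raise RuleError("feature group has no features")
        if not self.evalue_cutoff > 0:
            raise RuleError("e-value cutoff must be positive")


@dataclass(frozen=True)
class SiteRule:
    rule_id: str
    trigger: str
    template_accession: str
    feature_groups: tuple[FeatureGroup, ...]
    scope: TaxonomicScope | None = None
    keywords: tuple[str, ...] = ()
    comments: tuple[str, ...] = ()
    extra_lines: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.rule_id:
            raise RuleError("rule id must be non-empty")
        if not self.trigger:
            raise RuleError(f"rule {self.rule_id}: trigger must be non-empty")
        if not self.feature_groups:
            raise RuleError(f"rule {self.rule_id}: at least one feature group required")


# --------------------------------------------------------------------------
# parsing

_FT_RE = re.compile(
    r'^FT\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s+"((?:[^"\\]|\\.)*)"\s+(\S+)\s*$')


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def _parse_condition(token: str, line_no: int, rule_id: str | None
                     ) -> tuple[frozenset[str], ...]:
    groups = token.split("-")
    out = []
    for g in groups:
        if not g:
            raise RuleParseError("empty residue group in condition", line_no, rule_id)
        out.append(frozenset(g.upper()))
    return tuple(out)


def _format_condition(groups: tuple[frozenset[str], ...]) -> str:
    return "-".join("".join(sorted(g)) for g in groups)


def parse_rules(text: str) -> list[SiteRule]:
    """Parse a rule flat file into :class:`SiteRule` objects.

    The input is a concatenation of zero or more records, each terminated by
    a ``//`` line.  Unrecognized line types raise :class:`RuleFormatWarning`
    and are preserved on ``SiteRule.extra_lines``; structural problems raise
    :class:`RuleParseError` naming the rule and line number.
    """
    rules: list[SiteRule] = []
    seen_ids: set[str] = set()

    rec: dict = {}
    scope_inc: list[str] = []
    scope_exc: list[str] = []
    cur_case: dict | None = None
    in_scope = False
    started = False

    def reset():
        nonlocal rec, scope_inc, scope_exc, cur_case, in_scope, started
        rec = {"keywords": [], "comments": [], "extra": [], "groups": [],
               "scope": None, "id": None, "trigger": None, "template": None}
        scope_inc, scope_exc = [], []
        cur_case = None
        in_scope = False
        started = False

    reset()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped:
            continue
        rid = rec["id"]

        if stripped == "//":
            if not started:
                continue  # stray terminator between records
            if in_scope or cur_case is not None:
                raise RuleParseError("record ends inside an open block",
                                     line_no, rid)
            if rec["id"] is None:
                raise RuleParseError("record has no ID line", line_no)
            if rec["trigger"] is None:
                raise RuleParseError("record has no TR (trigger) line",
                                     line_no, rid)
            if rec["id"] in seen_ids:
                raise RuleParseError("duplicate rule id", line_no, rec["id"])
            try:
                rule = SiteRule(
                    rule_id=rec["id"],
                    trigger=rec["trigger"],
                    template_accession=rec["template"] or "",
                    feature_groups=tuple(rec["groups"]),
                    scope=rec["scope"],
                    keywords=tuple(rec["keywords"]),
                    comments=tuple(rec["comments"]),
                    extra_lines=tuple(rec["extra"]),
                )
            except RuleError as exc:
                raise RuleParseError(str(exc), line_no, rec["id"]) from exc
            seen_ids.add(rule.rule_id)
            rules.append(rule)
            reset()
            continue

        started = True

        if in_scope:
            if stripped.lower() == "end scope":
                try:
                    rec["scope"] = TaxonomicScope(frozenset(scope_inc),
                                                  frozenset(scope_exc))
                except RuleError as exc:
                    raise RuleParseError(str(exc), line_no, rid) from exc
                in_scope = False
            elif stripped.lower().startswith("include:"):
                scope_inc.append(stripped[len("include:"):].strip())
            elif stripped.lower().startswith("exclude:"):
                scope_exc.append(stripped[len("exclude:"):].strip())
            else:
                raise RuleParseError(
                    f"unexpected line in Scope block: {stripped!r}",
                    line_no, rid)
            continue

        if cur_case is not None:
            if stripped.lower() == "end case":
                try:
                    group = FeatureGroup(
                        group_id=cur_case["group_id"],
                        srhmm_id=cur_case["srhmm"] or "",
                        evalue_cutoff=cur_case["evalue"],
                        features=tuple(cur_case["features"]),
                    )
                except RuleError as exc:
                    raise RuleParseError(str(exc), line_no, rid) from exc
                rec["groups"].append(group)
                cur_case = None
            elif stripped.startswith("SRHMM"):
                cur_case["srhmm"] = stripped[len("SRHMM"):].strip()
            elif stripped.startswith("Evalue"):
                tok = stripped[len("Evalue"):].strip()
                try:
                    cur_case["evalue"] = float(tok)
                except ValueError:
                    raise RuleParseError(f"bad e-value {tok!r}", line_no, rid)
            elif stripped.startswith("FT"):
                m = _FT_RE.match(stripped)
                if not m:
                    raise RuleParseError(f"malformed FT line: {stripped!r}",
                                         line_no, rid)
                key, s_from, s_to, cond, desc, evid = m.groups()
                if not (s_from.isdigit() and s_to.isdigit()):
                    raise RuleParseError(
                        f"non-numeric FT positions {s_from!r}..{s_to!r}",
                        line_no, rid)
                if key not in FEATURE_KEYS:
                    raise RuleParseError(f"unknown feature key {key!r}",
                                         line_no, rid)
                try:
                    feat = FeatureTemplate(
                        feature_key=key,
                        template_from=int(s_from),
                        template_to=int(s_to),
                        allowed_residues=_parse_condition(cond, line_no, rid),
                        description=_unescape(desc),
                        evidence="" if evid == "." else evid,
                    )
                except RuleError as exc:
                    raise RuleParseError(str(exc), line_no, rid) from exc
                cur_case["features"].append(feat)
            else:
                raise RuleParseError(
                    f"unexpected line in Case block: {stripped!r}",
                    line_no, rid)
            continue

        tag = stripped.split(None, 1)[0]
        rest = stripped[len(tag):].strip()
        if tag == "ID":
            if not rest:
                raise RuleParseError("ID line without a rule id", line_no)
            rec["id"] = rest
        elif tag == "TR":
            rec["trigger"] = rest
        elif tag == "TPL":
            rec["template"] = rest
        elif tag == "KW":
            rec["keywords"].append(rest)
        elif tag == "CC":
            rec["comments"].append(rest)
        elif tag == "Scope":
            in_scope = True
        elif tag == "Case":
            try:
                gid = int(rest)
            except ValueError:
                raise RuleParseError(f"bad Case group id {rest!r}", line_no, rid)
            cur_case = {"group_id": gid, "srhmm": None,
                        "evalue": DEFAULT_EVALUE_CUTOFF, "features": []}
        else:
            warnings.warn(
                f"line {line_no}: unknown line type {tag!r} preserved verbatim",
                RuleFormatWarning, stacklevel=2)
            rec["extra"].append(stripped)

    if started:
        raise RuleParseError("input ends without a final '//' terminator",
                             line_no, rec["id"])
    return rules


def serialize_rule(rule: SiteRule) -> str:
    """Render one rule as a flat-file record (terminated by ``//``).

    Deterministic: scope taxa are sorted, feature groups emitted in
    ``group_id`` order, residue groups alphabetized.  Round-trips through
    :func:`parse_rules`.
    """
    if not isinstance(rule, SiteRule):
        raise RuleError("serialize_rule expects a SiteRule")
    lines = [f"ID   {rule.rule_id}", f"TR   {rule.trigger}"]
    if rule.template_accession:
        lines.append(f"TPL  {rule.template_accession}")
    for kw in rule.keywords:
        lines.append(f"KW   {kw}")
    for cc in rule.comments:
        lines.append(f"CC   {cc}")
    lines.extend(rule.extra_lines)
    if rule.scope is not None:
        lines.append("Scope")
        for t in sorted(rule.scope.include):
            lines.append(f"  include: {t}")
        for t in sorted(rule.scope.exclude):
            lines.append(f"  exclude: {t}")
        lines.append("end scope")
    for group in sorted(rule.feature_groups, key=lambda g: g.group_id):
        lines.append(f"Case {group.group_id}")
        lines.append(f"  SRHMM   {group.srhmm_id}")
        lines.append(f"  Evalue  {group.evalue_cutoff!r}")
        for ft in group.features:
            evid = ft.evidence if ft.evidence else "."
            lines.append(
                f"  FT   {ft.feature_key}   {ft.template_from}   "
                f"{ft.template_to}   {_format_condition(ft.allowed_residues)}   "
                f'"{_escape(ft.description)}"   {evid}')
        lines.append("end case")
    lines.append("//")
    return "\n".join(lines) + "\n"


def serialize_rules(rules: list[SiteRule]) -> str:
    return "".join(serialize_rule(r) for r in rules)


def validate_rule(rule: SiteRule, hmm_index: dict, templates: dict[str, str]
                  ) -> list[str]:
    """Curation-support lint: cross-check a rule against its resources.

    Reports (never raises): unresolvable SRHMM ids, template positions past
    the template length, template residues that violate the rule's own
    residue condition (self-inconsistency), and a missing template sequence.
    """
    issues: list[str] = []
    tpl = templates.get(rule.template_accession)
    if tpl is None:
        issues.append(
            f"{rule.rule_id}: template {rule.template_accession!r} not found")
    for group in rule.feature_groups:
        if group.srhmm_id not in hmm_index:
            issues.append(
                f"{rule.rule_id} case {group.group_id}: "
                f"SRHMM {group.srhmm_id!r} unresolvable")
        for ft in group.features:
            if tpl is None:
                continue
            if ft.template_to > len(tpl):
                issues.append(
                    f"{rule.rule_id} {ft.feature_key} {ft.template_from}.."
                    f"{ft.template_to}: beyond template length {len(tpl)}")
                continue
            for pos, allowed in zip(ft.checked_positions, ft.allowed_residues):
                res = tpl[pos - 1]
                if res not in allowed:
                    issues.append(
                        f"{rule.rule_id} {ft.feature_key} position {pos}: "
                        f"template violates own condition "
                        f"({res!r} not in {sorted(allowed)})")
    return issues
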