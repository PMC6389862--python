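"""Serialize predictions to the three interoperable output formats.

TSV, XML and GFF3 renderings of the same annotation list are
information-equivalent for feature (FT) records: each format ships with a
read-back parser and the (protein, feature_key, from, to) multiset survives
any of the three round trips.  All coordinates are 1-based inclusive in all
formats.
"""

from __future__ import annotations

import io
import urllib.parse
import xml.etree.ElementTree as ET

from .predictor import PredictedAnnotation

TOOL_NAME = "pirsite"

TSV_COLUMNS = ("protein_id", "nucleotide_id", "rule_id", "class",
               "feature_key", "from", "to", "description", "evidence")

#: Pragmatic feature-key -> Sequence Ontology term mapping for the GFF3 type
#: column; keys without a specific term fall back to ``sequence_feature``.
SO_TERMS = {
    "ACT_SITE": "catalytic_residue",
    "BINDING": "binding_site",
    "CARBOHYD": "glycosylation_site",
    "CHAIN": "mature_protein_region",
    "CROSSLNK": "cross_link",
    "DISULFID": "disulfide_bond",
    "DNA_BIND": "DNA_binding_site",
    "LIPID": "lipidation_site",
    "METAL": "metal_binding_site",
    "MOD_RES": "modified_amino_acid_feature",
    "MOTIF": "sequence_motif",
    "NP_BIND": "nucleotide_binding_site",
    "PROPEP": "propeptide",
    "REGION": "region_of_interest",
    "SITE": "sequence_feature",
    "ZN_FING": "zinc_finger_region",
}
SO_FALLBACK = "sequence_feature"


class WriterError(ValueError):
    pass


def _tsv_escape(text: str) -> str:
    return (text.replace("\\", "\\\\").replace("\t", "\\t")
            .replace("\n", "\\n").replace("\r", "\\r"))


def _tsv_unescape(text: str) -> str:
    out = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}.get(nxt,
                                                                        nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _dot(value) -> str:
    return "." if value in (None, "") else str(value)


def _undot(token: str):
    return None if token == "." else token


def write_tsv(annotations: list[PredictedAnnotation]) -> str:
    """Nine-column TSV with a header row; deterministic ordering."""
    lines = ["\t".join(TSV_COLUMNS)]
    for ann in sorted(annotations, key=lambda a: a.sort_key):
        lines.append("\t".join((
            ann.protein_id,
            _dot(ann.nucleotide_id),
            ann.rule_id,
            ann.annotation_class,
            _dot(ann.feature_key),
            _dot(ann.target_from),
            _dot(ann.target_to),
            _tsv_escape(ann.description) if ann.description else ".",
            _dot(ann.evidence),
        )))
    return "\n".join(lines) + "\n"


def read_tsv(text: str) -> list[PredictedAnnotation]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(TSV_COLUMNS):
        raise WriterError("not a predictions TSV (bad or missing header)")
    out = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        if len(cols) != len(TSV_COLUMNS):
            raise WriterError(
                f"expected {len(TSV_COLUMNS)} columns, got {len(cols)}")
        (pid, nid, rid, cls, key, s_from, s_to, desc, evid) = cols
        out.append(PredictedAnnotation(
            protein_id=pid,
            nucleotide_id=_undot(nid),
            rule_id=rid,
            annotation_class=cls,
            feature_key=_undot(key),
            target_from=None if s_from == "." else int(s_from),
            target_to=None if s_to == "." else int(s_to),
            description="" if desc == "." else _tsv_unescape(desc),
            evidence="" if evid == "." else evid,
        ))
    return out


# --------------------------------------------------------------------------
# XML

def write_xml(annotations: list[PredictedAnnotation],
              run_metadata: dict | None = None) -> str:
    """Tool-defined XML grouping FT/KW/CC children per protein.

    The schema ships with the package (``data/predictions.xsd``).
    """
    root = ET.Element("site-predictions", {"tool": TOOL_NAME})
    for key, value in sorted((run_metadata or {}).items()):
        root.set(str(key), str(value))
    proteins_el = ET.SubElement(root, "proteins")
    by_protein: dict[tuple[str, str | None], list[PredictedAnnotation]] = {}
    for ann in sorted(annotations, key=lambda a: a.sort_key):
        by_protein.setdefault((ann.protein_id, ann.nucleotide_id),
                              []).append(ann)
    for (pid, nid), anns in by_protein.items():
        prot_el = ET.SubElement(proteins_el, "protein", {"id": pid})
        if nid:
            prot_el.set("nucleotide-id", nid)
        for ann in anns:
            if ann.annotation_class == "FT":
                ET.SubElement(prot_el, "feature", {
                    "rule": ann.rule_id,
                    "key": ann.feature_key,
                    "from": str(ann.target_from),
                    "to": str(ann.target_to),
                    "description": ann.description,
                    "evidence": ann.evidence,
                })
            elif ann.annotation_class == "KW":
                kw = ET.SubElement(prot_el, "keyword", {"rule": ann.rule_id})
                kw.text = ann.description
            else:
                cc = ET.SubElement(prot_el, "comment", {"rule": ann.rule_id})
                cc.text = ann.description
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def read_xml(text: str) -> list[PredictedAnnotation]:
    root = ET.fromstring(text)
    if root.tag != "site-predictions":
        raise WriterError(f"unexpected root element {root.tag!r}")
    out = []
    for prot in root.iter("protein"):
        pid = prot.get("id")
        nid = prot.get("nucleotide-id")
        for child in prot:
            if child.tag == "feature":
                out.append(PredictedAnnotation(
                    protein_id=pid, nucleotide_id=nid,
                    rule_id=child.get("rule"), annotation_class="FT",
                    feature_key=child.get("key"),
                    target_from=int(child.get("from")),
                    target_to=int(child.get("to")),
                    description=child.get("description") or "",
                    evidence=child.get("evidence") or ""))
            elif child.tag in ("keyword", "comment"):
                out.append(PredictedAnnotation(
                    protein_id=pid, nucleotide_id=nid,
                    rule_id=child.get("rule"),
                    annotation_class="KW" if child.tag == "keyword" else "CC",
                    description=child.text or ""))
    return out


# --------------------------------------------------------------------------
# GFF3

_GFF3_SAFE = "".join(chr(c) for c in range(33, 127)
                     if chr(c) not in ";=&,%\t")


def _gff3_encode(text: str) -> str:
    return urllib.parse.quote(text, safe=_GFF3_SAFE + " ")


def write_gff3(annotations: list[PredictedAnnotation],
               sequence_lengths: dict[str, int],
               include_notes: bool = True) -> str:
    """GFF3 with one feature line per FT annotation.

    The type column maps the feature key to a Sequence Ontology term;
    attribute values are percent-encoded per the GFF3 escaping rules.
    KW/CC annotations are emitted as ``#`` comment lines when
    ``include_notes`` is set.  Refuses to write a feature extending past the
    protein length.
    """
    lines = ["##gff-version 3"]
    fts = sorted((a for a in annotations if a.annotation_class == "FT"),
                 key=lambda a: a.sort_key)
    others = sorted((a for a in annotations if a.annotation_class != "FT"),
                    key=lambda a: a.sort_key)
    for pid in sorted({a.protein_id for a in fts}):
        if pid not in sequence_lengths:
            raise WriterError(f"no sequence length known for {pid!r}")
        lines.append(f"##sequence-region {pid} 1 {sequence_lengths[pid]}")
    for ann in fts:
        if ann.target_to > sequence_lengths[ann.protein_id]:
            raise WriterError(
                f"{ann.protein_id}: feature {ann.target_from}.."
                f"{ann.target_to} exceeds sequence length "
                f"{sequence_lengths[ann.protein_id]}")
        attrs = [
            f"rule_id={_gff3_encode(ann.rule_id)}",
            f"site_key={_gff3_encode(ann.feature_key)}",
        ]
        if ann.description:
            attrs.append(f"Note={_gff3_encode(ann.description)}")
        if ann.evidence:
            attrs.append(f"evidence={_gff3_encode(ann.evidence)}")
        lines.append("\t".join((
            ann.protein_id, TOOL_NAME,
            SO_TERMS.get(ann.feature_key, SO_FALLBACK),
            str(ann.target_from), str(ann.target_to),
            ".", ".", ".", ";".join(attrs))))
    if include_notes:
        for ann in others:
            tag = "keyword" if ann.annotation_class == "KW" else "comment"
            lines.append(f"# {ann.protein_id} {ann.rule_id} {tag}: "
                         f"{ann.description}")
    return "\n".join(lines) + "\n"


_SO_TO_KEY = {}
for _k, _v in SO_TERMS.items():
    _SO_TO_KEY.setdefault(_v, _k)


def read_gff3(text: str) -> list[PredictedAnnotation]:
    """Parse back the FT records of a predictions GFF3 file."""
    out = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 9:
            raise WriterError(f"GFF3 line has {len(cols)} columns: {ln!r}")
        seqid, _source, sotype, start, end, _score, _strand, _phase, attrs = cols
        fields = {}
        for pair in attrs.split(";"):
            if "=" in pair:
                tag, value = pair.split("=", 1)
                fields[tag] = urllib.parse.unquote(value)
        key = fields.get("site_key") or _SO_TO_KEY.get(sotype)
        out.append(PredictedAnnotation(
            protein_id=seqid,
            rule_id=fields.get("rule_id", ""),
            annotation_class="FT",
            feature_key=key,
            target_from=int(start),
            target_to=int(end),
            description=fields.get("Note", ""),
            evidence=fields.get("evidence", "")))
    return out


def ft_multiset(annotations) -> dict:
    """(protein, feature_key, from, to) multiset of the FT records."""
    counts: dict = {}
    for ann in annotations:
        if ann.annotation_class != "FT":
            continue
        key = (ann.protein_id, ann.feature_key, ann.target_from, ann.target_to)
        counts[key] = counts.get(key, 0) + 1
    return counts


def write(annotations, fmt: str, *, sequence_lengths=None, run_metadata=None
          ) -> str:
    """Dispatch to one of the three writers by format name."""
    if fmt == "tsv":
        return write_tsv(annotations)
    if fmt == "xml":
        return write_xml(annotations, run_metadata)
    if fmt == "gff3":
        if sequence_lengths is None:
            raise WriterError("GFF3 output needs sequence lengths")
        return write_gff3(annotations, sequence_lengths)
    raise WriterError(f"unknown output format {fmt!r}; use tsv, xml or gff3")
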