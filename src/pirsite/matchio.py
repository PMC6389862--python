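"""Prediction inputs: InterProScan XML, FASTA sequences, organism lineages.

Targets arrive as InterProScan 5.x XML — either protein-centric
(``protein-matches`` root) or nucleotide-centric
(``nucleotide-sequence-matches`` root, where each ORF translation becomes a
target carrying its source transcript id and coordinates).  Parsing is
namespace- and attribute-order-insensitive and tolerant of minor schema
drift.  Organism lineage (Kingdom/sub-taxon, most general first) is supplied
per run or per sequence; the scope gate consumes it downstream.
"""

from __future__ import annotations

import io
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field


class InputError(ValueError):
    pass


@dataclass
class SignatureMatch:
    """One member-database signature hit on a target protein."""

    signature_accession: str
    interpro_accession: str | None = None
    locations: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for start, end in self.locations:
            if not 1 <= start <= end:
                raise InputError(
                    f"bad match location {start}..{end} for "
                    f"{self.signature_accession}")


@dataclass
class TargetProtein:
    protein_id: str
    sequence: str
    matches: list[SignatureMatch] = field(default_factory=list)
    lineage: list[str] | None = None
    nucleotide_id: str | None = None
    orf_coordinates: tuple[int, int, str] | None = None  # (start, end, strand)

    def __post_init__(self):
        # sequence may be bound later from a side FASTA; once present, every
        # match location must fall within it
        if self.sequence:
            n = len(self.sequence)
            for m in self.matches:
                for start, end in m.locations:
                    if end > n:
                        raise InputError(
                            f"protein {self.protein_id}: match "
                            f"{m.signature_accession} location {start}..{end} "
                            f"exceeds sequence length {n}")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_local(elem, name):
    for child in elem.iter():
        if _local(child.tag) == name:
            yield child


def _parse_matches(protein_elem) -> list[SignatureMatch]:
    matches = []
    for matches_elem in protein_elem:
        if _local(matches_elem.tag) != "matches":
            continue
        for match in matches_elem:
            sig_ac = None
            ipr_ac = None
            locs = []
            for sig in _iter_local(match, "signature"):
                sig_ac = sig.get("ac")
                for entry in _iter_local(sig, "entry"):
                    ipr_ac = entry.get("ac")
                break
            for locations in match:
                if _local(locations.tag) != "locations":
                    continue
                for loc in locations:
                    start, end = loc.get("start"), loc.get("end")
                    if start is not None and end is not None:
                        locs.append((int(start), int(end)))
            if sig_ac:
                matches.append(SignatureMatch(signature_accession=sig_ac,
                                              interpro_accession=ipr_ac,
                                              locations=locs))
    return matches


def _protein_record(protein_elem, nucleotide_id=None, orf=None) -> TargetProtein:
    seq = ""
    pid = None
    for child in protein_elem:
        name = _local(child.tag)
        if name == "sequence" and child.text:
            seq = child.text.strip().upper()
        elif name == "xref" and pid is None:
            pid = child.get("id") or child.get("name")
    if pid is None:
        pid = protein_elem.get("id") or "protein"
    return TargetProtein(protein_id=pid, sequence=seq,
                         matches=_parse_matches(protein_elem),
                         nucleotide_id=nucleotide_id, orf_coordinates=orf)


def parse_interproscan_xml(text: str) -> list[TargetProtein]:
    """Parse InterProScan XML into :class:`TargetProtein` records.

    Protein-centric files yield one record per ``protein`` element;
    nucleotide-centric files yield one record per ORF, with ``nucleotide_id``
    and ``orf_coordinates`` filled in.
    """
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise InputError(f"malformed XML: {exc}") from exc
    root_name = _local(root.tag)
    proteins: list[TargetProtein] = []
    if root_name == "protein-matches":
        for prot in root:
            if _local(prot.tag) == "protein":
                proteins.append(_protein_record(prot))
    elif root_name == "nucleotide-sequence-matches":
        for nt in root:
            if _local(nt.tag) != "nucleotide-sequence":
                continue
            nt_id = None
            for child in nt:
                if _local(child.tag) == "xref" and nt_id is None:
                    nt_id = child.get("id") or child.get("name")
            for orf in nt:
                if _local(orf.tag) != "orf":
                    continue
                coords = None
                try:
                    coords = (int(orf.get("start")), int(orf.get("end")),
                              orf.get("strand") or ".")
                except (TypeError, ValueError):
                    coords = None
                for prot in orf:
                    if _local(prot.tag) == "protein":
                        proteins.append(_protein_record(prot, nt_id, coords))
    else:
        raise InputError(
            f"unsupported schema: unknown root element {root_name!r}")
    return proteins


def read_fasta(text: str) -> dict[str, str]:
    """Read FASTA into an id -> sequence map.

    Ids are the first whitespace-delimited token after ``>``; sequences are
    uppercased and a terminal ``*`` (stop) is stripped.  Duplicate ids and
    empty records are errors.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise InputError(f"FASTA record {rec.id!r} has an empty sequence")
        if rec.id in out:
            raise InputError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: dict[str, str], width: int = 60) -> str:
    lines = []
    for sid, seq in sequences.items():
        lines.append(f">{sid}")
        for i in range(0, len(seq), width):
            lines.append(seq[i:i + width])
    return "\n".join(lines) + "\n"


def resolve_lineage(organism_spec: str,
                    taxonomy_table: dict[str, list[str]] | None = None
                    ) -> list[str]:
    """Turn an organism name or lineage string into an ordered lineage.

    A ``;``-separated spec is split as an explicit lineage (most general
    first); otherwise the name is looked up in ``taxonomy_table``; failing
    that it is returned as a single-element lineage.
    """
    if not organism_spec or not organism_spec.strip():
        raise InputError("organism spec must be non-empty")
    spec = organism_spec.strip()
    if ";" in spec:
        return [part.strip() for part in spec.split(";") if part.strip()]
    if taxonomy_table and spec in taxonomy_table:
        return list(taxonomy_table[spec])
    return [spec]


def read_organism_map(text: str) -> dict[str, list[str]]:
    """Parse a two-column TSV ``id<TAB>lineage-or-name`` into lineages."""
    out: dict[str, list[str]] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"organism map line {line_no}: expected 2 columns")
        out[parts[0].strip()] = resolve_lineage(parts[1])
    return out


def attach_lineages(proteins: list[TargetProtein],
                    organism: str | None = None,
                    organism_map: dict[str, list[str]] | None = None,
                    taxonomy_table: dict[str, list[str]] | None = None) -> None:
    """Assign lineages in place; a per-sequence map wins over the run-wide one."""
    default = resolve_lineage(organism, taxonomy_table) if organism else None
    for prot in proteins:
        if organism_map and prot.protein_id in organism_map:
            prot.lineage = list(organism_map[prot.protein_id])
        elif default is not None:
            prot.lineage = list(default)


def attach_sequences(proteins: list[TargetProtein],
                     fasta_map: dict[str, str]) -> None:
    """Override embedded sequences with a side FASTA (warns on conflict)."""
    for prot in proteins:
        side = fasta_map.get(prot.protein_id)
        if side is None:
            continue
        if prot.sequence and prot.sequence != side:
            warnings.warn(
                f"protein {prot.protein_id}: side FASTA sequence differs "
                "from the XML-embedded one; using the FASTA sequence",
                UserWarning, stacklevel=2)
        prot.sequence = side
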