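"""Rule performance statistics against reference annotations.

Each rule is scored against reference feature annotations (Swiss-Prot-style)
on the proteins where its trigger fired::

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

where TP counts annotations present in the reference and predicted by the
rule, FP annotations predicted but absent from the reference, and FN
reference annotations on trigger-matched proteins the rule failed to
predict.  An annotation matches on the exact (protein_id, feature_key,
from, to) tuple; descriptions are not compared, and duplicated rows are
deduplicated before counting.  Restricting the FN universe to
trigger-matched proteins keeps recall meaningful: reference features on
unrelated proteins are not misses.  Curators use these statistics to
iteratively refine rules.
"""

from __future__ import annotations

from dataclasses import dataclass

Key = tuple[str, str, int, int]  # (protein_id, feature_key, from, to)


@dataclass(frozen=True)
class EvaluationCounts:
    rule_id: str
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None


def _as_key(item) -> tuple[str, Key]:
    """(rule_id, key) from a PredictedAnnotation or a (rule, prot, key, f, t) tuple."""
    if hasattr(item, "annotation_class"):
        return item.rule_id, (item.protein_id, item.feature_key,
                              item.target_from, item.target_to)
    rule_id, protein_id, feature_key, f, t = item
    return rule_id, (protein_id, feature_key, int(f), int(t))


def compare_annotations(predicted, reference,
                        applicable_proteins: dict[str, set[str]],
                        ) -> dict[str, EvaluationCounts]:
    """Per-rule TP/FP/FN counts.

    ``predicted`` holds FT predictions (``PredictedAnnotation`` objects, of
    which non-FT classes are ignored, or (rule_id, protein_id, feature_key,
    from, to) tuples).  ``reference`` holds (protein_id, feature_key, from,
    to) tuples.  ``applicable_proteins`` maps each rule to the proteins on
    which its trigger fired; reference features outside that set do not
    count as FN for the rule.
    """
    ref_set: set[Key] = {(p, k, int(f), int(t)) for p, k, f, t in reference}
    pred_by_rule: dict[str, set[Key]] = {r: set() for r in applicable_proteins}
    for item in predicted:
        if hasattr(item, "annotation_class") and item.annotation_class != "FT":
            continue
        rule_id, key = _as_key(item)
        pred_by_rule.setdefault(rule_id, set()).add(key)

    out: dict[str, EvaluationCounts] = {}
    for rule_id, pred in sorted(pred_by_rule.items()):
        applicable = applicable_proteins.get(rule_id, set())
        ref_rule = {k for k in ref_set if k[0] in applicable}
        tp = len(pred & ref_set)
        fp = len(pred - ref_set)
        fn = len(ref_rule - pred)
        out[rule_id] = EvaluationCounts(rule_id=rule_id, tp=tp, fp=fp, fn=fn)
    return out


def aggregate_statistics(counts) -> dict:
    """Macro-averaged (unweighted per-rule mean) precision and recall.

    Rules with an undefined statistic (zero denominator) are excluded from
    the corresponding mean and reported in the ``undefined_*`` tallies.
    """
    counts = list(counts.values()) if isinstance(counts, dict) else list(counts)
    precisions = [c.precision for c in counts if c.precision is not None]
    recalls = [c.recall for c in counts if c.recall is not None]
    return {
        "n_rules": len(counts),
        "macro_precision": (sum(precisions) / len(precisions)
                            if precisions else None),
        "macro_recall": sum(recalls) / len(recalls) if recalls else None,
        "undefined_precision": len(counts) - len(precisions),
        "undefined_recall": len(counts) - len(recalls),
    }


def read_reference_tsv(text: str) -> list[tuple[str, str, int, int]]:
    """Reference annotations: protein_id, feature_key, from, to[, description]."""
    out = []
    for line_no, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) < 4:
            raise ValueError(
                f"reference line {line_no}: expected >= 4 columns")
        out.append((cols[0], cols[1], int(cols[2]), int(cols[3])))
    return out


def write_reference_tsv(rows) -> str:
    lines = []
    for row in rows:
        protein_id, key, f, t = row[:4]
        desc = row[4] if len(row) > 4 else ""
        lines.append(f"{protein_id}\t{key}\t{f}\t{t}\t{desc}")
    return "\n".join(lines) + "\n"
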