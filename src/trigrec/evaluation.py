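"""Precision / recall / F1 for trigger recognition.

Per trigger type, with TP correctly-classified triggers of that type, FP
tokens misclassified *to* it and FN gold triggers it missed::

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 P R / (P + R)

The TOTAL row is micro-averaged (counts summed over types before the
ratios).  All three are reported on the percent scale with half-up rounding
to two decimals for display; 0/0 is defined as 0.  Token-level counting is
the default; a span-level mode (exact boundary + type) is available for
standoff outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .corpus_io import NEGATIVE_LABEL
from .errors import ConfigError

__all__ = [
    "ConfusionCounts", "MetricsReport", "count_confusion",
    "count_confusion_spans", "compute_metrics", "f1_from_pr",
    "round_half_up", "compare_runs",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(
        Decimal("1." + "0" * ndigits), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """Per-type TP/FP/FN tallies; the negative label has no row."""

    counts: dict = field(default_factory=dict)  # type -> [tp, fp, fn]

    def row(self, label):
        return self.counts.setdefault(label, [0, 0, 0])

    def add(self, other: "ConfusionCounts") -> None:
        for label, (tp, fp, fn) in other.counts.items():
            r = self.row(label)
            r[0] += tp
            r[1] += fp
            r[2] += fn

    def totals(self):
        tp = sum(r[0] for r in self.counts.values())
        fp = sum(r[1] for r in self.counts.values())
        fn = sum(r[2] for r in self.counts.values())
        return tp, fp, fn


def count_confusion(gold, predicted, negative_label=NEGATIVE_LABEL) -> ConfusionCounts:
    """Token-level confusion counts over aligned tag sequences.

    ``gold`` / ``predicted`` are either flat tag lists or lists of per-sentence
    tag lists.  A token with gold type g and prediction p contributes TP to g
    if p == g, otherwise FN to g and (if p is not negative) FP to p.
    """
    def flatten(seqs):
        if seqs and isinstance(seqs[0], (list, tuple)):
            return [t for s in seqs for t in s]
        return list(seqs)

    g_flat, p_flat = flatten(gold), flatten(predicted)
    if len(g_flat) != len(p_flat):
        raise ConfigError(
            f"gold/predicted length mismatch: {len(g_flat)} vs {len(p_flat)}")
    cc = ConfusionCounts()
    for g, p in zip(g_flat, p_flat):
        if g == p:
            if g != negative_label:
                cc.row(g)[0] += 1
        else:
            if g != negative_label:
                cc.row(g)[2] += 1
            if p != negative_label:
                cc.row(p)[1] += 1
    return cc


def _spans(tags, negative_label):
    spans, start = [], None
    for i, t in enumerate(list(tags) + [negative_label]):
        if start is not None and (t != tags[start]):
            spans.append((start, i, tags[start]))
            start = None
        if i < len(tags) and t != negative_label and start is None:
            start = i
    return spans


def count_confusion_spans(gold, predicted, negative_label=NEGATIVE_LABEL) -> ConfusionCounts:
    """Span-level counts: a predicted span is TP only on exact boundary and
    type match with a gold span."""
    if len(gold) and not isinstance(gold[0], (list, tuple)):
        gold, predicted = [gold], [predicted]
    cc = ConfusionCounts()
    for g_seq, p_seq in zip(gold, predicted):
        if len(g_seq) != len(p_seq):
            raise ConfigError("gold/predicted sentence length mismatch")
        g_spans = set(_spans(list(g_seq), negative_label))
        p_spans = set(_spans(list(p_seq), negative_label))
        for s in g_spans & p_spans:
            cc.row(s[2])[0] += 1
        for s in g_spans - p_spans:
            cc.row(s[2])[2] += 1
        for s in p_spans - g_spans:
            cc.row(s[2])[1] += 1
    return cc


def _prf(tp, fp, fn):
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = f1_from_pr(p, r)
    return p, r, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean on the percent scale; 0 when P + R = 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """Per-type and TOTAL P/R/F1 (percent scale, unrounded floats; use
    :meth:`rounded` or :meth:`to_tsv` for the 2-decimal display form)."""

    per_type: dict          # type -> (P, R, F1)
    total: tuple            # (P, R, F1), micro-averaged
    run_id: str = ""

    TOTAL_KEY = "TOTAL"

    def rounded(self) -> dict:
        out = {t: tuple(round_half_up(v) for v in prf)
               for t, prf in self.per_type.items()}
        out[self.TOTAL_KEY] = tuple(round_half_up(v) for v in self.total)
        return out

    @property
    def total_f1(self) -> float:
        return self.total[2]

    def to_tsv(self) -> str:
        lines = ["Type\tP\tR\tF1"]
        table = self.rounded()
        for t, (p, r, f1) in table.items():
            if t == self.TOTAL_KEY:
                continue
            lines.append(f"{t}\t{p:.2f}\t{r:.2f}\t{f1:.2f}")
        p, r, f1 = table[self.TOTAL_KEY]
        lines.append(f"{self.TOTAL_KEY}\t{p:.2f}\t{r:.2f}\t{f1:.2f}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {"run_id": self.run_id, "per_type": self.rounded()}


def compute_metrics(counts: ConfusionCounts, labels=None, run_id="") -> MetricsReport:
    """P/R/F1 per type plus the micro-averaged TOTAL row.

    ``labels`` optionally fixes the row order and forces all-zero rows for
    types without any counts.
    """
    keys = list(labels) if labels is not None else sorted(counts.counts)
    per_type = {}
    for label in keys:
        tp, fp, fn = counts.counts.get(label, (0, 0, 0))
        per_type[label] = _prf(tp, fp, fn)
    total = _prf(*counts.totals())
    return MetricsReport(per_type, total, run_id=run_id)


def compare_runs(report_a: MetricsReport, report_b: MetricsReport) -> dict:
    """Per-type and TOTAL deltas (b - a) on the rounded percent scale."""
    a, b = report_a.rounded(), report_b.rounded()
    if set(a) != set(b):
        raise ConfigError("reports cover different label inventories")
    return {t: tuple(round_half_up(b[t][i] - a[t][i]) for i in range(3))
            for t in a}
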