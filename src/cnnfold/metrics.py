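"""Base-pair evaluation: precision/recall/F1, one-position-shifted variants,
length-weighted aggregation, and pseudoknot classification counts.

Metrics are computed per sequence over base-pair sets only (the "unpaired"
diagonal marks never enter the counts). The shifted variant additionally
credits a predicted pair (i, j) if the reference contains one of the four
one-position shifts (i+1, j), (i-1, j), (i, j+1), (i, j-1) — never a diagonal
shift like (i+1, j+1) — with each reference pair creditable at most once.

Empty-set conventions (documented, since corpora contain pair-free records):
both sets empty -> P = R = F1 = 1; prediction empty but reference not ->
P = 0 (and F1 = 0); reference empty but prediction not -> R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core import SecondaryStructure, is_pseudoknotted

__all__ = [
    "PairMetrics",
    "RecordEvaluation",
    "EvaluationReport",
    "pair_metrics",
    "shifted_pair_metrics",
    "aggregate",
    "pseudoknot_confusion",
    "write_report_tsv",
]


@dataclass(frozen=True)
class PairMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PairMetrics":
        if tp == 0 and fp == 0 and fn == 0:
            return cls(0, 0, 0, 1.0, 1.0, 1.0)
        p = tp / (tp + fp) if (tp + fp) else 0.0
        r = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        return cls(tp, fp, fn, p, r, f1)


def _check_lengths(pred: SecondaryStructure, ref: SecondaryStructure) -> None:
    if pred.length != ref.length:
        raise ValueError(f"length mismatch: pred {pred.length} vs ref {ref.length}")


def pair_metrics(pred: SecondaryStructure, ref: SecondaryStructure) -> PairMetrics:
    """Exact base-pair precision/recall/F1."""
    _check_lengths(pred, ref)
    tp = len(pred.pairs & ref.pairs)
    return PairMetrics.from_counts(tp, len(pred.pairs) - tp, len(ref.pairs) - tp)


_SHIFTS = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1))


def shifted_pair_metrics(pred: SecondaryStructure, ref: SecondaryStructure) -> PairMetrics:
    """One-position-shift-tolerant metrics.

    Predicted pairs are matched greedily in 5' order; exact hits are tried
    before shifted ones, and each reference pair can credit only one
    prediction, keeping tp <= min(|pred|, |ref|).
    """
    _check_lengths(pred, ref)
    available = set(ref.pairs)
    tp = 0
    for i, j in sorted(pred.pairs):
        for di, dj in _SHIFTS:
            cand = (i + di, j + dj)
            if cand in available:
                available.discard(cand)
                tp += 1
                break
    return PairMetrics.from_counts(tp, len(pred.pairs) - tp, len(ref.pairs) - tp)


@dataclass(frozen=True)
class RecordEvaluation:
    """Per-record row of an evaluation report."""

    id: str
    length: int
    plain: PairMetrics
    shifted: PairMetrics
    pseudoknotted_ref: bool
    pseudoknotted_pred: bool
    family: str | None = None


@dataclass(frozen=True)
class EvaluationReport:
    records: tuple[RecordEvaluation, ...]
    precision: float
    recall: float
    f1: float
    precision_shifted: float
    recall_shifted: float
    f1_shifted: float
    weighted_f1: float
    pseudoknot_confusion: dict[tuple[bool, bool], int] = field(default_factory=dict)


def aggregate(
    evaluations: Sequence[RecordEvaluation] | None = None,
    *,
    preds: Sequence[SecondaryStructure] | None = None,
    refs: Sequence[SecondaryStructure] | None = None,
    ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """Aggregate per-record metrics into plain means and the length-weighted
    F1 (weights w_k = L_k / sum_k L_k); also tallies the pseudoknot confusion.

    Either pass precomputed ``evaluations`` or parallel ``preds``/``refs``.
    """
    if evaluations is None:
        if preds is None or refs is None:
            raise ValueError("need either evaluations or preds+refs")
        if len(preds) != len(refs):
            raise ValueError("preds and refs differ in length")
        ids = ids or [f"record_{k}" for k in range(len(preds))]
        evaluations = [
            RecordEvaluation(
                id=i,
                length=r.length,
                plain=pair_metrics(p, r),
                shifted=shifted_pair_metrics(p, r),
                pseudoknotted_ref=is_pseudoknotted(r),
                pseudoknotted_pred=is_pseudoknotted(p),
            )
            for i, p, r in zip(ids, preds, refs)
        ]
    if not evaluations:
        raise ValueError("no records to aggregate")
    n = len(evaluations)
    total_len = sum(e.length for e in evaluations)
    confusion: dict[tuple[bool, bool], int] = {
        (r, p): 0 for r in (False, True) for p in (False, True)
    }
    for e in evaluations:
        confusion[(e.pseudoknotted_ref, e.pseudoknotted_pred)] += 1
    return EvaluationReport(
        records=tuple(evaluations),
        precision=sum(e.plain.precision for e in evaluations) / n,
        recall=sum(e.plain.recall for e in evaluations) / n,
        f1=sum(e.plain.f1 for e in evaluations) / n,
        precision_shifted=sum(e.shifted.precision for e in evaluations) / n,
        recall_shifted=sum(e.shifted.recall for e in evaluations) / n,
        f1_shifted=sum(e.shifted.f1 for e in evaluations) / n,
        weighted_f1=sum(e.length * e.plain.f1 for e in evaluations) / total_len,
        pseudoknot_confusion=confusion,
    )


def pseudoknot_confusion(
    preds: Sequence[SecondaryStructure], refs: Sequence[SecondaryStructure]
) -> dict[tuple[bool, bool], int]:
    """Counts of (reference pseudoknotted?, prediction pseudoknotted?)."""
    if len(preds) != len(refs):
        raise ValueError("preds and refs differ in length")
    out: dict[tuple[bool, bool], int] = {
        (r, p): 0 for r in (False, True) for p in (False, True)
    }
    for p, r in zip(preds, refs):
        out[(is_pseudoknotted(r), is_pseudoknotted(p))] += 1
    return out


def write_report_tsv(report: EvaluationReport, path: str | Path) -> None:
    """One row per record plus a summary block (means, weighted F1,
    pseudoknot confusion)."""
    cols = [
        "id", "length", "family",
        "precision", "recall", "f1",
        "precision_shifted", "recall_shifted", "f1_shifted",
        "pseudoknotted_ref", "pseudoknotted_pred",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in report.records:
            fh.write(
                "\t".join(
                    [
                        e.id,
                        str(e.length),
                        e.family or "",
                        f"{e.plain.precision:.4f}",
                        f"{e.plain.recall:.4f}",
                        f"{e.plain.f1:.4f}",
                        f"{e.shifted.precision:.4f}",
                        f"{e.shifted.recall:.4f}",
                        f"{e.shifted.f1:.4f}",
                        str(int(e.pseudoknotted_ref)),
                        str(int(e.pseudoknotted_pred)),
                    ]
                )
                + "\n"
            )
        fh.write("# summary\n")
        fh.write(f"# records\t{len(report.records)}\n")
        fh.write(f"# precision\t{report.precision:.4f}\n")
        fh.write(f"# recall\t{report.recall:.4f}\n")
        fh.write(f"# f1\t{report.f1:.4f}\n")
        fh.write(f"# precision_shifted\t{report.precision_shifted:.4f}\n")
        fh.write(f"# recall_shifted\t{report.recall_shifted:.4f}\n")
        fh.write(f"# f1_shifted\t{report.f1_shifted:.4f}\n")
        fh.write(f"# weighted_f1\t{report.weighted_f1:.4f}\n")
        c = report.pseudoknot_confusion
        fh.write(
            "# pseudoknot_confusion (ref,pred)\t"
            f"nn={c[(False, False)]}\tnp={c[(False, True)]}\t"
            f"pn={c[(True, False)]}\tpp={c[(True, True)]}\n"
        )
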