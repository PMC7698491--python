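"""Recovery scoring of inferred landscapes against planted architectures."""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic_data import Architecture
from .pipeline import LandscapeResult


@dataclass
class RecoveryScore:
    n_truth: int
    n_pred: int
    n_matched: int

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_pred if self.n_pred else float("nan")


def match_positions(
    truth: list[tuple[str, int]],
    predicted: list[tuple[str, int]],
    tolerance: int = 5,
) -> RecoveryScore:
    """Greedy one-to-one matching of stranded positions within a tolerance."""
    pairs = []
    for i, (st, pt) in enumerate(truth):
        for j, (sp, pp) in enumerate(predicted):
            if st == sp and abs(pt - pp) <= tolerance:
                pairs.append((abs(pt - pp), i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    for _, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
    return RecoveryScore(
        n_truth=len(truth), n_pred=len(predicted), n_matched=len(used_t)
    )


def promoter_recovery(
    arch: Architecture, result: LandscapeResult, tolerance: int = 5
) -> RecoveryScore:
    truth = arch.promoter_truth()
    pred = [(c.strand, c.tss) for c in result.active_promoters]
    return match_positions(truth, pred, tolerance)


def terminator_recovery(
    arch: Architecture, result: LandscapeResult, tolerance: int = 5
) -> RecoveryScore:
    truth = arch.terminator_truth()
    pred = [(t.strand, t.position) for t in result.terminators]
    return match_positions(truth, pred, tolerance)


def tu_partition_jaccard(arch: Architecture, result: LandscapeResult) -> float:
    """Mean, over planted coding TUs, of the best Jaccard index between the
    planted ORF set and any assembled TU's ORF set."""
    truth_sets = [set(tu.orf_ids) for tu in arch.coding_tus]
    pred_sets = [set(o.id for o in tu.orfs) for tu in result.assembly.tus]
    if not truth_sets:
        return float("nan")
    total = 0.0
    for t in truth_sets:
        best = 0.0
        for p in pred_sets:
            inter = len(t & p)
            if inter:
                best = max(best, inter / len(t | p))
        total += best
    return total / len(truth_sets)


def tu_class_accuracy(arch: Architecture, result: LandscapeResult) -> float:
    """Fraction of planted coding TUs whose best-overlap assembled TU carries
    the correct temporal class."""
    pred = [(set(o.id for o in tu.orfs), tu.tu_class) for tu in result.assembly.tus]
    truth = [(set(tu.orf_ids), tu.cls) for tu in arch.coding_tus]
    if not truth:
        return float("nan")
    correct = 0
    for t_set, t_cls in truth:
        best, best_j = None, 0.0
        for p_set, p_cls in pred:
            inter = len(t_set & p_set)
            if inter:
                j = inter / len(t_set | p_set)
                if j > best_j:
                    best, best_j = p_cls, j
        if best == t_cls:
            correct += 1
    return correct / len(truth)
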