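"""Guilt-by-association indication transfer and leave-one-out ROC evaluation.

The hypothesis: if two drugs are similar, an indication known for one is a
candidate for the other.  For a query drug, the indications of its top-N
most similar gold-standard drugs are pooled into a prediction; the query's
own indications are never consulted.  Leave-one-out cross-validation holds
out each drug's indications in turn, varies N, and pools the confusion
counts over all (drug, disease) cells into one sensitivity/specificity
point per N (micro-averaging).  The ROC curve gets (0,0) and (1,1) anchors
— N=0 predicts nothing, N→∞ everything — and is integrated by the trapezoid
rule.  The partial AUC over specificity >= 0.9 is normalized by the 0.1
width of that region so a perfect classifier scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import IndicationTable
from .similarity import SimilarityRecord

__all__ = ["GbaPrediction", "RocCurve", "gba_predict", "loo_roc", "auc_trapezoid"]


@dataclass(frozen=True)
class GbaPrediction:
    drug_id: str
    neighborhood_size: int
    predicted_diseases: frozenset[str]


@dataclass
class RocCurve:
    """ROC points (one per N plus anchors), trapezoid AUC, and the
    width-normalized partial AUC over specificity >= 0.9."""

    points: list[tuple[float, float]]   # (1 - specificity, sensitivity)
    auc: float
    pauc_spec90: float
    per_n: list[dict]                   # N, TP, FP, TN, FN, sensitivity, specificity


def _neighbor_ranking(
    drug: str, sim_lookup: dict, gold_drugs: list[str]
) -> list[str]:
    """Gold-standard drugs ranked by descending similarity to the query.

    Pairs without a (defined) similarity record rank last; ties break
    lexicographically by drug id for determinism.
    """
    def key(other: str):
        s = sim_lookup.get((min(drug, other), max(drug, other)))
        return (-(s if s is not None else float("-inf")), other)

    return sorted((d for d in gold_drugs if d != drug), key=key)


def _sim_lookup(similarities: list[SimilarityRecord]) -> dict:
    return {(r.drug_x, r.drug_y): r.sim for r in similarities}


def gba_predict(
    drug: str,
    similarities: list[SimilarityRecord],
    indications: IndicationTable,
    n_neighbors: int,
) -> GbaPrediction:
    """Predict indications for ``drug`` as the union over its top-N neighbors.

    Only drugs present in the gold standard can donate indications; the
    query's own indications are never consulted.  A drug with no similarity
    records yields an empty prediction.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    lookup = _sim_lookup(similarities)
    in_records = any(drug in pair for pair in lookup)
    if not in_records:
        return GbaPrediction(drug, n_neighbors, frozenset())
    gold_drugs = sorted(indications.drugs)
    ranking = _neighbor_ranking(drug, lookup, gold_drugs)
    predicted: set[str] = set()
    for neighbor in ranking[:n_neighbors]:
        predicted |= indications.indications_of(neighbor)
    return GbaPrediction(drug, n_neighbors, frozenset(predicted))


def loo_roc(
    similarities: list[SimilarityRecord],
    indications: IndicationTable,
    n_grid: list[int] | None = None,
) -> RocCurve:
    """Leave-one-out ROC over neighborhood sizes N.

    For each N and each gold drug d, hold out d's indications, predict from
    its top-N neighbors, and pool TP/FP/TN/FN over all (drug, disease) cells.
    Default n_grid is 1 .. n_gold_drugs - 1.
    """
    gold_drugs = sorted(indications.drugs)
    diseases = indications.diseases
    if len(gold_drugs) < 2 or len(diseases) < 2:
        raise ValueError(
            "degenerate gold standard: need >= 2 drugs and >= 2 diseases "
            f"(got {len(gold_drugs)} drugs, {len(diseases)} diseases)"
        )
    if n_grid is None:
        n_grid = list(range(1, len(gold_drugs)))
    n_grid = sorted(set(n_grid))
    if n_grid[0] < 1:
        raise ValueError("neighborhood sizes must be >= 1")

    lookup = _sim_lookup(similarities)
    truth = {d: indications.indications_of(d) for d in gold_drugs}
    rankings = {d: _neighbor_ranking(d, lookup, gold_drugs) for d in gold_drugs}

    n_cells = len(gold_drugs) * len(diseases)
    n_pos = sum(len(truth[d]) for d in gold_drugs)

    per_n = []
    # predictions grow monotonically with N, so walk the grid incrementally
    preds = {d: set() for d in gold_drugs}
    cursor = {d: 0 for d in gold_drugs}
    for n in n_grid:
        tp = fp = 0
        for d in gold_drugs:
            while cursor[d] < min(n, len(rankings[d])):
                preds[d] |= truth[rankings[d][cursor[d]]]
                cursor[d] += 1
            tp += len(preds[d] & truth[d])
            fp += len(preds[d] - truth[d])
        fn = n_pos - tp
        tn = n_cells - n_pos - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        per_n.append(
            {"N": n, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
             "sensitivity": sens, "specificity": spec}
        )

    points = sorted(
        [(0.0, 0.0)] + [(1 - r["specificity"], r["sensitivity"]) for r in per_n]
        + [(1.0, 1.0)]
    )
    return RocCurve(
        points=points,
        auc=auc_trapezoid(points),
        pauc_spec90=_partial_auc(points, x_max=0.1),
        per_n=per_n,
    )


def auc_trapezoid(points: list[tuple[float, float]]) -> float:
    """Trapezoid integral of an ROC polyline sorted by x."""
    xs = [p[0] for p in points]
    if any(b < a for a, b in zip(xs, xs[1:])):
        raise ValueError("ROC points must be sorted by non-decreasing x")
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def _partial_auc(points: list[tuple[float, float]], x_max: float) -> float:
    """Area under the polyline over x in [0, x_max], normalized by x_max.

    x is 1 - specificity, so x <= 0.1 is the specificity >= 90% region.
    The curve is linearly interpolated at the clip point.
    """
    clipped = [(x, y) for x, y in points if x <= x_max]
    if not clipped or clipped[-1][0] < x_max:
        # interpolate y at x_max from the bracketing segment
        for (x0, y0), (x1, y1) in zip(points, points[1:]):
            if x0 <= x_max <= x1 and x1 > x0:
                y_at = y0 + (y1 - y0) * (x_max - x0) / (x1 - x0)
                clipped.append((x_max, y_at))
                break
        else:
            clipped.append((x_max, points[-1][1]))
    return auc_trapezoid(clipped) / x_max
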