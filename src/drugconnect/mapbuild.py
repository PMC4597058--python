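"""Construction of the directional drug-to-protein connectivity map.

Three stages, composed by :func:`build_map`:

1. **Evidence aggregation.**  Every evidence item for a (drug, protein) pair
   carries a confidence ``prob`` in (0, 1] and a direction ``sign`` (+1
   activation, -1 inhibition).  The pair's aggregate confidence is the signed
   sum ``conf(d, p) = sum_i prob_i * sign_i``; its sign is the pair's net
   pharmacological direction.  Pairs whose evidence cancels exactly to zero
   carry no direction and are dropped.

2. **Protein weighting.**  Each protein is weighted by its context in a
   confidence-weighted PPI network: ``weight(p) = k * ln(S) - ln(n)`` where
   ``S`` is the sum of interaction confidences over p's neighbors, ``n`` is
   its degree, and ``k`` (default 2) is an empirical constant.  Proteins
   absent from the network have no defined context and get weight 0.

3. **Pharmacology score.**  ``p_score(d, p) = conf(d, p) * weight(p)``,
   combining the drug's directed action with the protein's network
   importance.  Each drug's proteins, ranked by descending p_score, form a
   connectivity-map-style ranked profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io import EvidenceRecord, PPIEdge, read_evidence, read_ppi

logger = logging.getLogger(__name__)

__all__ = [
    "DrugProteinEffect",
    "ProteinWeight",
    "DrugProfile",
    "aggregate_confidence",
    "protein_weight",
    "p_score",
    "build_map",
    "MapSummary",
]


@dataclass(frozen=True)
class DrugProteinEffect:
    """Aggregated, signed effect of one drug on one protein."""

    drug_id: str
    protein_id: str
    conf: float          # signed aggregate confidence, never exactly 0
    n_evidence: int

    @property
    def net_sign(self) -> int:
        return 1 if self.conf > 0 else -1

    def __post_init__(self):
        if self.conf == 0:
            raise ValueError("zero-balance effects carry no direction")
        if self.n_evidence < 1:
            raise ValueError("n_evidence must be positive")
        if abs(self.conf) > self.n_evidence + 1e-12:
            raise ValueError("|conf| cannot exceed the number of evidence items")


@dataclass(frozen=True)
class ProteinWeight:
    """PPI-derived weight for one protein: k*ln(sum_conf) - ln(degree)."""

    protein_id: str
    weight: float
    degree: int
    sum_conf: float


@dataclass
class DrugProfile:
    """Per-drug protein scores plus the derived descending ranked list.

    ``signs`` records each protein's net pharmacological direction (the sign
    of the aggregated evidence confidence), which is kept separately from the
    p_score sign because a negative network weight can flip the latter.
    """

    drug_id: str
    scores: dict[str, float]
    signs: dict[str, int] = field(default_factory=dict)
    ranked: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ranked:
            self.ranked = _rank(self.scores)
        if not self.signs:
            # fall back to score sign; zero scores default to +1
            self.signs = {p: (1 if s >= 0 else -1) for p, s in self.scores.items()}

    @classmethod
    def from_scores(cls, drug_id: str, scores: dict[str, float], signs=None):
        return cls(drug_id=drug_id, scores=dict(scores), signs=dict(signs or {}))

    @property
    def proteins(self) -> set[str]:
        return set(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


def _rank(scores: dict[str, float]) -> list[str]:
    """Descending score order with lexicographic tie-break on protein id."""
    return sorted(scores, key=lambda p: (-scores[p], p))


def aggregate_confidence(evidence: list[EvidenceRecord]) -> list[DrugProteinEffect]:
    """Collapse evidence items into one signed confidence per (drug, protein).

    conf(d, p) = sum_i prob_i * sign_i over all evidence for the pair.
    Pairs whose sum is exactly zero (perfectly balanced evidence) have no net
    direction and are excluded; the drop count is logged.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for rec in evidence:
        key = (rec.drug_id, rec.protein_id)
        sums[key] = sums.get(key, 0.0) + rec.prob * rec.sign
        counts[key] = counts.get(key, 0) + 1
    effects = []
    n_zero = 0
    for key in sorted(sums):
        if sums[key] == 0.0:
            n_zero += 1
            continue
        effects.append(
            DrugProteinEffect(
                drug_id=key[0], protein_id=key[1],
                conf=sums[key], n_evidence=counts[key],
            )
        )
    if n_zero:
        logger.info("dropped %d zero-balance drug-protein pairs", n_zero)
    return effects


def protein_weight(edges: list[PPIEdge], k: float = 2.0) -> list[ProteinWeight]:
    """Weight every protein in the PPI by k*ln(sum of edge confs) - ln(degree).

    ``k`` is an empirical constant, 2 by default.  The formula is evaluated
    exactly as written, as (k * ln S) - ln n; negative weights (possible when
    k*ln S < ln n) are kept as-is.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    sum_conf: dict[str, float] = {}
    degree: dict[str, int] = {}
    for e in edges:
        for p in (e.protein_a, e.protein_b):
            sum_conf[p] = sum_conf.get(p, 0.0) + e.conf
            degree[p] = degree.get(p, 0) + 1
    return [
        ProteinWeight(
            protein_id=p,
            weight=k * math.log(sum_conf[p]) - math.log(degree[p]),
            degree=degree[p],
            sum_conf=sum_conf[p],
        )
        for p in sorted(sum_conf)
    ]


def p_score(
    effects: list[DrugProteinEffect], weights: list[ProteinWeight]
) -> list[DrugProfile]:
    """Build per-drug profiles with p_score = conf * weight for every effect.

    Proteins absent from the PPI take weight 0; their score is 0 but they are
    retained in the profile, where they still carry rank information.
    """
    wmap = {w.protein_id: w.weight for w in weights}
    scores: dict[str, dict[str, float]] = {}
    signs: dict[str, dict[str, int]] = {}
    for eff in effects:
        w = wmap.get(eff.protein_id, 0.0)
        scores.setdefault(eff.drug_id, {})[eff.protein_id] = eff.conf * w
        signs.setdefault(eff.drug_id, {})[eff.protein_id] = eff.net_sign
    return [
        DrugProfile(drug_id=d, scores=scores[d], signs=signs[d])
        for d in sorted(scores)
    ]


@dataclass
class MapSummary:
    """Table-1-style construction counts."""

    n_drugs: int = 0
    n_proteins: int = 0
    n_effects: int = 0
    n_stimulatory: int = 0
    n_inhibitory: int = 0
    n_zero_dropped: int = 0
    n_evidence_rows: int = 0
    n_skipped_actions: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_map(evidence_path, ppi_path, k: float = 2.0):
    """Read inputs and compose the three stages into ranked drug profiles.

    Returns ``(profiles, summary)`` where summary counts drugs, proteins,
    effects, and the stimulatory/inhibitory split.
    """
    evidence, ev_stats = read_evidence(evidence_path, return_stats=True)
    edges = read_ppi(ppi_path)
    effects = aggregate_confidence(evidence)
    n_pairs_total = len({(r.drug_id, r.protein_id) for r in evidence})
    weights = protein_weight(edges, k=k)
    profiles = p_score(effects, weights)
    summary = MapSummary(
        n_drugs=len(profiles),
        n_proteins=len({e.protein_id for e in effects}),
        n_effects=len(effects),
        n_stimulatory=sum(1 for e in effects if e.net_sign > 0),
        n_inhibitory=sum(1 for e in effects if e.net_sign < 0),
        n_zero_dropped=n_pairs_total - len(effects),
        n_evidence_rows=ev_stats.n_kept,
        n_skipped_actions=ev_stats.n_skipped_action,
    )
    logger.info(
        "map built: %d drugs, %d proteins, %d effects (%d stimulatory, %d inhibitory)",
        summary.n_drugs, summary.n_proteins, summary.n_effects,
        summary.n_stimulatory, summary.n_inhibitory,
    )
    return profiles, summary


def write_map_summary_table(profiles, effects, weights, path) -> None:
    """Write the long-form map TSV: drug, protein, conf, weight, p_score."""
    wmap = {w.protein_id: w.weight for w in weights}
    emap = {(e.drug_id, e.protein_id): e.conf for e in effects}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\tconf\tweight\tp_score\n")
        for prof in profiles:
            for protein in prof.ranked:
                conf = emap[(prof.drug_id, protein)]
                w = wmap.get(protein, 0.0)
                fh.write(
                    f"{prof.drug_id}\t{protein}\t{conf!r}\t{w!r}\t{prof.scores[protein]!r}\n"
                )


def read_map_summary_table(path) -> list[DrugProfile]:
    """Rebuild drug profiles (scores and net signs) from the long-form map TSV."""
    from .io import FormatError, _data_lines, _parse_float

    scores: dict[str, dict[str, float]] = {}
    signs: dict[str, dict[str, int]] = {}
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    cols = header.split("\t")
    if cols[:5] != ["drug_id", "protein_id", "conf", "weight", "p_score"]:
        raise FormatError(f"{path}: unexpected header {cols!r}")
    for line_no, line in rows:
        drug, protein, conf_s, _w, ps = line.split("\t")[:5]
        conf = _parse_float(conf_s, line_no, "conf")
        scores.setdefault(drug, {})[protein] = _parse_float(ps, line_no, "p_score")
        signs.setdefault(drug, {})[protein] = 1 if conf > 0 else -1
    return [
        DrugProfile(drug_id=d, scores=scores[d], signs=signs[d]) for d in sorted(scores)
    ]
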