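"""Signed-Tanimoto drug-drug similarity and network diagnostics.

Two drugs are compared on their interacting-protein profiles.  Shared
proteins on which both drugs act in the same direction (both activate or
both inhibit) count toward the similarity; shared proteins acted on in
opposite directions count against it; the denominator is the union of the
two protein sets:

    SIM(x, y) = (|same-direction overlap| - |opposite-direction overlap|)
                / |p_x U p_y|

SIM lies in [-1, 1]: +1 for identical profiles with identical directions,
-1 for identical protein sets with every direction opposed.  A protein's
direction is its net evidence sign (the sign of the aggregated confidence),
not the p_score sign, so a negative network weight cannot flip a drug's
pharmacological direction.

The significant-pair filter keeps pairs with at least ``min_overlap`` shared
proteins whose similarity reaches the top ``top_fraction`` of the full
pairwise distribution.  Degree diagnostics fit log10(count) on log10(degree)
for each side of the drug-protein bipartite network, the standard scale-free
check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .mapbuild import DrugProfile

__all__ = [
    "SimilarityRecord",
    "DegreeFit",
    "signed_tanimoto",
    "all_pairs",
    "significant_pairs",
    "degree_fit",
    "write_similarity",
    "read_similarity",
]


@dataclass(frozen=True)
class SimilarityRecord:
    """One unordered drug pair with its signed-Tanimoto similarity.

    ``sim`` is None when both profiles are empty (no data, distinct from an
    orthogonal 0).
    """

    drug_x: str
    drug_y: str
    sim: float | None
    n_same: int
    n_opp: int
    n_union: int

    @property
    def n_overlap(self) -> int:
        return self.n_same + self.n_opp


@dataclass(frozen=True)
class DegreeFit:
    """Log-log OLS fit of a degree distribution for one bipartite side."""

    side: str                 # "drug" or "protein"
    available: bool
    r_squared: float | None = None
    slope: float | None = None
    n_points: int = 0


def signed_tanimoto(profile_x: DrugProfile, profile_y: DrugProfile) -> SimilarityRecord:
    """Signed Tanimoto similarity between two drug profiles.

    Raises ValueError if both profiles are empty (similarity undefined).
    """
    px, py = profile_x.proteins, profile_y.proteins
    union = px | py
    if not union:
        raise ValueError(
            f"similarity undefined: {profile_x.drug_id} and {profile_y.drug_id} "
            "have empty protein sets"
        )
    shared = px & py
    n_same = sum(1 for p in shared if profile_x.signs[p] == profile_y.signs[p])
    n_opp = len(shared) - n_same
    x, y = sorted((profile_x.drug_id, profile_y.drug_id))
    return SimilarityRecord(
        drug_x=x, drug_y=y,
        sim=(n_same - n_opp) / len(union),
        n_same=n_same, n_opp=n_opp, n_union=len(union),
    )


def all_pairs(profiles) -> list[SimilarityRecord]:
    """All n*(n-1)/2 unordered pair similarities, lexicographic by (x, y).

    Pairs for which similarity is undefined (both profiles empty) are emitted
    with ``sim=None`` rather than dropped.
    """
    by_id = {p.drug_id: p for p in profiles}
    if len(by_id) < 2:
        raise ValueError("need at least two profiles")
    records = []
    for x, y in itertools.combinations(sorted(by_id), 2):
        try:
            records.append(signed_tanimoto(by_id[x], by_id[y]))
        except ValueError:
            records.append(
                SimilarityRecord(drug_x=x, drug_y=y, sim=None,
                                 n_same=0, n_opp=0, n_union=0)
            )
    return records


def n_pairs(n_drugs: int) -> int:
    """Closed-form count of unordered drug pairs, n*(n-1)/2."""
    return n_drugs * (n_drugs - 1) // 2


def significant_pairs(
    records: list[SimilarityRecord],
    min_overlap: int = 2,
    top_fraction: float = 0.05,
) -> list[SimilarityRecord]:
    """Filter to pairs with >= min_overlap shared proteins in the top of the
    similarity distribution.

    The similarity cutoff is the (1 - top_fraction) quantile (linear
    interpolation) of the full input distribution, computed before the
    overlap filter; ties at the cutoff are kept.
    """
    if not records:
        raise ValueError("no similarity records given")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    sims = np.array([r.sim for r in records if r.sim is not None], dtype=float)
    if sims.size == 0:
        return []
    cutoff = -np.inf if top_fraction == 1.0 else float(
        np.quantile(sims, 1.0 - top_fraction)
    )
    return [
        r for r in records
        if r.sim is not None and r.sim >= cutoff and r.n_overlap >= min_overlap
    ]


def degree_fit(profiles) -> tuple[DegreeFit, DegreeFit]:
    """Scale-free diagnostics for the drug-protein bipartite network.

    For each side, tabulate the degree frequencies (a drug's degree is its
    number of scored proteins; a protein's degree the number of drugs scoring
    it), drop empty bins, and fit OLS of log10(count) on log10(degree).
    Returns (drug-side fit, protein-side fit); a side with fewer than three
    distinct degree values is marked unavailable.
    """
    drug_deg = [len(p) for p in profiles]
    prot_counter = Counter(q for p in profiles for q in p.proteins)
    return (
        _fit_side("drug", drug_deg),
        _fit_side("protein", list(prot_counter.values())),
    )


def _fit_side(side: str, degrees: list[int]) -> DegreeFit:
    freq = Counter(d for d in degrees if d > 0)
    if len(freq) < 3:
        return DegreeFit(side=side, available=False, n_points=len(freq))
    deg = np.array(sorted(freq))
    cnt = np.array([freq[d] for d in deg], dtype=float)
    res = _sps.linregress(np.log10(deg), np.log10(cnt))
    return DegreeFit(
        side=side, available=True,
        r_squared=float(res.rvalue**2), slope=float(res.slope),
        n_points=len(deg),
    )


def write_similarity(records, path, significant=None) -> None:
    """Write similarity records as a TSV; null similarities print as NA."""
    sig = set()
    if significant is not None:
        sig = {(r.drug_x, r.drug_y) for r in significant}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_x\tdrug_y\tsim\tn_same\tn_opp\tn_union\tsignificant\n")
        for r in records:
            sim = "NA" if r.sim is None else repr(r.sim)
            flag = int((r.drug_x, r.drug_y) in sig)
            fh.write(
                f"{r.drug_x}\t{r.drug_y}\t{sim}\t{r.n_same}\t{r.n_opp}\t"
                f"{r.n_union}\t{flag}\n"
            )


def read_similarity(path) -> list[SimilarityRecord]:
    from .io import FormatError, _data_lines, _parse_float

    records = []
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    cols = header.split("\t")
    need = ["drug_x", "drug_y", "sim", "n_same", "n_opp", "n_union"]
    idx = {c: cols.index(c) for c in need if c in cols}
    if len(idx) != len(need):
        raise FormatError(f"{path}: missing columns {set(need) - set(idx)}")
    for line_no, line in rows:
        parts = line.split("\t")
        sim_s = parts[idx["sim"]]
        records.append(
            SimilarityRecord(
                drug_x=parts[idx["drug_x"]],
                drug_y=parts[idx["drug_y"]],
                sim=None if sim_s == "NA" else _parse_float(sim_s, line_no, "sim"),
                n_same=int(parts[idx["n_same"]]),
                n_opp=int(parts[idx["n_opp"]]),
                n_union=int(parts[idx["n_union"]]),
            )
        )
    return records
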