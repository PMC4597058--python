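"""Kolmogorov-Smirnov connectivity scoring of disease signatures against
ranked drug profiles, with permutation significance and star ratings.

For one side of a signature (the up- or down-regulated genes), let ``t`` be
the length of the drug's ranked protein list and ``V(1) < ... < V(n)`` the
1-based positions of the n signature genes found in that list.  The
enrichment statistic is the classic two-sided KS form

    a  = max_j ( j/n - V(j)/t )
    b  = max_j ( V(j)/t - (j-1)/n )
    es = a  if a > b  else  -b

so es > 0 means the gene set concentrates at the top of the ranking and
es < 0 at the bottom; es is always in [-1, 1].

The connectivity score of a (drug, disease) pair is ``es_up - es_down`` when
the two enrichment scores have opposite algebraic signs and 0 otherwise.  A
treatment-like pattern — the disease's up genes pushed to the bottom of the
drug profile and its down genes to the top — gives a negative score.

Significance comes from a profile-permutation null: the score is recomputed
against profiles drawn uniformly with replacement from the compendium
(excluding the observed drug), and a one-sided add-one p-value is taken in
the direction of the observed score.  Star ratings bin the score, with any
pair at p >= 0.05 demoted to one star regardless of score.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import DiseaseSignature
from .mapbuild import DrugProfile

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentInput",
    "ConnectivityResult",
    "PermutationConfig",
    "NoOverlapError",
    "ks_enrichment",
    "connectivity_score",
    "permutation_p",
    "star_rating",
    "rank_candidates",
]

DEFAULT_PERMUTATIONS = 200
SIGNIFICANCE_LEVEL = 0.05


class NoOverlapError(ValueError):
    """The tagged gene set shares no member with the ranked list."""


@dataclass
class EnrichmentInput:
    """A ranked protein list and the positions of the tagged genes within it.

    Tagged genes absent from the ranked list are dropped; positions are
    1-based and sorted ascending.
    """

    ranked: list[str]
    tagged: set[str]
    positions: np.ndarray = field(init=False)

    def __post_init__(self):
        index = {p: i + 1 for i, p in enumerate(self.ranked)}
        pos = sorted(index[g] for g in self.tagged if g in index)
        if not pos:
            raise NoOverlapError("tagged set has no member in the ranked list")
        self.positions = np.asarray(pos, dtype=float)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def t(self) -> int:
        return len(self.ranked)


@dataclass
class ConnectivityResult:
    """KS connectivity outcome for one (drug, disease) pair."""

    drug_id: str
    disease_id: str
    es_up: float
    es_down: float
    score: float
    p_value: float | None = None
    n_permutations: int = 0
    stars: int | None = None

    @property
    def is_candidate(self) -> bool:
        """Treatment candidate: significantly negative connectivity score."""
        return (
            self.score < 0
            and self.p_value is not None
            and self.p_value < SIGNIFICANCE_LEVEL
        )


@dataclass
class PermutationConfig:
    n_permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    pool: list[DrugProfile] = field(default_factory=list)

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def ks_enrichment(inp: EnrichmentInput) -> float:
    """Two-max KS enrichment statistic of the tagged positions, in [-1, 1]."""
    j = np.arange(1, inp.n + 1, dtype=float)
    v = inp.positions
    a = float(np.max(j / inp.n - v / inp.t))
    b = float(np.max(v / inp.t - (j - 1) / inp.n))
    return a if a > b else -b


def connectivity_score(
    drug: DrugProfile, signature: DiseaseSignature
) -> tuple[float, float, float]:
    """(es_up, es_down, score) for one drug profile against one signature.

    Raises :class:`NoOverlapError` if either signature side shares no gene
    with the drug's ranked list; callers convert that to a null result.
    """
    es_up = ks_enrichment(EnrichmentInput(drug.ranked, signature.up))
    es_down = ks_enrichment(EnrichmentInput(drug.ranked, signature.down))
    if np.sign(es_up) == np.sign(es_down):
        return es_up, es_down, 0.0
    return es_up, es_down, es_up - es_down


def permutation_p(
    observed_score: float,
    config: PermutationConfig,
    signature: DiseaseSignature,
    exclude_drug: str | None = None,
) -> float:
    """One-sided add-one permutation p-value for an observed score.

    Profiles are drawn uniformly with replacement from ``config.pool``
    (minus the observed drug); each draw's connectivity score against the
    same signature forms the null.  Draws with no signature overlap score 0.
    For observed < 0, p = (#{null <= observed} + 1) / (R + 1); for
    observed >= 0, p = (#{null >= observed} + 1) / (R + 1).
    """
    pool = [p for p in config.pool if p.drug_id != exclude_drug]
    if len(pool) < 2:
        raise ValueError("permutation pool must contain >= 2 other profiles")
    if len(pool) < 10:
        logger.warning(
            "permutation pool has only %d profiles; p-values will be coarse "
            "— consider generating more profiles", len(pool)
        )
    # stable per-pair stream: same seed+pair always gives the same draws,
    # while distinct pairs get distinct draws
    pair_tag = zlib.crc32(f"{exclude_drug}\t{signature.disease_id}".encode())
    rng = np.random.default_rng([config.seed, pair_tag])
    null = np.empty(config.n_permutations)
    draws = rng.integers(0, len(pool), size=config.n_permutations)
    cache: dict[str, float] = {}
    for i, ix in enumerate(draws):
        prof = pool[ix]
        if prof.drug_id not in cache:
            try:
                cache[prof.drug_id] = connectivity_score(prof, signature)[2]
            except NoOverlapError:
                cache[prof.drug_id] = 0.0
        null[i] = cache[prof.drug_id]
    if observed_score < 0:
        exceed = int(np.sum(null <= observed_score))
    else:
        exceed = int(np.sum(null >= observed_score))
    return (exceed + 1) / (config.n_permutations + 1)


def star_rating(score: float, p_value: float) -> int:
    """Map (score, p) to the 1-5 star bins.

    Non-significant pairs (p >= 0.05) get one star regardless of score;
    otherwise more negative scores earn more stars:
    score < -0.3 -> 5; [-0.3, -0.2) -> 4; [-0.2, -0.1) -> 3; [-0.1, 0) -> 2;
    score >= 0 -> 1.
    """
    if p_value >= SIGNIFICANCE_LEVEL or score >= 0:
        return 1
    if score < -0.3:
        return 5
    if score < -0.2:
        return 4
    if score < -0.1:
        return 3
    return 2


def rank_candidates(
    profiles: list[DrugProfile],
    signature: DiseaseSignature,
    config: PermutationConfig | None = None,
) -> list[ConnectivityResult]:
    """Score every profile against a signature and rank, best candidates first.

    Results are sorted ascending by score (most negative — most
    treatment-like — first), ties broken by p-value then drug id.  Profiles
    with no overlap on either signature side are omitted.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if config is None:
        config = PermutationConfig(pool=list(profiles))
    elif not config.pool:
        config.pool = list(profiles)
    results = []
    for prof in profiles:
        try:
            es_up, es_down, score = connectivity_score(prof, signature)
        except NoOverlapError:
            logger.info(
                "skipping %s vs %s: no signature overlap",
                prof.drug_id, signature.disease_id,
            )
            continue
        p = permutation_p(score, config, signature, exclude_drug=prof.drug_id)
        results.append(
            ConnectivityResult(
                drug_id=prof.drug_id,
                disease_id=signature.disease_id,
                es_up=es_up, es_down=es_down, score=score,
                p_value=p, n_permutations=config.n_permutations,
                stars=star_rating(score, p),
            )
        )
    results.sort(key=lambda r: (r.score, r.p_value, r.drug_id))
    return results


def write_connectivity(results: list[ConnectivityResult], path) -> None:
    """Write connectivity results as a TSV in rank_candidates order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "disease\tdrug\tes_up\tes_down\tscore\tp_value\tstars\tcandidate\n"
        )
        for r in results:
            fh.write(
                f"{r.disease_id}\t{r.drug_id}\t{r.es_up!r}\t{r.es_down!r}\t"
                f"{r.score!r}\t{r.p_value!r}\t{r.stars}\t{int(r.is_candidate)}\n"
            )
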