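"""Synthetic benchmark generator with planted drug-disease structure.

Emulates the statistical shape of the toolkit's four inputs so every method
can be exercised and validated without database downloads:

* drug target counts follow a truncated power law and the PPI is built by
  preferential attachment, mirroring the scale-free degree distributions of
  real drug-target and protein-interaction networks;
* each disease gets an up-regulated and a down-regulated gene module, and
  each of its true treatment drugs *inhibits* a configurable fraction of the
  up module while *activating* a matching share of the down module — so the
  drug's ranked profile anti-correlates with the signature (a negative KS
  connectivity score) and drugs treating the same disease share signed
  targets (clustered similarity for guilt-by-association);
* evidence rows per pair have probabilities uniform in ``prob_range`` and
  agree with the pair's intended direction with probability
  ``sign_consistency``;
* ``indication_noise`` corrupts the gold standard by re-assigning a fraction
  of pairs to random diseases.

:func:`null_variant` writes a matched dataset with identical marginals
(degree sequences, module sizes, evidence counts) but indications permuted
among drugs and signatures re-sampled independently of the targets — the
null for calibration tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import io as iolib
from .io import DiseaseSignature, IndicationTable

__all__ = ["SynthConfig", "SynthTruth", "generate", "null_variant", "FILENAMES"]

FILENAMES = {
    "evidence": "evidence.tsv",
    "ppi": "ppi.tsv",
    "signatures": "signatures.gmt",
    "indications": "indications.tsv",
    "truth": "truth.json",
}


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give a small but structured benchmark."""

    n_drugs: int = 50
    n_proteins: int = 300
    n_diseases: int = 5
    # truncated power law for targets-per-drug
    target_exponent: float = 3.0
    min_targets: int = 12
    max_targets: int = 30
    ppi_attachment: int = 3            # edges per new node (preferential attachment)
    evidence_per_pair: float = 2.0     # mean of 1 + Poisson(mean - 1)
    prob_range: tuple[float, float] = (0.4, 0.95)
    sign_consistency: float = 0.9      # P(evidence sign == pair's intended sign)
    module_size: int = 8               # genes per signature side
    drugs_per_disease: int = 3
    treatment_inhibition_fraction: float = 0.7
    indication_noise: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.n_diseases) < 1:
            raise ValueError("all entity counts must be positive")
        if 2 * self.module_size > self.n_proteins:
            raise ValueError("module_size too large for n_proteins")
        if not (1 <= self.min_targets <= self.max_targets <= self.n_proteins):
            raise ValueError("invalid targets-per-drug range")
        if self.ppi_attachment < 1 or self.ppi_attachment >= self.n_proteins:
            raise ValueError("invalid ppi_attachment")
        if self.evidence_per_pair < 1:
            raise ValueError("evidence_per_pair must be >= 1")
        lo, hi = self.prob_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("prob_range must be within (0, 1]")
        if not (0.5 < self.sign_consistency <= 1.0):
            raise ValueError("sign_consistency must be in (0.5, 1]")
        if not (0.0 <= self.treatment_inhibition_fraction <= 1.0):
            raise ValueError("treatment_inhibition_fraction must be in [0, 1]")
        if not (0.0 <= self.indication_noise < 1.0):
            raise ValueError("indication_noise must be in [0, 1)")
        if self.drugs_per_disease > self.n_drugs:
            raise ValueError("drugs_per_disease exceeds n_drugs")

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        """Load a flat key:value (or key=value) text config; unknown keys error."""
        cfg = cls()
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                sep = ":" if ":" in line else "="
                key, _, value = line.partition(sep)
                key, value = key.strip(), value.strip()
                if not hasattr(cfg, key):
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(cfg, key)
                if key == "prob_range":
                    parts = [float(v) for v in value.replace(",", " ").split()]
                    setattr(cfg, key, (parts[0], parts[1]))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                else:
                    setattr(cfg, key, float(value))
        return cfg


@dataclass
class SynthTruth:
    """Planted ground truth, for recovery tests."""

    true_indications: set[tuple[str, str]] = field(default_factory=set)
    disease_modules: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)
    intended_signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_indications": sorted(list(p) for p in self.true_indications),
            "disease_modules": {
                z: {"up": sorted(up), "down": sorted(dn)}
                for z, (up, dn) in sorted(self.disease_modules.items())
            },
            "intended_signs": {
                f"{d}\t{p}": s for (d, p), s in sorted(self.intended_signs.items())
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _power_law_counts(rng, cfg: SynthConfig, size: int) -> np.ndarray:
    """Stratified draw from the truncated power law on [min, max] targets.

    One uniform is placed in each of ``size`` equal probability strata
    (systematic sampling), then mapped through the inverse CDF and shuffled.
    The marginal is the same truncated power law as iid sampling, but the
    realized degree histogram tracks the law closely even at small n, which
    keeps the scale-free shape of the bipartite network stable across seeds.
    """
    ks = np.arange(cfg.min_targets, cfg.max_targets + 1)
    pmf = ks.astype(float) ** -cfg.target_exponent
    cdf = np.cumsum(pmf / pmf.sum())
    u = (np.arange(size) + rng.uniform(0.0, 1.0, size)) / size
    return rng.permutation(ks[np.searchsorted(cdf, u)])


def _build(cfg: SynthConfig):
    """Deterministic core: returns (evidence rows, ppi rows, signatures,
    indication table, truth) without touching the filesystem."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.prob_range

    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    diseases = [f"Z{i:02d}" for i in range(cfg.n_diseases)]

    # scale-free PPI by preferential attachment, uniform edge confidences
    g = nx.barabasi_albert_graph(
        cfg.n_proteins, cfg.ppi_attachment, seed=int(rng.integers(2**31))
    )
    ppi_rows = []
    for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
        conf = float(rng.uniform(lo, hi))
        ppi_rows.append((proteins[a], proteins[b], conf))

    # disease modules: up/down disjoint within a disease
    truth = SynthTruth()
    signatures = []
    for z in diseases:
        picked = rng.choice(cfg.n_proteins, size=2 * cfg.module_size, replace=False)
        up = {proteins[i] for i in picked[: cfg.module_size]}
        down = {proteins[i] for i in picked[cfg.module_size:]}
        truth.disease_modules[z] = (up, down)
        signatures.append(DiseaseSignature(disease_id=z, up=up, down=down))

    # gold standard: drugs_per_disease drugs per disease, drawn independently
    # across diseases (a drug may treat several diseases, as in real gold
    # standards), weighted toward drugs with large target budgets — the
    # well-characterized drugs are the ones whose indications are known
    target_counts = _power_law_counts(rng, cfg, cfg.n_drugs)
    treats: dict[str, list[str]] = {d: [] for d in drugs}
    budget_p = target_counts.astype(float) / target_counts.sum()
    for z in diseases:
        for i in rng.choice(cfg.n_drugs, size=cfg.drugs_per_disease,
                            replace=False, p=budget_p):
            truth.true_indications.add((drugs[i], z))
            treats[drugs[i]].append(z)

    # drug target sets: planted treatment targets absorbed into the power-law
    # budget, remainder filled preferentially toward PPI hub proteins (so the
    # protein side of the bipartite network is heavy-tailed as well)
    n_planted_side = int(round(cfg.treatment_inhibition_fraction * cfg.module_size))
    hub_weight = np.array([g.degree(i) for i in range(cfg.n_proteins)], dtype=float)
    # random fill avoids disease-module genes: only a disease's treatment
    # drugs act on its module, so signature overlap is a planted signal, not
    # an accident of the fill
    module_union = set()
    for up, down in truth.disease_modules.values():
        module_union |= up | down
    drug_targets: dict[str, dict[str, int]] = {d: {} for d in drugs}
    for di, d in enumerate(drugs):
        targets = drug_targets[d]
        for z in treats[d]:
            up, down = truth.disease_modules[z]
            up_pick = rng.choice(sorted(up), size=min(n_planted_side, len(up)),
                                 replace=False)
            dn_pick = rng.choice(sorted(down), size=min(n_planted_side, len(down)),
                                 replace=False)
            for p in up_pick:
                targets.setdefault(p, -1)   # treatment inhibits disease-up genes
            for p in dn_pick:
                targets.setdefault(p, 1)    # ... and activates disease-down genes
        n_fill = max(int(target_counts[di]) - len(targets), 0)
        mask = np.array([
            proteins[i] not in targets and proteins[i] not in module_union
            for i in range(cfg.n_proteins)
        ])
        w = hub_weight * mask
        if w.sum() == 0:
            # modules can cover (almost) the whole proteome; fall back to
            # any protein the drug does not already target
            mask = np.array([p not in targets for p in proteins])
            w = hub_weight * mask
        w /= w.sum()
        fill = rng.choice(cfg.n_proteins, size=min(n_fill, int(mask.sum())),
                          replace=False, p=w)
        fill_signs = rng.choice([1, -1], size=len(fill))
        for i, s in zip(fill, fill_signs):
            targets[proteins[i]] = int(s)
        for p, s in targets.items():
            truth.intended_signs[(d, p)] = s

    # evidence rows: >= 1 per pair, signs agree with the intended direction
    # with probability sign_consistency
    evidence_rows = []
    for d in drugs:
        for p in sorted(drug_targets[d]):
            intended = drug_targets[d][p]
            n_items = 1 + int(rng.poisson(cfg.evidence_per_pair - 1.0))
            probs = rng.uniform(lo, hi, size=n_items)
            agree = rng.random(n_items) < cfg.sign_consistency
            for prob, ok in zip(probs, agree):
                sign = intended if ok else -intended
                action = "activation" if sign > 0 else "inhibition"
                evidence_rows.append((d, p, action, float(prob), "synth"))

    # gold standard with noise: re-assign exactly floor(noise * size) pairs,
    # each to a disease the drug does not already have
    gold = sorted(truth.true_indications)
    n_noise = int(cfg.indication_noise * len(gold))
    noisy = set(gold)
    if n_noise:
        order = rng.permutation(len(gold))
        n_done = 0
        for i in order:
            if n_done == n_noise:
                break
            d, z = gold[i]
            held = {zz for dd, zz in noisy if dd == d}
            options = [zz for zz in diseases if zz not in held]
            if not options:
                continue
            z_new = options[int(rng.integers(len(options)))]
            noisy.discard((d, z))
            noisy.add((d, z_new))
            n_done += 1
    indications = IndicationTable(associations=noisy)

    return evidence_rows, ppi_rows, signatures, indications, truth


def _write(out_dir, evidence_rows, ppi_rows, signatures, indications, truth):
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in FILENAMES.items()}
    with open(paths["evidence"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\taction\tscore\tsource\n")
        for d, p, action, prob, source in evidence_rows:
            fh.write(f"{d}\t{p}\t{action}\t{prob!r}\t{source}\n")
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tconf\n")
        for a, b, conf in ppi_rows:
            fh.write(f"{a}\t{b}\t{conf!r}\n")
    iolib.write_signatures(signatures, paths["signatures"])
    iolib.write_indications(indications, paths["indications"])
    truth.to_json(paths["truth"])
    return paths


def generate(config: SynthConfig, out_dir) -> tuple[dict, SynthTruth]:
    """Write the four input files plus a truth JSON; returns (paths, truth).

    Same config and seed always produce byte-identical files.
    """
    parts = _build(config)
    paths = _write(out_dir, *parts[:4], parts[4])
    return paths, parts[4]


def null_variant(config: SynthConfig, out_dir) -> tuple[dict, SynthTruth]:
    """Matched dataset with the planted structure destroyed.

    Evidence and PPI files are identical to :func:`generate` with the same
    config (same degree sequences, same row counts).  Each gold drug keeps
    its number of indications but every indication is re-drawn uniformly at
    random — independently across drugs — so the gold standard carries no
    information about the target structure.  (A bijective relabeling of the
    drugs would preserve the per-disease totals too, but at this scale the
    fixed totals deplete each query's leave-one-out donor pool and bias the
    null AUC visibly below 0.5; independent re-draws per drug are the
    bias-free null.)  Disease modules are re-sampled independently of every
    drug's targets.
    """
    evidence_rows, ppi_rows, signatures, indications, truth = _build(config)
    rng = np.random.default_rng([config.seed, 0x5EED])

    disease_ids = sorted({z for _, z in indications.associations})
    new_assoc: set[tuple[str, str]] = set()
    for d in sorted(indications.drugs):
        k = len(indications.indications_of(d))
        picked = rng.choice(len(disease_ids), size=min(k, len(disease_ids)),
                            replace=False)
        new_assoc.update((d, disease_ids[i]) for i in picked)
    indications = IndicationTable(associations=new_assoc)

    proteins = sorted({p for _, p, *_ in evidence_rows} | {
        q for a, b, _ in ppi_rows for q in (a, b)
    })
    null_signatures = []
    null_truth = SynthTruth(
        true_indications=set(indications.associations), intended_signs={}
    )
    for sig in signatures:
        picked = rng.choice(len(proteins), size=len(sig.up) + len(sig.down),
                            replace=False)
        up = {proteins[i] for i in picked[: len(sig.up)]}
        down = {proteins[i] for i in picked[len(sig.up):]}
        null_signatures.append(
            DiseaseSignature(disease_id=sig.disease_id, up=up, down=down)
        )
        null_truth.disease_modules[sig.disease_id] = (up, down)

    paths = _write(out_dir, evidence_rows, ppi_rows, null_signatures,
                   indications, null_truth)
    return paths, null_truth
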