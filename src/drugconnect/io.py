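"""Readers and writers for the tabular and gene-set formats the toolkit touches.

All tabular files are tab-delimited UTF-8 with one header line; lines starting
with ``#`` are comments.  Identifiers (drug ids, protein/gene ids, disease ids)
are opaque, case-sensitive strings; no database-specific syntax is enforced.

Evidence files follow the STITCH "actions" shape: one row per evidence item
with an action that is either ``activation`` (stimulatory, sign +1) or
``inhibition`` (sign -1).  Rows with any other action label (binding,
catalysis, ...) carry no direction and are skipped, with the skip counted.

Disease signatures use GMT with paired set names ``<disease>_UP`` /
``<disease>_DN``; ranked drug profiles round-trip through two-column
RNK-style files at full float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EvidenceRecord",
    "PPIEdge",
    "IndicationTable",
    "DiseaseSignature",
    "ReadStats",
    "FormatError",
    "RowValidationError",
    "read_evidence",
    "read_ppi",
    "read_signatures",
    "read_indications",
    "write_indications",
    "write_ranked_profile",
    "read_ranked_profile",
]


class FormatError(ValueError):
    """File-level structural problem (missing column, unpaired GMT set, ...)."""


class RowValidationError(ValueError):
    """A row failed validation; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass(frozen=True)
class EvidenceRecord:
    """One evidence item tying a drug to a protein with direction and confidence."""

    drug_id: str
    protein_id: str
    prob: float  # per-evidence confidence, in (0, 1]
    sign: int    # +1 activation, -1 inhibition
    source: str = ""

    def __post_init__(self):
        if not self.drug_id or not self.protein_id:
            raise ValueError("drug_id and protein_id must be non-empty")
        if not (0.0 < self.prob <= 1.0):
            raise ValueError(f"prob must be in (0, 1], got {self.prob}")
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected protein-protein interaction with a confidence in (0, 1].

    The endpoint pair is stored in canonical (lexicographically sorted) order.
    """

    protein_a: str
    protein_b: str
    conf: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError("self-loops are not valid PPI edges")
        if not (0.0 < self.conf <= 1.0):
            raise ValueError(f"conf must be in (0, 1], got {self.conf}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)


@dataclass
class IndicationTable:
    """Gold-standard drug -> disease associations as a set of pairs."""

    associations: set[tuple[str, str]] = field(default_factory=set)

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.associations}

    @property
    def diseases(self) -> set[str]:
        return {z for _, z in self.associations}

    def indications_of(self, drug_id: str) -> set[str]:
        return {z for d, z in self.associations if d == drug_id}


@dataclass
class DiseaseSignature:
    """Up- and down-regulated gene identifier sets for one disease.

    The two sets are disjoint; genes appearing in both input lines are
    ambiguous and removed from both sides.
    """

    disease_id: str
    up: set[str]
    down: set[str]

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")
        if not self.up or not self.down:
            raise ValueError("up and down sets must each be non-empty")


@dataclass
class ReadStats:
    """Counts of rows a reader dropped, by reason."""

    n_rows: int = 0
    n_kept: int = 0
    n_skipped_action: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    n_ambiguous_genes: int = 0


def _data_lines(path):
    """Yield (1-based line number, stripped line) skipping blanks and comments."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def _header_index(fields: list[str], required: list[str], path) -> dict[str, int]:
    idx = {name: i for i, name in enumerate(fields)}
    for col in required:
        if col not in idx:
            raise FormatError(f"{path}: missing required column {col!r}")
    return idx


def _parse_float(text: str, line_no: int, what: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise RowValidationError(line_no, f"malformed {what}: {text!r}") from None
    return value


def read_evidence(path, return_stats: bool = False):
    """Read an evidence TSV into :class:`EvidenceRecord` items.

    Columns: drug_id, protein_id, action, score, source.  Actions other than
    ``activation``/``inhibition`` are skipped and counted.  A score outside
    (0, 1] raises :class:`RowValidationError` with the line number.
    Duplicate rows are kept: they are independent evidence items and each
    contributes to the aggregated confidence.
    """
    stats = ReadStats()
    records: list[EvidenceRecord] = []
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    idx = _header_index(
        header.split("\t"), ["drug_id", "protein_id", "action", "score"], path
    )
    for line_no, line in rows:
        parts = line.split("\t")
        if len(parts) <= max(idx[c] for c in ("drug_id", "protein_id", "action", "score")):
            raise RowValidationError(line_no, f"expected at least {len(idx)} columns")
        stats.n_rows += 1
        action = parts[idx["action"]].strip().lower()
        if action == "activation":
            sign = 1
        elif action == "inhibition":
            sign = -1
        else:
            stats.n_skipped_action += 1
            continue
        prob = _parse_float(parts[idx["score"]], line_no, "score")
        if not (0.0 < prob <= 1.0):
            raise RowValidationError(line_no, f"score {prob} outside (0, 1]")
        source = parts[idx["source"]] if "source" in idx and len(parts) > idx["source"] else ""
        records.append(
            EvidenceRecord(
                drug_id=parts[idx["drug_id"]].strip(),
                protein_id=parts[idx["protein_id"]].strip(),
                prob=prob,
                sign=sign,
                source=source,
            )
        )
        stats.n_kept += 1
    return (records, stats) if return_stats else records


def read_ppi(path, return_stats: bool = False):
    """Read a PPI edge list TSV (columns protein_a, protein_b, conf).

    Edges are undirected: each pair is canonicalized to (min, max) id order and
    deduplicated (first occurrence wins).  Self-loops are dropped and counted.
    """
    stats = ReadStats()
    edges: list[PPIEdge] = []
    seen: set[tuple[str, str]] = set()
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    idx = _header_index(header.split("\t"), ["protein_a", "protein_b", "conf"], path)
    for line_no, line in rows:
        parts = line.split("\t")
        if len(parts) <= max(idx.values()):
            raise RowValidationError(line_no, f"expected {len(idx)} columns")
        stats.n_rows += 1
        a = parts[idx["protein_a"]].strip()
        b = parts[idx["protein_b"]].strip()
        conf = _parse_float(parts[idx["conf"]], line_no, "conf")
        if not (0.0 < conf <= 1.0):
            raise RowValidationError(line_no, f"conf {conf} outside (0, 1]")
        if a == b:
            stats.n_self_loops += 1
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            stats.n_duplicates += 1
            continue
        seen.add(key)
        edges.append(PPIEdge(protein_a=a, protein_b=b, conf=conf))
        stats.n_kept += 1
    return (edges, stats) if return_stats else edges


def read_signatures(path, return_stats: bool = False):
    """Read disease signatures from a GMT file with _UP/_DN paired set names.

    Each GMT line is ``name<TAB>description<TAB>gene...``.  Lines named
    ``<disease>_UP`` and ``<disease>_DN`` are paired into one signature; a
    suffix without its partner raises :class:`FormatError`.  Genes present in
    both lines of a pair are ambiguous and removed from both sides (counted).
    """
    stats = ReadStats()
    ups: dict[str, set[str]] = {}
    downs: dict[str, set[str]] = {}
    order: list[str] = []
    for line_no, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise RowValidationError(line_no, "GMT line needs name, description, >=1 gene")
        name = parts[0].strip()
        genes = {g.strip() for g in parts[2:] if g.strip()}
        if name.endswith("_UP"):
            disease, bucket = name[:-3], ups
        elif name.endswith("_DN"):
            disease, bucket = name[:-3], downs
        else:
            raise FormatError(f"{path}: set name {name!r} lacks _UP/_DN suffix")
        if disease in bucket:
            raise FormatError(f"{path}: duplicate set for disease {disease!r}")
        bucket[disease] = genes
        if disease not in order:
            order.append(disease)
    missing = set(ups) ^ set(downs)
    if missing:
        raise FormatError(
            f"{path}: unpaired _UP/_DN sets for disease(s): {', '.join(sorted(missing))}"
        )
    signatures = []
    for disease in order:
        up, down = ups[disease], downs[disease]
        both = up & down
        stats.n_ambiguous_genes += len(both)
        signatures.append(
            DiseaseSignature(disease_id=disease, up=up - both, down=down - both)
        )
        stats.n_kept += 1
    return (signatures, stats) if return_stats else signatures


def write_signatures(signatures, path) -> None:
    """Write signatures as a GMT file pairing _UP and _DN lines per disease."""
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            up = "\t".join(sorted(sig.up))
            dn = "\t".join(sorted(sig.down))
            fh.write(f"{sig.disease_id}_UP\t{sig.disease_id}\t{up}\n")
            fh.write(f"{sig.disease_id}_DN\t{sig.disease_id}\t{dn}\n")


def read_indications(path) -> IndicationTable:
    """Read a drug->indication TSV (columns drug_id, disease_id); pairs deduplicate."""
    table = IndicationTable()
    rows = _data_lines(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    idx = _header_index(header.split("\t"), ["drug_id", "disease_id"], path)
    for line_no, line in rows:
        parts = line.split("\t")
        if len(parts) <= max(idx.values()):
            raise RowValidationError(line_no, "expected drug_id and disease_id columns")
        drug = parts[idx["drug_id"]].strip()
        disease = parts[idx["disease_id"]].strip()
        if not drug or not disease:
            raise RowValidationError(line_no, "empty drug or disease identifier")
        table.associations.add((drug, disease))
    return table


def write_indications(table: IndicationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\n")
        for drug, disease in sorted(table.associations):
            fh.write(f"{drug}\t{disease}\n")


def write_ranked_profile(profile, path) -> None:
    """Serialize a drug profile as a two-column RNK-style file.

    Proteins are written in the profile's ranked order (descending score,
    lexicographic tie-break); scores use ``repr`` so the matching reader
    round-trips bit-exactly.
    """
    if not profile.scores:
        raise ValueError("profile has no scored proteins")
    with open(path, "w", encoding="utf-8") as fh:
        for protein in profile.ranked:
            fh.write(f"{protein}\t{profile.scores[protein]!r}\n")


def read_ranked_profile(path, drug_id: str):
    """Read an RNK-style two-column file back into a DrugProfile."""
    from .mapbuild import DrugProfile

    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RowValidationError(line_no, "expected two tab-separated columns")
            scores[parts[0]] = _parse_float(parts[1], line_no, "score")
    return DrugProfile.from_scores(drug_id, scores)
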