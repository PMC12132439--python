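"""Domain types and file I/O for deep-mutational-scanning (DMS) score tables.

Coordinates are 1-based and relative to the domain sequence, matching MaveDB
domain numbering. A signed per-protein offset maps domain coordinates onto
UniProt full-length coordinates (``full = domain + offset``).

Variant tokens are accepted in two dialects: the simple form ``A5V`` / ``Q17*``
and the HGVS-pro form ``p.Ala5Val`` / ``p.Gln17Ter``. The stop symbol is ``*``
internally; ``Ter`` is accepted on input and ``*`` is emitted on output.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class VariantParseError(ValueError):
    """Raised when a variant token cannot be parsed."""


class DatasetValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a single amino-acid substitution in one protein domain."""

    protein_id: str
    position: int  # 1-based domain coordinate
    wt_aa: str
    var_aa: str  # one-letter code or '*' for a stop

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DatasetValidationError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        if self.wt_aa not in CANONICAL_AAS:
            raise DatasetValidationError(f"invalid wild-type residue {self.wt_aa!r}")
        if self.var_aa not in CANONICAL_AAS and self.var_aa != STOP:
            raise DatasetValidationError(f"invalid variant residue {self.var_aa!r}")
        if self.wt_aa == self.var_aa:
            raise DatasetValidationError(
                f"synonymous token {self.wt_aa}{self.position}{self.var_aa} is not a substitution"
            )

    @property
    def is_nonsense(self) -> bool:
        return self.var_aa == STOP

    def token(self) -> str:
        """Simple-form token, e.g. ``A5V`` or ``Q17*``."""
        return f"{self.wt_aa}{self.position}{self.var_aa}"


_SIMPLE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)$")


def parse_variant(token: str) -> tuple[int, str, str]:
    """Parse a variant token into ``(position, wt_aa, var_aa)``.

    Accepts ``A5V`` / ``Q17*`` and ``p.Ala5Val`` / ``p.Gln17Ter``.
    """
    token = token.strip()
    m = _SIMPLE_RE.match(token)
    if m:
        wt, pos, var = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1:
            raise VariantParseError(f"position must be >= 1 in {token!r}")
        if wt not in CANONICAL_AAS:
            raise VariantParseError(f"unknown wild-type residue in {token!r}")
        if var not in CANONICAL_AAS and var != STOP:
            raise VariantParseError(f"unknown variant residue in {token!r}")
        return pos, wt, var
    m = _HGVS_RE.match(token)
    if m:
        wt3, pos, var3 = m.group(1), int(m.group(2)), m.group(3)
        if pos < 1:
            raise VariantParseError(f"position must be >= 1 in {token!r}")
        if wt3 not in THREE_TO_ONE or wt3 == "Ter":
            raise VariantParseError(f"unknown 3-letter code {wt3!r} in {token!r}")
        var = STOP if var3 == STOP else THREE_TO_ONE.get(var3)
        if var is None:
            raise VariantParseError(f"unknown 3-letter code {var3!r} in {token!r}")
        return pos, THREE_TO_ONE[wt3], var
    raise VariantParseError(f"malformed variant token {token!r}")


def format_variant(key: VariantKey, hgvs: bool = False) -> str:
    if not hgvs:
        return key.token()
    var3 = "Ter" if key.var_aa == STOP else ONE_TO_THREE[key.var_aa]
    return f"p.{ONE_TO_THREE[key.wt_aa]}{key.position}{var3}"


@dataclass
class DMSRecord:
    """One observed (or imputed) variant measurement."""

    key: VariantKey
    raw_score: float = math.nan
    norm_score: float = math.nan
    imputed: bool = False

    @property
    def is_nonsense(self) -> bool:
        return self.key.is_nonsense

    def has_score(self) -> bool:
        return not (math.isnan(self.raw_score) and math.isnan(self.norm_score))


@dataclass
class DomainEntry:
    """One protein domain: sequence, coordinate offset and study baselines."""

    protein_id: str
    sequence: str
    uniprot_offset: int = 0
    family_id: str | None = None
    wt_score: float = math.nan  # s_wt, determined by the DMS study
    nonsense_baseline: float = math.nan  # s_nons, if supplied by the study


@dataclass
class DMSDataset:
    """Variant records for one or more protein domains.

    ``aux_columns`` holds optional per-variant score columns (e.g. an
    evolutionary-model score) aligned with ``records``; missing entries are NaN.
    """

    domains: dict[str, DomainEntry] = field(default_factory=dict)
    records: list[DMSRecord] = field(default_factory=list)
    aux_columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[VariantKey] = set()
        for rec in self.records:
            if rec.key in seen:
                raise DatasetValidationError(
                    f"duplicate variant {rec.key.protein_id}:{rec.key.token()}"
                )
            seen.add(rec.key)
            dom = self.domains.get(rec.key.protein_id)
            if dom is None:
                raise DatasetValidationError(
                    f"record {rec.key.token()} references unknown protein "
                    f"{rec.key.protein_id!r}"
                )
            if dom.sequence:
                if rec.key.position > len(dom.sequence):
                    raise DatasetValidationError(
                        f"{dom.protein_id}: position {rec.key.position} beyond "
                        f"sequence length {len(dom.sequence)}"
                    )
                if dom.sequence[rec.key.position - 1] != rec.key.wt_aa:
                    raise DatasetValidationError(
                        f"{dom.protein_id}: wild-type mismatch at position "
                        f"{rec.key.position}: sequence has "
                        f"{dom.sequence[rec.key.position - 1]!r}, record says "
                        f"{rec.key.wt_aa!r}"
                    )
        for name, col in self.aux_columns.items():
            if len(col) != len(self.records):
                raise DatasetValidationError(
                    f"aux column {name!r} has length {len(col)}, expected "
                    f"{len(self.records)}"
                )

    # -- convenience views -------------------------------------------------
    def keys(self) -> list[VariantKey]:
        return [r.key for r in self.records]

    def substitution_records(self) -> list[DMSRecord]:
        return [r for r in self.records if not r.is_nonsense]

    def nonsense_records(self, protein_id: str | None = None) -> list[DMSRecord]:
        return [
            r
            for r in self.records
            if r.is_nonsense
            and (protein_id is None or r.key.protein_id == protein_id)
        ]

    def record_index(self) -> dict[VariantKey, int]:
        return {r.key: i for i, r in enumerate(self.records)}

    def aux_value(self, name: str, key: VariantKey) -> float:
        idx = self.record_index().get(key)
        if idx is None:
            return math.nan
        return float(self.aux_columns[name][idx])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: Default column-name map for MaveDB-style exports.
DEFAULT_DIALECT: dict[str, str] = {
    "protein_id": "protein_id",
    "variant": "hgvs_pro",
    "raw_score": "score",
    "norm_score": "norm_score",
}

_RESERVED_META_COLUMNS = {"imputed"}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read domain sequences; record id is the protein id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")


def read_scores_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sequences: Mapping[str, str] | None = None,
    offsets: Mapping[str, int] | None = None,
    families: Mapping[str, str] | None = None,
    wt_scores: Mapping[str, float] | None = None,
) -> DMSDataset:
    """Read a variant score table (CSV, header required) into a dataset.

    Columns not named by the dialect are attached as auxiliary per-variant
    score columns (non-numeric entries become NaN).
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    records: list[DMSRecord] = []
    aux_raw: dict[str, list[float]] = {}
    protein_ids: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DatasetValidationError(f"{path}: empty file, header required")
        known = {d["protein_id"], d["variant"], d["raw_score"], d["norm_score"]}
        aux_names = [
            c for c in reader.fieldnames if c not in known | _RESERVED_META_COLUMNS
        ]
        for c in aux_names:
            aux_raw[c] = []
        for row in reader:
            pid = row[d["protein_id"]]
            pos, wt, var = parse_variant(row[d["variant"]])
            key = VariantKey(pid, pos, wt, var)
            raw = _parse_float(row.get(d["raw_score"]))
            norm = _parse_float(row.get(d["norm_score"]))
            imputed = str(row.get("imputed", "")).lower() in {"1", "true"}
            records.append(DMSRecord(key, raw, norm, imputed=imputed))
            protein_ids.append(pid)
            for c in aux_names:
                aux_raw[c].append(_parse_float(row.get(c)))
    domains: dict[str, DomainEntry] = {}
    for pid in protein_ids:
        if pid in domains:
            continue
        domains[pid] = DomainEntry(
            protein_id=pid,
            sequence=(sequences or {}).get(pid, ""),
            uniprot_offset=(offsets or {}).get(pid, 0),
            family_id=(families or {}).get(pid),
            wt_score=(wt_scores or {}).get(pid, math.nan),
        )
    aux = {name: np.asarray(vals, dtype=float) for name, vals in aux_raw.items()}
    return DMSDataset(domains=domains, records=records, aux_columns=aux)


def _parse_float(value: str | None) -> float:
    if value is None or value == "":
        return math.nan
    try:
        return float(value)
    except ValueError:
        return math.nan


def write_scores_table(dataset: DMSDataset, path: str | Path) -> None:
    """Write a dataset back to CSV; round-trips keys and scores exactly."""
    fieldnames = ["protein_id", "hgvs_pro", "score", "norm_score", "imputed"]
    fieldnames += list(dataset.aux_columns)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fieldnames)
        for i, rec in enumerate(dataset.records):
            row = [
                rec.key.protein_id,
                rec.key.token(),
                repr(float(rec.raw_score)) if not math.isnan(rec.raw_score) else "",
                repr(float(rec.norm_score)) if not math.isnan(rec.norm_score) else "",
                "true" if rec.imputed else "false",
            ]
            for col in dataset.aux_columns.values():
                v = float(col[i])
                row.append(repr(v) if not math.isnan(v) else "")
            writer.writerow(row)


def apply_offset(dataset: DMSDataset, mode: str) -> DMSDataset:
    """Shift positions between domain and UniProt full-length coordinates.

    ``to_full_length`` adds each domain's signed offset, ``to_domain``
    subtracts it; the two compose to the identity.
    """
    if mode not in {"to_full_length", "to_domain"}:
        raise ValueError(f"unknown offset mode {mode!r}")
    sign = 1 if mode == "to_full_length" else -1
    new_records = []
    for rec in dataset.records:
        off = dataset.domains[rec.key.protein_id].uniprot_offset
        new_pos = rec.key.position + sign * off
        if new_pos < 1:
            raise DatasetValidationError(
                f"{rec.key.protein_id}: offset {sign * off:+d} maps position "
                f"{rec.key.position} to {new_pos} < 1"
            )
        new_records.append(replace(rec, key=replace(rec.key, position=new_pos)))
    # Sequence-consistency checks only make sense in domain coordinates, so
    # full-length datasets carry their domains without sequences re-validated.
    if mode == "to_full_length":
        domains = {
            pid: replace(dom, sequence="") for pid, dom in dataset.domains.items()
        }
        # keep original sequences accessible for the inverse trip
        ds = DMSDataset(domains=domains, records=new_records,
                        aux_columns=dict(dataset.aux_columns))
        ds._original_sequences = {  # type: ignore[attr-defined]
            pid: dom.sequence for pid, dom in dataset.domains.items()
        }
        return ds
    domains = {}
    originals = getattr(dataset, "_original_sequences", {})
    for pid, dom in dataset.domains.items():
        seq = dom.sequence or originals.get(pid, "")
        domains[pid] = replace(dom, sequence=seq)
    return DMSDataset(domains=domains, records=new_records,
                      aux_columns=dict(dataset.aux_columns))


def all_substitution_keys(domain: DomainEntry) -> list[VariantKey]:
    """Every possible single substitution for a domain: L x 19 cells."""
    keys = []
    for pos, wt in enumerate(domain.sequence, start=1):
        for var in CANONICAL_AAS:
            if var != wt:
                keys.append(VariantKey(domain.protein_id, pos, wt, var))
    return keys
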