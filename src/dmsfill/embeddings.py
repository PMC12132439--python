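"""Provider-agnostic per-residue embeddings and variant embedding triples.

A provider maps a protein sequence to an L x D matrix of per-residue
vectors. For a variant, the features used downstream are the wild-type row
at the mutated position, the variant-sequence row at that position, and
their difference ``delta = e_var - e_wt``, which captures the local shift in
representation space induced by the mutation.

Archives store one wild-type matrix per protein plus, per variant, only the
mutated-position row (an L x D matrix per variant would be wasteful since
only that row is consumed). The on-disk format is HDF5:
``/<protein_id>/wt`` and ``/<protein_id>/variants/<token>``.

Any provider honoring ``embed(sequence) -> L x D array`` can stand behind
this contract; a real protein language model is an optional plugin, and the
deterministic :class:`MockEmbeddingProvider` serves tests and simulations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .core_io import DMSDataset, VariantKey


class EmbeddingError(KeyError):
    """Raised on missing archive entries or dimension mismatches."""


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding matrix for one protein sequence."""

    protein_id: str
    values: np.ndarray  # L x D
    provider_tag: str = "unknown"
    layer_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (L x D)")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.protein_id}: non-finite embedding values")


@dataclass
class EmbeddingTriple:
    """Wild-type, variant, and difference vectors at a mutated position."""

    e_wt: np.ndarray
    e_var: np.ndarray
    delta: np.ndarray


def variant_triple(
    wt_matrix: EmbeddingMatrix, var_matrix: EmbeddingMatrix, position: int
) -> EmbeddingTriple:
    """Extract the triple at a 1-based position; ``delta = e_var - e_wt``."""
    if wt_matrix.values.shape[1] != var_matrix.values.shape[1]:
        raise EmbeddingError(
            f"dimension mismatch: {wt_matrix.values.shape[1]} vs "
            f"{var_matrix.values.shape[1]}"
        )
    for m in (wt_matrix, var_matrix):
        if not (1 <= position <= m.values.shape[0]):
            raise EmbeddingError(
                f"position {position} out of range for {m.protein_id} "
                f"(length {m.values.shape[0]})"
            )
    e_wt = wt_matrix.values[position - 1].copy()
    e_var = var_matrix.values[position - 1].copy()
    return EmbeddingTriple(e_wt, e_var, e_var - e_wt)


class MockEmbeddingProvider:
    """Deterministic stand-in provider for tests and synthetic corpora.

    Each residue's vector is a pure function of the seed and the local
    (2*window + 1)-mer context around it, so mutating one residue perturbs
    only rows within the context window — a caricature of the locality of
    real per-residue representations.
    """

    def __init__(self, seed: int, dim: int, window: int = 3):
        if dim < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {dim}")
        self.seed = seed
        self.dim = dim
        self.window = window
        self.provider_tag = f"mock-w{window}"

    def _row(self, context: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}|{context}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        return rng.standard_normal(self.dim)

    def embed(self, sequence: str) -> np.ndarray:
        pad = "-" * self.window
        padded = pad + sequence + pad
        rows = [
            self._row(padded[i : i + 2 * self.window + 1])
            for i in range(len(sequence))
        ]
        return np.vstack(rows)


@dataclass
class EmbeddingArchive:
    """In-memory archive: wild-type matrices plus mutated-position rows."""

    wt: dict[str, EmbeddingMatrix] = field(default_factory=dict)
    variant_rows: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    dim: int = 0
    provider_tag: str = "unknown"
    layer_tag: str = ""

    def add_wt(self, matrix: EmbeddingMatrix) -> None:
        if self.dim == 0:
            self.dim = matrix.values.shape[1]
        elif matrix.values.shape[1] != self.dim:
            raise EmbeddingError(
                f"{matrix.protein_id}: dimension {matrix.values.shape[1]} != "
                f"archive dimension {self.dim}"
            )
        self.wt[matrix.protein_id] = matrix

    def add_variant_row(self, protein_id: str, token: str, row: np.ndarray) -> None:
        row = np.asarray(row, dtype=float)
        if self.dim and row.shape != (self.dim,):
            raise EmbeddingError(
                f"{protein_id}:{token}: row shape {row.shape} != ({self.dim},)"
            )
        self.variant_rows[(protein_id, token)] = row

    def triple(self, key: VariantKey) -> EmbeddingTriple:
        wt = self.wt.get(key.protein_id)
        if wt is None:
            raise EmbeddingError(f"no wild-type matrix for {key.protein_id!r}")
        row = self.variant_rows.get((key.protein_id, key.token()))
        if row is None:
            raise EmbeddingError(
                f"no variant row for {key.protein_id}:{key.token()}"
            )
        if not (1 <= key.position <= wt.values.shape[0]):
            raise EmbeddingError(
                f"position {key.position} out of range for {key.protein_id}"
            )
        e_wt = wt.values[key.position - 1].copy()
        e_var = row.copy()
        return EmbeddingTriple(e_wt, e_var, e_var - e_wt)


def build_archive(
    dataset: DMSDataset,
    provider,
    keys=None,
) -> EmbeddingArchive:
    """Embed every domain and the mutated sequence of every variant.

    ``keys`` defaults to the dataset's substitution records; pass an explicit
    list to also cover unobserved cells (e.g. before imputation).
    """
    archive = EmbeddingArchive(
        dim=provider.dim, provider_tag=getattr(provider, "provider_tag", "unknown")
    )
    for pid, dom in dataset.domains.items():
        archive.add_wt(EmbeddingMatrix(pid, provider.embed(dom.sequence),
                                       archive.provider_tag))
    if keys is None:
        keys = [r.key for r in dataset.substitution_records()]
    for key in keys:
        seq = dataset.domains[key.protein_id].sequence
        mutated = seq[: key.position - 1] + key.var_aa + seq[key.position :]
        var_matrix = provider.embed(mutated)
        archive.add_variant_row(
            key.protein_id, key.token(), var_matrix[key.position - 1]
        )
    return archive


def write_archive(archive: EmbeddingArchive, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["dim"] = archive.dim
        fh.attrs["provider_tag"] = archive.provider_tag
        fh.attrs["layer_tag"] = archive.layer_tag
        for pid, matrix in archive.wt.items():
            grp = fh.create_group(pid) if pid not in fh else fh[pid]
            grp.create_dataset("wt", data=matrix.values)
        for (pid, token), row in archive.variant_rows.items():
            if pid not in fh:
                fh.create_group(pid)
            fh[pid].require_group("variants").create_dataset(token, data=row)


def read_archive(path: str | Path) -> EmbeddingArchive:
    archive = EmbeddingArchive()
    with h5py.File(path, "r") as fh:
        archive.dim = int(fh.attrs["dim"])
        archive.provider_tag = str(fh.attrs["provider_tag"])
        archive.layer_tag = str(fh.attrs["layer_tag"])
        for pid in fh:
            grp = fh[pid]
            if "wt" in grp:
                archive.add_wt(
                    EmbeddingMatrix(pid, grp["wt"][()], archive.provider_tag,
                                    archive.layer_tag)
                )
            if "variants" in grp:
                for token in grp["variants"]:
                    archive.add_variant_row(pid, token, grp["variants"][token][()])
    return archive


def merge_archives(a: EmbeddingArchive, b: EmbeddingArchive) -> EmbeddingArchive:
    if a.dim and b.dim and a.dim != b.dim:
        raise EmbeddingError(f"cannot merge archives of dimension {a.dim} and {b.dim}")
    merged = EmbeddingArchive(dict(a.wt), dict(a.variant_rows), a.dim or b.dim,
                              a.provider_tag, a.layer_tag)
    for m in b.wt.values():
        merged.add_wt(m)
    merged.variant_rows.update(b.variant_rows)
    return merged
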