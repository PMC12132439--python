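"""Per-variant feature construction and matrix assembly.

Feature groups
--------------
``pc``
    Physicochemical properties of the wild-type and variant residues —
    numeric and boolean values for each residue plus their absolute
    difference ``|p_wt - p_var|`` — and one-hot encodings of categorical
    descriptors (chemical group, charge class, polarity).
``sm`` / ``top5sm``
    Amino-acid substitution matrix scores, one column per matrix. The all25
    roster is the 24 protein matrices shipped with Biopython plus the
    Grantham distance matrix; top5 is {blosum62, blosum80, blosum90,
    grantham, gonnet1992}.
``snv``
    1 if the substitution is reachable by a single nucleotide change under
    the standard genetic code (any codon of the wild-type residue to any
    codon of the variant), else 0.
``mean_dms`` / ``jse_dms``
    Position-level tolerance priors (see :mod:`dmsfill.normalize`).
``wt_esm`` / ``var_esm`` / ``diff_esm``
    Per-residue embedding vectors at the mutated position: wild-type row,
    variant row, and their difference.
``eve``
    An auxiliary per-variant score column (e.g. an evolutionary-model score)
    carried on the dataset.

Column order is a pure function of the configuration, so identical inputs
always yield byte-identical headers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .core_io import CANONICAL_AAS, DMSDataset, VariantKey
from .normalize import PositionPrior, lookup_prior


class FeatureError(ValueError):
    """Raised when an enabled feature group is missing its inputs."""


# ---------------------------------------------------------------------------
# Property table
# ---------------------------------------------------------------------------


@dataclass
class PropertyTable:
    """Amino-acid property roster split by column kind.

    Numeric and boolean frames are indexed by one-letter residue;
    ``categories`` fixes the (ordered) category list per categorical
    descriptor so one-hot columns are stable.
    """

    numeric: pd.DataFrame
    boolean: pd.DataFrame
    categorical: pd.DataFrame
    categories: dict[str, list[str]]


def load_property_table() -> PropertyTable:
    """Load the shipped physicochemical property table.

    Sources: standard free-amino-acid molecular weights and pKa/pI values,
    the Kyte-Doolittle hydropathy scale, and Zamyatnin residue volumes;
    booleans mark side-chain hydrogen-bonding capability and the
    buried/exposed solvent-accessibility tendency.
    """
    with resources.files("dmsfill.data").joinpath("aa_properties.csv").open() as fh:
        df = pd.read_csv(fh, index_col="aa")
    num = df[[c for c in df.columns if c.startswith("num_")]].astype(float)
    num.columns = [c[4:] for c in num.columns]
    boo = df[[c for c in df.columns if c.startswith("bool_")]].astype(int)
    boo.columns = [c[5:] for c in boo.columns]
    cat = df[[c for c in df.columns if c.startswith("cat_")]].astype(str)
    cat.columns = [c[4:] for c in cat.columns]
    categories = {c: sorted(cat[c].unique()) for c in cat.columns}
    missing = set(CANONICAL_AAS) - set(df.index)
    if missing:
        raise FeatureError(f"property table lacks residues {sorted(missing)}")
    return PropertyTable(num, boo, cat, categories)


def property_features(
    wt_aa: str, var_aa: str, table: PropertyTable
) -> dict[str, float]:
    """Numeric/boolean properties for both residues plus |p_wt - p_var|."""
    for aa in (wt_aa, var_aa):
        if aa not in CANONICAL_AAS:
            raise FeatureError(
                f"property features undefined for non-canonical residue {aa!r}"
            )
    out: dict[str, float] = {}
    both = pd.concat([table.numeric, table.boolean.astype(float)], axis=1)
    for prop in both.columns:
        pw = float(both.at[wt_aa, prop])
        pv = float(both.at[var_aa, prop])
        out[f"pc_{prop}_wt"] = pw
        out[f"pc_{prop}_var"] = pv
        out[f"pc_{prop}_absdiff"] = abs(pw - pv)
    return out


def onehot_features(
    wt_aa: str, var_aa: str, table: PropertyTable
) -> dict[str, int]:
    """One indicator column per (descriptor, category, residue role)."""
    out: dict[str, int] = {}
    for desc, cats in table.categories.items():
        for role, aa in (("wt", wt_aa), ("var", var_aa)):
            value = table.categorical.at[aa, desc]
            if value not in cats:
                raise FeatureError(f"{aa}: {desc} category {value!r} not in roster")
            for cat in cats:
                out[f"pc_{desc}_{cat}_{role}"] = int(value == cat)
    return out


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

TOP5_MATRICES = ("blosum62", "blosum80", "blosum90", "grantham", "gonnet1992")


@dataclass
class SubstitutionMatrixSet:
    """Named 20x20 score matrices with symmetrized lookup."""

    matrices: dict[str, pd.DataFrame]
    subset: str = "all25"

    def score(self, name: str, wt_aa: str, var_aa: str) -> float:
        m = self.matrices[name]
        try:
            return float(m.at[wt_aa, var_aa])
        except KeyError:
            try:
                return float(m.at[var_aa, wt_aa])
            except KeyError:
                raise FeatureError(
                    f"matrix {name!r} lacks pair ({wt_aa}, {var_aa})"
                ) from None


@lru_cache(maxsize=None)
def _biopython_protein_matrix_names() -> tuple[str, ...]:
    aas = set(CANONICAL_AAS)
    names = []
    for name in substitution_matrices.load():
        m = substitution_matrices.load(name)
        if aas <= set(m.alphabet):
            names.append(name)
    return tuple(sorted(names))


def load_grantham() -> pd.DataFrame:
    with resources.files("dmsfill.data").joinpath("grantham.csv").open() as fh:
        return pd.read_csv(fh, index_col="aa").astype(float)


def load_substitution_matrices(subset: str = "all25") -> SubstitutionMatrixSet:
    """Load the 25-matrix roster (or the top-5 subset) as dataframes."""
    if subset not in {"all25", "top5"}:
        raise ValueError(f"unknown matrix subset {subset!r}")
    mats: dict[str, pd.DataFrame] = {}
    for name in _biopython_protein_matrix_names():
        arr = substitution_matrices.load(name)
        alphabet = list(arr.alphabet)
        df = pd.DataFrame(np.asarray(arr), index=alphabet, columns=alphabet)
        aas = list(CANONICAL_AAS)
        mats[name.lower()] = df.loc[aas, aas].astype(float)
    mats["grantham"] = load_grantham()
    if subset == "top5":
        mats = {k: mats[k] for k in TOP5_MATRICES}
    return SubstitutionMatrixSet(mats, subset)


def substitution_features(
    wt_aa: str, var_aa: str, matrices: SubstitutionMatrixSet
) -> dict[str, float]:
    return {
        f"sm_{name}": matrices.score(name, wt_aa, var_aa)
        for name in sorted(matrices.matrices)
    }


# ---------------------------------------------------------------------------
# SNV indicator
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _snv_table() -> dict[tuple[str, str], int]:
    """Single-nucleotide reachability for all ordered residue pairs."""
    code = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
    codons_of: dict[str, list[str]] = {aa: [] for aa in CANONICAL_AAS}
    for codon, aa in code.forward_table.items():
        if aa in codons_of:
            codons_of[aa].append(codon)
    table: dict[tuple[str, str], int] = {}
    for a, b in itertools.permutations(CANONICAL_AAS, 2):
        reachable = any(
            sum(x != y for x, y in zip(ca, cb)) == 1
            for ca in codons_of[a]
            for cb in codons_of[b]
        )
        table[(a, b)] = int(reachable)
    return table


def snv_indicator(wt_aa: str, var_aa: str) -> int:
    """1 iff some wild-type codon and some variant codon differ at one base."""
    if wt_aa == var_aa:
        raise ValueError("SNV indicator requires a substitution (wt != var)")
    return _snv_table()[(wt_aa, var_aa)]


# ---------------------------------------------------------------------------
# Feature-set configuration and assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSetConfig:
    """Flags selecting which feature groups enter the matrix."""

    wt_esm: bool = False
    var_esm: bool = False
    diff_esm: bool = False
    mean_dms: bool = False
    jse_dms: bool = False
    pc: bool = False
    sm: bool = False
    top5sm: bool = False
    snv: bool = False
    eve: bool = False

    def __post_init__(self) -> None:
        if not any(getattr(self, f.name) for f in dc_fields(self)):
            raise ValueError("at least one feature group must be enabled")
        if self.sm and self.top5sm:
            raise ValueError("sm and top5sm are mutually exclusive")

    @property
    def needs_priors(self) -> bool:
        return self.mean_dms or self.jse_dms

    @property
    def needs_embeddings(self) -> bool:
        return self.wt_esm or self.var_esm or self.diff_esm

    @classmethod
    def preset(cls, name: str) -> "FeatureSetConfig":
        presets = {
            "full": cls(wt_esm=True, var_esm=True, diff_esm=True, mean_dms=True,
                        pc=True, sm=True, snv=True, eve=True),
            "full_minus_diff_esm": cls(wt_esm=True, var_esm=True, mean_dms=True,
                                       pc=True, sm=True, snv=True, eve=True),
            "esm_plus_mean": cls(wt_esm=True, var_esm=True, diff_esm=True,
                                 mean_dms=True),
            "mean_only": cls(mean_dms=True),
            "no_esm": cls(mean_dms=True, pc=True, sm=True, snv=True, eve=True),
            # full_minus_diff_esm with positional priors removed: no per-protein
            # assay information reaches the model.
            "zero_shot": cls(wt_esm=True, var_esm=True, pc=True, sm=True,
                             snv=True, eve=True),
        }
        if name not in presets:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(presets)}"
            )
        return presets[name]

    def without_priors(self) -> "FeatureSetConfig":
        return FeatureSetConfig(**{
            **{f.name: getattr(self, f.name) for f in dc_fields(self)},
            "mean_dms": False, "jse_dms": False,
        })

    def without_snv(self) -> "FeatureSetConfig":
        return FeatureSetConfig(**{
            **{f.name: getattr(self, f.name) for f in dc_fields(self)},
            "snv": False,
        })


@dataclass
class FeatureMatrix:
    """n_variants x n_features numeric matrix with stable named columns."""

    keys: list[VariantKey]
    columns: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.keys), len(self.columns)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.keys)} keys x {len(self.columns)} columns"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            columns=self.columns,
            index=pd.Index([k.token() for k in self.keys], name="variant"),
        )


def _pair_feature_frame(config: FeatureSetConfig) -> pd.DataFrame:
    """All residue-pair-determined columns for the 380 ordered (wt, var) pairs."""
    parts: dict[str, dict[str, float]] = {}
    table = load_property_table() if config.pc else None
    matrices = (
        load_substitution_matrices("top5" if config.top5sm else "all25")
        if (config.sm or config.top5sm)
        else None
    )
    for wt, var in itertools.permutations(CANONICAL_AAS, 2):
        row: dict[str, float] = {}
        if table is not None:
            row.update(property_features(wt, var, table))
            row.update(onehot_features(wt, var, table))
        if matrices is not None:
            row.update(substitution_features(wt, var, matrices))
        if config.snv:
            row["snv"] = snv_indicator(wt, var)
        parts[wt + var] = row
    return pd.DataFrame.from_dict(parts, orient="index")


def assemble_features(
    dataset: DMSDataset,
    config: FeatureSetConfig,
    priors: PositionPrior | Mapping[str, PositionPrior] | None = None,
    embeddings=None,
    keys: Sequence[VariantKey] | None = None,
    prior_fallback: str = "protein_mean",
) -> FeatureMatrix:
    """Assemble the feature matrix for the dataset's substitution records.

    ``keys`` overrides the row set (used when featurizing unobserved cells
    during imputation). ``priors`` may carry one prior per kind
    (``{"mean_dms": ..., "jse_dms": ...}``) or a single
    :class:`~dmsfill.normalize.PositionPrior` whose kind must match the
    enabled group.
    """
    if keys is None:
        keys = [r.key for r in dataset.substitution_records()]
    else:
        keys = list(keys)
        if any(k.is_nonsense for k in keys):
            raise FeatureError("nonsense variants cannot be feature rows")

    prior_map: dict[str, PositionPrior] = {}
    if isinstance(priors, PositionPrior):
        prior_map[priors.kind] = priors
    elif priors is not None:
        prior_map.update(priors)
    for group in ("mean_dms", "jse_dms"):
        if getattr(config, group) and group not in prior_map:
            raise FeatureError(f"feature group {group!r} enabled but no "
                               f"{group} prior supplied")
    if config.needs_embeddings and embeddings is None:
        raise FeatureError("embedding groups enabled but no archive supplied")
    if config.eve and "eve" not in dataset.aux_columns:
        raise FeatureError("eve group enabled but dataset has no 'eve' column")

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    n = len(keys)

    if config.needs_embeddings:
        D = embeddings.dim
        triples = [embeddings.triple(k) for k in keys]
        if config.wt_esm:
            columns += [f"esm_wt_{i}" for i in range(D)]
            blocks.append(np.vstack([t.e_wt for t in triples]) if n else
                          np.empty((0, D)))
        if config.var_esm:
            columns += [f"esm_var_{i}" for i in range(D)]
            blocks.append(np.vstack([t.e_var for t in triples]) if n else
                          np.empty((0, D)))
        if config.diff_esm:
            columns += [f"esm_diff_{i}" for i in range(D)]
            blocks.append(np.vstack([t.delta for t in triples]) if n else
                          np.empty((0, D)))

    fallback_counts = {}
    for group in ("mean_dms", "jse_dms"):
        if getattr(config, group):
            prior = prior_map[group]
            lookups = [lookup_prior(prior, k, prior_fallback) for k in keys]
            columns.append(group)
            blocks.append(np.array([[lv.value] for lv in lookups])
                          if n else np.empty((0, 1)))
            fallback_counts[group] = sum(lv.fallback_used for lv in lookups)

    if config.pc or config.sm or config.top5sm or config.snv:
        pair = _pair_feature_frame(config)
        idx = [k.wt_aa + k.var_aa for k in keys]
        sub = pair.loc[idx] if n else pair.iloc[:0]
        columns += list(pair.columns)
        blocks.append(sub.to_numpy(dtype=float).reshape(n, len(pair.columns)))

    if config.eve:
        record_idx = dataset.record_index()
        col = dataset.aux_columns["eve"]
        vals = np.array([
            [float(col[record_idx[k]]) if k in record_idx else np.nan]
            for k in keys
        ]) if n else np.empty((0, 1))
        columns.append("eve")
        blocks.append(vals)

    values = np.hstack(blocks) if blocks else np.empty((n, 0))
    provenance = {
        "config": config,
        "prior_sources": {g: (prior_map[g].source, prior_map[g].within_protein)
                          for g in prior_map if getattr(config, g)},
        "prior_fallback_counts": fallback_counts,
    }
    return FeatureMatrix(keys, columns, values, provenance)
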