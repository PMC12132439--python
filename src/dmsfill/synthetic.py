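"""Seeded generator of site-saturation mutagenesis corpora with known truth.

The generator emulates a stability-assay domain corpus: many short domains,
every possible single substitution at every position, nonsense variants at
every position anchoring the loss-of-function baseline, and a wild-type
anchor score. The ground-truth normalized effect of a substitution is a
product of a per-position tolerance field and a substitution-similarity
penalty::

    g(P, pos, wt->var) = 1 - tau(P, pos) * (1 - rho(wt, var))

with tau ~ Beta(a, b) per position and rho a shipped substitution matrix
rescaled to [0, 1]. g is clipped below at -0.2, mimicking the slightly
out-of-bound scores real assays produce. Raw scores are the exact inverse of
the normalization transform applied to g, plus Gaussian noise, so at zero
noise normalizing the simulated raw scores recovers g identically.

Synthetic embeddings mix affine images of tau, rho and their product along
fixed random directions with isotropic noise; ``signal_fraction=0`` is a
pure-noise negative control. The generator also emits a conservation-proxy
auxiliary column ("eve"): a noisy affine image of 1 - g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    CANONICAL_AAS,
    DMSDataset,
    DMSRecord,
    DomainEntry,
    VariantKey,
)
from .embeddings import EmbeddingArchive, EmbeddingMatrix
from .features import load_substitution_matrices


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_domains: int = 30
    length_range: tuple[int, int] = (60, 100)
    n_families: int = 8
    zipf_exponent: float = 1.5  # family-size skew
    tolerance_beta: tuple[float, float] = (2.0, 2.0)  # Beta(a, b) for tau
    similarity_matrix: str = "blosum62"
    noise_sd: float = 0.05
    nonsense_level: float = 0.2  # raw-scale loss-of-function anchor
    wt_level: float = 1.0  # raw-scale wild-type anchor
    observed_fraction: float = 0.7
    eve_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_level == self.nonsense_level:
            raise ValueError("wt_level must differ from nonsense_level")
        if not (0.0 < self.observed_fraction <= 1.0):
            raise ValueError("observed_fraction must lie in (0, 1]")
        if self.n_domains < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid corpus size parameters")


@dataclass
class GroundTruth:
    """True normalized scores and the latent fields that generated them."""

    g: dict[VariantKey, float]
    tau: dict[tuple[str, int], float]
    rho: dict[tuple[str, str], float]
    families: dict[str, str]


def _similarity(spec: SyntheticSpec) -> dict[tuple[str, str], float]:
    mats = load_substitution_matrices("top5")
    m = mats.matrices[spec.similarity_matrix]
    lo, hi = float(m.values.min()), float(m.values.max())
    rho = {}
    for wt in CANONICAL_AAS:
        for var in CANONICAL_AAS:
            rho[(wt, var)] = (float(m.at[wt, var]) - lo) / (hi - lo)
    return rho


def simulate(spec: SyntheticSpec) -> tuple[DMSDataset, GroundTruth]:
    """Generate a corpus and its ground truth; fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    rho = _similarity(spec)

    family_weights = np.array(
        [1.0 / (i + 1) ** spec.zipf_exponent for i in range(spec.n_families)]
    )
    family_weights /= family_weights.sum()

    domains: dict[str, DomainEntry] = {}
    records: list[DMSRecord] = []
    eve_col: list[float] = []
    g_map: dict[VariantKey, float] = {}
    tau_map: dict[tuple[str, int], float] = {}
    families: dict[str, str] = {}
    a, b = spec.tolerance_beta
    scale = spec.wt_level - spec.nonsense_level

    for d in range(spec.n_domains):
        pid = f"DOM{d:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = "".join(rng.choice(list(CANONICAL_AAS), size=length))
        fam = f"FAM{rng.choice(spec.n_families, p=family_weights):03d}"
        families[pid] = fam
        domains[pid] = DomainEntry(pid, seq, family_id=fam,
                                   wt_score=spec.wt_level)
        tau = rng.beta(a, b, size=length)
        for pos in range(1, length + 1):
            tau_map[(pid, pos)] = float(tau[pos - 1])

        cells: list[VariantKey] = []
        for pos, wt in enumerate(seq, start=1):
            for var in CANONICAL_AAS:
                if var != wt:
                    key = VariantKey(pid, pos, wt, var)
                    g = 1.0 - tau[pos - 1] * (1.0 - rho[(wt, var)])
                    g = max(g, -0.2)
                    g_map[key] = g
                    cells.append(key)

        n_obs = int(round(spec.observed_fraction * len(cells)))
        observed_idx = rng.choice(len(cells), size=n_obs, replace=False)
        for i in sorted(observed_idx):
            key = cells[i]
            g = g_map[key]
            raw = (g - 1.0) * scale + spec.wt_level
            raw += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            records.append(DMSRecord(key, raw_score=raw))
            eve = 1.0 - g
            if spec.eve_noise_sd > 0:
                eve += rng.normal(0.0, spec.eve_noise_sd)
            eve_col.append(float(np.clip(eve, 0.0, 1.0)))
        # one nonsense variant per position anchors the baseline
        for pos, wt in enumerate(seq, start=1):
            raw = spec.nonsense_level
            raw += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            records.append(DMSRecord(VariantKey(pid, pos, wt, "*"),
                                     raw_score=raw))
            eve_col.append(math.nan)

    dataset = DMSDataset(
        domains=domains,
        records=records,
        aux_columns={"eve": np.asarray(eve_col, dtype=float)},
    )
    truth = GroundTruth(g_map, tau_map, rho, families)
    return dataset, truth


def simulate_embeddings(
    dataset: DMSDataset,
    truth: GroundTruth,
    dim: int = 16,
    signal_fraction: float = 0.8,
    seed: int = 0,
    all_cells: bool = False,
) -> EmbeddingArchive:
    """Synthesize an embedding archive correlated with the ground truth.

    Wild-type rows carry the position's tolerance tau along a fixed random
    direction; variant rows add components proportional to the substitution
    dissimilarity (1 - rho) and to tau*(1 - rho) (an affine image of the true
    effect) along two further directions. All informative components are
    scaled by ``signal_fraction`` and the isotropic noise by its complement.

    ``all_cells=True`` also generates rows for unobserved substitution cells
    (needed before imputation).
    """
    if dim < 2:
        raise ValueError(f"embedding dimension must be >= 2, got {dim}")
    if not (0.0 <= signal_fraction <= 1.0):
        raise ValueError("signal_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((3, dim))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    u_tau, u_rho, u_g = u
    s = signal_fraction
    noise = 1.0 - s

    archive = EmbeddingArchive(dim=dim, provider_tag="synthetic",
                               layer_tag=f"signal={s}")
    for pid, dom in dataset.domains.items():
        L = len(dom.sequence)
        eps = rng.standard_normal((L, dim)) * 0.5
        taus = np.array([truth.tau[(pid, pos)] for pos in range(1, L + 1)])
        wt = s * np.outer(taus, u_tau) + noise * eps
        archive.add_wt(EmbeddingMatrix(pid, wt, "synthetic"))

    if all_cells:
        keys = sorted(truth.g)
    else:
        keys = [r.key for r in dataset.substitution_records()]
    for key in keys:
        tau = truth.tau[(key.protein_id, key.position)]
        rho = truth.rho[(key.wt_aa, key.var_aa)]
        base = archive.wt[key.protein_id].values[key.position - 1]
        row = (
            base
            + s * ((1.0 - rho) * u_rho + tau * (1.0 - rho) * u_g)
            + noise * rng.standard_normal(dim) * 0.5
        )
        archive.add_variant_row(key.protein_id, key.token(), row)
    return archive
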