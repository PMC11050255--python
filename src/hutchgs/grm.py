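"""VanRaden genomic relationship matrix and marker-density subsampling.

The G matrix follows VanRaden method 1: with observed (possibly fractional,
imputed) dosages X and allele frequencies p_j estimated from the analysed
individuals, W = X - 2p column-centres the dosages and

    G = W W' / (2 * sum_j p_j (1 - p_j)).

Monomorphic markers contribute nothing to either the numerator or the
denominator and are excluded and counted.  Marker-density experiments draw
uniform subsets of markers without replacement; each (base_seed, density,
replicate) triple defines an independent, reproducible draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

# p(1-p) at or below this is treated as monomorphic (exact zeros plus float fuzz)
_MONOMORPHIC_EPS = 1e-12


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its VanRaden scaling."""

    sample_ids: list[str]
    matrix: np.ndarray           # (n, n) symmetric
    scaling_constant: float      # 2 * sum p(1-p) over markers used
    n_markers_used: int
    excluded_markers: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix shape inconsistent with sample_ids")
        if self.scaling_constant <= 0:
            raise ValueError("scaling_constant must be positive")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class MarkerSubset:
    """A reproducible random draw of marker indices at a given density."""

    density_label: str
    indices: np.ndarray
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("marker subset indices must be unique")
        object.__setattr__(self, "indices", idx)


def density_label(density: int) -> str:
    """Human-readable density tag (500 -> '0.5K', 50_000 -> '50K', 2_000_000 -> '2M')."""
    if density >= 1_000_000:
        v = density / 1_000_000
        return f"{v:g}M"
    if density >= 1000:
        return f"{density / 1000:g}K"
    return f"{density / 1000:g}K"


def subsample_markers(n_total: int, density: int, replicate: int, base_seed: int) -> MarkerSubset:
    """Draw ``density`` marker indices uniformly without replacement.

    The random stream is a pure function of (base_seed, density, replicate),
    so replicates are mutually independent and any draw can be reproduced in
    isolation.
    """
    if density < 1:
        raise ValueError("density must be >= 1")
    if density > n_total:
        raise ValueError(f"density {density} exceeds total marker count {n_total}")
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), int(density), int(replicate)]))
    idx = np.sort(rng.choice(n_total, size=density, replace=False))
    return MarkerSubset(density_label=density_label(density), indices=idx,
                        replicate=replicate, seed=base_seed)


def vanraden_grm(
    genotypes: GenotypeMatrix,
    marker_subset: MarkerSubset | np.ndarray | None = None,
    *,
    maf: float = 0.0,
) -> GRM:
    """Build the VanRaden method-1 G matrix from dosages.

    Allele frequencies are recomputed from the input individuals (dosage
    column means / 2).  Monomorphic markers -- and, when ``maf`` > 0, markers
    below that minor-allele-frequency cutoff -- are excluded from both W and
    the scaling constant and tallied in ``excluded_markers``.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals to build a GRM")
    X = genotypes.dosage
    if marker_subset is not None:
        idx = marker_subset.indices if isinstance(marker_subset, MarkerSubset) else np.asarray(marker_subset)
        X = X[:, idx]

    p = X.mean(axis=0) / 2.0
    pq = p * (1.0 - p)
    keep = pq > _MONOMORPHIC_EPS
    if maf > 0.0:
        keep &= np.minimum(p, 1.0 - p) >= maf
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all markers monomorphic (or below the MAF cutoff): scaling constant would be 0")

    W = X[:, keep] - 2.0 * p[keep]
    c = 2.0 * float(pq[keep].sum())
    G = (W @ W.T) / c
    G = (G + G.T) / 2.0  # enforce exact symmetry against float round-off
    return GRM(
        sample_ids=list(genotypes.sample_ids),
        matrix=G,
        scaling_constant=c,
        n_markers_used=int(keep.sum()),
        excluded_markers=n_excluded,
    )


def bend_grm(G: np.ndarray, *, eps_factor: float = 1e-6) -> np.ndarray:
    """Add eps*I (eps = eps_factor * mean diagonal) to a numerically
    indefinite G so downstream factorizations succeed.  Logged loudly."""
    eps = eps_factor * float(np.mean(np.diag(G)))
    logger.warning("bending GRM: adding %.3e to the diagonal to restore positive definiteness", eps)
    return G + eps * np.eye(G.shape[0])
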