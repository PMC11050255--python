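"""Synthetic half-sib populations with multi-trait additive genetics.

Generates the study system end-to-end: founder haplotypes at random allele
frequencies, gene-dropping with Poisson recombination through a paternal
half-sib mating design, pleiotropic QTL effects that induce a target genetic
correlation structure, and phenotypes with categorical fixed effects and
per-trait missingness.  All randomness flows from a single integer seed, so
every object produced here is byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Physical scale of the genetic map: 1 cM == 1 Mb, the classic rule of thumb.
BP_PER_MORGAN = 100_000_000
# Refuse to simulate populations larger than this (guards against config typos).
DEFAULT_MAX_INDIVIDUALS = 200_000


@dataclass(frozen=True)
class PopulationDesign:
    """Mating design and genome layout for a paternal half-sib population.

    Each sire is mated to ``dams_per_sire`` dams and every dam produces one
    litter of ``offspring_per_dam`` kits, so the offspring generation has
    ``n_sires * dams_per_sire * offspring_per_dam`` individuals grouped into
    paternal half-sib families.
    """

    n_sires: int = 20
    dams_per_sire: int = 5
    offspring_per_dam: int = 10
    n_batches: int = 5
    n_chromosomes: int = 10
    markers_per_chromosome: int = 500
    chromosome_length_morgans: float = 1.0
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sires", "dams_per_sire", "offspring_per_dam",
                     "n_batches", "n_chromosomes", "markers_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 < self.maf_floor <= 0.5):
            raise ValueError(f"maf_floor must lie in (0, 0.5], got {self.maf_floor}")
        if self.chromosome_length_morgans < 0:
            raise ValueError("chromosome_length_morgans must be >= 0")

    @property
    def n_offspring(self) -> int:
        return self.n_sires * self.dams_per_sire * self.offspring_per_dam

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


@dataclass(frozen=True)
class TraitArchitecture:
    """Truth parameters the simulator embeds: per-trait heritability, the
    genetic-correlation matrix realised through pleiotropic QTL, fixed-effect
    factors, and per-trait phenotyping rates.

    ``fixed_effects`` entries are ``(factor_name, n_levels, effect_sd)``;
    level effects are drawn N(0, effect_sd^2) on the phenotypic scale
    (phenotypic variance is normalised to 1 per trait before fixed effects).
    """

    trait_names: tuple[str, ...]
    h2: tuple[float, ...]
    genetic_corr: np.ndarray
    n_qtl: int = 500
    phenotyped_fraction: tuple[float, ...] = ()
    fixed_effects: tuple[tuple[str, int, float], ...] = (("sex", 2, 0.2), ("batch", 5, 0.15))
    residual_corr: np.ndarray | None = None  # default: diagonal residuals

    def __post_init__(self) -> None:
        t = len(self.trait_names)
        if t == 0 or len(set(self.trait_names)) != t:
            raise ValueError("trait_names must be non-empty and unique")
        if len(self.h2) != t:
            raise ValueError("h2 must have one entry per trait")
        for h in self.h2:
            if not (0.0 <= h <= 1.0):
                raise ValueError(f"heritability out of [0,1]: {h}")
        C = np.asarray(self.genetic_corr, dtype=float)
        if C.shape != (t, t):
            raise ValueError(f"genetic_corr must be {t}x{t}, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.any(np.abs(C) > 1 + 1e-10):
            raise ValueError("genetic_corr entries must lie in [-1, 1]")
        object.__setattr__(self, "genetic_corr", C)
        pf = self.phenotyped_fraction or tuple(1.0 for _ in range(t))
        if len(pf) != t:
            raise ValueError("phenotyped_fraction must have one entry per trait")
        for f in pf:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"phenotyped_fraction out of (0,1]: {f}")
        object.__setattr__(self, "phenotyped_fraction", tuple(pf))
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker metadata.

    ``dosage`` holds allele counts in [0, 2]; fractional values represent
    imputed expected dosages.  Positions are 1-based base pairs, strictly
    increasing within each chromosome.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray  # per-marker chromosome label (str)
    position: np.ndarray    # per-marker bp coordinate (int, 1-based)
    dosage: np.ndarray      # (n_individuals, n_markers) float

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValueError("dosage dimensions inconsistent with id lists")
        if self.dosage.size and (self.dosage.min() < -1e-9 or self.dosage.max() > 2 + 1e-9):
            raise ValueError("dosage entries must lie in [0, 2]")
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position, dtype=np.int64)
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class TrueValues:
    """Ground truth the generator embedded: per-individual true breeding
    values and the causal marker effects behind them."""

    sample_ids: list[str]
    trait_names: list[str]
    true_breeding_values: np.ndarray  # (n, t)
    qtl_ids: list[str]
    qtl_effects: np.ndarray           # (n_qtl, t), on the final phenotype scale


def _meiosis(haplotypes: np.ndarray, chrom_slices: list[slice],
             length_morgans: float, marker_pos_frac: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent.

    ``haplotypes`` is (2, m).  Crossover counts per chromosome are Poisson
    with mean ``length_morgans``; crossover positions are uniform on the map
    (markers sit at ``marker_pos_frac`` in [0,1] of their chromosome).
    """
    gamete = np.empty(haplotypes.shape[1], dtype=haplotypes.dtype)
    for sl in chrom_slices:
        start = rng.integers(2)
        n_cross = rng.poisson(length_morgans)
        frac = marker_pos_frac[sl]
        if n_cross == 0:
            gamete[sl] = haplotypes[start, sl]
            continue
        cuts = np.sort(rng.uniform(size=n_cross))
        # haplotype index flips at each crossover point
        source = (start + np.searchsorted(cuts, frac)) % 2
        gamete[sl] = np.take_along_axis(haplotypes[:, sl], source[None, :], axis=0)[0]
    return gamete


def simulate_genotypes(
    design: PopulationDesign,
    *,
    dosage_noise: float = 0.0,
    keep_haplotypes: bool = False,
    max_individuals: int = DEFAULT_MAX_INDIVIDUALS,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a paternal half-sib population by gene dropping.

    Founders (sires and dams) get haplotypes drawn allele-by-allele at
    frequencies uniform on [maf_floor, 1 - maf_floor]; offspring receive one
    recombinant gamete from each parent.  Returns the offspring
    ``GenotypeMatrix`` and a pedigree table (id, sire, dam, family).

    ``dosage_noise`` > 0 perturbs the exact {0,1,2} dosages with truncated
    Gaussian noise of that standard deviation, mimicking imputed expected
    dosages; the default keeps dosages exact.
    """
    if design.n_markers == 0:
        raise ValueError("design yields zero markers")
    n_parents = design.n_sires + design.n_sires * design.dams_per_sire
    if design.n_offspring + n_parents > max_individuals:
        raise ValueError(
            f"population size {design.n_offspring + n_parents} exceeds safety cap {max_individuals}"
        )

    rng = np.random.default_rng(design.seed)
    m_per = design.markers_per_chromosome
    m = design.n_markers

    # Marker map: evenly jittered, strictly increasing positions per chromosome.
    span = max(int(round(design.chromosome_length_morgans * BP_PER_MORGAN)), m_per + 1)
    chrom_labels = np.repeat([f"chr{i + 1}" for i in range(design.n_chromosomes)], m_per)
    positions = np.empty(m, dtype=np.int64)
    chrom_slices = [slice(c * m_per, (c + 1) * m_per) for c in range(design.n_chromosomes)]
    for sl in chrom_slices:
        pos = np.sort(rng.choice(span, size=m_per, replace=False)) + 1
        positions[sl] = pos
    pos_frac = np.empty(m, dtype=float)
    for sl in chrom_slices:
        pos_frac[sl] = (positions[sl] - 1) / span
    marker_ids = [f"{chrom_labels[j]}:{positions[j]}" for j in range(m)]

    freqs = rng.uniform(design.maf_floor, 1.0 - design.maf_floor, size=m)

    sire_ids = [f"sire_{i + 1:03d}" for i in range(design.n_sires)]
    dam_ids = [f"dam_{i + 1:04d}" for i in range(design.n_sires * design.dams_per_sire)]
    sire_haps = (rng.uniform(size=(design.n_sires, 2, m)) < freqs).astype(np.int8)
    dam_haps = (rng.uniform(size=(len(dam_ids), 2, m)) < freqs).astype(np.int8)

    n_off = design.n_offspring
    off_haps = np.empty((n_off, 2, m), dtype=np.int8)
    ped_rows = []
    idx = 0
    for s in range(design.n_sires):
        for d_local in range(design.dams_per_sire):
            d = s * design.dams_per_sire + d_local
            for _ in range(design.offspring_per_dam):
                off_haps[idx, 0] = _meiosis(sire_haps[s], chrom_slices,
                                            design.chromosome_length_morgans, pos_frac, rng)
                off_haps[idx, 1] = _meiosis(dam_haps[d], chrom_slices,
                                            design.chromosome_length_morgans, pos_frac, rng)
                ped_rows.append((f"ind_{idx + 1:05d}", sire_ids[s], dam_ids[d], s))
                idx += 1
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "family"])

    dosage = off_haps.sum(axis=1).astype(float)
    if dosage_noise > 0.0:
        dosage = np.clip(dosage + rng.normal(0.0, dosage_noise, size=dosage.shape), 0.0, 2.0)

    geno = GenotypeMatrix(
        sample_ids=list(pedigree["id"]),
        marker_ids=marker_ids,
        chromosome=chrom_labels,
        position=positions,
        dosage=dosage,
    )
    if keep_haplotypes:
        geno.offspring_haplotypes = off_haps          # type: ignore[attr-defined]
        geno.sire_haplotypes = sire_haps              # type: ignore[attr-defined]
        geno.dam_haplotypes = dam_haps                # type: ignore[attr-defined]
        geno.chrom_slices = chrom_slices              # type: ignore[attr-defined]
    return geno, pedigree


def simulate_unrelated(n_individuals: int, n_markers: int, *,
                       maf_floor: float = 0.05, seed: int = 0) -> GenotypeMatrix:
    """Unstructured Hardy-Weinberg genotypes (founder-like, no pedigree)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_markers)
    dosage = (rng.uniform(size=(n_individuals, 2, n_markers)) < freqs).sum(axis=1).astype(float)
    positions = np.arange(1, n_markers + 1, dtype=np.int64) * 1000
    return GenotypeMatrix(
        sample_ids=[f"ind_{i + 1:05d}" for i in range(n_individuals)],
        marker_ids=[f"chr1:{p}" for p in positions],
        chromosome=np.array(["chr1"] * n_markers),
        position=positions,
        dosage=dosage,
    )


def bend_correlation(C: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PSD correlation
    matrix by eigenvalue clipping followed by re-standardisation."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    w = np.maximum(w, floor)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    return B / np.outer(d, d)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int = 0,
    *,
    bend: bool = True,
) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate correlated phenotypes on top of a genotype matrix.

    ``arch.n_qtl`` polymorphic markers are drawn as shared (pleiotropic)
    causal loci; per-QTL effect vectors are multivariate normal with
    correlation ``arch.genetic_corr``, so the genetic correlation is carried
    by the marker-level architecture rather than painted onto breeding
    values.  True breeding values are rescaled per trait so that additive
    variance equals h2 on a unit phenotypic-variance scale; residuals are
    Gaussian with variance 1 - h2 (diagonal covariance unless
    ``arch.residual_corr`` is given).  Fixed-effect factors are added on top
    and each trait is independently masked to missing with probability
    1 - phenotyped_fraction.

    Returns the phenotype table (one row per individual: id, factor columns,
    trait columns with NaN for missing) and the embedded ``TrueValues``.
    """
    rng = np.random.default_rng(seed)
    n, m = genotypes.dosage.shape
    t = arch.n_traits

    C = arch.genetic_corr
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-10:
        if not bend:
            raise ValueError(f"genetic_corr is not PSD (min eigenvalue {eigmin:.3g}) and bending is disabled")
        C = bend_correlation(C)
    elif eigmin < 1e-12:
        C = bend_correlation(C)  # make Cholesky-safe for exactly singular inputs

    if arch.n_qtl > m:
        raise ValueError(f"n_qtl={arch.n_qtl} exceeds marker count {m}")
    p = genotypes.dosage.mean(axis=0) / 2.0
    polymorphic = np.flatnonzero(p * (1.0 - p) > 1e-12)
    if len(polymorphic) < arch.n_qtl:
        raise ValueError("not enough polymorphic markers for the requested n_qtl")
    qtl = np.sort(rng.choice(polymorphic, size=arch.n_qtl, replace=False))

    L = np.linalg.cholesky(C + 1e-12 * np.eye(t))
    effects = rng.standard_normal((arch.n_qtl, t)) @ L.T

    Wq = genotypes.dosage[:, qtl] - genotypes.dosage[:, qtl].mean(axis=0)
    tbv = Wq @ effects
    tbv -= tbv.mean(axis=0)
    h2 = np.asarray(arch.h2, dtype=float)
    sd = tbv.std(axis=0, ddof=1)
    scale = np.zeros(t)
    nonzero = (h2 > 0) & (sd > 0)
    scale[nonzero] = np.sqrt(h2[nonzero]) / sd[nonzero]
    tbv = tbv * scale
    effects_scaled = effects * scale

    R = arch.residual_corr
    resid_sd = np.sqrt(1.0 - h2)
    if R is None:
        resid = rng.standard_normal((n, t)) * resid_sd
    else:
        Rr = np.asarray(R, dtype=float)
        Lr = np.linalg.cholesky(Rr + 1e-12 * np.eye(t))
        resid = (rng.standard_normal((n, t)) @ Lr.T) * resid_sd

    pheno = pd.DataFrame({"id": genotypes.sample_ids})
    fixed_part = np.zeros((n, t))
    for fname, n_levels, effect_sd in arch.fixed_effects:
        levels = rng.integers(n_levels, size=n)
        pheno[fname] = [f"{fname}{lv + 1}" for lv in levels]
        level_effects = rng.normal(0.0, effect_sd, size=(n_levels, t)) if effect_sd > 0 else np.zeros((n_levels, t))
        fixed_part += level_effects[levels]

    y = tbv + resid + fixed_part
    for j, trait in enumerate(arch.trait_names):
        col = y[:, j].copy()
        frac = arch.phenotyped_fraction[j]
        if frac < 1.0:
            missing = rng.uniform(size=n) >= frac
            col[missing] = np.nan
        pheno[trait] = col

    truth = TrueValues(
        sample_ids=list(genotypes.sample_ids),
        trait_names=list(arch.trait_names),
        true_breeding_values=tbv,
        qtl_ids=[genotypes.marker_ids[j] for j in qtl],
        qtl_effects=effects_scaled,
    )
    return pheno, truth
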