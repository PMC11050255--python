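"""Truth presets for the meat-rabbit study system.

Published single-trait heritabilities and multi-trait genetic correlations
for the nine growth and slaughter traits (weights at 35/49/70 days, feed
conversion ratio, eviscerated / half-eviscerated / kidney / hind-leg /
fore-leg weights) serve as the TRUE parameters of the synthetic populations:
recovery tests then ask the estimators to give them back.

Correlations were published only for pairs involving the three weight
traits; the remaining slaughter-trait pairs are completed synthetically by a
single-factor rule through W70 (r_ij = r_iW70 * r_jW70) and the matrix is
bent to the nearest PSD correlation matrix.
"""

from __future__ import annotations

import numpy as np

from .simulate import PopulationDesign, TraitArchitecture, bend_correlation

TRAITS = ("W35", "W49", "W70", "FCR", "EW", "HEW", "KW", "HLW", "FLW")

#: published single-trait heritabilities (whole-sequence G matrix)
HERITABILITY = {
    "W35": 0.176, "W49": 0.205, "W70": 0.121, "FCR": 0.054, "EW": 0.216,
    "HEW": 0.205, "KW": 0.153, "HLW": 0.258, "FLW": 0.082,
}

#: published genetic correlations (pairs involving W35/W49/W70 only)
GENETIC_CORRELATION = {
    ("W35", "W49"): 0.810, ("W35", "W70"): 0.617, ("W49", "W70"): 0.881,
    ("W35", "FCR"): 0.191, ("W49", "FCR"): -0.246, ("W70", "FCR"): 0.081,
    ("W35", "EW"): 0.201, ("W49", "EW"): 0.756, ("W70", "EW"): 0.899,
    ("W35", "HEW"): 0.189, ("W49", "HEW"): 0.754, ("W70", "HEW"): 0.914,
    ("W35", "KW"): 0.182, ("W49", "KW"): 0.414, ("W70", "KW"): 0.689,
    ("W35", "HLW"): 0.160, ("W49", "HLW"): 0.654, ("W70", "HLW"): 0.732,
    ("W35", "FLW"): 0.226, ("W49", "FLW"): 0.794, ("W70", "FLW"): 0.870,
}

#: slaughter traits were recorded on 798 of the 1159 growth-phenotyped animals
SLAUGHTER_FRACTION = 798.0 / 1159.0
SLAUGHTER_TRAITS = ("EW", "HEW", "KW", "NHW", "HLW", "FLW")


def rg(trait_a: str, trait_b: str) -> float:
    """Published genetic correlation for a trait pair (order-free)."""
    if trait_a == trait_b:
        return 1.0
    key = (trait_a, trait_b) if (trait_a, trait_b) in GENETIC_CORRELATION else (trait_b, trait_a)
    return GENETIC_CORRELATION[key]


def full_correlation_matrix() -> np.ndarray:
    """9x9 genetic-correlation matrix over TRAITS: published entries where
    available, single-factor completion through W70 elsewhere, bent to PSD."""
    t = len(TRAITS)
    C = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            a, b = TRAITS[i], TRAITS[j]
            if (a, b) in GENETIC_CORRELATION or (b, a) in GENETIC_CORRELATION:
                C[i, j] = C[j, i] = rg(a, b)
            else:
                C[i, j] = C[j, i] = rg(a, "W70") * rg(b, "W70")
    return bend_correlation(C)


def paper_like_architecture(*, n_qtl: int = 500,
                            with_missingness: bool = True) -> TraitArchitecture:
    """Nine correlated traits with the published heritabilities; slaughter
    traits phenotyped on the published fraction of animals when
    ``with_missingness`` is set."""
    pf = tuple(SLAUGHTER_FRACTION if (with_missingness and t in SLAUGHTER_TRAITS) else 1.0
               for t in TRAITS)
    return TraitArchitecture(
        trait_names=TRAITS,
        h2=tuple(HERITABILITY[t] for t in TRAITS),
        genetic_corr=full_correlation_matrix(),
        n_qtl=n_qtl,
        phenotyped_fraction=pf,
    )


def bivariate_architecture(trait_a: str, trait_b: str, *, n_qtl: int = 500,
                           corr: float | None = None) -> TraitArchitecture:
    """Two traits with published heritabilities and (by default) the
    published genetic correlation between them."""
    c = rg(trait_a, trait_b) if corr is None else corr
    return TraitArchitecture(
        trait_names=(trait_a, trait_b),
        h2=(HERITABILITY[trait_a], HERITABILITY[trait_b]),
        genetic_corr=np.array([[1.0, c], [c, 1.0]]),
        n_qtl=n_qtl,
    )


def paper_like_design(seed: int = 0) -> PopulationDesign:
    """~1,200 offspring, 20,000 markers: the acceptance-scale fixture."""
    return PopulationDesign(n_sires=24, dams_per_sire=5, offspring_per_dam=10,
                            n_batches=5, n_chromosomes=20, markers_per_chromosome=1000,
                            chromosome_length_morgans=1.0, maf_floor=0.05, seed=seed)


def recovery_design(seed: int = 0) -> PopulationDesign:
    """1,000 offspring (20 sires x 5 dams x 10 kits), 5,000 markers: the
    parameter-recovery scale."""
    return PopulationDesign(n_sires=20, dams_per_sire=5, offspring_per_dam=10,
                            n_batches=5, n_chromosomes=10, markers_per_chromosome=500,
                            chromosome_length_morgans=1.0, maf_floor=0.05, seed=seed)


def tiny_design(seed: int = 0) -> PopulationDesign:
    """60 offspring, 500 markers: the unit-test fixture."""
    return PopulationDesign(n_sires=4, dams_per_sire=3, offspring_per_dam=5,
                            n_batches=2, n_chromosomes=2, markers_per_chromosome=250,
                            chromosome_length_morgans=1.0, maf_floor=0.1, seed=seed)


def tiny_architecture(n_qtl: int = 50) -> TraitArchitecture:
    return bivariate_architecture("W49", "W70", n_qtl=n_qtl)
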