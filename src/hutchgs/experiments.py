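"""The two computational experiments: marker-density titration and model
comparison under 10-fold cross-validation.

Prediction accuracy is the Pearson correlation r = cov(a, p) / sqrt(var(a)
var(p)) between validation-set GEBVs and phenotypes, pooled over the k folds
of one cross-validation cycle (one r per cycle; per-fold averaging is
available behind a flag).  Accuracy distributions across replicates are
compared with a two-sample t-test (Welch by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grm import GRM, subsample_markers, vanraden_grm, density_label
from .mixedmodel import (ModelSpec, build_design, reml_mv, reml_uv, solve_blup)
from .simulate import GenotypeMatrix


# ---------------------------------------------------------------------------
# fold assignment and the accuracy statistic
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """A random k-fold partition of individuals (fold sizes differ by <= 1)."""

    ids: list[str]
    fold_of: np.ndarray
    k: int
    seed: int

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def members(self, fold: int) -> list[str]:
        return [s for s, f in zip(self.ids, self.fold_of) if f == fold]


def kfold_split(individual_ids: list[str], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds of near-equal size."""
    n = len(individual_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[order] = np.arange(n) % k
    return FoldAssignment(ids=list(individual_ids), fold_of=fold_of, k=k, seed=seed)


def accuracy(gebv: np.ndarray, phenotype: np.ndarray) -> float:
    """Pearson correlation between predicted breeding values and phenotypes
    (sample covariance/variances, missing phenotypes pairwise-excluded)."""
    a = np.asarray(gebv, dtype=float)
    p = np.asarray(phenotype, dtype=float)
    if a.shape != p.shape:
        raise ValueError("gebv and phenotype must have equal length")
    keep = np.isfinite(a) & np.isfinite(p)
    a, p = a[keep], p[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations for an accuracy")
    sa, sp = a.std(ddof=1), p.std(ddof=1)
    if sa == 0 or sp == 0:
        raise ValueError("accuracy undefined: zero variance in GEBVs or phenotypes")
    cov = float(np.sum((a - a.mean()) * (p - p.mean()))) / (len(a) - 1)
    return cov / (sa * sp)


# ---------------------------------------------------------------------------
# cross-validated prediction
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """One full k-fold cross-validation for one focal trait."""

    spec: ModelSpec
    focal_trait: str
    table: pd.DataFrame          # id, fold, gebv, phenotype (validation cases)
    accuracy: float
    fold_diagnostics: pd.DataFrame  # fold, n_validation, converged, accuracy
    folds: FoldAssignment

    def per_fold_mean_accuracy(self) -> float:
        """Mean of per-fold correlations (alternative to the pooled default)."""
        return float(self.fold_diagnostics["accuracy"].mean())


def run_cv(
    phenotypes: pd.DataFrame,
    grm: GRM,
    spec: ModelSpec,
    focal_trait: str,
    folds: FoldAssignment,
    *,
    reestimate_per_fold: bool = True,
    max_flagged_folds: int = 2,
    reml_tol: float = 1e-8,
) -> CVResult:
    """k-fold cross-validated genomic prediction for one focal trait.

    Per fold, the focal-trait phenotypes of the validation individuals are
    masked, variance components are (by default) re-estimated on the
    remaining records, GEBVs are solved for everyone, and the validation
    predictions are pooled.  Under a multivariate spec the auxiliary traits
    of validation individuals stay observed -- they are the information
    channel that lets the multi-trait model outperform the single-trait one.
    Validation GEBVs are correlated against the raw phenotypes.

    Folds whose REML fit does not converge are flagged; the run fails if
    more than ``max_flagged_folds`` are flagged.  With
    ``reestimate_per_fold=False`` components are estimated once on the full
    data (cheaper, slightly optimistic).
    """
    if focal_trait not in spec.traits:
        raise ValueError(f"focal trait '{focal_trait}' not in the model spec")
    multivariate = len(spec.traits) > 1

    phenotyped = set(phenotypes.loc[phenotypes[focal_trait].notna(), "id"])
    pheno_of = dict(zip(phenotypes["id"], phenotypes[focal_trait]))

    # full-data fit: the estimate when not re-estimating, the warm start when we are
    full_data = build_design(phenotypes, spec, grm)
    if multivariate:
        vc_full = reml_mv(full_data, tol=reml_tol)
    else:
        vc_full = reml_uv(full_data, tol=reml_tol)

    rows = []
    diags = []
    for f in range(folds.k):
        val_ids = [s for s in folds.members(f) if s in phenotyped]
        if not val_ids:
            diags.append((f, 0, True, np.nan))
            continue
        masked = phenotypes.copy()
        masked.loc[masked["id"].isin(val_ids), focal_trait] = np.nan
        data_f = build_design(masked, spec, grm)
        if reestimate_per_fold:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if multivariate:
                    vc_f = reml_mv(data_f, tol=reml_tol, init=(vc_full.M, vc_full.R))
                else:
                    vc_f = reml_uv(data_f, tol=reml_tol)
        else:
            vc_f = vc_full
        gebv_df = solve_blup(data_f, vc_f)
        gmap = dict(zip(gebv_df["id"], gebv_df[f"gebv_{focal_trait}"]))
        fold_g = np.array([gmap[s] for s in val_ids])
        fold_p = np.array([pheno_of[s] for s in val_ids])
        for s, g, p in zip(val_ids, fold_g, fold_p):
            rows.append((s, f, g, p))
        try:
            fold_acc = accuracy(fold_g, fold_p)
        except ValueError:
            fold_acc = np.nan
        diags.append((f, len(val_ids), bool(vc_f.converged), fold_acc))

    diag_df = pd.DataFrame(diags, columns=["fold", "n_validation", "converged", "accuracy"])
    n_flagged = int((~diag_df["converged"]).sum())
    if n_flagged > max_flagged_folds:
        raise RuntimeError(f"{n_flagged} folds failed to converge (> {max_flagged_folds})")

    table = pd.DataFrame(rows, columns=["id", "fold", "gebv", "phenotype"])
    pooled = accuracy(table["gebv"].to_numpy(), table["phenotype"].to_numpy())
    return CVResult(spec=spec, focal_trait=focal_trait, table=table,
                    accuracy=pooled, fold_diagnostics=diag_df, folds=folds)


# ---------------------------------------------------------------------------
# marker-density titration
# ---------------------------------------------------------------------------

@dataclass
class DensityExperimentResult:
    """Replicate accuracies and heritability estimates across a marker-density
    grid; means and SDs are always recomputable from the replicate vectors."""

    densities: list[int]
    accuracies: np.ndarray   # (n_densities, n_replicates)
    h2: np.ndarray           # (n_densities, n_replicates)
    k: int
    base_seed: int
    trait: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "density": self.densities,
            "label": [density_label(d) for d in self.densities],
            "mean_accuracy": self.accuracies.mean(axis=1),
            "sd_accuracy": self.accuracies.std(axis=1, ddof=1) if self.accuracies.shape[1] > 1
                           else np.zeros(len(self.densities)),
            "mean_h2": self.h2.mean(axis=1),
            "sd_h2": self.h2.std(axis=1, ddof=1) if self.h2.shape[1] > 1
                     else np.zeros(len(self.densities)),
        })

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, dens in enumerate(self.densities):
            for r in range(self.accuracies.shape[1]):
                rows.append((dens, r, self.accuracies[i, r], self.h2[i, r]))
        return pd.DataFrame(rows, columns=["density", "replicate", "accuracy", "h2"])


def density_experiment(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    densities: list[int],
    *,
    trait: str,
    fixed_factors: tuple[str, ...] = (),
    n_replicates: int = 30,
    k: int = 10,
    base_seed: int = 0,
    reestimate_per_fold: bool = True,
) -> DensityExperimentResult:
    """Random marker-density titration.

    For each (density, replicate) pair: draw that many markers uniformly at
    random, rebuild the VanRaden GRM, estimate the heritability by univariate
    REML on all records, and run a fresh k-fold cross-validation for the
    prediction accuracy.  Marker draws and fold assignments are both
    re-randomised per replicate, deterministically from ``base_seed``.
    """
    m = genotypes.n_markers
    if max(densities) > m:
        raise ValueError(f"max density {max(densities)} exceeds marker count {m}")
    spec = ModelSpec(traits=(trait,), fixed_factors=fixed_factors)
    ids = list(phenotypes.loc[phenotypes[trait].notna(), "id"])

    acc = np.empty((len(densities), n_replicates))
    h2 = np.empty((len(densities), n_replicates))
    for i, dens in enumerate(densities):
        for r in range(n_replicates):
            try:
                subset = subsample_markers(m, dens, r, base_seed)
                g = vanraden_grm(genotypes, subset)
                data = build_design(phenotypes, spec, g)
                h2[i, r] = reml_uv(data).h2
                fold_seed = int(np.random.SeedSequence(
                    [base_seed, dens, r, 1]).generate_state(1)[0] % (2 ** 31))
                folds = kfold_split(ids, k=k, seed=fold_seed)
                acc[i, r] = run_cv(phenotypes, g, spec, trait, folds,
                                   reestimate_per_fold=reestimate_per_fold).accuracy
            except (ValueError, RuntimeError) as err:
                raise RuntimeError(
                    f"density experiment failed at density={dens}, replicate={r}: {err}"
                ) from err
    return DensityExperimentResult(densities=list(densities), accuracies=acc, h2=h2,
                                   k=k, base_seed=base_seed, trait=trait)


# ---------------------------------------------------------------------------
# significance testing of accuracy distributions
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTest:
    """Two-sample t-test on two accuracy vectors."""

    sample_a: np.ndarray
    sample_b: np.ndarray
    t_statistic: float
    p_value: float
    df: float
    kind: str = "welch"


def compare_accuracies(a: np.ndarray, b: np.ndarray, *,
                       equal_var: bool = False) -> ComparisonTest:
    """Welch two-sample t-test (default) or Student's pooled-variance variant.

    Degenerate limits: two zero-variance samples with equal means give
    t = 0, p = 1; with unequal means the difference is certain, so p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    kind = "student" if equal_var else "welch"

    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return ComparisonTest(a, b, 0.0, 1.0, float(na + nb - 2), kind)
        return ComparisonTest(a, b, float(np.sign(ma - mb)) * np.inf, 0.0,
                              float(na + nb - 2), kind)

    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = float((ma - mb) / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonTest(a, b, t, p, float(df), kind)
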