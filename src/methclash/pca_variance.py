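"""PCA of per-sample methylation profiles and per-site variance partition.

PCA operates on methylation fractions (comparable across coverage levels)
with site-wise mean centering and no variance scaling; scores come from a
singular value decomposition, with each component's sign fixed so that its
largest-magnitude site loading is positive, making results deterministic.

The variance partition is a per-site sequential sums-of-squares
decomposition on the fraction scale in the order breed, individual within
breed, season — the nesting-aware order for a design in which every animal
belongs to one breed and is measured in both seasons.  The remainder is
residual; reported fractions are means across sites with non-zero total
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coverage_matrix import SiteMatrix
from .io_formats import ConfigurationError, DataError


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_sites, n_components)
    sample_ids: list[str]


@dataclass
class VariancePartition:
    fractions: dict[str, float]  # breed, individual, season, residual (means)
    per_site: np.ndarray  # (n_sites_used, 4) in the same order
    n_sites_used: int
    n_sites_skipped: int

    ORDER = ("breed", "individual", "season", "residual")


def methylation_pca(matrix: SiteMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the sample x site methylation-fraction matrix."""
    if matrix.n_samples < 2 or matrix.n_sites < 2:
        raise DataError("PCA needs >=2 samples and >=2 sites")
    X = matrix.P.T.astype(float)  # samples x sites
    if np.isnan(X).any():
        raise DataError("PCA input contains undefined fractions "
                        "(zero-coverage cells); apply the coverage filter first")
    X = X - X.mean(axis=0, keepdims=True)
    max_comp = min(matrix.n_samples - 1, matrix.n_sites)
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)

    total_var = float((X ** 2).sum())
    if total_var == 0.0:
        warnings.warn("zero total variance; PCA scores and explained "
                      "fractions are all zero", stacklevel=2)
        return PcaResult(
            scores=np.zeros((matrix.n_samples, n_components)),
            explained_variance_ratio=np.zeros(n_components),
            loadings=np.zeros((matrix.n_sites, n_components)),
            sample_ids=matrix.sample_ids(),
        )

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| coordinate positive per component
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return PcaResult(
        scores=U * S,
        explained_variance_ratio=S ** 2 / total_var,
        loadings=Vt.T,
        sample_ids=matrix.sample_ids(),
    )


def variance_partition(matrix: SiteMatrix) -> VariancePartition:
    """Sequential SS decomposition per site: breed, individual, season.

    Requires every animal observed in at least two seasons (otherwise the
    season stratum is undefined).  Sites where all samples are identical
    carry no variance and are skipped (logged in ``n_sites_skipped``).
    """
    samples = matrix.samples
    seasons = sorted({s.season for s in samples})
    if len(seasons) < 2:
        raise ConfigurationError("variance partition needs >=2 seasons")
    animals = sorted({s.animal_id for s in samples})
    for a in animals:
        obs = {s.season for s in samples if s.animal_id == a}
        if len(obs) < 2:
            raise ConfigurationError(
                f"animal {a!r} observed in a single season")
    breeds = sorted({s.group for s in samples})

    P = matrix.P.astype(float)  # sites x samples
    grand = P.mean(axis=1, keepdims=True)
    total_ss = ((P - grand) ** 2).sum(axis=1)

    breed_idx = {b: np.array([i for i, s in enumerate(samples) if s.group == b])
                 for b in breeds}
    animal_idx = {a: np.array([i for i, s in enumerate(samples) if s.animal_id == a])
                  for a in animals}
    season_idx = {t: np.array([i for i, s in enumerate(samples) if s.season == t])
                  for t in seasons}

    ss_breed = np.zeros(matrix.n_sites)
    for b, idx in breed_idx.items():
        mb = P[:, idx].mean(axis=1)
        ss_breed += idx.size * (mb - grand[:, 0]) ** 2

    # individual within breed: animal means about their breed mean
    ss_ind = np.zeros(matrix.n_sites)
    for a, idx in animal_idx.items():
        b = next(s.group for s in samples if s.animal_id == a)
        ma = P[:, idx].mean(axis=1)
        mb = P[:, breed_idx[b]].mean(axis=1)
        ss_ind += idx.size * (ma - mb) ** 2

    # season, fitted after animal (hence breed) effects: season means of
    # the animal-centred residuals
    R = P.copy()
    for a, idx in animal_idx.items():
        R[:, idx] -= P[:, idx].mean(axis=1, keepdims=True)
    ss_season = np.zeros(matrix.n_sites)
    for t, idx in season_idx.items():
        ss_season += idx.size * R[:, idx].mean(axis=1) ** 2

    ss_resid = np.maximum(total_ss - ss_breed - ss_ind - ss_season, 0.0)

    used = total_ss > 0
    per_site = np.column_stack([
        ss_breed[used], ss_ind[used], ss_season[used], ss_resid[used]
    ]) / total_ss[used, None]
    fractions = {
        name: float(per_site[:, k].mean()) if used.any() else 0.0
        for k, name in enumerate(VariancePartition.ORDER)
    }
    return VariancePartition(
        fractions=fractions, per_site=per_site,
        n_sites_used=int(used.sum()), n_sites_skipped=int((~used).sum()),
    )
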