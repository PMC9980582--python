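"""Per-cytosine two-group differential methylation testing.

The test is a quasi-binomial likelihood-ratio test on per-sample counts: at
each site the two-group model (one methylation proportion per group, MLE =
the pooled within-group fraction) is compared against the pooled one-
proportion model.  Replicate overdispersion is absorbed by a quasi-
likelihood correction: the Pearson statistic of the two-group model divided
by its residual degrees of freedom, floored at 1, scales the LRT, and the
scaled statistic is referred to an F(1, df_resid) distribution (the usual
reference for quasi-binomial score/deviance tests, conservative at small
replicate numbers).  A Fisher-exact-on-pooled-counts mode is provided for
degenerate replicate structures.

A cytosine is declared differentially methylated (DMC) only under the dual
filter: Benjamini-Hochberg q <= fdr AND absolute between-group methylation
difference >= min_diff.  DMCs are classed by absolute difference into
<30%, 30-70% (boundaries inclusive) and >70%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .coverage_matrix import SiteMatrix
from .io_formats import ConfigurationError, DataError, DmcRecord


def _binom_loglik(m: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sum over the last axis of the binomial log-likelihood kernel."""
    return (xlogy(m, p) + xlogy(u, 1.0 - p)).sum(axis=-1)


def qlrt_statistics(M1: np.ndarray, U1: np.ndarray,
                    M2: np.ndarray, U2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised quasi-binomial LRT over sites.

    Inputs are (n_sites, n_samples_g) count arrays.  Returns per-site
    p-values and the dispersion estimates used.  Sites where either group
    has zero total coverage get p = NaN (to be skipped by the caller).
    """
    M1, U1, M2, U2 = (np.atleast_2d(np.asarray(a, dtype=float))
                      for a in (M1, U1, M2, U2))
    n1 = M1 + U1
    n2 = M2 + U2
    t1, t2 = n1.sum(axis=1), n2.sum(axis=1)
    valid = (t1 > 0) & (t2 > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(t1 > 0, M1.sum(axis=1) / np.maximum(t1, 1), 0.0)
        p2 = np.where(t2 > 0, M2.sum(axis=1) / np.maximum(t2, 1), 0.0)
        p0 = (M1.sum(axis=1) + M2.sum(axis=1)) / np.maximum(t1 + t2, 1)

    ll_full = (_binom_loglik(M1, U1, p1[:, None])
               + _binom_loglik(M2, U2, p2[:, None]))
    ll_null = (_binom_loglik(M1, U1, p0[:, None])
               + _binom_loglik(M2, U2, p0[:, None]))
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)

    # Pearson X^2 of the two-group model; terms with fitted p in {0,1}
    # contribute 0 (the pooled MLE is then exactly the shared observation).
    def _pearson(M: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
        mu = n * p[:, None]
        var = n * p[:, None] * (1.0 - p[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(var > 0, (M - mu) ** 2 / np.where(var > 0, var, 1.0), 0.0)
        return contrib.sum(axis=1)

    x2 = _pearson(M1, n1, p1) + _pearson(M2, n2, p2)
    n_obs = (n1 > 0).sum(axis=1) + (n2 > 0).sum(axis=1)
    df_resid = np.maximum(n_obs - 2, 1)
    phi = np.maximum(x2 / df_resid, 1.0)

    pvals = stats.f.sf(lrt / phi, 1, df_resid)
    pvals = np.where(valid, pvals, np.nan)
    return pvals, phi


def fisher_pooled_pvalues(M1, U1, M2, U2) -> np.ndarray:
    """Fisher exact test on within-group pooled counts, per site."""
    M1, U1, M2, U2 = (np.atleast_2d(np.asarray(a)) for a in (M1, U1, M2, U2))
    m1, u1 = M1.sum(axis=1), U1.sum(axis=1)
    m2, u2 = M2.sum(axis=1), U2.sum(axis=1)
    out = np.empty(m1.shape[0])
    for i in range(m1.shape[0]):
        if (m1[i] + u1[i]) == 0 or (m2[i] + u2[i]) == 0:
            out[i] = np.nan
            continue
        out[i] = stats.fisher_exact(
            [[m1[i], u1[i]], [m2[i], u2[i]]], alternative="two-sided"
        )[1]
    return out


def group_mean_fractions(M: np.ndarray, U: np.ndarray,
                         mode: str = "mean_of_fractions") -> np.ndarray:
    """Per-site group methylation level.

    ``mean_of_fractions`` (default) is the unweighted mean of per-sample
    fractions, robust to coverage imbalance across animals; ``pooled``
    divides summed counts.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n = M + U
    if mode == "pooled":
        tot = n.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, M.sum(axis=1) / np.maximum(tot, 1), np.nan)
    if mode != "mean_of_fractions":
        raise ConfigurationError(f"unknown diff mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, M / np.maximum(n, 1), np.nan)
    return np.nanmean(frac, axis=1)


def test_site(meth_g1: Sequence[int], unmeth_g1: Sequence[int],
              meth_g2: Sequence[int], unmeth_g2: Sequence[int],
              diff_mode: str = "mean_of_fractions") -> tuple[float, float]:
    """Quasi-binomial LRT for one cytosine; returns (p_value, abs_meth_diff)."""
    m1 = np.asarray(meth_g1, dtype=float)[None, :]
    u1 = np.asarray(unmeth_g1, dtype=float)[None, :]
    m2 = np.asarray(meth_g2, dtype=float)[None, :]
    u2 = np.asarray(unmeth_g2, dtype=float)[None, :]
    if int(((m1 + u1) > 0).sum()) < 2 or int(((m2 + u2) > 0).sum()) < 2:
        raise DataError("each group needs >=2 samples with positive coverage")
    p, _ = qlrt_statistics(m1, u1, m2, u2)
    g1 = group_mean_fractions(m1, u1, diff_mode)
    g2 = group_mean_fractions(m2, u2, diff_mode)
    return float(p[0]), float(abs(g1[0] - g2[0]))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_diff(abs_meth_diff: float) -> str:
    """Effect-size class of a DMC: <30%, 30-70% (inclusive), >70%."""
    if abs_meth_diff < 0.30:
        return "lt30"
    if abs_meth_diff <= 0.70:
        return "30to70"
    return "gt70"


@dataclass
class DmcSummary:
    n_tested: int
    n_dmc: int
    n_mc: int
    dmc_percent: float
    class_counts: dict[str, int]
    n_skipped: int
    skip_reasons: list[str]

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested, "n_dmc": self.n_dmc, "n_mc": self.n_mc,
            "dmc_percent": self.dmc_percent, "class_counts": self.class_counts,
            "n_skipped": self.n_skipped,
        }


def call_dmcs(
    matrix: SiteMatrix,
    fdr: float = 0.05,
    min_diff: float = 0.10,
    test: str = "qlrt",
    diff_mode: str = "mean_of_fractions",
) -> tuple[list[DmcRecord], DmcSummary]:
    """Test every site of the matrix and apply the dual DMC filter.

    Group labels are taken from the matrix's sample metadata (exactly two
    groups required; group 1 is the lexicographically smaller label).
    """
    groups = sorted({s.group for s in matrix.samples})
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly two groups, got {groups!r}")
    g1 = matrix.group_mask(groups[0])
    g2 = matrix.group_mask(groups[1])

    M1, U1 = matrix.M[:, g1], matrix.U[:, g1]
    M2, U2 = matrix.M[:, g2], matrix.U[:, g2]
    if test == "qlrt":
        pvals, _ = qlrt_statistics(M1, U1, M2, U2)
    elif test == "fisher":
        pvals = fisher_pooled_pvalues(M1, U1, M2, U2)
    else:
        raise ConfigurationError(f"unknown test {test!r}")

    mean1 = group_mean_fractions(M1, U1, diff_mode)
    mean2 = group_mean_fractions(M2, U2, diff_mode)
    absdiff = np.abs(mean1 - mean2)

    tested = ~np.isnan(pvals)
    skip_reasons = [
        f"{matrix.sites.iloc[i].chrom}:{matrix.sites.iloc[i].pos}: "
        "a group has zero total coverage"
        for i in np.flatnonzero(~tested)
    ]
    qvals = np.full_like(pvals, np.nan)
    qvals[tested] = bh_adjust(pvals[tested])

    records: list[DmcRecord] = []
    class_counts = {"lt30": 0, "30to70": 0, "gt70": 0}
    for i in np.flatnonzero(tested):
        is_dmc = bool(qvals[i] <= fdr and absdiff[i] >= min_diff)
        diff_class = classify_diff(float(absdiff[i])) if is_dmc else "none"
        if is_dmc:
            class_counts[diff_class] += 1
        site = matrix.sites.iloc[i]
        records.append(DmcRecord(
            chrom=str(site.chrom), pos=int(site.pos), strand=str(site.strand),
            mean_meth_g1=float(mean1[i]), mean_meth_g2=float(mean2[i]),
            abs_meth_diff=float(absdiff[i]), p_value=float(pvals[i]),
            q_value=float(qvals[i]), is_dmc=is_dmc, diff_class=diff_class,
        ))

    n_tested = len(records)
    n_dmc = sum(r.is_dmc for r in records)
    summary = DmcSummary(
        n_tested=n_tested, n_dmc=n_dmc, n_mc=n_tested - n_dmc,
        dmc_percent=(100.0 * n_dmc / n_tested) if n_tested else 0.0,
        class_counts=class_counts,
        n_skipped=len(skip_reasons), skip_reasons=skip_reasons,
    )
    return records, summary
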