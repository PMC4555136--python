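"""Negative-binomial differential expression on gene count tables.

The analysis chain is the classic count-based two-group workflow: filter
lowly expressed genes (CPM > 1 in at least 3 samples), normalize library
sizes by the trimmed mean of M-values (TMM), estimate a single common NB
dispersion by conditional maximum likelihood on library-size-equalized
pseudo-counts, test each gene with the two-sided NB exact test conditioned
on its total pseudo-count, adjust p-values by Benjamini-Hochberg, and call a
gene differentially expressed when |fold| > 1.5 and FDR < 0.05.

Model notes
-----------
Counts for gene g in sample i are NB with mean ``mu_gi = p_g * N_i`` and
variance ``mu + phi * mu^2``; ``phi`` is the common dispersion shared by all
genes (tagwise estimation is unstable with two replicates per group).  With
``r = 1/phi``, the distribution of one group's total conditioned on the
grand total is negative hypergeometric and free of ``p_g``, which is what
the exact test evaluates.  As ``phi -> 0`` the NB degenerates to Poisson and
the conditional law to a binomial, so the exact test reduces to the
two-sided binomial exact test; two-sidedness is by the minimum-likelihood
rule (sum the probabilities of all outcomes no more probable than the one
observed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

DE_FOLD_THRESHOLD = 1.5
DE_FDR_THRESHOLD = 0.05


@dataclass
class CountTable:
    """Genes x samples integer counts with a sample -> condition map."""

    counts: pd.DataFrame
    conditions: Mapping[str, str]
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {missing}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> dict[str, list[str]]:
        g: dict[str, list[str]] = {}
        for s in self.samples:
            g.setdefault(self.conditions[s], []).append(s)
        return g


def read_count_table(counts_path, sample_sheet_path) -> CountTable:
    """Load a genes x samples count TSV plus a sample sheet TSV.

    The sample sheet needs columns ``sample`` and ``condition`` (extra
    columns such as ``replicate`` are ignored here).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    conditions = dict(zip(sheet["sample"], sheet["condition"]))
    return CountTable(counts.astype(int), conditions)


def cpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    return counts / library_sizes * 1e6


def cpm_filter(table: CountTable, min_cpm: float = 1.0,
               min_samples: int = 3) -> CountTable:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_samples`` samples.

    Library sizes are kept from the unfiltered table (they are properties of
    the sample, not of the retained gene set).
    """
    if len(table.samples) < min_samples:
        raise ValueError(
            f"CPM filter needs >= {min_samples} samples, "
            f"got {len(table.samples)}")
    c = cpm(table.counts, table.library_sizes)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    return CountTable(table.counts.loc[keep], dict(table.conditions),
                      table.library_sizes.copy())


def tmm_factors(counts: pd.DataFrame,
                library_sizes: pd.Series | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile.  For each sample, genes expressed in both the
    sample and the reference contribute a log-ratio M and a mean abundance
    A; the most extreme 30% of M and 5% of A are trimmed and the factor is
    the precision-weighted mean of the remaining M values (weights are the
    inverse asymptotic variances of M).  Factors are normalized to have
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    mat = counts.to_numpy(dtype=float)
    libs = library_sizes.to_numpy(dtype=float)

    expressed = mat.sum(axis=1) > 0
    if expressed.sum() <= 1:
        import warnings
        warnings.warn("degenerate count table; TMM factors set to 1")
        return pd.Series(1.0, index=counts.columns)

    p = mat / libs  # proportions
    uq = np.array([np.quantile(p[expressed, j], 0.75)
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref], libs[j], libs[ref],
                               trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    ok = (obs > 0) & (ref > 0)
    if ok.sum() == 0:
        return 1.0
    obs, ref = obs[ok], ref[ok]
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = 1.0 / ((n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref))
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def effective_library_sizes(table: CountTable,
                            factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(table.counts, table.library_sizes)
    return table.library_sizes * factors


def equalize_libraries(counts: pd.DataFrame,
                       eff_libs: pd.Series) -> tuple[pd.DataFrame, float]:
    """Scale counts to a common (geometric-mean) library size.

    A linear rescaling — the simplest equalization that preserves expected
    proportions; the common size is returned for use by the exact test.
    """
    common = float(np.exp(np.mean(np.log(eff_libs.to_numpy()))))
    pseudo = counts * (common / eff_libs)
    return pseudo, common


def _conditional_loglik(pseudo: np.ndarray, groups: np.ndarray,
                        phi: float) -> float:
    """Summed NB conditional log-likelihood over genes, given group totals."""
    r = 1.0 / phi
    ll = 0.0
    for g in np.unique(groups):
        sub = pseudo[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            continue  # a single sample carries no dispersion information
        z = sub.sum(axis=1)
        ll += float(
            np.sum(gammaln(sub + r) - gammaln(r) - gammaln(sub + 1.0))
            - np.sum(gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1.0))
        )
    return ll


def common_dispersion(table: CountTable,
                      factors: pd.Series | None = None,
                      bounds: tuple[float, float] = (1e-6, 10.0)) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Maximizes the conditional likelihood of the library-size-equalized
    pseudo-counts given each gene's within-group total, over a single
    dispersion shared by all genes.  Returns the lower bound when the data
    look Poisson (underdispersed).
    """
    eff = effective_library_sizes(table, factors)
    pseudo, _ = equalize_libraries(table.counts, eff)
    mat = pseudo.to_numpy(dtype=float)
    groups = np.array([table.conditions[s] for s in table.counts.columns])

    def neg(log_phi: float) -> float:
        return -_conditional_loglik(mat, groups, float(np.exp(log_phi)))

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-4})
    phi = float(np.exp(res.x))
    # flat likelihood at the lower bound means "effectively Poisson"
    if neg(np.log(bounds[0])) <= res.fun + 1e-9:
        phi = bounds[0]
    return phi


def _min_likelihood_pvalue(logpmf: np.ndarray, observed: int) -> float:
    """Two-sided exact p: total probability of outcomes no more likely
    than the observed one (with a small tolerance for float ties)."""
    logp_obs = logpmf[observed]
    p = np.exp(logpmf)
    return float(min(1.0, p[logpmf <= logp_obs + 1e-10].sum()))


def _exact_pvalue(y1: int, z: int, n1: int, n2: int, phi: float) -> float:
    """Exact two-sided p for group-1 total y1 given grand total z."""
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi < 1e-8:
        # Poisson limit: conditional law is binomial(z, n1/(n1+n2))
        p = n1 / (n1 + n2)
        logpmf = (gammaln(z + 1) - gammaln(k + 1) - gammaln(z - k + 1)
                  + k * np.log(p) + (z - k) * np.log1p(-p))
    else:
        r = 1.0 / phi
        r1, r2 = n1 * r, n2 * r
        logpmf = (gammaln(k + r1) - gammaln(k + 1) - gammaln(r1)
                  + gammaln(z - k + r2) - gammaln(z - k + 1) - gammaln(r2)
                  - (gammaln(z + r1 + r2) - gammaln(z + 1)
                     - gammaln(r1 + r2)))
        logpmf = logpmf - _logsumexp(logpmf)
    return _min_likelihood_pvalue(logpmf, int(y1))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def nb_exact_test(table: CountTable,
                  factors: pd.Series | None = None,
                  dispersion: float | None = None,
                  group_order: Sequence[str] | None = None) -> pd.Series:
    """Per-gene two-sided exact NB test p-values between two conditions.

    Counts are equalized to a common library size using TMM effective sizes;
    each gene's rounded group totals are tested conditional on their sum.
    All-zero genes get p = 1.  The test is symmetric under swapping the two
    group labels.
    """
    groups = table.groups()
    if len(groups) != 2:
        raise ValueError(f"exact test needs 2 conditions, got {len(groups)}")
    if group_order is None:
        group_order = sorted(groups)
    g1, g2 = group_order
    if factors is None:
        factors = tmm_factors(table.counts, table.library_sizes)
    if dispersion is None:
        dispersion = common_dispersion(table, factors)
    eff = effective_library_sizes(table, factors)
    pseudo, _ = equalize_libraries(table.counts, eff)
    n1, n2 = len(groups[g1]), len(groups[g2])
    y1 = pseudo[groups[g1]].sum(axis=1).round().astype(int)
    y2 = pseudo[groups[g2]].sum(axis=1).round().astype(int)
    pvals = np.array([
        _exact_pvalue(a, a + b, n1, n2, dispersion)
        for a, b in zip(y1.to_numpy(), y2.to_numpy())
    ])
    return pd.Series(pvals, index=table.counts.index, name="pvalue")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_analysis(table: CountTable,
                numerator: str | None = None,
                denominator: str | None = None,
                min_cpm: float = 1.0, min_samples: int = 3,
                fold_threshold: float = DE_FOLD_THRESHOLD,
                fdr_threshold: float = DE_FDR_THRESHOLD) -> pd.DataFrame:
    """Full DE chain: CPM filter -> TMM -> dispersion -> exact test -> BH.

    Fold changes are ratios of group mean CPMs on effective library sizes
    (numerator condition over denominator).  ``is_de`` requires both
    |fold| > ``fold_threshold`` (in either direction) and
    FDR < ``fdr_threshold``.
    """
    filtered = cpm_filter(table, min_cpm, min_samples)
    groups = filtered.groups()
    if len(groups) != 2:
        raise ValueError("DE analysis needs exactly 2 conditions")
    conds = sorted(groups)
    if numerator is None or denominator is None:
        denominator, numerator = conds
    factors = tmm_factors(filtered.counts, filtered.library_sizes)
    dispersion = common_dispersion(filtered, factors)
    pvals = nb_exact_test(filtered, factors, dispersion,
                          group_order=(numerator, denominator))
    eff = effective_library_sizes(filtered, factors)
    norm_cpm = cpm(filtered.counts, eff)
    mean_num = norm_cpm[groups[numerator]].mean(axis=1)
    mean_den = norm_cpm[groups[denominator]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_num / mean_den
        logfc = np.log2(fold)
    fdr = bh_fdr(pvals.to_numpy())
    res = pd.DataFrame({
        "gene": filtered.counts.index,
        "mean_cpm_num": mean_num.to_numpy(),
        "mean_cpm_den": mean_den.to_numpy(),
        "fold": fold.to_numpy(),
        "logFC": logfc.to_numpy(),
        "pvalue": pvals.to_numpy(),
        "fdr": fdr,
    }).set_index("gene")
    res.attrs["dispersion"] = dispersion
    res.attrs["tmm_factors"] = factors.to_dict()
    return call_de(res, fold_threshold, fdr_threshold)


def call_de(results: pd.DataFrame,
            fold_threshold: float = DE_FOLD_THRESHOLD,
            fdr_threshold: float = DE_FDR_THRESHOLD) -> pd.DataFrame:
    """Flag DE genes and rank by |logFC| (largest effects first)."""
    res = results.copy()
    fold = res["fold"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        up = fold > fold_threshold
        down = fold < 1.0 / fold_threshold
    res["is_de"] = (up | down) & (res["fdr"] < fdr_threshold)
    res.attrs.update(results.attrs)
    return res.sort_values("logFC", key=lambda s: s.abs(), ascending=False)


def top_table(results: pd.DataFrame, n: int = 18) -> pd.DataFrame:
    """Top-N up- and down-regulated DE genes, signed-fold layout.

    Down-regulation is reported as a negative fold (-1/fold), the layout
    used in published top-gene tables.
    """
    de = results[results["is_de"]].copy()
    de["signed_fold"] = np.where(de["fold"] >= 1.0, de["fold"],
                                 -1.0 / de["fold"])
    up = de[de["signed_fold"] > 0].nlargest(n, "signed_fold")
    down = de[de["signed_fold"] < 0].nsmallest(n, "signed_fold")
    up = up.assign(direction="up")
    down = down.assign(direction="down")
    return pd.concat([up, down])[["direction", "signed_fold", "pvalue",
                                  "fdr"]]


def replicate_correlation(table: CountTable,
                          factors: pd.Series | None = None) -> pd.DataFrame:
    """R^2 of log-CPM between replicate pairs within each condition.

    The replicate-agreement QC: values above ~0.99 indicate well-behaved
    biological replicates.
    """
    eff = effective_library_sizes(table, factors)
    norm = cpm(table.counts, eff)
    rows = []
    for cond, samples in table.groups().items():
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a = np.log2(norm[samples[i]] + 0.5)
                b = np.log2(norm[samples[j]] + 0.5)
                r = float(np.corrcoef(a, b)[0, 1])
                rows.append((cond, samples[i], samples[j], r * r))
    return pd.DataFrame(rows, columns=["condition", "sample_a", "sample_b",
                                       "r_squared"])
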