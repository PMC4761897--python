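"""Normalization, filtering and per-gene allele-imbalance testing.

Within an F1 hybrid the two parental alleles of a gene share one nucleus
and therefore one trans environment, so a reproducible difference in
allele-resolved read counts is evidence of cis-regulatory divergence.
The statistical machinery is the classic count-based toolkit:

* TMM (trimmed mean of M-values) between-library normalization — one
  scaling factor per count column from doubly-trimmed, precision-weighted
  log-ratios against a reference column.
* A table-wide common negative-binomial dispersion, estimated by
  conditional maximum likelihood on counts quantile-adjusted to a common
  effective library size (the two alleles are treated as the same gene
  measured in two conditions with replicates).
* A two-sided conditional NB exact test per gene: condition on the total
  of the two allele-group sums and accumulate the probability of all
  outcomes at most as probable as the one observed.
* Storey q-values (or plain Benjamini-Hochberg) for FDR control.

Counts enter as an :class:`AlleleCountTable`; results leave as one
:class:`AseRecord` row per gene x hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

DEFAULT_MIN_READS = 10
DEFAULT_FDR = 0.05


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# count container


@dataclass
class AlleleCountTable:
    """Allele-resolved counts K[gene, (hybrid, allele, replicate)].

    Columns are a lexicographically sorted MultiIndex (hybrid, allele,
    replicate); library sizes are column sums and TMM factors are computed
    lazily over all columns of the table.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex) or self.counts.columns.nlevels != 3:
            raise ValueError("counts needs MultiIndex columns (hybrid, allele, replicate)")
        self.counts = self.counts.sort_index(axis=1).sort_index(axis=0)
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "AlleleCountTable":
        """Build from a tidy frame with columns gene, hybrid, allele, replicate, count."""
        df = df[df["allele"] != "uninformative"]
        wide = df.pivot_table(index="gene", columns=["hybrid", "allele", "replicate"],
                              values="count", fill_value=0, aggfunc="sum")
        return cls(wide)

    def to_tidy(self) -> pd.DataFrame:
        out = self.counts.stack(["hybrid", "allele", "replicate"], future_stack=True)
        out = out.rename("count").reset_index()
        return out[["gene", "hybrid", "allele", "replicate", "count"]]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def hybrids(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values("hybrid")))

    def alleles(self, hybrid: str) -> tuple[str, str]:
        cols = self.counts[hybrid].columns.get_level_values("allele")
        uniq = list(dict.fromkeys(cols))
        if len(uniq) != 2:
            raise ValueError(f"hybrid {hybrid} has {len(uniq)} alleles, expected 2")
        return uniq[0], uniq[1]

    @cached_property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    @cached_property
    def tmm(self) -> pd.Series:
        return tmm_factors(self.counts)

    @property
    def effective_sizes(self) -> pd.Series:
        return self.lib_sizes * self.tmm

    def normalized(self) -> pd.DataFrame:
        """Counts rescaled to the geometric-mean effective library size."""
        eff = self.effective_sizes
        target = float(np.exp(np.mean(np.log(eff))))
        return self.counts / eff * target


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per count column.

    The reference column is the one whose upper quartile of count
    fractions is closest to the mean upper quartile.  Against it, each
    column's factor is 2**(weighted trimmed mean of per-gene log2 ratios),
    with genes zero in either column excluded, two-sided rank trimming of
    the M values (``trim_m`` per tail) and of the average log abundances
    (``trim_a`` per tail), and inverse asymptotic variances as weights.
    Factors are rescaled so their geometric mean is 1.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise NormalizationError("TMM needs at least 2 columns")
    lib = mat.sum(axis=0)
    zero_cols = np.nonzero(lib == 0)[0]
    if zero_cols.size:
        name = counts.columns[zero_cols[0]]
        raise NormalizationError(f"all-zero count column: {name}")
    uq = np.percentile(mat / lib, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(mat[:, j], lib[j], mat[:, ref], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def _tmm_pair(obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 1.0
    y, r = obs[keep], ref[keep]
    m = np.log2((y / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((y / n_obs) * (r / n_ref))
    w = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(sel) or np.sum(w[sel]) == 0:
        return 1.0
    f = np.sum(w[sel] * m[sel]) / np.sum(w[sel])
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# detectability filters


def apply_filters(table: AlleleCountTable, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per-gene detectability flags from raw counts.

    ``detectable_<hybrid>`` is True iff some replicate of that hybrid has
    at least ``min_reads`` reads for *both* alleles; ``uda`` ("universally
    detectable") requires at least ``min_reads`` per allele in every
    replicate of every hybrid, making the gene comparable across crosses.
    """
    out = pd.DataFrame(index=table.genes)
    uda = np.ones(len(table.genes), dtype=bool)
    for h in table.hybrids:
        a1, a2 = table.alleles(h)
        c1 = table.counts[h][a1].to_numpy()
        c2 = table.counts[h][a2].to_numpy()
        both = (c1 >= min_reads) & (c2 >= min_reads)
        out[f"detectable_{h}"] = both.any(axis=1)
        uda &= both.all(axis=1)
    out["uda"] = uda
    return out


# ---------------------------------------------------------------------------
# quantile adjustment to a common library size


def q2qnbinom(x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray,
              dispersion: float = 0.0) -> np.ndarray:
    """Map counts between library sizes by matched NB quantiles.

    Each count is converted to a tail probability under normal and gamma
    approximations of NB(input_mean, dispersion) and back through the
    corresponding quantile at output_mean; the two transforms are
    averaged.  This preserves the mean-variance relationship, unlike a
    plain rescaling.
    """
    x = np.asarray(x, dtype=float)
    input_mean = np.broadcast_to(np.asarray(input_mean, dtype=float), x.shape).copy()
    output_mean = np.broadcast_to(np.asarray(output_mean, dtype=float), x.shape).copy()
    eps = 1e-14
    small = (input_mean < eps) | (output_mean < eps)
    input_mean[small] += 0.25
    output_mean[small] += 0.25

    ri = 1.0 + dispersion * input_mean
    vi = input_mean * ri
    ro = 1.0 + dispersion * output_mean
    vo = output_mean * ro

    upper = x >= input_mean
    q = np.empty_like(x)
    for mask, tail in ((upper, False), (~upper, True)):
        if not np.any(mask):
            continue
        xm, im, om = x[mask], input_mean[mask], output_mean[mask]
        vim, vom = vi[mask], vo[mask]
        rim, rom = ri[mask], ro[mask]
        if tail:
            p_norm = stats.norm.cdf(xm, im, np.sqrt(vim))
            p_gam = stats.gamma.cdf(xm, im / rim, scale=rim)
            q1 = stats.norm.ppf(p_norm, om, np.sqrt(vom))
            q2 = stats.gamma.ppf(p_gam, om / rom, scale=rom)
        else:
            p_norm = stats.norm.sf(xm, im, np.sqrt(vim))
            p_gam = stats.gamma.sf(xm, im / rim, scale=rim)
            q1 = stats.norm.isf(p_norm, om, np.sqrt(vom))
            q2 = stats.gamma.isf(p_gam, om / rom, scale=rom)
        q[mask] = (q1 + q2) / 2.0
    return np.clip(q, 0.0, None)


def equalize_counts(counts: np.ndarray, eff_sizes: np.ndarray,
                    dispersion: float = 0.0) -> tuple[np.ndarray, float]:
    """Adjust a genes x columns count block to a common effective size.

    Returns the pseudo-counts and the common (geometric-mean) size.  Each
    gene's expected count per column under the null is its pooled
    abundance times the column's effective size.
    """
    eff_sizes = np.asarray(eff_sizes, dtype=float)
    common = float(np.exp(np.mean(np.log(eff_sizes))))
    abundance = counts.sum(axis=1, keepdims=True) / eff_sizes.sum()
    input_mean = abundance * eff_sizes[None, :]
    output_mean = np.broadcast_to(abundance * common, counts.shape)
    return q2qnbinom(np.asarray(counts, float), input_mean, output_mean, dispersion), common


# ---------------------------------------------------------------------------
# common dispersion (conditional maximum likelihood)


def _cond_loglik(pseudo_groups: list[np.ndarray], phi: float) -> float:
    """Summed NB conditional log-likelihood given per-gene group totals."""
    r = 1.0 / phi
    total = 0.0
    for y in pseudo_groups:  # (genes, n_reps) per allele group
        n = y.shape[1]
        z = y.sum(axis=1)
        ll = (special.gammaln(y + r).sum(axis=1) - n * special.gammaln(r)
              + special.gammaln(n * r) - special.gammaln(z + n * r))
        total += float(ll.sum())
    return total


def estimate_common_dispersion(table: AlleleCountTable, hybrid: str,
                               genes: pd.Index | None = None) -> float:
    """Table-level NB dispersion for one hybrid by conditional ML.

    Both allele groups of every (optionally restricted) gene contribute;
    counts are first quantile-adjusted to the hybrid's common effective
    library size (one refinement pass with the interim estimate).
    """
    a1, a2 = table.alleles(hybrid)
    block = table.counts[hybrid]
    if genes is not None:
        block = block.loc[genes]
    g1 = block[a1].to_numpy(dtype=float)
    g2 = block[a2].to_numpy(dtype=float)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("common dispersion needs >= 2 replicates per allele")
    eff = table.effective_sizes[hybrid]
    e1 = eff[a1].to_numpy(dtype=float)
    e2 = eff[a2].to_numpy(dtype=float)

    phi = 0.01
    for _ in range(2):
        p1, _ = equalize_counts(g1, e1, dispersion=phi)
        p2, _ = equalize_counts(g2, e2, dispersion=phi)
        groups = [p1, p2]
        res = optimize.minimize_scalar(
            lambda lp: -_cond_loglik(groups, np.exp(lp)),
            bounds=(np.log(1e-6), np.log(10.0)), method="bounded",
            options={"xatol": 1e-8})
        phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


# ---------------------------------------------------------------------------
# conditional exact test


def _double_tail_p(log_pmf: np.ndarray, observed: int) -> float:
    """Two-sided exact p: total conditional probability of outcomes no more
    probable than the observed one."""
    log_pmf = log_pmf - special.logsumexp(log_pmf)
    thresh = log_pmf[observed] + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(log_pmf[log_pmf <= thresh]))))


def ase_test(counts1: np.ndarray, counts2: np.ndarray, eff_sizes1: np.ndarray,
             eff_sizes2: np.ndarray, dispersion: float) -> tuple[float, float]:
    """Two-sided conditional NB exact test for allele imbalance in one gene.

    Counts are quantile-adjusted to a common effective library size and
    summed per allele group; conditioning on the grand total, the first
    group's sum follows (phi = 0) a binomial or (phi > 0) the conditional
    law of two NB sums, enumerated exactly.  Returns (M, p) with M the
    log2 ratio of pseudocounted (+0.5) per-replicate allele means.
    """
    counts1 = np.atleast_1d(np.asarray(counts1, dtype=float))
    counts2 = np.atleast_1d(np.asarray(counts2, dtype=float))
    eff_sizes1 = np.atleast_1d(np.asarray(eff_sizes1, dtype=float))
    eff_sizes2 = np.atleast_1d(np.asarray(eff_sizes2, dtype=float))
    if np.any(eff_sizes1 <= 0) or np.any(eff_sizes2 <= 0):
        raise ValueError("effective library sizes must be positive")
    n1, n2 = len(counts1), len(counts2)

    all_counts = np.concatenate([counts1, counts2])[None, :]
    all_sizes = np.concatenate([eff_sizes1, eff_sizes2])
    pseudo, _ = equalize_counts(all_counts, all_sizes, dispersion=dispersion)
    s1 = int(np.round(pseudo[0, :n1].sum()))
    s2 = int(np.round(pseudo[0, n1:].sum()))
    t = s1 + s2

    m = float(np.log2((s1 / n1 + 0.5) / (s2 / n2 + 0.5)))
    if t == 0:
        return m, 1.0

    x = np.arange(t + 1)
    if dispersion <= 0:
        # Poisson limit: conditional law is binomial(t, n1/(n1+n2))
        log_pmf = stats.binom.logpmf(x, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / dispersion, n2 / dispersion
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        log_pmf = stats.nbinom.logpmf(x, r1, p1) + stats.nbinom.logpmf(t - x, r2, p2)
    return m, _double_tail_p(log_pmf, s1)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate with cubic-smoother extrapolation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid; a
    least-squares cubic in lambda is evaluated at the grid maximum and
    clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = len(p)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lam, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """q-values: the minimum FDR at which each test is called significant."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = estimate_pi0(p)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    return np.minimum(pi0 * bh_adjust(p), 1.0)


# ---------------------------------------------------------------------------
# driver


def run_ase(table: AlleleCountTable, min_reads: int = DEFAULT_MIN_READS,
            qvalue_method: str = "storey",
            dispersion: float | None = None) -> pd.DataFrame:
    """Full ASE analysis: filters, dispersion, exact tests and q-values.

    Each hybrid is analysed over its detectable genes; q-values are
    computed within hybrid (each hybrid has its own gene set).  Returns a
    tidy frame with one row per tested gene x hybrid: M (log2 allelic
    ratio, allele1 vs allele2 in sorted order), mean normalized
    abundance, dispersion used, p, q, and the detectability flags.
    Non-detectable genes are carried with NaN statistics and a reason.
    """
    flags = apply_filters(table, min_reads=min_reads)
    norm = table.normalized()
    frames = []
    for h in table.hybrids:
        a1, a2 = table.alleles(h)
        eff = table.effective_sizes[h]
        e1 = eff[a1].to_numpy(float)
        e2 = eff[a2].to_numpy(float)
        detectable = flags[f"detectable_{h}"]
        tested = table.genes[detectable]
        phi = dispersion if dispersion is not None else (
            estimate_common_dispersion(table, h, genes=tested) if len(tested) else 0.0)
        c1 = table.counts[h][a1]
        c2 = table.counts[h][a2]
        rows = []
        for g in table.genes:
            if not detectable.loc[g]:
                rows.append((g, np.nan, np.nan, np.nan, "not_detectable"))
                continue
            m, p = ase_test(c1.loc[g].to_numpy(), c2.loc[g].to_numpy(), e1, e2, phi)
            abundance = float(norm[h].loc[g].mean())
            rows.append((g, m, p, abundance, ""))
        df = pd.DataFrame(rows, columns=["gene", "M", "p", "abundance", "reason"])
        df["hybrid"] = h
        df["allele1"], df["allele2"] = a1, a2
        df["dispersion"] = phi
        df["q"] = np.nan
        mask = df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = qvalues(df.loc[mask, "p"].to_numpy(), method=qvalue_method)
        df["detectable"] = detectable.to_numpy()
        df["uda"] = flags["uda"].to_numpy()
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene", "hybrid", "allele1", "allele2", "M", "abundance",
                "dispersion", "p", "q", "detectable", "uda", "reason"]]
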