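"""Genome-wide association of allele-specific binding with ASE.

For each TF and hybrid, the per-gene allele-specific binding difference
(ASB, from promoter scanning) is correlated with the measured allelic
expression ratio (ASE log2 M).  Because one set of promoter variants
perturbs many overlapping motifs at once, per-gene causality is out of
reach; the signal of interest is distributional: activator-like motifs
produce positive ASB~ASE correlations (the allele bound more is
expressed more) and repressor-like motifs negative ones.

Significance is assessed two ways:

* per TF, against a gene-label permutation null — the ASE vector's gene
  labels are shuffled (ASB left untouched, preserving its cross-TF
  dependence) and the correlation recomputed;
* globally, by a two-sample Kolmogorov-Smirnov test of the pooled
  observed correlations against the pooled permuted ones.

Per-motif reporting uses the analytic Spearman p with Bonferroni
correction; the permutation p is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_GENES = 10


def _align(asb: pd.DataFrame, ase: pd.DataFrame, hybrid: str) -> tuple[pd.DataFrame, pd.Series]:
    """Complete-case gene x TF ASB matrix and matching ASE M vector.

    Uses the hybrid-specific ASE set (detectable genes with a finite M);
    genes missing an ASB value for any TF are dropped so every TF sees
    the same permutation frame.
    """
    a = asb[asb["hybrid"] == hybrid].pivot(index="gene", columns="tf", values="asb")
    e = ase[(ase["hybrid"] == hybrid) & ase["M"].notna()].set_index("gene")["M"]
    genes = a.dropna().index.intersection(e.index)
    return a.loc[genes], e.loc[genes]


def correlate_asb_ase(asb: pd.DataFrame, ase: pd.DataFrame, hybrid: str,
                      method: str = "pearson", min_n: int = MIN_GENES) -> pd.DataFrame:
    """Per-TF correlation of ASB with ASE for one hybrid.

    Returns a frame (tf, hybrid, n, r, p_analytic, flag); zero-variance
    ASB columns are flagged ``undefined`` and under-populated ones
    ``insufficient``.
    """
    a, y = _align(asb, ase, hybrid)
    rows = []
    for tf in a.columns:
        x = a[tf].to_numpy()
        flag = ""
        r = p = np.nan
        if len(x) < min_n:
            flag = "insufficient"
        elif np.std(x) == 0 or np.std(y.to_numpy()) == 0:
            flag = "undefined"
        else:
            if method == "pearson":
                r, p = stats.pearsonr(x, y.to_numpy())
            elif method == "spearman":
                res = stats.spearmanr(x, y.to_numpy())
                r, p = res.statistic, res.pvalue
            else:
                raise ValueError(f"unknown method {method!r}")
        rows.append({"tf": tf, "hybrid": hybrid, "n": len(x), "r": r,
                     "p_analytic": p, "flag": flag})
    return pd.DataFrame(rows)


def permutation_null(asb: pd.DataFrame, ase: pd.DataFrame, hybrid: str,
                     n_perm: int = 1000, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-label permutation null of the per-TF Pearson correlations.

    One permutation of the ASE vector is shared by all TFs (preserving
    the ASB dependence structure across motifs).  Returns (observed
    frame with empirical two-sided p, null R array of shape
    (n_perm, n_tfs) in the frame's TF order).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a, y = _align(asb, ase, hybrid)
    x = a.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, n_tf = x.shape

    xc = x - x.mean(axis=0)
    xn = np.sqrt((xc ** 2).sum(axis=0))
    yc = yv - yv.mean()
    yn = np.sqrt((yc ** 2).sum())
    ok = (xn > 0) & (yn > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_obs = (xc.T @ yc) / (xn * yn)

    rng = np.random.default_rng(seed)
    null = np.full((n_perm, n_tf), np.nan)
    for k in range(n_perm):
        perm = rng.permutation(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            null[k] = (yc[perm] @ xc) / (xn * yn)

    p_emp = np.full(n_tf, np.nan)
    p_emp[ok] = (1.0 + (np.abs(null[:, ok]) >= np.abs(r_obs[ok])).sum(axis=0)) / (n_perm + 1.0)
    obs = pd.DataFrame({"tf": a.columns, "hybrid": hybrid, "n": n,
                        "r": np.where(ok, r_obs, np.nan), "p_perm": p_emp,
                        "flag": np.where(ok, "", "undefined")})
    return obs, null


def ks_actual_vs_permuted(observed: np.ndarray, permuted: np.ndarray) -> tuple[float, float]:
    """Two-sample K-S comparison of observed vs permuted correlation pools."""
    observed = np.asarray(observed, dtype=float)
    permuted = np.asarray(permuted, dtype=float).ravel()
    observed = observed[np.isfinite(observed)]
    permuted = permuted[np.isfinite(permuted)]
    if observed.size == 0 or permuted.size == 0:
        raise ValueError("empty correlation pool")
    res = stats.ks_2samp(observed, permuted, method="asymp")
    return float(res.statistic), float(res.pvalue)


def per_motif_significance(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-corrected per-motif calls from analytic Spearman p-values.

    ``results`` needs columns tf, r and p_analytic (one row per tested
    motif).  Adds p_bonferroni and a significance flag; returns the frame
    sorted by r (most activator-like first).
    """
    out = results.copy()
    tested = out["p_analytic"].notna()
    m = int(tested.sum())
    out["p_bonferroni"] = np.minimum(out["p_analytic"] * m, 1.0)
    out["significant"] = tested & (out["p_bonferroni"] < alpha)
    return out.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)


@dataclass
class CisMapResult:
    per_tf: pd.DataFrame          # per (tf, hybrid): n, r pearson/spearman, p's
    null_r: dict[str, np.ndarray]  # hybrid -> (n_perm, n_tf) null Pearson Rs
    ks_pooled: tuple[float, float]
    ks_per_hybrid: dict[str, tuple[float, float]]


def run_cis(asb: pd.DataFrame, ase: pd.DataFrame, hybrids: list[str] | None = None,
            n_perm: int = 1000, seed: int = 0, alpha: float = 0.05) -> CisMapResult:
    """Full ASB~ASE association across hybrids.

    Pearson correlations feed the permutation null and the K-S stage
    (per hybrid and pooled across hybrids); Spearman correlations feed
    the Bonferroni per-motif calls.  Each hybrid's permutations use a
    seed offset so hybrids are independent but reproducible.
    """
    if hybrids is None:
        hybrids = sorted(ase["hybrid"].unique())
    frames, nulls, ks_h = [], {}, {}
    for i, h in enumerate(hybrids):
        obs, null = permutation_null(asb, ase, h, n_perm=n_perm, seed=seed + 7919 * i)
        sp = correlate_asb_ase(asb, ase, h, method="spearman")
        merged = obs.merge(
            sp.rename(columns={"r": "r_spearman", "p_analytic": "p_analytic",
                               "flag": "flag_spearman"}),
            on=["tf", "hybrid", "n"])
        frames.append(merged)
        nulls[h] = null
        o = merged["r"].to_numpy()
        ks_h[h] = ks_actual_vs_permuted(o[np.isfinite(o)], null)
    per_tf = per_motif_significance(pd.concat(frames, ignore_index=True).rename(
        columns={"r": "r_pearson"}).assign(r=lambda d: d["r_spearman"]), alpha=alpha)
    all_obs = per_tf["r_pearson"].to_numpy(dtype=float)
    all_null = np.concatenate([v.ravel() for v in nulls.values()])
    ks_pooled = ks_actual_vs_permuted(all_obs[np.isfinite(all_obs)], all_null)
    return CisMapResult(per_tf=per_tf, null_r=nulls, ks_pooled=ks_pooled, ks_per_hybrid=ks_h)
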