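"""Context-specific expression (CSE) and differential trans-activity.

Each parental allele is measured in three hybrid contexts (one per
possible partner strain).  Because the allele's cis sequence is the
same in all three, systematic expression differences between contexts
must come from the partner's trans environment.  The context-specific
expression of query allele *a* in foreground context *b* is

    CSE(a, b) = 2 * Expr(a, b) / (Expr(a, c) + Expr(a, d))

where Expr(a, h) is the allele's TMM-normalized, replicate-averaged
expression in the hybrid pairing *a* with *h*, and *c*, *d* are the two
background contexts.  CSE > 1 means the foreground strain's trans
factors activate the allele more than the backgrounds' do.

A TF whose activity differs in strain *b* shifts the CSE of its target
genes (defined from promoter motif scores) relative to non-targets, in
every query parent.  Per (TF, foreground) pair the target/non-target
contrast is a Welch t-test on log2 CSE, required to agree in sign
across all three query parents, with one pooled test per pair entering
a Benjamini-Hochberg correction at alpha = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ase_quant import AlleleCountTable, bh_adjust

DEFAULT_EPS = 0.5     # pseudocount on normalized expression
DEFAULT_ALPHA = 0.1
DEFAULT_MIN_TARGETS = 50
DEFAULT_MAX_TARGET_FRAC = 0.10


def expression_matrix(table: AlleleCountTable) -> pd.DataFrame:
    """Replicate-mean TMM-normalized expression per (gene; allele, partner).

    Columns are a MultiIndex (allele strain, partner strain): the
    expression of the allele in the hybrid pairing it with that partner.
    """
    norm = table.normalized()
    cols = {}
    for h in table.hybrids:
        a1, a2 = table.alleles(h)
        block = norm[h]
        cols[(a1, a2)] = block[a1].mean(axis=1)
        cols[(a2, a1)] = block[a2].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["allele", "partner"])
    return out.sort_index(axis=1)


def compute_cse(expr: pd.DataFrame, query: str, foreground: str,
                eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """CSE of every gene's ``query`` allele in the ``foreground`` context.

    Backgrounds are the remaining partner strains of the query allele.
    A pseudocount ``eps`` is added to every expression term; genes whose
    background expression is zero before pseudocounting are flagged
    invalid (their ratio is driven purely by the pseudocount).
    """
    partners = list(expr[query].columns)
    if foreground not in partners:
        raise ValueError(f"no hybrid pairs query {query} with foreground {foreground}")
    backgrounds = [s for s in partners if s != foreground]
    fg = expr[(query, foreground)]
    bg = sum(expr[(query, b)] for b in backgrounds)
    cse = (len(backgrounds) * (fg + eps)) / (bg + len(backgrounds) * eps)
    valid = bg > 0
    return pd.DataFrame({
        "gene": expr.index, "query": query, "foreground": foreground,
        "cse": cse.to_numpy(), "log2_cse": np.log2(cse.to_numpy()),
        "valid": valid.to_numpy(),
    }).set_index("gene")


def define_targets(scores: pd.Series, min_n: int = DEFAULT_MIN_TARGETS,
                   max_frac: float = DEFAULT_MAX_TARGET_FRAC) -> list[str]:
    """A TF's target genes from its per-gene motif scores.

    Targets are genes scoring at least half the maximum observed score;
    if fewer than ``min_n`` qualify the top ``min_n`` are taken, and if
    more than ``max_frac`` of the scored genes qualify only the top
    floor(max_frac * total) are kept.  Ties at a cutoff break by gene id.
    """
    scores = scores.dropna()
    if scores.empty:
        raise ValueError("empty score vector")
    total = len(scores)
    # sort by (-score, gene id) so every cutoff is deterministic
    ordered = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    half_max = scores.max() / 2.0
    n_half = int((ordered >= half_max).sum())
    cap = int(np.floor(max_frac * total))
    if n_half < min_n:
        k = min(min_n, total)
    elif n_half > cap:
        k = cap
    else:
        k = n_half
    return sorted(ordered.index[:k])


def tf_activity_test(cse: pd.DataFrame, targets: set[str] | list[str]) -> dict:
    """Welch t-test of log2 CSE, targets vs non-targets, for one query.

    Returns t, p, the mean log2 difference, the natural-scale mean CSE
    difference (target - non-target), group sizes and an ``untestable``
    flag when either group has < 2 valid genes or zero variance.
    """
    targets = set(targets)
    valid = cse[cse["valid"]]
    is_t = valid.index.isin(targets)
    x = valid.loc[is_t, "log2_cse"].to_numpy()
    y = valid.loc[~is_t, "log2_cse"].to_numpy()
    out = {"n_target": len(x), "n_other": len(y), "t": np.nan, "p": np.nan,
           "mean_log2_diff": np.nan, "delta_cse": np.nan, "untestable": False}
    if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
        out["untestable"] = True
        return out
    t, p = stats.ttest_ind(x, y, equal_var=False)
    out.update(t=float(t), p=float(p),
               mean_log2_diff=float(x.mean() - y.mean()),
               delta_cse=float(valid.loc[is_t, "cse"].mean() - valid.loc[~is_t, "cse"].mean()))
    return out


def consolidate_activity(per_query: list[dict], pooled: dict,
                         tf: str, foreground: str) -> dict:
    """One row for a (TF, foreground) pair from its three query-parent tests.

    ``consistent`` requires the target/non-target mean difference to
    share a sign in all queries; the pooled test's p enters the BH
    family downstream.  Direction is up (activating more in this
    context) when the pooled mean difference is positive.
    """
    diffs = [q["mean_log2_diff"] for q in per_query]
    complete = len(per_query) == 3 and all(np.isfinite(d) for d in diffs) \
        and np.isfinite(pooled.get("p", np.nan))
    consistent = complete and (all(d > 0 for d in diffs) or all(d < 0 for d in diffs))
    return {
        "tf": tf, "foreground": foreground,
        "p": pooled.get("p", np.nan), "t": pooled.get("t", np.nan),
        "delta_cse": pooled.get("delta_cse", np.nan),
        "mean_log2_diff": pooled.get("mean_log2_diff", np.nan),
        "direction": ("up" if pooled.get("mean_log2_diff", 0) > 0 else "down")
        if complete else "na",
        "consistent": bool(consistent), "complete": bool(complete),
        "query_diffs": diffs,
    }


@dataclass
class TransMapResult:
    records: pd.DataFrame      # one row per (tf, foreground) with q and flags
    cse: pd.DataFrame          # all per-gene CSE records (long)


def run_trans(table: AlleleCountTable, motif_scores: pd.DataFrame,
              alpha: float = DEFAULT_ALPHA, eps: float = DEFAULT_EPS,
              min_targets: int = DEFAULT_MIN_TARGETS,
              max_target_frac: float = DEFAULT_MAX_TARGET_FRAC) -> TransMapResult:
    """Differential trans-activity scan over all (TF, foreground) pairs.

    ``motif_scores`` is genes x TFs (e.g. mean GOMER P_bound across
    strains).  For every foreground strain and TF, the three query
    parents' CSE vectors are tested separately (for the sign-consistency
    requirement) and pooled (for the single p per pair); pooled p-values
    of complete pairs enter one BH family, and a pair is significant iff
    q <= alpha and consistent.
    """
    expr = expression_matrix(table)
    strains = sorted(expr.columns.get_level_values("allele").unique())
    targets = {tf: set(define_targets(motif_scores[tf], min_n=min_targets,
                                      max_frac=max_target_frac))
               for tf in motif_scores.columns}

    cse_frames = []
    cse_cache: dict[tuple[str, str], pd.DataFrame] = {}
    for fg in strains:
        for q in strains:
            if q == fg:
                continue
            c = compute_cse(expr, q, fg, eps=eps)
            cse_cache[(q, fg)] = c
            cse_frames.append(c.reset_index())

    rows = []
    for tf in motif_scores.columns:
        tgt = targets[tf]
        for fg in strains:
            queries = [s for s in strains if s != fg]
            per_query = [tf_activity_test(cse_cache[(q, fg)], tgt) for q in queries]
            pooled_cse = pd.concat([cse_cache[(q, fg)] for q in queries])
            pooled = tf_activity_test(pooled_cse, tgt)
            rows.append(consolidate_activity(per_query, pooled, tf, fg))
    rec = pd.DataFrame(rows)
    rec["q"] = np.nan
    fam = rec["complete"]
    if fam.any():
        rec.loc[fam, "q"] = bh_adjust(rec.loc[fam, "p"].to_numpy())
    rec["significant"] = fam & (rec["q"] <= alpha) & rec["consistent"]
    rec = rec.sort_values(["q", "tf"], na_position="last").reset_index(drop=True)
    return TransMapResult(records=rec, cse=pd.concat(cse_frames, ignore_index=True))
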