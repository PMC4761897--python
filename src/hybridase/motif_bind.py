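"""PWM scanning of promoters under the GOMER occupancy model.

A transcription factor's sequence preference is a position frequency
matrix theta[j, b]: the probability of base b at motif position j.  The
GOMER occupancy model treats every length-L window on both strands of a
promoter as an independent potential site with per-site binding
probability p_i, and aggregates them into the probability that at least
one site is occupied::

    P_bound = 1 - prod_i (1 - p_i)

Two per-site scores are supported:

``prob``
    p_i = prod_j theta[j, base_ij] — the PWM probability of emitting the
    window (default; equivalently a relative affinity with unit
    concentration, capped at 1 since it is a probability product).
``affinity``
    p_i = K_i / (1 + K_i) with K_i = prod_j theta[j, base_ij] / bg[base_ij],
    a saturating relative-affinity form against a background model.

Allele-specific binding (ASB) of a promoter pair is the difference of
the two alleles' occupancy probabilities and therefore lies in [-1, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_PSEUDOCOUNT = 0.01
UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


class MotifParseError(ValueError):
    """Raised for malformed MEME-style motif files (carries a line number)."""


@dataclass
class MotifModel:
    """A TF's position probability matrix, pseudocounted at load time."""

    name: str
    theta: np.ndarray  # (L, 4), rows sum to 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 4 or self.theta.shape[0] < 1:
            raise ValueError("theta must be an (L, 4) matrix with L >= 1")
        if np.any(self.theta < 0):
            raise ValueError("theta entries must be non-negative")
        rows = self.theta.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise ValueError("theta rows must sum to 1")
        if self.pseudocount > 0:
            self.theta = self.theta + self.pseudocount
            self.theta /= self.theta.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.theta.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.theta.argmax(axis=1))

    def max_information_position(self) -> int:
        """Motif position with the highest information content (bits)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            info = 2.0 + np.where(self.theta > 0, self.theta * np.log2(self.theta), 0.0).sum(axis=1)
        return int(np.argmax(info))

    def reverse_complement(self) -> "MotifModel":
        rc = MotifModel.__new__(MotifModel)
        rc.name = self.name
        rc.theta = self.theta[::-1, ::-1].copy()
        rc.pseudocount = self.pseudocount
        return rc


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> -1 (window containing it is skipped)."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def load_motifs(source, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[MotifModel]:
    """Parse a MEME-style minimal motif file into MotifModel objects.

    Accepts a path or an open text handle.  Each MOTIF block must carry a
    ``letter-probability matrix`` whose rows sum to ~1.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()

    motifs: list[MotifModel] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"line {i + 1}: MOTIF line without a name")
            name = parts[1]
            # find the matrix header
            j = i + 1
            while j < n and "letter-probability matrix" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    raise MotifParseError(f"line {j + 1}: MOTIF {name} has no matrix")
                j += 1
            if j >= n:
                raise MotifParseError(f"line {i + 1}: MOTIF {name} has no matrix")
            rows = []
            j += 1
            while j < n:
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise MotifParseError(f"line {j + 1}: expected 4 probabilities, got {len(vals)}")
                try:
                    row = [float(v) for v in vals]
                except ValueError as e:
                    raise MotifParseError(f"line {j + 1}: {e}") from None
                if abs(sum(row) - 1.0) > 1e-3:
                    raise MotifParseError(f"line {j + 1}: row sums to {sum(row):.4f}, not ~1")
                rows.append(row)
                j += 1
            if not rows:
                raise MotifParseError(f"line {i + 1}: MOTIF {name} matrix is empty")
            mat = np.array(rows)
            mat /= mat.sum(axis=1, keepdims=True)
            motifs.append(MotifModel(name, mat, pseudocount=pseudocount))
            i = j
        else:
            i += 1
    return motifs


def write_motifs(motifs: list[MotifModel], path) -> None:
    """Write motifs in MEME minimal format (already-pseudocounted matrices)."""
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for m in motifs:
        buf.write(f"MOTIF {m.name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {m.length}\n")
        for row in m.theta:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def window_score(motif: MotifModel, window: str, mode: str = "prob",
                 background: np.ndarray = UNIFORM_BACKGROUND) -> float:
    """Per-site binding probability of a single length-L window."""
    if len(window) != motif.length:
        raise ValueError(f"window length {len(window)} != motif length {motif.length}")
    idx = _encode(window)
    if np.any(idx < 0):
        raise ValueError(f"window contains non-ACGT characters: {window!r}")
    probs = motif.theta[np.arange(motif.length), idx]
    p = float(np.prod(probs))
    if mode == "prob":
        return p
    if mode == "affinity":
        k = float(np.prod(probs / background[idx]))
        return k / (1.0 + k)
    raise ValueError(f"unknown scoring mode {mode!r}")


def _site_probs(motif: MotifModel, encoded: np.ndarray, mode: str,
                background: np.ndarray) -> np.ndarray:
    """Per-offset site probabilities on one strand; NaN for windows with N."""
    L = motif.length
    n_win = len(encoded) - L + 1
    if n_win <= 0:
        return np.empty(0)
    offsets = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    win = encoded[offsets]  # (n_win, L)
    bad = (win < 0).any(axis=1)
    win_safe = np.where(win < 0, 0, win)
    with np.errstate(divide="ignore"):  # theta may contain exact zeros
        logp = np.log(motif.theta)[np.arange(L)[None, :], win_safe].sum(axis=1)
    if mode == "prob":
        p = np.exp(logp)
    elif mode == "affinity":
        logk = logp - np.log(background)[win_safe].sum(axis=1)
        k = np.exp(logk)
        p = k / (1.0 + k)
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    p[bad] = np.nan
    return p


def site_probabilities(motif: MotifModel, promoter: str, mode: str = "prob",
                       background: np.ndarray = UNIFORM_BACKGROUND) -> dict[str, np.ndarray]:
    """Per-offset site probabilities on the forward and reverse strands.

    The reverse strand is scored by scanning the reverse complement of the
    motif along the forward sequence, so both arrays are indexed by
    forward-strand offset.  Windows overlapping non-ACGT characters are NaN.
    """
    seq = promoter.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"promoter contains invalid characters: {sorted(invalid)}")
    enc = _encode(seq)
    return {
        "+": _site_probs(motif, enc, mode, background),
        "-": _site_probs(motif.reverse_complement(), enc, mode, background),
    }


def gomer_pbound(motif: MotifModel, promoter: str, mode: str = "prob",
                 background: np.ndarray = UNIFORM_BACKGROUND) -> float:
    """Probability the promoter is bound at one or more sites (either strand).

    Windows overlapping N contribute no binding (skipped).  A promoter
    shorter than the motif has no windows and P_bound = 0.
    """
    sites = site_probabilities(motif, promoter, mode, background)
    p = np.concatenate([sites["+"], sites["-"]])
    p = p[~np.isnan(p)]
    if p.size == 0:
        return 0.0
    # complement product in log space for numerical stability at p near 1
    if np.any(p >= 1.0):
        return 1.0
    return float(-np.expm1(np.sum(np.log1p(-p))))


def asb(motif: MotifModel, promoter_a: str, promoter_b: str, mode: str = "prob",
        background: np.ndarray = UNIFORM_BACKGROUND) -> float:
    """Allele-specific binding: P_bound(allele A) - P_bound(allele B)."""
    return gomer_pbound(motif, promoter_a, mode, background) - gomer_pbound(
        motif, promoter_b, mode, background)


def snp_binding_report(motif: MotifModel, promoter_a: str, promoter_b: str,
                       mode: str = "prob", score_threshold: float = 0.0,
                       background: np.ndarray = UNIFORM_BACKGROUND) -> pd.DataFrame:
    """Attribute binding changes to individual SNPs between two alleles.

    For each discriminating position, reports the maximal per-site score
    among windows overlapping it in each allele, the score change
    (best_b - best_a) and its relative counterpart, sorted by absolute
    score change (relative change is unstable when both windows score
    near zero).  Rows whose better allele never reaches
    ``score_threshold`` are flagged.
    """
    if len(promoter_a) != len(promoter_b):
        raise ValueError("alleles must have equal length (substitution-only model)")
    a, b = promoter_a.upper(), promoter_b.upper()
    snps = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    cols = ["position", "base_a", "base_b", "best_score_a", "best_score_b",
            "score_change", "relative_change", "above_threshold"]
    if not snps:
        return pd.DataFrame(columns=cols)
    sa = site_probabilities(motif, a, mode, background)
    sb = site_probabilities(motif, b, mode, background)
    L = motif.length
    rows = []
    for pos in snps:
        lo = max(0, pos - L + 1)
        hi = pos + 1  # exclusive, offsets whose window covers pos
        best = {}
        for probs, key in ((sa, "a"), (sb, "b")):
            vals = np.concatenate([probs["+"][lo:hi], probs["-"][lo:hi]])
            vals = vals[~np.isnan(vals)]
            best[key] = float(vals.max()) if vals.size else 0.0
        denom = best["a"] if best["a"] > 0 else np.nan
        rel = (best["b"] - best["a"]) / denom if denom == denom else np.nan
        rows.append({
            "position": pos, "base_a": a[pos], "base_b": b[pos],
            "best_score_a": best["a"], "best_score_b": best["b"],
            "score_change": best["b"] - best["a"], "relative_change": rel,
            "above_threshold": max(best["a"], best["b"]) >= score_threshold,
        })
    df = pd.DataFrame(rows, columns=cols)
    return df.reindex(df["score_change"].abs().sort_values(ascending=False).index).reset_index(drop=True)


def asb_table(motifs: list[MotifModel], promoters: dict[str, dict[str, str]],
              hybrids: list[tuple[str, str]], mode: str = "prob") -> pd.DataFrame:
    """ASB for every (gene, TF, hybrid).

    ``promoters`` maps gene -> {strain: promoter sequence}.  For a hybrid
    (s1, s2), ASB = P_bound(s1 allele) - P_bound(s2 allele).  Returns a tidy
    frame (gene, tf, hybrid, asb) plus per-strain P_bound columns on request
    via :func:`pbound_table`.
    """
    pb = pbound_table(motifs, promoters, mode=mode)
    wide = pb.pivot(index=["gene", "tf"], columns="strain", values="p_bound")
    frames = []
    for s1, s2 in hybrids:
        if s1 not in wide.columns or s2 not in wide.columns:
            continue
        d = (wide[s1] - wide[s2]).dropna().rename("asb").reset_index()
        d["hybrid"] = f"{s1}x{s2}"
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene", "tf", "hybrid", "asb"]]


def gomer_pbound_many(motifs: list[MotifModel], promoter: str,
                      mode: str = "prob",
                      background: np.ndarray = UNIFORM_BACKGROUND) -> dict[str, float]:
    """P_bound of one promoter for many motifs, sharing the window build.

    Equivalent to calling :func:`gomer_pbound` per motif; window index
    matrices are constructed once per motif length, which matters when
    scanning thousands of promoters against a motif library.
    """
    enc = _encode(promoter.upper())
    invalid = set(promoter.upper()) - set("ACGTN")
    if invalid:
        raise ValueError(f"promoter contains invalid characters: {sorted(invalid)}")
    by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    log_bg = np.log(background)
    out: dict[str, float] = {}
    for m in motifs:
        L = m.length
        n_win = len(enc) - L + 1
        if n_win <= 0:
            out[m.name] = 0.0
            continue
        if L not in by_len:
            offsets = np.arange(n_win)[:, None] + np.arange(L)[None, :]
            win = enc[offsets]
            good = ~(win < 0).any(axis=1)
            by_len[L] = (np.where(win < 0, 0, win), good)
        win_safe, good = by_len[L]
        cols = np.arange(L)[None, :]
        ps = []
        for theta in (m.theta, m.theta[::-1, ::-1]):
            with np.errstate(divide="ignore"):
                logp = np.log(theta)[cols, win_safe].sum(axis=1)
            if mode == "affinity":
                k = np.exp(logp - log_bg[win_safe].sum(axis=1))
                p = k / (1.0 + k)
            else:
                p = np.exp(logp)
            ps.append(p[good])
        p = np.concatenate(ps)
        if p.size == 0:
            out[m.name] = 0.0
        elif np.any(p >= 1.0):
            out[m.name] = 1.0
        else:
            out[m.name] = float(-np.expm1(np.sum(np.log1p(-p))))
    return out


def pbound_table(motifs: list[MotifModel], promoters: dict[str, dict[str, str]],
                 mode: str = "prob") -> pd.DataFrame:
    """P_bound for every (gene, TF, strain) with a scannable promoter."""
    records = []
    for gene, by_strain in promoters.items():
        # identical alleles share one scan
        cache: dict[str, dict[str, float]] = {}
        for strain, seq in by_strain.items():
            if seq is None:
                continue
            scores = cache.get(seq)
            if scores is None:
                scores = gomer_pbound_many(motifs, seq, mode=mode)
                cache[seq] = scores
            for tf, p in scores.items():
                records.append({"gene": gene, "tf": tf, "strain": strain, "p_bound": p})
    return pd.DataFrame(records, columns=["gene", "tf", "strain", "p_bound"])
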