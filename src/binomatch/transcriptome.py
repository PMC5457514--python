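"""Bulk RNA-seq statistics: RPKM, regularized differential expression,
posterior probability of differential expression, and set enrichment.

The differential-expression test is a Bayesian-regularized t-test in the
CyberT tradition: each gene's within-group variance is stabilized by
pooling it with a background variance — the mean sample variance over a
sliding window of genes of similar expression (window 101 genes), weighted
by a confidence hyperparameter (v0 = 10 pseudo-observations per group):

    s²_reg = (v0·σ²_bg + (n − 1)·s²) / (v0 + n − 2)

Multiple testing is handled by modelling the raw p-value distribution as a
two-component mixture — a uniform component (non-DE genes) plus a beta
component concentrated near zero (DE genes) — fitted by EM; each gene's
posterior probability of belonging to the DE component (PPDE) is reported
and genes with PPDE > 0.6 are called significant. Gene-set enrichment uses
the Fisher exact test with sample odds ratios on an explicit gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln

__all__ = [
    "rpkm",
    "cybert_test",
    "ppde",
    "PpdeFit",
    "de_gene_lists",
    "fisher_enrichment",
    "EnrichmentResult",
    "triple_intersection",
    "read_gmt",
]

PPDE_THRESHOLD = 0.6
CYBERT_WINDOW = 101
CYBERT_CONFIDENCE = 10.0


# ---------------------------------------------------------------------------
# normalization


def rpkm(counts, gene_length_bp, library_size):
    """Reads per kilobase of exon model per million mapped reads.

    RPKM = counts·10⁹ / (length · library size); broadcasting follows
    numpy rules (counts may be a genes × samples matrix with per-gene
    lengths and per-sample library sizes).
    """
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene lengths must be > 0")
    if np.any(lib <= 0):
        raise ValueError("library sizes must be > 0")
    if counts.ndim == 2:
        return counts * 1e9 / (length[:, None] * lib[None, :])
    return counts * 1e9 / (length * lib)


# ---------------------------------------------------------------------------
# regularized t


def _sliding_background(values: np.ndarray, order: np.ndarray, window: int) -> np.ndarray:
    """Mean of ``values`` over a centred rank window (truncated at edges)."""
    v = values[order]
    n = v.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    bg_sorted = (csum[hi] - csum[lo]) / (hi - lo)
    bg = np.empty(n)
    bg[order] = bg_sorted
    return bg


def cybert_test(
    matrix: pd.DataFrame,
    groups: dict,
    group_a: str,
    group_b: str,
    window: int = CYBERT_WINDOW,
    confidence: float = CYBERT_CONFIDENCE,
    *,
    log_transform: bool = True,
    df_mode: str = "augmented",
) -> pd.DataFrame:
    """Bayesian-regularized two-sample t-test per gene.

    Parameters
    ----------
    matrix
        Genes × samples expression (linear scale unless
        ``log_transform=False`` and the caller pre-transformed).
    groups
        sample name → group name.
    group_a, group_b
        The two groups to compare (difference reported as B − A).
    window
        Odd sliding-window size (genes) for the background variance,
        centred on each gene in overall mean-expression rank.
    confidence
        Pseudo-observation weight v0 of the background variance; 0 disables
        regularization entirely and gives the ordinary (Welch-statistic)
        t-test.
    log_transform
        Test log2(x + 1) values (the usual scale for expression data).
    df_mode
        ``augmented`` (default): df = nA + nB − 2 + 2·v0, crediting the
        pseudo-observations; ``classic``: df = nA + nB − 2.

    Returns a DataFrame indexed by gene with columns mean_a, mean_b,
    log2_ratio, t, p_value, direction.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if confidence < 0:
        raise ValueError("confidence must be >= 0")
    if df_mode not in ("augmented", "classic"):
        raise ValueError(f"unknown df_mode: {df_mode!r}")
    cols_a = [s for s, g in groups.items() if g == group_a]
    cols_b = [s for s, g in groups.items() if g == group_b]
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")

    X = matrix.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    ia = [matrix.columns.get_loc(c) for c in cols_a]
    ib = [matrix.columns.get_loc(c) for c in cols_b]
    A, B = X[:, ia], X[:, ib]

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    var_a, var_b = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)

    if confidence == 0:
        reg_a, reg_b = var_a, var_b
        df = na + nb - 2 if df_mode == "classic" else na + nb - 2
    else:
        order = np.argsort(X.mean(axis=1), kind="stable")
        bg_a = _sliding_background(var_a, order, window)
        bg_b = _sliding_background(var_b, order, window)
        reg_a = (confidence * bg_a + (na - 1) * var_a) / (confidence + na - 2)
        reg_b = (confidence * bg_b + (nb - 1) * var_b) / (confidence + nb - 2)
        df = na + nb - 2 + (2 * confidence if df_mode == "augmented" else 0)

    se = np.sqrt(reg_a / na + reg_b / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_b - mean_a) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se > 0, p, 1.0)

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_ratio": mean_b - mean_a if log_transform
            else np.log2((mean_b + 1e-12) / (mean_a + 1e-12)),
            "t": t,
            "p_value": p,
            "direction": np.where(mean_b >= mean_a, "up", "down"),
        },
        index=matrix.index,
    )


# ---------------------------------------------------------------------------
# posterior probability of differential expression


@dataclass
class PpdeFit:
    """Uniform + beta p-value mixture fit."""

    lam: float          # fitted weight of the uniform (non-DE) component
    a: float
    b: float
    pi0: float          # uniform floor λ + (1−λ)·Beta(p=1), the null weight bound
    loglik: float
    n_iter: int
    converged: bool


def ppde(
    p_values,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    init: tuple = (0.8, 0.3, 3.0),
):
    """Posterior probability of differential expression for each p-value.

    Fits f(p) = λ·1 + (1−λ)·Beta(a, b) with a ≤ 1 ≤ b by EM (deterministic
    initialization), so the beta component is concentrated near zero — the
    signature of differentially expressed genes. Because a uniform can hide
    inside the beta component, the null weight is bounded from the fitted
    density at p = 1 (π0 = f̂(1), the standard identifiability resolution),
    and PPDE(p) = max(0, 1 − π0 / f̂(p)). PPDE is therefore monotone
    non-increasing in p. On a null (uniform) sample π0 → 1 and all PPDE → 0.

    Returns ``(ppde_values, fit)``; EM failure falls back to λ = 1 (all
    PPDE 0) with ``converged=False``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, 1e-300, 1.0)
    lam, a, b = init

    def beta_pdf(a_, b_):
        return stats.beta.pdf(p, a_, b_)

    loglik_old = -np.inf
    converged = False
    it = 0
    try:
        for it in range(1, max_iter + 1):
            dens = beta_pdf(a, b)
            f = lam + (1.0 - lam) * dens
            z = (1.0 - lam) * dens / f
            loglik = float(np.sum(np.log(f)))
            if abs(loglik - loglik_old) < tol * (1 + abs(loglik_old)):
                converged = True
                break
            loglik_old = loglik
            lam = float(np.clip(1.0 - z.mean(), 1e-9, 1.0 - 1e-9))
            lp, l1p = np.log(p), np.log1p(-np.clip(p, 0, 1 - 1e-16))

            # weighted beta MLE with a in (0, 1], b in [1, inf)
            def neg_q(theta):
                a_, b_ = theta
                return -float(np.sum(z * ((a_ - 1) * lp + (b_ - 1) * l1p - betaln(a_, b_))))

            res = optimize.minimize(
                neg_q,
                x0=[a, b],
                bounds=[(1e-3, 1.0), (1.0, 1e4)],
                method="L-BFGS-B",
            )
            if not res.success:
                raise RuntimeError("beta M-step failed")
            a, b = float(res.x[0]), float(res.x[1])
    except Exception:
        fit = PpdeFit(1.0, 1.0, 1.0, 1.0, -np.inf, it, False)
        return np.zeros_like(p), fit

    dens = beta_pdf(a, b)
    f = lam + (1.0 - lam) * dens
    beta_at_one = float(stats.beta.pdf(1.0 - 1e-12, a, b)) if b <= 1.0 + 1e-9 else 0.0
    pi0 = float(min(1.0, lam + (1.0 - lam) * beta_at_one))
    vals = np.maximum(0.0, 1.0 - pi0 / f)
    fit = PpdeFit(lam, a, b, pi0, loglik_old, it, converged)
    return vals, fit


def de_gene_lists(de_result: pd.DataFrame, ppde_threshold: float = PPDE_THRESHOLD):
    """Split significant genes (PPDE above threshold) into up/down sets.

    ``de_result`` must carry ``ppde`` and ``direction`` columns (direction
    is the sign of the B − A group-mean difference).
    """
    sig = de_result[de_result["ppde"] > ppde_threshold]
    up = set(sig.index[sig["direction"] == "up"])
    down = set(sig.index[sig["direction"] == "down"])
    return up, down


# ---------------------------------------------------------------------------
# enrichment and intersections


@dataclass
class EnrichmentResult:
    overlap: int
    odds_ratio: float
    p_value: float
    table: tuple          # ((a, b), (c, d))
    corrected: bool       # Haldane 0.5 applied to a zero cell


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by exact hypergeometric enumeration.

    Sums P(X = k) over every table with the observed margins whose
    probability does not exceed that of the observed table. All arithmetic
    is exact (integer binomial coefficients), so ties at the observed
    probability are handled without floating-point slack.
    """
    from math import comb

    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    K, D, N = a + b, a + c, a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    lo, hi = max(0, K + D - N), min(K, D)
    obs = comb(K, a) * comb(N - K, D - a)
    total = 0
    for k in range(lo, hi + 1):
        w = comb(K, k) * comb(N - K, D - k)
        if w <= obs:
            total += w
    return total / comb(N, D)


def fisher_enrichment(target_set, de_set, universe) -> EnrichmentResult:
    """Fisher exact enrichment of a target gene set in a DE gene set.

    The 2×2 table classifies every universe gene by target membership and
    DE membership; the sample odds ratio ad/bc is reported, with a 0.5
    continuity correction (flagged) only when a cell is zero. The two-sided
    p-value comes from exact hypergeometric enumeration
    (:func:`fisher_exact_two_sided`).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not (set(target_set) <= universe and set(de_set) <= universe):
        raise ValueError("target and DE sets must be subsets of the universe")
    target = set(target_set)
    de = set(de_set)
    a = len(target & de)
    b = len(target - de)
    c = len(de - target)
    d = len(universe) - a - b - c
    p = fisher_exact_two_sided(a, b, c, d)
    corrected = 0 in (a, b, c, d)
    if corrected:
        orv = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orv = a * d / (b * c)
    return EnrichmentResult(a, float(orv), float(p), ((a, b), (c, d)), corrected)


def triple_intersection(set_a, set_b, set_c):
    """All seven Venn region counts plus the triple-overlap members.

    Returns ``(counts, triple)`` where counts maps region labels
    ('a', 'b', 'c', 'ab', 'ac', 'bc', 'abc' — exclusive regions) to sizes.
    """
    A, B, C = set(set_a), set(set_b), set(set_c)
    abc = A & B & C
    counts = {
        "a": len(A - B - C),
        "b": len(B - A - C),
        "c": len(C - A - B),
        "ab": len((A & B) - C),
        "ac": len((A & C) - B),
        "bc": len((B & C) - A),
        "abc": len(abc),
    }
    return counts, sorted(abc)


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (name, description, members per line)."""
    from gseapy.parser import read_gmt as _read_gmt

    return {name: sorted(set(members)) for name, members in _read_gmt(str(path)).items()}
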