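"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own comparison logic: range
membership works by explicit enumeration of every code in a band, AUC
by enumerating all case-control pairs, and the Hosmer-Lemeshow
statistic by explicit bin slicing.
"""

from __future__ import annotations

import string

import numpy as np

LETTERS = string.ascii_uppercase


def dotless(code: str) -> str:
    return code.strip().upper().replace(".", "")


def expand_span(span: str) -> tuple[set[str], int]:
    """All codes (at endpoint granularity) inside a printed span."""
    parts = [dotless(p) for p in span.split("-")]
    low, high = (parts[0], parts[0]) if len(parts) == 1 else (parts[0], parts[1])
    g = len(low)
    width = g - 1
    out: set[str] = set()
    for letter in LETTERS[LETTERS.index(low[0]): LETTERS.index(high[0]) + 1]:
        lo = int(low[1:]) if letter == low[0] else 0
        hi = int(high[1:]) if letter == high[0] else 10 ** width - 1
        out.update(f"{letter}{i:0{width}d}" for i in range(lo, hi + 1))
    return out, g


def member(code: str, span: str, exact: bool = False) -> bool:
    """Membership of a canonical code in a printed span, by enumeration."""
    code = dotless(code)
    if exact:
        return code == dotless(span)
    pool, g = expand_span(span)
    if len(code) >= g:
        return code[:g] in pool
    # shorter code: any digit-extension to granularity g
    k = g - len(code)
    return any(code + f"{i:0{k}d}" in pool for i in range(10 ** k))


def condition_hit(code_set, spans: str, exact_spans: str = "") -> bool:
    """True iff any code hits any span of one condition row."""
    spans_l = [s for s in str(spans).split(";") if s and s != "nan"]
    exact_l = [s for s in str(exact_spans).split(";") if s and s != "nan"]
    for c in code_set:
        if any(member(c, s) for s in spans_l):
            return True
        if any(member(c, s, exact=True) for s in exact_l):
            return True
    return False


def auc_pairwise(pred, y) -> float:
    """AUC by enumerating every case-control pair (ties count 1/2)."""
    pred, y = np.asarray(pred, float), np.asarray(y, bool)
    pos, neg = pred[y], pred[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def hl_by_slicing(pred, y, groups: int) -> float:
    """H-L statistic by sorting and explicit equal slicing (no ties)."""
    pred, y = np.asarray(pred, float), np.asarray(y, float)
    order = np.argsort(pred, kind="stable")
    pred, y = pred[order], y[order]
    splits = np.array_split(np.arange(len(pred)), groups)
    stat = 0.0
    for idx in splits:
        e1 = pred[idx].sum()
        e0 = (1.0 - pred[idx]).sum()
        o1 = y[idx].sum()
        o0 = len(idx) - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    return stat


def jackknife_auc_diff_var(pred_a, pred_b, y) -> float:
    """Leave-one-out jackknife variance of AUC_a - AUC_b."""
    pred_a, pred_b, y = map(np.asarray, (pred_a, pred_b, y))
    n = len(y)
    diffs = np.empty(n)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        diffs[i] = auc_pairwise(pred_a[keep], y[keep].astype(bool)) - auc_pairwise(
            pred_b[keep], y[keep].astype(bool)
        )
    return (n - 1) / n * ((diffs - diffs.mean()) ** 2).sum()
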