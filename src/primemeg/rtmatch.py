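"""Greedy within-subject matching of trials on reaction time.

Compatible and incompatible trials are paired by repeatedly extracting the
globally smallest absolute RT difference without replacement, until the
smaller condition is exhausted.  A cutoff on the pair differences is then
chosen — largest first — to retain as many pairs as possible while an
independent-samples t-test between the retained RTs is non-significant,
abolishing the RT confound before MEG contrasts are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MatchResult", "greedy_match", "select_cutoff", "matched_summary"]


@dataclass
class MatchResult:
    pairs: list  # (index_a, index_b, delta_rt) for retained pairs
    cutoff: float
    retained_a: np.ndarray  # positions into rts_a
    retained_b: np.ndarray
    post_t: float
    post_p: float


def greedy_match(rts_a, rts_b) -> list:
    """Ordered greedy pairing by absolute RT difference.

    Returns ``(i, j, delta)`` triples (positions into the input lists) in the
    order drawn; the sequence of deltas is non-decreasing.  Ties are broken
    by the lowest (a, b) index pair after sorting each list by (RT, index),
    making the result order-independent for permuted inputs.
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both RT lists must be non-empty")
    order_a = np.lexsort((np.arange(a.size), a))
    order_b = np.lexsort((np.arange(b.size), b))
    diff = np.abs(a[order_a][:, None] - b[order_b][None, :])
    pairs = []
    n_pairs = min(a.size, b.size)
    for _ in range(n_pairs):
        flat = np.argmin(diff)  # ties: lowest (row, col) in sorted order
        i, j = np.unravel_index(flat, diff.shape)
        pairs.append((int(order_a[i]), int(order_b[j]), float(diff[i, j])))
        diff[i, :] = np.inf
        diff[:, j] = np.inf
    return pairs


def _independent_t_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided independent-samples t; degenerate data give t = 0, p = 1."""
    if len(x) < 2 or len(y) < 2:
        return 0.0, 1.0
    if np.std(x, ddof=1) == 0.0 and np.std(y, ddof=1) == 0.0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y)
    if np.isnan(p):
        return 0.0, 1.0
    return float(t), float(p)


def select_cutoff(pairs: list, rts_a, rts_b, alpha: float = 0.05) -> MatchResult:
    """Largest delta cutoff whose retained pairs show no significant RT
    difference (independent-samples t, p >= alpha).

    Candidate cutoffs are the distinct pair deltas, scanned from largest to
    smallest; the first (i.e. most inclusive) cutoff that passes wins.  If
    none does, an error reports the best achievable p.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two matched pairs")
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    deltas = np.array([d for _, _, d in pairs])
    best_p = -np.inf
    for cutoff in np.unique(deltas)[::-1]:
        keep = deltas <= cutoff
        if keep.sum() < 2:  # too few pairs to test, not a valid cutoff
            continue
        ia = np.array([p[0] for p, k in zip(pairs, keep) if k], dtype=int)
        ib = np.array([p[1] for p, k in zip(pairs, keep) if k], dtype=int)
        t, p = _independent_t_p(a[ia], b[ib])
        best_p = max(best_p, p)
        if p >= alpha:
            kept = [pr for pr, k in zip(pairs, keep) if k]
            return MatchResult(
                pairs=kept,
                cutoff=float(cutoff),
                retained_a=ia,
                retained_b=ib,
                post_t=t,
                post_p=p,
            )
    raise ValueError(
        f"no cutoff abolishes the RT difference (best p = {best_p:.4g})"
    )


def match_subject(rts_a, rts_b, alpha: float = 0.05) -> MatchResult:
    """Greedy matching followed by cutoff selection, with invariant checks."""
    result = select_cutoff(greedy_match(rts_a, rts_b), rts_a, rts_b, alpha=alpha)
    assert len(result.retained_a) == len(result.retained_b)
    assert len(set(result.retained_a)) == len(result.retained_a)
    assert len(set(result.retained_b)) == len(result.retained_b)
    assert all(d <= result.cutoff for _, _, d in result.pairs)
    return result


def matched_summary(results: dict, rts_by_subject: dict) -> pd.DataFrame:
    """Per-subject and mean retained counts with pre/post mean RTs.

    ``results`` maps subject id -> MatchResult; ``rts_by_subject`` maps
    subject id -> (rts_a, rts_b).
    """
    if not results:
        raise ValueError("need at least one subject")
    rows = []
    for subject, res in results.items():
        a, b = (np.asarray(x, dtype=float) for x in rts_by_subject[subject])
        rows.append(
            {
                "subject_id": subject,
                "n_retained": len(res.retained_a),
                "cutoff": res.cutoff,
                "rt_a_pre": a.mean(),
                "rt_b_pre": b.mean(),
                "rt_a_post": a[res.retained_a].mean(),
                "rt_b_post": b[res.retained_b].mean(),
                "post_t": res.post_t,
                "post_p": res.post_p,
            }
        )
    table = pd.DataFrame(rows).set_index("subject_id")
    table.loc["mean"] = table.mean()
    return table
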