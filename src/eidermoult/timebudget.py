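"""Scan-sample time budgets and a from-scratch Mann-Whitney U test.

Behaviour is scan-sampled: every 5 minutes the number of birds in and out
of the water is recorded.  A session's in-water proportion is the pooled
count ratio.  Treatments are compared on per-session proportions with the
Mann-Whitney U (Wilcoxon rank-sum) test, implemented here from first
principles: midranks for ties, exact enumeration of the rank-sum null
distribution for small samples (total n < 8), and the tie-corrected
normal approximation with continuity correction otherwise.  Two-sided
p-values double the one-sided tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["ScanSession", "session_proportion", "mann_whitney_u",
           "treatment_summary"]


@dataclass(frozen=True)
class ScanSession:
    """One videotaped scan-sampling session.

    ``scans`` is a sequence of (n_in_water, n_out_of_water) count pairs,
    one per 5-minute scan.
    """

    session_id: str
    treatment: str
    scans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for n_in, n_out in self.scans:
            if n_in < 0 or n_out < 0:
                raise ValueError("scan counts must be non-negative")


def session_proportion(session: ScanSession) -> float:
    """Pooled in-water proportion for one session: sum(in)/sum(in+out)."""
    if not session.scans:
        raise ValueError("session has no scans")
    n_in = sum(s[0] for s in session.scans)
    total = n_in + sum(s[1] for s in session.scans)
    if total == 0:
        raise ValueError("all scan totals are zero")
    return n_in / total


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with tied values sharing the mean of their rank block."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


def _u_from_ranks(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    r_x = float(ranks_x.sum())
    return r_x - n_x * (n_x + 1) / 2.0


def _exact_tail(all_ranks: np.ndarray, n_x: int, u_obs: float) -> float:
    """P(U_x <= u_obs) by enumerating all choose(N, n_x) rank assignments."""
    n = len(all_ranks)
    count = 0
    total = 0
    offset = n_x * (n_x + 1) / 2.0
    for idx in combinations(range(n), n_x):
        u = all_ranks[list(idx)].sum() - offset
        total += 1
        if u <= u_obs + 1e-12:
            count += 1
    return count / total


def mann_whitney_u(x, y) -> dict:
    """Two-sample Mann-Whitney U test on raw values.

    Returns
    -------
    dict
        ``U``: min(U_x, U_y); ``U_x``, ``U_y``; ``p_two_sided``;
        ``method``: 'exact' (total n < 8) or 'normal' (tie-corrected
        normal approximation with continuity correction).

    Notes
    -----
    U_x counts pairs (i, j) with x_i > y_j plus half the ties, via the
    rank-sum identity U_x = R_x - n_x(n_x+1)/2 with midranks.
    U_x + U_y = n_x * n_y always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_x = _u_from_ranks(ranks[:n_x], n_x, n_y)
    u_y = n_x * n_y - u_x
    u = min(u_x, u_y)

    if n_x + n_y < 8:
        # one-sided tail of the smaller U under the exact permutation null
        p_one = _exact_tail(ranks, n_x if u_x <= u_y else n_y, u)
        method = "exact"
    else:
        mean_u = n_x * n_y / 2.0
        n = n_x + n_y
        # tie correction on the variance
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / (n * (n - 1))
        var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return {"U": u, "U_x": u_x, "U_y": u_y,
                    "p_two_sided": 1.0, "method": "normal"}
        z = (u - mean_u + 0.5) / math.sqrt(var_u)  # continuity correction
        p_one = 0.5 * math.erfc(-z / math.sqrt(2.0))
        method = "normal"

    return {"U": u, "U_x": u_x, "U_y": u_y,
            "p_two_sided": min(1.0, 2.0 * p_one), "method": method}


def treatment_summary(sessions: list[ScanSession]) -> dict:
    """Per-treatment mean in/out-of-water percentages and the U test on
    per-session in-water proportions (cold vs warm)."""
    props: dict[str, list[float]] = {}
    for s in sessions:
        props.setdefault(s.treatment, []).append(session_proportion(s))
    out: dict = {"per_treatment": {}}
    for treatment, p in sorted(props.items()):
        pin = float(np.mean(p))
        out["per_treatment"][treatment] = {
            "pct_in_water": 100.0 * pin,
            "pct_out_of_water": 100.0 * (1.0 - pin),
            "n_sessions": len(p),
        }
    if {"cold", "warm"} <= props.keys():
        out["test"] = mann_whitney_u(props["cold"], props["warm"])
    return out
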