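"""Pre/post-stimulation comparison of cycle metrics.

For each session separately, OFF-PRE vs OFF-POST cycle-level RMS and
iEMG are compared per muscle/side with a two-sided Wilcoxon rank-sum
(Mann-Whitney) test; the ON block is never tested.  Small tie-free
samples use the exact null distribution; otherwise a normal
approximation with tie and continuity corrections.  Cycles within a
block are treated as independent observations — a deliberate mirror of
the target analysis, with the caveat that consecutive gait cycles are
not truly independent.

No multiple-testing correction is applied by default (matching the
uncorrected p < 0.05 convention of the target analysis); Holm
adjustment is available behind a flag.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import ValidationError

__all__ = ["rank_sum_test", "compare_blocks", "summary_table", "parse_summary_table"]

EXACT_MAX_N = 20


@lru_cache(maxsize=32)
def _assignments(n: int, na: int) -> np.ndarray:
    """All C(n, na) index sets for group A (cached: reused across tests)."""
    return np.fromiter(
        (i for c in combinations(range(n), na) for i in c), dtype=np.intp
    ).reshape(-1, na)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments.

    Midranks make the enumeration valid under ties; the two-sided p is
    twice the smaller tail (capped at 1), matching the usual convention.
    """
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    u_all = ranks[_assignments(na + nb, na)].sum(axis=1) - na * (na + 1) / 2.0
    total = comb(na + nb, na)
    eps = 1e-9
    p_le = np.count_nonzero(u_all <= u_obs + eps) / total
    p_ge = np.count_nonzero(u_all >= u_obs - eps) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration for ``n_a + n_b <= 20``; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if a.size + b.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(a, b)
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def compare_blocks(
    metrics: pd.DataFrame,
    session: str | None = None,
    alpha: float = 0.05,
    pre_block: str = "OFF-PRE",
    post_block: str = "OFF-POST",
    holm: bool = False,
    use_median: bool = False,
) -> pd.DataFrame:
    """One comparison row per channel x metric: percent change and p-value.

    ``percent_change = 100 * (mean_post - mean_pre) / mean_pre`` computed
    from block means of cycle-level metrics (medians with
    ``use_median``).  Sessions are never pooled: pass cycle metrics of a
    single session (or set ``session`` to filter).  Channels missing
    either block are skipped.
    """
    df = metrics
    if session is not None:
        df = df[df["session"] == session]
    sessions = df["session"].unique()
    if len(sessions) > 1:
        raise ValidationError(
            f"metrics mix sessions {sorted(sessions)}; compare one session at a time"
        )
    center = np.median if use_median else np.mean
    rows = []
    for channel, g in df.groupby("channel", sort=True):
        pre = g[g["block"] == pre_block]
        post = g[g["block"] == post_block]
        if pre.empty or post.empty:
            continue
        for metric in ("rms", "iemg"):
            a = pre[metric].to_numpy()
            b = post[metric].to_numpy()
            m_pre, m_post = float(center(a)), float(center(b))
            p = rank_sum_test(a, b)
            rows.append(
                {
                    "session": df["session"].iloc[0] if len(df) else session,
                    "channel": channel,
                    "metric": metric,
                    "n_pre": a.size,
                    "n_post": b.size,
                    "mean_pre": m_pre,
                    "mean_post": m_post,
                    "percent_change": 100.0 * (m_post - m_pre) / m_pre,
                    "p_value": p,
                    "alpha": alpha,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "session", "channel", "metric", "n_pre", "n_post",
            "mean_pre", "mean_post", "percent_change", "p_value", "alpha",
        ],
    )
    if holm and len(out):
        out["p_value"] = _holm(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha if len(out) else pd.Series(dtype=bool)
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summary_table(rows: pd.DataFrame, mode: str = "paper") -> pd.DataFrame:
    """Wide percent-change summary: muscle/side rows, session x metric columns.

    Cells show the signed percent change with significance markers
    (``*`` p < 0.05, ``**`` p < 0.001).  ``mode="paper"`` leaves
    non-significant cells empty; ``mode="full"`` populates all.
    """
    if rows.empty:
        raise ValidationError("no comparison rows to summarize")
    if mode not in ("paper", "full"):
        raise ValidationError(f"unknown mode {mode!r}")
    cells = {}
    for _, r in rows.iterrows():
        if mode == "paper" and not r["significant"]:
            text = ""
        else:
            text = f"{r['percent_change']:+.1f}{_stars(r['p_value'])}"
        cells[(r["channel"], f"{r['session']}:{r['metric']}")] = text
    channels = sorted(rows["channel"].unique())
    cols = sorted({c for _, c in cells})
    table = pd.DataFrame(
        [[cells.get((ch, c), "") for c in cols] for ch in channels],
        index=pd.Index(channels, name="channel"),
        columns=cols,
    )
    return table


def parse_summary_table(text_table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of ``summary_table`` formatting: recover numbers and markers."""
    records = []
    for ch in text_table.index:
        for col in text_table.columns:
            cell = text_table.loc[ch, col]
            if not isinstance(cell, str) or cell == "":
                continue
            session, metric = col.split(":")
            stars = len(cell) - len(cell.rstrip("*"))
            records.append(
                {
                    "channel": ch,
                    "session": session,
                    "metric": metric,
                    "percent_change": float(cell.rstrip("*")),
                    "stars": stars,
                }
            )
    return pd.DataFrame(records)
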