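"""Log-ratio biomarker panels from ranked features.

Given features ranked by their differential with a phenotype, the selector
scans all (n_top, n_bottom) pairs, forms the per-sample log-ratio of summed
numerator counts over summed denominator counts (depth cancels), and keeps
the pair whose log-ratio maximizes the signed Spearman correlation with the
target.  Because the panel is chosen to maximize the very correlation it
reports, the in-sample rho is optimistic; an optional held-out split
re-evaluates the selected panel on unseen samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import spearman_association

logger = logging.getLogger(__name__)

__all__ = ["LogRatioSelection", "sample_log_ratio", "clr_transform", "optimize_top_bottom"]

OPTIMISM_CAVEAT = (
    "panel chosen to maximize in-sample correlation; the reported rho is "
    "optimistic under selection and should be confirmed on held-out samples"
)


@dataclass(frozen=True)
class LogRatioSelection:
    n_top: int
    n_bottom: int
    numerator: frozenset[str]
    denominator: frozenset[str]
    per_sample_log_ratio: pd.Series  # natural log, retained samples only
    retained_samples: frozenset[str]
    n_dropped: int  # samples with a zero numerator or denominator sum
    rho: float
    p_value: float
    rho_holdout: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_top": int(self.n_top),
            "n_bottom": int(self.n_bottom),
            "numerator": sorted(self.numerator),
            "denominator": sorted(self.denominator),
            "n_retained": len(self.retained_samples),
            "n_dropped": int(self.n_dropped),
            "rho": float(self.rho),
            "p_value": float(self.p_value),
            "caveat": OPTIMISM_CAVEAT,
        }
        if self.rho_holdout is not None:
            d["rho_holdout"] = float(self.rho_holdout)
        return d


def sample_log_ratio(table: pd.DataFrame, numerator, denominator):
    """Per-sample ln(sum of numerator counts / sum of denominator counts).

    Returns ``(values, mask)``: ``values`` holds the log-ratio for samples
    where both sums are positive, ``mask`` is a boolean Series over all
    samples (False where the sample was excluded for a zero sum).  Raw
    count sums are used — sequencing depth cancels in the ratio."""
    num = sorted(set(map(str, numerator)))
    den = sorted(set(map(str, denominator)))
    if not num or not den:
        raise ValueError("numerator and denominator must be non-empty")
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(f"numerator and denominator overlap: {sorted(overlap)}")
    missing = [f for f in num + den if f not in table.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    num_sum = table[num].sum(axis=1).astype(float)
    den_sum = table[den].sum(axis=1).astype(float)
    mask = (num_sum > 0) & (den_sum > 0)
    values = np.log(num_sum[mask] / den_sum[mask])
    values.name = "log_ratio"
    return values, mask


def clr_transform(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio per sample: ln(count + pseudocount) minus the
    sample mean of ln(count + pseudocount); rows sum to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logged = np.log(table.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=table.index, columns=table.columns)


def _rho_for_pair(table, ranked, n_top, n_bottom, target):
    numerator = ranked[:n_top]
    denominator = ranked[-n_bottom:]
    values, mask = sample_log_ratio(table, numerator, denominator)
    t = target.loc[values.index]
    ok = t.notna()
    if int(ok.sum()) < 3:
        return None
    assoc = spearman_association(values[ok].to_numpy(), t[ok].to_numpy())
    return numerator, denominator, values[ok], assoc


def optimize_top_bottom(
    ranked: list[str],
    table: pd.DataFrame,
    target: pd.Series,
    max_n: int = 30,
    holdout_fraction: float = 0.0,
    seed: int = 0,
) -> LogRatioSelection:
    """Exhaustive grid search over n_top, n_bottom in [1, max_n].

    The numerator takes the first n_top of ``ranked`` (most positively
    associated with the target), the denominator the last n_bottom; the
    pair maximizing the signed Spearman rho wins, with ties going to the
    smallest n_top + n_bottom, then smallest n_top.  With
    ``holdout_fraction`` > 0 the grid is scanned on a train split and the
    winning panel's rho re-evaluated on the held-out samples."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    ranked = [str(f) for f in ranked]
    extra = [f for f in ranked if f not in table.columns]
    if extra:
        raise KeyError(f"ranked features absent from table: {extra[:5]}")
    target = pd.Series(target).astype(float)
    target = target.reindex(table.index)
    limit = min(max_n, len(ranked) // 2)
    if limit < 1:
        raise ValueError("need at least two ranked features")

    scan_table, holdout_table = table, None
    if holdout_fraction > 0:
        rng = np.random.default_rng(seed)
        ids = np.array(sorted(map(str, table.index)))
        n_hold = int(round(holdout_fraction * len(ids)))
        hold = set(rng.choice(ids, size=n_hold, replace=False).tolist())
        scan_table = table.loc[[i for i in table.index if str(i) not in hold]]
        holdout_table = table.loc[[i for i in table.index if str(i) in hold]]

    best = None
    best_key = None
    for n_top in range(1, limit + 1):
        for n_bottom in range(1, limit + 1):
            hit = _rho_for_pair(scan_table, ranked, n_top, n_bottom, target)
            if hit is None:
                continue
            numerator, denominator, values, assoc = hit
            key = (-assoc.estimate, n_top + n_bottom, n_top)
            if best_key is None or key < best_key:
                best_key = key
                best = (n_top, n_bottom, numerator, denominator, values, assoc)
    if best is None:
        raise ValueError("no (n_top, n_bottom) pair retained >= 3 samples with a target value")

    n_top, n_bottom, numerator, denominator, values, assoc = best
    n_dropped = len(scan_table) - len(values)

    rho_holdout = None
    if holdout_table is not None and len(holdout_table):
        h_values, _ = sample_log_ratio(holdout_table, numerator, denominator)
        h_target = target.loc[h_values.index]
        ok = h_target.notna()
        if int(ok.sum()) >= 3:
            rho_holdout = spearman_association(
                h_values[ok].to_numpy(), h_target[ok].to_numpy()
            ).estimate
    logger.info("optimize_top_bottom: %s", OPTIMISM_CAVEAT)

    return LogRatioSelection(
        n_top=n_top,
        n_bottom=n_bottom,
        numerator=frozenset(numerator),
        denominator=frozenset(denominator),
        per_sample_log_ratio=values,
        retained_samples=frozenset(map(str, values.index)),
        n_dropped=n_dropped,
        rho=float(assoc.estimate),
        p_value=float(assoc.p_value),
        rho_holdout=rho_holdout,
    )
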