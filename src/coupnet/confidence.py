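"""FBS -> PPV calibration and assembly of the final network.

The positive predictive value PPV = TP/(TP+FP) is measured over FBS
thresholds on equal-sized positive (gold standard) and resampled negative
samples, a logistic curve a / (1 + exp(-b(x - c))) is fitted to the
PPV-vs-FBS relation, and the final network is the union over gold
standards keeping each link's maximum PPV.  Links supported by gold
standards carry a membership-based floor confidence (gsPPV); only links
with PPV >= 0.85 are retained, and a positive GRG contribution makes a
link directed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

from .bayes import FBSResult
from .containers import Link, Network, Pair, canonical_pair


def ppv_curve(
    fbs_pos: Sequence[float],
    fbs_neg_pool: Sequence[float],
    n_resamples: int = 30,
    n_thresholds: int = 1000,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean PPV over FBS thresholds, averaged over negative resamples.

    Each resample draws as many negatives as there are positives
    (uniformly from the negative pool, without replacement when the pool
    allows).  At each of ``n_thresholds`` evenly spaced thresholds the PPV
    is TP/(TP+FP) among examples with FBS >= threshold; thresholds with no
    examples above them are omitted.  Returns (thresholds, mean PPV).
    """
    pos = np.sort(np.asarray(fbs_pos, dtype=float))
    pool = np.asarray(fbs_neg_pool, dtype=float)
    if len(pos) == 0:
        raise ValueError("need positive examples")
    if len(pool) == 0:
        raise ValueError("need negative examples (all-positive input rejected)")
    rng = np.random.default_rng(seed)
    lo = min(pos[0], float(pool.min()))
    hi = max(pos[-1], float(pool.max()))
    thresholds = np.linspace(lo, hi, n_thresholds)
    tp = len(pos) - np.searchsorted(pos, thresholds, side="left")
    ppv_sum = np.zeros(n_thresholds)
    ppv_cnt = np.zeros(n_thresholds, dtype=int)
    for _ in range(n_resamples):
        neg = np.sort(
            rng.choice(pool, size=len(pos), replace=len(pool) < len(pos))
        )
        fp = len(neg) - np.searchsorted(neg, thresholds, side="left")
        denom = tp + fp
        ok = denom > 0
        ppv_sum[ok] += tp[ok] / denom[ok]
        ppv_cnt[ok] += 1
    keep = ppv_cnt > 0
    return thresholds[keep], ppv_sum[keep] / ppv_cnt[keep]


@dataclass
class PPVModel:
    """Fitted logistic PPV(x) = a / (1 + exp(-b(x - c))) for one gold
    standard; ``a`` is the asymptotic maximum (typically 1)."""

    a: float
    b: float
    c: float
    r2: float
    gold_standard: str = ""

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        val = self.a / (1.0 + np.exp(-self.b * (x - self.c)))
        return np.clip(val, 0.0, 1.0)


@dataclass
class CalibrationRejection:
    gold_standard: str
    reason: str


def _logistic(x, a, b, c):
    return a / (1.0 + np.exp(-b * (x - c)))


def _logistic_printed(x, a, b, c):
    # the singular variant with a minus in the denominator, kept for audit
    return a / (1.0 - np.exp(-b * (x - c)))


def fit_ppv_logistic(
    curve: Tuple[Sequence[float], Sequence[float]],
    min_r2: float = 0.9,
    gold_standard: str = "",
    printed_form: bool = False,
) -> Union[PPVModel, CalibrationRejection]:
    """Least-squares logistic fit of the PPV-vs-FBS curve.

    Rejected ("poor fitting") when R^2 < ``min_r2`` or the optimizer
    fails; fewer than 10 curve points are rejected outright.
    """
    x = np.asarray(curve[0], dtype=float)
    y = np.asarray(curve[1], dtype=float)
    if len(x) < 10:
        return CalibrationRejection(gold_standard, "too few curve points")
    func = _logistic_printed if printed_form else _logistic
    p0 = (min(max(float(y.max()), 0.5), 1.0), 1.0, float(np.median(x)))
    try:
        params, _ = curve_fit(
            func,
            x,
            y,
            p0=p0,
            bounds=([1e-6, 1e-6, -np.inf], [1.2, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return CalibrationRejection(gold_standard, "poor fitting")
    fitted = func(x, *params)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < min_r2:
        return CalibrationRejection(gold_standard, "poor fitting")
    a, b, c = (float(v) for v in params)
    return PPVModel(a=a, b=b, c=c, r2=r2, gold_standard=gold_standard)


_GSPPV = {1: 0.85, 2: 0.90, 3: 0.95}


def assign_gsppv(n_supporting_gs: int) -> Optional[float]:
    """Floor confidence from gold-standard membership counts.

    0.85 / 0.90 / 0.95 for one / two / three supporting gold standards and
    1.0 for more than three; None when the link is in no gold standard.
    """
    if n_supporting_gs <= 0:
        return None
    return _GSPPV.get(n_supporting_gs, 1.0)


def assemble_network(
    fbs_tables: Mapping[str, Union[FBSResult, Mapping[Pair, float]]],
    ppv_models: Mapping[str, PPVModel],
    gs_membership: Mapping[Pair, Iterable[str]],
    grg_llrs: Optional[Mapping[Pair, float]] = None,
    cutoff: float = 0.85,
) -> Network:
    """Union of the per-gold-standard networks at maximum PPV.

    Each pair's evidence PPV is the maximum over accepted calibrations of
    PPV(FBS); the final PPV is the larger of the evidence PPV and the
    membership gsPPV (an evidence PPV exceeding the gsPPV discards it).
    Only links with final PPV >= ``cutoff`` are kept.  A positive directed
    GRG LLR orients the link regulator -> target.
    """
    grg_llrs = grg_llrs or {}
    membership = {canonical_pair(*p): set(v) for p, v in gs_membership.items()}
    fbs_by_gs: Dict[str, Mapping[Pair, float]] = {}
    breakdown_by_gs: Dict[str, Mapping[Pair, Dict[str, float]]] = {}
    for gs, table in fbs_tables.items():
        if isinstance(table, FBSResult):
            fbs_by_gs[gs] = table.fbs
            breakdown_by_gs[gs] = table.breakdown
        else:
            fbs_by_gs[gs] = table
            breakdown_by_gs[gs] = {}
    universe: Set[Pair] = set(membership)
    for table in fbs_by_gs.values():
        universe |= set(table)
    # direction lookup: canonical pair -> (flag, grg llr)
    direction_of: Dict[Pair, Tuple[str, float]] = {}
    for (reg, tgt), llr in grg_llrs.items():
        if llr <= 0:
            continue
        key = canonical_pair(reg, tgt)
        flag = "ab" if key == (reg, tgt) else "ba"
        prev = direction_of.get(key)
        if prev is None or llr > prev[1]:
            direction_of[key] = (flag, llr)
    net = Network()
    for pair in sorted(universe):
        ev_ppv = -1.0
        winner = ""
        winner_fbs = float("nan")
        winner_llrs: Dict[str, float] = {}
        for gs in sorted(ppv_models):
            table = fbs_by_gs.get(gs)
            if table is None or pair not in table:
                continue
            p = float(ppv_models[gs].evaluate(table[pair]))
            if p > ev_ppv:
                ev_ppv = p
                winner = gs
                winner_fbs = table[pair]
                winner_llrs = dict(breakdown_by_gs.get(gs, {}).get(pair, {}))
        supporting = membership.get(pair, set())
        gsppv = assign_gsppv(len(supporting))
        if ev_ppv < 0 and gsppv is None:
            continue
        if gsppv is not None and gsppv > ev_ppv:
            final_ppv = gsppv
            source = "gold_standard"
            gs_label = winner if winner else ",".join(sorted(supporting))
        else:
            final_ppv = ev_ppv
            source = "evidence"
            gs_label = winner
        if final_ppv < cutoff:
            continue
        flag, grg = direction_of.get(pair, ("none", None))
        net.add(
            Link(
                a=pair[0],
                b=pair[1],
                ppv=min(final_ppv, 1.0),
                direction=flag,
                gold_standard=gs_label,
                fbs=winner_fbs,
                ppv_source=source,
                llrs=winner_llrs,
                grg_llr=grg,
            )
        )
    return net
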