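"""Bin-free naive-Bayes training: KDE likelihoods, polynomial LLR curves,
sequential redundancy weighting and final Bayesian scores.

For each (evidence dataset, gold standard) combination the raw-score
densities of known couplings (gold-standard pairs) and unknown pairs are
estimated with Gaussian-kernel KDE (Silverman bandwidth), their pointwise
log-ratio is fitted with a low-order polynomial, and per-pair LLRs from
multiple datasets of one evidence type are combined with a sequential
redundancy-discounting weight.  The final Bayesian score (FBS) of a pair
is the sum of its per-evidence-type LLRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .containers import EvidenceScoreTable, GoldStandard, Pair, canonical_pair


def silverman_bandwidth(scores: Sequence[float]) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    if h <= 0:
        raise ValueError("zero bandwidth: input is (nearly) constant")
    return h


def fit_kde_likelihood(scores: Sequence[float]) -> stats.gaussian_kde:
    """Gaussian-kernel density with Silverman bandwidth.

    The bandwidth factor is passed explicitly so that the kernel standard
    deviation equals 0.9*min(sd, IQR/1.34)*n^(-1/5) exactly.
    """
    x = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("KDE requires at least two distinct values")
    h = silverman_bandwidth(x)
    sd = float(np.std(x, ddof=1))
    return stats.gaussian_kde(x, bw_method=h / sd)


@dataclass
class LLRModel:
    """A fitted polynomial LLR curve for one (evidence dataset, gold
    standard) combination.

    ``coefficients`` are beta0..beta4 in ascending order (high orders zero
    for degree < 4).  Evaluation clamps the raw score to ``valid_range``.
    """

    evidence_type: str
    dataset_id: str
    gold_standard: str
    coefficients: Tuple[float, float, float, float, float]
    degree: int
    valid_range: Tuple[float, float]
    r2: float
    n_pos: int
    n_neg: int

    def evaluate(self, x) -> np.ndarray:
        lo, hi = self.valid_range
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        return np.polynomial.polynomial.polyval(xc, np.asarray(self.coefficients))


@dataclass
class TrainingRejection:
    """Why a (dataset, gold standard) combination failed to train."""

    evidence_type: str
    dataset_id: str
    gold_standard: str
    reason: str


def estimate_llr_curve(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    *,
    max_percentile: float = 98.0,
    min_n: int = 1_000,
    max_n: int = 1_000_000,
    min_r2: float = 0.9,
    degrees: Sequence[int] = (2, 3, 4),
    grid_size: int = 512,
    flat_rmse_tol: float = 0.05,
    evidence_type: str = "",
    dataset_id: str = "",
    gold_standard: str = "",
) -> Union[LLRModel, TrainingRejection]:
    """Fit a polynomial LLR curve from positive and negative score samples.

    The pointwise LLR ln(KDE_pos/KDE_neg) is computed on a grid over the
    pooled score range truncated at the (100 - max_percentile)th and
    max_percentile-th percentiles (outliers excluded on both sides), and
    the lowest polynomial degree in ``degrees`` reaching R^2 >= ``min_r2``
    is selected.  Near-constant LLR curves (identical positive and
    negative distributions) make R^2 ill-posed; a fit whose absolute
    residual RMSE is <= ``flat_rmse_tol`` is accepted in that case.
    Training counts outside [min_n, max_n] (on the positives, the scarcer
    class) are rejected.
    """

    def reject(reason: str) -> TrainingRejection:
        return TrainingRejection(evidence_type, dataset_id, gold_standard, reason)

    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        return reject("lack of data")
    if len(pos) < min_n:
        return reject("lack of data")
    if len(pos) > max_n:
        return reject("too much data")
    pooled = np.concatenate([pos, neg])
    lo = float(np.percentile(pooled, 100.0 - max_percentile))
    hi = float(np.percentile(pooled, max_percentile))
    if not lo < hi:
        return reject("degenerate score range")
    try:
        kde_pos = fit_kde_likelihood(pos)
        kde_neg = fit_kde_likelihood(neg)
    except ValueError:
        return reject("constant scores")
    grid = np.linspace(lo, hi, grid_size)
    dp = kde_pos(grid)
    dn = kde_neg(grid)
    mask = (dp > 1e-300) & (dn > 1e-300)
    if int(mask.sum()) < 10:
        return reject("no common support")
    x = grid[mask]
    llr = np.log(dp[mask] / dn[mask])
    ss_tot = float(np.sum((llr - llr.mean()) ** 2))
    for degree in sorted(degrees):
        coeffs = np.polynomial.polynomial.polyfit(x, llr, degree)
        fitted = np.polynomial.polynomial.polyval(x, coeffs)
        ss_res = float(np.sum((llr - fitted) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rmse = float(np.sqrt(ss_res / len(x)))
        if r2 >= min_r2 or rmse <= flat_rmse_tol:
            padded = tuple(
                float(coeffs[i]) if i < len(coeffs) else 0.0 for i in range(5)
            )
            return LLRModel(
                evidence_type=evidence_type,
                dataset_id=dataset_id,
                gold_standard=gold_standard,
                coefficients=padded,
                degree=degree,
                valid_range=(lo, hi),
                r2=max(r2, 0.0),
                n_pos=len(pos),
                n_neg=len(neg),
            )
    return reject("poor fitting")


def evaluate_llr(model: LLRModel, x):
    """Evaluate a fitted LLR polynomial at raw score(s) ``x``, clamped to
    the model's valid range."""
    out = model.evaluate(x)
    return float(out) if np.isscalar(x) else out


def redundancy_weighted_llr(
    dataset_llrs: Sequence[Tuple[str, float]],
    dataset_correlations: Dict[Tuple[str, str], float],
    alpha: float = 0.7,
    pairing: str = "previous",
) -> float:
    """Combine one pair's LLRs from several datasets of one evidence type.

    LLRs are ranked in decreasing order; the top dataset enters with
    weight 1, and each subsequent weight is
    alpha * (1 - max(0, r)) * w_prev, where r is the Spearman correlation
    between the dataset and its reference dataset.  With
    ``pairing="previous"`` the reference is the immediately preceding
    ranked dataset; with ``pairing="most_correlated"`` it is the earlier
    dataset most correlated with the current one.
    """
    if pairing not in {"previous", "most_correlated"}:
        raise ValueError(f"unknown pairing {pairing!r}")
    if not dataset_llrs:
        return 0.0

    def corr(d1: str, d2: str) -> float:
        return dataset_correlations.get(
            (d1, d2), dataset_correlations.get((d2, d1), 0.0)
        )

    ranked = sorted(dataset_llrs, key=lambda t: (-t[1], t[0]))
    weights = [1.0]
    total = ranked[0][1]
    for k in range(1, len(ranked)):
        dk = ranked[k][0]
        if pairing == "previous":
            i = k - 1
            r = corr(dk, ranked[i][0])
        else:
            i, r = max(
                ((j, corr(dk, ranked[j][0])) for j in range(k)),
                key=lambda t: t[1],
            )
        w = alpha * (1.0 - max(0.0, r)) * weights[i]
        weights.append(w)
        total += w * ranked[k][1]
    return total


def dataset_correlation_matrix(
    per_dataset_llrs: Dict[str, Dict[Pair, float]],
    min_shared: int = 10,
) -> Dict[Tuple[str, str], float]:
    """Spearman correlations between datasets' per-pair LLRs.

    Computed on pairs scored in both datasets; fewer than ``min_shared``
    shared pairs gives r = 0 (no redundancy evidence).
    """
    ids = sorted(per_dataset_llrs)
    out: Dict[Tuple[str, str], float] = {}
    for i, d1 in enumerate(ids):
        for d2 in ids[i + 1 :]:
            shared = sorted(set(per_dataset_llrs[d1]) & set(per_dataset_llrs[d2]))
            if len(shared) < min_shared:
                out[(d1, d2)] = 0.0
                continue
            x = [per_dataset_llrs[d1][p] for p in shared]
            y = [per_dataset_llrs[d2][p] for p in shared]
            rho = stats.spearmanr(x, y).statistic
            out[(d1, d2)] = float(rho) if np.isfinite(rho) else 0.0
    return out


def compute_fbs(per_type_llrs: Dict[str, float]) -> float:
    """Final Bayesian score: sum of per-evidence-type (and per source
    species) weighted LLRs."""
    return float(sum(per_type_llrs.values()))


@dataclass
class FBSResult:
    """Per-pair final Bayesian scores against one gold standard, with the
    per-evidence-type LLR breakdown and the trained models."""

    gold_standard: str
    fbs: Dict[Pair, float]
    breakdown: Dict[Pair, Dict[str, float]]
    llr_models: Dict[Tuple[str, str], LLRModel]
    rejections: List[TrainingRejection] = field(default_factory=list)


def train_gold_standard(
    tables: Sequence[EvidenceScoreTable],
    gold_standard: GoldStandard,
    *,
    alpha: float = 0.7,
    pairing: str = "previous",
    min_shared: int = 10,
    **llr_kwargs,
) -> FBSResult:
    """Train LLR models for every evidence table against one gold standard
    and integrate them into per-pair FBS values.

    The positive score population is the gold-standard pairs scored by a
    table; the negative population is the remaining scored pairs
    ("unknown" functional status).  Datasets of the same evidence type are
    combined with the sequential redundancy weighting; distinct evidence
    types (including orthology-transferred tables, which keep their source
    species in the dataset id) contribute additive terms.
    """
    gs_links = gold_standard.undirected_links()
    models: Dict[Tuple[str, str], LLRModel] = {}
    rejections: List[TrainingRejection] = []
    # evidence type -> dataset -> pair -> LLR
    per_type: Dict[str, Dict[str, Dict[Pair, float]]] = {}
    for table in tables:
        scores = table.undirected_scores()
        pos = [s for p, s in scores.items() if p in gs_links]
        neg = [s for p, s in scores.items() if p not in gs_links]
        result = estimate_llr_curve(
            pos,
            neg,
            evidence_type=table.evidence_type,
            dataset_id=table.dataset_id,
            gold_standard=gold_standard.name,
            **llr_kwargs,
        )
        if isinstance(result, TrainingRejection):
            rejections.append(result)
            continue
        models[(table.evidence_type, table.dataset_id)] = result
        raw = np.array(list(scores.values()))
        llrs = result.evaluate(raw)
        # orthology-transferred tables (dataset id "name@source_species")
        # form their own additive term per (evidence type, source species)
        if "@" in table.dataset_id:
            type_key = f"{table.evidence_type}@{table.dataset_id.split('@', 1)[1]}"
        else:
            type_key = table.evidence_type
        per_type.setdefault(type_key, {})[table.dataset_id] = {
            p: float(v) for p, v in zip(scores, llrs)
        }
    fbs: Dict[Pair, float] = {}
    breakdown: Dict[Pair, Dict[str, float]] = {}
    for ev_type, per_dataset in per_type.items():
        corrs = dataset_correlation_matrix(per_dataset, min_shared=min_shared)
        pairs = set()
        for d in per_dataset.values():
            pairs |= set(d)
        for pair in pairs:
            entries = [
                (did, llrs[pair])
                for did, llrs in per_dataset.items()
                if pair in llrs
            ]
            llr_t = redundancy_weighted_llr(
                entries, corrs, alpha=alpha, pairing=pairing
            )
            breakdown.setdefault(pair, {})[ev_type] = llr_t
    for pair, per_ev in breakdown.items():
        fbs[pair] = compute_fbs(per_ev)
    return FBSResult(
        gold_standard=gold_standard.name,
        fbs=fbs,
        breakdown=breakdown,
        llr_models=models,
        rejections=rejections,
    )
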