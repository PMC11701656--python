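"""Top-level modelling interface.

`FunctionalCouplingModel` bundles evidence score tables and gold standards;
`fit()` runs the full inference — KDE/polynomial LLR training per
(dataset, gold standard), redundancy-weighted FBS integration, logistic
PPV calibration, and assembly of the final calibrated network — and
returns a `FunctionalCouplingResults` carrying the fitted models, their
diagnostics and the network, with a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .bayes import FBSResult, TrainingRejection, train_gold_standard
from .confidence import (
    CalibrationRejection,
    PPVModel,
    assemble_network,
    fit_ppv_logistic,
    ppv_curve,
)
from .containers import EvidenceScoreTable, GoldStandard, Network, Pair


@dataclass
class TrainingConfig:
    """Tunable parameters of the inference pipeline.

    Defaults follow the framework's published operating point: redundancy
    factor alpha = 0.7, fit-acceptance R^2 >= 0.9 with polynomial degrees
    2-4, score truncation at the 98th percentile, 10^3-10^6 training
    observations, 30 negative resamples over 1000 PPV thresholds, and a
    final network cutoff of PPV >= 0.85.
    """

    alpha: float = 0.7
    pairing: str = "previous"
    min_shared: int = 10
    min_r2: float = 0.9
    degrees: Tuple[int, ...] = (2, 3, 4)
    max_percentile: float = 98.0
    min_n: int = 1_000
    max_n: int = 1_000_000
    grid_size: int = 512
    flat_rmse_tol: float = 0.05
    n_resamples: int = 30
    n_thresholds: int = 1000
    ppv_min_r2: float = 0.9
    cutoff: float = 0.85


class FunctionalCouplingModel:
    """Naive-Bayes functional-coupling model over evidence tables and gold
    standards for one species."""

    def __init__(
        self,
        evidence_tables: Sequence[EvidenceScoreTable],
        gold_standards: Sequence[GoldStandard],
        config: Optional[TrainingConfig] = None,
    ) -> None:
        if not evidence_tables:
            raise ValueError("need at least one evidence table")
        if not gold_standards:
            raise ValueError("need at least one gold standard")
        names = [gs.name for gs in gold_standards]
        if len(set(names)) != len(names):
            raise ValueError("gold standard names must be unique")
        self.evidence_tables = list(evidence_tables)
        self.gold_standards = list(gold_standards)
        self.config = config or TrainingConfig()

    def fit(self, seed: int = 0) -> "FunctionalCouplingResults":
        cfg = self.config
        fbs_results: Dict[str, FBSResult] = {}
        ppv_models: Dict[str, PPVModel] = {}
        calibration_rejections: List[CalibrationRejection] = []
        for gs in self.gold_standards:
            result = train_gold_standard(
                self.evidence_tables,
                gs,
                alpha=cfg.alpha,
                pairing=cfg.pairing,
                min_shared=cfg.min_shared,
                max_percentile=cfg.max_percentile,
                min_n=cfg.min_n,
                max_n=cfg.max_n,
                min_r2=cfg.min_r2,
                degrees=cfg.degrees,
                grid_size=cfg.grid_size,
                flat_rmse_tol=cfg.flat_rmse_tol,
            )
            fbs_results[gs.name] = result
            if not result.llr_models:
                calibration_rejections.append(
                    CalibrationRejection(gs.name, "lack of data")
                )
                continue
            links = gs.undirected_links()
            pos = [v for p, v in result.fbs.items() if p in links]
            neg = [v for p, v in result.fbs.items() if p not in links]
            if not pos or not neg:
                calibration_rejections.append(
                    CalibrationRejection(gs.name, "lack of data")
                )
                continue
            curve = ppv_curve(
                pos,
                neg,
                n_resamples=cfg.n_resamples,
                n_thresholds=cfg.n_thresholds,
                seed=seed,
            )
            fitted = fit_ppv_logistic(
                curve, min_r2=cfg.ppv_min_r2, gold_standard=gs.name
            )
            if isinstance(fitted, CalibrationRejection):
                calibration_rejections.append(fitted)
            else:
                ppv_models[gs.name] = fitted
        membership: Dict[Pair, set] = {}
        for gs in self.gold_standards:
            for pair in gs.undirected_links():
                membership.setdefault(pair, set()).add(gs.name)
        grg_llrs = self._directed_grg_llrs(fbs_results)
        network = assemble_network(
            fbs_results,
            ppv_models,
            membership,
            grg_llrs=grg_llrs,
            cutoff=cfg.cutoff,
        )
        return FunctionalCouplingResults(
            model=self,
            fbs=fbs_results,
            ppv_models=ppv_models,
            calibration_rejections=calibration_rejections,
            network=network,
            seed=seed,
        )

    def _directed_grg_llrs(
        self, fbs_results: Mapping[str, FBSResult]
    ) -> Dict[Pair, float]:
        """Directed GRG LLRs (regulator, target) -> best LLR across gold
        standards, used to orient assembled links."""
        out: Dict[Pair, float] = {}
        for table in self.evidence_tables:
            if table.evidence_type != "GRG" or not table.directed:
                continue
            for gs_name, result in fbs_results.items():
                model = result.llr_models.get(("GRG", table.dataset_id))
                if model is None:
                    continue
                for (reg, tgt), raw in table.scores.items():
                    llr = float(model.evaluate(raw))
                    key = (reg, tgt)
                    if key not in out or llr > out[key]:
                        out[key] = llr
        return out


@dataclass
class FunctionalCouplingResults:
    """Fitted LLR/PPV models, diagnostics and the calibrated network."""

    model: FunctionalCouplingModel
    fbs: Dict[str, FBSResult]
    ppv_models: Dict[str, PPVModel]
    calibration_rejections: List[CalibrationRejection]
    network: Network
    seed: int

    @property
    def llr_rejections(self) -> List[TrainingRejection]:
        out: List[TrainingRejection] = []
        for result in self.fbs.values():
            out.extend(result.rejections)
        return out

    def summary(self) -> str:
        lines = []
        lines.append("Functional coupling network inference")
        lines.append("=" * 60)
        n_tables = len(self.model.evidence_tables)
        lines.append(f"Evidence tables: {n_tables}")
        lines.append(f"Gold standards:  {len(self.model.gold_standards)}")
        lines.append(f"Seed:            {self.seed}")
        lines.append("")
        lines.append("LLR training (per gold standard)")
        lines.append("-" * 60)
        for gs_name, result in sorted(self.fbs.items()):
            lines.append(
                f"  {gs_name:<12} accepted={len(result.llr_models):<3} "
                f"rejected={len(result.rejections):<3} pairs={len(result.fbs)}"
            )
            for key, m in sorted(result.llr_models.items()):
                lines.append(
                    f"    {key[0]}/{key[1]:<14} degree={m.degree} "
                    f"R2={m.r2:.3f} n_pos={m.n_pos}"
                )
        lines.append("")
        lines.append("PPV calibration")
        lines.append("-" * 60)
        for gs_name, m in sorted(self.ppv_models.items()):
            lines.append(
                f"  {gs_name:<12} a={m.a:.3f} b={m.b:.3f} c={m.c:.3f} "
                f"R2={m.r2:.3f}"
            )
        for rej in self.calibration_rejections:
            lines.append(f"  {rej.gold_standard:<12} REJECTED: {rej.reason}")
        lines.append("")
        n_dir = sum(1 for l in self.network.links.values() if l.direction != "none")
        lines.append(
            f"Assembled network: {len(self.network)} links "
            f"({n_dir} directed), {len(self.network.nodes())} proteins, "
            f"PPV >= {self.model.config.cutoff}"
        )
        return "\n".join(lines)
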