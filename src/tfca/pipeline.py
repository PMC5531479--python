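"""Per-subject analysis and cohort orchestration.

``analyze_pair`` runs the full time-frequency and spectral analysis on one
detrended 2 Hz ABP/CBFV segment; ``run_cohort`` applies it across subjects
and states and attaches the paired group statistics, isolating per-subject
failures so one bad record does not abort a cohort run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import BANDS, SmoothingKernel, area_fraction_above, atfcoh, tf_coherence
from .phase import NoValidArea, atfps, exclude_wrap_regions, tf_phase
from .spectral import SCOH_THRESHOLD, WelchConfig, spectral_summary
from .stationarity import StationarityConfig, test_stationarity_phase, test_stationarity_power
from .stats import wilcoxon_paired
from .tfr import ZAMDConfig

__all__ = ["PipelineConfig", "analyze_pair", "run_cohort"]


@dataclass
class PipelineConfig:
    """Everything one run depends on; hashed into the result records so a
    result can always be traced to its exact configuration."""

    zamd: ZAMDConfig = field(default_factory=ZAMDConfig)
    kernel: SmoothingKernel = field(default_factory=SmoothingKernel)
    welch: WelchConfig = field(default_factory=WelchConfig)
    stationarity: StationarityConfig = field(default_factory=StationarityConfig)
    coherence_threshold: float = 0.9
    scoh_threshold: float = SCOH_THRESHOLD
    seed: int = 0
    run_stationarity: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "zamd": self.zamd.__dict__,
                "kernel": self.kernel.__dict__,
                "welch": {**self.welch.__dict__},
                "stationarity": {
                    **{k: v for k, v in self.stationarity.__dict__.items() if k != "bins"},
                    "bins": [list(b) for b in self.stationarity.bins],
                },
                "th": self.coherence_threshold,
                "scoh_th": self.scoh_threshold,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_pair(abp: np.ndarray, cbfv: np.ndarray, cfg: PipelineConfig | None = None) -> dict:
    """Full analysis of one detrended 2 Hz segment.

    Returns a flat record: per band aTFCoh, % area above threshold, aTFPS
    (degrees, NaN when no significantly coherent area), aSCoh and SPS, plus
    the wrap-exclusion count and the coherence overflow diagnostic.
    """
    cfg = cfg or PipelineConfig()
    coh = tf_coherence(abp, cbfv, cfg.zamd, cfg.kernel)
    pmap = exclude_wrap_regions(tf_phase(coh, cfg.coherence_threshold))
    rec: dict = {
        "config_hash": cfg.config_hash(),
        "coh_overflow_fraction": coh.overflow_fraction,
        "n_wrap_regions": len(pmap.wrap_excluded),
    }
    for name, band in BANDS.items():
        rec[f"aTFCoh_{name}"] = atfcoh(coh, band)
        rec[f"area_{name}"] = area_fraction_above(coh, band, cfg.coherence_threshold)
        ps = atfps(pmap, band)
        rec[f"aTFPS_{name}"] = np.nan if isinstance(ps, NoValidArea) else ps
    for s in spectral_summary(abp, cbfv, cfg.welch, threshold=cfg.scoh_threshold):
        rec[f"aSCoh_{s.band}"] = s.ascoh
        rec[f"SPS_{s.band}"] = s.sps_deg
        rec[f"lowSCoh_{s.band}"] = s.low_coherence
    if cfg.run_stationarity:
        rec["nonstat_abp"] = test_stationarity_power(abp, cfg.stationarity).nonstationary
        rec["nonstat_cbfv"] = test_stationarity_power(cbfv, cfg.stationarity).nonstationary
        rec["nonstat_phase"] = test_stationarity_phase(abp, cbfv, cfg.stationarity).nonstationary
    return rec


def run_cohort(
    subjects: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Analyse a cohort and compare states.

    ``subjects`` maps subject id -> state -> (abp, cbfv) detrended 2 Hz
    arrays.  Returns (records, paired Wilcoxon comparisons per metric,
    failed subject ids).  Per-subject failures are caught and reported, not
    raised.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    failures = []
    for sid, states in subjects.items():
        try:
            for state, (abp, cbfv) in states.items():
                rec = analyze_pair(abp, cbfv, cfg)
                rec.update({"subject": sid, "state": state})
                rows.append(rec)
        except Exception as err:  # noqa: BLE001 - isolate per-subject failures
            failures.append(f"{sid}: {err}")
    df = pd.DataFrame(rows)
    comparisons: dict = {}
    if not df.empty and {"normocapnia", "hypercapnia"} <= set(df["state"]):
        wide = df.pivot(index="subject", columns="state")
        for metric in [c for c in df.columns if c.startswith(("aTFCoh", "aTFPS", "area", "aSCoh", "SPS"))]:
            pair = wide[metric].dropna()
            if len(pair) >= 6:
                res = wilcoxon_paired(pair["normocapnia"], pair["hypercapnia"])
                comparisons[metric] = {"statistic": res.statistic, "p": res.p_value, "n": len(pair)}
    return df, comparisons, failures
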