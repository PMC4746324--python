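"""Multi-omics reconciliation of flux predictions.

qPCR side: per-well amplification efficiency is estimated from the
exponential phase of the fluorescence curve (log-linear sliding-window
fit), and relative expression ratios follow the efficiency-corrected
Pfaffl model E_t^dCt_t / E_ref^dCt_ref with one or more reference genes
(geometric mean across references). Records with failed melt curves are
excluded.

Metabolomics side: intensities are normalized by cell number and then by
total ion content (TIC), log2 fold changes between conditions are tested
per analyte (Welch) with Benjamini-Hochberg adjustment, and concordance
compares the sign of the measured change with the sign implied by the
model's sensitive-reaction net fluxes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sensitivity import NetFluxRecord

__all__ = [
    "FluorescenceCurve",
    "QpcrRecord",
    "ExpressionRatio",
    "MetaboliteTable",
    "ValidationError",
    "estimate_efficiency",
    "pfaffl_ratio",
    "normalize_metabolites",
    "log2_fold_change",
    "concordance",
    "E_MIN",
    "E_MAX",
]

E_MIN, E_MAX = 1.0, 2.2
WINDOW_WIDTHS = (4, 5, 6)
R2_MIN = 0.99


class ValidationError(ValueError):
    pass


@dataclass
class FluorescenceCurve:
    """Raw per-cycle fluorescence of one qPCR well (typically 40 cycles)."""

    well: str
    gene: str
    condition: str
    replicate: int
    cycles: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if len(self.cycles) != len(self.readings):
            raise ValidationError(f"well {self.well}: cycle/reading length mismatch")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValidationError(f"well {self.well}: cycles not strictly increasing")
        if np.any(self.readings < 0):
            raise ValidationError(f"well {self.well}: negative fluorescence")


@dataclass(frozen=True)
class QpcrRecord:
    """One quantification: gene, condition (low/high CO2), Ct, efficiency."""

    gene: str
    condition: str
    ct: float
    efficiency: float
    replicate: int = 1
    melt_ok: bool = True

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValidationError(f"{self.gene}: Ct must be positive")
        if not (E_MIN < self.efficiency <= E_MAX):
            raise ValidationError(
                f"{self.gene}: efficiency {self.efficiency} outside ({E_MIN}, {E_MAX}]"
            )


@dataclass(frozen=True)
class ExpressionRatio:
    gene: str
    ratio: float
    reference_genes: tuple[str, ...]


@dataclass
class MetaboliteTable:
    """Sample x analyte intensity matrix plus per-sample cell counts."""

    intensities: pd.DataFrame  # index sample, columns analytes
    cell_counts: pd.Series
    conditions: pd.Series  # sample -> condition label

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValidationError("negative intensities")
        if (self.cell_counts <= 0).any():
            raise ValidationError("non-positive cell count")


# ---------------------------------------------------------------------------
# qPCR

def estimate_efficiency(curve: FluorescenceCurve) -> float:
    """Amplification factor per cycle from the exponential phase.

    Subtracts the baseline (median of the first five readings), fits
    log10(F - baseline) against cycle over every sliding window of width
    4-6 that sits clearly above the baseline noise floor, keeps the window
    with the highest R^2, and
    returns E = 10^slope clipped into (1, 2.2]. Raises when no window
    reaches R^2 >= 0.99 with a positive slope — a flat or erratic curve
    has no measurable exponential phase.
    """
    f = curve.readings
    background = float(np.median(f[:5])) if len(f) >= 5 else float(f.min())
    signal = f - background  # baseline-subtracted amplification signal
    # fit only where amplification dominates the baseline (else the
    # subtraction noise dominates the log) and below the saturation
    # shoulder (else plateau truncation biases the slope)
    floor = max(2.0 * abs(background), 1e-12)
    ceiling = 0.5 * float(signal.max(initial=0.0))
    chosen: tuple[float, float] | None = None  # (r2, slope)
    # widest window first: more cycles in the fit means a lower-variance
    # slope, so narrower widths are only a fallback
    for width in sorted(WINDOW_WIDTHS, reverse=True):
        best: tuple[float, float] | None = None
        for start in range(0, len(f) - width + 1):
            window_f = signal[start : start + width]
            if np.any(window_f <= floor) or np.any(window_f >= ceiling):
                continue
            x = curve.cycles[start : start + width]
            y = np.log10(window_f)
            slope, _, r, _, _ = stats.linregress(x, y)
            if slope <= 0:
                continue
            r2 = r * r
            if r2 >= R2_MIN and (best is None or r2 > best[0]):
                best = (r2, slope)
        if best is not None:
            chosen = best
            break
    if chosen is None:
        raise ValidationError(
            f"well {curve.well}: no exponential-phase window with R^2 >= {R2_MIN}"
        )
    e = 10.0 ** chosen[1]
    if e <= E_MIN:
        raise ValidationError(f"well {curve.well}: efficiency {e:.3f} not > 1")
    return min(e, E_MAX)


def _condition_stats(records: list[QpcrRecord], condition: str, gene: str):
    usable = [r for r in records if r.condition == condition and r.melt_ok]
    dropped = [r for r in records if r.condition == condition and not r.melt_ok]
    if dropped:
        warnings.warn(
            f"{gene}: excluded {len(dropped)} record(s) with failed melt curve "
            f"in condition {condition!r}",
            stacklevel=3,
        )
    if not usable:
        raise ValidationError(f"{gene}: no usable records for condition {condition!r}")
    mean_ct = float(np.mean([r.ct for r in usable]))
    mean_e = float(np.mean([r.efficiency for r in usable]))
    return mean_ct, mean_e


def pfaffl_ratio(
    target: list[QpcrRecord],
    references: dict[str, list[QpcrRecord]],
    low: str = "low",
    high: str = "high",
) -> ExpressionRatio:
    """Efficiency-corrected relative expression of the target gene.

    ratio = E_t^(dCt_t) / geo-mean_ref E_ref^(dCt_ref), with
    dCt = Ct(high) - Ct(low), so ratio > 1 means higher expression at low
    CO2. With all efficiencies equal to 2 this reduces to the classical
    2^(-ddCt).
    """
    if not target:
        raise ValidationError("no target records")
    if not references:
        raise ValidationError("at least one reference gene is required")
    gene = target[0].gene
    ct_low, e_low = _condition_stats(target, low, gene)
    ct_high, e_high = _condition_stats(target, high, gene)
    e_t = (e_low + e_high) / 2.0
    numer = e_t ** (ct_high - ct_low)
    log_denom = 0.0
    for ref_gene, recs in references.items():
        rct_low, re_low = _condition_stats(recs, low, ref_gene)
        rct_high, re_high = _condition_stats(recs, high, ref_gene)
        e_r = (re_low + re_high) / 2.0
        log_denom += (rct_high - rct_low) * math.log(e_r)
    denom = math.exp(log_denom / len(references))
    return ExpressionRatio(
        gene=gene, ratio=numer / denom, reference_genes=tuple(sorted(references))
    )


# ---------------------------------------------------------------------------
# metabolomics

def normalize_metabolites(table: MetaboliteTable) -> pd.DataFrame:
    """Divide intensities by cell count, then by total ion content.

    After normalization every sample's analyte values sum to 1, and the
    result is invariant to any per-sample rescaling of the raw data.
    """
    per_cell = table.intensities.div(table.cell_counts, axis=0)
    tic = per_cell.sum(axis=1)
    if (tic <= 0).any():
        bad = tic[tic <= 0].index.tolist()
        raise ValidationError(f"zero total ion content in sample(s) {bad}")
    return per_cell.div(tic, axis=0)


def log2_fold_change(
    normalized: pd.DataFrame,
    conditions: pd.Series,
    low: str = "low",
    high: str = "high",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-analyte log2(high/low) with Welch tests and BH adjustment.

    Returns a frame indexed by analyte with columns log2fc, pvalue, padj,
    significant, flagged (analyte missing/zero in a condition).
    """
    low_idx = conditions[conditions == low].index
    high_idx = conditions[conditions == high].index
    if len(low_idx) < 2 or len(high_idx) < 2:
        raise ValidationError("need >= 2 replicates per condition")
    rows = []
    for analyte in normalized.columns:
        lo = normalized.loc[low_idx, analyte].to_numpy(dtype=float)
        hi = normalized.loc[high_idx, analyte].to_numpy(dtype=float)
        flagged = bool(np.any(lo <= 0) or np.any(hi <= 0))
        if flagged:
            rows.append((analyte, np.nan, np.nan, True))
            continue
        log2fc = float(np.log2(hi.mean() / lo.mean()))
        _, p = stats.ttest_ind(np.log2(hi), np.log2(lo), equal_var=False)
        rows.append((analyte, log2fc, float(p), False))
    df = pd.DataFrame(rows, columns=["analyte", "log2fc", "pvalue", "flagged"])
    df = df.set_index("analyte")
    mask = ~df["pvalue"].isna()
    padj = pd.Series(np.nan, index=df.index)
    if mask.any():
        padj[mask] = multipletests(df.loc[mask, "pvalue"], method="fdr_bh")[1]
    df["padj"] = padj
    df["significant"] = df["padj"] < alpha
    return df


# ---------------------------------------------------------------------------
# concordance with model net fluxes

@dataclass
class ConcordanceReport:
    records: list[NetFluxRecord] = field(default_factory=list)
    concordant: int = 0
    discordant: int = 0
    unevaluable: int = 0

    @property
    def evaluable(self) -> int:
        return self.concordant + self.discordant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite": r.metabolite_id,
                    "net_flux_low": r.net_flux_low,
                    "net_flux_high": r.net_flux_high,
                    "ratio_low_high": r.ratio,
                    "concordant": r.concordant,
                }
                for r in self.records
            ]
        )


def concordance(
    netflux_records: list[NetFluxRecord],
    fold_changes: pd.DataFrame,
    name_map: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Compare model-predicted direction of change with measured log2FC.

    A metabolite is concordant when sign(log2(net_high / net_low)) equals
    sign(measured log2FC high-vs-low). Metabolites with undefined ratios,
    non-positive net fluxes on either side, or missing measurements are
    unevaluable.
    """
    name_map = name_map or {}
    report = ConcordanceReport()
    matched = False
    for rec in netflux_records:
        analyte = name_map.get(rec.metabolite_id, rec.metabolite_id)
        rec = NetFluxRecord(**rec.__dict__)
        if analyte in fold_changes.index:
            matched = True
        if (
            analyte not in fold_changes.index
            or rec.ratio is None
            or rec.net_flux_low <= 0
            or rec.net_flux_high <= 0
            or np.isnan(fold_changes.at[analyte, "log2fc"])
        ):
            rec.concordant = None
            report.unevaluable += 1
        else:
            predicted = math.copysign(
                1.0, math.log2(rec.net_flux_high / rec.net_flux_low)
            )
            measured = math.copysign(1.0, fold_changes.at[analyte, "log2fc"])
            rec.concordant = predicted == measured
            if rec.concordant:
                report.concordant += 1
            else:
                report.discordant += 1
        report.records.append(rec)
    if not matched:
        warnings.warn("no shared metabolites between model and measurements",
                      stacklevel=2)
    return report
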