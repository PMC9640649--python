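"""Epithelial/mesenchymal (EMT) scoring and paired-site comparison.

The per-sample score is the mean observed abundance of mesenchymal-class
features minus the mean observed abundance of epithelial-class features;
higher means more mesenchymal.  Paired comparisons pick Student's paired
t-test or the Wilcoxon signed-rank test according to a Shapiro-Wilk
normality check on the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EMTScore",
    "PairedTestResult",
    "read_signature",
    "emt_score",
    "compare_paired",
]

EPI = "Epi"
MES = "Mes"


@dataclass(frozen=True)
class EMTScore:
    sample_id: str
    score: float
    n_mes_used: int
    n_epi_used: int
    valid: bool


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str  # paired_t | wilcoxon | degenerate
    statistic: float
    p: float
    shapiro_p: float
    degenerate: bool = False


def read_signature(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, class in {Epi, Mes})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    sig = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    bad = {c for c in sig.values() if c not in (EPI, MES)}
    if bad:
        raise ValueError(f"signature classes must be Epi/Mes, got {sorted(bad)}")
    if EPI not in sig.values() or MES not in sig.values():
        raise ValueError("signature needs at least one gene per class")
    return sig


def emt_score(
    table: pd.DataFrame,
    signature: Mapping[str, str],
    min_per_class: int = 3,
) -> list[EMTScore]:
    """Per-sample mean(Mes) - mean(Epi) over observed values.

    Samples with fewer than ``min_per_class`` observed values in either
    class are flagged invalid (score still reported when computable).
    """
    mes_ids = [g for g, c in signature.items() if c == MES and g in table.index]
    epi_ids = [g for g, c in signature.items() if c == EPI and g in table.index]
    if not mes_ids and not epi_ids:
        raise ValueError("signature has zero overlap with the table")

    scores = []
    for sample in table.columns:
        mes = table.loc[mes_ids, sample].dropna() if mes_ids else pd.Series(dtype=float)
        epi = table.loc[epi_ids, sample].dropna() if epi_ids else pd.Series(dtype=float)
        valid = len(mes) >= min_per_class and len(epi) >= min_per_class
        score = (
            float(mes.mean() - epi.mean()) if len(mes) and len(epi) else float("nan")
        )
        scores.append(
            EMTScore(
                sample_id=str(sample),
                score=score,
                n_mes_used=len(mes),
                n_epi_used=len(epi),
                valid=valid,
            )
        )
    return scores


def compare_paired(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    normality_alpha: float = 0.05,
) -> PairedTestResult:
    """Normality-guided paired comparison of two matched score vectors.

    Shapiro-Wilk on the paired differences selects the paired t-test
    (normal) or the Wilcoxon signed-rank test (non-normal, zero
    differences dropped).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and matched")
    if len(a) < 4:
        raise ValueError("need at least 4 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedTestResult("degenerate", 0.0, 1.0, float("nan"), degenerate=True)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p > normality_alpha:
        res = stats.ttest_rel(a, b)
        return PairedTestResult("paired_t", float(res.statistic), float(res.pvalue), shapiro_p)
    nz = d[d != 0]
    res = stats.wilcoxon(nz)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), shapiro_p)
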