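"""Differential metabolites and transcript-metabolite association.

Differential metabolites follow the screening rule used for untargeted
profiles: Welch two-sample t-test on log-transformed replicate abundances,
flagged when p < alpha and the condition-mean fold change exceeds ``min_fc``
in either direction.  Association between an AS transcript and a metabolite
is the Pearson correlation of their condition-mean profiles over shared
conditions; |r| above a threshold (default 0.7) marks a strong association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ExpressionMatrix

#: log-transform applied to metabolite replicate values before testing
def _log(x: np.ndarray) -> np.ndarray:
    return np.log2(x + 1.0)


DEFAULT_CORR_THRESHOLD = 0.7


class MetaboliteError(ValueError):
    pass


@dataclass
class MetaboliteMatrix:
    """Metabolite x sample abundance matrix with condition labels."""

    values: pd.DataFrame
    samples: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise MetaboliteError("negative metabolite abundances")
        missing = set(self.values.columns) - set(self.samples)
        if missing:
            raise MetaboliteError(f"samples without condition label: {missing}")

    def condition_columns(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.samples[s] == condition]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.samples[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        return pd.DataFrame({
            c: self.values[self.condition_columns(c)].mean(axis=1)
            for c in self.conditions()
        })


def read_metabolites(path, sample_conditions: Optional[Mapping[str, str]] = None
                     ) -> MetaboliteMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_conditions is None:
        sample_conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
    return MetaboliteMatrix(df, dict(sample_conditions))


def call_diff_metabolites(matrix: MetaboliteMatrix, contrast: tuple[str, str],
                          min_fc: float = 2.0, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Welch t-test screen for differential metabolites in one contrast."""
    cols_a = matrix.condition_columns(contrast[0])
    cols_b = matrix.condition_columns(contrast[1])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise MetaboliteError(
            f"contrast {contrast}: each condition needs >= 2 replicates"
        )
    block_a = matrix.values[cols_a].values
    block_b = matrix.values[cols_b].values
    t, p = stats.ttest_ind(_log(block_a), _log(block_b), axis=1,
                           equal_var=False)
    # zero-variance metabolites with equal means: p = 1 by convention
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    mean_a, mean_b = block_a.mean(axis=1), block_b.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2((mean_a + 1e-9) / (mean_b + 1e-9))
    fc_pass = np.abs(log2fc) > math.log2(min_fc)
    return pd.DataFrame({
        "metabolite_id": matrix.values.index,
        "contrast": f"{contrast[0]}:{contrast[1]}",
        "mean_a": mean_a, "mean_b": mean_b,
        "log2_fold_change": log2fc,
        "statistic": t, "p_value": p,
        "is_differential": (p < alpha) & fc_pass,
    }).reset_index(drop=True)


@dataclass
class AssociationResult:
    transcript_id: str
    metabolite_id: str
    r: Optional[float]
    n_conditions: int
    p_value: Optional[float]
    is_strong: bool


def correlate(expr: ExpressionMatrix, metab: MetaboliteMatrix,
              pairs: Optional[Iterable[tuple[str, str]]] = None,
              threshold: float = DEFAULT_CORR_THRESHOLD,
              level: str = "condition-means",
              ) -> list[AssociationResult]:
    """Pearson association between transcripts and metabolites.

    By default correlates condition-mean profiles over the conditions shared
    by the two matrices (the time-course framing); ``level='replicates'``
    correlates matched replicate columns instead.  ``pairs`` restricts the
    computation; otherwise all transcript x metabolite pairs are tested.
    Zero-variance series yield r = None.
    """
    if level == "condition-means":
        e_prof = expr.transcript_condition_means()
        m_prof = metab.condition_means()
        shared = [c for c in e_prof.columns if c in set(m_prof.columns)]
        if len(shared) < 3:
            raise MetaboliteError(
                f"association needs >= 3 shared conditions, got {len(shared)}"
            )
        e_prof, m_prof = e_prof[shared], m_prof[shared]
    elif level == "replicates":
        shared = [c for c in expr.values.columns if c in set(metab.values.columns)]
        if len(shared) < 3:
            raise MetaboliteError("replicate-level association needs >= 3 shared samples")
        e_prof, m_prof = expr.values[shared], metab.values[shared]
    else:
        raise ValueError(f"unknown level {level!r}")

    if pairs is None:
        pairs = [(t, m) for t in e_prof.index for m in m_prof.index]

    n = len(e_prof.columns)
    out = []
    for tid, mid in pairs:
        x = e_prof.loc[tid].values.astype(float)
        y = m_prof.loc[mid].values.astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(AssociationResult(tid, mid, None, n, None, False))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        # p from the t-distribution with n-2 df
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tstat = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
        out.append(AssociationResult(
            tid, mid, r, n, p, bool(abs(r) > threshold)
        ))
    return out


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "transcript_id": a.transcript_id, "metabolite_id": a.metabolite_id,
        "r": a.r if a.r is not None else np.nan,
        "n_conditions": a.n_conditions,
        "p_value": a.p_value if a.p_value is not None else np.nan,
        "sign": ("+" if a.r > 0 else "-") if a.r else ".",
        "is_strong": a.is_strong,
    } for a in results])


def correlation_matrix(expr: ExpressionMatrix, metab: MetaboliteMatrix,
                       transcripts: Optional[Sequence[str]] = None,
                       metabolites: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Transcript x metabolite condition-mean correlation matrix (for
    heatmap rendering)."""
    e_prof = expr.transcript_condition_means()
    m_prof = metab.condition_means()
    shared = [c for c in e_prof.columns if c in set(m_prof.columns)]
    e_prof, m_prof = e_prof[shared], m_prof[shared]
    if transcripts is not None:
        e_prof = e_prof.loc[list(transcripts)]
    if metabolites is not None:
        m_prof = m_prof.loc[list(metabolites)]
    ez = e_prof.sub(e_prof.mean(axis=1), axis=0)
    mz = m_prof.sub(m_prof.mean(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = ez.values @ mz.values.T
        den = np.outer(np.sqrt((ez.values ** 2).sum(axis=1)),
                       np.sqrt((mz.values ** 2).sum(axis=1)))
        corr = num / den
    return pd.DataFrame(corr, index=e_prof.index, columns=m_prof.index)
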