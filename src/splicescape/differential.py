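"""Differential gene expression, differential AS genes (DAGs) and term
enrichment.

The two-condition test is an MA-plot normal approximation on pooled,
library-rescaled pseudo-counts: replicate TPM values are averaged per
condition, gene sums rescaled to an integer library of nominal size, and the
log2 ratio M tested against its binomial-propagated null variance (the
two-library test popularized by DEGseq).  A gene is differentially expressed
when its BH q-value is below ``alpha`` AND its condition-mean fold change
exceeds ``min_fc`` in either direction; a DE gene that also undergoes AS in
either condition of the contrast is a DAG.  A replicate-aware Welch-t
alternative is exposed for designs with more replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: pseudo-value added to condition means before fold-change computation
FC_PSEUDO = 0.1
#: nominal library size for pseudo-count rescaling
NOMINAL_LIBRARY = 1_000_000


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Transcript x sample TPM-scale matrix with condition/replicate labels.

    ``samples`` maps sample id -> condition label; ``gene_map`` maps
    transcript id -> gene id.
    """

    values: pd.DataFrame
    samples: Mapping[str, str]
    gene_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ExpressionError("negative expression values")
        missing = set(self.values.columns) - set(self.samples)
        if missing:
            raise ExpressionError(f"samples without condition label: {missing}")

    def condition_columns(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.samples[s] == condition]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.samples[s]
            if c not in seen:
                seen.append(c)
        return seen

    def gene_values(self) -> pd.DataFrame:
        """Gene expression = sum of the gene's transcript values."""
        gene_ids = [self.gene_map.get(t, t) for t in self.values.index]
        return self.values.groupby(pd.Index(gene_ids, name="gene_id")).sum()

    def gene_condition_means(self) -> pd.DataFrame:
        gv = self.gene_values()
        cols = {c: gv[self.condition_columns(c)].mean(axis=1)
                for c in self.conditions()}
        return pd.DataFrame(cols)

    def transcript_condition_means(self) -> pd.DataFrame:
        cols = {c: self.values[self.condition_columns(c)].mean(axis=1)
                for c in self.conditions()}
        return pd.DataFrame(cols)


def read_expression(path, sample_conditions: Optional[Mapping[str, str]] = None,
                    gene_map: Optional[Mapping[str, str]] = None
                    ) -> ExpressionMatrix:
    """Read a transcripts x samples TSV (columns named ``COND_rep`` unless a
    sample->condition mapping is supplied)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_conditions is None:
        sample_conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
    if gene_map is None:
        gene_map = {t: t.rsplit(".", 1)[0] for t in df.index}
    return ExpressionMatrix(df, dict(sample_conditions), dict(gene_map))


@dataclass
class DagResult:
    gene_id: str
    contrast: tuple[str, str]
    mean_a: float
    mean_b: float
    log2_fold_change: float
    statistic: float
    p_value: float
    q_value: float = math.nan
    is_de: bool = False
    has_as: bool = False
    is_dag: bool = False


def _ma_test(counts_a: np.ndarray, counts_b: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Two-library MA-plot normal-approximation test.

    Under the null that gene g's proportion is the same in both libraries,
    M = log2(k_a) - log2(k_b) has expectation log2(n_a/n_b) and variance
    (1-p)/(n_a p) + (1-p)/(n_b p) propagated to log2 space (delta method on
    the binomial counts).  Returns (Z, two-sided p).
    """
    n_a, n_b = counts_a.sum(), counts_b.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (counts_a + counts_b) / (n_a + n_b)
        m = np.log2(counts_a) - np.log2(counts_b)
        m0 = np.log2(n_a / n_b)
        var = ((1 - p_hat) / (n_a * p_hat) + (1 - p_hat) / (n_b * p_hat)) \
            / (math.log(2) ** 2)
        z = (m - m0) / np.sqrt(var)
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return z, p


def _welch_test(block_a: pd.DataFrame, block_b: pd.DataFrame
                ) -> tuple[np.ndarray, np.ndarray]:
    """Welch t on log2(x + pseudo) replicate values per gene."""
    la = np.log2(block_a.values + FC_PSEUDO)
    lb = np.log2(block_b.values + FC_PSEUDO)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def call_de(matrix: ExpressionMatrix, contrast: tuple[str, str],
            alpha: float = 0.01, min_fc: float = 2.0,
            method: str = "ma", library_size: int = NOMINAL_LIBRARY,
            ) -> list[DagResult]:
    """Differential expression for one condition contrast.

    ``method='ma'`` is the pooled two-library binomial approximation;
    ``method='welch'`` is the replicate-aware alternative.  Genes with zero
    signal in both conditions are excluded (their count is available on the
    returned list via ``call_de.n_excluded`` semantics in the frame variant).
    """
    cond_a, cond_b = contrast
    gv = matrix.gene_values()
    cols_a = matrix.condition_columns(cond_a)
    cols_b = matrix.condition_columns(cond_b)
    if not cols_a or not cols_b:
        raise ExpressionError(f"contrast {contrast}: condition missing samples")
    mean_a = gv[cols_a].mean(axis=1)
    mean_b = gv[cols_b].mean(axis=1)
    if mean_a.sum() == 0 or mean_b.sum() == 0:
        raise ExpressionError(f"contrast {contrast}: condition with zero signal")

    keep = (mean_a > 0) | (mean_b > 0)
    genes = gv.index[keep]
    ma_, mb_ = mean_a[keep], mean_b[keep]

    if method == "ma":
        ka = np.rint(ma_ / ma_.sum() * library_size).astype(np.int64)
        kb = np.rint(mb_ / mb_.sum() * library_size).astype(np.int64)
        z, p = _ma_test(ka.values.astype(float), kb.values.astype(float))
    elif method == "welch":
        z, p = _welch_test(gv.loc[genes, cols_a], gv.loc[genes, cols_b])
    else:
        raise ValueError(f"unknown method {method!r}")

    q = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2((ma_.values + FC_PSEUDO) / (mb_.values + FC_PSEUDO))

    out = []
    for i, g in enumerate(genes):
        fc_pass = abs(log2fc[i]) > math.log2(min_fc)
        out.append(DagResult(
            gene_id=str(g), contrast=(cond_a, cond_b),
            mean_a=float(ma_.iloc[i]), mean_b=float(mb_.iloc[i]),
            log2_fold_change=float(log2fc[i]),
            statistic=float(z[i]), p_value=float(p[i]), q_value=float(q[i]),
            is_de=bool(q[i] < alpha and fc_pass),
        ))
    return out


def call_dags(de: Sequence[DagResult],
              as_gene_sets: Mapping[str, set]) -> list[DagResult]:
    """Flag DE genes that undergo AS in either condition of their contrast."""
    for r in de:
        union = set()
        for cond in r.contrast:
            union |= set(as_gene_sets.get(cond, set()))
        r.has_as = r.gene_id in union
        r.is_dag = r.is_de and r.has_as
    return list(de)


def dag_overlap(dags_by_contrast: Mapping[str, Sequence[DagResult]]) -> dict:
    """Counts, pairwise overlaps and per-contrast unique DAG sets."""
    sets = {
        name: {r.gene_id for r in results if r.is_dag}
        for name, results in dags_by_contrast.items()
    }
    names = list(sets)
    overlap = {
        f"{a}&{b}": len(sets[a] & sets[b])
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    unique = {
        a: len(sets[a] - set.union(set(), *(sets[b] for b in names if b != a)))
        for a in names
    }
    return {
        "counts": {a: len(sets[a]) for a in names},
        "pairwise_overlap": overlap,
        "unique": unique,
        "common": len(set.intersection(*sets.values())) if sets else 0,
    }


def de_results_to_frame(results: Sequence[DagResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id,
        "contrast": f"{r.contrast[0]}:{r.contrast[1]}",
        "mean_a": r.mean_a, "mean_b": r.mean_b,
        "log2_fold_change": r.log2_fold_change,
        "statistic": r.statistic, "p_value": r.p_value, "q_value": r.q_value,
        "is_de": r.is_de, "has_as": r.has_as, "is_dag": r.is_dag,
    } for r in results])


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich(genes: set, universe: set,
           term_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with BH correction.

    ``term_map`` maps gene -> iterable of terms.  Returns every term sorted
    by ascending p (thresholds such as fdr < 0.05 are presentation defaults,
    not output filters).  Columns: term, k (study hits), K (term size in
    universe), n (study size), N (universe size), p, fdr.
    """
    if not term_map:
        raise ValueError("empty term map")
    if not genes <= universe:
        raise ValueError("study genes must be a subset of the universe")
    by_term: dict[str, set] = {}
    for g, terms in term_map.items():
        if g not in universe:
            continue
        for term in terms:
            by_term.setdefault(term, set()).add(g)
    n, big_n = len(genes), len(universe)
    rows = []
    for term, members in sorted(by_term.items()):
        big_k = len(members)
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def read_term_map(path) -> dict[str, list[str]]:
    """gene<TAB>term pairs, one per line, into a gene -> terms mapping."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, []).append(term)
    return out
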