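"""Negative-binomial differential expression between two conditions.

A transparent two-group count test in the DESeq2 tradition: median-of-ratios
size factors, per-gene method-of-moments dispersion pooled across the two
groups, a Wald statistic on the log2 fold change with a delta-method standard
error from the NB variance mu + alpha*mu^2, and Benjamini-Hochberg correction
over the tested genes. Deliberately simpler than DESeq2 itself: no dispersion
trend or shrinkage, no Cook's-distance outlier handling, no shrunken fold
changes. The reference distribution for the Wald statistic is Student t with
n_ref + n_alt - 2 degrees of freedom; with the handful of replicates typical
of these designs the plug-in dispersion makes a normal reference visibly
anti-conservative, and the t reference restores type-I calibration while
converging to the normal as replication grows.

Genes whose mean normalized count falls below ``min_base_mean`` are excluded
from testing and from the BH family (independent filtering); they carry NaN
p and FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

__all__ = [
    "DEResult",
    "DegRule",
    "PERTURBATION_RULE",
    "DRUG_RULE",
    "size_factors",
    "nb_wald_contrast",
    "bh_adjust",
    "call_degs",
]


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast.

    ``table`` is indexed by gene with columns ``base_mean``, ``log2fc``,
    ``se``, ``p``, ``fdr``. Untested genes (independent filter) have NaN in
    ``p``/``fdr``.
    """

    table: pd.DataFrame
    ref: str
    alt: str

    def __post_init__(self) -> None:
        need = ["base_mean", "log2fc", "se", "p", "fdr"]
        if list(self.table.columns) != need:
            raise ValueError(f"DEResult table must have columns {need}")
        tested = self.table["p"].notna()
        p = self.table.loc[tested, "p"]
        fdr = self.table.loc[tested, "fdr"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if (fdr + 1e-12 < p).any():
            raise ValueError("BH-adjusted values must not fall below raw p")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


AlphaOn = Literal["fdr", "raw_p"]


@dataclass(frozen=True)
class DegRule:
    """A DEG-calling rule: strict |log2fc| threshold plus significance cut.

    ``alpha_on`` chooses whether ``alpha`` applies to the BH-adjusted FDR or
    to the raw p-value.
    """

    lfc_threshold: float
    alpha: float
    alpha_on: AlphaOn = "fdr"

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha_on not in ("fdr", "raw_p"):
            raise ValueError("alpha_on must be 'fdr' or 'raw_p'")


#: Stringent rule for the strong perturbation contrast: |log2FC| > 1.5, FDR < 0.05.
PERTURBATION_RULE = DegRule(lfc_threshold=1.5, alpha=0.05, alpha_on="fdr")

#: Permissive rule for the drug contrast: fold change > 1.5 (log2 threshold
#: log2(1.5) ~ 0.585), raw p < 0.05 — drugs move expression less than the
#: perturbation does.
DRUG_RULE = DegRule(lfc_threshold=math.log2(1.5), alpha=0.05, alpha_on="raw_p")


def size_factors(cm: CountMatrix | np.ndarray, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample normalization factors.

    The reference for each gene is its geometric mean over samples (genes
    with any zero are excluded); each sample's factor is the median ratio of
    its counts to the reference, rescaled so the factors have geometric mean
    one. With ``pseudo_reference`` the geometric mean is computed on counts
    plus 0.5 so sparse matrices with no universally expressed gene still
    normalize.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    c = counts.astype(float)
    if pseudo_reference:
        c = c + 0.5
        expressed = np.ones(c.shape[0], dtype=bool)
    else:
        expressed = (counts > 0).all(axis=1)
        if not expressed.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to normalize against counts + 0.5"
            )
    logc = np.log(c[expressed])
    log_geomean = logc.mean(axis=1)
    factors = np.median(np.exp(logc - log_geomean[:, None]), axis=0)
    return factors / np.exp(np.log(factors).mean())


def nb_wald_contrast(
    cm: CountMatrix,
    ref: str,
    alt: str,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    min_base_mean: float = 1.0,
) -> DEResult:
    """Test every gene for differential expression between two conditions.

    Counts are normalized by size factors computed on the samples of the two
    conditions; the gene-wise dispersion is estimated by method of moments
    from the pooled within-group variance of normalized counts (floored at
    ``dispersion_floor``); the log2 fold change uses a pseudocount for
    stability at zero means. Two-sided p-values come from a t reference with
    pooled degrees of freedom; BH adjustment spans the tested genes only.
    """
    for cond in (ref, alt):
        idx = cm.column_indices(cond)
        if idx.size == 0:
            raise ValueError(f"condition {cond!r} absent from count matrix")
        if idx.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
    i_ref = cm.column_indices(ref)
    i_alt = cm.column_indices(alt)
    cols = np.concatenate([i_ref, i_alt])
    sub = cm.counts[:, cols]
    factors = size_factors(sub)
    norm = sub / factors[None, :]
    a = norm[:, : i_ref.size]
    b = norm[:, i_ref.size :]
    n_r, n_a = a.shape[1], b.shape[1]

    m_ref = a.mean(axis=1)
    m_alt = b.mean(axis=1)
    base_mean = norm.mean(axis=1)

    v_pool = ((n_r - 1) * a.var(axis=1, ddof=1) + (n_a - 1) * b.var(axis=1, ddof=1)) / (
        n_r + n_a - 2
    )
    m_pool = (m_ref + m_alt) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v_pool - m_pool) / np.where(m_pool > 0, m_pool, 1.0) ** 2
    disp = np.maximum(np.nan_to_num(disp, nan=0.0), dispersion_floor)

    log2fc = np.log2((m_alt + pseudocount) / (m_ref + pseudocount))
    var_alt = (m_alt + disp * m_alt**2) / n_a
    var_ref = (m_ref + disp * m_ref**2) / n_r
    se = (
        np.sqrt(var_alt / (m_alt + pseudocount) ** 2 + var_ref / (m_ref + pseudocount) ** 2)
        / np.log(2)
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(log2fc == 0.0, 0.0, log2fc / np.where(se > 0, se, np.inf))
    p = 2.0 * stats.t.sf(np.abs(z), df=n_r + n_a - 2)

    tested = base_mean >= min_base_mean
    p = np.where(tested, p, np.nan)
    fdr = bh_adjust(p)

    table = pd.DataFrame(
        {"base_mean": base_mean, "log2fc": log2fc, "se": se, "p": p, "fdr": fdr},
        index=pd.Index(cm.gene_ids, name="gene"),
    )
    return DEResult(table=table, ref=ref, alt=alt)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN entries passed through.

    NaN marks genes excluded from the family (independent filtering); they
    are removed before adjustment and reinserted as NaN, so the family size
    is the number of finite p-values.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_degs(de: DEResult, rule: DegRule) -> dict[str, str]:
    """Classify genes as 'up'/'down' under a DegRule (strict inequalities).

    Untested genes (NaN p) are never called.
    """
    sig_col = "fdr" if rule.alpha_on == "fdr" else "p"
    t = de.table
    sig = t[sig_col] < rule.alpha
    up = sig & (t["log2fc"] > rule.lfc_threshold)
    down = sig & (t["log2fc"] < -rule.lfc_threshold)
    calls: dict[str, str] = {}
    for g in t.index[up]:
        calls[g] = "up"
    for g in t.index[down]:
        calls[g] = "down"
    return calls
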