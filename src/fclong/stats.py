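"""Significance tests and descriptive tables for FC change.

Covers the one-sample Bonferroni-corrected t-test applied to the 105
network-block changes, sign-count tables of subjects increasing/decreasing
in a block (and in total FC) per subgroup, the cross-sectional young-vs-old
group comparison (Welch's two-sample t-test per block), and phenotype-change
Pearson correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import BlockKey, NetworkPartition
from .errors import DataError
from .netblocks import (
    ScanPair,
    SingleScan,
    edge_block_index,
    subject_block_table,
    total_fc,
)

log = logging.getLogger(__name__)

#: Default multiple-comparison factor: the 105 network blocks of the
#: 14-network parcellation.
DEFAULT_M_COMPARISONS = 105


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_raw: float
    p_bonf: float
    n: int
    degenerate: bool = False


def block_ttest(
    changes: Sequence[float] | np.ndarray,
    m_comparisons: int = DEFAULT_M_COMPARISONS,
) -> TTestResult:
    """Two-sided one-sample t-test of block changes against zero.

    ``p_bonf = min(1, m_comparisons * p_raw)``.  Zero dispersion with a
    nonzero mean is degenerate: the t statistic diverges and ``p_raw`` is
    reported as 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(changes, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise DataError("t-test requires at least 2 observations")
    sd = np.std(x, ddof=1)
    # fp-tolerant zero-dispersion check (identical values stored inexactly)
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        if np.mean(x) == 0.0:
            return TTestResult(t=0.0, p_raw=1.0, p_bonf=1.0, n=n)
        return TTestResult(t=float(np.sign(np.mean(x)) * np.inf),
                           p_raw=0.0, p_bonf=0.0, n=n, degenerate=True)
    res = sps.ttest_1samp(x, popmean=0.0)
    p_raw = float(res.pvalue)
    return TTestResult(
        t=float(res.statistic),
        p_raw=p_raw,
        p_bonf=min(1.0, m_comparisons * p_raw),
        n=n,
    )


# ---------------------------------------------------------------------------
# Table-3-style sign counts

_SUBGROUPS = (
    ("male", lambda p: p.sex == "male"),
    ("female", lambda p: p.sex == "female"),
    ("younger", lambda p: p.age_group == "younger"),
    ("older", lambda p: p.age_group == "older"),
)


def sign_counts(
    cohort: Sequence[ScanPair],
    partition: NetworkPartition,
    block: BlockKey = (0, 6),
) -> pd.DataFrame:
    """Counts of subjects with increasing/decreasing block FC and total FC.

    One row per subgroup (male, female, younger <55, older >65) with strictly
    positive and strictly negative counts; exact zeros get their own column
    rather than being folded into either sign.  Percentages are of the
    subgroup total.
    """
    tab = subject_block_table(cohort, partition)
    col = tab.column(block)
    block_change = tab.change[:, col]
    total_change = np.array(
        [total_fc(p.older) - total_fc(p.younger) for p in cohort]
    )

    rows = []
    for name, member in _SUBGROUPS:
        sel = np.array([bool(member(p)) for p in cohort])
        n = int(sel.sum())
        if n == 0:
            log.warning("subgroup %s is empty", name)
        bc, tc = block_change[sel], total_change[sel]
        row = {"group": name, "n": n}
        for prefix, ch in (("block", bc), ("total", tc)):
            ok = np.isfinite(ch)
            pos, neg = int((ch[ok] > 0).sum()), int((ch[ok] < 0).sum())
            zero = int((ch[ok] == 0).sum())
            row[f"{prefix}_pos"] = pos
            row[f"{prefix}_neg"] = neg
            row[f"{prefix}_zero"] = zero
            row[f"{prefix}_pos_pct"] = 100.0 * pos / n if n else float("nan")
            row[f"{prefix}_neg_pct"] = 100.0 * neg / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Cross-sectional young-vs-old comparison


@dataclass
class CrossSectionalSummary:
    """Per-block old-minus-young group comparison plus a Total FC row.

    Dispersions of the per-subject block averages are reported separately for
    each group and pooled; the test is Welch's unequal-variance two-sample
    t-test (the groups differ in size by several fold in the cohorts this
    mirrors).
    """

    table: pd.DataFrame
    edge_diff: np.ndarray
    n_young: int
    n_old: int


def _scan_block_means(
    scans: Sequence[SingleScan], partition: NetworkPartition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    keys, edge_key, counts = edge_block_index(partition)
    n_blk = len(keys)
    out = np.empty((len(scans), n_blk))
    totals = np.empty(len(scans))
    vecs = np.empty((len(scans), len(edge_key)))
    for s, scan in enumerate(scans):
        vec = scan.fc
        vecs[s] = vec
        bad = np.bincount(edge_key, weights=(~np.isfinite(vec)).astype(float),
                          minlength=n_blk) > 0
        sums = np.bincount(edge_key, weights=np.nan_to_num(vec), minlength=n_blk)
        row = sums / counts
        row[bad] = np.nan
        out[s] = row
        totals[s] = total_fc(vec)
    return out, totals, vecs


def cross_sectional_compare(
    young: Sequence[SingleScan],
    old: Sequence[SingleScan],
    partition: NetworkPartition,
) -> CrossSectionalSummary:
    """Old-group minus young-group difference in mean block FC.

    Different subjects in each group (cross-sectional contrast, as opposed to
    the paired longitudinal one).  Also returns the edge-level mean difference
    map.
    """
    if len(young) < 2 or len(old) < 2:
        raise DataError("each cross-sectional group needs at least 2 subjects")
    keys, _, _ = edge_block_index(partition)
    by, ty, vy = _scan_block_means(young, partition)
    bo, to, vo = _scan_block_means(old, partition)

    rows = []
    for i, key in enumerate(list(keys) + ["total"]):
        if key == "total":
            a, b = ty, to
            name, block = "total", "Total FC"
        else:
            a, b = by[:, i], bo[:, i]
            name, block = f"{key[0]}-{key[1]}", partition.block_name(key)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        diff = float(np.mean(b) - np.mean(a))
        sd_y, sd_o = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
        pooled = float(np.sqrt(
            ((a.size - 1) * sd_y**2 + (b.size - 1) * sd_o**2)
            / (a.size + b.size - 2)
        ))
        welch = sps.ttest_ind(b, a, equal_var=False)
        rows.append({
            "block": name,
            "networks": block,
            "diff": diff,
            "sd_young": sd_y,
            "sd_old": sd_o,
            "sd_pooled": pooled,
            "p": float(welch.pvalue),
            "n_young": int(a.size),
            "n_old": int(b.size),
        })
    table = pd.DataFrame(rows).set_index("block")

    n = partition.n_rois
    iu = np.triu_indices(n, k=1)
    d = np.nanmean(vo, axis=0) - np.nanmean(vy, axis=0)
    edge_diff = np.zeros((n, n))
    edge_diff[iu] = d
    edge_diff[(iu[1], iu[0])] = d
    return CrossSectionalSummary(table=table, edge_diff=edge_diff,
                                 n_young=len(young), n_old=len(old))


def cross_sectional_by_sex(
    scans: Sequence[SingleScan], partition: NetworkPartition
) -> dict[str, CrossSectionalSummary]:
    """Young-vs-old comparison run separately per sex."""
    out = {}
    for sex in ("male", "female"):
        young = [s for s in scans if s.sex == sex and s.age_group == "younger"]
        old = [s for s in scans if s.sex == sex and s.age_group == "older"]
        if len(young) < 2 or len(old) < 2:
            log.warning("sex=%s lacks enough young/old subjects; skipped", sex)
            continue
        out[sex] = cross_sectional_compare(young, old, partition)
    return out


# ---------------------------------------------------------------------------
# Phenotype correlations


@dataclass(frozen=True)
class PhenotypeCorrelation:
    phenotype: str
    r: float
    p: float
    n: int
    degenerate: bool = False


def phenotype_correlation(
    cohort: Sequence[ScanPair],
    block: BlockKey,
    partition: NetworkPartition,
    phenotype: str,
) -> PhenotypeCorrelation:
    """Pearson correlation between per-subject block change and a phenotype.

    Subjects with a missing phenotype (or block) value are pairwise-deleted;
    the effective n is reported.  A constant phenotype leaves r undefined and
    is flagged.
    """
    tab = subject_block_table(cohort, partition)
    change = tab.change[:, tab.column(block)]
    pheno = np.array(
        [float(p.phenotypes.get(phenotype, np.nan)) for p in cohort]
    )
    ok = np.isfinite(change) & np.isfinite(pheno)
    n = int(ok.sum())
    if n < 3:
        raise DataError(
            f"phenotype {phenotype!r} present for only {n} subjects (need >= 3)"
        )
    x, y = change[ok], pheno[ok]
    if np.std(y) == 0.0 or np.std(x) == 0.0:
        log.warning("constant phenotype or change; correlation undefined")
        return PhenotypeCorrelation(phenotype, float("nan"), float("nan"),
                                    n, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return PhenotypeCorrelation(phenotype, float(r), float(p), n)
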