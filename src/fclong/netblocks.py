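"""Network-block reduction of edge-level FC and longitudinal change maps.

An FC "block" is the set of edges whose endpoints fall in a given pair of
functional networks; its unweighted mean is one inter-network connectivity.
With 14 networks there are 105 blocks (within-network blocks included).
This module reduces edge-level FC vectors to block averages, computes
per-subject longitudinal block changes (older scan minus younger scan), and
aggregates them into cohort-level summaries: per-block mean change, two
dispersion variants, one-sample t statistics with Bonferroni correction, and
full edge-level mean/std change maps.

The two dispersion variants are deliberately distinct:

``sigma_subject``
    std across subjects of the per-subject *block-average* change — the
    dispersion the one-sample t-test uses;
``sigma_edge``
    mean over the block's edges of the per-edge change std across subjects —
    the edge-map summary (0.26 for the headline somatomotor-visual block in
    the cohort this package is calibrated to).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .atlas import BlockKey, NetworkPartition, block_pairs
from .errors import DataError
from .fc import FCMatrix, FCVector, vectorize_fc

log = logging.getLogger(__name__)

AGE_YOUNGER_MAX = 55.0   # "younger" subgroup: age < 55
AGE_OLDER_MIN = 65.0     # "older" subgroup: age > 65


def age_group_of(age: float | None) -> str | None:
    if age is None or not np.isfinite(age):
        return None
    if age < AGE_YOUNGER_MAX:
        return "younger"
    if age > AGE_OLDER_MIN:
        return "older"
    return "middle"


@dataclass
class ScanPair:
    """One subject's two longitudinal scans as FC upper-triangle vectors.

    ``younger`` is the chronologically earlier scan; the acquisition order is
    known by construction.
    """

    subject_id: str
    younger: np.ndarray
    older: np.ndarray
    n_rois: int
    sex: str | None = None
    age: float | None = None
    age_group: str | None = None
    phenotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.younger = np.asarray(self.younger, dtype=float)
        self.older = np.asarray(self.older, dtype=float)
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.younger.shape != (expected,) or self.older.shape != (expected,):
            raise DataError(
                f"scan vectors for subject {self.subject_id} must have length "
                f"{expected} (N(N-1)/2 for N={self.n_rois})"
            )
        if self.age_group is None:
            self.age_group = age_group_of(self.age)


@dataclass
class SingleScan:
    """A single (cross-sectional) scan with covariates."""

    subject_id: str
    fc: np.ndarray
    n_rois: int
    sex: str | None = None
    age: float | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.fc.shape != (expected,):
            raise DataError(f"scan vector must have length {expected}")
        if self.age_group is None:
            self.age_group = age_group_of(self.age)


def edge_block_index(
    partition: NetworkPartition,
) -> tuple[list[BlockKey], np.ndarray, np.ndarray]:
    """Map every upper-triangle edge to its block.

    Returns ``(keys, edge_key, counts)`` where ``keys`` is the canonical
    block-key list, ``edge_key[e]`` indexes into it for edge ``e`` of the
    row-major strict upper triangle, and ``counts`` are edges per block.
    """
    keys = block_pairs(partition)
    pos = {k: i for i, k in enumerate(keys)}
    labels = partition.roi_labels()
    n = partition.n_rois
    iu, ju = np.triu_indices(n, k=1)
    la, lb = labels[iu], labels[ju]
    lo, hi = np.minimum(la, lb), np.maximum(la, lb)
    edge_key = np.array([pos[(int(a), int(b))] for a, b in zip(lo, hi)], dtype=int)
    counts = np.bincount(edge_key, minlength=len(keys))
    return keys, edge_key, counts


def _as_vector(fc, partition: NetworkPartition) -> np.ndarray:
    if isinstance(fc, FCMatrix) or (
        isinstance(fc, np.ndarray) and fc.ndim == 2
    ):
        return vectorize_fc(fc).values
    if isinstance(fc, FCVector):
        return fc.values
    return np.asarray(fc, dtype=float)


def block_average(fc, partition: NetworkPartition) -> dict[BlockKey, float]:
    """Unweighted mean FC over each block's edge set.

    Accepts an :class:`FCMatrix`, an :class:`FCVector`, or a bare vector.
    Each undirected edge is counted once (strict upper triangle).  A block
    whose edges are all missing maps to NaN and is logged.
    """
    vec = _as_vector(fc, partition)
    keys, edge_key, _ = edge_block_index(partition)
    finite = np.isfinite(vec)
    sums = np.bincount(edge_key, weights=np.where(finite, vec, 0.0),
                       minlength=len(keys))
    valid_counts = np.bincount(edge_key, weights=finite.astype(float),
                               minlength=len(keys))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / valid_counts
    out = {}
    for i, key in enumerate(keys):
        if valid_counts[i] == 0:
            log.warning("block %s has no valid edges; flagged missing", key)
            out[key] = float("nan")
        else:
            out[key] = float(means[i])
    return out


def block_matrix(block_means: dict[BlockKey, float],
                 partition: NetworkPartition) -> pd.DataFrame:
    """K x K symmetric DataFrame of block means, indexed by network label."""
    labels = partition.labels
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for (a, b), v in block_means.items():
        out.loc[a, b] = v
        out.loc[b, a] = v
    return out


def subject_block_change(
    pair: ScanPair, key: BlockKey, partition: NetworkPartition
) -> float:
    """Block-average difference older - younger for one subject and block."""
    older = block_average(pair.older, partition)[key]
    younger = block_average(pair.younger, partition)[key]
    return older - younger


def total_fc(vec: np.ndarray) -> float:
    """Unweighted mean of the full FC vector ("Total FC")."""
    return float(np.nanmean(np.asarray(vec, dtype=float)))


def subject_block_table(
    cohort: Sequence[ScanPair], partition: NetworkPartition
) -> "SubjectBlockTable":
    """Per-subject block averages for both scans, computed in one pass.

    A subject with any missing (NaN) edge in a block gets NaN for that block
    in the corresponding scan; exclusion counts are logged per block.
    """
    if not cohort:
        raise DataError("empty cohort")
    keys, edge_key, counts = edge_block_index(partition)
    n_sub, n_blk = len(cohort), len(keys)
    younger = np.empty((n_sub, n_blk))
    older = np.empty((n_sub, n_blk))
    for s, pair in enumerate(cohort):
        for arr, vec in ((younger, pair.younger), (older, pair.older)):
            bad = np.bincount(edge_key, weights=(~np.isfinite(vec)).astype(float),
                              minlength=n_blk) > 0
            sums = np.bincount(edge_key, weights=np.nan_to_num(vec),
                               minlength=n_blk)
            with np.errstate(invalid="ignore"):
                row = sums / counts
            row[bad] = np.nan
            arr[s] = row
    n_excluded = np.isnan(younger).sum(axis=0) + np.isnan(older).sum(axis=0)
    for i, key in enumerate(keys):
        if n_excluded[i]:
            log.info("block %s: %d subject-scans excluded (missing edges)",
                     key, int(n_excluded[i]))
    return SubjectBlockTable(keys=keys, younger=younger, older=older,
                             subjects=[p.subject_id for p in cohort])


@dataclass
class SubjectBlockTable:
    keys: list[BlockKey]
    younger: np.ndarray  # (n_subjects, n_blocks)
    older: np.ndarray
    subjects: list[str]

    @property
    def change(self) -> np.ndarray:
        return self.older - self.younger

    def column(self, key: BlockKey) -> int:
        return self.keys.index(key)


@dataclass
class BlockChangeSummary:
    """Cohort-level longitudinal change statistics.

    ``table`` has one row per block key ("a-b"), with the block mean change,
    both dispersion variants, t statistic, raw and Bonferroni-corrected
    p-values, scan means and three percent-change definitions.  ``edge_mean``
    and ``edge_std`` are the full N x N change maps (mean and std across
    subjects of the per-edge difference older - younger).
    """

    table: pd.DataFrame
    edge_mean: np.ndarray
    edge_std: np.ndarray
    n_subjects: int
    m_comparisons: int


def cohort_change_summary(
    cohort: Sequence[ScanPair],
    partition: NetworkPartition,
    m_comparisons: int | None = None,
) -> BlockChangeSummary:
    """Per-block longitudinal change statistics plus edge-level change maps.

    The t-test is a two-sided one-sample test of the per-subject block-average
    changes against zero; p-values are Bonferroni-corrected by the number of
    blocks actually tested (105 for the full atlas) unless ``m_comparisons``
    overrides it.
    """
    from .stats import block_ttest  # local import to avoid a cycle

    if len(cohort) < 2:
        raise DataError("cohort change summary needs at least 2 subjects")
    keys, edge_key, counts = edge_block_index(partition)
    m = m_comparisons if m_comparisons is not None else len(keys)
    tab = subject_block_table(cohort, partition)

    # streaming edge-level moments of the per-edge change
    n_edges = len(edge_key)
    s1 = np.zeros(n_edges)
    s2 = np.zeros(n_edges)
    n_ok = np.zeros(n_edges)
    for pair in cohort:
        d = pair.older - pair.younger
        ok = np.isfinite(d)
        d0 = np.where(ok, d, 0.0)
        s1 += d0
        s2 += d0 * d0
        n_ok += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        edge_mu = s1 / n_ok
        edge_var = (s2 - n_ok * edge_mu**2) / (n_ok - 1)
    edge_var = np.clip(edge_var, 0.0, None)
    edge_sd = np.sqrt(edge_var)

    rows = []
    for i, key in enumerate(keys):
        changes = tab.change[:, i]
        changes = changes[np.isfinite(changes)]
        n = changes.size
        mu = float(np.mean(changes)) if n else float("nan")
        sigma_subject = float(np.std(changes, ddof=1)) if n > 1 else float("nan")
        in_block = edge_key == i
        sigma_edge = float(np.nanmean(edge_sd[in_block]))
        if n > 1:
            tt = block_ttest(changes, m_comparisons=m)
            t, p_raw, p_bonf = tt.t, tt.p_raw, tt.p_bonf
        else:
            t = p_raw = p_bonf = float("nan")
        y = tab.younger[:, i]
        o = tab.older[:, i]
        both = np.isfinite(y) & np.isfinite(o)
        mean_y = float(np.mean(y[both])) if both.any() else float("nan")
        mean_o = float(np.mean(o[both])) if both.any() else float("nan")
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_subject = float(np.nanmean(
                100.0 * (o[both] - y[both]) / np.abs(y[both])
            )) if both.any() else float("nan")
        rows.append({
            "block": f"{key[0]}-{key[1]}",
            "networks": partition.block_name(key),
            "n": n,
            "n_edges": int(counts[i]),
            "mu": mu,
            "sigma_subject": sigma_subject,
            "sigma_edge": sigma_edge,
            "t": t,
            "p_raw": p_raw,
            "p_bonf": p_bonf,
            "mean_younger": mean_y,
            "mean_older": mean_o,
            "pct_of_younger": 100.0 * mu / abs(mean_y) if mean_y else float("nan"),
            "pct_of_older": 100.0 * mu / abs(mean_o) if mean_o else float("nan"),
            "pct_subject_mean": pct_subject,
        })
    table = pd.DataFrame(rows).set_index("block")

    n_rois = partition.n_rois
    mean_map = np.full((n_rois, n_rois), np.nan)
    std_map = np.full((n_rois, n_rois), np.nan)
    iu = np.triu_indices(n_rois, k=1)
    mean_map[iu] = edge_mu
    mean_map[(iu[1], iu[0])] = edge_mu
    std_map[iu] = edge_sd
    std_map[(iu[1], iu[0])] = edge_sd
    np.fill_diagonal(mean_map, 0.0)
    np.fill_diagonal(std_map, 0.0)

    return BlockChangeSummary(table=table, edge_mean=mean_map, edge_std=std_map,
                              n_subjects=len(cohort), m_comparisons=m)


def subgroup_summaries(
    cohort: Sequence[ScanPair],
    partition: NetworkPartition,
    by: Literal["sex", "age_group"] = "sex",
    m_comparisons: int | None = None,
) -> dict[str, BlockChangeSummary]:
    """Change summaries restricted to each subgroup of ``sex`` or ``age_group``.

    Subgroups with fewer than 2 subjects are skipped with a warning.  Note the
    age grouping leaves 55-65 year-olds in neither subgroup, mirroring the
    younger (<55) / older (>65) contrast; they still count in whole-cohort
    statistics.
    """
    groups: dict[str, list[ScanPair]] = {}
    for pair in cohort:
        label = getattr(pair, by)
        if label is None or (by == "age_group" and label == "middle"):
            continue
        groups.setdefault(str(label), []).append(pair)
    out = {}
    for label, members in sorted(groups.items()):
        if len(members) < 2:
            log.warning("subgroup %s=%s has %d subject(s); skipped",
                        by, label, len(members))
            continue
        out[label] = cohort_change_summary(members, partition, m_comparisons)
    return out
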