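"""Scan-order prediction from signed FC differences.

Whether the chronologically later of a subject's two scans can be identified
from their FC difference is a direct measure of systematic longitudinal
change.  Each subject contributes one sample: with a random sign s = +-1,
the feature is s * (older FC - younger FC) and the label is s.  An
L2-regularized logistic regression (inverse regularization strength fixed at
C = 1) is trained on random subsets and evaluated on the held-out remainder,
repeated 20 times per training size to form a learning curve.  Features are
either the full upper-triangle FC difference or a single network-block
average difference; ranking all 105 blocks by their single-feature accuracy
identifies which inter-network connection carries the most order information.

For a single sign-symmetric Gaussian feature with mean shift mu and
dispersion sigma, the Bayes-optimal accuracy is Phi(|mu|/sigma); the
logistic model converges to this, which the test-suite uses as an oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .atlas import BlockKey, NetworkPartition
from .errors import ConfigError, DataError
from .netblocks import ScanPair, subject_block_table
from .stats import block_ttest

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Logistic-model and resampling settings for scan-order prediction.

    ``with_replacement`` switches the 20 "bootstrap" repetitions from
    repeated disjoint train/test partitions (the default: the test set is
    everything not drawn for training) to classical resampling with
    replacement with out-of-bag evaluation.
    """

    C: float = 1.0
    n_repetitions: int = 20
    train_sizes: tuple[int, ...] = (2000,)
    seed: int = 0
    with_replacement: bool = False
    max_iter: int = 10_000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ConfigError("C must be positive")
        if self.n_repetitions < 1:
            raise ConfigError("need at least one repetition")
        if not self.train_sizes or any(t < 1 for t in self.train_sizes):
            raise ConfigError("training sizes must be positive")


@dataclass
class DiffSamples:
    """Signed FC-difference features with their sign labels (+1: older minus
    younger; -1: younger minus older)."""

    X: np.ndarray            # (n_samples, n_features)
    y: np.ndarray            # (n_samples,) in {+1, -1}
    subjects: list[str]
    feature: str

    def __post_init__(self) -> None:
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if self.X.shape[0] != self.y.shape[0]:
            raise DataError("X and y must have equal sample counts")


@dataclass
class LearningCurve:
    """Mean held-out accuracy per training size, with per-repetition detail."""

    summary: pd.DataFrame       # index train_size: accuracy_mean, accuracy_sd, n_test
    repetitions: pd.DataFrame   # rows (train_size, repetition, accuracy, n_test)

    def accuracy(self, train_size: int) -> float:
        return float(self.summary.loc[train_size, "accuracy_mean"])


def make_diff_samples(
    cohort: Sequence[ScanPair],
    feature: str | BlockKey = "full",
    partition: NetworkPartition | None = None,
    seed: int = 0,
) -> DiffSamples:
    """One signed difference sample per subject.

    ``feature="full"`` uses the whole upper-triangle FC difference; a block
    key uses that block's average difference as a single feature.  Signs are
    drawn +-1 with equal probability from a generator seeded by ``seed``, so
    the class balance is binomial around one half and the representation is
    symmetric: negating a sample's feature and label gives an equivalent
    sample.
    """
    if not cohort:
        raise DataError("empty cohort")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=len(cohort)) * 2 - 1
    if feature == "full":
        diffs = np.stack([p.older - p.younger for p in cohort])
        name = "full"
    else:
        if partition is None:
            raise ConfigError("block features require a partition")
        tab = subject_block_table(cohort, partition)
        diffs = tab.change[:, [tab.column(tuple(feature))]]
        name = f"{feature[0]}-{feature[1]}"
    X = signs[:, None] * diffs
    return DiffSamples(X=X, y=signs.astype(int),
                       subjects=[p.subject_id for p in cohort], feature=name)


def _fit(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig) -> LogisticRegression:
    # L2 penalty is the LogisticRegression default; C is the inverse strength
    model = LogisticRegression(C=cfg.C, solver="lbfgs",
                               max_iter=cfg.max_iter, tol=cfg.tol)
    model.fit(X, y)
    return model


def _split(
    rng: np.random.Generator, n: int, n_train: int, with_replacement: bool
) -> tuple[np.ndarray, np.ndarray]:
    if with_replacement:
        train = rng.integers(0, n, size=n_train)
        test = np.setdiff1d(np.arange(n), np.unique(train))
    else:
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
    return train, test


def learning_curve(samples: DiffSamples, cfg: ClassifierConfig) -> LearningCurve:
    """Held-out accuracy of the logistic model at each training size.

    Each repetition draws a fresh seeded train/test split; a draw whose
    training labels are single-class is redrawn (logged), since the model is
    undefined there.
    """
    n = samples.X.shape[0]
    if max(cfg.train_sizes) + 1 > n:
        raise ConfigError(
            f"largest training size {max(cfg.train_sizes)} leaves no test "
            f"samples out of {n}"
        )
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for n_train in cfg.train_sizes:
        for rep in range(cfg.n_repetitions):
            for attempt in range(100):
                train, test = _split(rng, n, n_train, cfg.with_replacement)
                if np.unique(samples.y[train]).size == 2 and test.size:
                    break
                log.info("single-class training draw redrawn "
                         "(size %d, repetition %d)", n_train, rep)
            else:
                raise DataError("could not draw a two-class training set")
            model = _fit(samples.X[train], samples.y[train], cfg)
            acc = float(np.mean(model.predict(samples.X[test]) == samples.y[test]))
            rows.append({"train_size": n_train, "repetition": rep,
                         "accuracy": acc, "n_test": int(test.size)})
    reps = pd.DataFrame(rows)
    summary = reps.groupby("train_size").agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        n_test=("n_test", "mean"),
    )
    return LearningCurve(summary=summary, repetitions=reps)


def rank_blocks(
    cohort: Sequence[ScanPair],
    partition: NetworkPartition,
    cfg: ClassifierConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank all network blocks by single-feature scan-order accuracy.

    For each block, the per-subject block-average difference (with the same
    per-subject random signs across blocks) is the lone feature of a logistic
    model evaluated at the largest configured training size.  Each block's
    accuracy is paired with the Bonferroni-corrected two-sided one-sample
    t-test p-value of its (unsigned) change.  Rows are sorted by descending
    accuracy, ties broken by block-key order; ``rank`` is 1-based.
    """
    if partition.n_networks < 2:
        raise DataError("block ranking needs at least 2 networks")
    tab = subject_block_table(cohort, partition)
    n_train = max(cfg.train_sizes)
    sub_cfg = ClassifierConfig(
        C=cfg.C, n_repetitions=cfg.n_repetitions, train_sizes=(n_train,),
        seed=cfg.seed, with_replacement=cfg.with_replacement,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    sign_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(sign_seed)
    signs = rng.integers(0, 2, size=len(cohort)) * 2 - 1

    rows = []
    for i, key in enumerate(tab.keys):
        change = tab.change[:, i]
        ok = np.isfinite(change)
        if ok.sum() < 2:
            log.warning("block %s has <2 valid subjects; excluded from ranking",
                        key)
            continue
        samples = DiffSamples(
            X=(signs[ok] * change[ok])[:, None],
            y=signs[ok].astype(int),
            subjects=[s for s, keep in zip(tab.subjects, ok) if keep],
            feature=f"{key[0]}-{key[1]}",
        )
        curve = learning_curve(samples, sub_cfg)
        tt = block_ttest(change[ok], m_comparisons=len(tab.keys))
        rows.append({
            "block": f"{key[0]}-{key[1]}",
            "networks": partition.block_name(key),
            "accuracy": curve.accuracy(n_train),
            "t": tt.t,
            "p_bonf": tt.p_bonf,
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["accuracy", "block"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("block")
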