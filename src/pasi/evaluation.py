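"""Group testing and the mock-randomization evaluation framework.

Pathway (or gene) values are compared between case and control samples with
a two-sided Wilcoxon rank-sum test per row; p-values are converted to FDR
with Benjamini-Hochberg and averaged over rows (mean FDR).  The headline
statistic is the FDR ratio

    FDR_ratio = -log2( meanFDR(real) / mean_i meanFDR(mock_i) )

where each mock dataset pools the real case and control samples and splits
them at random into two equally sized artificial groups with no expected
biological difference.  Positive ratios mean the method separates the real
group structure from random relabelling noise.

Two further experiments probe practical robustness: a sample-size curve
(mean FDR as one group is subsampled) and a structural-uncertainty
experiment (detection rate of a target pathway after random removal of
nodes or relations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .expression import CASE, CONTROL, ExpressionMatrix, ScaledMatrix, preprocess
from .kgml import Pathway, remove_random
from .scoring import (
    MIN_NODES_DEFAULT,
    PathwayScorer,
    PathwayScores,
    rank_pathways,
)

logger = logging.getLogger(__name__)

DEFAULT_N_MOCK = 10
DEFAULT_FRACTIONS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_TOP_K = 25

#: largest per-group size for which the exact rank-sum distribution is used
EXACT_MAX_GROUP = 25


def _coerce(scores, labels):
    if isinstance(scores, PathwayScores):
        return scores.values, scores.labels
    if labels is None:
        raise InputError("labels are required when passing a bare matrix")
    return scores, labels


def wilcoxon_groups(scores, labels=None) -> pd.Series:
    """Two-sided two-sample rank-sum p-value for each row.

    The exact null distribution is used when both groups have at most
    25 samples and the row has no ties; otherwise the tie-corrected normal
    approximation.  Rows that are entirely constant carry no evidence and
    get p = 1.
    """
    values, labels = _coerce(scores, labels)
    case_cols = [s for s in values.columns if labels.get(s) == CASE]
    ctrl_cols = [s for s in values.columns if labels.get(s) == CONTROL]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InputError(
            f"need >=2 samples per group, got {len(case_cols)} case / {len(ctrl_cols)} control"
        )
    x = values[case_cols].to_numpy(dtype=float)
    y = values[ctrl_cols].to_numpy(dtype=float)
    n = x.shape[1] + y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    p = np.ones(len(values))
    constant = np.ptp(combined, axis=1) == 0
    has_ties = np.array(
        [np.unique(row).size < n for row in combined], dtype=bool
    )
    small = x.shape[1] <= EXACT_MAX_GROUP and y.shape[1] <= EXACT_MAX_GROUP

    exact_rows = (~has_ties) & small
    if exact_rows.any():
        res = stats.mannwhitneyu(
            x[exact_rows], y[exact_rows], axis=1, alternative="two-sided", method="exact"
        )
        p[exact_rows] = res.pvalue
    approx_rows = ~exact_rows & ~constant
    if approx_rows.any():
        res = stats.mannwhitneyu(
            x[approx_rows],
            y[approx_rows],
            axis=1,
            alternative="two-sided",
            method="asymptotic",
        )
        p[approx_rows] = res.pvalue
    return pd.Series(np.clip(p, 0.0, 1.0), index=values.index, name="p_value")


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted values (each <= 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        raise InputError("empty p-value vector")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise InputError("p-values must lie in (0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adjusted, index=p_values.index, name="fdr")
    return adjusted


def mean_fdr(scores, labels=None) -> float:
    """Mean BH-FDR over rows of case-vs-control rank-sum tests."""
    values, labels = _coerce(scores, labels)
    return float(bh_fdr(wilcoxon_groups(values, labels)).mean())


@dataclass
class GroupComparison:
    """Per-row p-values and FDRs plus their average."""

    table: pd.DataFrame  # columns: p_value, fdr
    mean_fdr: float


def group_comparison(scores, labels=None) -> GroupComparison:
    values, labels = _coerce(scores, labels)
    p = wilcoxon_groups(values, labels)
    fdr = bh_fdr(p)
    return GroupComparison(pd.DataFrame({"p_value": p, "fdr": fdr}), float(fdr.mean()))


@dataclass
class MockSplit:
    """Artificial relabelling of the pooled samples into two groups."""

    labels: pd.Series
    seed: object

    def __post_init__(self) -> None:
        n = len(self.labels)
        n_ctrl = int((self.labels == CONTROL).sum())
        if abs(2 * n_ctrl - n) > 1:
            raise InputError("mock groups must be equally sized (within one)")


def make_mock(labels: pd.Series, seed) -> MockSplit:
    """Pool all samples and split them uniformly at random into two groups.

    The first artificial group (size ``ceil(n/2)``) takes the control
    (reference) role; with an odd pooled count the groups differ by one.
    """
    n = len(labels)
    if n < 4:
        raise InputError(f"need at least 4 pooled samples, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(np.asarray(labels.index, dtype=object))
    n_ctrl = math.ceil(n / 2)
    mock = pd.Series(CASE, index=labels.index, dtype=object)
    mock.loc[perm[:n_ctrl]] = CONTROL
    return MockSplit(mock, seed)


def fdr_ratio(fdr_real: float, fdr_mock_list) -> float:
    """-log2 of real mean FDR over the average mock mean FDR."""
    mocks = np.asarray(fdr_mock_list, dtype=float)
    if fdr_real <= 0 or np.any(mocks <= 0):
        raise InputError("mean FDR values must be positive")
    return float(-np.log2(fdr_real / mocks.mean()))


@dataclass
class FdrRatioResult:
    """Real mean FDR, the per-mock mean FDRs, and the log2-ratio statistic."""

    fdr_real: float
    fdr_mock: list
    ratio: float
    real_table: pd.DataFrame | None = None


def run_fdr_ratio_experiment(
    score_fn, labels: pd.Series, n_mock: int = DEFAULT_N_MOCK, seed: int = 0
) -> FdrRatioResult:
    """Score under real labels and under ``n_mock`` seeded mock relabellings.

    ``score_fn(labels) -> DataFrame | PathwayScores`` is the pluggable
    scoring arm: pathway scoring (whose control reference follows the active
    labels) or the gene-level arm (label-free values).  Mock split ``i`` uses
    the derived seed ``[seed, i]``.
    """
    real = group_comparison(*_coerce(score_fn(labels), labels))
    mock_fdrs = []
    for i in range(int(n_mock)):
        split = make_mock(labels, np.random.default_rng([int(seed), i]))
        mock_scores = score_fn(split.labels)
        mock_fdrs.append(mean_fdr(*_coerce(mock_scores, split.labels)))
    return FdrRatioResult(
        real.mean_fdr, mock_fdrs, fdr_ratio(real.mean_fdr, mock_fdrs), real.table
    )


def pasi_score_fn(scaled: ScaledMatrix, pathways, min_nodes: int = MIN_NODES_DEFAULT):
    """Closure scoring the compiled pathway collection under arbitrary labels."""
    scorer = PathwayScorer(pathways, scaled.values.index, min_nodes=min_nodes)

    def score_fn(labels: pd.Series):
        return scorer.score(scaled.values, labels).values

    return score_fn


def gene_level_arm(scaled: ScaledMatrix, labels: pd.Series | None = None) -> GroupComparison:
    """The pathway-free comparison arm: identical Wilcoxon + BH machinery
    applied directly to per-gene scaled values."""
    if labels is None:
        labels = scaled.labels
    return group_comparison(scaled.values, labels)


def sample_size_experiment(
    data: ExpressionMatrix,
    pathways,
    sizes=tuple(range(5, 31)),
    which: str = CASE,
    n_reps: int = 10,
    seed: int = 0,
    noise_q: float = 0.05,
    min_nodes: int = MIN_NODES_DEFAULT,
) -> pd.DataFrame:
    """Mean FDR as a function of the size of one sample group.

    Real arm: the ``which`` group is subsampled to each size (the other
    group intact), the subset is re-preprocessed and scored, and the mean
    FDR recorded; ``n_reps`` random subsets per size.  Mock arm: the control
    pool is split into two artificial groups (one held at half the pool),
    and the artificial ``which`` group is subsampled the same way, so the
    curve has a matched no-difference reference.
    """
    if which not in (CASE, CONTROL):
        raise InputError(f"which must be 'case' or 'control', got {which!r}")
    sizes = [int(s) for s in sizes]
    varied = data.case_samples if which == CASE else data.control_samples
    fixed = data.control_samples if which == CASE else data.case_samples
    if max(sizes) > len(varied):
        raise InputError(
            f"requested size {max(sizes)} exceeds the {len(varied)} available {which} samples"
        )
    pool = data.control_samples
    n_half = len(pool) // 2
    if max(sizes) > len(pool) - n_half:
        raise InputError(
            f"requested size {max(sizes)} exceeds the mock pool ({len(pool) - n_half} free controls)"
        )

    # the gene index is the same for every subset, so compile once
    scorer = PathwayScorer(pathways, data.values.index, min_nodes=min_nodes)

    def run_subset(columns: list, labels: pd.Series) -> float:
        sub = ExpressionMatrix(data.values[columns], labels)
        scaled = preprocess(sub, q=noise_q)
        return mean_fdr(scorer.score(scaled.values, labels).values, labels)

    records = []
    for si, size in enumerate(sizes):
        for arm in ("real", "mock"):
            fdrs = []
            for rep in range(int(n_reps)):
                rng = np.random.default_rng([int(seed), si, rep, 0 if arm == "real" else 1])
                if arm == "real":
                    chosen = list(rng.choice(varied, size=size, replace=False))
                    columns = chosen + fixed
                    labels = data.labels.loc[columns]
                else:
                    perm = list(rng.permutation(pool))
                    other, rest = perm[:n_half], perm[n_half:]
                    chosen = rest[:size]
                    columns = list(other) + list(chosen)
                    group_of_other = CONTROL if which == CASE else CASE
                    labels = pd.Series(
                        [group_of_other] * len(other) + [which] * len(chosen),
                        index=columns,
                        dtype=object,
                    )
                fdrs.append(run_subset(columns, labels))
            records.append(
                {"size": size, "arm": arm, "which": which, "mean_fdr": float(np.mean(fdrs))}
            )
    return pd.DataFrame.from_records(records)


def uncertainty_experiment(
    scaled: ScaledMatrix,
    pathways,
    target_pathway_id: str,
    fractions=DEFAULT_FRACTIONS,
    what: str = "nodes",
    n_reps: int = 100,
    top_k: int = DEFAULT_TOP_K,
    seed: int = 0,
    min_nodes: int = MIN_NODES_DEFAULT,
) -> pd.DataFrame:
    """Detection rate of a target pathway under random structural loss.

    For each removal fraction, ``n_reps`` seeded degraded copies of the
    target pathway are scored against the (unchanged) rest of the
    collection, the whole collection is re-ranked by case-control median
    score difference, and the rate of replicates in which the target stays
    within the top ``top_k`` is reported.  Only the target's score depends
    on its own structure, so the other pathways' scores are computed once.
    """
    target = next((p for p in pathways if p.pathway_id == target_pathway_id), None)
    if target is None:
        raise InputError(f"target pathway {target_pathway_id!r} not in collection")
    scorer = PathwayScorer(pathways, scaled.values.index, min_nodes=min_nodes)
    if target_pathway_id not in scorer.pathway_ids:
        raise InputError(f"target pathway {target_pathway_id!r} is not scorable")
    base = scorer.score(scaled.values, scaled.labels)

    records = []
    for fi, fraction in enumerate(fractions):
        detected = 0
        for rep in range(int(n_reps)):
            rng = np.random.default_rng([int(seed), fi, rep])
            degraded = remove_random(target, float(fraction), what, rng)
            mini = PathwayScorer([degraded], scaled.values.index, min_nodes=min_nodes)
            if not mini.pathway_ids:
                continue  # degraded below min_nodes: counted as undetected
            row = mini.score(scaled.values, scaled.labels)
            values = base.values.copy()
            values.loc[target_pathway_id] = row.values.iloc[0]
            ranking = rank_pathways(PathwayScores(values, base.labels, base.names))
            rank = int(
                ranking.loc[ranking["pathway_id"] == target_pathway_id, "rank"].iloc[0]
            )
            if rank <= int(top_k):
                detected += 1
        records.append(
            {
                "fraction": float(fraction),
                "what": what,
                "detection_rate": detected / int(n_reps),
            }
        )
    return pd.DataFrame.from_records(records)
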