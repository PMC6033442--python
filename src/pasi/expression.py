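"""Expression preprocessing: load, map to Entrez, noise-filter and scale.

This is the first stage of the scoring workflow.  Expression values are kept
on linear (non-log) scale throughout; already-logged data are exponentiated
on load.  Probe rows are mapped to Entrez gene IDs and collapsed by
arithmetic mean, values beneath a global detection threshold are floored
(noise filtering), and each gene is min-max scaled to [0, 1] across all
samples so that genes with very different dynamic ranges become comparable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
LABELS = (CASE, CONTROL)

#: below this many control samples a warning is emitted: the control-median
#: reference used downstream becomes unstable for small control groups.
RECOMMENDED_MIN_CONTROLS = 15

DEFAULT_NOISE_QUANTILE = 0.05


def _validate_labels(values: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise InputError(f"samples without a case/control label: {missing[:5]}")
    bad = set(labels.unique()) - set(LABELS)
    if bad:
        raise InputError(f"labels must be one of {LABELS}, got {sorted(bad)}")
    n_case = int((labels == CASE).sum())
    n_control = int((labels == CONTROL).sum())
    if n_case < 2 or n_control < 2:
        raise InputError(
            f"need at least 2 samples per group, got {n_case} case / {n_control} control"
        )
    return labels


def _validate_matrix(values: pd.DataFrame) -> None:
    if values.index.duplicated().any():
        raise InputError("duplicated gene identifiers in expression matrix")
    if values.columns.duplicated().any():
        raise InputError("duplicated sample identifiers in expression matrix")
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        raise InputError("expression values must be finite")
    if (arr < 0).any():
        raise InputError("expression values must be non-negative (linear scale)")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative linear-scale expression values.

    ``values`` is indexed by integer Entrez gene IDs with sample IDs as
    columns; ``labels`` assigns each sample to ``"case"`` or ``"control"``.
    ``noise_threshold`` records the detection floor once :func:`filter_noise`
    has been applied.
    """

    values: pd.DataFrame
    labels: pd.Series
    noise_threshold: float | None = None

    def __post_init__(self) -> None:
        _validate_matrix(self.values)
        self.labels = _validate_labels(self.values, self.labels)

    @property
    def gene_ids(self) -> list[int]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])


@dataclass
class ScaledMatrix:
    """Per-gene min-max scaled matrix; every value lies in [0, 1]."""

    values: pd.DataFrame
    labels: pd.Series
    noise_threshold: float | None = None

    def __post_init__(self) -> None:
        _validate_matrix(self.values)
        arr = self.values.to_numpy()
        if arr.size and arr.max() > 1.0 + 1e-12:
            raise InputError("scaled values must lie in [0, 1]")
        self.labels = _validate_labels(self.values, self.labels)

    @property
    def gene_ids(self) -> list[int]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneMapping:
    """Many-to-one mapping from probe / platform gene IDs to Entrez IDs."""

    pairs: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, source_id: str) -> bool:
        return source_id in self.pairs

    def __getitem__(self, source_id: str) -> int:
        return self.pairs[source_id]

    @classmethod
    def identity(cls, entrez_ids) -> "GeneMapping":
        """Trivial mapping str(entrez) -> entrez, used for pre-mapped matrices."""
        return cls({str(int(e)): int(e) for e in entrez_ids})

    @classmethod
    def read(cls, path) -> "GeneMapping":
        """Read a two-column tab-separated (source_id, entrez) table.

        A header row is detected automatically: if the second field of the
        first row does not parse as an integer it is treated as a header.
        A source ID mapping to two different Entrez IDs is an error.
        """
        try:
            table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise InputError(f"cannot parse mapping table {path}: {exc}") from exc
        if table.shape[1] < 2:
            raise InputError("mapping table must have two columns (source_id, entrez)")
        first = str(table.iloc[0, 1])
        try:
            int(first)
        except ValueError:
            table = table.iloc[1:]
        pairs: dict[str, int] = {}
        for source, entrez in zip(table.iloc[:, 0], table.iloc[:, 1]):
            source = str(source)
            try:
                entrez = int(entrez)
            except ValueError as exc:
                raise InputError(f"non-integer Entrez ID {entrez!r} for {source}") from exc
            if source in pairs and pairs[source] != entrez:
                raise InputError(f"source ID {source} maps to multiple Entrez IDs")
            pairs[source] = entrez
        return cls(pairs)


def read_labels(path) -> pd.Series:
    """Read a two-column tab-separated (sample_id, case|control) table."""
    try:
        table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse label table {path}: {exc}") from exc
    if table.shape[1] < 2:
        raise InputError("label table must have two columns (sample_id, label)")
    if str(table.iloc[0, 1]).strip().lower() not in LABELS:
        table = table.iloc[1:]
    labels = pd.Series(
        [str(v).strip().lower() for v in table.iloc[:, 1]],
        index=[str(s) for s in table.iloc[:, 0]],
    )
    return labels


def load_expression(matrix_file, mapping: GeneMapping, label_file, is_log: bool = False) -> ExpressionMatrix:
    """Load an expression matrix, map rows to Entrez IDs and attach labels.

    The matrix file is tab-separated with probe/gene IDs in the first column
    and sample IDs in the header row.  ``is_log`` signals log2-scale input,
    which is exponentiated back to linear scale before anything else.
    Probe rows sharing an Entrez ID are collapsed by arithmetic mean;
    unmapped rows are dropped (count logged).
    """
    try:
        df = pd.read_csv(matrix_file, sep="\t", index_col=0)
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise InputError(f"malformed expression matrix {matrix_file}: {exc}") from exc
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)

    if is_log:
        df = np.power(2.0, df)

    mapped_ids = df.index.map(lambda s: mapping.pairs.get(s))
    keep = mapped_ids.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise InputError("no expression rows map to an Entrez ID")
    if n_dropped:
        logger.info("dropped %d unmapped expression rows", n_dropped)
    df = df.loc[keep]
    df.index = pd.Index([int(mapping.pairs[s]) for s in df.index], name="entrez")
    # collapse probes measuring the same gene by arithmetic mean
    df = df.groupby(level=0, sort=True).mean()

    labels = read_labels(label_file)
    matrix = ExpressionMatrix(df, labels)
    n_control = len(matrix.control_samples)
    if n_control < RECOMMENDED_MIN_CONTROLS:
        warnings.warn(
            f"only {n_control} control samples; at least "
            f"{RECOMMENDED_MIN_CONTROLS} are recommended for a stable reference",
            UserWarning,
            stacklevel=2,
        )
    return matrix


def noise_threshold(values: np.ndarray, q: float) -> float:
    """Nearest-rank q-quantile of all matrix values (the detection floor)."""
    flat = np.sort(values, axis=None)
    k = max(1, math.ceil(q * flat.size))
    return float(flat[k - 1])


def filter_noise(m: ExpressionMatrix, q: float = DEFAULT_NOISE_QUANTILE) -> ExpressionMatrix:
    """Floor all values at the global nearest-rank ``q``-quantile.

    Flooring (rather than dropping rows) keeps the matrix shape stable and
    stops unexpressed genes from contributing spurious deviation downstream.
    The threshold is recorded on the returned matrix.  Idempotent for a
    fixed ``q``.
    """
    if not 0.0 <= q < 1.0:
        raise InputError(f"noise quantile must be in [0, 1), got {q}")
    t = noise_threshold(m.values.to_numpy(), q)
    floored = m.values.clip(lower=t)
    return ExpressionMatrix(floored, m.labels.copy(), noise_threshold=t)


def scale_genes(m: ExpressionMatrix) -> ScaledMatrix:
    """Min-max scale each gene to [0, 1] across all samples.

    Genes with zero range carry no information and map to 0.5 everywhere.
    The noise threshold recorded by :func:`filter_noise` is carried forward.
    """
    arr = m.values.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (arr - lo) / rng
    scaled[np.repeat(rng == 0, arr.shape[1], axis=1)] = 0.5
    out = pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns)
    return ScaledMatrix(out, m.labels.copy(), noise_threshold=m.noise_threshold)


def preprocess(m: ExpressionMatrix, q: float = DEFAULT_NOISE_QUANTILE) -> ScaledMatrix:
    """Noise-filter then scale: the full gene-level preprocessing pipeline."""
    return scale_genes(filter_noise(m, q))
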