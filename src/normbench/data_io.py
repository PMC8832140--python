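"""Reading, validation, alignment and writing of count matrices and results.

The canonical on-disk format is delimited text (TSV by default, CSV accepted):
markers in rows, samples in columns, a header row of sample IDs and a first
column of marker IDs.  Group annotations are two-column tables
``sample_id<TAB>group`` with exactly two group levels.  miRNA panels are small
and dense, so no sparse or binary container is offered.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateDesignError,
    DegenerateLibraryError,
    DomainError,
    IdentifierError,
)

logger = logging.getLogger(__name__)

#: tolerance for accepting "integer-valued" floats in count tables
_INT_TOL = 1e-9


@dataclass(frozen=True)
class CountMatrix:
    """A markers x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    marker_ids : sequence of str
        Row identifiers (e.g. miRNA names); unique, order preserved.
    sample_ids : sequence of str
        Column identifiers; unique, order preserved.
    counts : ndarray of shape (n_markers, n_samples)
        Non-negative integer counts, stored as float64 for downstream math.
    """

    marker_ids: tuple
    sample_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        markers = tuple(str(m) for m in self.marker_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape != (len(markers), len(samples)):
            raise DomainError(
                f"counts shape {counts.shape} does not match "
                f"{len(markers)} markers x {len(samples)} samples"
            )
        if len(set(markers)) != len(markers):
            raise IdentifierError("duplicate marker identifiers")
        if len(set(samples)) != len(samples):
            raise IdentifierError("duplicate sample identifiers")
        if not np.all(np.isfinite(counts)):
            raise DomainError("non-finite count values")
        if np.any(counts < 0):
            raise DomainError("negative count values")
        rounded = np.rint(counts)
        if np.max(np.abs(counts - rounded)) > _INT_TOL:
            raise DomainError("non-integral count values")
        counts = rounded
        lib = counts.sum(axis=0)
        if np.any(lib <= 0):
            bad = [samples[i] for i in np.where(lib <= 0)[0]]
            raise DegenerateLibraryError(f"all-zero library for sample(s): {bad}")
        object.__setattr__(self, "marker_ids", markers)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "counts", counts)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts d_i = sum_g x_gi."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.marker_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    def subset(self, markers=None, samples=None) -> "CountMatrix":
        """Restrict (and reorder) to the given marker/sample IDs."""
        df = self.to_frame()
        if markers is not None:
            df = df.loc[list(markers)]
        if samples is not None:
            df = df[list(samples)]
        return CountMatrix.from_frame(df)


@dataclass(frozen=True)
class GroupAssignment:
    """Two-level factor over samples (e.g. the two tumour subtypes)."""

    sample_ids: tuple
    labels: tuple

    def __post_init__(self):
        samples = tuple(str(s) for s in self.sample_ids)
        labels = tuple(str(v) for v in self.labels)
        if len(samples) != len(labels):
            raise DomainError("sample_ids and labels differ in length")
        if len(set(samples)) != len(samples):
            raise IdentifierError("duplicate sample identifiers in groups")
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise DegenerateDesignError(
                f"expected exactly 2 group levels, found {len(levels)}: {levels}"
            )
        for lev in levels:
            if labels.count(lev) < 2:
                raise DegenerateDesignError(
                    f"group level {lev!r} has fewer than 2 samples"
                )
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "labels", labels)

    @property
    def levels(self) -> tuple:
        return tuple(sorted(set(self.labels)))

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.sample_ids.index(sample_id)]

    def indicator(self, sample_order=None) -> np.ndarray:
        """0/1 indicator of the second (lexicographically later) level."""
        order = self.sample_ids if sample_order is None else tuple(sample_order)
        lab = dict(zip(self.sample_ids, self.labels))
        second = self.levels[1]
        return np.array([1.0 if lab[s] == second else 0.0 for s in order])

    def subset(self, samples) -> "GroupAssignment":
        lab = dict(zip(self.sample_ids, self.labels))
        samples = tuple(str(s) for s in samples)
        return GroupAssignment(samples, tuple(lab[s] for s in samples))


@dataclass(frozen=True)
class PairedStudy:
    """A benchmark matrix, a test matrix and a two-level group assignment.

    Both matrices carry identical marker order and identical sample order;
    the assignment covers every shared sample.
    """

    benchmark: CountMatrix
    test: CountMatrix
    groups: GroupAssignment
    dropped_markers: tuple = field(default_factory=tuple)
    dropped_samples: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.benchmark.marker_ids != self.test.marker_ids:
            raise AlignmentError("benchmark/test marker IDs differ or are misordered")
        if self.benchmark.sample_ids != self.test.sample_ids:
            raise AlignmentError("benchmark/test sample IDs differ or are misordered")
        if set(self.groups.sample_ids) != set(self.benchmark.sample_ids):
            raise AlignmentError("group assignment does not cover the shared samples")


def read_count_matrix(path, delimiter=None) -> CountMatrix:
    """Read a delimited count table (first row samples, first column markers).

    Non-integral values within 1e-9 of an integer are rounded; anything else
    is rejected.  The delimiter defaults to ',' for ``.csv`` files and TAB
    otherwise.
    """
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        raise IdentifierError(f"duplicate sample IDs in header of {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.columns = header
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.has_duplicates:
        raise IdentifierError(f"duplicate marker IDs in {path}")
    if df.columns.has_duplicates:
        raise IdentifierError(f"duplicate sample IDs in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DomainError(f"non-numeric entries in {path}: {exc}") from exc
    return CountMatrix(tuple(df.index), tuple(df.columns), values)


def read_groups(path, delimiter="\t") -> GroupAssignment:
    """Read a two-column ``sample_id<sep>group`` annotation table."""
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if df.shape[1] < 2:
        raise DomainError(f"group table {path} needs two columns")
    return GroupAssignment(tuple(df.iloc[:, 0]), tuple(df.iloc[:, 1]))


def write_count_matrix(cm: CountMatrix, path, delimiter="\t") -> None:
    df = cm.to_frame()
    df.index.name = "marker_id"
    df.to_csv(path, sep=delimiter)


def write_groups(groups: GroupAssignment, path, delimiter="\t") -> None:
    pd.DataFrame(
        {"sample_id": list(groups.sample_ids), "group": list(groups.labels)}
    ).to_csv(path, sep=delimiter, index=False)


def align_paired_study(benchmark: CountMatrix, test: CountMatrix,
                       groups: GroupAssignment) -> PairedStudy:
    """Restrict both matrices to their shared markers/samples and align order.

    Ordering after alignment is lexicographic by ID for determinism.  Markers
    with zero counts across all samples of BOTH matrices are dropped with a
    logged warning: they are undefined under log transforms and carry no
    information.  Dropped IDs are recorded on the returned study.
    """
    shared_markers = sorted(set(benchmark.marker_ids) & set(test.marker_ids))
    shared_samples = sorted(
        set(benchmark.sample_ids) & set(test.sample_ids) & set(groups.sample_ids)
    )
    if not shared_markers or not shared_samples:
        raise AlignmentError("empty marker or sample intersection")
    dropped_m = sorted(
        (set(benchmark.marker_ids) | set(test.marker_ids)) - set(shared_markers)
    )
    dropped_s = sorted(
        (set(benchmark.sample_ids) | set(test.sample_ids)) - set(shared_samples)
    )

    bench = benchmark.subset(markers=shared_markers, samples=shared_samples)
    tst = test.subset(markers=shared_markers, samples=shared_samples)

    both_zero = (bench.counts.sum(axis=1) == 0) & (tst.counts.sum(axis=1) == 0)
    if np.any(both_zero):
        zero_ids = [shared_markers[i] for i in np.where(both_zero)[0]]
        logger.warning(
            "dropping %d marker(s) with zero counts in all samples of both "
            "matrices: %s", len(zero_ids), zero_ids[:10],
        )
        keep = [m for m in shared_markers if m not in set(zero_ids)]
        if not keep:
            raise AlignmentError("no markers left after dropping all-zero rows")
        bench = bench.subset(markers=keep)
        tst = tst.subset(markers=keep)
        dropped_m = sorted(set(dropped_m) | set(zero_ids))

    sub_groups = groups.subset(shared_samples)  # raises if a level drops below 2
    if dropped_m or dropped_s:
        logger.info(
            "alignment dropped %d marker(s) and %d sample(s)",
            len(dropped_m), len(dropped_s),
        )
    return PairedStudy(bench, tst, sub_groups,
                       dropped_markers=tuple(dropped_m),
                       dropped_samples=tuple(dropped_s))


def write_results(results: pd.DataFrame, path, delimiter="\t") -> None:
    """Write a result table as delimited text with a header row.

    Floats are written at full precision (17 significant digits) so a read
    round-trip stays within 1e-12 relative drift; NaN rates are written as NA.
    """
    out_dir = os.path.dirname(os.path.abspath(path))
    os.makedirs(out_dir, exist_ok=True)
    results.to_csv(path, sep=delimiter, index=False, na_rep="NA",
                   float_format="%.17g")


def read_results(path, delimiter="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, na_values=["NA"])


def write_run_metadata(path, **metadata) -> None:
    """JSON sidecar with run metadata (methods, alpha, seed, versions...)."""
    out_dir = os.path.dirname(os.path.abspath(path))
    os.makedirs(out_dir, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
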